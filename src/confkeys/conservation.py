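"""Per-position evolutionary conservation from an MSA, Henikoff-weighted.

Sequences are weighted by the Henikoff & Henikoff position-based scheme
(each sequence collects 1/(r·s) per column, r = distinct residue types in
the column, s = multiplicity of its own type), weighted amino-acid
frequencies give a normalized Shannon-entropy conservation index per
column, and the structure-mapped indices are standardized into
Zscore_evol (higher = more conserved).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = set(AA_ALPHABET)
GAP_CHARS = set("-.")

MIN_COVERAGE = 0.8
MIN_HOMOLOGS = 100
HIGH_GAP_FRACTION = 0.5  # columns above this are flagged low-confidence


class ConservationError(ValueError):
    pass


@dataclass
class AlignmentSet:
    """Aligned rows over {20 aa, gap}; row 0 conventions are free, the
    reference row is named explicitly."""

    ids: list[str]
    rows: np.ndarray  # (n_seq, n_col) of single characters
    reference: int = 0

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows)
        if self.rows.ndim != 2:
            raise ConservationError("rows must be a 2-D character array")

    @property
    def n_seq(self) -> int:
        return self.rows.shape[0]

    @property
    def n_col(self) -> int:
        return self.rows.shape[1]

    def reference_columns(self) -> np.ndarray:
        """Column indices where the reference row is ungapped, in order;
        these map one-to-one onto structure residues."""
        ref = self.rows[self.reference]
        return np.where(~np.isin(ref, list(GAP_CHARS)))[0]

    def coverage(self) -> np.ndarray:
        """Per-sequence non-gap fraction over reference columns."""
        cols = self.reference_columns()
        sub = self.rows[:, cols]
        return (~np.isin(sub, list(GAP_CHARS))).mean(axis=1)


@dataclass
class ConservationProfile:
    weights: np.ndarray  # Henikoff sequence weights, sum 1
    index: np.ndarray  # per reference-mapped position, ∈ [0, 1]
    zscore: np.ndarray  # Zscore_evol per structure residue
    low_confidence: np.ndarray  # bool flags (gap fraction > 50 %)
    warnings: list[str] = field(default_factory=list)


def read_alignment(path: str, fmt: str | None = None,
                   reference_id: str | None = None) -> AlignmentSet:
    """Read an aligned FASTA or Stockholm file.

    The reference (structure) sequence is the named row, else the first.
    """
    from Bio import AlignIO

    if fmt is None:
        with open(path) as fh:
            first = fh.readline()
        fmt = "stockholm" if first.startswith("# STOCKHOLM") else "fasta"
    aln = AlignIO.read(path, fmt)
    ids = [rec.id for rec in aln]
    rows = np.array([list(str(rec.seq).upper()) for rec in aln])
    ref = 0
    if reference_id is not None:
        if reference_id not in ids:
            raise ConservationError(f"reference {reference_id!r} not in alignment")
        ref = ids.index(reference_id)
    return AlignmentSet(ids=ids, rows=rows, reference=ref)


def filter_alignment(
    aln: AlignmentSet,
    min_coverage: float = MIN_COVERAGE,
    min_homologs: int = MIN_HOMOLOGS,
) -> tuple[AlignmentSet, list[str]]:
    """Drop rows with coverage below threshold; warn (never fail) when the
    survivors are ≤ ``min_homologs``. The reference row is always kept."""
    cov = aln.coverage()
    keep = (cov >= min_coverage) | (np.arange(aln.n_seq) == aln.reference)
    if not keep.any():
        raise ConservationError("empty alignment after coverage filtering")
    new_ref = int(np.cumsum(keep)[aln.reference] - 1)
    out = AlignmentSet(
        ids=[i for i, k in zip(aln.ids, keep) if k],
        rows=aln.rows[keep],
        reference=new_ref,
    )
    warns = []
    if out.n_seq - 1 <= min_homologs:
        msg = (f"only {out.n_seq - 1} homologs survive filtering "
               f"(≤ {min_homologs})")
        warns.append(msg)
        logger.warning(msg)
    return out, warns


def henikoff_weights(aln: AlignmentSet) -> np.ndarray:
    """Position-based sequence weights, normalized to sum 1.

    Per column each sequence scores 1/(r·s), r = number of distinct residue
    types present, s = count of the sequence's own type; gaps contribute 0.
    """
    if aln.n_seq < 2:
        raise ConservationError("need ≥ 2 sequences for weighting")
    w = np.zeros(aln.n_seq)
    for col in aln.rows.T:
        isaa = np.isin(col, list(_AA_SET))
        if not isaa.any():
            continue
        types, inverse, counts = np.unique(
            col[isaa], return_inverse=True, return_counts=True)
        r = len(types)
        contrib = 1.0 / (r * counts[inverse])
        w[isaa] += contrib
    total = w.sum()
    if total == 0:
        raise ConservationError("alignment has no amino-acid content")
    return w / total


def conservation_index(
    aln: AlignmentSet, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-column conservation index ∈ [0, 1] and low-confidence flags.

    p_a = Henikoff-weighted frequency of amino acid a (gaps excluded,
    renormalized); index = 1 − H/ln 20 with H the Shannon entropy of p, so
    invariant columns score 1 and uniform 20-residue columns score 0.
    Entirely-gapped columns get NaN and a flag.
    """
    n_col = aln.n_col
    index = np.full(n_col, np.nan)
    lowconf = np.zeros(n_col, dtype=bool)
    for c in range(n_col):
        col = aln.rows[:, c]
        isaa = np.isin(col, list(_AA_SET))
        gap_frac = 1.0 - isaa.mean()
        if gap_frac > HIGH_GAP_FRACTION:
            lowconf[c] = True
        if not isaa.any():
            continue
        wcol = weights[isaa]
        p = {}
        for aa, wt in zip(col[isaa], wcol):
            p[aa] = p.get(aa, 0.0) + wt
        probs = np.array(list(p.values()))
        probs = probs / probs.sum()
        H = float(-(probs * np.log(probs)).sum())
        index[c] = 1.0 - H / np.log(20.0)
    return index, lowconf


def zscore_evolution(
    index: np.ndarray, mapped_columns: np.ndarray
) -> np.ndarray:
    """Standardize the conservation index over structure-mapped columns.

    Zscore_evol_i has mean 0 / sd 1; higher values = more conserved.
    """
    vals = np.asarray(index, dtype=float)[mapped_columns]
    if len(vals) < 2:
        raise ConservationError("fewer than 2 mapped columns")
    if np.any(~np.isfinite(vals)):
        raise ConservationError("undefined conservation index at mapped column")
    sd = vals.std()
    if sd == 0:
        raise ConservationError("constant conservation index (sd = 0)")
    return (vals - vals.mean()) / sd


def conservation_profile(aln: AlignmentSet) -> ConservationProfile:
    """Full pipeline: weights → per-column index → structure-mapped Z-score."""
    w = henikoff_weights(aln)
    index, lowconf = conservation_index(aln, w)
    cols = aln.reference_columns()
    z = zscore_evolution(index, cols)
    return ConservationProfile(
        weights=w, index=index[cols], zscore=z, low_confidence=lowconf[cols]
    )


def correlate_scores(
    zscore_s: np.ndarray, zscore_evol: np.ndarray
) -> tuple[float, float]:
    """Spearman ρ (with two-sided p) between the 7 Å-averaged perturbation
    and conservation profiles. A negative ρ means dynamically critical
    positions are evolutionarily conserved."""
    a = np.asarray(zscore_s, float)
    b = np.asarray(zscore_evol, float)
    if len(a) != len(b) or len(a) < 3:
        raise ConservationError("profiles must have equal length ≥ 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ConservationError("constant input profile")
    res = spearmanr(a, b)
    return float(res.statistic), float(res.pvalue)


def write_conservation_table(
    profile: ConservationProfile, res_numbers: np.ndarray, path: str
) -> None:
    import pandas as pd

    pd.DataFrame({
        "position": np.arange(1, len(profile.zscore) + 1),
        "resnum": res_numbers,
        "index": profile.index,
        "zscore_evol": profile.zscore,
        "low_confidence": profile.low_confidence.astype(int),
    }).to_csv(path, sep="\t", index=False, float_format="%.6g")
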