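"""End-to-end orchestration: structures → ENM → subspace → scan → reports.

The stages mirror the analysis of a ligand-free/ligand-bound conformer
pair: cutoff calibration against experimental B-factors, normal modes of
both conformers, the weighted conformational-change vector and its mode
subspace S, the residue-wise perturbation scan with key-position selection,
and (optionally) conservation scoring from an MSA plus the structural
characterization. Every stage failure is re-raised with the stage name.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


from . import conservation as cons
from . import enm_core, modespace, perturb_scan, structio

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Run parameters; defaults follow the published analysis protocol."""

    free_pdb: str = ""
    bound_pdb: str = ""
    chain_free: str | None = None
    chain_bound: str | None = None
    msa: str | None = None
    dssp_free: str | None = None
    sites: str | None = None  # TSV (chain, resnum)
    out_dir: str = "confkeys_out"

    r_c_min: float = 7.0
    r_c_max: float = 20.0
    r_c_step: float = 0.5
    r_c: float | None = None  # fixed cutoff skips calibration
    w: float = 0.01
    delta: float = 0.05
    key_fraction: float = 0.05
    neighbor_radius: float = 7.0
    null_mode_rtol: float = 1e-8
    use_experimental_b: bool = False  # Eq-12 weighting source
    rank_on_averaged: bool = False
    seed: int = 0

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    pair: structio.ConformerPair
    r_c: float
    calibration_spearman: float | None
    modes_free: enm_core.ModeSet
    expansion: modespace.ModeExpansion
    subspace: modespace.ModeSubspace
    scores: perturb_scan.ScoreProfile
    keys: perturb_scan.KeyPositionSet
    conservation: cons.ConservationProfile | None = None
    conservation_rho: tuple[float, float] | None = None
    qc: structio.QCReport | None = None
    warnings: list[str] = field(default_factory=list)


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return wrapper
    return deco


def read_sites(path: str, structure: structio.CaStructure) -> list[list[int]]:
    """Active-site TSV (chain <tab> resnum [<tab> site-id]) → index sets."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = ["chain", "resnum", "site"][: df.shape[1]]
    if "site" not in df.columns:
        df["site"] = 0
    lookup = {(c, int(r)): i for i, (c, r) in
              enumerate(zip(structure.chain_ids, structure.res_numbers))}
    sites = []
    for _, grp in df.groupby("site"):
        idx = [lookup[(str(c), int(r))] for c, r in zip(grp.chain, grp.resnum)
               if (str(c), int(r)) in lookup]
        if idx:
            sites.append(idx)
    return sites


def analyze_pair(
    free: structio.CaStructure,
    bound: structio.CaStructure,
    config: RunConfig | None = None,
    free_full_atom: str | None = None,
    bound_full_atom: str | None = None,
    msa: cons.AlignmentSet | None = None,
) -> PipelineResult:
    """Run the core analysis on in-memory structures (the library entry
    point; the CLI wraps file reading around it)."""
    cfg = config or RunConfig()
    warnings_log: list[str] = []

    pair = _stage("superpose")(structio.pair_and_superpose)(free, bound)

    # --- cutoff calibration on the ligand-free conformer
    calib_s: float | None = None
    if cfg.r_c is not None:
        r_c = cfg.r_c
    else:
        grid = np.arange(cfg.r_c_min, cfg.r_c_max + 1e-9, cfg.r_c_step)
        r_c, calib_s, _ = _stage("calibrate")(enm_core.calibrate_cutoff)(
            free, free.bfactors, full_atom_path=free_full_atom, grid=grid)

    build = _stage("enm")(enm_core.build_enm)
    model_free, modes_free = build(free, r_c=r_c, full_atom_path=free_full_atom)

    # --- conformational-change vector on the ligand-free mode basis
    # (the bound-side ENM exists only to supply Eq-style B weights, so it
    # is not built when w = 0 or experimental B-factors are requested)
    if cfg.use_experimental_b:
        b_free, b_bound = free.bfactors, bound.bfactors
    elif cfg.w == 0.0:
        b_free = np.zeros(len(free))
        b_bound = np.zeros(len(bound))
    else:
        _, modes_bound = build(pair.bound, r_c=r_c,
                               full_atom_path=bound_full_atom)
        b_free = enm_core.theoretical_bfactors(modes_free).values
        b_bound = enm_core.theoretical_bfactors(modes_bound).values
    wd = _stage("modespace")(modespace.weighted_difference)(
        pair, b_free, b_bound, w=cfg.w)
    expansion = modespace.expand_on_modes(wd, modes_free)
    S = modespace.select_subspace(expansion, modes_free, label="S")

    # --- perturbation scan
    scores = _stage("scan")(perturb_scan.scan_all_residues)(
        model_free, modes_free, S, delta=cfg.delta,
        neighbor_radius=cfg.neighbor_radius)
    keys = perturb_scan.select_key_positions(
        scores, fraction=cfg.key_fraction, use_averaged=cfg.rank_on_averaged)

    # --- conservation (optional)
    conservation = None
    rho = None
    if msa is not None:
        filtered, warns = _stage("conservation")(cons.filter_alignment)(msa)
        warnings_log.extend(warns)
        conservation = cons.conservation_profile(filtered)
        if len(conservation.zscore) == len(free):
            evo_avg = perturb_scan.neighbor_average(
                conservation.zscore, free, radius=cfg.neighbor_radius)
            rho = cons.correlate_scores(scores.zscore_averaged, evo_avg)
        else:
            warnings_log.append(
                "conservation profile length differs from structure; "
                "correlation skipped")

    return PipelineResult(
        pair=pair, r_c=r_c, calibration_spearman=calib_s,
        modes_free=modes_free, expansion=expansion, subspace=S,
        scores=scores, keys=keys, conservation=conservation,
        conservation_rho=rho, warnings=warnings_log,
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """File-driven pipeline: read inputs, analyze, write the report bundle."""
    free = _stage("read")(structio.read_ca_structure)(
        config.free_pdb, chain=config.chain_free)
    bound = _stage("read")(structio.read_ca_structure)(
        config.bound_pdb, chain=config.chain_bound)
    msa = None
    if config.msa:
        msa = _stage("read")(cons.read_alignment)(config.msa)
    elif config.msa is not None:
        logger.warning("MSA missing: conservation stage skipped")

    result = analyze_pair(
        free, bound, config,
        free_full_atom=config.free_pdb, bound_full_atom=config.bound_pdb,
        msa=msa,
    )
    write_reports(result, config)
    return result


def write_reports(result: PipelineResult, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    structio.write_pair_report(result.pair, str(out / "pair_report.tsv"))
    modespace.write_subspace_report(
        result.expansion, result.modes_free, str(out / "subspace.tsv"))
    perturb_scan.write_score_table(
        result.scores, result.pair.free, result.keys, str(out / "scores.tsv"))
    if result.conservation is not None:
        cons.write_conservation_table(
            result.conservation,
            result.pair.free.res_numbers,
            str(out / "conservation.tsv"))
    summary = summarize(result, config)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    config.to_yaml(str(out / "config.yaml"))


def summarize(result: PipelineResult, config: RunConfig) -> dict:
    n = len(result.pair.free)
    summary = {
        "n_residues": n,
        "rmsd": result.pair.rmsd,
        "r_c": result.r_c,
        "calibration_spearman": result.calibration_spearman,
        "participation_number": result.expansion.participation,
        "subspace_size": result.expansion.subspace_size,
        "subspace_fraction": result.expansion.participation / (3 * n - 6),
        "discarded_null_fraction": result.expansion.discarded_fraction,
        "n_key_positions": result.keys.count,
        "key_resnums": [int(result.pair.free.res_numbers[i])
                        for i in result.keys.indices],
        "parameters": {
            "w": config.w, "delta": config.delta,
            "key_fraction": config.key_fraction,
            "neighbor_radius": config.neighbor_radius,
        },
        "warnings": result.warnings,
    }
    if result.conservation_rho is not None:
        summary["conservation_spearman_rho"] = result.conservation_rho[0]
        summary["conservation_spearman_p"] = result.conservation_rho[1]
    return summary


# ---------------------------------------------------------------------------
# synthetic self-test


def run_synth(config: RunConfig | None = None, seed: int | None = None,
              n_residues: int = 60, out_dir: str | None = None) -> dict:
    """Generate a seeded two-domain fixture, run the pipeline on it, and
    report ground-truth recovery metrics."""
    from . import synthdata

    cfg = config or RunConfig()
    if seed is not None:
        cfg.seed = seed
    spec = synthdata.FixtureSpec(seed=cfg.seed, n_residues=n_residues,
                                 planted_modes=[(0, 6.0)])
    free, truth = synthdata.make_structure(spec)
    _, modes0 = enm_core.build_enm(free, r_c=10.0)
    bound = synthdata.make_bound(free, modes0, spec.planted_modes,
                                 seed=cfg.seed)
    free.bfactors = synthdata.make_bfactors(modes0, noise_sd=0.0,
                                            seed=cfg.seed)
    bound.bfactors = free.bfactors.copy()

    cfg2 = dataclasses.replace(cfg, r_c=10.0, w=0.0)
    result = analyze_pair(free, bound, cfg2)

    planted = sorted(pos for pos, _ in spec.planted_modes)
    recovered = sorted(int(i) for i in result.subspace.mode_indices)
    region = set(truth.region_indices.tolist())
    keys_in_region = sum(1 for i in result.keys.indices if int(i) in region)
    region_fraction = len(region) / len(free)
    key_fraction_in_region = keys_in_region / max(result.keys.count, 1)
    enrichment = (key_fraction_in_region / region_fraction
                  if region_fraction > 0 else float("nan"))
    report = {
        "seed": cfg.seed,
        "n_residues": len(free),
        "planted_modes": planted,
        "recovered_modes": recovered,
        "planted_mode_recovered": recovered == planted,
        "participation_number": result.expansion.participation,
        "hinge_region_size": len(region),
        "keys_in_region": keys_in_region,
        "hinge_enrichment": enrichment,
        "n_key_positions": result.keys.count,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        synthdata.write_structure_pdb(free, str(out / "free.pdb"),
                                      full_atom=True)
        synthdata.write_structure_pdb(bound, str(out / "bound.pdb"),
                                      full_atom=True)
        with open(out / "synth_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
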