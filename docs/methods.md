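# Methods

This note documents the models and numerical choices behind `confkeys`:
what is computed, under which assumptions, and what the synthetic fixtures
do and do not establish.

## Elastic network model

The protein is a set of N Cα beads with harmonic pair energies
E(r_i, r_j) = ½ k_ij (|r_ij| − |r⁰_ij|)², the crystal structure taken as
the minimum. Force constants encode contact chemistry:

| contact class | rule | k_ij |
|---|---|---|
| covalent neighbour | \|i−j\| = 1 | γ |
| disulfide | CYS SG–SG ≤ 2.5 Å | γ |
| hydrogen bond / salt bridge | N/O pair ≤ 3.5 Å; opposite-charge side-chain N/O ≤ 4.0 Å | 0.1 γ |
| generic | Cα distance ≤ r_c | 0.01 γ |

γ = 1 throughout: the absolute energy scale cancels because only rank
correlations (B-factor calibration) and normalized vectors (subspaces)
are consumed. Masses are uniform and unweighted, the standard choice for
Cα networks. The hydrogen-bond/salt-bridge rule is a deliberately simple
geometric surrogate for a full interaction-typing program; it errs toward
over-detection at the stated thresholds, which only promotes a pair from
k = 0.01 γ to 0.1 γ. Disulfides are not gated by r_c; hydrogen bonds and
generic contacts are.

The Hessian is assembled from 3×3 blocks k_ij·(r̂_ij r̂_ij^T) with the
usual anisotropic-network sign structure, so each row-block sums to zero
(translation invariance holds to 1e-10 in the tests). Eigenvalues below
1e-8 × λ_max (relative threshold, configurable) count as null modes; a
connected non-collinear network has exactly six, and more than six raises
an error naming the connected components rather than silently proceeding
with a floppy network.

Theoretical B-factors are B_i = (8π²/3)·3 k_BT·Σ_k λ_k⁻¹ (q_k q_k^T)_ii
over the 3N−6 internal modes (k_BT = 1, arbitrary units). This equals the
diagonal of the Hessian pseudo-inverse times the prefactor; both routes
are computed in the test suite and must agree to 1e-6 relative.

**Cutoff calibration.** r_c is scanned over [7, 20] Å in 0.5 Å steps
(27 evaluations) and the value maximizing Spearman(theoretical B,
experimental B) is kept, ties toward smaller r_c (a sparser, more
parsimonious network). Grid points where the network is disconnected are
skipped. 0.5 Å resolves the correlation curve at desk cost; nothing
downstream is sensitive to finer steps.

## Binding subspace

The conformers are superposed by least-squares (Kabsch/SVD) over residues
mapped by (chain, residue number, insertion code); a mapped amino-acid
mismatch is an error because a conformer pair is the same protein. The
displacement vector is weighted per residue by exp(−(B_i^lf + B_i^lb)·w)
and unit-normalized. The weighting suppresses flexible loops and termini
whose displacement reflects disorder, not binding; w defaults to 0.01,
the value appropriate for experimental B-factors in Å². By default the
weights use theoretical B-factors from each conformer's own network (a
config switch selects experimental ones); with theoretical B in arbitrary
units, w must be rescaled accordingly, and the synthetic self-tests use
w = 0, which disables the weighting entirely.

Expansion coefficients c_k = v·q_k are computed over internal modes only.
After superposition a residual rigid-body component of v remains at
numerical level; the coefficients are renormalized to unit length within
the internal-mode span and the discarded fraction is reported. This keeps
the participation number P = (Σ c_k⁴)⁻¹ in [1, 3N−6] as its
interpretation requires. The subspace S holds the M = ceil(P) modes of
largest c_k² (ceil is fixed by the published worked examples: a
125-residue protein yields 7 key positions and a 183-residue one yields
10 under the 5 % rule, which forces ceil at P = 6.25 and 9.15). Ties in
c_k² break toward the lower mode index. The flexibility subspace S_B is
built identically from the per-residue B-factor replicated over each
residue's three coordinates and unit-normalized; without that
normalization P_B would depend on the arbitrary B scale.

Collectivity κ = (1/N)·exp(−Σ_i r_i² ln r_i²), with r_i² the residue's
summed squared mode components, is 1 for a uniformly distributed mode and
1/N for a single-residue mode (0·ln 0 := 0). This is the standard
convention and what the formula yields; prose that swaps the two extremes
is a known source of confusion and is not followed.

## Perturbation scan

A mutation at residue i multiplies every spring incident to i by
(1 + δγ), |δγ| ≤ 0.5, default 0.05, both signs. The multiplicative form
is chosen over an additive one deliberately: subtracting 0.05 γ from a
generic spring (k = 0.01 γ) would make it negative and destroy positive
semi-definiteness, while scaling preserves the spring-class ratios. The
perturbed network is re-diagonalized exactly (no first-order
approximation), so δγ need not be infinitesimal.

Perturbed modes are matched one-to-one to unperturbed modes by maximizing
Σ O_kk'² with O = Q^T Q^i, solved as a linear assignment problem
(Jonker–Volgenant via `scipy.optimize.linear_sum_assignment`) over all
internal modes, so the permutation is globally consistent; only the
images of S are consumed. Degenerate eigenvalues need no special casing —
the squared-overlap objective handles arbitrary mixing.

The similarity of S and its image S^i is the mean eigenvalue of the
Gramian of the perturbed modes projected onto span(S). Algebraically
ζ = trace(A^T A)/M with A = Q_S^T Q_{S^i}, i.e. (1/M)·Σ(q^i_j·q_k)²;
the eigenvalue route and this trace identity are computed independently
in the tests and agree to 1e-10. Eigenvalues are clipped to [0, 1] at a
1e-9 tolerance; anything further outside raises.

ζ̄_i = (ζ at +δγ + ζ at −δγ)/2 is standardized over residues to ZscoreS_i
(mean 0, sd 1 exactly, by construction). Key positions are the
ceil(0.05·N) residues of lowest ZscoreS, boundary ties toward the lower
residue index. Ranking uses the un-averaged ZscoreS; the 7 Å
neighbour-averaged profile (mean over residues with Cα within 7 Å,
self included) is used for the conservation correlation, where the
analysis targets spatial regions rather than single residues. Both
choices are switchable.

## Conservation

Sequences with coverage < 80 % over the reference columns are dropped
(the reference row is always kept); fewer than ~100 surviving homologs
triggers a warning, not a failure. Henikoff position-based weights give
each sequence 1/(r·s) per column (r = distinct residue types, s = its own
type's multiplicity), summed and normalized. Note that duplicating a
sequence lowers each copy's weight but can still raise the pair's
combined share — the scheme is sub-additive, not share-preserving, and
the property tests assert exactly that.

Per column, weighted amino-acid frequencies (gaps excluded, renormalized)
give the conservation index 1 − H/ln 20 ∈ [0, 1]; the entropy base
cancels in the normalization. Columns with more than 50 % gaps are
flagged low-confidence; entirely gapped columns are undefined (NaN).
Structure-mapped indices are standardized into Zscore_evol (higher = more
conserved). The headline statistic is the Spearman correlation between
the 7 Å-averaged ZscoreS and Zscore_evol profiles with its two-sided
p-value; the method predicts it negative.

## Synthetic fixtures

The generator exists to make every stage testable with known ground
truth; its defaults are fixed once and shared by tests and the acceptance
script.

**Geometry.** The two-domain topology grows two compact self-avoiding
random walks (3.8 Å steps, ≥ 3.4 Å non-bonded separation, sphere
confinement at globular density) joined by a kinked 3-residue bridge,
with a small direct contact patch between the domains and 0.15 Å
coordinate jitter. Two hard-won constraints are built in: the bridge must
be non-collinear and the domains must share at least a minimal contact
patch, because a straight tether leaves an exact zero-energy torsion of
one domain about the line through the bridge beads (rotations preserve
distances to collinear anchors). Each fixture is verified to have exactly
six zero modes before being returned, with deterministic rejection
resampling from the seeded stream otherwise. Default size is 60 residues,
small enough that a full ±δγ scan diagonalizes 120 networks of 180×180 in
about a second. The ground-truth "hinge/contact region" is the bridge
plus every residue carrying an inter-domain contact — the springs that
store the strain of the hinge-bending modes.

**Conformers and B-factors.** Bound fixtures displace the free structure
along chosen internal modes and then apply a random rigid transform so
the superposition code is genuinely exercised; an optional check rejects
amplitudes that change the contact topology. Experimental-style B-factors
are the theoretical profile rescaled to a crystallographic mean of 30 Å²
plus seeded Gaussian noise, floored at 0.01.

**Coupled MSAs.** Each column substitutes with probability
logistic(logit(0.3) + coupling·score_i + η_i), η_i ~ N(0, 0.5), rows
independent, reference preserved, 150 homolog rows (comfortably above the
100-homolog QC threshold). With coupling 1 the planted ZscoreS profile is
anti-correlated with the resulting conservation, emulating the
purifying-selection signal; the per-column noise η is irreducible (no
number of rows averages it out) and sets the attainable correlation
magnitude, which at these defaults comes out around ρ ≈ −0.6 on 60-residue
fixtures.

**What the fixtures do not show.** Random-walk beads have no secondary
structure, no side-chain packing, no correlated substitution process, and
the planted displacement is exactly one or two modes — real
conformational changes are messier. Passing the synthetic recovery tests
shows the machinery is self-consistent and recovers planted truth; it
does not validate biological conclusions on real proteins, for which the
dataset-scale statistics in the literature are the reference.

**Statistical power of the coupled-MSA check.** With 60-residue fixtures
a two-sided p < 0.01 needs |ρ| ≳ 0.33. The per-seed success probability
of (ρ < 0, p < 0.01) measured over 80 seeds is ≈ 0.93, so a 20-seed block
occasionally dips below 18/20 — the self-test suite reports this check at
exactly those conditions rather than enlarging fixtures or reducing noise
to mask it.

## Numerical details and edge cases

- Null-mode threshold: relative 1e-8 (configurable). Disconnected
  networks error with component sizes.
- Coincident Cα on a spring: error (zero equilibrium distance).
- Identical conformers: the displacement vector is undefined → error
  "no conformational change".
- A degenerate ζ profile (sd = 0 across residues, e.g. on a perfectly
  symmetric toy) cannot be standardized → error.
- Altloc records keep the highest occupancy, ties toward the
  first-listed ('A'). Missing experimental B-factors are an error when
  calibration or experimental weighting is requested.
- Inertial axes of SSE segments come from the Cα gyration tensor
  (descending variance), sign-disambiguated so inter-axis angles lie in
  [0°, 90°]; Δθ is the largest change among the three axis pairs.
  Segments under 3 residues or collinear segments are errors.
- RSA uses the Tien et al. (2013) theoretical ALA-X-ALA maxima embedded
  as constants; residues ≥ 10 % are exposed. Inter-residue contacts are
  heavy-atom pairs ≤ 5 Å with |i−j| ≥ 2.
- The inter-SSE incidence denominator counts, among non-key residues on
  SSE X, those with at least one contact to SSE Y (like-for-like
  frequency ratio); cells with an empty denominator are reported as
  undefined, never as numbers.

## Limitations

- Cα-only harmonic model: no side-chain dynamics, no anharmonicity, no
  ligand atoms; mutations are spring-scale changes, not chemical changes.
- The CSU/RING/NACCESS-style annotations are approximated by documented
  geometric rules, not reimplementations of those programs; DSSP output
  is consumed, not computed.
- Scaling is O(N³) per diagonalization and 2N diagonalizations per scan;
  practical to a few hundred residues on one core, beyond which sparse or
  perturbative variants (out of scope here) become attractive.
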