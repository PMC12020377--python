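# Methods

This note records the models, conventions and numerical choices behind the
package, what the synthetic generators do and do not emulate, and the known
limitations.

## Geometric features and state classification

A frame is reduced to eight features measured on heavy atoms only (the
criteria are donor–acceptor distances, so the pipeline is independent of
protonation):

| feature | definition | unit |
|---|---|---|
| d_N1_O2 | G9(N1)–U6(O2) | Å |
| d_N2_O2 | G9(N2)–U6(O2) | Å |
| d_O2p6_O6 | U6(O2′)–G9(O6) | Å |
| d_O2p7_N7 | U7(O2′)–G9(N7) | Å |
| d_N4_proRP | C8(N4)–U6(pro-R_P) | Å |
| chi_G9 | O4′-C1′-N9-C4 torsion of G9 | degrees |
| rmsd_loop | superposed heavy-atom RMSD of U6,U7,C8,G9 vs reference | Å |
| rmsd_all | superposed heavy-atom RMSD of all 14 residues vs reference | Å |

The reference is the user-supplied starting/native structure.  Superposition
uses the Kabsch SVD solution with reflection guard
(`scipy.spatial.transform.Rotation.align_vectors`).

Torsions follow the convention shared by the major trajectory packages:
positive = right-handed rotation about the b→c axis, cis = 0°, reported on
(−180°, 180°].  Torsions are invariant under atom-order reversal.

The classifier applies the eleven state rules with strict inequalities at
the published thresholds (3.5 / 3.7 / 4.0 / 4.2 / 5.0 / 5.2 Å distances,
3.0 / 4.6 Å RMSD cuts, syn window ⟨−25°, 115°⟩).  Precedence:
stem+loop-disrupted (rmsd_all > 4.6 Å) overrides everything; then rules run
from least to most disrupted (native, sugar-base N7 lost, 7BPh lost, both
sugar-base lost, C8 bulge, G9 bulge syn, G9 bulge anti, G9 back in pocket,
U6+U7+C8 bulge, loop disrupted).  A frame matching the U6+U7+C8-bulge
criteria is never relabelled loop-disrupted.  Frames matching no rule get an
explicit `unclassified` label rather than nearest-state imputation, so
populations stay auditable.

Angular windows are closed at their printed endpoints.  The syn window and
the anti/high-anti union therefore share the two boundary points −25° and
115°; because syn rules precede anti rules, the classification remains a
deterministic partition (the shared points are measure-zero).

## εRMSD

Each base is reduced to a local frame: origin at the centroid of the
six-membered ring (atom names N1,C2,N3,C4,C5,C6 for both purines and
pyrimidines), z = best-fit ring normal (SVD) with its sign fixed by
(C2−o)×(C4−o), x = the in-plane projection of C2−o.  For an ordered pair
(i, j), the vector from origin i to origin j in frame i is scaled
anisotropically, r̃ = (x/a, y/a, z/b) with a = 5 Å and b = 3 Å, and mapped
through

G(r̃) = ( sin(γρ)·x̃/ρ, sin(γρ)·ỹ/ρ, sin(γρ)·z̃/ρ, 1 + cos(γρ) ),
ρ = |r̃|, γ = π/2.4,

with G = 0 for ρ ≥ 2.4.  εRMSD between two structures with identical
sequence is √(Σ_pairs |ΔG|² / N_res).  The folded/unfolded indicator is
εRMSD < 0.7 against the native reference.

The in-plane axis convention only affects the decomposition of G's x/y
components; because it is anchored to the same atoms in both structures, the
metric is insensitive to it for (near-)planar rings.  Other implementations
use a slightly different origin (centroid of C2,C4,C6); values agree closely
but not to machine precision, so the constants and convention here are fixed
and documented rather than borrowed.  Modified residues without the
tabulated ring atoms are rejected, not guessed.

## Two-state thermodynamics

ΔG°fold = −RT ln(p/(1−p)) with R = 0.0019872 kcal mol⁻¹ K⁻¹ and T = 298 K
by default.  p is the weighted folded fraction; per-frame weights accept
biased-ensemble reweighting factors (computing those factors is out of
scope).  p ∈ {0, 1} yields an explicit unbounded estimate rather than a
number.

Errors come from a block bootstrap: the concatenated series is cut into 16
contiguous equal blocks (remainder frames join the last block, preserving
within-block autocorrelation), blocks are resampled with replacement 1000
times, and the folded fraction is recomputed per resample.  The reported
interval is p̂ ± t(0.975, 15) × SD of the resampled fractions, clipped to
[0, 1]; dG_err is the half-width of the mapped ΔG interval.  The t-quantile
form was chosen over raw 2.5/97.5 percentiles after calibration on the
package's own two-state ensembles (200 seeds, n = 4000, p* ∈ {0.1, 0.5,
0.9}): percentile intervals covered the true fraction 92–94 % of the time —
a known small-sample artefact with only 16 blocks — while the t-form covers
92.5–95.5 %, closer to the nominal 95 %.  Everything is deterministic for a
given seed.

Reported table-style values use one-decimal rounding with ties away from
zero; full precision is retained internally.  Multi-run aggregation is the
arithmetic mean ± sample SD of per-run ΔG values.  Folding events are
counted as false→true transitions of the per-frame indicator in a continuous
replica.

## NMR observables and χ²

³J couplings: J(θ) = A cos²(θ+Δ) + B cos(θ+Δ) + C evaluated per frame on a
structural torsion and ensemble-averaged.  Coefficient sets are
configuration data, not hard-coded: the shipped defaults are standard
literature parameterisations (H-C-C-H 9.67/−2.03/0 Hz; H-C-O-P
15.3/−6.2/1.5 Hz; C-C-O-P 6.9/−3.4/0.7 Hz) and can be replaced per table.

NOEs are compared as effective distances r_eff = ⟨r⁻⁶⟩⁻¹ᐟ⁶ (weighted frame
average); ambiguous NOEs sum r⁻⁶ over their 2–4 contributing pairs per frame
before averaging.  Comparison is in Å with σ in Å; intensity-domain
comparison is out of scope.

χ² per class is the mean of squared σ-normalised residuals; the total is
Σ w_c χ²_c / Σ w_c with w_c defaulting to the class counts (63 backbone ³J,
33 sugar ³J, 253 NOE, 27 ambNOE in the default synthetic tables), which
makes the default total the plain mean over all observables.  Weights are
overridable; the report echoes the definition and weights used.
Unresolvable observables are skipped with a warning and excluded from their
class count.

## Synthetic data

The scaffold is a deterministic, idealised 14-mer hairpin
(GGCACUUCGGUGCC): planar bases with correct ring topology and exocyclic
substituents, ribose rings with a C3′-endo-like pucker, a five-base-pair
A-form-like stem, and a loop whose four residues are posed by a
deterministic least-squares refinement (Levenberg–Marquardt over rigid pose
parameters, converged parameters frozen in code with a short polish at build
time).  The refinement drives the five native contacts to 2.9–3.2 Å, keeps
χ_G9 = 20° (syn), and applies a soft 2.4 Å clash floor for the loop
residues.  It is a classifier/metric fixture, **not** a model of the
experimental structure: base pairing in the stem is geometrically naive
(paired bases approach below van-der-Waals contact), there are no hydrogens,
ions or solvent, and no energetics.  A user-supplied native PDB can replace
it everywhere.

Per-state conformers are produced by constrained randomisation of the
scaffold — rigid residue translations along contact axes, rigid rotations
about pivot atoms, glycosidic rotation of G9, Gaussian coordinate jitter
(default SD 0.04 Å) — followed by verification through the classifier, with
rejection sampling bounded at 1000 retries (failure raises, never silent).
Target distances are sampled uniformly inside each state's admissible
region.

Two-state ensembles draw each frame Bernoulli(p*) from small pools of
distinct folded (jittered scaffold, εRMSD < 0.7 verified) and unfolded
(extended chain, εRMSD ≥ 0.7 verified) conformers; the folded indicator is
therefore iid, which is what the bootstrap calibration consumes.  Pool-based
frames mean the ensemble has no conformational diversity beyond the pool
size — adequate for testing the folded/unfolded machinery, not a model of
unfolded-state heterogeneity.

Markov timelines are sampled from a user-supplied row-stochastic matrix
started at its stationary distribution.  Synthetic NMR tables back-calculate
observables from a given ensemble (torsion quadruples drawn from backbone
and sugar atoms, NOE pairs drawn from atoms within 6 Å in the first frame)
and add Gaussian noise of SD σ_noise (default equal to the reported error
σ, so residuals are standard normal and χ² calibrates to 1; σ_noise = 0
gives a noiseless self-consistent table).

Because the generators exercise exactly the published criteria regions and
iid two-state statistics, passing tests demonstrate correctness of the
analysis machinery — not force-field realism, kinetics, or agreement with
experimental ensembles.

## Problem sizes used in the test suite

Classifier fidelity runs an exhaustive threshold-straddling grid (≈10⁵
combinations) plus 10⁵ random feature vectors against an independently coded
decision-table oracle, and round-trips all eleven states through the
generator at 25 seeds each.  Bootstrap calibration uses iid Bernoulli series
of n = 16 000 (SE against √(pq/n), 50 seeds) and two-state ensembles of
n = 4000 at p* ∈ {0.1, 0.5, 0.9} (interval coverage over 50 seeded
repetitions).  χ² calibration uses the default 376-observable table over 20
seeds.  These sizes keep the full suite around half a minute on one CPU.

## Known limitations

- The scaffold's stem geometry is schematic; only the loop region is refined
  against contact targets.  Analyses that depend on realistic stem geometry
  (e.g. helical parameters) are out of scope.
- The classifier implements the published criteria literally; the feature
  space region not covered by any rule is reported as `unclassified` rather
  than imputed.  The published criteria themselves admit known quirks (a
  U6-departed geometry can satisfy the G9-bulge-syn rule); no geometric
  patch is applied.
- Karplus coefficients and the χ² weighting are declared defaults, not
  fitted constants; published total-χ² values for real NMR data are not
  reproducible from synthetic ensembles and are not targeted.
- Kinetic modelling (rates, Markov-state models, dwell statistics beyond
  folding-event counts) is out of scope.
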