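# tetraloop

Trajectory analysis for RNA tetraloop simulations: geometric
conformational-state classification, εRMSD-based two-state folding
thermodynamics, and back-calculation of NMR observables with a weighted-χ²
agreement score.

The package targets the UUCG tetraloop — the hyperstable 5′-UUCG-3′ hairpin
loop that is a standard benchmark for RNA force fields.  Its native state is
held together by a *trans*-wobble G·U pair (requiring the loop guanosine in
the unusual *syn* glycosidic conformation), two sugar–base hydrogen bonds,
and a 7BPh base–phosphate contact.  Molecular-dynamics simulations of this
motif lose and regain these interactions in characteristic ways, and the
tools here quantify that behaviour frame by frame:

- **State classification** (`tetraloop.states`).  Each frame is reduced to
  eight features — five donor–acceptor heavy-atom distances, the glycosidic
  torsion χ of the loop guanosine (syn window ⟨−25°, 115°⟩), and two
  superposition RMSDs against the native reference — and assigned to exactly
  one of eleven published states (*native*, *sugar-base (N7) lost*, *7BPh
  lost*, …, *stem + loop disrupted*) or to an explicit `unclassified` label.
- **εRMSD and folding free energy** (`tetraloop.ermsd`, `tetraloop.thermo`).
  The base-centric εRMSD metric (ellipsoidally scaled inter-base vectors
  mapped through a smooth G-vector; a = 5 Å, b = 3 Å, cutoff 2.4) separates
  folded from un/misfolded conformers at the 0.7 threshold.  The folded
  population p maps to ΔG°fold = −RT ln(p/(1−p)) at T = 298 K, with
  statistical errors from a 16-block bootstrap over the concatenated
  trajectory (weights supported for biased-ensemble reweighting).
- **NMR back-calculation** (`tetraloop.nmr`).  ³J scalar couplings via
  Karplus relations J(θ) = A cos²θ + B cos θ + C, NOEs via r⁻⁶ ensemble
  averaging, ambiguous NOEs as sums over 2–4 pairs; agreement with an
  experimental table is scored per class (backbone ³J / sugar ³J / NOE /
  ambNOE) and combined into a total χ² as a weighted arithmetic mean.
- **Synthetic data** (`tetraloop.synthetic`).  Seeded generators for a
  deterministic idealised 14-mer hairpin scaffold, per-state conformers,
  Markov state timelines, two-state ensembles with prescribed folded
  fraction, and noisy NMR observable tables — so the whole pipeline runs and
  is tested without any MD engine or download.

## Worked example

```python
import numpy as np
from tetraloop.synthetic import build_reference_scaffold, generate_two_state_ensemble, GeneratorConfig
from tetraloop.states import classify_trajectory
from tetraloop.geometry import AtomMap
from tetraloop.ermsd import ermsd
from tetraloop.thermo import FoldSeries, block_bootstrap

reference = build_reference_scaffold()
frames, _ = generate_two_state_ensemble(p_star=0.6, n=2000, cfg=GeneratorConfig(seed=42))

timeline, populations = classify_trajectory(frames[:200], AtomMap(), reference)
print({lab.value: round(p, 3) for lab, p in populations.items()})

folded = np.array([ermsd(fr, reference) < 0.7 for fr in frames])
est = block_bootstrap(FoldSeries(folded), n_blocks=16, n_resamples=1000, seed=42)
print(f"p_native = {est.p_native:.3f}  dG = {est.dG:+.3f} +/- {est.dG_err:.3f} kcal/mol")
```

prints

```
{'stem_loop_disrupted': 0.47, 'native': 0.53}
p_native = 0.586  dG = -0.205 +/- 0.055 kcal/mol
```

The ensemble was generated with a 60 % folded fraction: folded frames
classify as *native* and extended frames as *stem + loop disrupted*, the
εRMSD indicator recovers p ≈ 0.59, and the two-state relation converts that
to ΔG°fold ≈ −0.21 kcal/mol with a bootstrap half-width of 0.06.

## Command line

`tetraloop` exposes the stages as subcommands that compose through files:

```bash
tetraloop simulate --out-dir demo --seed 1 --n-frames 200   # synthetic fixtures
tetraloop classify demo/two_state.pdb demo/reference.pdb    # states + populations
tetraloop ermsd    demo/two_state.pdb demo/reference.pdb    # per-frame εRMSD
tetraloop dgfold   folded.csv --temperature 298 --blocks 16 --seed 1
tetraloop chi2     demo/two_state.pdb demo/observables.tsv
tetraloop run      config.json                              # integrated pipeline
```

All reports are plain CSV/JSON and embed the exact thresholds used.

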