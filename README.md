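# sbsphase

Chromatin folding at the single-molecule level, modelled as polymer phase
separation.  A locus is a self-avoiding chain of beads carrying typed
binding sites ("colors"); diffusing binder molecules of matching types
bridge cognate sites (the Strings-and-Binders, SBS, picture).  Above a
threshold binder concentration the chain switches from an open **coil** to
a **globule phase-separated** state in which same-color regions self-
assemble into compact, partially segregated globules — the degeneracy of
that state produces the broad cell-to-cell variability of TAD-like contact
patterns seen in chromatin-tracing experiments.

The package is for computational genomics / biophysics groups who want the
full analysis chain behind that picture as tested, reusable code:

* **Inference** (`sbsphase.prismr`) — find the minimal bead coloring whose
  physics-predicted contact map explains an input contact matrix, by
  simulated annealing on the distance-scaled cost
  `H = H0 + lambda * (colored beads)`,
  `H0 = <(pred_ij - target_ij)^2 / dbar(|i-j|)>`, with train/test selection
  of the color number n\*, penalty λ\* and beads-per-window r\*.
* **Equilibrium simulation** (`sbsphase.core`) — Metropolis Monte Carlo of
  the SBS Hamiltonian (FENE bonds + WCA cores + 1.5 σ binder wells),
  concentration scans exposing the coil → globule transition through the
  order parameters Rg/Rg_SAW, binding energy and mean separation score.
* **Single-molecule analysis** (`sbsphase.metrics`, `sbsphase.matching`,
  `sbsphase.dynamics`) — distance matrices, the genomic-distance-corrected
  correlation r′, separation-score profiles and boundary calling with the
  published parameter presets, single-cell quality filters, Kabsch-RMSD
  ensemble matching with state classification, coil/globule mixture
  decomposition, steady-state time correlations with stretched-exponential
  summaries, and the reduced-to-physical unit map
  (τ = 6πησ³/kBT, c = P/(V·N_A), σ from matching Rg medians).
* **Synthetic studies** (`sbsphase.synth`) — ground-truth colorings with
  controlled domain overlap, Poisson-noised contact maps, imaging-like
  distance matrices with probe dropout: every stage is testable without
  external data.

## Worked example

Recover a planted 3-color binding-domain architecture from a noisy contact
map:

```python
import numpy as np
from sbsphase.prismr import (SAConfig, forward_contact_map, get_templates,
                             matched_bead_agreement, sa_optimize,
                             select_hyperparameters)
from sbsphase.synth import generate_coloring, synthesize_hic

truth = generate_coloring(n_windows=60, n=3, r=1, seed=5)
tpl = get_templates(60, 1)                      # simulator-calibrated decay
clean = forward_contact_map(truth.model, tpl)   # predicted contact map
noisy = synthesize_hic(clean, depth=1e4, seed=9)  # Poisson-count Hi-C stand-in

res = sa_optimize(noisy, SAConfig(n=3, lambda_=0.0, seed=0), templates=tpl)
print(f"bead agreement: {matched_bead_agreement(truth.model, res.coloring):.1%}")
print(f"train H0 {res.h0_train:.2e}   held-out H0 {res.h0_test:.2e}")

sel = select_hyperparameters(noisy, n_grid=range(1, 7), lambda_grid=[0.0],
                             r_grid=[1], config=SAConfig(n_runs=20, seed=0))
print(f"selected n* = {sel.n_star}")
```

Output:

```
bead agreement: 100.0%
train H0 2.72e-04   held-out H0 2.67e-04
selected n* = 3
```

All 60 beads recover their planted color (after the optimal color
permutation), the residual cost sits at the Poisson noise floor, and the
held-out cost curve picks the true number of binding-site types.

Simulating the phase transition of a 100-bead two-color chain:

```python
import numpy as np
from sbsphase.core import PolymerModel, SimulationParams, phase_scan

colors = np.r_[np.ones(25, int), np.full(25, 2), np.ones(25, int), np.full(25, 2)]
model = PolymerModel(colors=colors, n=2)
grid = np.array([0, .02, .05, .1, .15, .2, .275, .35]) * 1e-6  # mol/l
scan = phase_scan(model, grid, SimulationParams(seed=0, n_steps=16000,
                  equilibration_steps=12000, samples_per_chain=4),
                  n_molecules=32)
print(np.round(scan.rg_norm, 2), scan.threshold)
```

```
[1.01 0.72 0.68 0.64 0.61 0.53 0.67 0.69] 1e-08
```

The SAW-normalized gyration radius collapses by ~40-50% across a threshold
of ~10 nmol/l — the transition sits in the tens-of-nanomolar range, the
physiological scale of transcription-factor concentrations.

A `sbsphase` console script exposes the workflow as subcommands
(`synth`, `simulate`, `scan`, `infer`, `metrics`, `match`, `dynamics`);
every run logs its parameters and writes its resolved configuration next to
its outputs.

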