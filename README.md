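# ptpdyn

Analysis toolkit for WPD-loop dynamics and catalysis in protein tyrosine
phosphatases (PTPs), built around the kind of study that combines long
molecular-dynamics (MD) sampling of the SHP-1/SHP-2 catalytic domains with
empirical valence bond (EVB) free-energy calculations of the
phosphoenzyme-hydrolysis step.

## The scientific problem

PTPs such as SHP-1 and SHP-2 close a mobile WPD loop over the active-site
P loop to position the general-acid aspartate for catalysis. Oncogenic
mutations far from the active site can shift the open/closed balance of this
loop and change catalytic rates, suggesting an allosteric communication
network that connects distal surface sites to the catalytic machinery.
Quantifying that picture requires several linked analyses:

- **Loop-state landscapes** — project each trajectory frame onto two
  internal-coordinate metrics: the distance RMSD (dRMSD) of all
  WPD-loop x P-loop Calpha pair distances against a closed reference
  structure, and the WPD-P center-of-mass distance. Frames are classified
  as closed / semi-closed / open by proximity to the metric-space anchors of
  reference open and closed structures.
- **Flexibility and correlation** — per-residue RMSF (and ΔRMSF between
  conditions), dynamic cross-correlation maps (DCCM) over Calpha atoms, and
  dominant-mode analysis.
- **Shortest-path maps (SPM)** — a contact-gated correlation graph whose
  edges are scored by how many all-pairs shortest paths traverse them; the
  high-usage subgraph is the allosteric communication network.
- **Variant overlay** — mutation hotspots (positions with ≥ 2 distinct
  substitutions in a COSMIC-like table) classified as on / near (< 4 Å) /
  far (≥ 4 Å) from the SPM by closest-heavy-atom distance.
- **EVB free-energy assembly** — forward FEP chaining of mapping windows,
  free-energy profile along the energy-gap coordinate, activation and
  reaction free energies, replicate statistics (ANOVA + Tukey HSD), and
  transition-state-theory (TST) conversion of experimental k_cat values.

Microsecond MD and EVB sampling are far beyond desk scale, so the package
ships a synthetic-data module whose generators have closed-form ground truth
(Gaussian ensembles with prescribed covariance, two-state Markov loop
switching, exactly sampled harmonic diabats, planted variant tables). Every
analysis stage is validated against those oracles.

## Worked example

```python
import numpy as np
from ptpdyn import (
    LoopDefinition, build_reference, compute_drmsd, compute_com_distance,
    classify_states, tst_barrier,
)
from ptpdyn.loops import anchor_point
from ptpdyn.ensemble import ensemble_from_arrays
from ptpdyn.synthetic import TwoStateLoopSpec, gen_two_state_loop

# a two-state loop: closed = straight 8-bead chain, open = WPD half displaced
closed = np.column_stack([np.arange(8) * 3.8, np.zeros(8), np.zeros(8)])
open_ = closed.copy(); open_[:4, 1] += 6.0
spec = TwoStateLoopSpec(open_, closed, occupancy_closed=0.7, mean_dwell=25,
                        jitter_sd=0.25, n_frames=10_000, seed=3)
ens, labels = gen_two_state_loop(spec)

wpd, ploop = LoopDefinition.from_range("WPD", 1, 4), LoopDefinition.from_range("P", 5, 8)
ref_c = ensemble_from_arrays(closed[None], res_ids=np.arange(1, 9))
ref_o = ensemble_from_arrays(open_[None], res_ids=np.arange(1, 9))
ref = build_reference(ref_c, wpd, ploop)

drmsd = compute_drmsd(ens, ref)
com = compute_com_distance(ens, wpd, ploop, mode="ca")
anchors = {"closed": anchor_point(ref_c, ref, wpd, ploop),
           "open": anchor_point(ref_o, ref, wpd, ploop)}
states = classify_states(drmsd, com, anchors, r_closed=np.inf, r_open=np.inf)
print(round(float(np.mean(states == "closed")), 4))   # 0.701
print(round(spec.occupancy_se(), 4))                  # 0.0171
print(round(tst_barrier(1.0, 300.0), 3))              # 17.565
```

The recovered closed fraction (0.701) matches the generator's stationary
occupancy (0.7) well within one Markov-chain standard error (0.0171), and a
k_cat of 1 s⁻¹ at 300 K converts to a TST activation free energy of
17.565 kcal/mol.

The same stages run end to end from the CLI. With this config,

```yaml
# run.yaml
out_dir: scratch/readme_run
seed: 3
synth: {n_frames: 5000, n_residues: 8}
evb: {frames_per_window: 1000, n_windows: 51}
```

```bash
ptpdyn run --config run.yaml --stages synth,metrics,rmsf,dccm,spm,variants,evb
```

prints the per-stage summaries

```json
{"synth": {"n_frames": 5000},
 "metrics": {"n_frames": 5000, "closed_fraction": 0.4662,
             "anchors": {"closed": [0.0, 15.2], "open": [1.4917, 16.3414]}},
 "rmsf": {"mean_rmsf": 0.7393},
 "dccm": {"n_residues": 8},
 "spm": {"n_edges": 7, "n_spm_residues": 8},
 "variants": {"n_hotspots": 11, "n_classified": 11},
 "evb": {"dg_act": 10.6108, "dg_rxn": -1.9928}}
```

and writes CSV/NPZ/JSON artifacts (with seed and config-digest provenance)
under `scratch/readme_run/<stage>/`. The EVB reaction free energy recovers
the generator's exothermic ΔG0 = −2 kcal/mol; `closed_fraction` here is the
conservative strict-radius count (frames outside both anchor radii stay
`semi_closed`), so it undercounts the 0.7 stationary occupancy by design —
the nearest-anchor estimate in the Python example above is the occupancy
estimator. Single-stage subcommands (`ptpdyn synth`, `landscape`, `rmsf`,
`dccm`, `spm`, `variants`, `evb`, `stats`, `plan`, `identity`) expose the
same computations on user-supplied files.

## Reproduction

`scripts/acceptance.py` recomputes the package's headline quantities on
self-generated data and writes them as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

With seed 1 this reports, among others: MD plan cumulative 399.0 μs, EVB plan
10.2 ns/trajectory, 306 ns/system and 1.8 μs cumulative; planted sequence
identities recovered at exactly 59.0 / 60.0 / 38.0 %; a planted DCCM
correlation of 0.9 recovered as 0.9007 (n = 50,000); two-state closed
fraction 0.6873 against the 0.7 target (SE 0.0171, n = 10,000); EVB barriers
within 0.095 (ΔG‡) and 0.017 (ΔG0) kcal/mol of the analytic oracle at
51 x 5,000 frames; TST ΔG‡ = 17.565 kcal/mol for k_cat = 1 s⁻¹ at 300 K.
All randomness derives from `--seed`; the same seed reproduces the same JSON
byte for byte.

The test suite (`python -m pytest -q tests/`) includes a dedicated acceptance
module (`tests/test_acceptance.py`) with one test per release criterion.

See `docs/methods.md` for the modelling assumptions, parameter defaults and
numerical choices.
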