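# Methods

Models, parameter defaults and numerical choices used throughout `ptpdyn`.
Every quantitative statement here is either a definition or is verified by
the test suite / `scripts/acceptance.py`; nothing below is an empirical
claim about real PTP trajectories.

## 1. Coordinate ensembles

All analyses operate on `CoordinateEnsemble` objects: frames x atoms x 3
arrays with residue/atom metadata, loaded from NPZ trajectories or PDB
structures (parsed with biotite). Units are Å, ps, and kcal/mol throughout.

## 2. Loop metrics and state landscape

**dRMSD.** For WPD-loop residues W and P-loop residues P, the reference set
holds all |W|x|P| inter-loop Cα pair distances (optionally intra-loop pairs
too). Per frame,

    dRMSD(t) = sqrt( mean_pairs ( d_pair(t) − d_ref )² ).

Because it is built from internal distances, dRMSD is exactly invariant
under rigid motion — the tests verify invariance to 1e-6 Å across 100
random rotations/translations. Cross-protein comparison maps residue ids
through an explicit alignment map; an unmapped pair aborts rather than
silently shrinking the pair set, which would change the metric's scale.

A consequence worth keeping in mind: under isotropic Gaussian jitter of
standard deviation σ per coordinate, dRMSD has a *positive floor* of about
σ·sqrt(2) even for frames in the reference basin, because every pair
distance fluctuates. The closed-state cloud therefore sits above, not on,
the closed anchor.

**COM distance.** Unweighted Cα centroid distance between the two loops
(mass weighting over all atoms is available via `mode="mass"`).

**Landscape.** `build_landscape` bins (dRMSD, COM) with
`numpy.histogram2d` (default 50x50 automatic bins covering all frames;
explicit edges that exclude frames are an error, never a silent drop).

**State classification.** Open and closed reference structures are mapped
to anchor points in the same (dRMSD, COM) plane. Both axes are normalized
by the inter-anchor span, so the anchors are unit-separated per axis and
the two metrics (Å-scale dRMSD vs tens-of-Å COM distance) get equal voice.
A frame within `r_closed` of the closed anchor is `closed`, within
`r_open` of the open anchor is `open`, otherwise `semi_closed`; frames
inside both radii resolve to the nearer anchor. The default radius is 25 %
of the inter-anchor distance: strict enough that the two state balls never
overlap, loose enough to absorb basin jitter. This default deliberately
*undercounts* occupancy — jitter tails (and the dRMSD noise floor above)
push basin frames into `semi_closed`, asymmetrically for the closed state.

**Occupancy estimation.** When the goal is the closed/open population
rather than a conservative per-frame call, pass infinite radii: the
classifier then degenerates to a nearest-anchor (Voronoi) partition of the
plane, every frame is assigned, and the closed fraction is an unbiased
occupancy estimate for well-separated basins. The acceptance suite checks
this estimate against the generator's stationary occupancy within three
Markov-chain standard errors, and additionally that no default-radius
`closed`/`open` call ever disagrees with the nearest-anchor partition
(strict radii may abstain, never flip basins).

**RMSF.** Per-residue Cα fluctuation about the ensemble mean,
sqrt(<|r_i − <r_i>|²>), after iterated least-squares superposition (Kabsch,
2 iterations against the running average; `align=False` skips fitting).
For isotropic Gaussian coordinates of standard deviation σ the expectation
is σ·sqrt(3) without fitting; fitting absorbs the 6 rigid-body degrees of
freedom out of 3n, giving sqrt(3σ²(1 − 6/3n)) — both limits are tested.
`delta_rmsf` subtracts profiles over shared residues and warns when the
residue sets differ.

**Reactive-geometry criteria.** `default_reactive_criteria` encodes the
productive-snapshot filter for the PTP hydrolysis step: general-acid Asp
carboxylate oxygen (OD1, residue 419) within 4.5 Å of the substrate
phosphorus, and the Gln (CD, residue 500) within 8.0 Å, with the
nucleophilic Cys at 453; residue/atom names and cutoffs are all
overridable. Cutoffs are strict (`<`), tested at the boundary.

## 3. Correlation and modes

The DCCM uses the scalar-product normal form
C_ij = <Δr_i·Δr_j> / sqrt(<Δr_i²><Δr_j²>) over Cα displacements from the
mean, optionally after superposition; replicas are concatenated, which the
tests show is identical to a single concatenated run. The sampling error
of an empirical correlation is ~1/sqrt(n_frames); planted correlations
(via `correlated_pair_covariance`, which builds an exact PSD covariance
with a chosen off-diagonal ρ) are recovered within 3/sqrt(n).
`dominant_modes` diagonalizes the 3n x 3n covariance (numpy `eigh`),
orders by eigenvalue, fixes the sign convention (largest-magnitude loading
positive) and warns on rank deficiency.

## 4. Shortest-path maps

Nodes are residues; an edge joins i, j when the trajectory-mean Cα–Cα
distance is below the contact cutoff (default 6.0 Å) **and** C_ij ≠ 0,
with weight w_ij = −log|C_ij|. The absolute value is used because
anti-correlated contacts carry communication just as correlated ones do;
the sign is kept as edge metadata. Zero-correlation contacts would have
infinite weight and are dropped with a warning.

Edge usage counts *all* shortest paths: a path-counting Dijkstra computes
per-source distances and path multiplicities σ, and edge (u,v) receives
σ_s(u)·σ_t(v) for every pair (s,t) with d(s,u) + w_uv + d(v,t) = d(s,t)
(floating-point ties resolved with a relative tolerance of 1e-9).
Counting all ties makes usage independent of node iteration order —
a plain single-predecessor Dijkstra would give arbitrary, run-dependent
usages on tie-rich graphs. Usages are normalized by the maximum; edges at
or above the usage threshold (default 0.3) form the SPM, and residues
incident to them are the SPM residues. The implementation is validated
against a brute-force oracle (networkx `all_simple_paths` enumeration) on
randomized tie-prone graphs, and pruning is verified monotone in the
threshold. SPM conservation between two proteins is reported in both
directions through an explicit alignment map (unmapped residues count as
non-conserved and are listed).

## 5. Variant overlay

A variant table (COSMIC-like: position, wt_aa, alt_aa, count) defines
hotspots as positions with ≥ 2 *distinct* substitutions (`min_distinct=2`;
recurrence of one substitution is not enough). Each hotspot is classified
against the SPM on a structure: `on_spm` if the position is itself an SPM
residue, else `near_spm` when the minimum closest-atom distance to any SPM
residue is strictly below 4.0 Å, else `far_spm`. Distances use heavy atoms
only by default (hydrogens, rarely resolved crystallographically, would
bias minima). The 4.0 Å default is a conventional heavy-atom contact
distance; the boundary is strict and tested at 3.999/4.0/4.001 Å.

## 6. EVB assembly

Mapping potentials E_m = (1−λ_m)·ε1 + λ_m·ε2 over a λ grid (default
51 windows). Window free energies are chained by forward Zwanzig
perturbation, ΔG(λ_{m+1}) = ΔG(λ_m) − kT ln<exp(−(E_{m+1}−E_m)/kT)>_m,
with an effective-sample-size warning (< 10) for poor overlap. The free
energy along the gap coordinate x = ε1 − ε2 is assembled per bin as
ΔG(λ_m) − kT ln<exp(−(E_g−E_m)/kT)>_{m,b}, combining multi-window bins by
sample-count weighting, where E_g is the lower adiabatic surface
½(ε1+ε2) − sqrt(¼(ε1−ε2)² + H12²).

Numerical choices: the gap range is trimmed at the 0.5 % quantile tails
(single extreme samples otherwise stretch the binning), split into
**150 bins** and lightly smoothed (moving average, window 3). With 50-ish
bins the barrier-top bin is wide enough to clip the maximum of a sharply
curved profile; 150 bins at the default sampling (thousands of frames per
window) keeps every bin well populated while resolving the barrier. The
reactant-state bin is anchored to zero.

The synthetic oracle uses two equal-force-constant harmonic diabats
(the tests use k = 100 kcal/mol/Å², minima 1 Å apart, constant H12). Equal force constants make every mapping potential
harmonic, so window sampling is an *exact* Gaussian draw and the adiabatic
profile, ΔG‡ and ΔG0 have closed forms (`analytic_barriers`), including
the classic λ_reorg/4 Marcus limit at H12 = 0 and the ~H12 barrier
depression when coupled. The acceptance test sweeps a 3x3 grid of
(ΔG0, H12) and requires profile barriers within 0.3 kcal/mol of the
analytic values, plus agreement of the FEP chain with the per-window
Gaussian closed form ΔA = μ − σ²/(2kT) within sampling error.

Replicate barrier statistics use one-way ANOVA and Tukey HSD (scipy);
stars follow the adjusted p-values. `tst_barrier` converts rates by
transition state theory, ΔG‡ = RT·ln(k_B T/(h·k_cat)) with transmission
coefficient 1; identities tested include ΔΔG‡ = RT·ln 2 per k_cat
doubling and ΔG‡(k_cat = 1 s⁻¹, 300 K) = 17.565 kcal/mol.
`cluster_reactive_geometries` groups reactive snapshots by hierarchical
agglomeration (scipy, average linkage by default) on the pairwise RMSD of
superposed reacting-atom geometries, cut at either a cluster count or an
RMSD cutoff, reporting the medoid of each cluster.

## 7. Simulation-plan accounting

Plans are rows of (system, n_states, n_replicas, length_us); lengths are
parsed as exact rationals (`fractions.Fraction`), so cumulative times like
8·4·8·1.5 + 3·1·5·1 = 399 µs are exact rather than float-accumulated
(3 x 0.1 equals 3/10 exactly). CSV round-trips preserve exactness.

## 8. Sequence identity

`pairwise_identity` defaults to global alignment (biotite,
BLOSUM62, gap open 10 / extend 0.5), identity = matches over aligned
columns with terminal gaps excluded and internal gaps counted as
mismatches. A `given_alignment` mode scores pre-aligned rows. Caveat
verified in testing: at low planted identity (~38 %), *random*
substitutions admit gapped alignments that score above the gapless truth,
so the measured identity under global alignment is legitimately lower than
the planted value; conservative substitutions keep the two equal.

## 9. What the synthetic generators emulate — and don't

- `gen_gaussian_ensemble`: stationary harmonic fluctuations with an exact
  prescribed 3n x 3n covariance. No anharmonicity, no kinetics.
- `gen_two_state_loop`: hidden two-state Markov chain (closed-state mean
  dwell in frames; the open-state dwell follows from detailed balance at
  the requested stationary occupancy — infeasible combinations raise
  rather than silently re-normalizing) emitting the state anchor plus
  isotropic Gaussian jitter. It reproduces occupancy, dwell statistics and
  the Markov-CLT occupancy standard error, but has no transition pathway:
  frames jump between basins with no semi-closed intermediate of its own.
- `gen_evb_windows`: exact Boltzmann draws from harmonic mapping
  potentials. Real EVB windows carry MD autocorrelation and anharmonicity;
  here samples are i.i.d., so error bars are at their theoretical floor.
- `gen_variant_table`: planted hotspot positions among random passenger
  substitutions; no mutational signature model.

None of the generators model solvent, force-field error, or sampling
non-ergodicity; they exist to give every analysis stage a ground truth
with known statistics.

## 10. Reproducibility

All generators take explicit integer seeds (numpy `default_rng`).
`scripts/acceptance.py` derives all stage seeds from a single `--seed`
via `(seed · 1_000_003 + offset) mod (2³¹ − 1)` and writes
byte-identical JSON for identical seeds. The pipeline records seed and a
config digest in every stage's JSON summary.

## 11. Limitations

- State classification assumes two metrically separated anchors; it
  aborts if the references coincide in (dRMSD, COM) space (e.g. two
  structures related by a rigid motion, which is invisible to both
  metrics by construction).
- The occupancy estimator (infinite radii) is unbiased only when basins
  are well separated relative to jitter; overlapping basins need a
  density-based assignment it does not provide.
- Forward-only Zwanzig chaining is adequate for the default 51-window
  grid on harmonic diabats; sparse λ grids on rough surfaces would need
  BAR/MBAR-style estimators.
- The SPM's −log|C| weight treats correlation magnitude as the only
  communication measure; mutual-information or energy-flux weights are
  out of scope.
- dRMSD's jitter floor means absolute dRMSD values are not comparable
  across conditions with different fluctuation amplitudes; the anchors
  and classification are computed per condition for this reason.
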