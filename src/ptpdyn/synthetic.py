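"""Synthetic inputs with analytically known ground truth.

Microsecond MD and EVB sampling are far outside desk scale, so every stage of
the pipeline is validated against generated data whose true answer is known in
closed form:

* Gaussian positional ensembles with a prescribed displacement covariance
  (oracle for RMSF, DCCM and mode analysis);
* two-state (open/closed) loop switching as a discrete-time Markov chain with
  prescribed stationary occupancy and mean dwell time (oracle for landscape
  construction and state classification);
* harmonic diabatic energy surfaces sampled exactly under EVB mapping
  potentials (oracle for free-energy assembly — with equal force constants the
  mapping potential is itself harmonic, so window sampling is exact Gaussian
  draws, no MCMC error);
* toy variant tables with planted mutation hotspots.

Seeds are explicit spec fields, never global state, so parallel tests are safe
and every generator is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from ptpdyn.constants import KCAL_PER_MOL_K
from ptpdyn.ensemble import CoordinateEnsemble, ensemble_from_arrays
from ptpdyn.evb import EVBWindowSeries
from ptpdyn.variants import VariantTable

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Gaussian positional ensembles
# ---------------------------------------------------------------------------

@dataclass
class GaussianEnsembleSpec:
    """Stationary Gaussian fluctuations about a mean structure.

    ``covariance`` is the full symmetric PSD matrix over the 3*n_residues
    displacement components, in Angstrom^2.
    """

    mean_coordinates: np.ndarray  # (n_res, 3), Angstrom
    covariance: np.ndarray        # (3n, 3n), Angstrom^2
    n_frames: int
    seed: int

    def __post_init__(self) -> None:
        self.mean_coordinates = np.asarray(self.mean_coordinates, float)
        self.covariance = np.asarray(self.covariance, float)
        n = self.mean_coordinates.shape[0]
        if self.mean_coordinates.shape != (n, 3):
            raise ValueError("mean_coordinates must have shape (n_residues, 3)")
        if self.covariance.shape != (3 * n, 3 * n):
            raise ValueError(
                f"covariance must be ({3*n}, {3*n}) for {n} residues, "
                f"got {self.covariance.shape}"
            )
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        eigvals = np.linalg.eigvalsh(self.covariance)
        if eigvals.min() < -1e-8:
            raise ValueError(
                f"covariance is not positive semi-definite: "
                f"smallest eigenvalue {eigvals.min():.3e}"
            )
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")


def gen_gaussian_ensemble(spec: GaussianEnsembleSpec) -> CoordinateEnsemble:
    """Draw a Calpha bead-model ensemble from the spec's Gaussian."""
    rng = np.random.default_rng(spec.seed)
    n_res = spec.mean_coordinates.shape[0]
    dim = 3 * n_res
    w, v = np.linalg.eigh(spec.covariance)
    w = np.clip(w, 0.0, None)
    transform = v * np.sqrt(w)  # maps iid normals to the target covariance
    z = rng.standard_normal((spec.n_frames, dim))
    disp = z @ transform.T
    coords = spec.mean_coordinates[None] + disp.reshape(spec.n_frames, n_res, 3)
    ens = ensemble_from_arrays(coords, res_ids=np.arange(1, n_res + 1))
    ens.metadata["generator"] = "gaussian_ensemble"
    ens.metadata["seed"] = spec.seed
    return ens


def diagonal_covariance(n_residues: int, sigma2: float = 1.0) -> np.ndarray:
    """Isotropic per-component covariance sigma^2 * I (Angstrom^2)."""
    return np.eye(3 * n_residues) * sigma2


def correlated_pair_covariance(
    n_residues: int, i: int, j: int, rho: float, sigma2: float = 1.0
) -> np.ndarray:
    """Isotropic covariance with correlation ``rho`` planted between the
    matching Cartesian components of residues ``i`` and ``j`` (0-based)."""
    cov = diagonal_covariance(n_residues, sigma2)
    for axis in range(3):
        a, b = 3 * i + axis, 3 * j + axis
        cov[a, b] = cov[b, a] = rho * sigma2
    return cov


# ---------------------------------------------------------------------------
# Two-state loop switching
# ---------------------------------------------------------------------------

@dataclass
class TwoStateLoopSpec:
    """Open/closed loop interconversion as a two-state Markov chain.

    ``mean_dwell`` is the mean residence time (frames) of the *closed* state;
    the open-state dwell follows from detailed balance at the requested
    stationary occupancy.  Emitted coordinates are the state anchor plus
    isotropic Gaussian jitter.
    """

    open_coordinates: np.ndarray   # (n_res, 3)
    closed_coordinates: np.ndarray
    occupancy_closed: float
    mean_dwell: float              # frames, closed state
    jitter_sd: float               # Angstrom
    n_frames: int
    seed: int

    def __post_init__(self) -> None:
        self.open_coordinates = np.asarray(self.open_coordinates, float)
        self.closed_coordinates = np.asarray(self.closed_coordinates, float)
        if self.open_coordinates.shape != self.closed_coordinates.shape:
            raise ValueError(
                "open and closed coordinate sets must have identical residue counts: "
                f"{self.open_coordinates.shape} vs {self.closed_coordinates.shape}"
            )
        if not 0.0 <= self.occupancy_closed <= 1.0:
            raise ValueError("occupancy_closed must be in [0, 1]")
        if self.mean_dwell < 1:
            raise ValueError("mean_dwell must be >= 1 frame")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    def transition_probs(self) -> tuple[float, float]:
        """(p_leave_closed, p_leave_open) of the hidden chain."""
        p = self.occupancy_closed
        if p in (0.0, 1.0):
            return 0.0, 0.0
        q_closed = 1.0 / self.mean_dwell
        q_open = q_closed * p / (1.0 - p)
        if q_open > 1.0:
            # clipping here would silently shift the stationary occupancy
            raise ValueError(
                f"mean_dwell={self.mean_dwell} too short for occupancy "
                f"{p}: open-state exit probability {q_open:.3f} > 1; "
                f"need mean_dwell >= {p / (1.0 - p):.3f}"
            )
        return q_closed, q_open

    def lag1_autocorrelation(self) -> float:
        q_c, q_o = self.transition_probs()
        return 1.0 - q_c - q_o

    def occupancy_se(self) -> float:
        """Standard error of the empirical closed fraction under the chain.

        Markov-chain CLT: var = p(1-p)/n * (1+rho)/(1-rho) with rho the lag-1
        autocorrelation of the state indicator.
        """
        p = self.occupancy_closed
        if p in (0.0, 1.0):
            return 0.0
        rho = self.lag1_autocorrelation()
        return float(np.sqrt(p * (1 - p) / self.n_frames * (1 + rho) / (1 - rho)))


def gen_two_state_loop(spec: TwoStateLoopSpec) -> tuple[CoordinateEnsemble, np.ndarray]:
    """Generate the ensemble and return it with the true hidden-state labels.

    Labels are strings ``'closed'`` / ``'open'``; the initial state is drawn
    from the stationary distribution.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    q_c, q_o = spec.transition_probs()
    p = spec.occupancy_closed
    states = np.empty(n, dtype=int)  # 1 = closed, 0 = open
    if p == 1.0:
        states[:] = 1
    elif p == 0.0:
        states[:] = 0
    else:
        u = rng.random(n)
        states[0] = 1 if u[0] < p else 0
        for t in range(1, n):
            if states[t - 1] == 1:
                states[t] = 0 if u[t] < q_c else 1
            else:
                states[t] = 1 if u[t] < q_o else 0
    n_res = spec.open_coordinates.shape[0]
    anchors = np.stack([spec.open_coordinates, spec.closed_coordinates])
    coords = anchors[states]
    if spec.jitter_sd > 0:
        coords = coords + rng.normal(0.0, spec.jitter_sd, size=(n, n_res, 3))
    else:
        coords = coords.copy()
    ens = ensemble_from_arrays(coords, res_ids=np.arange(1, n_res + 1))
    ens.metadata["generator"] = "two_state_loop"
    ens.metadata["seed"] = spec.seed
    labels = np.where(states == 1, "closed", "open")
    return ens, labels


# ---------------------------------------------------------------------------
# Harmonic diabats / EVB windows
# ---------------------------------------------------------------------------

@dataclass
class HarmonicDiabatSpec:
    """Two equal-force-constant harmonic diabats coupled by a constant H12.

    Diabat 1: e1(x) = k/2 (x - x1)^2.  Diabat 2: e2(x) = k/2 (x - x2)^2 + dG0.
    With equal force constants every mapping potential
    E_m = (1-lambda) e1 + lambda e2 is itself harmonic, so Boltzmann sampling
    of each window is an exact Gaussian draw and the assembled free-energy
    profile has a closed-form oracle (the lower adiabatic surface).
    """

    k_force: float       # kcal/mol/A^2
    x1: float            # A
    x2: float            # A
    dG0: float           # kcal/mol
    H12: float           # kcal/mol
    temperature: float   # K
    lambdas: np.ndarray
    frames_per_window: int
    seed: int

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, float)
        if self.k_force <= 0:
            raise ValueError("k_force must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        lam = self.lambdas
        if lam.ndim != 1 or len(lam) < 2:
            raise ValueError("lambdas must be a 1D list of at least 2 values")
        if lam[0] != 0.0 or lam[-1] != 1.0:
            raise ValueError("lambdas must start at 0 and end at 1")
        if np.any(np.diff(lam) <= 0):
            raise ValueError("lambdas must be strictly increasing")
        if self.frames_per_window < 1:
            raise ValueError("frames_per_window must be >= 1")

    @property
    def kT(self) -> float:
        return KCAL_PER_MOL_K * self.temperature

    def diabats(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, float)
        e1 = 0.5 * self.k_force * (x - self.x1) ** 2
        e2 = 0.5 * self.k_force * (x - self.x2) ** 2 + self.dG0
        return e1, e2

    def adiabatic(self, x: np.ndarray) -> np.ndarray:
        """Lower adiabatic (EVB ground-state) surface."""
        e1, e2 = self.diabats(x)
        return 0.5 * (e1 + e2) - 0.5 * np.sqrt((e1 - e2) ** 2 + 4.0 * self.H12 ** 2)

    @property
    def reorganization_energy(self) -> float:
        """Marcus reorganization energy lambda = k/2 (x2-x1)^2."""
        return 0.5 * self.k_force * (self.x2 - self.x1) ** 2


@dataclass
class AnalyticEVB:
    """Closed-form reference for the synthetic EVB problem."""

    dg_act: float
    dg_rxn: float
    x_rs: float
    x_ts: float
    x_ps: float
    reorganization_energy: float


def analytic_barriers(spec: HarmonicDiabatSpec) -> AnalyticEVB:
    """Stationary points of the lower adiabatic surface.

    In this 1D classical problem the free-energy profile along the energy-gap
    coordinate equals the adiabatic potential up to a constant (the gap is a
    strictly monotonic function of x for equal force constants), so the
    adiabatic stationary values are the exact oracle for the assembled
    profile's barriers.
    """
    lo, hi = sorted((spec.x1, spec.x2))
    span = max(hi - lo, 1e-6)
    neg = lambda x: -spec.adiabatic(x)
    rs = minimize_scalar(spec.adiabatic, bounds=(lo - span, lo + 0.49 * span), method="bounded")
    ps = minimize_scalar(spec.adiabatic, bounds=(hi - 0.49 * span, hi + span), method="bounded")
    ts = minimize_scalar(neg, bounds=(rs.x, ps.x), method="bounded")
    g_rs, g_ts, g_ps = spec.adiabatic(rs.x), spec.adiabatic(ts.x), spec.adiabatic(ps.x)
    # orient so that RS is the diabat-1 side
    if spec.x1 <= spec.x2:
        x_rs, x_ps, dg_rxn = rs.x, ps.x, g_ps - g_rs
        dg_act = g_ts - g_rs
    else:  # pragma: no cover - symmetric orientation
        x_rs, x_ps, dg_rxn = ps.x, rs.x, g_rs - g_ps
        dg_act = g_ts - g_ps
    return AnalyticEVB(
        dg_act=float(dg_act),
        dg_rxn=float(dg_rxn),
        x_rs=float(x_rs),
        x_ts=float(ts.x),
        x_ps=float(x_ps),
        reorganization_energy=spec.reorganization_energy,
    )


def gen_evb_windows(spec: HarmonicDiabatSpec) -> EVBWindowSeries:
    """Exact Boltzmann sampling of every mapping window.

    E_m(x) = (1-lam) e1 + lam e2 is harmonic with force constant k and minimum
    x_m = (1-lam) x1 + lam x2, so x ~ Normal(x_m, kT/k) exactly.  Per-frame
    diabatic energies (e1, e2) are recorded per window.
    """
    rng = np.random.default_rng(spec.seed)
    sigma = np.sqrt(spec.kT / spec.k_force)
    energies = []
    for lam in spec.lambdas:
        x_min = (1.0 - lam) * spec.x1 + lam * spec.x2
        x = rng.normal(x_min, sigma, size=spec.frames_per_window)
        e1, e2 = spec.diabats(x)
        energies.append(np.column_stack([e1, e2]))
    return EVBWindowSeries(
        lambdas=spec.lambdas.copy(),
        energies=energies,
        h12=spec.H12,
        temperature=spec.temperature,
    )


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

def gen_variant_table(
    seed: int,
    n_positions: int,
    substitution_rate: float = 0.3,
    gene: str = "SYNTH",
    planted_hotspots=None,
    position_range: tuple[int, int] = (250, 550),
) -> VariantTable:
    """Toy COSMIC-like variant table with a known hotspot set.

    Each sampled position receives one substitution plus Binomial(3,
    substitution_rate) further *distinct* substitutions; positions in
    ``planted_hotspots`` are forced to carry at least two distinct
    substitutions.  The ground-truth hotspot set is exactly the positions with
    >= 2 distinct alternate amino acids.
    """
    if n_positions < 0:
        raise ValueError("n_positions must be >= 0")
    rng = np.random.default_rng(seed)
    planted = sorted(set(planted_hotspots or []))
    lo, hi = position_range
    pool = [p for p in range(lo, hi + 1) if p not in planted]
    n_random = max(0, n_positions - len(planted))
    positions = planted + sorted(
        rng.choice(pool, size=min(n_random, len(pool)), replace=False).tolist()
    )
    rows = []
    aas = list(AA_ORDER)
    for pos in positions:
        wt = aas[rng.integers(len(aas))]
        n_subs = 1 + int(rng.binomial(3, substitution_rate))
        if pos in planted:
            n_subs = max(2, n_subs)
        alts = [a for a in aas if a != wt]
        chosen = rng.choice(alts, size=n_subs, replace=False)
        for alt in chosen:
            rows.append((gene, pos, wt, str(alt), int(rng.integers(1, 20))))
    rows.sort(key=lambda r: (r[1], r[3]))
    return VariantTable.from_rows(rows, gene=gene, numbering="synthetic")
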