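"""EVB free-energy assembly, barrier statistics and rate conversion.

An empirical valence bond (EVB) run samples a ladder of mapping potentials
E_m = (1 - lambda_m) e1 + lambda_m e2 between two diabatic states.  Free
energies of adjacent windows are chained by forward exponential averaging
(Zwanzig), and the profile along the energy-gap coordinate x = e1 - e2 is
assembled by binning frames and correcting each window's contribution to the
EVB ground state E_g = (e1+e2)/2 - sqrt((e1-e2)^2 + 4 H12^2)/2.  Barriers from
replicate trajectories are compared across systems by one-way ANOVA with a
Tukey HSD post-hoc, and experimental rate constants are converted to
activation free energies with transition state theory.

Units: kcal/mol and Kelvin throughout, with kT = 0.0019872041 * T.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import logsumexp

from ptpdyn.constants import BOLTZMANN_SI, KCAL_PER_MOL_K, PLANCK_SI
from ptpdyn.superpose import superpose_frames


@dataclass
class EVBWindowSeries:
    """Per-window, per-frame diabatic energies of one EVB trajectory."""

    lambdas: np.ndarray
    energies: list[np.ndarray]  # one (n_frames_m, 2) array of (e1, e2) per window
    h12: float
    temperature: float

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, float)
        if self.lambdas.ndim != 1 or len(self.lambdas) < 2:
            raise ValueError("need at least 2 lambda windows")
        if self.lambdas[0] != 0.0 or self.lambdas[-1] != 1.0:
            raise ValueError("lambda ladder must span [0, 1]")
        if np.any(np.diff(self.lambdas) <= 0):
            raise ValueError("lambdas must be strictly increasing")
        if len(self.energies) != len(self.lambdas):
            raise ValueError("one energy block per window required")
        self.energies = [np.asarray(e, float) for e in self.energies]
        for m, block in enumerate(self.energies):
            if block.ndim != 2 or block.shape[1] != 2 or block.shape[0] == 0:
                raise ValueError(f"window {m}: energies must be a non-empty (n, 2) array")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def kT(self) -> float:
        return KCAL_PER_MOL_K * self.temperature

    @property
    def n_windows(self) -> int:
        return len(self.lambdas)

    def to_csv(self, path) -> None:
        frames = []
        for lam, block in zip(self.lambdas, self.energies):
            frames.append(
                pd.DataFrame(
                    {
                        "lambda": lam,
                        "frame": np.arange(block.shape[0]),
                        "e1": block[:, 0],
                        "e2": block[:, 1],
                    }
                )
            )
        pd.concat(frames).to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path, h12: float, temperature: float) -> "EVBWindowSeries":
        df = pd.read_csv(path)
        lambdas = np.array(sorted(df["lambda"].unique()))
        energies = [
            df.loc[df["lambda"] == lam, ["e1", "e2"]].to_numpy() for lam in lambdas
        ]
        return cls(lambdas, energies, h12, temperature)

    def ground_state(self, m: int) -> np.ndarray:
        """Lower adiabatic energy of each frame of window m."""
        e1, e2 = self.energies[m][:, 0], self.energies[m][:, 1]
        return 0.5 * (e1 + e2) - 0.5 * np.sqrt((e1 - e2) ** 2 + 4.0 * self.h12 ** 2)


def mapping_energies(series: EVBWindowSeries, m: int) -> np.ndarray:
    """Per-frame mapping-potential energy E_m = (1 - lam) e1 + lam e2."""
    if not 0 <= m < series.n_windows:
        raise IndexError(f"window {m} out of range (0..{series.n_windows - 1})")
    lam = series.lambdas[m]
    e1, e2 = series.energies[m][:, 0], series.energies[m][:, 1]
    return (1.0 - lam) * e1 + lam * e2


def fep_increments(series: EVBWindowSeries, min_ess: float = 10.0) -> np.ndarray:
    """Cumulative window free energies dG(lambda_m), forward Zwanzig chaining.

    dG(lam_{m+1}) = dG(lam_m) - kT ln < exp(-(E_{m+1} - E_m)/kT) >_m with
    dG(lam_0) = 0.  A warning is raised when the exponential average's
    effective sample size falls below ``min_ess`` (poor window overlap).
    """
    kT = series.kT
    dg = np.zeros(series.n_windows)
    for m in range(series.n_windows - 1):
        lam0, lam1 = series.lambdas[m], series.lambdas[m + 1]
        e1, e2 = series.energies[m][:, 0], series.energies[m][:, 1]
        delta = (lam1 - lam0) * (e2 - e1)  # E_{m+1} - E_m evaluated in window m
        logw = -delta / kT
        n = len(logw)
        log_mean = logsumexp(logw) - np.log(n)
        ess = np.exp(2 * logsumexp(logw) - logsumexp(2 * logw))
        if ess < min_ess:
            warnings.warn(
                f"window {m}->{m + 1}: effective sample size {ess:.1f} < {min_ess}",
                stacklevel=2,
            )
        dg[m + 1] = dg[m] - kT * log_mean
    return dg


@dataclass
class FreeEnergyProfile:
    """Free energy along the energy-gap coordinate x = e1 - e2."""

    bin_centers: np.ndarray
    dg: np.ndarray
    counts: np.ndarray
    dg_act: float
    dg_rxn: float
    rs_bin: int
    ts_bin: int
    ps_bin: int
    metadata: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.bin_centers, "dg": self.dg, "count": self.counts})


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.copy()
    half = window // 2
    padded = np.pad(values, half, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def gap_profile(
    series: EVBWindowSeries,
    dg_windows: np.ndarray | None = None,
    n_bins: int = 150,
    trim: float = 0.005,
    smooth_window: int = 3,
) -> FreeEnergyProfile:
    """Assemble the free-energy profile along x = e1 - e2.

    Within bin b, window m contributes
    dG(lam_m) - kT ln < exp(-(E_g - E_m)/kT) >_{m,b}; multi-window
    contributions are combined by sample-count-weighted averaging.  The gap
    range is trimmed at the ``trim`` quantile tails before binning.  The
    default of 150 equal-width bins keeps the bin-averaging bias at a sharp
    (weak-coupling) barrier cusp well below typical statistical error; coarser
    binning systematically underestimates such barriers.  Empty
    interior bins are linearly interpolated (with a warning).  Reactant (RS)
    and product (PS) basins are the two outermost local minima of the smoothed
    profile, oriented by which basin is sampled by low-lambda windows; the
    transition state (TS) is the maximum between them.  The profile is shifted
    so the RS minimum is exactly 0.
    """
    if dg_windows is None:
        dg_windows = fep_increments(series)
    dg_windows = np.asarray(dg_windows, float)
    kT = series.kT
    all_x = np.concatenate([e[:, 0] - e[:, 1] for e in series.energies])
    lo, hi = np.quantile(all_x, [trim, 1.0 - trim])
    if hi <= lo:
        raise ValueError("degenerate energy-gap range")
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    num = np.zeros(n_bins)       # count-weighted sum of window contributions
    counts = np.zeros(n_bins)
    lam_weight = np.zeros(n_bins)
    for m in range(series.n_windows):
        e1, e2 = series.energies[m][:, 0], series.energies[m][:, 1]
        x = e1 - e2
        e_m = mapping_energies(series, m)
        e_g = series.ground_state(m)
        inside = (x >= lo) & (x <= hi)
        if not inside.any():
            continue
        bins = np.clip(np.digitize(x[inside], edges) - 1, 0, n_bins - 1)
        logw = -(e_g[inside] - e_m[inside]) / kT
        for b in np.unique(bins):
            sel = bins == b
            n_mb = int(sel.sum())
            log_mean = logsumexp(logw[sel]) - np.log(n_mb)
            val = dg_windows[m] - kT * log_mean
            num[b] += n_mb * val
            counts[b] += n_mb
            lam_weight[b] += n_mb * series.lambdas[m]

    occupied = counts > 0
    if occupied.sum() < 3:
        raise ValueError(f"only {int(occupied.sum())} occupied gap bins; profile unusable")
    vals = np.full(n_bins, np.nan)
    vals[occupied] = num[occupied] / counts[occupied]
    first, last = np.flatnonzero(occupied)[[0, -1]]
    interior_empty = np.flatnonzero(~occupied[first : last + 1]) + first
    if interior_empty.size:
        warnings.warn(
            f"{interior_empty.size} empty interior gap bin(s) interpolated", stacklevel=2
        )
        occ_idx = np.flatnonzero(occupied)
        vals[interior_empty] = np.interp(
            centers[interior_empty], centers[occ_idx], vals[occ_idx]
        )
    vals = vals[first : last + 1]
    centers = centers[first : last + 1]
    counts = counts[first : last + 1]
    lam_weight = lam_weight[first : last + 1]

    smoothed = _moving_average(vals, smooth_window)
    n = len(smoothed)
    minima = [
        i
        for i in range(n)
        if (i == 0 or smoothed[i] <= smoothed[i - 1])
        and (i == n - 1 or smoothed[i] <= smoothed[i + 1])
    ]
    if len(minima) < 2 or minima[0] == minima[-1]:
        raise ValueError("could not locate two basins in the gap profile")
    left, right = minima[0], minima[-1]
    ts = left + int(np.argmax(smoothed[left : right + 1]))
    if ts in (left, right):
        raise ValueError("transition state coincides with a basin; no barrier")

    # orient: the basin dominated by low-lambda windows is the reactant side
    def mean_lambda(sl: slice) -> float:
        c = counts[sl].sum()
        return float(lam_weight[sl].sum() / c) if c > 0 else np.inf

    left_lam = mean_lambda(slice(0, ts))
    right_lam = mean_lambda(slice(ts + 1, n))
    if left_lam <= right_lam:
        rs_side, ps_side = slice(0, ts), slice(ts + 1, n)
    else:
        rs_side, ps_side = slice(ts + 1, n), slice(0, ts)
    rs = rs_side.start + int(np.argmin(vals[rs_side]))
    ps = ps_side.start + int(np.argmin(vals[ps_side]))

    shift = vals[rs]
    dg = vals - shift
    return FreeEnergyProfile(
        bin_centers=centers,
        dg=dg,
        counts=counts,
        dg_act=float(dg[ts]),
        dg_rxn=float(dg[ps]),
        rs_bin=rs,
        ts_bin=ts,
        ps_bin=ps,
        metadata={
            "n_bins": n_bins,
            "trim": trim,
            "smooth_window": smooth_window,
            "h12": series.h12,
            "temperature": series.temperature,
        },
    )


# ---------------------------------------------------------------------------
# Replicate statistics
# ---------------------------------------------------------------------------

def barrier_stats(replicates: dict[str, list[float]]) -> pd.DataFrame:
    """Mean +/- SEM of replicate barriers per system."""
    rows = []
    for system, values in replicates.items():
        v = np.asarray(values, float)
        if v.size < 2:
            raise ValueError(f"system {system!r}: need >= 2 replicates for statistics")
        rows.append((system, v.mean(), v.std(ddof=1) / np.sqrt(v.size), v.size))
    return pd.DataFrame(rows, columns=["system", "mean", "sem", "n"]).set_index("system")


@dataclass
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, p_value, stars
    group_sd: dict[str, float]

    def stars_for(self, a: str, b: str) -> str:
        t = self.pairwise
        hit = t[((t.group_a == a) & (t.group_b == b)) | ((t.group_a == b) & (t.group_b == a))]
        return str(hit["stars"].iloc[0]) if len(hit) else ""


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def anova_tukey(replicates: dict[str, list[float]]) -> AnovaTukeyResult:
    """One-way ANOVA across systems followed by Tukey HSD on all pairs.

    Unequal group variances are not an error; per-group SDs are reported so
    the caller can judge homogeneity.  Significance stars follow the usual
    convention (* p<0.05, ** p<0.01).
    """
    names = list(replicates.keys())
    if len(names) < 2:
        raise ValueError("need at least 2 systems")
    groups = []
    for name in names:
        v = np.asarray(replicates[name], float)
        if v.size < 2:
            raise ValueError(f"system {name!r}: need >= 2 replicates")
        groups.append(v)
    f_stat, p = stats.f_oneway(*groups)
    if np.allclose([g.var(ddof=1) for g in groups], 0) and np.allclose(
        [g.mean() for g in groups], groups[0].mean()
    ):
        f_stat, p = 0.0, 1.0
    tk = stats.tukey_hsd(*groups)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pv = float(tk.pvalue[i, j])
            rows.append((names[i], names[j], pv, _stars(pv)))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "p_value", "stars"])
    group_sd = {n: float(g.std(ddof=1)) for n, g in zip(names, groups)}
    return AnovaTukeyResult(float(f_stat), float(p), pairwise, group_sd)


def tst_barrier(kcat: float, temperature: float) -> float:
    """Activation free energy from a rate constant via transition state theory.

    dG_act = RT ln(k_B T / (h kcat)), transmission coefficient 1, in kcal/mol
    for kcat in 1/s and temperature in K.
    """
    if kcat <= 0 or temperature <= 0:
        raise ValueError("kcat and temperature must be positive")
    rt = KCAL_PER_MOL_K * temperature
    prefactor = BOLTZMANN_SI * temperature / PLANCK_SI
    return rt * np.log(prefactor / kcat)


# ---------------------------------------------------------------------------
# Reactive-geometry clustering
# ---------------------------------------------------------------------------

def cluster_reactive_geometries(
    frames: np.ndarray,
    n_clusters: int | None = None,
    distance_cutoff: float | None = None,
    linkage_method: str = "average",
) -> tuple[np.ndarray, dict[int, int]]:
    """Hierarchical agglomerative clustering of reacting-atom geometries.

    ``frames`` is (n_frames, n_atoms, 3) over the selected (heavy) atoms.
    Frames are superposed before the pairwise-RMSD matrix is built; clusters
    come from average-linkage (default) agglomeration cut either at
    ``n_clusters`` or at an RMSD ``distance_cutoff``.  Exactly one of the two
    must be given.  Returns 0-based labels (relabelled in order of first
    appearance) and a representative frame per cluster: the medoid (frame with
    the smallest mean RMSD to its cluster mates).
    """
    frames = np.asarray(frames, float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need at least 2 frames of shape (n_frames, n_atoms, 3)")
    if (n_clusters is None) == (distance_cutoff is None):
        raise ValueError("give exactly one of n_clusters or distance_cutoff")
    n = frames.shape[0]
    fitted = superpose_frames(frames, iterations=1)
    flat = fitted.reshape(n, -1)
    # pairwise RMSD: condensed distance vector
    sq = np.sum((flat[:, None, :] - flat[None, :, :]) ** 2, axis=2) / frames.shape[1]
    rmsd = np.sqrt(np.clip(sq, 0, None))
    iu = np.triu_indices(n, 1)
    condensed = rmsd[iu]
    z = linkage(condensed, method=linkage_method)
    if n_clusters is not None:
        raw = fcluster(z, t=min(n_clusters, n), criterion="maxclust")
    else:
        raw = fcluster(z, t=distance_cutoff, criterion="distance")
    labels = np.empty(n, int)
    mapping: dict[int, int] = {}
    for idx, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping)
        labels[idx] = mapping[r]
    representatives: dict[int, int] = {}
    for lab in range(len(mapping)):
        members = np.flatnonzero(labels == lab)
        sub = rmsd[np.ix_(members, members)]
        representatives[lab] = int(members[np.argmin(sub.mean(axis=1))])
    return labels, representatives
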