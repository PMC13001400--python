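"""Per-frame WPD-loop metrics and conformational landscapes.

The loop-mobility landscape places every frame in a 2D space of (i) distance
RMSD of all WPD-loop/P-loop Calpha pair distances against a closed reference
structure and (ii) the distance between the WPD- and P-loop centers of mass.
Both metrics depend only on internal distances (no superposition), so they are
invariant under rigid-body motion of a frame.

Reactive-conformation filtering applies strict distance cutoffs on active-site
atom pairs — by default the general-acid aspartate oxygen and the Q-loop
glutamine carbon relative to the phospho-cysteine phosphorus, at 4.5 A and
8 A respectively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ptpdyn.ensemble import CoordinateEnsemble, LoopDefinition, select_loop
from ptpdyn.sequences import AlignmentMap
from ptpdyn.superpose import superpose_frames


# ---------------------------------------------------------------------------
# dRMSD
# ---------------------------------------------------------------------------

@dataclass
class ReferenceDistanceSet:
    """Fixed cross-loop Calpha-Calpha distances from a closed reference.

    ``pairs`` holds (WPD residue id, P residue id) in the reference protein's
    numbering; ``d_ref`` the corresponding distances in the single reference
    frame.
    """

    pairs: list[tuple[int, int]]
    d_ref: np.ndarray
    source: str = ""
    aggregate: str = "root_mean"  # recorded so outputs are self-describing

    def __post_init__(self) -> None:
        self.d_ref = np.asarray(self.d_ref, float)
        if len(self.pairs) != len(self.d_ref):
            raise ValueError("one reference distance per pair required")
        if np.any(self.d_ref <= 0):
            raise ValueError("reference distances must be > 0")


def _ca_index_by_residue(ensemble: CoordinateEnsemble, loop: LoopDefinition) -> dict[int, int]:
    idx = select_loop(ensemble, loop, mode="ca")
    rids = ensemble.atoms["res_id"].to_numpy()[idx]
    return dict(zip(rids.tolist(), idx.tolist()))


def build_reference(
    reference: CoordinateEnsemble,
    wpd_loop: LoopDefinition,
    p_loop: LoopDefinition,
    include_intra_loop: bool = False,
    frame: int = 0,
    source: str = "",
) -> ReferenceDistanceSet:
    """Reference distance set from a closed structure.

    By default the pair list is the full WPD x P cross product of Calpha
    atoms.  ``include_intra_loop=True`` additionally adds all pairs within the
    union of the two loops (the alternative reading of "all combined"
    distances).
    """
    wpd_map = _ca_index_by_residue(reference, wpd_loop)
    p_map = _ca_index_by_residue(reference, p_loop)
    pairs = [(w, p) for w in wpd_loop.residue_ids for p in p_loop.residue_ids]
    if include_intra_loop:
        union = sorted(set(wpd_loop.residue_ids) | set(p_loop.residue_ids))
        extra = [
            (a, b)
            for i, a in enumerate(union)
            for b in union[i + 1 :]
            if (a, b) not in set(pairs)
        ]
        pairs = pairs + extra
    index = {**p_map, **wpd_map}
    coords = reference.coords[frame]
    d_ref = np.array(
        [np.linalg.norm(coords[index[a]] - coords[index[b]]) for a, b in pairs]
    )
    if np.any(d_ref <= 0):
        bad = [pairs[i] for i in np.flatnonzero(d_ref <= 0)]
        raise ValueError(f"coincident reference atoms for pairs {bad}")
    return ReferenceDistanceSet(pairs, d_ref, source=source)


def compute_drmsd(
    ensemble: CoordinateEnsemble,
    reference: ReferenceDistanceSet,
    alignment_map: AlignmentMap | None = None,
) -> np.ndarray:
    """Per-frame distance RMSD against the reference distance set.

    dRMSD_t = sqrt( mean over pairs of (d_pair(t) - d_ref)^2 ).  When the
    trajectory protein differs from the reference protein, residue ids are
    mapped through ``alignment_map`` (reference residues on the A side); any
    unmapped pair aborts rather than silently shrinking the pair count, which
    would change the metric's scale.
    """
    if alignment_map is not None:
        mapping = alignment_map.a_to_b()
    else:
        mapping = None
    atoms = ensemble.atoms
    ca = (atoms["atom_name"].to_numpy() == "CA")
    rid_to_idx: dict[int, int] = {}
    for i in np.flatnonzero(ca):
        rid_to_idx.setdefault(int(atoms["res_id"].iloc[i]), int(i))

    idx_a, idx_b, unmapped = [], [], []
    for a, b in reference.pairs:
        ma = mapping.get(a) if mapping is not None else a
        mb = mapping.get(b) if mapping is not None else b
        if ma is None or mb is None or ma not in rid_to_idx or mb not in rid_to_idx:
            unmapped.append((a, b))
            continue
        idx_a.append(rid_to_idx[ma])
        idx_b.append(rid_to_idx[mb])
    if unmapped:
        raise KeyError(
            f"{len(unmapped)} reference pair(s) cannot be mapped onto the "
            f"trajectory protein: {unmapped[:10]}"
        )
    diff = ensemble.coords[:, idx_a] - ensemble.coords[:, idx_b]
    d = np.linalg.norm(diff, axis=2)
    return np.sqrt(np.mean((d - reference.d_ref[None, :]) ** 2, axis=1))


def compute_com_distance(
    ensemble: CoordinateEnsemble,
    loop_a: LoopDefinition,
    loop_b: LoopDefinition,
    mass_weighted: bool = True,
    mode: str = "heavy",
) -> np.ndarray:
    """Per-frame distance between loop centers of mass (Angstrom)."""
    ia = select_loop(ensemble, loop_a, mode=mode)
    ib = select_loop(ensemble, loop_b, mode=mode)
    masses = ensemble.atoms["mass"].to_numpy()

    def com(indices: np.ndarray) -> np.ndarray:
        w = masses[indices] if mass_weighted else np.ones(len(indices))
        if w.sum() <= 0:
            w = np.ones(len(indices))
        return (ensemble.coords[:, indices] * w[None, :, None]).sum(1) / w.sum()

    return np.linalg.norm(com(ia) - com(ib), axis=1)


# ---------------------------------------------------------------------------
# Landscape histograms and state classification
# ---------------------------------------------------------------------------

@dataclass
class LandscapeHistogram:
    """2D occupancy histogram over (dRMSD, COM distance)."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    anchors: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format (x_center, y_center, count) table."""
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        xx, yy = np.meshgrid(xc, yc, indexing="ij")
        return pd.DataFrame(
            {"drmsd": xx.ravel(), "com_distance": yy.ravel(), "count": self.counts.ravel()}
        )


def anchor_point(
    reference: CoordinateEnsemble,
    ref_distances: ReferenceDistanceSet,
    wpd_loop: LoopDefinition,
    p_loop: LoopDefinition,
    alignment_map: AlignmentMap | None = None,
) -> tuple[float, float]:
    """(dRMSD, COM distance) of a reference structure under the same metrics."""
    d = compute_drmsd(reference, ref_distances, alignment_map)
    c = compute_com_distance(reference, wpd_loop, p_loop)
    return float(d[0]), float(c[0])


def build_landscape(
    drmsd: np.ndarray,
    com: np.ndarray,
    bins=50,
    anchors: dict[str, tuple[float, float]] | None = None,
) -> LandscapeHistogram:
    """Bin per-frame metrics into a 2D landscape histogram.

    ``bins`` follows numpy.histogram2d semantics (int, (int, int), or explicit
    edge arrays).  Every frame must land in a bin: explicit edges that exclude
    data are an error, automatic edges always cover it.
    """
    drmsd = np.asarray(drmsd, float)
    com = np.asarray(com, float)
    if drmsd.shape != com.shape:
        raise ValueError(f"series length mismatch: {drmsd.shape} vs {com.shape}")
    anchors = dict(anchors or {})
    if drmsd.size == 0:
        edges = np.linspace(0.0, 1.0, 2)
        return LandscapeHistogram(edges, edges.copy(), np.zeros((1, 1)), anchors)
    counts, x_edges, y_edges = np.histogram2d(drmsd, com, bins=bins)
    if int(counts.sum()) != drmsd.size:
        raise ValueError("provided bin edges do not cover all frames")
    return LandscapeHistogram(x_edges, y_edges, counts, anchors)


def classify_states(
    drmsd: np.ndarray,
    com: np.ndarray,
    anchors: dict[str, tuple[float, float]],
    r_closed: float | None = None,
    r_open: float | None = None,
) -> np.ndarray:
    """Per-frame label in {closed, semi_closed, open}.

    Both metric axes are normalized by the inter-anchor span so the two anchors
    are unit-separated per axis; a frame within ``r_closed`` of the closed
    anchor (default 25% of the inter-anchor distance in that space) is closed,
    within ``r_open`` of the open anchor is open, otherwise semi_closed.
    Frames inside both radii resolve to the nearer anchor.
    """
    for key in ("closed", "open"):
        if key not in anchors:
            raise KeyError(f"anchors must provide the {key!r} reference point")
    xc, yc = anchors["closed"]
    xo, yo = anchors["open"]
    sx = abs(xo - xc) or 1.0
    sy = abs(yo - yc) or 1.0
    pts = np.column_stack([np.asarray(drmsd, float) / sx, np.asarray(com, float) / sy])
    a_closed = np.array([xc / sx, yc / sy])
    a_open = np.array([xo / sx, yo / sy])
    d_anchor = np.linalg.norm(a_open - a_closed)
    if d_anchor == 0:
        raise ValueError("open and closed anchors coincide")
    if r_closed is None:
        r_closed = 0.25 * d_anchor
    if r_open is None:
        r_open = 0.25 * d_anchor
    dc = np.linalg.norm(pts - a_closed, axis=1)
    do = np.linalg.norm(pts - a_open, axis=1)
    labels = np.full(len(pts), "semi_closed", dtype="U11")
    in_c = dc < r_closed
    in_o = do < r_open
    both = in_c & in_o
    labels[in_c & ~both] = "closed"
    labels[in_o & ~both] = "open"
    labels[both] = np.where(dc[both] <= do[both], "closed", "open")
    return labels


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------

@dataclass
class RMSFProfile:
    residue_ids: np.ndarray
    values: np.ndarray
    reference: str = "ensemble average"

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, int)
        self.values = np.asarray(self.values, float)
        if self.residue_ids.shape != self.values.shape:
            raise ValueError("one RMSF value per residue required")
        if np.any(self.values < -1e-12):
            raise ValueError("RMSF values must be non-negative")


def compute_rmsf(
    ensemble: CoordinateEnsemble,
    align: bool = True,
    fit_selection: LoopDefinition | None = None,
    iterations: int = 2,
) -> RMSFProfile:
    """Per-residue Calpha RMSF about the ensemble mean.

    RMSF_i = sqrt(<|r_i(t) - <r_i>|^2>), computed after optional least-squares
    superposition of every frame onto the iterated average structure.  The fit
    uses the whole Calpha set unless ``fit_selection`` restricts it.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    ca = ensemble.ca_indices()
    if ca.size == 0:
        raise ValueError("no CA atoms in ensemble")
    coords = ensemble.coords
    if align:
        fit_idx = ca
        if fit_selection is not None:
            fit_idx = select_loop(ensemble, fit_selection, mode="ca")
        coords = superpose_frames(coords, fit_indices=fit_idx, iterations=iterations)
    sub = coords[:, ca]
    mean = sub.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((sub - mean) ** 2, axis=2), axis=0))
    rids = ensemble.atoms["res_id"].to_numpy()[ca]
    ref = f"iterated average ({iterations} pass)" if align else "no superposition"
    return RMSFProfile(rids, rmsf, reference=ref)


def delta_rmsf(
    a: RMSFProfile,
    b: RMSFProfile,
    alignment_map: AlignmentMap | None = None,
) -> pd.DataFrame:
    """Per-residue RMSF(a) - RMSF(b); positive means more flexibility in a.

    Residues are matched by id, or through ``alignment_map`` (a on the A side)
    when the two profiles use different numbering.  Unmatched residues are
    dropped with a warning.
    """
    vals_b = dict(zip(b.residue_ids.tolist(), b.values.tolist()))
    mapping = alignment_map.a_to_b() if alignment_map is not None else None
    rows = []
    skipped = 0
    for rid, val in zip(a.residue_ids.tolist(), a.values.tolist()):
        partner = mapping.get(rid, None) if mapping is not None else rid
        if partner is None or partner not in vals_b:
            skipped += 1
            continue
        rows.append((rid, partner, val - vals_b[partner]))
    if skipped:
        warnings.warn(f"{skipped} residue(s) had no partner and were dropped", stacklevel=2)
    return pd.DataFrame(rows, columns=["res_id_a", "res_id_b", "delta_rmsf"])


# ---------------------------------------------------------------------------
# Reactive-conformation filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomSpec:
    res_id: int
    atom_name: str
    chain_id: str | None = None

    def __str__(self) -> str:
        chain = f"{self.chain_id}:" if self.chain_id else ""
        return f"{chain}{self.res_id}:{self.atom_name}"


@dataclass
class ReactiveCriteria:
    """Strict distance constraints defining a catalytically productive frame.

    A frame is productive iff every (atom A, atom B, max distance) constraint
    holds with strict inequality.
    """

    constraints: list[tuple[AtomSpec, AtomSpec, float]]

    def __post_init__(self) -> None:
        if not self.constraints:
            raise ValueError("at least one distance constraint required")
        for a, b, dmax in self.constraints:
            if dmax <= 0:
                raise ValueError(f"constraint {a}-{b}: max distance must be > 0")


def default_reactive_criteria(
    asp_res: int = 419,
    cys_res: int = 453,
    gln_res: int = 500,
    asp_atom: str = "OD1",
    phosphorus_atom: str = "P",
    gln_atom: str = "CD",
    asp_cutoff: float = 4.5,
    gln_cutoff: float = 8.0,
) -> ReactiveCriteria:
    """Default productive-snapshot criteria for the PTP hydrolysis step.

    General-acid aspartate oxygen within 4.5 A of the phospho-cysteine
    phosphorus, and Q-loop glutamine side-chain carbon within 8 A of the same
    phosphorus (residue numbers default to SHP-1 numbering: Asp419, pCys453,
    Gln500).
    """
    return ReactiveCriteria(
        [
            (AtomSpec(asp_res, asp_atom), AtomSpec(cys_res, phosphorus_atom), asp_cutoff),
            (AtomSpec(gln_res, gln_atom), AtomSpec(cys_res, phosphorus_atom), gln_cutoff),
        ]
    )


def _resolve_atom(ensemble: CoordinateEnsemble, spec: AtomSpec) -> int:
    atoms = ensemble.atoms
    mask = (atoms["res_id"].to_numpy() == spec.res_id) & (
        atoms["atom_name"].to_numpy() == spec.atom_name
    )
    if spec.chain_id is not None:
        mask &= atoms["chain_id"].to_numpy() == spec.chain_id
    hits = np.flatnonzero(mask)
    if hits.size == 0:
        raise KeyError(f"atom spec {spec} not present in the structure")
    return int(hits[0])


def reactive_fraction(
    ensemble: CoordinateEnsemble,
    criteria: ReactiveCriteria,
) -> tuple[float, np.ndarray]:
    """Fraction of frames satisfying all criteria, plus their frame indices."""
    passes = np.ones(ensemble.n_frames, dtype=bool)
    for spec_a, spec_b, dmax in criteria.constraints:
        ia = _resolve_atom(ensemble, spec_a)
        ib = _resolve_atom(ensemble, spec_b)
        d = np.linalg.norm(ensemble.coords[:, ia] - ensemble.coords[:, ib], axis=1)
        passes &= d < dmax
    indices = np.flatnonzero(passes)
    return float(indices.size / max(ensemble.n_frames, 1)), indices
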