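"""Dynamic cross-correlation maps and dominant-mode analysis.

The DCCM entry for residues i, j is the normalized scalar product of their
Calpha displacement vectors,

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>),

computed after (optional) superposition of all frames onto the average
structure so rigid-body drift does not inflate correlations.  Multi-replica
data is concatenated after independent superposition to the common average.
Restriction to structurally conserved regions shared by several proteins keeps
only positions mapped in every protein, so maps of different PTPs are
comparable entry by entry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ptpdyn.ensemble import CoordinateEnsemble
from ptpdyn.sequences import AlignmentMap
from ptpdyn.superpose import kabsch_fit, superpose_frames


@dataclass
class CorrelationMap:
    """Residue x residue normalized cross-correlation matrix."""

    residue_ids: np.ndarray
    matrix: np.ndarray
    n_frames: int
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, int)
        self.matrix = np.asarray(self.matrix, float)
        n = len(self.residue_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match residue id count")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 1.0, atol=1e-10):
            raise ValueError("correlation matrix diagonal must be 1")
        if np.any(np.abs(self.matrix) > 1.0 + 1e-10):
            raise ValueError("correlation entries must lie in [-1, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.residue_ids, columns=self.residue_ids)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="res_id")

    @classmethod
    def from_csv(cls, path) -> "CorrelationMap":
        df = pd.read_csv(path, index_col=0)
        return cls(df.index.to_numpy(int), df.to_numpy(float), n_frames=0)


def compute_dccm(
    ensembles,
    superpose: bool = True,
    iterations: int = 2,
) -> CorrelationMap:
    """DCCM over Calpha atoms of one ensemble or a list of replicas.

    Replicas must share the atom table; each is superposed independently onto
    the common average before displacement vectors are pooled.  A residue with
    zero displacement variance gets zero off-diagonal correlation (diagonal
    kept at 1) with a warning.
    """
    if isinstance(ensembles, CoordinateEnsemble):
        ensembles = [ensembles]
    if not ensembles:
        raise ValueError("at least one ensemble required")
    first = ensembles[0]
    ca = first.ca_indices()
    if ca.size == 0:
        raise ValueError("no CA atoms")
    rids = first.atoms["res_id"].to_numpy()[ca]
    blocks = []
    for ens in ensembles:
        if ens.n_atoms != first.n_atoms:
            raise ValueError("replicas must share the atom table")
        blocks.append(ens.coords[:, ca])
    total_frames = sum(b.shape[0] for b in blocks)
    if total_frames < 2:
        raise ValueError("DCCM requires at least 2 frames")
    if superpose:
        # iterate (fit all frames onto shared average, recompute average)
        common_mean = np.concatenate(blocks).mean(axis=0)
        for _ in range(max(1, iterations)):
            blocks = [
                np.stack([kabsch_fit(frame, common_mean) for frame in b]) for b in blocks
            ]
            common_mean = np.concatenate(blocks).mean(axis=0)
    coords = np.concatenate(blocks)
    disp = coords - coords.mean(axis=0)
    n_res = len(ca)
    dots = np.einsum("tix,tjx->ij", disp, disp) / coords.shape[0]
    var = np.diag(dots).copy()
    zero = var <= 1e-15
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} residue(s) have zero displacement variance; "
            "their correlations are set to 0",
            stacklevel=2,
        )
        var[zero] = 1.0
    denom = np.sqrt(np.outer(var, var))
    c = dots / denom
    c[zero, :] = 0.0
    c[:, zero] = 0.0
    np.fill_diagonal(c, 1.0)
    c = np.clip(0.5 * (c + c.T), -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return CorrelationMap(rids, c, n_frames=coords.shape[0])


def restrict_common(
    maps: dict[str, CorrelationMap],
    alignment_maps: dict[str, AlignmentMap],
    anchor: str,
) -> tuple[dict[str, CorrelationMap], np.ndarray]:
    """Subset every protein's DCCM to positions shared by all proteins.

    ``alignment_maps[p]`` maps anchor residues (A side) to protein ``p``.  The
    anchor itself needs no map.  Output rows/columns follow anchor order; the
    retained anchor residue ids are returned explicitly because the edges of
    the restricted map are not the protein termini.
    """
    if anchor not in maps:
        raise KeyError(f"anchor protein {anchor!r} missing from maps")
    anchor_ids = [int(r) for r in maps[anchor].residue_ids]
    keep = []
    for rid in anchor_ids:
        ok = True
        for name, cmap in maps.items():
            if name == anchor:
                continue
            amap = alignment_maps.get(name)
            if amap is None:
                raise KeyError(f"no alignment map for protein {name!r}")
            partner = amap.a_to_b().get(rid)
            if partner is None or partner not in set(cmap.residue_ids.tolist()):
                ok = False
                break
        if ok:
            keep.append(rid)
    if not keep:
        raise ValueError("no positions are shared by all proteins")
    out: dict[str, CorrelationMap] = {}
    for name, cmap in maps.items():
        if name == anchor:
            ids = keep
        else:
            a2b = alignment_maps[name].a_to_b()
            ids = [a2b[r] for r in keep]
        pos = {int(r): k for k, r in enumerate(cmap.residue_ids)}
        sel = np.array([pos[r] for r in ids], int)
        sub = cmap.matrix[np.ix_(sel, sel)]
        out[name] = CorrelationMap(np.asarray(ids), sub, cmap.n_frames)
    return out, np.asarray(keep, int)


@dataclass
class ModeSet:
    """Principal modes of the Calpha displacement covariance."""

    eigenvalues: np.ndarray          # A^2, descending
    eigenvectors: np.ndarray         # (3N, k), orthonormal columns
    residue_ids: np.ndarray
    cumulative_variance: np.ndarray = field(init=False)
    total_variance: float = 0.0

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, float)
        if np.any(self.eigenvalues < -1e-8):
            raise ValueError("negative eigenvalue in mode set")
        gram = self.eigenvectors.T @ self.eigenvectors
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-6):
            raise ValueError("eigenvectors must be orthonormal")
        total = self.total_variance if self.total_variance > 0 else self.eigenvalues.sum()
        csum = np.cumsum(np.clip(self.eigenvalues, 0, None))
        self.cumulative_variance = csum / total if total > 0 else np.zeros_like(csum)


def dominant_modes(
    ensemble: CoordinateEnsemble,
    k: int = 3,
    superpose: bool = True,
) -> tuple[ModeSet, np.ndarray]:
    """Top-k principal modes of Calpha motion and per-frame projections.

    Sign convention: each eigenvector's largest-magnitude component is made
    positive, so modes are deterministic across eigensolvers.
    """
    ca = ensemble.ca_indices()
    coords = ensemble.coords[:, ca]
    n_frames, n_atoms, _ = coords.shape
    if n_frames < 2:
        raise ValueError("mode analysis requires at least 2 frames")
    if n_frames <= 3 * n_atoms:
        warnings.warn(
            f"only {n_frames} frames for {3 * n_atoms} degrees of freedom; "
            "mode estimates will be rank-deficient",
            stacklevel=2,
        )
    if superpose:
        coords = superpose_frames(coords)
    disp = (coords - coords.mean(axis=0)).reshape(n_frames, 3 * n_atoms)
    cov = disp.T @ disp / n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int(np.sum(evals > max(evals.max(), 0) * 1e-12)) if evals.size else 0
    if k > rank:
        warnings.warn(f"requested {k} modes but covariance rank is {rank}; truncating",
                      stacklevel=2)
        k = max(rank, 1)
    evals_k, evecs_k = np.clip(evals[:k], 0, None), evecs[:, :k]
    for m in range(k):
        lead = np.argmax(np.abs(evecs_k[:, m]))
        if evecs_k[lead, m] < 0:
            evecs_k[:, m] *= -1
    rids = ensemble.atoms["res_id"].to_numpy()[ca]
    modes = ModeSet(evals_k, evecs_k, rids, total_variance=float(np.trace(cov)))
    projections = disp @ evecs_k
    return modes, projections
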