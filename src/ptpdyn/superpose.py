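"""Least-squares rigid-body superposition (Kabsch) helpers."""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray, weights=None) -> np.ndarray:
    """Superpose one frame onto a reference, minimizing (weighted) RMSD.

    Parameters
    ----------
    mobile, reference : ndarray, shape (n_atoms, 3)
    weights : ndarray, optional
        Per-atom weights (e.g. masses); uniform when omitted.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if weights is None:
        weights = np.ones(len(mobile))
    weights = np.asarray(weights, float)
    wsum = weights.sum()
    com_m = (weights[:, None] * mobile).sum(0) / wsum
    com_r = (weights[:, None] * reference).sum(0) / wsum
    mc = mobile - com_m
    rc = reference - com_r
    rot, _ = Rotation.align_vectors(rc, mc, weights=weights)
    return rot.apply(mc) + com_r


def superpose_frames(
    coords: np.ndarray,
    weights=None,
    fit_indices=None,
    iterations: int = 2,
) -> np.ndarray:
    """Superpose every frame onto the iterated average structure.

    The fit is computed on ``fit_indices`` (default: all atoms) but applied to
    the whole frame.  Two iterations of (average, refit) are standard practice;
    ``iterations=1`` is a single pass onto the plain mean.
    """
    coords = np.asarray(coords, float)
    n_frames, n_atoms, _ = coords.shape
    if fit_indices is None:
        fit_indices = np.arange(n_atoms)
    fit_indices = np.asarray(fit_indices, int)
    w = None if weights is None else np.asarray(weights, float)[fit_indices]
    out = coords.copy()
    reference = out[:, fit_indices].mean(axis=0)
    for _ in range(max(1, iterations)):
        for f in range(n_frames):
            sub = out[f, fit_indices]
            if w is None:
                wts = np.ones(len(fit_indices))
            else:
                wts = w
            wsum = wts.sum()
            com_m = (wts[:, None] * sub).sum(0) / wsum
            com_r = (wts[:, None] * reference).sum(0) / wsum
            rot, _ = Rotation.align_vectors(reference - com_r, sub - com_m, weights=wts)
            out[f] = rot.apply(out[f] - com_m) + com_r
        reference = out[:, fit_indices].mean(axis=0)
    return out


def random_rigid_transform(rng: np.random.Generator, max_translation: float = 50.0):
    """Random rotation + translation, for invariance tests."""
    rot = Rotation.random(random_state=rng)
    trans = rng.uniform(-max_translation, max_translation, size=3)
    return lambda xyz: rot.apply(xyz) + trans
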