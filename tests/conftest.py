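import numpy as np
import pytest

from ptpdyn.ensemble import ensemble_from_arrays
from ptpdyn.synthetic import HarmonicDiabatSpec, TwoStateLoopSpec


def straight_chain(n_res: int, spacing: float = 3.8) -> np.ndarray:
    """Calpha bead chain along x."""
    return np.column_stack(
        [np.arange(n_res) * spacing, np.zeros(n_res), np.zeros(n_res)]
    )


@pytest.fixture
def two_state_spec() -> TwoStateLoopSpec:
    closed = straight_chain(8)
    open_ = closed.copy()
    open_[:4, 1] += 6.0  # displace the WPD half only (rigid shifts are invisible)
    return TwoStateLoopSpec(
        open_coordinates=open_,
        closed_coordinates=closed,
        occupancy_closed=0.7,
        mean_dwell=25,
        jitter_sd=0.25,
        n_frames=10_000,
        seed=11,
    )


@pytest.fixture
def evb_spec() -> HarmonicDiabatSpec:
    return HarmonicDiabatSpec(
        k_force=100.0,
        x1=0.0,
        x2=1.0,
        dG0=-2.0,
        H12=1.0,
        temperature=300.0,
        lambdas=np.linspace(0.0, 1.0, 51),
        frames_per_window=2000,
        seed=5,
    )


def tripeptide_pdb(path) -> str:
    """Gly-Ala-Ser toy structure with full heavy-atom complements (4+5+6)."""
    atoms = [
        # res_id, res_name, atom_name, x, y, z
        (1, "GLY", "N", 0.0, 0.0, 0.0),
        (1, "GLY", "CA", 1.5, 0.0, 0.0),
        (1, "GLY", "C", 2.2, 1.3, 0.0),
        (1, "GLY", "O", 1.6, 2.4, 0.0),
        (2, "ALA", "N", 3.5, 1.3, 0.0),
        (2, "ALA", "CA", 4.3, 2.5, 0.0),
        (2, "ALA", "CB", 5.1, 2.5, 1.3),
        (2, "ALA", "C", 5.2, 2.6, -1.2),
        (2, "ALA", "O", 5.0, 1.9, -2.2),
        (3, "SER", "N", 6.2, 3.5, -1.2),
        (3, "SER", "CA", 7.2, 3.7, -2.3),
        (3, "SER", "CB", 8.3, 4.7, -1.9),
        (3, "SER", "OG", 9.1, 4.2, -0.9),
        (3, "SER", "C", 7.9, 2.4, -2.8),
        (3, "SER", "O", 7.8, 1.3, -2.2),
    ]
    lines = []
    for serial, (rid, rname, aname, x, y, z) in enumerate(atoms, start=1):
        lines.append(
            f"ATOM  {serial:5d} {aname:<4s} {rname:>3s} A{rid:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{aname[0]:>2s}"
        )
    lines.append("END")
    text = "\n".join(lines) + "\n"
    path.write_text(text)
    return text


@pytest.fixture
def tripeptide_path(tmp_path):
    p = tmp_path / "tripeptide.pdb"
    tripeptide_pdb(p)
    return p


def bead_ensemble(coords: np.ndarray, res_ids=None):
    coords = np.asarray(coords, float)
    n = coords.shape[-2]
    if res_ids is None:
        res_ids = np.arange(1, n + 1)
    return ensemble_from_arrays(coords, res_ids=res_ids)
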