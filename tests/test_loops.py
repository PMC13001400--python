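import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptpdyn.ensemble import LoopDefinition
from ptpdyn.loops import (
    AtomSpec,
    ReactiveCriteria,
    ReferenceDistanceSet,
    anchor_point,
    build_landscape,
    build_reference,
    classify_states,
    compute_com_distance,
    compute_drmsd,
    compute_rmsf,
    default_reactive_criteria,
    delta_rmsf,
    reactive_fraction,
)
from ptpdyn.sequences import AlignmentMap
from ptpdyn.superpose import random_rigid_transform
from ptpdyn.synthetic import (
    GaussianEnsembleSpec,
    diagonal_covariance,
    gen_gaussian_ensemble,
)

from conftest import bead_ensemble, straight_chain

WPD = LoopDefinition.from_range("WPD", 1, 3)
PLOOP = LoopDefinition.from_range("P", 6, 8)


def reference_chain():
    return bead_ensemble(straight_chain(8)[None])


class TestDRMSD:
    def test_zero_against_itself(self):
        ref = reference_chain()
        dists = build_reference(ref, WPD, PLOOP)
        assert len(dists.pairs) == 9
        assert compute_drmsd(ref, dists)[0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_single_pair(self):
        # single WPD residue vs single P residue: dRMSD = |d - d_ref|
        ref = ReferenceDistanceSet([(1, 2)], [2.0])
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 3.0
        assert compute_drmsd(bead_ensemble(coords), ref)[0] == pytest.approx(1.0)

    def test_hand_computed_two_pairs(self):
        # deviations 1 and 0 over two pairs -> sqrt(1/2)
        ref = ReferenceDistanceSet([(1, 2), (1, 3)], [2.0, 5.0])
        coords = np.zeros((1, 3, 3))
        coords[0, 1, 0] = 3.0
        coords[0, 2, 0] = 5.0
        val = compute_drmsd(bead_ensemble(coords), ref)[0]
        assert val == pytest.approx(np.sqrt(0.5))

    def test_rigid_motion_invariance(self):
        ref = reference_chain()
        dists = build_reference(ref, WPD, PLOOP)
        rng = np.random.default_rng(12)
        base = straight_chain(8) + rng.normal(0, 0.5, size=(8, 3))
        value = compute_drmsd(bead_ensemble(base[None]), dists)[0]
        for _ in range(100):
            moved = random_rigid_transform(rng)(base)
            assert compute_drmsd(bead_ensemble(moved[None]), dists)[0] == pytest.approx(
                value, abs=1e-9
            )

    def test_unmapped_pair_aborts(self):
        ref = reference_chain()
        dists = build_reference(ref, WPD, PLOOP)
        short = bead_ensemble(straight_chain(7)[None])  # residue 8 missing
        with pytest.raises(KeyError):
            compute_drmsd(short, dists)

    def test_alignment_map_renumbers(self):
        ref = reference_chain()
        dists = build_reference(ref, WPD, PLOOP)
        shifted = bead_ensemble(
            straight_chain(8)[None], res_ids=np.arange(101, 109)
        )
        amap = AlignmentMap([(i, i + 100) for i in range(1, 9)], 1.0)
        assert compute_drmsd(shifted, dists, amap)[0] == pytest.approx(0.0, abs=1e-12)

    def test_include_intra_loop_grows_pair_set(self):
        ref = reference_chain()
        full = build_reference(ref, WPD, PLOOP, include_intra_loop=True)
        # 9 cross pairs + C(6,2)=15 union pairs - 9 already present = 15 total
        assert len(full.pairs) == 15


class TestCOMDistance:
    def test_two_point_loops(self):
        coords = np.zeros((1, 2, 3))
        coords[0, 1] = [3.0, 4.0, 0.0]
        ens = bead_ensemble(coords)
        d = compute_com_distance(
            ens, LoopDefinition("a", [1]), LoopDefinition("b", [2]), mode="ca"
        )
        assert d[0] == pytest.approx(5.0)

    def test_unweighted_centroid(self):
        coords = np.zeros((1, 4, 3))
        coords[0, 1, 0] = 2.0   # loop a: x=0 and x=2 -> centroid x=1
        coords[0, 2, 0] = 10.0
        coords[0, 3, 0] = 12.0  # loop b centroid x=11
        ens = bead_ensemble(coords)
        d = compute_com_distance(
            ens,
            LoopDefinition("a", [1, 2]),
            LoopDefinition("b", [3, 4]),
            mass_weighted=False,
            mode="ca",
        )
        assert d[0] == pytest.approx(10.0)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(5)
        base = straight_chain(8)
        ens = bead_ensemble(base[None])
        la, lb = LoopDefinition("a", [1, 2]), LoopDefinition("b", [7, 8])
        val = compute_com_distance(ens, la, lb, mode="ca")[0]
        moved = random_rigid_transform(rng)(base)
        val2 = compute_com_distance(bead_ensemble(moved[None]), la, lb, mode="ca")[0]
        assert val2 == pytest.approx(val, abs=1e-9)


class TestLandscape:
    def test_counts_conserve_frames(self):
        rng = np.random.default_rng(0)
        d, c = rng.random(1000), rng.random(1000)
        hist = build_landscape(d, c, bins=20)
        assert hist.n_frames == 1000
        assert hist.to_dataframe()["count"].sum() == 1000

    def test_explicit_edges_must_cover(self):
        edges = np.linspace(0, 0.5, 5)
        with pytest.raises(ValueError, match="cover"):
            build_landscape(np.array([0.1, 0.9]), np.array([0.1, 0.2]),
                            bins=(edges, edges))

    def test_empty_series(self):
        hist = build_landscape(np.array([]), np.array([]))
        assert hist.n_frames == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            build_landscape(np.zeros(3), np.zeros(4))


class TestClassifyStates:
    ANCHORS = {"closed": (0.0, 10.0), "open": (4.0, 16.0)}

    def test_anchor_points_label_as_their_state(self):
        labels = classify_states(
            np.array([0.0, 4.0]), np.array([10.0, 16.0]), self.ANCHORS
        )
        assert list(labels) == ["closed", "open"]

    def test_midpoint_is_semi_closed(self):
        labels = classify_states(np.array([2.0]), np.array([13.0]), self.ANCHORS)
        assert labels[0] == "semi_closed"

    def test_explicit_radius_boundary_is_exclusive(self):
        # normalized anchor separation is sqrt(2); a point at exactly r_closed
        # from the closed anchor stays semi_closed (strict inequality)
        anchors = {"closed": (0.0, 0.0), "open": (1.0, 1.0)}
        labels = classify_states(
            np.array([0.5, 0.49]), np.array([0.0, 0.0]), anchors, r_closed=0.5, r_open=0.5
        )
        assert list(labels) == ["semi_closed", "closed"]

    def test_overlap_resolves_to_nearer_anchor(self):
        anchors = {"closed": (0.0, 0.0), "open": (1.0, 0.0)}
        labels = classify_states(
            np.array([0.4, 0.6]), np.array([0.0, 0.0]), anchors,
            r_closed=0.9, r_open=0.9,
        )
        assert list(labels) == ["closed", "open"]

    def test_missing_anchor_is_error(self):
        with pytest.raises(KeyError, match="open"):
            classify_states(np.zeros(1), np.zeros(1), {"closed": (0.0, 0.0)})

    def test_coincident_anchors_error(self):
        with pytest.raises(ValueError):
            classify_states(np.zeros(1), np.zeros(1),
                            {"closed": (1.0, 2.0), "open": (1.0, 2.0)})


class TestRMSF:
    def test_isotropic_gaussian_gives_sqrt3_sigma(self):
        sigma2 = 0.49
        spec = GaussianEnsembleSpec(
            straight_chain(5), diagonal_covariance(5, sigma2), 50_000, seed=21
        )
        ens = gen_gaussian_ensemble(spec)
        prof = compute_rmsf(ens, align=False)
        assert np.allclose(prof.values, np.sqrt(3 * sigma2), atol=0.02)

    def test_superposition_removes_rigid_drift(self):
        rng = np.random.default_rng(8)
        base = straight_chain(6)
        frames = []
        for _ in range(400):
            jittered = base + rng.normal(0, 0.3, base.shape)
            frames.append(random_rigid_transform(rng)(jittered))
        ens = bead_ensemble(np.stack(frames))
        aligned = compute_rmsf(ens, align=True)
        raw = compute_rmsf(ens, align=False)
        assert np.all(aligned.values < raw.values)
        # fitting absorbs 6 rigid degrees of freedom out of 3n=18, so the
        # expected post-fit RMSF is sqrt(3 sigma^2 (1 - 6/(3n))) on average
        expected = np.sqrt(3 * 0.3**2 * (1 - 6 / 18))
        assert aligned.values.mean() == pytest.approx(expected, abs=0.05)

    def test_requires_two_frames(self):
        with pytest.raises(ValueError):
            compute_rmsf(bead_ensemble(straight_chain(4)[None]))

    def test_delta_rmsf_sign_convention(self):
        from ptpdyn.loops import RMSFProfile

        a = RMSFProfile([1, 2], [2.0, 1.0])
        b = RMSFProfile([1, 2], [1.0, 1.0])
        df = delta_rmsf(a, b)
        assert df["delta_rmsf"].tolist() == [1.0, 0.0]

    def test_delta_rmsf_drops_unmatched_with_warning(self):
        from ptpdyn.loops import RMSFProfile

        a = RMSFProfile([1, 2, 3], [1.0, 1.0, 1.0])
        b = RMSFProfile([1, 2], [0.5, 0.5])
        with pytest.warns(UserWarning, match="dropped"):
            df = delta_rmsf(a, b)
        assert len(df) == 2


class TestReactiveFraction:
    @staticmethod
    def active_site(d_asp: float, d_gln: float) -> np.ndarray:
        """One frame with prescribed Asp(OD1)-P and Gln(CD)-P distances."""
        return np.array([
            [d_asp, 0.0, 0.0],   # Asp OD1
            [0.0, 0.0, 0.0],     # phosphorus
            [0.0, d_gln, 0.0],   # Gln CD
        ])

    def build(self, pairs):
        from ptpdyn.ensemble import CoordinateEnsemble
        import pandas as pd

        coords = np.stack([self.active_site(a, g) for a, g in pairs])
        atoms = pd.DataFrame({
            "res_id": [419, 453, 500],
            "res_name": ["ASP", "CYS", "GLN"],
            "atom_name": ["OD1", "P", "CD"],
            "chain_id": ["A"] * 3,
            "element": ["O", "P", "C"],
            "mass": [16.0, 31.0, 12.0],
            "hetero": [False] * 3,
            "ca_only": [False] * 3,
        })
        return CoordinateEnsemble(coords, atoms)

    def test_strict_cutoffs_on_boundary_grid(self):
        pairs = [(4.4, 7.9), (4.6, 7.9), (4.4, 8.1), (4.6, 8.1), (4.5, 8.0)]
        ens = self.build(pairs)
        frac, idx = reactive_fraction(ens, default_reactive_criteria())
        assert frac == pytest.approx(1 / 5)
        assert idx.tolist() == [0]

    def test_missing_atom_is_error(self):
        ens = self.build([(4.0, 7.0)])
        crit = ReactiveCriteria([(AtomSpec(1, "XX"), AtomSpec(453, "P"), 5.0)])
        with pytest.raises(KeyError):
            reactive_fraction(ens, crit)

    def test_empty_criteria_rejected(self):
        with pytest.raises(ValueError):
            ReactiveCriteria([])
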