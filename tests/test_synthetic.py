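import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptpdyn.synthetic import (
    GaussianEnsembleSpec,
    HarmonicDiabatSpec,
    TwoStateLoopSpec,
    analytic_barriers,
    correlated_pair_covariance,
    diagonal_covariance,
    gen_evb_windows,
    gen_gaussian_ensemble,
    gen_two_state_loop,
    gen_variant_table,
)

from conftest import straight_chain


class TestGaussianEnsemble:
    def test_reproducible_by_seed(self):
        spec = GaussianEnsembleSpec(straight_chain(4), diagonal_covariance(4), 50, seed=7)
        a = gen_gaussian_ensemble(spec)
        b = gen_gaussian_ensemble(spec)
        assert np.array_equal(a.coords, b.coords)

    def test_sample_covariance_matches_target(self):
        n = 3
        cov = correlated_pair_covariance(n, 0, 2, rho=0.8, sigma2=2.0)
        spec = GaussianEnsembleSpec(straight_chain(n), cov, 200_000, seed=1)
        ens = gen_gaussian_ensemble(spec)
        disp = (ens.coords - ens.coords.mean(0)).reshape(ens.n_frames, -1)
        sample = disp.T @ disp / ens.n_frames
        assert np.allclose(sample, cov, atol=0.05)

    def test_rejects_asymmetric_covariance(self):
        cov = diagonal_covariance(2)
        cov[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            GaussianEnsembleSpec(straight_chain(2), cov, 10, seed=0)

    def test_rejects_indefinite_covariance(self):
        cov = correlated_pair_covariance(2, 0, 1, rho=1.5)
        with pytest.raises(ValueError, match="positive semi-definite"):
            GaussianEnsembleSpec(straight_chain(2), cov, 10, seed=0)

    def test_rejects_wrong_shapes(self):
        with pytest.raises(ValueError):
            GaussianEnsembleSpec(straight_chain(3), diagonal_covariance(2), 10, seed=0)
        with pytest.raises(ValueError):
            GaussianEnsembleSpec(straight_chain(3), diagonal_covariance(3), 1, seed=0)


class TestTwoStateLoop:
    def test_occupancy_recovered_within_markov_se(self, two_state_spec):
        _, labels = gen_two_state_loop(two_state_spec)
        frac = float(np.mean(labels == "closed"))
        assert abs(frac - two_state_spec.occupancy_closed) < 3 * two_state_spec.occupancy_se()

    def test_mean_closed_dwell_matches_spec(self):
        spec = TwoStateLoopSpec(
            open_coordinates=straight_chain(3),
            closed_coordinates=straight_chain(3) + 1.0,
            occupancy_closed=0.5,
            mean_dwell=20,
            jitter_sd=0.0,
            n_frames=200_000,
            seed=2,
        )
        _, labels = gen_two_state_loop(spec)
        s = (labels == "closed").astype(int)
        # mean length of maximal closed runs
        changes = np.flatnonzero(np.diff(s) != 0) + 1
        runs = np.split(s, changes)
        closed_runs = [len(r) for r in runs[1:-1] if r[0] == 1]  # drop censored ends
        assert np.mean(closed_runs) == pytest.approx(20, rel=0.05)

    def test_zero_jitter_frames_sit_on_anchors(self):
        closed = straight_chain(3)
        open_ = closed + np.array([0.0, 5.0, 0.0])
        spec = TwoStateLoopSpec(open_, closed, 0.5, 10, 0.0, 500, seed=3)
        ens, labels = gen_two_state_loop(spec)
        for t in range(ens.n_frames):
            anchor = closed if labels[t] == "closed" else open_
            assert np.array_equal(ens.coords[t], anchor)

    def test_degenerate_occupancies(self):
        closed = straight_chain(2)
        for p, lab in [(1.0, "closed"), (0.0, "open")]:
            spec = TwoStateLoopSpec(closed + 1, closed, p, 10, 0.0, 50, seed=0)
            _, labels = gen_two_state_loop(spec)
            assert set(labels) == {lab}

    def test_infeasible_dwell_is_error(self):
        closed = straight_chain(2)
        with pytest.raises(ValueError, match="mean_dwell"):
            TwoStateLoopSpec(closed + 1, closed, 0.9, 2, 0.0, 50, seed=0).transition_probs()

    @given(
        p=st.floats(0.1, 0.9),
        dwell=st.floats(20, 200),
    )
    @settings(max_examples=25, deadline=None)
    def test_transition_probs_have_requested_stationary_dist(self, p, dwell):
        spec = TwoStateLoopSpec(
            straight_chain(2) + 1, straight_chain(2), p, dwell, 0.0, 10, seed=0
        )
        q_c, q_o = spec.transition_probs()
        # stationary closed fraction of the 2-state chain is q_o / (q_c + q_o)
        assert q_o / (q_c + q_o) == pytest.approx(p, rel=1e-9)
        assert q_c == pytest.approx(1.0 / dwell)


class TestHarmonicDiabats:
    def test_reorganization_energy_closed_form(self, evb_spec):
        assert evb_spec.reorganization_energy == pytest.approx(
            0.5 * evb_spec.k_force * (evb_spec.x2 - evb_spec.x1) ** 2
        )

    def test_symmetric_uncoupled_barrier_is_quarter_lambda(self):
        spec = HarmonicDiabatSpec(
            k_force=80.0, x1=0.0, x2=1.0, dG0=0.0, H12=0.0,
            temperature=300.0, lambdas=np.linspace(0, 1, 11),
            frames_per_window=10, seed=0,
        )
        ref = analytic_barriers(spec)
        assert ref.dg_act == pytest.approx(spec.reorganization_energy / 4.0, abs=1e-6)
        assert ref.dg_rxn == pytest.approx(0.0, abs=1e-6)

    def test_coupling_lowers_barrier_by_h12_when_symmetric(self):
        base = dict(
            k_force=80.0, x1=0.0, x2=1.0, dG0=0.0, temperature=300.0,
            lambdas=np.linspace(0, 1, 11), frames_per_window=10, seed=0,
        )
        g0 = analytic_barriers(HarmonicDiabatSpec(H12=0.0, **base)).dg_act
        g1 = analytic_barriers(HarmonicDiabatSpec(H12=1.0, **base)).dg_act
        # symmetric crossing: adiabatic TS drops by exactly H12 at the seam,
        # and the RS minimum shifts only second order in H12
        assert g0 - g1 == pytest.approx(1.0, abs=0.05)

    def test_window_samples_have_exact_gaussian_moments(self, evb_spec):
        series = gen_evb_windows(evb_spec)
        sigma2 = evb_spec.kT / evb_spec.k_force
        # invert x from e1: x = x1 + sqrt(2 e1 / k) only up to sign, so check
        # the gap instead: e1 - e2 is linear in x for equal force constants
        k, x1, x2 = evb_spec.k_force, evb_spec.x1, evb_spec.x2
        slope = k * (x2 - x1)  # d(e1-e2)/dx
        for lam, e in zip(evb_spec.lambdas, series.energies):
            gap = e[:, 0] - e[:, 1]
            x = (gap + evb_spec.dG0 + 0.5 * k * (x2**2 - x1**2)) / slope
            x_min = (1 - lam) * x1 + lam * x2
            assert np.mean(x) == pytest.approx(x_min, abs=4 * np.sqrt(sigma2 / len(x)))

    def test_lambda_grid_validation(self):
        base = dict(k_force=1.0, x1=0.0, x2=1.0, dG0=0.0, H12=0.0,
                    temperature=300.0, frames_per_window=5, seed=0)
        with pytest.raises(ValueError):
            HarmonicDiabatSpec(lambdas=np.array([0.0, 0.5, 0.9]), **base)
        with pytest.raises(ValueError):
            HarmonicDiabatSpec(lambdas=np.array([0.0, 0.5, 0.5, 1.0]), **base)


class TestVariantTable:
    def test_planted_hotspots_have_two_distinct_alts(self):
        table = gen_variant_table(seed=4, n_positions=30, planted_hotspots=[300, 400])
        df = table.data
        for pos in (300, 400):
            assert df.loc[df["position"] == pos, "alt_aa"].nunique() >= 2

    def test_reproducible_and_distinct_alts(self):
        a = gen_variant_table(seed=9, n_positions=25)
        b = gen_variant_table(seed=9, n_positions=25)
        assert a.data.equals(b.data)
        dup = a.data.groupby(["position", "alt_aa"]).size()
        assert (dup == 1).all()

    def test_alt_never_equals_wt(self):
        table = gen_variant_table(seed=1, n_positions=40, substitution_rate=0.9)
        assert (table.data["alt_aa"] != table.data["wt_aa"]).all()
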