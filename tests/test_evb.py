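import numpy as np
import pandas as pd
import pytest

from ptpdyn.constants import BOLTZMANN_SI, KCAL_PER_MOL_K, PLANCK_SI
from ptpdyn.evb import (
    EVBWindowSeries,
    anova_tukey,
    barrier_stats,
    cluster_reactive_geometries,
    fep_increments,
    gap_profile,
    mapping_energies,
    tst_barrier,
)
from ptpdyn.synthetic import HarmonicDiabatSpec, analytic_barriers, gen_evb_windows

from conftest import straight_chain


class TestWindowSeries:
    def test_validation(self, evb_spec):
        series = gen_evb_windows(evb_spec)
        with pytest.raises(ValueError, match="span"):
            EVBWindowSeries(np.array([0.1, 1.0]), series.energies[:2], 1.0, 300.0)
        with pytest.raises(ValueError, match="one energy block"):
            EVBWindowSeries(np.array([0.0, 1.0]), series.energies[:1], 1.0, 300.0)
        with pytest.raises(ValueError, match="temperature"):
            EVBWindowSeries(np.array([0.0, 1.0]), series.energies[:2], 1.0, -10.0)

    def test_csv_roundtrip(self, evb_spec, tmp_path):
        series = gen_evb_windows(evb_spec)
        p = tmp_path / "windows.csv"
        series.to_csv(p)
        back = EVBWindowSeries.from_csv(p, h12=series.h12, temperature=series.temperature)
        assert np.allclose(back.lambdas, series.lambdas)
        for a, b in zip(back.energies, series.energies):
            assert np.allclose(a, b, atol=1e-9)

    def test_mapping_energy_endpoints(self, evb_spec):
        series = gen_evb_windows(evb_spec)
        e0 = mapping_energies(series, 0)
        assert np.allclose(e0, series.energies[0][:, 0])  # lambda=0 -> pure e1
        last = series.n_windows - 1
        assert np.allclose(mapping_energies(series, last), series.energies[last][:, 1])
        with pytest.raises(IndexError):
            mapping_energies(series, 99)


class TestFEP:
    def test_gaussian_closed_form_increment(self):
        # Sampling a harmonic window exactly: the Zwanzig estimate of each
        # increment has known mean mu - sigma^2/(2 kT) where delta ~ N(mu, sigma^2)
        spec = HarmonicDiabatSpec(
            k_force=50.0, x1=0.0, x2=1.0, dG0=0.0, H12=0.0,
            temperature=300.0, lambdas=np.linspace(0, 1, 21),
            frames_per_window=50_000, seed=13,
        )
        series = gen_evb_windows(spec)
        dg = fep_increments(series)
        kT = spec.kT
        k, x1, x2 = spec.k_force, spec.x1, spec.x2
        for m in range(series.n_windows - 1):
            lam0, lam1 = spec.lambdas[m], spec.lambdas[m + 1]
            dlam = lam1 - lam0
            x_min = (1 - lam0) * x1 + lam0 * x2
            # delta = dlam * (e2 - e1) is linear in x with x ~ N(x_min, kT/k)
            slope = dlam * k * (x1 - x2)
            mu = dlam * (0.5 * k * ((x_min - x2) ** 2 - (x_min - x1) ** 2) + spec.dG0)
            sigma2 = slope ** 2 * kT / k
            expected = mu - sigma2 / (2 * kT)
            observed = dg[m + 1] - dg[m]
            se = np.sqrt(sigma2 / spec.frames_per_window) * 3  # ~3 SE at leading order
            assert observed == pytest.approx(expected, abs=max(3 * se, 5e-4))

    def test_endpoint_free_energy_matches_dg0(self):
        # for symmetric harmonic diabats dG(1) - dG(0) converges to dG0
        spec = HarmonicDiabatSpec(
            k_force=100.0, x1=0.0, x2=1.0, dG0=-2.0, H12=0.0,
            temperature=300.0, lambdas=np.linspace(0, 1, 51),
            frames_per_window=20_000, seed=7,
        )
        dg = fep_increments(gen_evb_windows(spec))
        assert dg[-1] == pytest.approx(-2.0, abs=0.05)

    def test_poor_overlap_warns(self):
        spec = HarmonicDiabatSpec(
            k_force=100.0, x1=0.0, x2=4.0, dG0=0.0, H12=0.0,
            temperature=300.0, lambdas=np.array([0.0, 1.0]),
            frames_per_window=100, seed=3,
        )
        with pytest.warns(UserWarning, match="effective sample size"):
            fep_increments(gen_evb_windows(spec))


class TestGapProfile:
    def test_recovers_analytic_barriers(self, evb_spec):
        series = gen_evb_windows(evb_spec)
        profile = gap_profile(series)
        ref = analytic_barriers(evb_spec)
        assert profile.dg_act == pytest.approx(ref.dg_act, abs=0.3)
        assert profile.dg_rxn == pytest.approx(ref.dg_rxn, abs=0.3)

    def test_rs_is_exactly_zero(self, evb_spec):
        profile = gap_profile(gen_evb_windows(evb_spec))
        assert profile.dg[profile.rs_bin] == 0.0
        assert profile.dg_act > 0

    def test_orientation_follows_lambda_not_sign(self):
        # endothermic reaction: the PS basin is higher, RS must still be the
        # low-lambda basin and dg_rxn positive
        spec = HarmonicDiabatSpec(
            k_force=100.0, x1=0.0, x2=1.0, dG0=3.0, H12=0.5,
            temperature=300.0, lambdas=np.linspace(0, 1, 51),
            frames_per_window=3000, seed=19,
        )
        profile = gap_profile(gen_evb_windows(spec))
        ref = analytic_barriers(spec)
        assert profile.dg_rxn == pytest.approx(ref.dg_rxn, abs=0.3)
        assert profile.dg_rxn > 0

    def test_too_few_occupied_bins_is_error(self):
        energies = [np.array([[0.0, 1.0]] * 5), np.array([[0.0, 1.0]] * 5)]
        series = EVBWindowSeries(np.array([0.0, 1.0]), energies, 0.0, 300.0)
        with pytest.raises(ValueError):
            gap_profile(series)


class TestBarrierStats:
    def test_mean_and_sem(self):
        df = barrier_stats({"wt": [10.0, 12.0, 14.0]})
        assert df.loc["wt", "mean"] == pytest.approx(12.0)
        assert df.loc["wt", "sem"] == pytest.approx(2.0 / np.sqrt(3))
        assert df.loc["wt", "n"] == 3

    def test_single_replicate_is_error(self):
        with pytest.raises(ValueError, match="replicates"):
            barrier_stats({"wt": [10.0]})


class TestAnovaTukey:
    def test_separated_groups_get_stars(self):
        rng = np.random.default_rng(29)
        res = anova_tukey({
            "wt": (14.0 + 0.2 * rng.standard_normal(8)).tolist(),
            "mut": (18.0 + 0.2 * rng.standard_normal(8)).tolist(),
            "mut2": (14.0 + 0.2 * rng.standard_normal(8)).tolist(),
        })
        assert res.p_value < 0.01
        assert res.stars_for("wt", "mut") == "**"
        assert res.stars_for("wt", "mut2") == ""
        # stars always follow the p-value rule
        for _, row in res.pairwise.iterrows():
            p = row["p_value"]
            expected = "**" if p < 0.01 else "*" if p < 0.05 else ""
            assert row["stars"] == expected

    def test_identical_groups_not_significant(self):
        res = anova_tukey({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]})
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0

    def test_cross_checks_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multicomp")
        rng = np.random.default_rng(31)
        data = {
            "a": rng.normal(10, 1, 10),
            "b": rng.normal(12, 1, 10),
            "c": rng.normal(10.5, 1, 10),
        }
        res = anova_tukey({k: v.tolist() for k, v in data.items()})
        values = np.concatenate(list(data.values()))
        groups = np.repeat(list(data.keys()), [len(v) for v in data.values()])
        sm = statsmodels.pairwise_tukeyhsd(values, groups)
        sm_p = {}
        for row in sm.summary().data[1:]:
            sm_p[(str(row[0]), str(row[1]))] = float(row[3])
        for _, r in res.pairwise.iterrows():
            key = (r["group_a"], r["group_b"])
            expected = sm_p.get(key, sm_p.get(key[::-1]))
            assert r["p_value"] == pytest.approx(expected, abs=1e-3)


class TestTST:
    def test_kcat_equal_to_prefactor_gives_zero(self):
        T = 300.0
        prefactor = BOLTZMANN_SI * T / PLANCK_SI
        assert tst_barrier(prefactor, T) == pytest.approx(0.0, abs=1e-12)

    def test_halving_rate_adds_rt_ln2(self):
        T = 300.0
        rt = KCAL_PER_MOL_K * T
        assert tst_barrier(0.5, T) - tst_barrier(1.0, T) == pytest.approx(rt * np.log(2))

    def test_one_per_second_at_300k(self):
        assert tst_barrier(1.0, 300.0) == pytest.approx(17.565, abs=0.01)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            tst_barrier(0.0, 300.0)
        with pytest.raises(ValueError):
            tst_barrier(1.0, -1.0)


class TestClustering:
    def test_two_well_separated_families(self):
        rng = np.random.default_rng(37)
        base_a = straight_chain(4)
        base_b = base_a.copy()
        base_b[0] += np.array([0.0, 6.0, 0.0])  # internally different shape
        frames = []
        truth = []
        for i in range(30):
            base = base_a if i % 2 == 0 else base_b
            frames.append(base + rng.normal(0, 0.05, base.shape))
            truth.append(i % 2)
        labels, reps = cluster_reactive_geometries(np.stack(frames), n_clusters=2)
        truth = np.array(truth)
        # labels should match truth up to permutation
        agreement = max(
            np.mean(labels == truth), np.mean(labels == 1 - truth)
        )
        assert agreement == 1.0
        assert set(reps) == {0, 1}
        for lab, rep in reps.items():
            assert labels[rep] == lab

    def test_exactly_one_cut_criterion_required(self):
        frames = np.random.default_rng(0).normal(size=(4, 3, 3))
        with pytest.raises(ValueError):
            cluster_reactive_geometries(frames)
        with pytest.raises(ValueError):
            cluster_reactive_geometries(frames, n_clusters=2, distance_cutoff=1.0)

    def test_distance_cutoff_mode(self):
        rng = np.random.default_rng(41)
        base = straight_chain(3)
        frames = np.stack([base + rng.normal(0, 0.01, base.shape) for _ in range(10)])
        labels, _ = cluster_reactive_geometries(frames, distance_cutoff=1.0)
        assert set(labels) == {0}
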