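"""Posterior summaries, normalised SCIRs, sex ratios, flags, concordance."""

import numpy as np
import pandas as pd
import pytest

import famclust as fc
from famclust.mixture import PosteriorDraws


def synthetic_draws(theta, z, pi=None, groups=None):
    """Build a PosteriorDraws object from explicit arrays."""
    theta = np.asarray(theta, dtype=float)
    z = np.asarray(z, dtype=bool)
    t, j = theta.shape
    if groups is None:
        groups = pd.DataFrame(
            {
                "municipality": [f"M{i}" for i in range(j)],
                "surname": [f"S{i}" for i in range(j)],
                "sex": ["male"] * j,
                "site": ["stomach"] * j,
                "observed": [1] * j,
                "expected": [1.0] * j,
            }
        )
    return PosteriorDraws(
        theta=theta,
        z=z,
        pi=np.full(t, 0.1) if pi is None else np.asarray(pi),
        hyper=np.tile([1.0, 1.0, 5.0, 1.0], (t, 1)),
        log_posterior=np.zeros(t),
        chain_id=np.zeros(t, dtype=int),
        groups=groups,
    )


class TestGroupSummaries:
    def test_constant_draws_collapse_ci(self):
        d = synthetic_draws(np.full((100, 2), 3.5), np.zeros((100, 2)))
        s = fc.summarise_groups(d)
        assert (s["scir_median"] == 3.5).all()
        assert (s["scir_ci_low"] == 3.5).all()
        assert (s["scir_ci_high"] == 3.5).all()

    def test_always_high_gives_unit_probability(self):
        d = synthetic_draws(np.ones((50, 3)), np.ones((50, 3)))
        s = fc.summarise_groups(d)
        assert (s["p_high"] == 1.0).all()

    def test_median_matches_sort_oracle(self):
        rng = np.random.default_rng(1)
        theta = rng.gamma(2.0, 1.0, size=(5000, 4))
        d = synthetic_draws(theta, rng.random((5000, 4)) < 0.3)
        s = fc.summarise_groups(d)
        for jcol in range(4):
            col = np.sort(theta[:, jcol])
            oracle = 0.5 * (col[2499] + col[2500])
            assert s["scir_median"].iloc[jcol] == pytest.approx(oracle, rel=1e-12)

    def test_cis_contain_medians(self):
        rng = np.random.default_rng(2)
        d = synthetic_draws(
            rng.gamma(1.5, 2.0, size=(800, 6)), rng.random((800, 6)) < 0.5
        )
        s = fc.summarise_groups(d)
        assert (s["scir_ci_low"] <= s["scir_median"]).all()
        assert (s["scir_median"] <= s["scir_ci_high"]).all()

    def test_empty_draws_rejected(self):
        d = synthetic_draws(np.empty((0, 2)), np.empty((0, 2)))
        with pytest.raises(ValueError):
            fc.summarise_groups(d)


class TestNormalisedScir:
    def test_hand_example(self):
        s = pd.DataFrame({"scir_median": [1.0, 1.0, 1.0, 3.0]})
        out = fc.normalise_scirs(s)
        assert out["normalised_scir"].iloc[3] == pytest.approx(2.0)

    def test_degenerate_spread_all_zero(self):
        s = pd.DataFrame({"scir_median": [2.0, 2.0, 2.0]})
        out = fc.normalise_scirs(s)
        assert (out["normalised_scir"] == 0).all()

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(3)
        med = rng.gamma(2.0, 1.5, size=500)
        out = fc.normalise_scirs(pd.DataFrame({"scir_median": med}))
        oracle = (med - np.median(med)) / np.std(med, ddof=1)
        assert np.abs(out["normalised_scir"].to_numpy() - oracle).max() < 1e-12

    def test_shift_and_scale_invariances(self):
        rng = np.random.default_rng(4)
        med = rng.gamma(2.0, 1.5, size=100)
        base = fc.normalise_scirs(pd.DataFrame({"scir_median": med}))
        shifted = fc.normalise_scirs(pd.DataFrame({"scir_median": med + 7.0}))
        scaled = fc.normalise_scirs(pd.DataFrame({"scir_median": med * 3.0}))
        np.testing.assert_allclose(
            base["normalised_scir"], shifted["normalised_scir"], atol=1e-10
        )
        np.testing.assert_allclose(
            base["normalised_scir"], scaled["normalised_scir"], atol=1e-10
        )


class TestAnalysisSummary:
    def test_all_high_degenerate(self):
        d = synthetic_draws(np.full((60, 3), 2.0), np.ones((60, 3)))
        a = fc.summarise_analysis(d)
        assert a.group_proportion["median"] == 1.0
        assert a.scir_ratio["median"] == 1.0

    def test_two_group_hand_computation(self):
        theta = np.tile([1.0, 3.0], (40, 1))
        z = np.tile([False, True], (40, 1))
        a = fc.summarise_analysis(synthetic_draws(theta, z))
        assert a.scir_avg_overall["median"] == 2.0
        assert a.scir_avg_high["median"] == 3.0
        assert a.scir_ratio["median"] == 1.5

    def test_matches_per_iteration_brute_force(self):
        rng = np.random.default_rng(5)
        theta = rng.gamma(2.0, 1.0, size=(300, 7))
        z = rng.random((300, 7)) < 0.4
        ser = fc.analysis_series(synthetic_draws(theta, z))
        for t in (0, 123, 299):
            assert ser["group_proportion"].iloc[t] == z[t].mean()
            assert ser["scir_avg_overall"].iloc[t] == pytest.approx(theta[t].mean())
            if z[t].any():
                assert ser["scir_avg_high"].iloc[t] == pytest.approx(
                    theta[t][z[t]].mean()
                )
                assert ser["scir_ratio"].iloc[t] == pytest.approx(
                    theta[t][z[t]].mean() / theta[t].mean()
                )

    def test_no_high_iterations_dropped_and_counted(self):
        theta = np.ones((10, 2))
        z = np.zeros((10, 2), dtype=bool)
        z[:4] = True
        a = fc.summarise_analysis(synthetic_draws(theta, z))
        assert a.n_ratio_dropped == 6

    def test_proportion_mean_equals_mean_p_high(self):
        """Exchange of summation order: E[fraction high] == mean of p_high."""
        rng = np.random.default_rng(6)
        theta = rng.gamma(2.0, 1.0, size=(500, 9))
        z = rng.random((500, 9)) < 0.25
        d = synthetic_draws(theta, z)
        ser = fc.analysis_series(d)
        s = fc.summarise_groups(d)
        assert abs(ser["group_proportion"].mean() - s["p_high"].mean()) < 1e-12

    def test_cancer_weighted_variant(self):
        groups = pd.DataFrame(
            {
                "municipality": ["M0", "M1"],
                "surname": ["S0", "S1"],
                "sex": ["male", "male"],
                "site": ["stomach", "stomach"],
                "observed": [1, 9],
                "expected": [1.0, 1.0],
            }
        )
        theta = np.ones((20, 2))
        z = np.tile([False, True], (20, 1))
        ser = fc.analysis_series(synthetic_draws(theta, z, groups=groups),
                                 weight_by_cancers=True)
        assert (ser["group_proportion"] == 0.9).all()


class TestSexComparison:
    def test_identical_draws_give_unit_ratios(self):
        rng = np.random.default_rng(7)
        theta = rng.gamma(2.0, 1.0, size=(200, 5))
        z = rng.random((200, 5)) < 0.4
        z[:, 0] = True  # ensure every iteration has a high group
        d = synthetic_draws(theta, z)
        comp = fc.compare_sexes(d, d)
        assert comp["ratio_group_proportion"]["median"] == 1.0
        assert comp["ratio_group_proportion"]["ci_low"] == 1.0
        assert comp["ratio_scir_ratio"]["ci_high"] == 1.0

    def test_doubled_proportion_halves_ratio(self):
        theta = np.ones((50, 4))
        zm = np.tile([True, False, False, False], (50, 1))
        zf = np.tile([True, True, False, False], (50, 1))
        comp = fc.compare_sexes(synthetic_draws(theta, zm), synthetic_draws(theta, zf))
        assert comp["ratio_group_proportion"]["median"] == 0.5

    def test_ci_matches_paired_ratio_quantiles(self):
        rng = np.random.default_rng(8)
        tm = rng.gamma(2.0, 1.0, size=(400, 6))
        tf = rng.gamma(2.0, 1.0, size=(400, 6))
        zm = np.ones((400, 6), dtype=bool)
        zf = np.ones((400, 6), dtype=bool)
        comp = fc.compare_sexes(synthetic_draws(tm, zm), synthetic_draws(tf, zf))
        ratios = tm.mean(axis=1) / tm.mean(axis=1)  # scir_ratio is 1 for all-high
        assert comp["ratio_scir_ratio"]["median"] == pytest.approx(1.0)
        prop = np.ones(400) / np.ones(400)
        lo, hi = np.quantile(prop, [0.025, 0.975])
        assert comp["ratio_group_proportion"]["ci_low"] == pytest.approx(lo)
        assert comp["ratio_group_proportion"]["ci_high"] == pytest.approx(hi)

    def test_length_mismatch_bootstraps_with_warning(self):
        rng = np.random.default_rng(9)
        a = synthetic_draws(rng.gamma(2, 1, (100, 3)), np.ones((100, 3)))
        b = synthetic_draws(rng.gamma(2, 1, (80, 3)), np.ones((80, 3)))
        comp1 = fc.compare_sexes(a, b, seed=1)
        comp2 = fc.compare_sexes(a, b, seed=1)
        assert comp1 == comp2  # seeded bootstrap is deterministic


class TestFlagsAndConcordance:
    def test_strict_threshold_boundary(self):
        s = pd.DataFrame({"p_high": [0.95, 0.96, 0.5], "scir_median": [3, 4, 1]})
        flagged = fc.flag_clusters(s)
        at_90 = flagged.loc[flagged["threshold"] == 0.9, "p_high"].tolist()
        at_95 = flagged.loc[flagged["threshold"] == 0.95, "p_high"].tolist()
        assert at_90 == [0.95, 0.96]
        assert at_95 == [0.96]

    def test_concordant_requires_both_sexes(self):
        records = pd.DataFrame(
            {
                "municipality": ["M1", "M1", "M2", "M2"],
                "surname": ["S1", "S1", "S2", "S2"],
                "sex": ["male", "female", "male", "female"],
                "site": ["stomach"] * 4,
                "observed": [2, 1, 3, 0],
                "expected": [0.5] * 4,
                "scir": [4, 2, 6, 0],
                "excluded": [False, False, False, True],
            }
        )
        sm = pd.DataFrame(
            {
                "municipality": ["M1", "M2"],
                "surname": ["S1", "S2"],
                "site": ["stomach", "stomach"],
                "p_high": [0.8, 0.9],
            }
        )
        sf = pd.DataFrame(
            {
                "municipality": ["M1"],
                "surname": ["S1"],
                "site": ["stomach"],
                "p_high": [0.6],
            }
        )
        out = fc.extract_concordant(records, sm, sf)
        assert len(out) == 1  # M2/S2 female arm has no observed cancer
        assert out["p_high_male"].iloc[0] == 0.8
        assert out["p_high_female"].iloc[0] == 0.6

    def test_concordant_matches_double_loop_oracle(self, demo_config):
        rng = np.random.default_rng(10)
        mns = [(f"M{i%5}", f"S{i}", sex) for i in range(30) for sex in ("male", "female")]
        records = pd.DataFrame(
            {
                "municipality": [m for m, _, _ in mns],
                "surname": [s for _, s, _ in mns],
                "sex": [x for _, _, x in mns],
                "site": "colon",
                "observed": rng.integers(0, 3, len(mns)),
                "expected": 0.5,
            }
        )
        summaries = records.assign(p_high=rng.random(len(mns)))
        sm = summaries.loc[summaries["sex"] == "male"]
        sf = summaries.loc[summaries["sex"] == "female"]
        out = fc.extract_concordant(records, sm, sf)
        oracle = set()
        for _, male in records.loc[records["sex"] == "male"].iterrows():
            for _, fem in records.loc[records["sex"] == "female"].iterrows():
                if (
                    male["municipality"] == fem["municipality"]
                    and male["surname"] == fem["surname"]
                    and male["site"] == fem["site"]
                    and male["observed"] >= 1
                    and fem["observed"] >= 1
                ):
                    oracle.add((male["municipality"], male["surname"], male["site"]))
        assert set(zip(out["municipality"], out["surname"], out["site"])) == oracle
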