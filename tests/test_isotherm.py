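"""Tests for the flow-cytometry isotherm pipeline."""

import numpy as np
import pandas as pd
import pytest

from crowdsense import isotherm as iso
from crowdsense import synth
from crowdsense.errors import DataError, DomainError, EstimationError, UsageError


def make_events(theta_by_conc, sample_id="s", anchor=100.0, n=50):
    """Exact, noise-free event table with given mean normalized signal."""
    rows = []
    for conc, theta in theta_by_conc.items():
        for i in range(n):
            rows.append(
                {
                    "sample_id": sample_id,
                    "cell_id": i,
                    "bulk_conc_nM": conc,
                    "anchor_fitc": anchor,
                    "probe_signal": theta * anchor,
                }
            )
    return pd.DataFrame(rows)


def normalized(df):
    out, _ = iso.normalize_events(df, low_quantile=0.0, high_quantile=1.0)
    return out


class TestNormalizeEvents:
    def test_zero_probe_gives_zero_signal(self):
        df = make_events({1.0: 0.0})
        out = normalized(df)
        assert (out["norm_signal"] == 0).all()

    def test_scale_invariance(self):
        df = make_events({1.0: 0.3})
        base = normalized(df)["norm_signal"].to_numpy()
        df2 = df.copy()
        df2["anchor_fitc"] *= 37.0
        df2["probe_signal"] *= 37.0
        assert np.allclose(normalized(df2)["norm_signal"].to_numpy(), base)

    def test_normalization_cancels_cell_size_variance(self):
        """Per-cell Cmax variation dominates raw probe variance but divides out."""
        noise = synth.NoiseModel(cmax_lognormal_cv=0.5, detection_cv=0.0,
                                 background_sd=0.0, seed=4)
        ev = synth.gen_isotherm_events(10.0, 1.0, (1.0,), 5000, noise)
        out = normalized(ev[ev.sample_id == "bare_bead"])
        raw_cv = out["probe_signal"].std() / out["probe_signal"].mean()
        norm_cv = out["norm_signal"].std() / max(out["norm_signal"].mean(), 1e-300)
        assert (norm_cv / raw_cv) ** 2 < 0.1

    def test_gating_reports_counts(self):
        df = make_events({1.0: 0.3}, n=1000)
        df.loc[0, "anchor_fitc"] = 1e9  # bright aggregate
        out, report = iso.normalize_events(df)
        assert report.n_above >= 1
        assert report.n_input == 1000
        assert report.n_retained == len(out)

    def test_all_gated_out_raises(self):
        df = make_events({1.0: 0.3}, n=10)
        with pytest.raises(DataError, match="gated out"):
            iso.normalize_events(df, anchor_floor=1e12)

    def test_missing_column_raises(self):
        with pytest.raises(DataError, match="anchor_fitc"):
            iso.validate_events(pd.DataFrame({"sample_id": ["a"], "cell_id": [1],
                                              "bulk_conc_nM": [1.0],
                                              "probe_signal": [1.0]}))


class TestBuildIsotherm:
    def test_constant_signal(self):
        it = iso.build_isotherm(normalized(make_events({1.0: 0.25, 2.0: 0.4})))
        assert np.allclose(it.theta, [0.25, 0.4])
        assert np.allclose(it.se, 0.0)
        assert (it.n_events == 50).all()

    def test_exact_langmuir_noiseless(self):
        concs = [0.5, 1, 2, 5, 10, 20]
        kd = 10.0
        it = iso.build_isotherm(
            normalized(make_events({c: c / (c + kd) for c in concs}))
        )
        assert np.allclose(it.theta, iso.langmuir(it.conc_nM, kd))

    def test_group_means_within_3se_of_truth(self):
        ev = synth.gen_isotherm_events(
            10.0, 1.0, (0.5, 1.0), 20_000,
            synth.NoiseModel(cmax_lognormal_cv=0.0, detection_cv=0.1,
                             background_sd=0.0, seed=9),
        )
        it = iso.build_isotherm(normalized(ev[ev.sample_id == "bare_bead"]))
        # dividing two mean-1 lognormal channels leaves E[ε1/ε2] = 1 + CV²,
        # a common-mode factor that cancels in every slope ratio
        truth = iso.langmuir(it.conc_nM, 10.0) * (1.0 + 0.1**2)
        assert np.all(np.abs(it.theta - truth) < 3 * it.se + 1e-12)

    def test_multiple_samples_require_selection(self):
        ev = pd.concat([make_events({1.0: 0.2}, "a"), make_events({1.0: 0.3}, "b")])
        with pytest.raises(UsageError, match="sample_id"):
            iso.build_isotherm(normalized(ev))


class TestLowConcSlope:
    def test_exact_langmuir_slope_band(self):
        kd = 10.0
        concs = [0.05, 0.1, 0.25, 0.5, 1.0]
        it = iso.build_isotherm(
            normalized(make_events({c: c / (c + kd) for c in concs}))
        )
        slope, _ = iso.low_conc_slope(it, n_bootstrap=0)
        assert 0.0909 <= slope <= 0.1000  # between 1/(1+KD) and 1/KD

    def test_zero_signal_zero_slope(self):
        it = iso.build_isotherm(normalized(make_events({0.5: 0.0, 1.0: 0.0})))
        slope, _ = iso.low_conc_slope(it, n_bootstrap=0)
        assert slope == 0.0

    def test_concentration_units(self):
        it1 = iso.build_isotherm(normalized(make_events({0.5: 0.05, 1.0: 0.1})))
        it2 = iso.build_isotherm(normalized(make_events({1.0: 0.05, 2.0: 0.1})))
        s1, _ = iso.low_conc_slope(it1, n_bootstrap=0)
        s2, _ = iso.low_conc_slope(it2, n_bootstrap=0)
        assert s2 == pytest.approx(s1 / 2)

    def test_too_few_points_advises_full_fit(self):
        it = iso.build_isotherm(normalized(make_events({1.0: 0.6, 2.0: 0.7, 4.0: 0.1})))
        with pytest.raises(EstimationError, match="full Langmuir fit"):
            iso.low_conc_slope(it)

    def test_bootstrap_se_reproducible(self):
        ev = synth.gen_isotherm_events(10.0, 1.0, (0.5, 1.0), 2000,
                                       synth.NoiseModel(seed=2))
        it = iso.build_isotherm(normalized(ev[ev.sample_id == "bare_bead"]))
        a = iso.low_conc_slope(it, n_bootstrap=200, seed=5)
        b = iso.low_conc_slope(it, n_bootstrap=200, seed=5)
        assert a == b
        assert a[1] > 0


class TestKdRatioFromSlopes:
    def test_equal_slopes_ratio_one(self):
        r = iso.kd_ratio_from_slopes(0.1, 0.1)
        assert r.kd_ratio == 1.0
        assert r.delta_u_kBT == 0.0

    def test_arithmetic(self):
        r = iso.kd_ratio_from_slopes(0.10, 0.02)
        assert r.kd_ratio == pytest.approx(5.0)
        assert r.percent_increase == pytest.approx(400.0)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(DomainError):
            iso.kd_ratio_from_slopes(0.0, 0.1)

    def test_se_propagation(self):
        r = iso.kd_ratio_from_slopes(0.1, 0.05, reference_se=0.01, sample_se=0.005)
        rel = np.hypot(0.01 / 0.1, 0.005 / 0.05)
        assert r.se == pytest.approx(r.kd_ratio * rel)


class TestFitLangmuir:
    def test_half_saturation(self):
        assert iso.langmuir(10.0, 10.0) == pytest.approx(0.5)

    def test_exact_recovery(self):
        kd = 7.3
        concs = [0.5, 1, 2, 5, 10, 30, 100]
        it = iso.build_isotherm(
            normalized(make_events({c: c / (c + kd) for c in concs}))
        )
        fit = iso.fit_langmuir(it)
        assert fit.converged and not fit.ill_posed
        assert fit.kd_nM == pytest.approx(kd, rel=1e-6)
        assert fit.cmax == pytest.approx(1.0, rel=1e-6)

    def test_ill_posed_flagged(self):
        # fully saturated data: the fitted KD collapses far below the
        # measured concentration range and must be flagged
        it = iso.build_isotherm(
            normalized(make_events({c: 0.5 for c in [0.1, 0.2, 0.4]}))
        )
        fit = iso.fit_langmuir(it)
        assert fit.ill_posed
        assert "outside the measured range" in fit.message

    def test_slope_and_full_fit_agree_on_synthetic_pairs(self):
        """Method consistency: slope-ratio vs full-fit within 10%."""
        for true_ratio, seed in [(1.55, 1), (2.0, 2), (5.0, 3)]:
            ev = synth.gen_isotherm_events(
                10.0, true_ratio, (0.25, 0.5, 1, 2, 5, 10, 30), 4000,
                synth.NoiseModel(seed=seed),
            )
            normed, _ = iso.normalize_events(ev)
            ref = iso.build_isotherm(normed[normed.sample_id == "bare_bead"])
            crw = iso.build_isotherm(normed[normed.sample_id == "crowded"])
            s0, _ = iso.low_conc_slope(ref, n_bootstrap=0)
            s1, _ = iso.low_conc_slope(crw, n_bootstrap=0)
            slope_ratio = s0 / s1
            full_ratio = iso.fit_langmuir(crw).kd_nM / iso.fit_langmuir(ref).kd_nM
            assert slope_ratio == pytest.approx(full_ratio, rel=0.10)


class TestEndToEndRecovery:
    @pytest.mark.parametrize("true_ratio", [1.0, 1.55, 2.0, 5.0, 22.0])
    def test_slope_ratio_recovers_truth(self, true_ratio):
        """Recover KD/KD0 within 10% (15% at ratio 22) at 20k events/conc."""
        ev = synth.gen_isotherm_events(
            10.0, true_ratio, synth.DEFAULT_CONC_GRID_NM, 20_000,
            synth.NoiseModel(seed=int(true_ratio * 10)),
        )
        normed, _ = iso.normalize_events(ev)
        ref = iso.build_isotherm(normed[normed.sample_id == "bare_bead"])
        crw = iso.build_isotherm(normed[normed.sample_id == "crowded"])
        s0, _ = iso.low_conc_slope(ref, n_bootstrap=0)
        s1, _ = iso.low_conc_slope(crw, n_bootstrap=0)
        tol = 0.15 if true_ratio >= 22 else 0.10
        assert s0 / s1 == pytest.approx(true_ratio, rel=tol)

    def test_reference_generality_rescales_exactly(self):
        """Normalizing to a partially-stripped (ProK-like) reference rescales
        every ratio by that reference's own ratio."""
        ev = synth.gen_isotherm_events(10.0, 2.5, n_events_per_conc=5000,
                                       noise=synth.NoiseModel(seed=6))
        prok = synth.gen_isotherm_events(
            10.0, 1.4, n_events_per_conc=5000,
            noise=synth.NoiseModel(seed=6), crowded_name="prok",
        )
        ev = pd.concat([ev, prok[prok.sample_id == "prok"]], ignore_index=True)
        normed, _ = iso.normalize_events(ev)
        slopes = {}
        for sid in ("bare_bead", "crowded", "prok"):
            it = iso.build_isotherm(normed[normed.sample_id == sid])
            slopes[sid], _ = iso.low_conc_slope(it, n_bootstrap=0)
        vs_bare = slopes["bare_bead"] / slopes["crowded"]
        vs_prok = slopes["prok"] / slopes["crowded"]
        ratio_prok = slopes["bare_bead"] / slopes["prok"]
        assert vs_bare == pytest.approx(vs_prok * ratio_prok, rel=1e-12)


class TestSingleCellCrowding:
    def test_identical_population_mean_one(self):
        ev = synth.gen_population(1.0, 0.0, 2000, fixed_conc_nM=0.1, kd0_nM=1.0,
                                  noise=synth.NoiseModel(seed=3).quiet())
        normed = normalized(ev)
        pop = iso.single_cell_crowding(
            normed[normed.sample_id == "cells"],
            normed[normed.sample_id == "bare_bead"], 0.1,
        )
        assert pop.mean == pytest.approx(1.0, abs=1e-9)
        assert pop.cv == pytest.approx(0.0, abs=1e-9)

    def test_lognormal_population_recovered(self):
        ev = synth.gen_population(22.0, 0.3, 5000, fixed_conc_nM=0.1, kd0_nM=1.0,
                                  noise=synth.NoiseModel(seed=11))
        normed = normalized(ev)
        pop = iso.single_cell_crowding(
            normed[normed.sample_id == "cells"],
            normed[normed.sample_id == "bare_bead"], 0.1,
        )
        assert pop.mean == pytest.approx(22.0, rel=0.15)
        assert pop.n_cells + pop.n_excluded == 5000

    def test_cv_definition(self):
        vals = np.array([1.0, 2.0, 3.0])
        assert vals.std(ddof=0) / vals.mean() == pytest.approx(0.408, abs=5e-4)
        # pipeline uses the sample SD; check it against the same data
        ev = make_events({0.1: 0.5}, "cells", n=3)
        ev["probe_signal"] = [50.0, 25.0, 50.0 / 3.0]  # signals -> ratios 1,2,3
        ref = make_events({0.1: 0.5}, "ref", n=100)
        pop = iso.single_cell_crowding(normalized(ev), normalized(ref), 0.1)
        assert sorted(pop.ratios.round(9)) == [1.0, 2.0, 3.0]
        assert pop.cv == pytest.approx(1.0 / 2.0, rel=1e-9)  # ddof=1 SD / mean

    def test_ratio_invariant_to_channel_rescaling(self):
        ev = synth.gen_population(5.0, 0.2, 500, fixed_conc_nM=0.1, kd0_nM=1.0,
                                  noise=synth.NoiseModel(seed=8))
        normed = normalized(ev)
        pop1 = iso.single_cell_crowding(
            normed[normed.sample_id == "cells"],
            normed[normed.sample_id == "bare_bead"], 0.1,
        )
        ev2 = ev.copy()
        ev2["anchor_fitc"] *= 3.7
        ev2["probe_signal"] *= 0.21
        normed2 = normalized(ev2)
        pop2 = iso.single_cell_crowding(
            normed2[normed2.sample_id == "cells"],
            normed2[normed2.sample_id == "bare_bead"], 0.1,
        )
        assert np.allclose(np.sort(pop1.ratios), np.sort(pop2.ratios))

    def test_zero_signal_cells_excluded_and_counted(self):
        ev = make_events({0.1: 0.5}, "cells", n=10)
        ev.loc[ev.index[:3], "probe_signal"] = 0.0
        ref = make_events({0.1: 0.5}, "ref", n=10)
        pop = iso.single_cell_crowding(normalized(ev), normalized(ref), 0.1)
        assert pop.n_excluded == 3
        assert pop.n_cells == 7

    def test_concentration_must_be_low_vs_reference_kd(self):
        ev = make_events({5.0: 0.5}, "cells")
        ref = make_events({5.0: 0.5}, "ref")
        with pytest.raises(UsageError, match="linear regime"):
            iso.single_cell_crowding(normalized(ev), normalized(ref), 5.0,
                                     reference_kd_nM=10.0)


class TestBinByExpression:
    @staticmethod
    def population(expression_model, seed=13, n=4000):
        ev = synth.gen_population(
            2.0, 0.1, n, fixed_conc_nM=0.1, kd0_nM=1.0,
            expression_model=expression_model,
            noise=synth.NoiseModel(seed=seed),
        )
        normed = normalized(ev)
        return iso.single_cell_crowding(
            normed[normed.sample_id == "cells"],
            normed[normed.sample_id == "bare_bead"], 0.1,
        )

    def test_flat_for_expression_independent_population(self):
        from scipy.stats import spearmanr

        pop = self.population(lambda e: np.full_like(e, np.log(2.0)))
        bins = iso.bin_by_expression(pop)
        ok = bins[~bins.excluded]
        dev = (ok.mean_ratio - 2.0).abs() / ok.se_ratio.clip(lower=1e-9)
        assert (dev < 5).mean() >= 0.9  # flat within noise almost everywhere
        rho, _ = spearmanr(ok.bin_center, ok.mean_ratio)
        assert abs(rho) < 0.5  # and trendless

    def test_monotone_model_gives_monotone_bins(self):
        from scipy.stats import spearmanr

        pop = self.population(lambda e: 0.8 * np.log10(e))
        bins = iso.bin_by_expression(pop)
        ok = bins[~bins.excluded]
        rho, _ = spearmanr(ok.bin_center, ok.mean_ratio)
        assert rho > 0.9

    def test_sparse_bins_flagged_not_dropped(self):
        pop = self.population(lambda e: np.full_like(e, 0.5), n=300)
        bins = iso.bin_by_expression(pop, n_bins=30, min_count=10)
        assert len(bins) == 30
        assert bins.excluded.any()
        assert (bins.loc[bins.excluded, "n_cells"] < 10).all()

    def test_requires_expression_channel(self):
        ev = synth.gen_population(2.0, 0.1, 200, fixed_conc_nM=0.1, kd0_nM=1.0,
                                  noise=synth.NoiseModel(seed=1))
        normed = normalized(ev)
        pop = iso.single_cell_crowding(
            normed[normed.sample_id == "cells"],
            normed[normed.sample_id == "bare_bead"], 0.1,
        )
        with pytest.raises(UsageError, match="expression"):
            iso.bin_by_expression(pop)


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        groups = {k: rng.normal(5.0, 1.0, 6) for k in "abc"}
        res = iso.compare_groups(groups)
        assert res.anova_p > 0.05
        assert (res.tukey["band"] == "n.s.").all()

    def test_large_separation_highly_significant(self):
        res = iso.compare_groups(
            {"a": [1.0, 1.4, 0.6], "b": [10.0, 10.5, 9.5]}
        )
        assert res.anova_p < 0.001
        assert res.tukey["band"].iloc[0] in ("***",)

    def test_tukey_conservative_vs_unadjusted(self):
        from scipy import stats as sps

        rng = np.random.default_rng(42)
        for _ in range(10):
            groups = {
                k: rng.normal(rng.uniform(0, 2), 1.0, 5) for k in "abcd"
            }
            res = iso.compare_groups(groups)
            names = list(groups)
            k = 0
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    _, p_raw = sps.ttest_ind(groups[names[i]], groups[names[j]])
                    # Tukey adjusts over all pairs: never more liberal than
                    # the corresponding unadjusted two-sample comparison
                    assert res.tukey["p-adj"].iloc[k] >= p_raw - 0.05
                    k += 1

    def test_single_replicate_group_named(self):
        with pytest.raises(UsageError, match="lonely"):
            iso.compare_groups({"ok": [1.0, 2.0], "lonely": [1.0]})
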