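"""Mixed-model maps, cluster permutation, FDR traces, coupling models."""

import numpy as np
import pandas as pd
import pytest

from neuroadapt.spectral import log_freq_grid
from neuroadapt.stats import (
    ClusterConfig, LMEDesign, cluster_permutation_2d, coupling_decision_prediction,
    coupling_stage_contrast, coupling_variable_correlation, fit_lme,
    tf_regression_map, timecourse_regression_fdr,
)

GRID = log_freq_grid()
TIMES = np.arange(0.0, 2.0, 0.02)


def make_pixel_data(seed, n_pat=4, n_ch=2, n_tr=40, effect=0.0,
                    fmask=None, tmask=None):
    """Trial × channel pixel stack with an optional injected reward effect."""
    rng = np.random.default_rng(seed)
    if fmask is None:
        fmask = (GRID.values >= 4) & (GRID.values <= 9)
    if tmask is None:
        tmask = (TIMES > 0.3) & (TIMES < 1.2)
    rows, Y = [], []
    for p in range(n_pat):
        for c in range(n_ch):
            offset = rng.normal(0, 0.5)  # channel random intercept
            rew = rng.integers(0, 2, n_tr)
            dec = rng.integers(0, 2, n_tr)
            for i in range(n_tr):
                pix = rng.standard_normal((GRID.n_bins, len(TIMES))) + offset
                pix[np.ix_(fmask, tmask)] += effect * rew[i]
                Y.append(pix.astype(np.float32))
                rows.append({"patient": p, "channel": f"{p}:{c}",
                             "reward": rew[i], "decision": dec[i]})
    return np.array(Y), pd.DataFrame(rows), fmask, tmask


@pytest.fixture(scope="module")
def effect_data():
    return make_pixel_data(0, effect=0.8)


class TestFitLme:
    def _scalar_table(self, seed, effect):
        Y, tab, fmask, tmask = make_pixel_data(seed, n_tr=30, effect=effect)
        tab = tab.copy()
        tab["erd"] = Y[:, fmask, :][:, :, tmask].mean(axis=(1, 2))
        return tab

    def test_known_effect_detected(self):
        tab = self._scalar_table(1, 0.5)
        res = fit_lme(tab, LMEDesign(fixed=("reward", "decision")))
        assert res.loc[res.term == "reward", "t"].iloc[0] > 3

    def test_null_effect_not_detected(self):
        hits = 0
        for seed in range(10):
            tab = self._scalar_table(100 + seed, 0.0)
            res = fit_lme(tab, LMEDesign(fixed=("reward",)))
            hits += abs(res["t"].iloc[0]) < 2
        assert hits >= 9

    def test_flipping_coding_flips_t_sign(self):
        tab = self._scalar_table(2, 0.5)
        res = fit_lme(tab, LMEDesign(fixed=("reward",)))
        tab2 = tab.copy()
        tab2["reward"] = 1 - tab2["reward"]
        res2 = fit_lme(tab2, LMEDesign(fixed=("reward",)))
        assert res2["t"].iloc[0] == pytest.approx(-res["t"].iloc[0], rel=1e-4)

    def test_requires_multiple_patients(self):
        tab = self._scalar_table(3, 0.0)
        with pytest.raises(ValueError):
            fit_lme(tab[tab.patient == 0], LMEDesign(fixed=("reward",)))


class TestTFRegressionMap:
    def test_injected_effect_localized(self, effect_data):
        Y, tab, fmask, tmask = effect_data
        design = LMEDesign(fixed=("reward", "decision"))
        rm = tf_regression_map(Y, tab, design, times=TIMES, grid=GRID)
        assert rm.t.shape == (2, GRID.n_bins, len(TIMES))
        inside = rm.t[0][np.ix_(fmask, tmask)]
        assert np.median(inside) > 5
        # specificity: no systematic effect above 30 Hz
        above30 = rm.t[0][GRID.values > 30, :]
        assert np.mean(np.abs(above30) > 3) < 0.01

    def test_fast_and_lme_paths_agree_on_small_map(self):
        Y, tab, fmask, tmask = make_pixel_data(5, n_pat=3, n_ch=2, n_tr=25,
                                               effect=0.6)
        small = Y[:, ::10, ::20]
        design = LMEDesign(fixed=("reward",))
        fast = tf_regression_map(small, tab, design)
        slow = tf_regression_map(small, tab, design, method="lme")
        mask = np.isfinite(slow.t)
        # same estimand; small df differences allowed
        assert np.nanmax(np.abs(fast.t[mask] - slow.t[mask])) < 0.7
        assert np.corrcoef(fast.t[mask].ravel(), slow.t[mask].ravel())[0, 1] > 0.99


class TestClusterPermutation:
    def test_default_area_threshold(self):
        assert ClusterConfig().min_area_hzms == 320.0
        assert ClusterConfig(n_fixed=3).alpha == pytest.approx(0.05 / 3)

    def test_small_clusters_dropped(self):
        # an isolated suprathreshold pixel has area well under 320 Hz·ms
        from neuroadapt.stats import _clusters_from_tmap, _pixel_areas
        areas = _pixel_areas(GRID, TIMES)
        tmap = np.zeros((GRID.n_bins, len(TIMES)))
        tmap[5, 50] = 10.0
        assert _clusters_from_tmap(tmap, 2.0, areas, 320.0) == []
        big = np.zeros_like(tmap)
        big[0:8, 40:70] = 10.0
        assert len(_clusters_from_tmap(big, 2.0, areas, 320.0)) == 1

    def test_injected_effect_yields_overlapping_significant_cluster(self, effect_data):
        Y, tab, fmask, tmask = effect_data
        design = LMEDesign(fixed=("reward", "decision"))
        res = cluster_permutation_2d(
            Y, tab, design, GRID, TIMES,
            config=ClusterConfig(n_fixed=2, n_perm=200), term="reward", seed=0)
        assert res.any_significant
        best = max(res.clusters, key=lambda c: c["stat"])
        injected = np.zeros((GRID.n_bins, len(TIMES)), bool)
        injected[np.ix_(fmask, tmask)] = True
        overlap = (best["mask"] & injected).sum() / injected.sum()
        assert overlap > 0.5

    def test_null_data_rarely_significant(self):
        sig = 0
        for seed in range(8):
            Y, tab, *_ = make_pixel_data(200 + seed, n_pat=3, n_ch=2, n_tr=25,
                                         effect=0.0)
            res = cluster_permutation_2d(
                Y, tab, LMEDesign(fixed=("reward",)), GRID, TIMES,
                config=ClusterConfig(n_fixed=1, n_perm=100), seed=seed)
            sig += res.any_significant
        assert sig <= 2


class TestTimecourseFDR:
    def _band_data(self, seed, effect, n_pat=4, n_ch=2, n_tr=40):
        rng = np.random.default_rng(seed)
        times = np.arange(0.0, 2.0, 0.01)
        win = (times > 0.5) & (times < 0.9)  # 400 ms injected window
        rows, Y = [], []
        for p in range(n_pat):
            for c in range(n_ch):
                pe = rng.standard_normal(n_tr)
                for i in range(n_tr):
                    tr = rng.standard_normal(len(times))
                    tr[win] += effect * pe[i]
                    Y.append(tr)
                    rows.append({"patient": p, "channel": f"{p}:{c}", "pe": pe[i]})
        return np.array(Y), pd.DataFrame(rows), times, win

    def test_injected_window_covered(self):
        Y, tab, times, win = self._band_data(0, 0.8)
        res = timecourse_regression_fdr(Y, tab, LMEDesign(fixed=("pe",)),
                                        times=times)
        assert res["mask"][0][win].mean() >= 0.5

    def test_null_mask_mostly_empty(self):
        empty = 0
        for seed in range(10):
            Y, tab, times, _ = self._band_data(50 + seed, 0.0, n_pat=3, n_tr=25)
            res = timecourse_regression_fdr(Y, tab, LMEDesign(fixed=("pe",)),
                                            times=times)
            empty += not res["mask"].any()
        assert empty >= 9

    def test_mask_subset_of_uncorrected(self):
        Y, tab, times, _ = self._band_data(1, 0.4)
        res = timecourse_regression_fdr(Y, tab, LMEDesign(fixed=("pe",)),
                                        times=times, q=0.001)
        uncorrected = res["p"][0] < 0.001
        assert np.all(uncorrected[res["mask"][0]])


def make_coupling_table(seed, stage_shift=0.0, decision_shift=0.0, pe_slope=0.0,
                        pe_slope_switch_only=False, n_pat=6, n_tr=60):
    """Synthetic coupling table with configurable generating effects."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_pat):
        intercept = rng.normal(0, 0.3)
        for tr in range(n_tr):
            dec = rng.integers(0, 2)
            pe = rng.standard_normal()
            rv, ru = rng.random(), rng.random()
            for stage in ("post_feedback", "pre_selection"):
                val = intercept + rng.normal(0, 0.5)
                if stage == "pre_selection":
                    val += stage_shift
                val += decision_shift * dec
                if pe_slope and (not pe_slope_switch_only or dec == 0):
                    val += pe_slope * pe
                rows.append({"patient": p, "trial": tr, "stage": stage,
                             "value": val, "decision": float(dec), "pe": pe,
                             "rv": rv, "ru": ru})
    return pd.DataFrame(rows)


class TestCouplingModels:
    def test_stage_contrast_sign(self):
        # stronger post-feedback coupling → negative stage t (pre-selection=1)
        tab = make_coupling_table(0, stage_shift=-0.5)
        t, p = coupling_stage_contrast(tab, "value")
        assert t < -3 and p < 0.01
        # swapping stage codes flips the sign exactly
        tab2 = tab.copy()
        tab2["stage"] = tab2["stage"].map({"post_feedback": "pre_selection",
                                           "pre_selection": "post_feedback"})
        t2, _ = coupling_stage_contrast(tab2, "value")
        assert t2 == pytest.approx(-t, rel=1e-6)

    def test_stage_contrast_null(self):
        tab = make_coupling_table(1, stage_shift=0.0)
        t, _ = coupling_stage_contrast(tab, "value")
        assert abs(t) < 2.5

    def test_single_stage_rejected(self):
        tab = make_coupling_table(2)
        with pytest.raises(ValueError):
            coupling_stage_contrast(tab[tab.stage == "post_feedback"], "value")

    def test_decision_prediction_sign(self):
        # coupling higher before switches (decision 0) → negative t
        tab = make_coupling_table(3, decision_shift=-0.6)
        t, p = coupling_decision_prediction(tab, "value", stage="pre_selection")
        assert t < -3 and p < 0.01

    def test_decision_prediction_scale_invariance(self):
        tab = make_coupling_table(4, decision_shift=-0.5)
        t1, _ = coupling_decision_prediction(tab, "value", stage="pre_selection")
        tab2 = tab.copy()
        tab2["value"] = 10 * tab2["value"] + 3
        t2, _ = coupling_decision_prediction(tab2, "value", stage="pre_selection")
        assert t1 == pytest.approx(t2, rel=1e-3)

    def test_constant_decision_rejected(self):
        tab = make_coupling_table(5)
        tab["decision"] = 1.0
        with pytest.raises(ValueError):
            coupling_decision_prediction(tab, "value")

    def test_variable_correlation_subset_specificity(self):
        # negative PE slope generated on switch trials only
        tab = make_coupling_table(6, pe_slope=-0.6, pe_slope_switch_only=True)
        post = tab[tab.stage == "post_feedback"]
        sw = coupling_variable_correlation(post, "value", decision_subset="switch")
        stay = coupling_variable_correlation(post, "value", decision_subset="stay")
        t_sw = sw["fit"].loc[sw["fit"].term == "pe", "t"].iloc[0]
        t_st = stay["fit"].loc[stay["fit"].term == "pe", "t"].iloc[0]
        assert t_sw < -3
        assert abs(t_st) < 2.5

    def test_percentile_bins_cover_all_trials(self):
        tab = make_coupling_table(7)
        res = coupling_variable_correlation(tab, "value")
        bins = res["bins"]["pe"]
        assert len(bins) == 25
        assert bins["n"].sum() == res["n_trials"]

    def test_empty_subset_rejected(self):
        tab = make_coupling_table(8)
        with pytest.raises(ValueError):
            coupling_variable_correlation(tab.iloc[:0], "value")
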