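"""Activity statistics: shifts, CDFs, Welch/Wilcoxon, DEG filter, sensor."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tdmd import (
    TargetSet,
    cdf_table,
    cluster_enrichment,
    gen_flow_events,
    mirna_differential,
    per_mirna_summary,
    sensor_repression,
    serum_deg_filter,
    target_set_shift,
)


def _reg(values, contrast="8h"):
    return pd.DataFrame({contrast: values}, index=[f"g{i}" for i in range(len(values))])


class TestTargetSetShift:
    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 0.5, 10000)
        vals[:1000] -= 0.2
        reg = _reg(vals)
        ts = TargetSet.from_iterable("planted", [f"g{i}" for i in range(1000)])
        delta, p = target_set_shift(reg, ts, "8h")
        assert delta == pytest.approx(-0.2, abs=0.05)
        assert p < 1e-10

    def test_all_genes_set_rejected(self):
        reg = _reg(np.arange(10.0))
        ts = TargetSet.from_iterable("all", reg.index)
        with pytest.raises(ValueError):
            target_set_shift(reg, ts, "8h")

    def test_null_type_i_error_controlled(self):
        # sets drawn from the background: rejection rate at alpha=0.05
        # stays near nominal over 1000 resamplings
        rng = np.random.default_rng(1)
        n, k = 2000, 200
        rejections = 0
        values = rng.normal(0, 1, (1000, n))
        for row in values:
            reg = pd.DataFrame({"c": row}, index=[f"g{i}" for i in range(n)])
            members = [f"g{i}" for i in rng.choice(n, k, replace=False)]
            _, p = target_set_shift(reg, TargetSet.from_iterable("s", members), "c")
            rejections += p < 0.05
        assert rejections / 1000 <= 0.06


class TestCdfTable:
    def test_single_value_step(self):
        reg = _reg([1.0, 0.0, 2.0])
        out = cdf_table(reg, [TargetSet.from_iterable("s", ["g0"])], "8h")
        x, y = out["s"]
        assert y[-1] == 1.0 and 1.0 in x

    def test_planted_shift_moves_curve_left(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 0.5, 5000)
        vals[:500] -= 0.5
        reg = _reg(vals)
        out = cdf_table(
            reg, [TargetSet.from_iterable("s", [f"g{i}" for i in range(500)])], "8h"
        )
        xs, ys = out["s"]
        xn, yn = out["non-targets"]
        at0_set = ys[np.searchsorted(xs, 0.0)]
        at0_bg = yn[np.searchsorted(xn, 0.0)]
        assert at0_set > at0_bg  # more mass below zero

    def test_cdf_reaches_one(self):
        reg = _reg(np.random.default_rng(4).normal(size=100))
        for x, y in cdf_table(reg, [], "8h").values():
            assert y[-1] == 1.0


class TestPerMirnaSummary:
    def test_min_target_threshold(self):
        rng = np.random.default_rng(5)
        reg = _reg(rng.normal(size=1000))
        sets = {
            "miR-49": set(f"g{i}" for i in range(49)),
            "miR-50": set(f"g{i}" for i in range(50)),
        }
        out = per_mirna_summary(reg, sets, "8h", min_targets=50)
        assert "miR-49" not in out.index and "miR-50" in out.index

    def test_matches_direct_median(self):
        rng = np.random.default_rng(6)
        reg = _reg(rng.normal(size=500))
        genes = set(f"g{i}" for i in rng.choice(500, 80, replace=False))
        out = per_mirna_summary(reg, {"m": genes}, "8h")
        assert out["m"] == pytest.approx(reg.loc[sorted(genes), "8h"].median())

    def test_planted_mirna_ranks_most_negative(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(0, 0.3, 5000)
        vals[:200] -= 0.4
        reg = _reg(vals)
        sets = {"miR-planted": set(f"g{i}" for i in range(200))}
        for j in range(10):
            sets[f"miR-null-{j}"] = set(
                f"g{i}" for i in rng.choice(5000, 200, replace=False)
            )
        out = per_mirna_summary(reg, sets, "8h")
        assert out.index[0] == "miR-planted"

    def test_all_zero_table(self):
        reg = _reg(np.zeros(100))
        out = per_mirna_summary(reg, {"m": set(f"g{i}" for i in range(60))}, "8h")
        assert out["m"] == 0.0


class TestMirnaDifferential:
    def test_identical_groups_null(self):
        cpm = pd.DataFrame({"r1": [100.0], "r2": [100.0]}, index=["m"])
        out = mirna_differential(cpm, cpm)
        assert out.loc["m", "log2fc"] == 0.0
        assert np.isnan(out.loc["m", "welch_p"]) or out.loc["m", "welch_p"] == 1.0

    def test_planted_doubling_recovered(self):
        rng = np.random.default_rng(8)
        n_mir = 50
        wt = pd.DataFrame(
            2 ** rng.normal(7.0, 0.1, (n_mir, 4)),
            index=[f"m{i}" for i in range(n_mir)],
            columns=[f"wt{j}" for j in range(4)],
        )
        ko = pd.DataFrame(
            2 ** rng.normal(8.0, 0.1, (n_mir, 3)),
            index=wt.index,
            columns=[f"ko{j}" for j in range(3)],
        )
        out = mirna_differential(wt, ko, pseudocount=0.0)
        assert out["log2fc"].mean() == pytest.approx(1.0, abs=0.15)
        assert (out["welch_p"] < 0.05).mean() > 0.9

    def test_matches_scipy_direct(self):
        rng = np.random.default_rng(9)
        wt = pd.DataFrame(rng.uniform(50, 150, (3, 4)), index=list("abc"))
        ko = pd.DataFrame(rng.uniform(50, 150, (3, 3)), index=list("abc"))
        out = mirna_differential(wt, ko)
        lw, lk = np.log2(wt + 1), np.log2(ko + 1)
        for m in "abc":
            t = stats.ttest_ind(lk.loc[m], lw.loc[m], equal_var=False)
            assert out.loc[m, "welch_p"] == pytest.approx(t.pvalue)

    def test_null_type_i_error_controlled(self):
        rng = np.random.default_rng(10)
        reps = 1000
        x = rng.normal(0, 1, (reps, 4))
        y = rng.normal(0, 1, (reps, 4))
        p = stats.ttest_ind(x, y, axis=1, equal_var=False).pvalue
        wt = pd.DataFrame(2.0**x, index=[f"m{i}" for i in range(reps)])
        ko = pd.DataFrame(2.0**y, index=wt.index)
        out = mirna_differential(wt, ko, pseudocount=0.0)
        np.testing.assert_allclose(np.sort(out["welch_p"]), np.sort(p))
        assert (out["welch_p"] < 0.05).mean() <= 0.06

    def test_single_replicate_rejected(self):
        cpm = pd.DataFrame({"r1": [1.0]}, index=["m"])
        with pytest.raises(ValueError):
            mirna_differential(cpm, cpm)


class TestSerumDegFilter:
    def _series(self, genes, data):
        return pd.DataFrame(data, index=genes, columns=["0h", "8h", "12h"])

    def test_single_clone_change_excluded(self):
        genes = ["g"]
        wt = self._series(genes, [[10, 10, 10]])
        ko1 = self._series(genes, [[10, 25, 10]])  # |lfc| > 1 only in clone 1
        ko2 = self._series(genes, [[10, 10, 10]])
        assert serum_deg_filter(wt, ko1, ko2) == []

    def test_concordant_change_included(self):
        genes = ["g"]
        wt = self._series(genes, [[10, 10, 10]])
        ko1 = self._series(genes, [[10, 25, 10]])
        ko2 = self._series(genes, [[10, 26, 10]])
        assert serum_deg_filter(wt, ko1, ko2) == ["g"]

    def test_discordant_signs_excluded(self):
        genes = ["g"]
        wt = self._series(genes, [[10, 10, 10]])
        ko1 = self._series(genes, [[10, 25, 10]])
        ko2 = self._series(genes, [[10, 4, 10]])
        assert serum_deg_filter(wt, ko1, ko2) == []

    def test_planted_deg_set_recovered_exactly(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(500)]
        base = rng.uniform(5, 50, (500, 3))
        wt = self._series(genes, base)
        fold = np.ones((500, 3))
        planted = sorted(rng.choice(500, 40, replace=False))
        for i in planted:
            fold[i, 1] = rng.choice([4.0, 0.25])
        ko1 = self._series(genes, base * fold)
        ko2 = self._series(genes, base * fold)
        assert serum_deg_filter(wt, ko1, ko2) == sorted(f"g{i}" for i in planted)

    def test_monotone_in_lfc_threshold(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(200)]
        wt = self._series(genes, rng.uniform(5, 50, (200, 3)))
        ko1 = self._series(genes, rng.uniform(5, 50, (200, 3)))
        ko2 = self._series(genes, rng.uniform(5, 50, (200, 3)))
        previous = None
        for lfc_min in (0.5, 1.0, 1.5, 2.0):
            current = set(serum_deg_filter(wt, ko1, ko2, lfc_min=lfc_min))
            if previous is not None:
                assert current <= previous
            previous = current


class TestClusterEnrichment:
    def test_closed_form_2x2(self):
        # cluster of 100 with 30 targets vs 100 others with 10: Pearson
        # chi-square = n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 12.5
        assign = pd.Series(
            ["I"] * 100 + ["II"] * 100, index=[f"g{i}" for i in range(200)]
        )
        targets = set(f"g{i}" for i in range(30)) | set(
            f"g{i}" for i in range(100, 110)
        )
        out = cluster_enrichment(assign, targets).set_index("cluster")
        expected = 200 * (30 * 90 - 70 * 10) ** 2 / (100 * 100 * 40 * 160)
        assert out.loc["I", "chi2"] == pytest.approx(expected) == pytest.approx(12.5)

    def test_random_assignment_null(self):
        rng = np.random.default_rng(13)
        genes = [f"g{i}" for i in range(2000)]
        assign = pd.Series(rng.choice(list("ABCDE"), 2000), index=genes)
        targets = set(rng.choice(genes, 300, replace=False))
        out = cluster_enrichment(assign, targets)
        assert (out["p"] < 0.001).sum() == 0

    def test_seeded_cluster_detected(self):
        rng = np.random.default_rng(14)
        genes = [f"g{i}" for i in range(1000)]
        assign = pd.Series(["bg"] * 800 + ["hot"] * 200, index=genes)
        targets = set(rng.choice(genes[:800], 80, replace=False)) | set(
            rng.choice(genes[800:], 60, replace=False)
        )  # 3x density in "hot"
        out = cluster_enrichment(assign, targets).set_index("cluster")
        assert out.loc["hot", "p"] < 1e-4
        assert out.loc["hot", "enrichment"] > 2.0

    def test_degenerate_cluster_flagged(self):
        assign = pd.Series(["A", "A"], index=["g0", "g1"])
        out = cluster_enrichment(assign, set())
        assert np.isnan(out.loc[0, "p"])


class TestSensorRepression:
    def test_identical_populations_fold_one(self):
        pop, _ = gen_flow_events(120000, repression_fold=1.0, seed=15)
        folds, mean_fold = sensor_repression(pop, pop.copy())
        np.testing.assert_allclose(folds, 1.0)
        assert mean_fold == 1.0

    def test_planted_fold_recovered(self):
        sensor, control = gen_flow_events(200000, repression_fold=5.5, seed=16)
        _, mean_fold = sensor_repression(sensor, control)
        assert mean_fold == pytest.approx(5.5, rel=0.04)

    def test_scale_invariance(self):
        sensor, control = gen_flow_events(110000, repression_fold=3.0, seed=17)
        _, base = sensor_repression(sensor, control)
        _, scaled = sensor_repression(sensor * 10.0, control * 10.0)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_monotone_ngfr_rescale_invariance(self):
        sensor, control = gen_flow_events(110000, repression_fold=3.0, seed=18)
        _, base = sensor_repression(sensor, control)
        s2, c2 = sensor.copy(), control.copy()
        s2["dngfr"] = s2["dngfr"] ** 1.7
        c2["dngfr"] = c2["dngfr"] ** 1.7
        _, rescaled = sensor_repression(s2, c2)
        assert rescaled == pytest.approx(base, rel=1e-9)

    def test_scarce_events_shrink_bins(self):
        sensor, control = gen_flow_events(5000, repression_fold=2.0, seed=19)
        folds, mean_fold = sensor_repression(sensor, control)
        assert len(folds) == 100
        assert mean_fold == pytest.approx(2.0, rel=0.1)

    def test_empty_population_rejected(self):
        pop, _ = gen_flow_events(1000, repression_fold=1.0, seed=20)
        with pytest.raises(ValueError):
            sensor_repression(pop.iloc[:0], pop)
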