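"""Chemosensitivity prediction: cell-line selection, centroid classifier, metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sigscreen import (
    CellLinePanel,
    GeneSignature,
    ResponsePrediction,
    SimulationConfig,
    build_centroid,
    classify_by_centroid,
    classify_by_clustering,
    dichotomize_drfs,
    km_by_prediction,
    response_metrics,
    select_sensitive_cell_lines,
    simulate_neoadjuvant_cohort,
)


class TestDichotomize:
    @pytest.mark.parametrize(
        "time,event,expected",
        [
            (2.0, 1, "early_event"),
            (5.0, 0, "survivor"),
            (5.0, 1, "survivor"),  # event after the horizon still counts as 3y survivor
            (2.0, 0, "indeterminate"),
            (3.0, 1, "early_event"),  # boundary: event at the horizon
        ],
    )
    def test_cases(self, time, event, expected):
        assert dichotomize_drfs(time, event, horizon=3.0) == expected

    @given(st.floats(min_value=0.01, max_value=30), st.integers(min_value=0, max_value=1))
    def test_total_and_exclusive(self, time, event):
        out = dichotomize_drfs(time, event)
        assert out in ("early_event", "survivor", "indeterminate")


class TestLineSelection:
    def _panel(self, taxane, anthracycline, her2=None):
        lines = [f"L{i}" for i in range(len(taxane))]
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            rng.normal(size=(8, len(lines))), index=[f"G{i}" for i in range(8)], columns=lines
        )
        ic50 = pd.DataFrame({"taxane": taxane, "anthracycline": anthracycline}, index=lines)
        h = pd.Series(her2, index=lines) if her2 else None
        return CellLinePanel(expression=expr, log_ic50=ic50, her2_status=h)

    def test_strict_cutoff_boundary(self):
        panel = self._panel([-1.5, -1.0, -0.5], [2.0, 2.0, 2.0])
        assert select_sensitive_cell_lines(panel, ["taxane", "anthracycline"]) == ["L0"]

    def test_and_or_semantics(self):
        panel = self._panel([-1.5, 1.0], [1.0, -2.0])
        selected = select_sensitive_cell_lines(panel, ["taxane", "anthracycline"])
        assert selected == ["L0", "L1"]
        taxane_only = select_sensitive_cell_lines(panel, ["taxane"])
        assert taxane_only == ["L0"]  # drug subset selects a subset of lines

    def test_her2_filter(self):
        panel = self._panel([-1.5, -1.5], [2.0, 2.0], her2=["neg", "pos"])
        assert select_sensitive_cell_lines(panel, ["taxane"]) == ["L0"]

    def test_no_sensitive_lines_raises(self):
        panel = self._panel([0.5, 1.0], [0.5, 1.0])
        with pytest.raises(ValueError, match="no sensitive"):
            select_sensitive_cell_lines(panel, ["taxane"])


class TestCentroid:
    def _panel(self):
        genes = [f"G{i}" for i in range(6)]
        lines = ["L0", "L1", "L2"]
        expr = pd.DataFrame(
            [[1.0, 3.0, 5.0]] * 6, index=genes, columns=lines
        )
        ic50 = pd.DataFrame({"taxane": [-2.0, -2.0, -2.0]}, index=lines)
        return CellLinePanel(expression=expr, log_ic50=ic50)

    def test_centroid_is_per_gene_mean(self):
        panel = self._panel()
        sig = GeneSignature(id="S", genes=tuple(panel.expression.index))
        cen = build_centroid(panel, ["L0", "L1"], sig)
        assert (cen.values == 2.0).all()
        assert cen.n_lines_used == 2

    def test_single_line_raises(self):
        panel = self._panel()
        sig = GeneSignature(id="S", genes=tuple(panel.expression.index))
        with pytest.raises(ValueError, match="at least 2"):
            build_centroid(panel, ["L0"], sig)

    def test_line_order_invariant(self):
        panel = self._panel()
        sig = GeneSignature(id="S", genes=tuple(panel.expression.index))
        a = build_centroid(panel, ["L0", "L2"], sig)
        b = build_centroid(panel, ["L2", "L0"], sig)
        pd.testing.assert_series_equal(a.values, b.values)

    def test_too_few_shared_genes_raises(self):
        panel = self._panel()
        sig = GeneSignature(id="S", genes=("G0", "G1", "XX", "YY", "ZZ"))
        with pytest.raises(ValueError, match="need >= 5"):
            build_centroid(panel, ["L0", "L1"], sig)


class TestCentroidClassifier:
    def _centroid(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"G{i}" for i in range(n)]
        from sigscreen import DrugSensitivityCentroid

        return DrugSensitivityCentroid(
            signature_id="S",
            values=pd.Series(rng.normal(size=n), index=genes),
            n_lines_used=5,
            drug_tag="taxane",
        )

    def test_identical_profile_is_sensitive(self):
        cen = self._centroid()
        label, rho = classify_by_centroid(cen.values.copy(), cen)
        assert (label, rho) == ("sensitive", pytest.approx(1.0))

    def test_threshold_is_strict(self):
        # build a profile with Spearman rho mathematically equal to 0.35 by
        # rank surgery: rho = 1 - 6*sum(d^2)/(n(n^2-1)); at n=15 the required
        # squared rank-distance sum (364) is an even integer, hence reachable
        cen = self._centroid(n=15)
        n = 15
        target_sum = round((1 - 0.35) * n * (n**2 - 1) / 6)
        assert (1 - 6 * target_sum / (n * (n**2 - 1))) == pytest.approx(0.35, abs=1e-15)
        perm = _permutation_with_d2(n, target_sum)
        centroid_ranks = np.argsort(np.argsort(cen.values.to_numpy()))
        prof = pd.Series(perm[centroid_ranks].astype(float), index=cen.values.index)
        label, rho = classify_by_centroid(prof, cen)
        assert rho == pytest.approx(0.35, abs=1e-12)
        # a correlation sitting exactly at the threshold must not be called
        # sensitive ("larger than" is strict); pass the realized rho as the
        # threshold so the comparison is bit-exact
        label_at_threshold, _ = classify_by_centroid(prof, cen, threshold=rho)
        assert label_at_threshold == "insensitive"

    def test_decreasing_transform_is_insensitive(self):
        cen = self._centroid()
        label, rho = classify_by_centroid(-2.0 * cen.values + 5.0, cen)
        assert (label, rho) == ("insensitive", pytest.approx(-1.0))

    def test_invariant_to_increasing_transforms(self):
        cen = self._centroid(seed=3)
        rng = np.random.default_rng(4)
        profile = pd.Series(rng.normal(size=len(cen.values)), index=cen.values.index)
        base_label, base_rho = classify_by_centroid(profile, cen)
        for transform in (lambda x: np.exp(x), lambda x: 3 * x - 7):
            label, rho = classify_by_centroid(transform(profile), cen)
            assert label == base_label
            assert rho == pytest.approx(base_rho, abs=1e-12)

    def test_constant_profile_raises(self):
        cen = self._centroid()
        with pytest.raises(ValueError, match="constant"):
            classify_by_centroid(pd.Series(1.0, index=cen.values.index), cen)


def _permutation_with_d2(n: int, target: int) -> np.ndarray:
    """A permutation of 0..n-1 whose squared rank-distance sum equals target.

    Greedy: repeatedly apply the transposition that adds the largest
    achievable even increment without overshooting (swapping i<j adds
    2*(j-i)^2 when both are fixed points).
    """
    perm = np.arange(n)
    remaining = target
    free = list(range(n))
    while remaining > 0:
        best = None
        for ai in range(len(free)):
            for bi in range(ai + 1, len(free)):
                add = 2 * (free[bi] - free[ai]) ** 2
                if add <= remaining and (best is None or add > best[0]):
                    best = (add, ai, bi)
        if best is None:
            raise AssertionError("target squared-distance sum unreachable")
        add, ai, bi = best
        i, j = free[ai], free[bi]
        perm[i], perm[j] = perm[j], perm[i]
        remaining -= add
        del free[bi], free[ai]
    return perm


class TestClusteringPredictor:
    def test_signal_cohort_insensitive_group_has_more_rd(self):
        cfg = SimulationConfig(n_genes=1500, n_samples=150, program_size=50, seed=0)
        hits = 0
        n_rep = 10
        for s in range(n_rep):
            ds, truth = simulate_neoadjuvant_cohort(
                cfg, n_patients=150, pcr_slope=-1.5, pcr_intercept=-0.5, seed=700 + s
            )
            pred = classify_by_clustering(ds, truth.planted_signature())
            rd = ds.clinical["pcr"] == "RD"
            ins = pred.labels == "insensitive"
            hits += rd[ins].mean() > rd[~ins].mean()
        assert hits >= 9

    def test_failed_stratification_raises(self, two_block_dataset):
        sig = GeneSignature(id="S", genes=("NOPE1", "NOPE2", "NOPE3"))
        with pytest.raises(ValueError, match="stratification failed"):
            classify_by_clustering(two_block_dataset, sig)


class TestMetrics:
    def _pred(self, labels):
        return ResponsePrediction(
            method="clustering",
            labels=pd.Series(labels, index=[f"P{i}" for i in range(len(labels))]),
        )

    def _clinical(self, pcr, times=None, events=None):
        n = len(pcr)
        return pd.DataFrame(
            {
                "pcr": pcr,
                "time": times if times is not None else np.full(n, 5.0),
                "event": events if events is not None else np.zeros(n, int),
            },
            index=[f"P{i}" for i in range(n)],
        )

    def test_worked_example(self):
        # 10 predicted insensitive, 8 RD; 20 predicted sensitive, 17 pCR
        labels = ["insensitive"] * 10 + ["sensitive"] * 20
        pcr = ["RD"] * 8 + ["pCR"] * 2 + ["pCR"] * 17 + ["RD"] * 3
        m = response_metrics(self._pred(labels), self._clinical(pcr), "pCR/RD")
        assert m.ppv == pytest.approx(80.0)
        assert m.npv == pytest.approx(85.0)
        assert m.n_evaluable == 30

    def test_perfect_predictor(self):
        labels = ["insensitive"] * 5 + ["sensitive"] * 5
        pcr = ["RD"] * 5 + ["pCR"] * 5
        m = response_metrics(self._pred(labels), self._clinical(pcr), "pCR/RD")
        assert (m.ppv, m.npv, m.sensitivity, m.specificity) == (100.0, 100.0, 100.0, 100.0)

    def test_drfs_mode_excludes_indeterminate(self):
        labels = ["insensitive", "insensitive", "sensitive", "sensitive"]
        clin = self._clinical(
            ["RD"] * 4,
            times=[1.0, 2.0, 5.0, 2.5],
            events=[1, 0, 0, 1],  # P1 censored early: indeterminate
        )
        m = response_metrics(self._pred(labels), clin, "DRFS3y")
        assert m.n_indeterminate == 1
        assert m.n_evaluable == 3
        assert m.tp == 1 and m.fn == 1 and m.tn == 1

    def test_one_sided_predictions_raise(self):
        labels = ["insensitive"] * 4
        with pytest.raises(ValueError, match="NPV undefined"):
            response_metrics(self._pred(labels), self._clinical(["RD"] * 4), "pCR/RD")

    def test_rcb_mode(self):
        labels = ["insensitive"] * 2 + ["sensitive"] * 2
        clin = self._clinical(["RD"] * 4)
        clin["rcb"] = ["II", "III", "0", "I"]
        m = response_metrics(self._pred(labels), clin, "RCB")
        assert (m.ppv, m.npv) == (100.0, 100.0)


class TestKMByPrediction:
    def test_label_name_swap_leaves_p_unchanged(self):
        rng = np.random.default_rng(0)
        n = 60
        times = rng.exponential(5, n)
        events = (rng.random(n) < 0.8).astype(int)
        labels = np.where(rng.random(n) < 0.5, "sensitive", "insensitive")
        pred = ResponsePrediction(
            method="clustering", labels=pd.Series(labels, index=[f"P{i}" for i in range(n)])
        )
        swapped = ResponsePrediction(
            method="clustering",
            labels=pd.Series(
                np.where(labels == "sensitive", "insensitive", "sensitive"),
                index=pred.labels.index,
            ),
        )
        a = km_by_prediction(pred, times, events)
        b = km_by_prediction(swapped, times, events)
        assert a.p == pytest.approx(b.p)
        assert set(a.curves) == {"sensitive", "insensitive"}
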