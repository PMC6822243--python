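import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from diarefine.biomarker_stats import (
    paired_differential,
    panel_auc,
    pearson_pairwise_complete,
    replicate_cv_percent,
    technical_cv,
)
from diarefine.synth_dia import simulate_paired_cohort_table
from diarefine.types import (
    AnnotationTable,
    QuantTable,
    SampleAnnotation,
    ValidationError,
)


def _paired_annotations(n_patients, groups=("tumor", "benign")):
    return AnnotationTable([
        SampleAnnotation(run_id=f"P{p}_{g}", sample_id=f"P{p}_{g}",
                         patient_id=f"P{p}", group=g, tech_replicate=1)
        for p in range(n_patients) for g in groups
    ])


def _paired_table(a_vals, b_vals, groups=("tumor", "benign")):
    n = len(a_vals)
    cols = {}
    for p in range(n):
        cols[f"P{p}_{groups[0]}"] = [a_vals[p]]
        cols[f"P{p}_{groups[1]}"] = [b_vals[p]]
    return QuantTable(level="protein", values=pd.DataFrame(cols, index=["X"]))


def t_pvalue_oracle(diffs):
    """Two-tailed paired-t p by direct quadrature of the t density."""
    diffs = np.asarray(diffs, float)
    n = diffs.size
    t_stat = diffs.mean() / (diffs.std(ddof=1) / math.sqrt(n))
    nu = n - 1
    const = math.gamma((nu + 1) / 2) / (math.sqrt(nu * math.pi) * math.gamma(nu / 2))
    pdf = lambda x: const * (1 + x * x / nu) ** (-(nu + 1) / 2)
    tail, _ = integrate.quad(pdf, abs(t_stat), np.inf)
    return 2.0 * tail


class TestPairedDifferential:
    def test_identical_groups_null(self):
        vals = [10.0, 20.0, 30.0, 40.0]
        res = paired_differential(_paired_table(vals, vals),
                                  _paired_annotations(4), "tumor", "benign")[0]
        assert res.median_fc == pytest.approx(1.0)
        assert res.p_value == 1.0
        assert not res.significant

    def test_constant_fourfold_change_degenerate(self):
        b = [10.0, 20.0, 30.0, 40.0]
        a = [4 * x for x in b]
        res = paired_differential(_paired_table(a, b),
                                  _paired_annotations(4), "tumor", "benign")[0]
        assert res.median_fc == pytest.approx(4.0)
        assert res.degenerate and res.p_value == 0.0
        assert res.significant

    def test_p_matches_t_distribution_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            n = int(rng.integers(4, 12))
            b = rng.lognormal(5, 0.5, n)
            a = b * 2 ** rng.normal(1.0, 0.5, n)
            res = paired_differential(_paired_table(a, b),
                                      _paired_annotations(n), "tumor", "benign")[0]
            assert res.p_value == pytest.approx(
                t_pvalue_oracle(np.log2(a) - np.log2(b)), rel=1e-9)

    def test_antisymmetric_in_group_order(self):
        rng = np.random.default_rng(3)
        b = rng.lognormal(5, 0.5, 6)
        a = b * 2 ** rng.normal(1.5, 0.4, 6)
        fwd = paired_differential(_paired_table(a, b), _paired_annotations(6),
                                  "tumor", "benign")[0]
        rev = paired_differential(_paired_table(a, b), _paired_annotations(6),
                                  "benign", "tumor")[0]
        assert rev.median_fc == pytest.approx(1.0 / fwd.median_fc, rel=1e-12)
        assert rev.p_value == pytest.approx(fwd.p_value, rel=1e-12)

    def test_lt3_pairs_gives_no_p(self):
        res = paired_differential(_paired_table([40.0, 40.0], [10.0, 10.0]),
                                  _paired_annotations(2), "tumor", "benign")[0]
        assert res.p_value is None and not res.significant
        assert res.reason == "lt3_complete_pairs"

    def test_pairs_with_missing_member_dropped(self):
        a = [40.0, 40.0, 40.0, np.nan]
        b = [10.0, 10.0, 10.0, 10.0]
        res = paired_differential(_paired_table(a, b),
                                  _paired_annotations(4), "tumor", "benign")[0]
        assert res.n_pairs_used == 3

    def test_null_calibration_five_percent(self):
        """Under a simulated global null the raw p<=0.05 rate stays near 5%."""
        table, ann, _ = simulate_paired_cohort_table(
            n_null=1000, n_true=0, n_patients=12, seed=11)
        res = paired_differential(table, ann, "tumor", "benign")
        ps = np.array([r.p_value for r in res if r.p_value is not None])
        assert 0.03 <= float((ps <= 0.05).mean()) <= 0.07

    def test_benjamini_hochberg_is_more_conservative(self):
        table, ann, _ = simulate_paired_cohort_table(
            n_null=300, n_true=20, n_patients=12, seed=5)
        raw = paired_differential(table, ann, "tumor", "benign")
        bh = paired_differential(table, ann, "tumor", "benign",
                                 benjamini_hochberg=True)
        assert sum(r.significant for r in bh) <= sum(r.significant for r in raw)


class TestTechnicalCv:
    def test_identical_replicates_zero_cv(self):
        assert replicate_cv_percent([100.0, 100.0]) == 0.0

    def test_closed_form_pair(self):
        assert replicate_cv_percent([90.0, 110.0]) == pytest.approx(
            math.sqrt(200.0) / 100.0 * 100.0)

    def test_lognormal_median_cv_matches_analytic(self):
        """Median CV of multiplicative noise sigma_log=0.15 approaches
        sqrt(exp(sigma^2)-1) x 100 once enough replicates tame the
        small-sample bias of the SD estimator."""
        rng = np.random.default_rng(15)
        sigma = 0.15
        n_rows = 1000
        reps = range(1, 9)
        base = rng.lognormal(8, 1, n_rows)
        runs = {}
        for s in ("smpA", "smpB"):
            for r in reps:
                runs[f"{s}_R{r}"] = base * rng.lognormal(0, sigma, n_rows)
        ann = AnnotationTable([
            SampleAnnotation(run_id=f"{s}_R{r}", sample_id=s, patient_id=s,
                             group="tumor", tech_replicate=r)
            for s in ("smpA", "smpB") for r in reps
        ])
        table = QuantTable(level="precursor", values=pd.DataFrame(runs))
        _, summary = technical_cv(table, ann)
        expected = math.sqrt(math.exp(sigma**2) - 1) * 100.0
        assert summary == pytest.approx(expected, abs=1.5)


class TestPearsonPairwiseComplete:
    def test_identity_and_negation(self):
        x = np.arange(10.0)
        assert pearson_pairwise_complete(x, x) == pytest.approx(1.0)
        assert pearson_pairwise_complete(x, -x) == pytest.approx(-1.0)

    def test_matches_subset_oracle_with_missing(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            x = rng.normal(size=20)
            y = 0.7 * x + rng.normal(size=20)
            x[rng.choice(20, 3, replace=False)] = np.nan
            y[rng.choice(20, 2, replace=False)] = np.nan
            got = pearson_pairwise_complete(x, y)
            mask = np.isfinite(x) & np.isfinite(y)
            xs, ys = x[mask], y[mask]
            oracle = (np.mean(xs * ys) - xs.mean() * ys.mean()) / (
                xs.std() * ys.std())
            assert got == pytest.approx(oracle, rel=1e-9)

    def test_insufficient_pairs_undefined(self):
        x = np.array([1.0, 2.0, np.nan, np.nan])
        y = np.array([1.0, np.nan, 2.0, np.nan])
        assert pearson_pairwise_complete(x, y) is None


class TestPanelAuc:
    def test_perfect_separation(self):
        scores = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        labels = np.array([0, 0, 0, 1, 1, 1], dtype=bool)
        assert panel_auc(scores, labels) == 1.0

    def test_constant_scores_give_half(self):
        assert panel_auc(np.ones(8), np.arange(8) % 2 == 0) == 0.5

    def test_matches_pairwise_count_oracle_with_ties(self):
        rng = np.random.default_rng(30)
        for _ in range(20):
            scores = rng.integers(0, 5, size=12).astype(float)
            labels = np.zeros(12, dtype=bool)
            labels[rng.choice(12, 6, replace=False)] = True
            got = panel_auc(scores, labels)
            pos = scores[labels]
            neg = scores[~labels]
            wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            assert got == pytest.approx(wins / (pos.size * neg.size), rel=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(31)
        scores = rng.normal(size=20)
        labels = rng.random(20) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        assert panel_auc(np.exp(scores), labels) == pytest.approx(
            panel_auc(scores, labels))

    def test_matches_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(32)
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.4
        labels[0], labels[1] = True, False
        assert panel_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            panel_auc(np.arange(4.0), np.ones(4, dtype=bool))
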