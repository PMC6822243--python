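"""Cohort-level biomarker statistics.

Paired differential abundance with volcano classification (median
fold-change across patients plus a two-tailed paired t-test on log2
values), technical coefficient of variation, pairwise-complete Pearson
correlation, and rank-based panel AUC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import AnnotationTable, QuantTable, ValidationError


@dataclass
class DifferentialResult:
    row_id: str
    median_fc: float | None
    median_log2_fc: float | None
    p_value: float | None
    n_pairs_used: int
    significant: bool
    degenerate: bool = False
    reason: str = ""


def _sample_groups(
    annotations: AnnotationTable, group_a: str, group_b: str
) -> dict[str, dict[str, str]]:
    """patient_id -> {group: sample_id} for the two groups of interest."""
    out: dict[str, dict[str, str]] = {}
    for sample_id, (patient, group) in annotations.sample_meta().items():
        if group in (group_a, group_b):
            out.setdefault(patient, {})[group] = sample_id
    return out


def paired_differential(
    table: QuantTable,
    annotations: AnnotationTable,
    group_a: str,
    group_b: str,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    benjamini_hochberg: bool = False,
) -> list[DifferentialResult]:
    """Per-row paired comparison of group_a over group_b across patients.

    fc = median over patients of (a/b), the median taken on the log2 scale
    so that swapping the groups inverts it exactly; p = two-tailed paired
    t-test on the log2 values.  A row is significant when (fc >= threshold or
    fc <= 1/threshold) and p <= alpha.  Patients missing either member are
    dropped per row; fewer than 3 complete pairs yields no p-value.  Rows
    with constant nonzero log2 differences are degenerate: p is reported as
    0 and flagged, significance decided by the fold-change alone.  With
    ``benjamini_hochberg`` the rule is applied to BH-adjusted p-values.
    """
    pairs_by_patient = _sample_groups(annotations, group_a, group_b)
    pairs = [
        (p[group_a], p[group_b])
        for _, p in sorted(pairs_by_patient.items())
        if group_a in p and group_b in p
    ]
    if not pairs:
        raise ValidationError(
            f"no patients with both groups {group_a!r} and {group_b!r}"
        )
    results: list[DifferentialResult] = []
    for row_id in table.row_ids:
        series = table.values.loc[row_id]
        a_vals, b_vals = [], []
        for sa, sb in pairs:
            va = series.get(sa, np.nan)
            vb = series.get(sb, np.nan)
            if math.isfinite(va) and math.isfinite(vb) and va > 0 and vb > 0:
                a_vals.append(va)
                b_vals.append(vb)
        n = len(a_vals)
        if n == 0:
            results.append(DifferentialResult(
                row_id, None, None, None, 0, False, reason="no_complete_pairs"))
            continue
        # median fold-change taken in log space: with an even number of
        # patients the two central ratios average geometrically, keeping
        # the group swap exactly antisymmetric (fc -> 1/fc)
        log2_fc = float(np.median(np.log2(a_vals) - np.log2(b_vals)))
        fc = float(2.0 ** log2_fc)
        fc_hit = fc >= fc_threshold or fc <= 1.0 / fc_threshold
        if n < 3:
            results.append(DifferentialResult(
                row_id, fc, log2_fc, None, n, False, reason="lt3_complete_pairs"))
            continue
        diffs = np.log2(a_vals) - np.log2(b_vals)
        # rounding can leave a constant difference with ~1e-16 variance
        if float(np.std(diffs)) <= 1e-12 * max(1.0, float(np.abs(np.mean(diffs)))):
            if float(np.mean(diffs)) == 0.0:
                results.append(DifferentialResult(
                    row_id, fc, log2_fc, 1.0, n, False,
                    degenerate=True, reason="identical_groups"))
            else:
                results.append(DifferentialResult(
                    row_id, fc, log2_fc, 0.0, n, fc_hit,
                    degenerate=True, reason="zero_variance_differences"))
            continue
        t_res = stats.ttest_rel(np.log2(a_vals), np.log2(b_vals))
        p = float(t_res.pvalue)
        results.append(DifferentialResult(
            row_id, fc, log2_fc, p, n, fc_hit and p <= alpha))

    if benjamini_hochberg:
        testable = [r for r in results if r.p_value is not None and not r.degenerate]
        if testable:
            adjusted = stats.false_discovery_control(
                [r.p_value for r in testable], method="bh"
            )
            for r, q in zip(testable, adjusted):
                q = float(q)
                fc_hit = (r.median_fc is not None
                          and (r.median_fc >= fc_threshold
                               or r.median_fc <= 1.0 / fc_threshold))
                r.p_value = q
                r.significant = fc_hit and q <= alpha
    return results


def differential_to_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.row_id, r.median_fc, r.median_log2_fc, r.p_value, r.n_pairs_used,
          int(r.significant), int(r.degenerate), r.reason) for r in results],
        columns=["row_id", "median_fc", "median_log2_fc", "p_value",
                 "n_pairs_used", "significant", "degenerate", "reason"],
    )


# ---------------------------------------------------------------------------
# Technical CV
# ---------------------------------------------------------------------------

def technical_cv(
    table: QuantTable, annotations: AnnotationTable
) -> tuple[pd.Series, float]:
    """Per-row median technical CV (%) across samples, plus the overall median.

    For each row and sample with >= 2 replicate values, CV = sample standard
    deviation / mean x 100; the row CV is the median over its samples and
    the summary is the median over rows.  Zero-mean cells are skipped.
    """
    by_sample = annotations.runs_by_sample()
    run_cols = set(table.column_ids)
    row_cvs = {}
    for row in table.row_ids:
        series = table.values.loc[row]
        cvs = []
        for sample, runs in by_sample.items():
            vals = [series[r] for r in runs if r in run_cols and math.isfinite(series[r])]
            if len(vals) < 2:
                continue
            mean = float(np.mean(vals))
            if mean == 0:
                continue
            cvs.append(float(np.std(vals, ddof=1)) / mean * 100.0)
        if cvs:
            row_cvs[row] = float(np.median(cvs))
    per_row = pd.Series(row_cvs, dtype=float)
    summary = float(per_row.median()) if len(per_row) else float("nan")
    return per_row, summary


def replicate_cv_percent(values: np.ndarray) -> float:
    """CV (%) of one replicate set: sd(ddof=1)/mean x 100."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("CV needs >= 2 replicate values")
    mean = float(values.mean())
    if mean == 0:
        raise ValidationError("CV undefined for zero mean")
    return float(values.std(ddof=1)) / mean * 100.0


# ---------------------------------------------------------------------------
# Correlation and AUC
# ---------------------------------------------------------------------------

def pearson_pairwise_complete(x: np.ndarray, y: np.ndarray) -> float | None:
    """Pearson r over the jointly non-missing indices only.

    Mirrors R's ``cor(..., use="pairwise.complete.obs")``.  Fewer than 3
    complete pairs, or zero variance in either subset, yields None.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must share a length")
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3:
        return None
    xs, ys = x[mask], y[mask]
    if np.std(xs) == 0 or np.std(ys) == 0:
        return None
    return float(np.corrcoef(xs, ys)[0, 1])


def panel_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    AUC = P(score_case > score_control) + 0.5 P(tie), computed from average
    ranks; invariant under any strictly monotone transform of the scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("panel_auc needs both classes non-empty")
    ranks = stats.rankdata(scores)
    u = float(ranks[labels].sum()) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)
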