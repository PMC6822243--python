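"""Retention-time calibration and fragment peak-shape modelling.

Covers the per-run linear iRT calibration, sub-trace extraction around an
expected apex, peak-boundary detection by outward walk from the apex,
trapezoidal area integration, and the fragment "good peak shape" score:
the Pearson correlation of a fragment trace against the peak-group
consensus (the pointwise median of the max-normalized fragment traces).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .config import QuantConfig
from .types import FragmentTrace, RtCalibration, ValidationError


class NoSignalError(ValueError):
    """Trace carries no usable signal for boundary detection."""


# ---------------------------------------------------------------------------
# iRT calibration
# ---------------------------------------------------------------------------

def _ols(irt: np.ndarray, rt: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(irt, rt, 1)
    return float(slope), float(intercept)


def fit_rt_calibration(anchor_pairs: Sequence[tuple[float, float]]) -> RtCalibration:
    """Least-squares iRT -> RT line with one pass of outlier rejection.

    An initial fit over all anchors defines residuals; pairs whose absolute
    residual exceeds 3x the median absolute residual are dropped (only if at
    least 4 pairs would survive) and the line is refit on the survivors.
    """
    pairs = [(float(i), float(r)) for i, r in anchor_pairs]
    if len(pairs) < 2:
        raise ValidationError("insufficient anchors: need >= 2 (iRT, RT) pairs")
    irt = np.array([p[0] for p in pairs])
    rt = np.array([p[1] for p in pairs])
    if np.unique(irt).size < 2:
        raise ValidationError("degenerate calibration: all iRT values identical")

    slope, intercept = _ols(irt, rt)
    resid = np.abs(rt - (slope * irt + intercept))
    med = float(np.median(resid))
    keep = resid <= 3.0 * med
    if med > 0 and keep.sum() >= 4 and keep.sum() < len(pairs):
        if np.unique(irt[keep]).size >= 2:
            irt, rt = irt[keep], rt[keep]
            slope, intercept = _ols(irt, rt)

    final_resid = rt - (slope * irt + intercept)
    n = int(irt.size)
    sd = float(np.sqrt(np.sum(final_resid ** 2) / (n - 2))) if n > 2 else 0.0
    return RtCalibration(slope=slope, intercept=intercept, residual_sd=sd, n_points=n)


def predict_rt(cal: RtCalibration, irt: float) -> float:
    return cal.slope * irt + cal.intercept


# ---------------------------------------------------------------------------
# Trace windowing
# ---------------------------------------------------------------------------

def window_trace(trace: FragmentTrace, center: float, half_width: float) -> FragmentTrace:
    """Closed-interval sub-trace on [center - half_width, center + half_width]."""
    if half_width <= 0:
        raise ValidationError("half_width must be > 0")
    mask = (trace.times >= center - half_width) & (trace.times <= center + half_width)
    flags = trace.flags
    if not mask.any():
        flags = tuple(set(flags) | {"empty_window"})
    return FragmentTrace(
        run_id=trace.run_id,
        precursor_id=trace.precursor_id,
        fragment_id=trace.fragment_id,
        times=trace.times[mask],
        intensities=trace.intensities[mask],
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Boundary detection
# ---------------------------------------------------------------------------

def detect_boundaries(
    trace: FragmentTrace,
    apex_rt: float,
    cap_s: float = 60.0,
    baseline_frac: float = 0.05,
    apex_search_halfwidth_s: float = 15.0,
) -> tuple[float, float, float]:
    """Locate (rt_start, rt_end, refined apex) around a seeded apex.

    The apex is re-centered on the most intense point within the search
    radius of the seed; each boundary then walks outward to the first local
    minimum (strictly below its inward neighbour and not above its outward
    one) whose intensity falls to max(baseline_frac x apex, the minimum
    intensity on that side), capped at ``cap_s`` from the apex.
    """
    if trace.is_empty:
        raise NoSignalError("empty trace")
    t, y = trace.times, trace.intensities
    if not np.any(y > 0):
        raise NoSignalError("no signal: all intensities zero")

    seed = float(np.clip(apex_rt, t[0], t[-1]))
    near = np.abs(t - seed) <= apex_search_halfwidth_s
    if near.any():
        idx_near = np.flatnonzero(near)
        apex_idx = int(idx_near[np.argmax(y[idx_near])])
    else:
        apex_idx = int(np.argmin(np.abs(t - seed)))
    if y[apex_idx] <= 0:  # seed landed on a dead region; fall back to global max
        apex_idx = int(np.argmax(y))
    apex_t = float(t[apex_idx])
    apex_y = float(y[apex_idx])

    def _walk(direction: int) -> float:
        idx = apex_idx
        within = np.abs(t - apex_t) <= cap_s
        if direction < 0:
            rng = range(apex_idx - 1, -1, -1)
        else:
            rng = range(apex_idx + 1, t.size)
        side_vals = [y[j] for j in rng if within[j]]
        side_min = min(side_vals) if side_vals else apex_y
        thresh = max(baseline_frac * apex_y, side_min)
        last = apex_idx
        for j in rng:
            if not within[j]:
                break
            inward = j - direction
            outward = j + direction
            descended = y[j] < y[inward]
            turned = outward < 0 or outward >= t.size or y[j] <= y[outward]
            if descended and turned and y[j] <= thresh:
                return float(t[j])
            last = j
        # no qualifying minimum: cap at the furthest in-range point
        if last == apex_idx:
            return apex_t + direction * min(cap_s, 1.0)
        return float(t[last])

    rt_start = _walk(-1)
    rt_end = _walk(+1)
    if not (rt_start < apex_t < rt_end):
        raise NoSignalError("degenerate boundaries around apex")
    return rt_start, rt_end, apex_t


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def integrate_area(trace: FragmentTrace, rt_start: float, rt_end: float) -> float:
    """Trapezoidal area of the trace restricted to [rt_start, rt_end].

    Bounds falling between samples are handled by linear interpolation, so
    the integral is exactly additive over adjacent intervals.  Returns 0
    when no sample point lies inside the bounds.
    """
    if rt_start >= rt_end:
        raise ValidationError("require rt_start < rt_end")
    t, y = trace.times, trace.intensities
    if t.size == 0:
        return 0.0
    inside = (t >= rt_start) & (t <= rt_end)
    if not inside.any():
        return 0.0
    lo = max(rt_start, float(t[0]))
    hi = min(rt_end, float(t[-1]))
    if hi <= lo:
        return 0.0
    interior = t[(t > lo) & (t < hi)]
    ts = np.concatenate([[lo], interior, [hi]])
    ys = np.interp(ts, t, y)
    return float(np.trapezoid(ys, ts))


# ---------------------------------------------------------------------------
# Consensus and shape scoring
# ---------------------------------------------------------------------------

def _resample(trace: FragmentTrace, grid: np.ndarray) -> np.ndarray:
    if trace.times.size == 0:
        return np.zeros_like(grid)
    return np.interp(grid, trace.times, trace.intensities, left=0.0, right=0.0)


def consensus_trace(
    traces: Sequence[FragmentTrace],
    rt_lo: float,
    rt_hi: float,
    step_s: float = 1.0,
) -> FragmentTrace:
    """Pointwise median of max-normalized fragment traces on a uniform grid.

    The median makes the consensus robust to a minority of interfered
    fragments; max-normalization removes the library-intensity scale so
    every fragment votes on shape alone.
    """
    if not traces:
        raise ValidationError("consensus needs >= 1 trace")
    grid = np.arange(rt_lo, rt_hi + step_s * 0.5, step_s)
    rows = []
    for tr in traces:
        y = _resample(tr, grid)
        m = y.max()
        rows.append(y / m if m > 0 else y)
    cons = np.median(np.vstack(rows), axis=0)
    first = traces[0]
    return FragmentTrace(
        run_id=first.run_id,
        precursor_id=first.precursor_id,
        fragment_id="__consensus__",
        times=grid,
        intensities=np.maximum(cons, 0.0),
    )


def shape_score(
    fragment: FragmentTrace,
    consensus: FragmentTrace,
    rt_start: float,
    rt_end: float,
    step_s: float = 1.0,
) -> float:
    """Pearson correlation of fragment vs consensus on a uniform grid.

    Both traces are linearly resampled onto a ``step_s`` grid spanning
    [rt_start, rt_end].  A zero-variance vector yields 0 (never "good").
    """
    grid = np.arange(rt_start, rt_end + step_s * 0.5, step_s)
    if grid.size < 4:
        raise ValidationError("shape score needs >= 4 grid points")
    a = _resample(fragment, grid)
    b = _resample(consensus, grid)
    sa, sb = float(np.std(a)), float(np.std(b))
    if sa == 0.0 or sb == 0.0:
        return 0.0
    r = float(np.corrcoef(a, b)[0, 1])
    return max(-1.0, min(1.0, r))


def apex_snr(
    fragment: FragmentTrace,
    rt_start: float,
    rt_end: float,
) -> float:
    """Apex intensity over the median intensity outside the peak boundaries.

    Computed within the (already windowed) extraction trace.  With no
    points outside the boundaries, or a zero outside-median, the SNR is
    infinite: there is no measurable background to argue against the peak.
    """
    t, y = fragment.times, fragment.intensities
    inside = (t >= rt_start) & (t <= rt_end)
    if not inside.any():
        return 0.0
    apex = float(y[inside].max())
    outside = y[~inside]
    if outside.size == 0:
        return math.inf
    noise = float(np.median(outside))
    if noise <= 0:
        return math.inf if apex > 0 else 0.0
    return apex / noise


def score_fragments(
    traces: dict[str, FragmentTrace],
    apex_seed: float,
    cfg: QuantConfig,
) -> tuple[dict[str, float], dict[str, float], tuple[float, float, float]]:
    """Window, build consensus, detect boundaries and score every fragment.

    Returns (shape scores, SNRs, (rt_start, rt_end, apex)).  Raises
    :class:`NoSignalError` when the consensus carries no signal.
    """
    half = cfg.rt_extraction_halfwidth_s
    windowed = {
        fid: window_trace(tr, apex_seed, half) for fid, tr in sorted(traces.items())
    }
    cons = consensus_trace(
        list(windowed.values()), apex_seed - half, apex_seed + half,
        step_s=cfg.resample_step_s,
    )
    rt_start, rt_end, apex = detect_boundaries(
        cons, apex_seed,
        cap_s=cfg.boundary_cap_s,
        baseline_frac=cfg.boundary_baseline_frac,
        apex_search_halfwidth_s=cfg.apex_search_halfwidth_s,
    )
    scores = {}
    snrs = {}
    for fid, tr in windowed.items():
        scores[fid] = shape_score(tr, cons, rt_start, rt_end, step_s=cfg.resample_step_s)
        snrs[fid] = apex_snr(tr, rt_start, rt_end)
    return scores, snrs, (rt_start, rt_end, apex)
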