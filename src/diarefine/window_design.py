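"""Variable isolation-window design by equal segmentation of precursor signal.

Window boundaries are placed at the k/n quantiles of the cumulative
precursor ion-signal distribution over the mass range, so that every
window isolates (approximately) the same total precursor signal.  Linear
interpolation inside histogram bins makes the boundary placement exact and
reproducible.
"""

from __future__ import annotations

import numpy as np

from .types import Ms1Density, ValidationError, WindowScheme


def _restrict(density: Ms1Density, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
    """Clip the histogram to [lo, hi], splitting edge bins proportionally."""
    edges = density.bin_edges
    counts = density.bin_ion_counts
    if lo < edges[0] - 1e-9 or hi > edges[-1] + 1e-9:
        raise ValidationError(
            f"mz_range [{lo}, {hi}] outside density support "
            f"[{edges[0]}, {edges[-1]}]"
        )
    new_edges = [lo]
    new_counts = []
    for i in range(counts.size):
        a, b = edges[i], edges[i + 1]
        s, e = max(a, lo), min(b, hi)
        if e <= s:
            continue
        frac = (e - s) / (b - a)
        new_edges.append(e)
        new_counts.append(counts[i] * frac)
    return np.asarray(new_edges), np.asarray(new_counts)


def _invert_cdf(edges: np.ndarray, counts: np.ndarray, target: float) -> float:
    """m/z at which the cumulative ion count equals ``target`` (linear in-bin)."""
    cum = np.concatenate([[0.0], np.cumsum(counts)])
    i = int(np.searchsorted(cum, target, side="left"))
    i = min(max(i, 1), counts.size)
    inside = target - cum[i - 1]
    width = edges[i] - edges[i - 1]
    frac = inside / counts[i - 1] if counts[i - 1] > 0 else 0.0
    return float(edges[i - 1] + frac * width)


def design_windows(
    density: Ms1Density,
    n_windows: int,
    mz_range: tuple[float, float],
    overlap_margin: float = 0.5,
) -> WindowScheme:
    """Equal-ion-signal window boundaries over ``mz_range``.

    Interior boundaries sit at the k/n quantiles (k = 1..n-1) of the
    cumulative ion-count distribution; the first and last boundary clamp
    to the mass range.  The scheme records ``overlap_margin`` for the
    acquisition-side expanded windows.
    """
    lo, hi = float(mz_range[0]), float(mz_range[1])
    if not lo < hi:
        raise ValidationError("mz_range must satisfy lo < hi")
    if n_windows < 1:
        raise ValidationError("n_windows must be >= 1")
    edges, counts = _restrict(density, lo, hi)
    total = counts.sum()
    if total <= 0:
        raise ValidationError("no ion signal inside mz_range")
    boundaries = [lo]
    for k in range(1, n_windows):
        boundaries.append(_invert_cdf(edges, counts, total * k / n_windows))
    boundaries.append(hi)
    b = np.asarray(boundaries)
    if not np.all(np.diff(b) > 0):
        raise ValidationError(
            f"n_windows={n_windows} exceeds the resolvable quantiles of the density"
        )
    return WindowScheme(boundaries=b, overlap_margin=overlap_margin)


def design_windows_by_count(
    precursor_mzs: np.ndarray,
    n_windows: int,
    mz_range: tuple[float, float],
    overlap_margin: float = 0.5,
    bin_width: float = 1.0,
) -> WindowScheme:
    """Count-based variant: equal numbers of precursors per window."""
    mzs = np.asarray(precursor_mzs, dtype=float)
    lo, hi = float(mz_range[0]), float(mz_range[1])
    edges = np.arange(lo, hi + bin_width * 0.5, bin_width)
    if edges[-1] < hi:
        edges = np.append(edges, hi)
    counts, _ = np.histogram(mzs, bins=edges)
    density = Ms1Density(bin_edges=edges, bin_ion_counts=counts.astype(float))
    return design_windows(density, n_windows, mz_range, overlap_margin)


def scheme_balance(density: Ms1Density, scheme: WindowScheme) -> np.ndarray:
    """Fraction of total ion count isolated by each window (margins ignored)."""
    lo = float(scheme.boundaries[0])
    hi = float(scheme.boundaries[-1])
    edges, counts = _restrict(density, lo, hi)
    total = counts.sum()
    if total <= 0:
        raise ValidationError("no ion signal under the scheme")
    cum_edges = np.concatenate([[0.0], np.cumsum(counts)])

    def cdf(x: float) -> float:
        i = int(np.searchsorted(edges, x, side="right"))
        i = min(max(i, 1), edges.size - 1)
        a, b = edges[i - 1], edges[i]
        frac = (min(x, b) - a) / (b - a) if b > a else 0.0
        return float(cum_edges[i - 1] + frac * counts[i - 1])

    fracs = np.array([
        (cdf(e) - cdf(s)) / total for s, e in scheme.windows
    ])
    return fracs
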