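"""Run-level normalization and technical-replicate filtering.

Three corrections applied between precursor quantification and protein
roll-up: per-SWATH-window MS2-TIC normalization (removes per-run,
per-window injection and instrument response factors), discordant
technical-duplicate exclusion (duplicates with a fold-change of two or
more are discarded, concordant ones merged), and run-median normalization
of the final matrix.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .types import (
    AnnotationTable,
    QuantTable,
    TicTable,
    ValidationError,
    WindowScheme,
)

logger = logging.getLogger(__name__)


def assign_window(precursor_mz: float, scheme: WindowScheme) -> int:
    """Index of the isolation window containing ``precursor_mz``.

    Windows are half-open [start, end); when margin-expanded windows
    overlap, the lower index wins.
    """
    for i, (start, end) in enumerate(scheme.windows):
        if start <= precursor_mz < end:
            return i
    raise ValidationError(f"uncovered m/z: {precursor_mz}")


def precursor_windows(
    precursor_mzs: dict[str, float], scheme: WindowScheme
) -> dict[str, int]:
    return {p: assign_window(mz, scheme) for p, mz in precursor_mzs.items()}


def tic_normalize(
    table: QuantTable,
    tics: TicTable,
    windows: dict[str, int],
) -> QuantTable:
    """Scale each cell by median-run TIC over its window's run TIC.

    normalized(run, p) = raw(run, p) x median_runs(tic(., w_p)) / tic(run, w_p).
    Anchoring at the cross-run median TIC keeps values in area units.  A
    zero or absent TIC for a needed (run, window) pair is an error.
    """
    out = table.copy()
    runs = out.column_ids
    needed = sorted({w for w in windows.values()})
    factors: dict[int, dict[str, float]] = {}
    for w in needed:
        per_run = {}
        for run in runs:
            tic = tics.get(run, w)
            if tic is None or tic <= 0:
                raise ValidationError(f"tic missing or zero for (run={run}, window={w})")
            per_run[run] = tic
        med = float(np.median(list(per_run.values())))
        factors[w] = {run: med / tic for run, tic in per_run.items()}
    for row in out.row_ids:
        if row not in windows:
            raise ValidationError(f"no window assignment for row {row}")
        f = factors[windows[row]]
        out.values.loc[row] = out.values.loc[row] * pd.Series(f)
    return out


def filter_tech_replicates(
    table: QuantTable,
    annotations: AnnotationTable,
    fc_threshold: float = 2.0,
) -> tuple[QuantTable, pd.DataFrame]:
    """Collapse run-level columns to samples, dropping discordant duplicates.

    Per row and sample: with >= 2 replicate values present, a max/min ratio
    at or above ``fc_threshold`` discards the value (reason
    ``tech_fc_ge2``); concordant replicates merge by geometric mean; a
    single present replicate is carried with flag ``single_replicate``.
    """
    by_sample = annotations.runs_by_sample()
    run_cols = set(table.column_ids)
    sample_ids = sorted(by_sample)
    values = pd.DataFrame(
        np.nan, index=table.row_ids, columns=sample_ids, dtype=float
    )
    reasons: dict[tuple[str, str], str] = {}
    flags: dict[tuple[str, str], str] = {}
    log_rows = []
    for row in table.row_ids:
        series = table.values.loc[row]
        for sample, runs in by_sample.items():
            present = [series[r] for r in runs if r in run_cols and math.isfinite(series[r])]
            if not present:
                reasons[(row, sample)] = "no_replicate_value"
                continue
            if len(present) == 1:
                values.loc[row, sample] = present[0]
                flags[(row, sample)] = "single_replicate"
                continue
            ratio = max(present) / min(present)
            if ratio >= fc_threshold:
                reasons[(row, sample)] = "tech_fc_ge2"
                log_rows.append((row, sample, len(present), ratio, "excluded"))
            else:
                merged = float(np.exp(np.mean(np.log(present))))
                values.loc[row, sample] = merged
                log_rows.append((row, sample, len(present), ratio, "merged"))
    filtered = QuantTable(
        level=table.level, values=values,
        provenance=dict(table.provenance), reasons=reasons, flags=flags,
    )
    log = pd.DataFrame(
        log_rows, columns=["row_id", "sample_id", "n_replicates", "fold_change", "action"]
    )
    return filtered, log


def median_normalize(table: QuantTable) -> QuantTable:
    """Equalize per-run medians, anchored at the grand median of run medians.

    Each column is divided by its median over non-missing rows and scaled
    by the grand median, preserving within-run rank order and the overall
    abundance scale.  An all-missing column is an error.
    """
    out = table.copy()
    medians = out.values.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = list(medians.index[medians.isna()])
        raise ValidationError(f"column(s) with all values missing: {', '.join(bad)}")
    if (medians <= 0).any():
        bad = list(medians.index[medians <= 0])
        raise ValidationError(f"column(s) with nonpositive median: {', '.join(bad)}")
    grand = float(np.median(medians.to_numpy()))
    out.values = out.values.div(medians, axis=1) * grand
    return out
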