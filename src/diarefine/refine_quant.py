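"""Reference-anchored precursor quantification.

The core procedure: for every peptide precursor, the run with the lowest
identification m_score becomes the reference; fragments forming a good
peak shape in the reference are retained (precursors with fewer than four
good fragments are excluded); every other run is then quantified against
the reference as the median of per-fragment area ratios, scaled by the
reference quantity (the sum of the retained reference fragment areas).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import QuantConfig
from .peak_model import (
    NoSignalError,
    fit_rt_calibration,
    integrate_area,
    predict_rt,
    score_fragments,
    window_trace,
)
from .types import (
    AnnotationTable,
    ChromatogramStore,
    Exclusion,
    IdentificationRecord,
    QuantTable,
    RefinedPrecursor,
    RtCalibration,
    ScoreTable,
    TransitionLibrary,
    ValidationError,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Reference selection
# ---------------------------------------------------------------------------

def _apex_window_intensity(
    store: ChromatogramStore,
    run_id: str,
    precursor_id: str,
    apex_rt: float,
    half_width: float,
) -> float:
    total = 0.0
    for tr in store.traces_for(run_id, precursor_id).values():
        sub = window_trace(tr, apex_rt, half_width)
        total += float(sub.intensities.sum())
    return total


def select_reference(
    records: list[IdentificationRecord],
    store: ChromatogramStore | None = None,
    cfg: QuantConfig | None = None,
) -> str:
    """Run with the lowest m_score; ties broken by higher apex-window summed
    intensity, then lexicographic run_id."""
    if not records:
        raise ValidationError("no identification records for precursor")
    cfg = cfg or QuantConfig()
    best_score = min(r.m_score for r in records)
    tied = [r for r in records if r.m_score == best_score]
    if len(tied) == 1 or store is None:
        return sorted(tied, key=lambda r: r.run_id)[0].run_id

    def sort_key(rec: IdentificationRecord):
        inten = _apex_window_intensity(
            store, rec.run_id, rec.precursor_id, rec.apex_rt,
            cfg.rt_extraction_halfwidth_s,
        )
        return (-inten, rec.run_id)

    return sorted(tied, key=sort_key)[0].run_id


# ---------------------------------------------------------------------------
# Reference refinement
# ---------------------------------------------------------------------------

def refine_reference(
    precursor_id: str,
    reference_run: str,
    store: ChromatogramStore,
    library: TransitionLibrary,
    cal: RtCalibration,
    scores: ScoreTable,
    cfg: QuantConfig | None = None,
) -> RefinedPrecursor | Exclusion:
    """Score every library fragment in the reference run and keep the good ones.

    Good = consensus shape correlation >= shape_good_threshold AND apex SNR
    >= snr_threshold.  Fewer than ``min_good_fragments`` good fragments
    excludes the precursor ("lt4_good_fragments" under the default of 4).
    """
    cfg = cfg or QuantConfig()
    traces = store.traces_for(reference_run, precursor_id)
    if not traces or all(tr.intensities.sum() <= 0 for tr in traces.values()):
        return Exclusion(precursor_id, "no_reference_signal",
                         detail=f"reference_run={reference_run}")

    rec = scores.get(reference_run, precursor_id)
    apex_seed = rec.apex_rt if rec is not None else predict_rt(cal, library.irt_of(precursor_id))

    try:
        shape, snr, (rt_start, rt_end, apex) = score_fragments(traces, apex_seed, cfg)
    except NoSignalError:
        return Exclusion(precursor_id, "no_reference_signal",
                         detail=f"reference_run={reference_run}")

    good = [
        fid for fid in sorted(traces)
        if shape[fid] >= cfg.shape_good_threshold and snr[fid] >= cfg.snr_threshold
    ]
    if len(good) < cfg.min_good_fragments:
        return Exclusion(
            precursor_id, "lt4_good_fragments",
            detail=f"n_good={len(good)} reference_run={reference_run}",
        )
    areas = {
        fid: integrate_area(window_trace(traces[fid], apex_seed,
                                         cfg.rt_extraction_halfwidth_s),
                            rt_start, rt_end)
        for fid in good
    }
    return RefinedPrecursor(
        precursor_id=precursor_id,
        reference_run=reference_run,
        retained_fragments=good,
        reference_areas=areas,
        reference_quantity=float(sum(areas.values())),
        rt_start=rt_start,
        rt_end=rt_end,
        apex_rt=apex,
    )


# ---------------------------------------------------------------------------
# Target-run quantification
# ---------------------------------------------------------------------------

def median_ratio_abundance(
    reference_areas: dict[str, float],
    target_areas: dict[str, float],
    reference_quantity: float,
    min_nonzero: int = 4,
) -> tuple[float | None, str | None]:
    """Median of per-fragment target/reference area ratios, anchored at the
    reference quantity.

    Fragments with zero reference area contribute no ratio; if fewer than
    ``min_nonzero`` fragments have a nonzero target area the result is
    missing with reason ``weak_target_signal``.
    """
    ratios = []
    n_nonzero = 0
    for fid, ref_area in reference_areas.items():
        tgt = target_areas.get(fid, 0.0)
        if tgt > 0:
            n_nonzero += 1
        if ref_area > 0:
            ratios.append(tgt / ref_area)
    if n_nonzero < min_nonzero:
        return None, "weak_target_signal"
    if not ratios:
        return None, "no_reference_area"
    return float(np.median(ratios)) * reference_quantity, None


def quantify_run(
    refined: RefinedPrecursor,
    run_id: str,
    store: ChromatogramStore,
    library: TransitionLibrary,
    cal: RtCalibration,
    scores: ScoreTable,
    cfg: QuantConfig | None = None,
) -> tuple[float | None, str | None]:
    """Abundance of one precursor in one target run, or (None, reason).

    The reference run quantifies as its own reference quantity (ratio 1 by
    construction).  Target boundaries are re-detected on the target's
    consensus over the retained fragments, seeded at the target's scored
    apex when present, else at the calibrated library retention time.
    """
    cfg = cfg or QuantConfig()
    if run_id == refined.reference_run:
        return refined.reference_quantity, None

    all_traces = store.traces_for(run_id, refined.precursor_id)
    traces = {fid: all_traces[fid] for fid in refined.retained_fragments
              if fid in all_traces}
    if not traces:
        return None, "no_traces"

    rec = scores.get(run_id, refined.precursor_id)
    apex_seed = (rec.apex_rt if rec is not None
                 else predict_rt(cal, library.irt_of(refined.precursor_id)))
    try:
        _, _, (rt_start, rt_end, _) = score_fragments(traces, apex_seed, cfg)
    except NoSignalError:
        return None, "weak_target_signal"

    target_areas = {
        fid: integrate_area(window_trace(tr, apex_seed, cfg.rt_extraction_halfwidth_s),
                            rt_start, rt_end)
        for fid, tr in traces.items()
    }
    return median_ratio_abundance(
        refined.reference_areas, target_areas, refined.reference_quantity,
        min_nonzero=cfg.min_good_fragments,
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class PrecursorQuantResult:
    table: QuantTable
    exclusions: list[Exclusion]
    refined: dict[str, RefinedPrecursor] = field(default_factory=dict)
    reference_m_scores: dict[str, float] = field(default_factory=dict)


def fit_run_calibrations(
    library: TransitionLibrary,
    scores: ScoreTable,
    run_ids: list[str] | None = None,
) -> dict[str, RtCalibration]:
    """Per-run iRT calibration from the identified precursors' (iRT, apex)."""
    runs = run_ids if run_ids is not None else scores.run_ids()
    cals: dict[str, RtCalibration] = {}
    for run in runs:
        pairs = [
            (library.irt_of(rec.precursor_id), rec.apex_rt)
            for rec in scores
            if rec.run_id == run and rec.precursor_id in library.precursor_index
        ]
        if len(pairs) >= 2:
            cals[run] = fit_rt_calibration(pairs)
    return cals


def build_precursor_table(
    library: TransitionLibrary,
    store: ChromatogramStore,
    scores: ScoreTable,
    annotations: AnnotationTable,
    cals: dict[str, RtCalibration] | None = None,
    cfg: QuantConfig | None = None,
) -> PrecursorQuantResult:
    """Quantify every library precursor in every annotated run.

    Runs present in the annotations but without any chromatograms are
    dropped with a warning.  Every excluded precursor appears in the
    exclusion log with a typed reason; every missing cell carries a reason
    code.
    """
    cfg = cfg or QuantConfig()
    run_ids = [r for r in annotations.run_ids() if store.precursors_in(r)]
    dropped = sorted(set(annotations.run_ids()) - set(run_ids))
    if dropped:
        logger.warning("runs without chromatograms dropped: %s", ", ".join(dropped))
    if not run_ids:
        raise ValidationError("no runs with chromatograms")

    if cals is None:
        cals = fit_run_calibrations(library, scores, run_ids)

    rows: dict[str, dict[str, float]] = {}
    provenance: dict[str, str] = {}
    reasons: dict[tuple[str, str], str] = {}
    exclusions: list[Exclusion] = []
    refined_map: dict[str, RefinedPrecursor] = {}
    ref_m: dict[str, float] = {}

    for precursor_id in library.precursor_ids:
        if library.transitions_for(precursor_id)[0].is_decoy:
            continue
        records = [r for r in scores.for_precursor(precursor_id) if r.run_id in run_ids]
        if not records:
            exclusions.append(Exclusion(precursor_id, "no_identification"))
            logger.info("precursor %s skipped: no identification records", precursor_id)
            continue
        reference_run = select_reference(records, store=store, cfg=cfg)
        cal = cals.get(reference_run)
        if cal is None:
            exclusions.append(Exclusion(precursor_id, "no_calibration",
                                        detail=f"run={reference_run}"))
            continue
        refined = refine_reference(
            precursor_id, reference_run, store, library, cal, scores, cfg
        )
        if isinstance(refined, Exclusion):
            exclusions.append(refined)
            continue
        refined_map[precursor_id] = refined
        ref_rec = scores.get(reference_run, precursor_id)
        if ref_rec is not None:
            ref_m[precursor_id] = ref_rec.m_score
        provenance[precursor_id] = reference_run
        row: dict[str, float] = {}
        for run in run_ids:
            run_cal = cals.get(run, cal)
            if not store.traces_for(run, precursor_id):
                reasons[(precursor_id, run)] = "no_traces"
                row[run] = np.nan
                continue
            value, reason = quantify_run(
                refined, run, store, library, run_cal, scores, cfg
            )
            if value is None:
                reasons[(precursor_id, run)] = reason or "missing"
                row[run] = np.nan
            else:
                row[run] = value
        rows[precursor_id] = row

    values = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    values = values.reindex(columns=run_ids)
    values = values.loc[sorted(values.index)] if len(values) else values
    table = QuantTable(level="precursor", values=values,
                       provenance=provenance, reasons=reasons)
    return PrecursorQuantResult(
        table=table, exclusions=exclusions,
        refined=refined_map, reference_m_scores=ref_m,
    )


def exclusions_to_frame(exclusions: list[Exclusion]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.precursor_id, e.reason, e.detail) for e in exclusions],
        columns=["precursor_id", "reason", "detail"],
    )
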