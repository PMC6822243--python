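"""Best-flier protein roll-up.

A protein's abundance profile is represented by its single most reliably
quantified peptide precursor — the one with the fewest missing sample
values — copied verbatim.  Poorly responding peptides are thereby kept out
of the protein estimate entirely.  Shared (non-proteotypic) peptides are
excluded from inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import Exclusion, QuantTable, TransitionLibrary, ValidationError


@dataclass(frozen=True)
class ProteinRollup:
    protein_id: str
    best_flier: str
    n_candidate_precursors: int
    missing_count_of_best: int


def _missing_count(row: pd.Series) -> int:
    return int(row.isna().sum())


def select_best_flier(
    rows: pd.DataFrame,
    reference_m_scores: dict[str, float] | None = None,
) -> str:
    """Precursor with the fewest missing values.

    Ties break by higher median abundance over non-missing values, then by
    lower reference-run m_score, then lexicographic precursor_id.
    """
    if rows.empty:
        raise ValidationError("no precursor rows to select from")
    ref_m = reference_m_scores or {}

    def key(precursor_id: str):
        row = rows.loc[precursor_id]
        med = row.median(skipna=True)
        med = -math.inf if pd.isna(med) else float(med)
        return (
            _missing_count(row),
            -med,
            ref_m.get(precursor_id, math.inf),
            precursor_id,
        )

    return min(rows.index, key=key)


def rollup_to_proteins(
    table: QuantTable,
    library: TransitionLibrary,
    reference_m_scores: dict[str, float] | None = None,
) -> tuple[QuantTable, list[ProteinRollup], list[Exclusion]]:
    """Collapse a precursor-level table to protein level by best flier.

    Each protein row is the best flier's row copied verbatim (no new
    numbers are invented).  Precursors mapping to more than one protein
    are excluded with reason ``non_proteotypic``; proteins whose every
    precursor was excluded upstream are absent from the output.
    """
    exclusions: list[Exclusion] = []
    candidates: dict[str, list[str]] = {}
    for precursor_id in table.row_ids:
        if precursor_id not in library.precursor_index:
            exclusions.append(Exclusion(precursor_id, "not_in_library"))
            continue
        proteins = library.proteins_of(precursor_id)
        if len(proteins) != 1:
            exclusions.append(Exclusion(
                precursor_id, "non_proteotypic",
                detail=";".join(proteins),
            ))
            continue
        candidates.setdefault(proteins[0], []).append(precursor_id)

    rollups: list[ProteinRollup] = []
    rows: dict[str, pd.Series] = {}
    provenance: dict[str, str] = {}
    for protein_id in sorted(candidates):
        precursors = candidates[protein_id]
        sub = table.values.loc[precursors]
        best = select_best_flier(sub, reference_m_scores)
        rows[protein_id] = table.values.loc[best]
        provenance[protein_id] = best
        rollups.append(ProteinRollup(
            protein_id=protein_id,
            best_flier=best,
            n_candidate_precursors=len(precursors),
            missing_count_of_best=_missing_count(table.values.loc[best]),
        ))

    values = (pd.DataFrame(rows).T if rows
              else pd.DataFrame(columns=table.column_ids, dtype=float))
    values = values.reindex(columns=table.column_ids).astype(float)
    protein_table = QuantTable(level="protein", values=values, provenance=provenance)
    return protein_table, rollups, exclusions


def rollups_to_frame(rollups: list[ProteinRollup]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.protein_id, r.best_flier, r.n_candidate_precursors,
          r.missing_count_of_best) for r in rollups],
        columns=["protein_id", "best_flier", "n_candidate_precursors",
                 "missing_count_of_best"],
    )
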