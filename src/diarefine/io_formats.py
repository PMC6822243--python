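"""Readers and writers for every on-disk artifact.

All tables are tab-separated UTF-8 with '.' decimal separators and the
literal token ``NA`` for missing abundances.  Lines starting with ``#`` are
treated as comments (the CLI stamps provenance headers this way).  Floats
are serialized with 12 significant digits, which the round-trip tests pin
down.

Dialects
--------
transitions.tsv   precursor_id, peptide_sequence, precursor_charge,
                  precursor_mz, fragment_id, fragment_mz, irt,
                  library_intensity, protein_id, is_decoy
chromatograms.tsv run_id, precursor_id, fragment_id, rt_s, intensity
scores.tsv        run_id, precursor_id, m_score, apex_rt_s
tic.tsv           run_id, window_index, tic
annotations.tsv   run_id, sample_id, patient_id, group, tech_replicate
windows.tsv       window_index, start_mz, end_mz      (pre-margin tiling)
ms1 density .tsv  bin_start_mz, bin_end_mz, ion_count
quant tables      first column precursor_id / protein_id, one column per
                  run or sample, NA for missing
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import (
    AnnotationTable,
    ChromatogramStore,
    FormatError,
    FragmentTrace,
    IdentificationRecord,
    LibraryTransition,
    MISSING_TOKEN,
    Ms1Density,
    QuantTable,
    RunWindowTic,
    SampleAnnotation,
    ScoreTable,
    TicTable,
    TransitionLibrary,
    ValidationError,
    WindowScheme,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"

_TRANSITION_COLUMNS = [
    "precursor_id", "peptide_sequence", "precursor_charge", "precursor_mz",
    "fragment_id", "fragment_mz", "irt", "library_intensity", "protein_id",
    "is_decoy",
]
_CHROM_COLUMNS = ["run_id", "precursor_id", "fragment_id", "rt_s", "intensity"]
_SCORE_COLUMNS = ["run_id", "precursor_id", "m_score", "apex_rt_s"]
_TIC_COLUMNS = ["run_id", "window_index", "tic"]
_ANNOTATION_COLUMNS = ["run_id", "sample_id", "patient_id", "group", "tech_replicate"]
_WINDOW_COLUMNS = ["window_index", "start_mz", "end_mz"]
_DENSITY_COLUMNS = ["bin_start_mz", "bin_end_mz", "ion_count"]


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    return df


def _to_float(df: pd.DataFrame, column: str, path: str | Path) -> np.ndarray:
    raw = df[column]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & (raw != MISSING_TOKEN)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise FormatError(
            f"{path}: non-numeric value {raw[bad].iloc[0]!r} in column "
            f"{column!r} at line {line}"
        )
    return out.to_numpy(dtype=float)


def _write_tsv(df: pd.DataFrame, path: str | Path,
               header_comments: Iterable[str] = ()) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT,
                  na_rep=MISSING_TOKEN, lineterminator="\n")


# ---------------------------------------------------------------------------
# Transition library
# ---------------------------------------------------------------------------

def read_transition_list(path: str | Path) -> TransitionLibrary:
    """Parse a flattened transition-list TSV into a validated library.

    Decoy transitions are retained with ``is_decoy=True``.  Duplicate
    (precursor_id, fragment_id) rows raise a :class:`ValidationError`
    naming the offending key.
    """
    df = _read_tsv(path, _TRANSITION_COLUMNS)
    for col in ("precursor_mz", "fragment_mz", "irt", "library_intensity"):
        _to_float(df, col, path)
    entries = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            entries.append(LibraryTransition(
                precursor_id=row.precursor_id,
                peptide_sequence=row.peptide_sequence,
                precursor_charge=int(row.precursor_charge),
                precursor_mz=float(row.precursor_mz),
                fragment_id=row.fragment_id,
                fragment_mz=float(row.fragment_mz),
                irt=float(row.irt),
                library_intensity=float(row.library_intensity),
                protein_id=row.protein_id,
                is_decoy=_parse_bool(row.is_decoy),
            ))
        except (ValueError, ValidationError) as exc:
            raise FormatError(f"{path}: line {i + 2}: {exc}") from exc
    return TransitionLibrary(entries)


def _parse_bool(token: str) -> bool:
    t = str(token).strip().lower()
    if t in ("1", "true", "t", "yes"):
        return True
    if t in ("0", "false", "f", "no", ""):
        return False
    raise ValueError(f"cannot parse boolean {token!r}")


def write_transition_list(library: TransitionLibrary, path: str | Path,
                          header_comments: Iterable[str] = ()) -> None:
    rows = [
        {
            "precursor_id": t.precursor_id,
            "peptide_sequence": t.peptide_sequence,
            "precursor_charge": t.precursor_charge,
            "precursor_mz": t.precursor_mz,
            "fragment_id": t.fragment_id,
            "fragment_mz": t.fragment_mz,
            "irt": t.irt,
            "library_intensity": t.library_intensity,
            "protein_id": t.protein_id,
            "is_decoy": int(t.is_decoy),
        }
        for t in library.entries
    ]
    _write_tsv(pd.DataFrame(rows, columns=_TRANSITION_COLUMNS), path, header_comments)


# ---------------------------------------------------------------------------
# Chromatograms
# ---------------------------------------------------------------------------

def read_chromatograms(path: str | Path) -> ChromatogramStore:
    """Load long-format extracted fragment traces.

    Points within one trace are sorted ascending by time; duplicate time
    points are summed.  Traces with fewer than 3 points are kept but
    flagged ``unscorable``.
    """
    df = _read_tsv(path, _CHROM_COLUMNS)
    rt = _to_float(df, "rt_s", path)
    inten = _to_float(df, "intensity", path)
    if np.any(inten < 0):
        line = int(np.flatnonzero(inten < 0)[0]) + 2
        raise FormatError(f"{path}: negative intensity at line {line}")
    store = ChromatogramStore()
    work = df[["run_id", "precursor_id", "fragment_id"]].copy()
    work["rt_s"] = rt
    work["intensity"] = inten
    grouped = work.groupby(["run_id", "precursor_id", "fragment_id"], sort=True)
    for (run_id, precursor_id, fragment_id), g in grouped:
        agg = g.groupby("rt_s", sort=True)["intensity"].sum()
        times = agg.index.to_numpy(dtype=float)
        flags = ("unscorable",) if times.size < 3 else ()
        store.add(FragmentTrace(
            run_id=run_id, precursor_id=precursor_id, fragment_id=fragment_id,
            times=times, intensities=agg.to_numpy(dtype=float), flags=flags,
        ))
    return store


def write_chromatograms(store: ChromatogramStore, path: str | Path,
                        header_comments: Iterable[str] = ()) -> None:
    frames = []
    for tr in store:
        frames.append(pd.DataFrame({
            "run_id": tr.run_id,
            "precursor_id": tr.precursor_id,
            "fragment_id": tr.fragment_id,
            "rt_s": tr.times,
            "intensity": tr.intensities,
        }))
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=_CHROM_COLUMNS))
    _write_tsv(df, path, header_comments)


# ---------------------------------------------------------------------------
# Scores, TIC, annotations
# ---------------------------------------------------------------------------

def read_scores(path: str | Path,
                annotations: AnnotationTable | None = None) -> ScoreTable:
    df = _read_tsv(path, _SCORE_COLUMNS)
    m = _to_float(df, "m_score", path)
    apex = _to_float(df, "apex_rt_s", path)
    records = []
    for i in range(len(df)):
        try:
            records.append(IdentificationRecord(
                precursor_id=df["precursor_id"].iloc[i],
                run_id=df["run_id"].iloc[i],
                m_score=float(m[i]),
                apex_rt=float(apex[i]),
            ))
        except ValidationError as exc:
            raise FormatError(f"{path}: line {i + 2}: {exc}") from exc
    table = ScoreTable(records)
    if annotations is not None:
        known = set(annotations.run_ids())
        unknown = sorted({r.run_id for r in records} - known)
        if unknown:
            warnings.warn(
                f"{path}: run_id(s) absent from annotations (records kept): "
                f"{', '.join(unknown)}",
                stacklevel=2,
            )
    return table


def write_scores(scores: ScoreTable, path: str | Path,
                 header_comments: Iterable[str] = ()) -> None:
    df = pd.DataFrame(
        [(r.run_id, r.precursor_id, r.m_score, r.apex_rt) for r in scores],
        columns=_SCORE_COLUMNS,
    )
    _write_tsv(df, path, header_comments)


def read_tic_table(path: str | Path) -> TicTable:
    df = _read_tsv(path, _TIC_COLUMNS)
    tic = _to_float(df, "tic", path)
    records = []
    for i in range(len(df)):
        try:
            records.append(RunWindowTic(
                run_id=df["run_id"].iloc[i],
                window_index=int(df["window_index"].iloc[i]),
                tic=float(tic[i]),
            ))
        except (ValueError, ValidationError) as exc:
            raise FormatError(f"{path}: line {i + 2}: {exc}") from exc
    return TicTable(records)


def write_tic_table(tics: TicTable, path: str | Path,
                    header_comments: Iterable[str] = ()) -> None:
    df = pd.DataFrame(
        [(r.run_id, r.window_index, r.tic) for r in tics.records],
        columns=_TIC_COLUMNS,
    )
    _write_tsv(df, path, header_comments)


def read_annotations(path: str | Path) -> AnnotationTable:
    df = _read_tsv(path, _ANNOTATION_COLUMNS)
    annotations = []
    for i in range(len(df)):
        try:
            annotations.append(SampleAnnotation(
                run_id=df["run_id"].iloc[i],
                sample_id=df["sample_id"].iloc[i],
                patient_id=df["patient_id"].iloc[i],
                group=df["group"].iloc[i],
                tech_replicate=int(df["tech_replicate"].iloc[i]),
            ))
        except ValueError as exc:
            raise FormatError(f"{path}: line {i + 2}: {exc}") from exc
    return AnnotationTable(annotations)


def write_annotations(annotations: AnnotationTable, path: str | Path,
                      header_comments: Iterable[str] = ()) -> None:
    df = pd.DataFrame(
        [(a.run_id, a.sample_id, a.patient_id, a.group, a.tech_replicate)
         for a in annotations],
        columns=_ANNOTATION_COLUMNS,
    )
    _write_tsv(df, path, header_comments)


# ---------------------------------------------------------------------------
# Quant tables
# ---------------------------------------------------------------------------

def write_quant_table(table: QuantTable, path: str | Path,
                      header_comments: Iterable[str] = ()) -> None:
    id_col = f"{table.level}_id"
    df = table.values.copy()
    df.insert(0, id_col, df.index)
    _write_tsv(df.reset_index(drop=True), path, header_comments)


def read_quant_table(path: str | Path, level: str | None = None) -> QuantTable:
    df = _read_tsv(path, [])
    if df.shape[1] < 2:
        raise FormatError(f"{path}: quant table needs an id column plus >=1 run column")
    id_col = df.columns[0]
    if id_col not in ("precursor_id", "protein_id"):
        raise FormatError(f"{path}: first column must be precursor_id or protein_id")
    inferred = "precursor" if id_col == "precursor_id" else "protein"
    if level is not None and level != inferred:
        raise FormatError(f"{path}: expected a {level}-level table, found {id_col}")
    values = df.set_index(id_col)
    for col in values.columns:
        values[col] = _to_float(values, col, path)
    values.index.name = None
    return QuantTable(level=inferred, values=values.astype(float))


# ---------------------------------------------------------------------------
# Window schemes and MS1 density
# ---------------------------------------------------------------------------

def read_window_scheme(path: str | Path, overlap_margin: float = 0.0) -> WindowScheme:
    df = _read_tsv(path, _WINDOW_COLUMNS)
    start = _to_float(df, "start_mz", path)
    end = _to_float(df, "end_mz", path)
    order = np.argsort(df["window_index"].astype(int).to_numpy())
    start, end = start[order], end[order]
    if not np.allclose(start[1:], end[:-1], rtol=0, atol=1e-9):
        raise FormatError(f"{path}: windows must tile without gaps")
    boundaries = np.concatenate([start, end[-1:]])
    return WindowScheme(boundaries=boundaries, overlap_margin=overlap_margin)


def write_window_scheme(scheme: WindowScheme, path: str | Path,
                        header_comments: Iterable[str] = ()) -> None:
    df = pd.DataFrame(
        [(i, s, e) for i, (s, e) in enumerate(scheme.windows)],
        columns=_WINDOW_COLUMNS,
    )
    _write_tsv(df, path, header_comments)


def read_ms1_density(path: str | Path) -> Ms1Density:
    df = _read_tsv(path, _DENSITY_COLUMNS)
    start = _to_float(df, "bin_start_mz", path)
    end = _to_float(df, "bin_end_mz", path)
    counts = _to_float(df, "ion_count", path)
    order = np.argsort(start)
    start, end, counts = start[order], end[order], counts[order]
    if not np.allclose(start[1:], end[:-1], rtol=0, atol=1e-9):
        raise FormatError(f"{path}: density bins must be contiguous")
    return Ms1Density(
        bin_edges=np.concatenate([start, end[-1:]]),
        bin_ion_counts=counts,
    )


def write_ms1_density(density: Ms1Density, path: str | Path,
                      header_comments: Iterable[str] = ()) -> None:
    df = pd.DataFrame({
        "bin_start_mz": density.bin_edges[:-1],
        "bin_end_mz": density.bin_edges[1:],
        "ion_count": density.bin_ion_counts,
    })
    _write_tsv(df, path, header_comments)
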