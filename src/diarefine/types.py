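"""Domain containers shared across the toolkit.

The central objects mirror the artifacts of a targeted DIA/SWATH analysis:
a transition library (precursor -> fragment inventory), per-run extracted
fragment chromatograms, OpenSWATH-style identification scores, per-window
MS2 total-ion-chromatogram tables, sample annotations, and the quantitative
matrices produced by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

MISSING_TOKEN = "NA"


class FormatError(ValueError):
    """A table violates its documented on-disk dialect."""


class ValidationError(ValueError):
    """In-memory data violates a structural invariant."""


# ---------------------------------------------------------------------------
# Transition library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibraryTransition:
    """One precursor->fragment assay coordinate.

    ``protein_id`` may contain several accessions joined by ';' for shared
    (non-proteotypic) peptides; such precursors are excluded from protein
    roll-up downstream.
    """

    precursor_id: str
    peptide_sequence: str
    precursor_charge: int
    precursor_mz: float
    fragment_id: str
    fragment_mz: float
    irt: float
    library_intensity: float
    protein_id: str
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValidationError(f"precursor_mz must be > 0 ({self.precursor_id})")
        if self.fragment_mz <= 0:
            raise ValidationError(f"fragment_mz must be > 0 ({self.fragment_id})")
        if self.library_intensity < 0:
            raise ValidationError(
                f"library_intensity must be >= 0 ({self.precursor_id}/{self.fragment_id})"
            )
        if self.precursor_charge <= 0:
            raise ValidationError(f"precursor_charge must be positive ({self.precursor_id})")

    @property
    def protein_ids(self) -> tuple[str, ...]:
        return tuple(p for p in self.protein_id.split(";") if p)


@dataclass
class TransitionLibrary:
    """Validated set of library transitions with precursor/protein indices."""

    entries: list[LibraryTransition]
    precursor_index: dict[str, list[LibraryTransition]] = field(init=False)
    protein_index: dict[str, list[str]] = field(init=False)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        self.precursor_index = {}
        self.protein_index = {}
        meta: dict[str, tuple[str, int]] = {}
        for tr in self.entries:
            key = (tr.precursor_id, tr.fragment_id)
            if key in seen:
                raise ValidationError(f"duplicate (precursor_id, fragment_id): {key}")
            seen.add(key)
            prev = meta.get(tr.precursor_id)
            cur = (tr.peptide_sequence, tr.precursor_charge)
            if prev is not None and prev != cur:
                raise ValidationError(
                    f"precursor_id {tr.precursor_id!r} maps to conflicting "
                    f"(sequence, charge): {prev} vs {cur}"
                )
            meta[tr.precursor_id] = cur
            self.precursor_index.setdefault(tr.precursor_id, []).append(tr)
            for prot in tr.protein_ids:
                lst = self.protein_index.setdefault(prot, [])
                if tr.precursor_id not in lst:
                    lst.append(tr.precursor_id)

    @property
    def precursor_ids(self) -> list[str]:
        return sorted(self.precursor_index)

    def transitions_for(self, precursor_id: str) -> list[LibraryTransition]:
        return self.precursor_index[precursor_id]

    def irt_of(self, precursor_id: str) -> float:
        return self.precursor_index[precursor_id][0].irt

    def proteins_of(self, precursor_id: str) -> tuple[str, ...]:
        return self.precursor_index[precursor_id][0].protein_ids

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# Identification scores, annotations, TIC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IdentificationRecord:
    """OpenSWATH-style identification of one precursor in one run.

    ``m_score`` is an FDR-controlled confidence score; lower is better.
    """

    precursor_id: str
    run_id: str
    m_score: float
    apex_rt: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.m_score <= 1.0:
            raise ValidationError(
                f"m_score outside [0,1]: {self.m_score} "
                f"({self.run_id}/{self.precursor_id})"
            )
        if self.apex_rt < 0:
            raise ValidationError(f"apex_rt must be >= 0 ({self.run_id}/{self.precursor_id})")


class ScoreTable:
    """Identification records indexed by (run, precursor)."""

    def __init__(self, records: Iterable[IdentificationRecord]):
        self.records: list[IdentificationRecord] = list(records)
        self._by_key: dict[tuple[str, str], IdentificationRecord] = {}
        self._by_precursor: dict[str, list[IdentificationRecord]] = {}
        for rec in self.records:
            self._by_key[(rec.run_id, rec.precursor_id)] = rec
            self._by_precursor.setdefault(rec.precursor_id, []).append(rec)

    def get(self, run_id: str, precursor_id: str) -> IdentificationRecord | None:
        return self._by_key.get((run_id, precursor_id))

    def for_precursor(self, precursor_id: str) -> list[IdentificationRecord]:
        return self._by_precursor.get(precursor_id, [])

    def run_ids(self) -> list[str]:
        return sorted({r.run_id for r in self.records})

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[IdentificationRecord]:
        return iter(self.records)


@dataclass(frozen=True)
class SampleAnnotation:
    run_id: str
    sample_id: str
    patient_id: str
    group: str
    tech_replicate: int


class AnnotationTable:
    def __init__(self, annotations: Iterable[SampleAnnotation]):
        self.annotations = list(annotations)
        seen: set[str] = set()
        for a in self.annotations:
            if a.run_id in seen:
                raise ValidationError(f"duplicate run_id in annotations: {a.run_id}")
            seen.add(a.run_id)
        self._by_run = {a.run_id: a for a in self.annotations}

    def get(self, run_id: str) -> SampleAnnotation:
        return self._by_run[run_id]

    def run_ids(self) -> list[str]:
        return sorted(self._by_run)

    def sample_of(self, run_id: str) -> str:
        return self._by_run[run_id].sample_id

    def runs_by_sample(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for a in self.annotations:
            out.setdefault(a.sample_id, []).append(a.run_id)
        return {s: sorted(rs) for s, rs in sorted(out.items())}

    def sample_meta(self) -> dict[str, tuple[str, str]]:
        """sample_id -> (patient_id, group)."""
        out: dict[str, tuple[str, str]] = {}
        for a in self.annotations:
            out[a.sample_id] = (a.patient_id, a.group)
        return out

    def __iter__(self) -> Iterator[SampleAnnotation]:
        return iter(self.annotations)

    def __len__(self) -> int:
        return len(self.annotations)


@dataclass(frozen=True)
class RunWindowTic:
    run_id: str
    window_index: int
    tic: float

    def __post_init__(self) -> None:
        if self.window_index < 0:
            raise ValidationError("window_index must be >= 0")
        if self.tic < 0:
            raise ValidationError(f"tic must be >= 0 ({self.run_id}, {self.window_index})")


class TicTable:
    def __init__(self, records: Iterable[RunWindowTic]):
        self.records = list(records)
        self._by_key: dict[tuple[str, int], float] = {}
        for rec in self.records:
            key = (rec.run_id, rec.window_index)
            if key in self._by_key:
                raise ValidationError(f"duplicate (run_id, window_index): {key}")
            self._by_key[key] = rec.tic

    def get(self, run_id: str, window_index: int) -> float | None:
        return self._by_key.get((run_id, window_index))

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Chromatograms
# ---------------------------------------------------------------------------

@dataclass
class FragmentTrace:
    """One fragment's extracted ion chromatogram in one run."""

    run_id: str
    precursor_id: str
    fragment_id: str
    times: np.ndarray
    intensities: np.ndarray
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValidationError("times and intensities must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError(
                f"times must be strictly ascending "
                f"({self.run_id}/{self.precursor_id}/{self.fragment_id})"
            )
        if np.any(self.intensities < 0):
            raise ValidationError("intensities must be nonnegative")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def is_empty(self) -> bool:
        return self.times.size == 0


class ChromatogramStore:
    """Map (run_id, precursor_id, fragment_id) -> FragmentTrace."""

    def __init__(self, traces: Iterable[FragmentTrace] = ()):
        self._data: dict[str, dict[str, dict[str, FragmentTrace]]] = {}
        self.n_traces = 0
        for tr in traces:
            self.add(tr)

    def add(self, trace: FragmentTrace) -> None:
        frags = self._data.setdefault(trace.run_id, {}).setdefault(trace.precursor_id, {})
        if trace.fragment_id in frags:
            raise ValidationError(
                f"duplicate trace {(trace.run_id, trace.precursor_id, trace.fragment_id)}"
            )
        frags[trace.fragment_id] = trace
        self.n_traces += 1

    def get(self, run_id: str, precursor_id: str, fragment_id: str) -> FragmentTrace | None:
        return self._data.get(run_id, {}).get(precursor_id, {}).get(fragment_id)

    def traces_for(self, run_id: str, precursor_id: str) -> dict[str, FragmentTrace]:
        return dict(self._data.get(run_id, {}).get(precursor_id, {}))

    def run_ids(self) -> list[str]:
        return sorted(self._data)

    def precursors_in(self, run_id: str) -> list[str]:
        return sorted(self._data.get(run_id, {}))

    def __len__(self) -> int:
        return self.n_traces

    def __iter__(self) -> Iterator[FragmentTrace]:
        for run in sorted(self._data):
            for prec in sorted(self._data[run]):
                for frag in sorted(self._data[run][prec]):
                    yield self._data[run][prec][frag]


# ---------------------------------------------------------------------------
# Peak model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RtCalibration:
    """Linear iRT -> observed retention time map for one run."""

    slope: float
    intercept: float
    residual_sd: float
    n_points: int


@dataclass
class PeakGroup:
    """Refined peak-group boundaries and per-fragment areas for one
    precursor in one run."""

    run_id: str
    precursor_id: str
    rt_start: float
    rt_end: float
    apex_rt: float
    fragment_areas: dict[str, float]
    fragment_shape_scores: dict[str, float]
    good_fragments: set[str]

    def __post_init__(self) -> None:
        if not (self.rt_start < self.apex_rt < self.rt_end):
            raise ValidationError("require rt_start < apex_rt < rt_end")
        if not self.good_fragments <= set(self.fragment_areas):
            raise ValidationError("good_fragments must be a subset of scored fragments")
        if any(a < 0 for a in self.fragment_areas.values()):
            raise ValidationError("areas must be nonnegative")


@dataclass
class RefinedPrecursor:
    """Reference-run refinement outcome for one precursor."""

    precursor_id: str
    reference_run: str
    retained_fragments: list[str]
    reference_areas: dict[str, float]
    reference_quantity: float
    rt_start: float
    rt_end: float
    apex_rt: float


@dataclass(frozen=True)
class Exclusion:
    precursor_id: str
    reason: str
    detail: str = ""


# ---------------------------------------------------------------------------
# Quantitative matrices
# ---------------------------------------------------------------------------

@dataclass
class QuantTable:
    """Row (precursor or protein) x column (run or sample) abundance matrix.

    Missing cells are NaN in ``values``; ``reasons`` records a typed cause per
    missing cell and ``flags`` records non-fatal annotations (for example a
    sample quantified by a single technical replicate).
    """

    level: str
    values: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)
    reasons: dict[tuple[str, str], str] = field(default_factory=dict)
    flags: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.level not in ("precursor", "protein"):
            raise ValidationError(f"unknown level {self.level!r}")
        vals = self.values.to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] < 0):
            raise ValidationError("abundances must be nonnegative")

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def column_ids(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "QuantTable":
        return QuantTable(
            level=self.level,
            values=self.values.copy(),
            provenance=dict(self.provenance),
            reasons=dict(self.reasons),
            flags=dict(self.flags),
        )


# ---------------------------------------------------------------------------
# Window schemes and MS1 density
# ---------------------------------------------------------------------------

@dataclass
class WindowScheme:
    """Ordered, gap-free tiling of precursor m/z by isolation windows.

    ``boundaries`` are the pre-margin edges (length n_windows + 1, strictly
    ascending); acquisition-side windows expanded by ``overlap_margin`` on
    each side are available via :meth:`expanded_windows`.
    """

    boundaries: np.ndarray
    overlap_margin: float = 0.0

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.boundaries.size < 2:
            raise ValidationError("scheme needs at least one window")
        if not np.all(np.diff(self.boundaries) > 0):
            raise ValidationError("window boundaries must be strictly ascending")
        if self.overlap_margin < 0:
            raise ValidationError("overlap_margin must be >= 0")

    @property
    def n_windows(self) -> int:
        return int(self.boundaries.size - 1)

    @property
    def windows(self) -> list[tuple[float, float]]:
        b = self.boundaries
        return [(float(b[i]), float(b[i + 1])) for i in range(self.n_windows)]

    def expanded_windows(self) -> list[tuple[float, float]]:
        lo, hi = float(self.boundaries[0]), float(self.boundaries[-1])
        m = self.overlap_margin
        return [
            (max(lo, s - m), min(hi, e + m)) for s, e in self.windows
        ]


@dataclass
class Ms1Density:
    """Histogram of precursor ion signal along m/z."""

    bin_edges: np.ndarray
    bin_ion_counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.bin_ion_counts = np.asarray(self.bin_ion_counts, dtype=float)
        if self.bin_edges.size != self.bin_ion_counts.size + 1:
            raise ValidationError("need len(bin_edges) == len(bin_ion_counts) + 1")
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValidationError("bin_edges must be strictly ascending")
        if np.any(self.bin_ion_counts < 0):
            raise ValidationError("bin counts must be nonnegative")
        if self.bin_ion_counts.sum() <= 0:
            raise ValidationError("total ion count must be > 0")
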