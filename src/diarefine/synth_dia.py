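"""Ground-truth synthetic DIA cohort generator.

Emits a transition library, per-run extracted fragment chromatograms,
identification scores, per-window MS2 TIC tables and sample annotations
with fully known abundances, so every pipeline stage can be exercised and
checked against truth offline.

The model: each peptide precursor elutes as a Gaussian peak at a
calibrated retention time (linear iRT map with small per-run jitter);
fragment intensities are proportional to library intensities and the
sample's true abundance; measurement error is multiplicative lognormal
noise; fragment-level interference adds a co-eluting contaminant peak;
global per-run scale factors emulate injection/response drift; precursors
drop out of runs at a configurable missing rate; technical duplicates
re-measure the same sample with independent noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io_formats
from .normalize_filter import assign_window
from .types import (
    AnnotationTable,
    ChromatogramStore,
    FragmentTrace,
    IdentificationRecord,
    LibraryTransition,
    QuantTable,
    RunWindowTic,
    SampleAnnotation,
    ScoreTable,
    TicTable,
    TransitionLibrary,
    ValidationError,
    WindowScheme,
)

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a small but structurally faithful DIA experiment:
    duplicate injections per sample, six fragments per precursor, a 6 s
    elution peak sigma on a 30-minute-style gradient sampled every 3 s
    (the SWATH cycle time), 10% multiplicative intensity noise, and a
    protein abundance spread of ~1.5 natural-log units with moderate
    per-peptide response variability.
    """

    n_proteins: int = 20
    peptides_per_protein: tuple[int, int] = (1, 3)
    fragments_per_precursor: tuple[int, int] = (6, 6)
    n_patients: int = 3
    groups: tuple[str, ...] = ("tumor", "benign")
    n_tech_replicates: int = 2
    true_fc_fraction: float = 0.2
    true_fc_magnitude: float = 4.0
    peak_sigma_s: float = 6.0
    noise_cv: float = 0.1
    interference_rate: float = 0.0
    missing_rate: float = 0.0
    run_scale_factors: dict[str, float] = field(default_factory=dict)
    rt_gradient_s: float = 1800.0
    mz_range: tuple[float, float] = (400.0, 1200.0)
    cycle_s: float = 3.0
    n_windows: int = 8
    tic_background_factor: float = 500.0
    protein_log_sigma: float = 1.5
    peptide_response_log_sigma: float = 0.3
    biological_log_sigma: float = 0.5
    base_abundance: float = 1.0e4
    rt_slope_jitter: float = 0.002
    rt_intercept_jitter_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("true_fc_fraction", "noise_cv", "interference_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        if self.peak_sigma_s <= 0:
            raise ValidationError("peak_sigma_s must be > 0")
        if self.seed is None:
            raise ValidationError("seed is mandatory")


@dataclass
class GroundTruth:
    """What the generator actually put into the data."""

    true_abundance: pd.DataFrame          # precursor x sample
    true_protein_abundance: pd.DataFrame  # protein x sample
    true_protein_fc: dict[str, float]
    interfered_cells: set[tuple[str, str, str]]
    injected_run_scales: dict[str, float]
    missing_cells: set[tuple[str, str]]   # (run, precursor)


@dataclass
class CohortData:
    store: ChromatogramStore
    scores: ScoreTable
    tics: TicTable
    annotations: AnnotationTable
    scheme: WindowScheme
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Library
# ---------------------------------------------------------------------------

def simulate_library(cfg: SimConfig) -> TransitionLibrary:
    """Random transition library: one protein -> 1..k peptide precursors,
    each with b/y fragments whose library intensities are Dirichlet
    distributed (summing to 1).  Deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    entries: list[LibraryTransition] = []
    for i in range(cfg.n_proteins):
        protein_id = f"PROT{i:04d}"
        lo, hi = cfg.peptides_per_protein
        n_pep = int(rng.integers(lo, hi + 1))
        for j in range(n_pep):
            length = int(rng.integers(8, 16))
            seq = "".join(rng.choice(_AMINO_ACIDS, size=length))
            charge = int(rng.choice([2, 3]))
            precursor_id = f"{seq}_{charge}"
            precursor_mz = float(rng.uniform(*cfg.mz_range))
            irt = float(rng.uniform(0.0, 100.0))
            flo, fhi = cfg.fragments_per_precursor
            n_frag = int(rng.integers(flo, fhi + 1))
            lib_int = rng.dirichlet(np.full(n_frag, 1.5))
            for k in range(n_frag):
                series = "b" if k % 2 else "y"
                ordinal = 3 + k
                entries.append(LibraryTransition(
                    precursor_id=precursor_id,
                    peptide_sequence=seq,
                    precursor_charge=charge,
                    precursor_mz=precursor_mz,
                    fragment_id=f"{series}{ordinal}^1",
                    fragment_mz=float(rng.uniform(200.0, 1500.0)),
                    irt=irt,
                    library_intensity=float(lib_int[k]),
                    protein_id=protein_id,
                ))
    return TransitionLibrary(entries)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def uniform_scheme(cfg: SimConfig) -> WindowScheme:
    return WindowScheme(
        boundaries=np.linspace(cfg.mz_range[0], cfg.mz_range[1], cfg.n_windows + 1),
        overlap_margin=0.0,
    )


def _build_annotations(cfg: SimConfig) -> AnnotationTable:
    rows = []
    for p in range(cfg.n_patients):
        patient = f"P{p + 1:02d}"
        for g in cfg.groups:
            sample = f"{patient}_{g}"
            for r in range(cfg.n_tech_replicates):
                rows.append(SampleAnnotation(
                    run_id=f"{sample}_R{r + 1}",
                    sample_id=sample,
                    patient_id=patient,
                    group=g,
                    tech_replicate=r + 1,
                ))
    return AnnotationTable(rows)


def simulate_cohort(
    cfg: SimConfig,
    library: TransitionLibrary,
    scheme: WindowScheme | None = None,
) -> CohortData:
    """Emit chromatograms, scores, TICs and annotations with known truth.

    The m_score is a decreasing function of the sample-level analyte
    amount (clipped to [1e-5, 0.2]) with a multiplicative jitter so
    reference selection has a unique, deterministic ordering.  It is
    deliberately independent of the injected per-run scale factors, so a
    global intensity injection changes nothing but the traces and TICs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    scheme = scheme or uniform_scheme(cfg)
    annotations = _build_annotations(cfg)
    run_ids = annotations.run_ids()
    sample_ids = sorted({a.sample_id for a in annotations})
    group_of = {s: g for s, (_, g) in annotations.sample_meta().items()}

    protein_ids = sorted(library.protein_index)
    precursor_ids = library.precursor_ids

    # --- truth -------------------------------------------------------------
    base = {
        prot: float(rng.lognormal(np.log(cfg.base_abundance), cfg.protein_log_sigma))
        for prot in protein_ids
    }
    n_fc = int(round(cfg.true_fc_fraction * len(protein_ids)))
    fc_proteins = set(rng.choice(protein_ids, size=n_fc, replace=False)) if n_fc else set()
    true_protein_fc = {
        prot: (cfg.true_fc_magnitude if prot in fc_proteins else 1.0)
        for prot in protein_ids
    }
    prot_abund = pd.DataFrame(index=protein_ids, columns=sample_ids, dtype=float)
    for prot in protein_ids:
        for sample in sample_ids:
            fc = true_protein_fc[prot] if group_of[sample] == cfg.groups[0] else 1.0
            bio = float(rng.lognormal(0.0, cfg.biological_log_sigma))
            prot_abund.loc[prot, sample] = base[prot] * fc * bio
    response = {
        prec: float(rng.lognormal(0.0, cfg.peptide_response_log_sigma))
        for prec in precursor_ids
    }
    prec_protein = {prec: library.proteins_of(prec)[0] for prec in precursor_ids}
    true_abund = pd.DataFrame(
        {
            sample: [prot_abund.loc[prec_protein[p], sample] * response[p]
                     for p in precursor_ids]
            for sample in sample_ids
        },
        index=precursor_ids,
    )

    # --- retention-time model ---------------------------------------------
    slope0 = 0.8 * cfg.rt_gradient_s / 100.0
    intercept0 = 0.1 * cfg.rt_gradient_s
    run_rt = {
        run: (
            slope0 * (1.0 + float(rng.normal(0.0, cfg.rt_slope_jitter))),
            intercept0 + float(rng.normal(0.0, cfg.rt_intercept_jitter_s)),
        )
        for run in run_ids
    }

    # --- emission ----------------------------------------------------------
    run_scales = {run: float(cfg.run_scale_factors.get(run, 1.0)) for run in run_ids}
    offsets = np.arange(-16, 17) * cfg.cycle_s
    sigma2 = 2.0 * cfg.peak_sigma_s ** 2
    shape0 = np.exp(-offsets ** 2 / sigma2)
    sigma_log = float(np.sqrt(np.log1p(cfg.noise_cv ** 2)))

    store = ChromatogramStore()
    score_records: list[IdentificationRecord] = []
    tic_acc: dict[tuple[str, int], float] = {}
    interfered: set[tuple[str, str, str]] = set()
    missing: set[tuple[str, str]] = set()
    prec_window = {
        p: assign_window(library.transitions_for(p)[0].precursor_mz, scheme)
        for p in precursor_ids
    }
    # Stable co-isolated MS2 background per window: in real DIA the window
    # TIC sums thousands of peptides plus unassigned signal, so it tracks
    # global run response, not the biology of the few monitored analytes.
    bg_window: dict[int, float] = {}
    for p in precursor_ids:
        w = prec_window[p]
        bg_window[w] = bg_window.get(w, 0.0) + (
            cfg.tic_background_factor
            * float(true_abund.loc[p].mean())
            * float(shape0.sum())
        )

    for run in run_ids:
        sample = annotations.sample_of(run)
        scale = run_scales[run]
        slope_r, intercept_r = run_rt[run]
        for prec in precursor_ids:
            if rng.random() < cfg.missing_rate:
                missing.add((run, prec))
                continue
            amount = float(true_abund.loc[prec, sample])
            apex = slope_r * library.irt_of(prec) + intercept_r
            times = apex + offsets
            run_total = 0.0
            for tr in library.transitions_for(prec):
                amp = amount * scale * tr.library_intensity
                y = amp * shape0
                if rng.random() < cfg.interference_rate:
                    delta = float(rng.uniform(5.0, 20.0)) * float(rng.choice([-1.0, 1.0]))
                    mult = float(rng.uniform(0.5, 5.0))
                    y = y + mult * amp * np.exp(-(offsets - delta) ** 2 / sigma2)
                    interfered.add((run, prec, tr.fragment_id))
                if cfg.noise_cv > 0:
                    y = y * np.exp(rng.normal(0.0, sigma_log, size=y.size))
                store.add(FragmentTrace(
                    run_id=run, precursor_id=prec, fragment_id=tr.fragment_id,
                    times=times, intensities=y,
                ))
                run_total += float(y.sum())
            w = prec_window[prec]
            tic_acc[(run, w)] = tic_acc.get((run, w), 0.0) + run_total
            m = 0.2 * float(rng.uniform(0.5, 1.5)) / (1.0 + np.log1p(amount))
            score_records.append(IdentificationRecord(
                precursor_id=prec, run_id=run,
                m_score=float(np.clip(m, 1e-5, 0.2)),
                apex_rt=float(apex),
            ))

    tics = TicTable([
        RunWindowTic(
            run_id=run, window_index=w,
            tic=run_scales[run] * bg_window.get(w, 0.0) + tic_acc.get((run, w), 0.0),
        )
        for run in run_ids
        for w in sorted(bg_window)
    ])
    truth = GroundTruth(
        true_abundance=true_abund,
        true_protein_abundance=prot_abund,
        true_protein_fc=true_protein_fc,
        interfered_cells=interfered,
        injected_run_scales=run_scales,
        missing_cells=missing,
    )
    return CohortData(
        store=store, scores=ScoreTable(score_records), tics=tics,
        annotations=annotations, scheme=scheme, truth=truth,
    )


def write_fixture_dir(
    cfg: SimConfig,
    outdir: str | Path,
    scheme: WindowScheme | None = None,
) -> tuple[TransitionLibrary, CohortData]:
    """Simulate and write a complete fixture directory of TSV artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    library = simulate_library(cfg)
    cohort = simulate_cohort(cfg, library, scheme)
    io_formats.write_transition_list(library, outdir / "transitions.tsv")
    io_formats.write_chromatograms(cohort.store, outdir / "chromatograms.tsv")
    io_formats.write_scores(cohort.scores, outdir / "scores.tsv")
    io_formats.write_tic_table(cohort.tics, outdir / "tic.tsv")
    io_formats.write_annotations(cohort.annotations, outdir / "annotations.tsv")
    io_formats.write_window_scheme(cohort.scheme, outdir / "windows.tsv")
    truth = cohort.truth
    ta = truth.true_abundance.copy()
    ta.insert(0, "precursor_id", ta.index)
    io_formats._write_tsv(ta.reset_index(drop=True), outdir / "truth_abundance.tsv")
    tp = truth.true_protein_abundance.copy()
    tp.insert(0, "protein_id", tp.index)
    io_formats._write_tsv(tp.reset_index(drop=True), outdir / "truth_protein.tsv")
    meta_rows = (
        [("run_scale", run, f"{v:.12g}") for run, v in sorted(truth.injected_run_scales.items())]
        + [("protein_fc", prot, f"{v:.12g}") for prot, v in sorted(truth.true_protein_fc.items())]
        + [("seed", "seed", str(cfg.seed))]
    )
    io_formats._write_tsv(
        pd.DataFrame(meta_rows, columns=["kind", "key", "value"]),
        outdir / "truth_meta.tsv",
    )
    return library, cohort


# ---------------------------------------------------------------------------
# Truth-based evaluation helpers
# ---------------------------------------------------------------------------

def log2_ratio_errors(
    table: QuantTable,
    truth: GroundTruth,
    annotations: AnnotationTable,
) -> np.ndarray:
    """Per-cell log2(estimated / true) between-run ratio errors.

    For each precursor row, every non-reference run's estimate is divided
    by the reference run's estimate and compared with the corresponding
    ratio of true abundances (including injected run scales).  Returns the
    finite errors as a flat array.
    """
    errors = []
    scales = truth.injected_run_scales
    for prec in table.row_ids:
        ref = table.provenance.get(prec)
        if ref is None or ref not in table.column_ids:
            continue
        est_ref = table.values.loc[prec, ref]
        if not np.isfinite(est_ref) or est_ref <= 0:
            continue
        truth_ref = (truth.true_abundance.loc[prec, annotations.sample_of(ref)]
                     * scales.get(ref, 1.0))
        for run in table.column_ids:
            if run == ref:
                continue
            est = table.values.loc[prec, run]
            if not np.isfinite(est) or est <= 0:
                continue
            truth_run = (truth.true_abundance.loc[prec, annotations.sample_of(run)]
                         * scales.get(run, 1.0))
            errors.append(np.log2((est / est_ref) / (truth_run / truth_ref)))
    return np.asarray(errors, dtype=float)


def protein_profile_spearman(
    protein_table: QuantTable,
    truth: GroundTruth,
) -> pd.Series:
    """Per-protein Spearman correlation of the estimated sample profile
    against the true protein abundance profile (>= 3 complete samples)."""
    out = {}
    for prot in protein_table.row_ids:
        if prot not in truth.true_protein_abundance.index:
            continue
        est = protein_table.values.loc[prot]
        tru = truth.true_protein_abundance.loc[prot]
        common = [s for s in est.index if s in tru.index and np.isfinite(est[s])]
        if len(common) < 3:
            continue
        rho = stats.spearmanr(est[common].to_numpy(), tru[common].to_numpy()).statistic
        if np.isfinite(rho):
            out[prot] = float(rho)
    return pd.Series(out, dtype=float)


# ---------------------------------------------------------------------------
# Lightweight paired-cohort table simulator (differential-statistics checks)
# ---------------------------------------------------------------------------

def simulate_paired_cohort_table(
    n_null: int = 1000,
    n_true: int = 50,
    n_patients: int = 12,
    fc: float = 4.0,
    sigma_log2: float = 0.8,
    patient_sigma_log2: float = 1.0,
    groups: tuple[str, str] = ("tumor", "benign"),
    seed: int = 0,
) -> tuple[QuantTable, AnnotationTable, list[str]]:
    """Protein-level paired cohort with known differential rows.

    Each row is lognormal around a per-row baseline with a shared
    per-patient offset (cancelled by pairing) and independent measurement
    noise of ``sigma_log2`` log2 units; the first ``n_true`` rows carry a
    true fold change of ``fc`` in the first group.  Returns the table, the
    matching annotations (one run per sample), and the true-change row ids.
    """
    rng = np.random.default_rng(seed)
    n_rows = n_null + n_true
    row_ids = [f"TRUE{i:04d}" for i in range(n_true)] + \
              [f"NULL{i:04d}" for i in range(n_null)]
    true_rows = row_ids[:n_true]
    baselines = rng.normal(14.0, 1.5, size=n_rows)
    annotations = []
    columns: dict[str, np.ndarray] = {}
    for p in range(n_patients):
        patient = f"P{p + 1:02d}"
        offset = rng.normal(0.0, patient_sigma_log2, size=n_rows)
        for g in groups:
            sample = f"{patient}_{g}"
            effect = np.zeros(n_rows)
            if g == groups[0]:
                effect[:n_true] = np.log2(fc)
            log2_vals = baselines + offset + effect + rng.normal(0.0, sigma_log2, n_rows)
            columns[sample] = np.exp2(log2_vals)
            annotations.append(SampleAnnotation(
                run_id=sample, sample_id=sample, patient_id=patient,
                group=g, tech_replicate=1,
            ))
    values = pd.DataFrame(columns, index=row_ids)
    table = QuantTable(level="protein", values=values)
    return table, AnnotationTable(annotations), true_rows
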