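import numpy as np
import pytest

from diarefine.types import (
    AnnotationTable,
    ChromatogramStore,
    FragmentTrace,
    IdentificationRecord,
    LibraryTransition,
    SampleAnnotation,
    ScoreTable,
    TransitionLibrary,
)


def gaussian_trace(run, prec, frag, apex, amp, sigma=6.0, step=3.0, n=16, shift=0.0):
    """Gaussian elution peak sampled at the SWATH cycle time around the apex."""
    t = apex + np.arange(-n, n + 1) * step
    y = amp * np.exp(-((t - (apex + shift)) ** 2) / (2.0 * sigma**2))
    return FragmentTrace(run_id=run, precursor_id=prec, fragment_id=frag,
                         times=t, intensities=y)


def flat_trace(run, prec, frag, apex, level, step=3.0, n=16):
    t = apex + np.arange(-n, n + 1) * step
    return FragmentTrace(run_id=run, precursor_id=prec, fragment_id=frag,
                         times=t, intensities=np.full(t.size, float(level)))


@pytest.fixture
def make_gaussian_trace():
    return gaussian_trace


@pytest.fixture
def make_flat_trace():
    return flat_trace


def build_constructed_cohort(run_scales=None, n_good_precursors=8, n_bad_precursors=2):
    """Hand-built cohort of co-eluting Gaussian peak groups.

    "Good" precursors have six well-correlated fragments; "bad" ones have
    only three (the other three are flat, giving zero shape correlation),
    so the reference refinement must exclude them.  Target runs are exact
    scaled copies of the reference run.
    """
    run_scales = run_scales or {"S1": 1.0, "S2": 0.5, "S3": 2.0, "S4": 1.0}
    runs = sorted(run_scales)
    annotations = AnnotationTable([
        SampleAnnotation(run_id=r, sample_id=f"smp_{r}", patient_id=f"pat_{r}",
                         group="tumor" if i % 2 == 0 else "benign", tech_replicate=1)
        for i, r in enumerate(runs)
    ])
    entries, records, store = [], [], ChromatogramStore()
    slope, intercept = 10.0, 300.0
    n_total = n_good_precursors + n_bad_precursors
    for i in range(n_total):
        prec = f"PREC{i:02d}_2"
        bad = i >= n_good_precursors
        irt = 10.0 + 8.0 * i
        apex = slope * irt + intercept
        amps = [1000.0, 800.0, 600.0, 400.0, 300.0, 200.0]
        for k in range(6):
            frag = f"y{k + 3}^1"
            entries.append(LibraryTransition(
                precursor_id=prec, peptide_sequence=f"PEPTIDE{i:02d}K",
                precursor_charge=2, precursor_mz=450.0 + 7.0 * i,
                fragment_id=frag, fragment_mz=300.0 + 50.0 * k,
                irt=irt, library_intensity=amps[k] / sum(amps),
                protein_id=f"PROT{i // 2:03d}",
            ))
        for run in runs:
            scale = run_scales[run]
            for k in range(6):
                frag = f"y{k + 3}^1"
                if bad and k >= 3:
                    store.add(flat_trace(run, prec, frag, apex, amps[k] * scale * 0.3))
                else:
                    store.add(gaussian_trace(run, prec, frag, apex, amps[k] * scale))
            records.append(IdentificationRecord(
                precursor_id=prec, run_id=run,
                m_score=0.001 if run == "S1" else 0.01, apex_rt=apex,
            ))
    return TransitionLibrary(entries), store, ScoreTable(records), annotations


@pytest.fixture
def constructed_cohort():
    return build_constructed_cohort()
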