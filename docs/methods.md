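# Methods

This note documents the models, numerical choices and validation logic
behind `diarefine`, and what the bundled synthetic-data generator does and
does not emulate.

## Reference-anchored quantification

DIA quantification here is *relative and reference-anchored*: for each
peptide precursor, the single run with the strongest identification
evidence (lowest m_score) defines the fragment basis and the abundance
scale; all other runs are expressed against it.

**Reference selection.** Minimum m_score across the precursor's
identification records. Ties break by larger summed intensity inside the
RT extraction window, then lexicographic run id, so selection is total and
deterministic.

**Peak boundaries.** Boundaries are detected on the *consensus* trace —
the pointwise median of the precursor's max-normalized fragment XICs on a
uniform grid (default 1 s). The apex is re-centered on the most intense
point within ±15 s of the seeded retention time (the run's scored apex
when identified, else the calibrated library RT). Each boundary walks
outward to the first local minimum — a point strictly below its inward
neighbour and not above its outward one — whose intensity has fallen to
max(5% of apex, the minimum on that side), capped at ±60 s. The cap stops
runaway integration on shoulders; the 5% floor tolerates baseline ripple.
On a flat trace no local minimum qualifies and the boundaries sit at the
cap. Max-normalization lets every fragment vote on shape regardless of
intensity; the median makes the consensus robust as long as fewer than
half of the fragments are interfered.

**Good fragments.** A fragment is retained when (a) its Pearson
correlation against the consensus, both linearly resampled onto the grid
inside the boundaries, is at least `shape_good_threshold` (default 0.8),
and (b) its apex signal-to-noise — apex intensity over the median
intensity outside the boundaries but inside the extraction window — is at
least `snr_threshold` (default 3). A zero-variance trace scores 0 and is
never good. With no measurable background (no points, or zero median,
outside the boundaries) the SNR is infinite by convention: there is no
noise estimate to argue against the peak. Precursors with fewer than
`min_good_fragments` (default 4) good fragments are excluded with reason
`lt4_good_fragments`.

**Quantification.** Fragment areas are trapezoidal integrals inside the
boundaries, with linearly interpolated endpoints so integration is exactly
additive over adjacent intervals. The target run's abundance is
median(area_f(target)/area_f(reference)) × Σ area_f(reference), over the
retained fragments with nonzero reference area. Anchoring at the summed
reference areas keeps between-run ratios intact and the output in
interpretable area units. The reference run itself reports exactly the
reference quantity. Targets in which fewer than four retained fragments
show signal are typed missing (`weak_target_signal`), never zero. The
fragment set is fixed by the reference and not re-refined per target run;
re-refinement would let each target renegotiate its own basis and break
cross-run comparability.

**Retention-time calibration.** Per-run ordinary least squares of observed
apex RT on library iRT, with one rejection pass: points whose absolute
residual exceeds 3× the median absolute residual are dropped when at least
four anchors survive, then the line is refit. On noiseless collinear
anchors the fit is exact to floating-point precision.

## Normalization and filtering

**Per-window TIC normalization.** Each cell is multiplied by
median_runs(TIC(·, w)) / TIC(run, w) for its precursor's isolation window
w. Any multiplicative per-(run, window) factor — injection amount,
spray/response drift — cancels exactly; anchoring at the cross-run median
keeps area units. A zero or absent TIC for a needed pair is an error, not
a silent skip.

**Technical replicates.** Duplicates disagreeing by a max/min ratio ≥ 2
are discarded (`tech_fc_ge2`); with more than two replicates the same
max/min rule applies. Concordant replicates merge by geometric mean
(symmetric on the log scale, where the noise is approximately additive).
A lone replicate is carried, flagged `single_replicate`. Normalization
runs before the filter, so replicate concordance is judged on values free
of injection-scale differences; the order is a config key.

**Median normalization.** Each run (column) is divided by its median over
non-missing rows and re-scaled by the grand median of the run medians.
Run medians equalize exactly; within-run rank order is untouched.

## Protein inference

Best-flier roll-up: for each protein, the proteotypic precursor with the
fewest missing sample values represents the protein, its row copied
verbatim — no new numbers are invented, and poorly responding peptides
cannot dilute the profile. Ties break by higher median abundance, then
lower reference m_score, then precursor id. Precursors mapping to more
than one protein are excluded (`non_proteotypic`).

## Isolation-window design

Window boundaries sit at the k/n quantiles of the cumulative MS1
ion-signal histogram, interpolated linearly inside bins, so each window
isolates the same precursor signal load. Linear interpolation makes the
placement exact, reproducible and oracle-checkable, and allows n to exceed
the number of occupied bins (a single hot bin is split proportionally).
Windows may be expanded by an overlap margin (default 0.5 Th per side,
typical SWATH practice) for acquisition; assignment of precursors to
windows uses the pre-margin half-open tiling, lower index winning on
overlap. A count-based mode (equal precursor counts instead of summed
intensity) is provided.

## Biomarker statistics

**Paired differential analysis.** Per row, patients contribute one
tumor/benign pair; pairs with a missing member are dropped. The fold
change is the median of patient ratios taken on the log2 scale — for even
patient counts the two central ratios average geometrically, which keeps
the group swap exactly antisymmetric (fc → 1/fc). The p-value is a
two-tailed paired t-test on log2 values, computed only with ≥ 3 complete
pairs. A row is significant when (fc ≥ 2 or fc ≤ 0.5) and p ≤ 0.05; both
thresholds are parameters. Constant nonzero log2 differences (zero
variance, to ~1e-12 to absorb rounding) are a typed degenerate outcome:
p reported as 0, flagged, significance decided by the fold change — never
NaN propagation. Raw p-values are the default rule; a Benjamini–Hochberg
flag applies the same rule to adjusted p-values for larger unpaired-style
screens.

**Technical CV** is sd/mean × 100 per replicate set (sample sd, ddof 1),
summarized as the median over rows. Note the n = 2 sample sd is biased
low by the c4 factor (≈ 0.80), so duplicate-based median CVs sit below
the population CV of the noise process.

**Pairwise-complete Pearson** mirrors R's `use = "pairwise.complete.obs"`:
the correlation is computed over jointly observed indices only, undefined
(missing) below 3 complete pairs or at zero variance.

**Panel AUC** is the Mann–Whitney rank statistic
P(score_case > score_control) + ½ P(tie); ties get average ranks, and the
statistic is invariant under strictly monotone transforms of the score.

## The synthetic cohort generator

The generator exists so that every pipeline stage can be validated against
known truth without instrument data. It emulates:

- Gaussian elution peaks (σ default 6 s) at linearly calibrated retention
  times with small per-run slope/intercept jitter, sampled every 3 s (the
  SWATH cycle time), centered on the true apex;
- fragment intensities proportional to Dirichlet-distributed library
  intensities and the sample's true abundance;
- protein abundances lognormal across proteins (σ_ln 1.5), per-sample
  biological variation (σ_ln 0.5), moderate per-peptide response factors
  (σ_ln 0.3), and a configurable fraction of proteins carrying a true
  fold change between groups;
- multiplicative lognormal measurement noise (CV default 10%);
- fragment-level interference: a co-eluting contaminant Gaussian offset
  5–20 s at 0.5–5× the fragment's amplitude, at a configurable rate;
- global per-run scale factors (injection/response drift), precursor
  dropout at a configurable missing rate, and technical duplicates that
  re-measure the same sample with independent noise;
- per-window MS2 TICs modelled as run_scale × stable co-isolated
  background + the emitted analyte signal, the background set to 500× the
  window's mean analyte signal. In real DIA a window's TIC sums hundreds
  to thousands of co-isolated peptides plus unassigned signal, so it
  tracks global run response rather than the biology of the few monitored
  analytes; without this term, a toy-scale TIC would inject spurious
  normalization factors no real experiment exhibits.
- m_score as a decreasing function of the sample-level analyte amount
  with deterministic jitter, clipped to [1e-5, 0.2]. Only its ordering
  matters (reference selection); it is deliberately independent of the
  injected run-scale factors, which model post-identification intensity
  drift.

It does **not** emulate: chimeric MS2 spectra beyond per-fragment
interference, nonlinear RT distortions, detector saturation, missingness
correlated with abundance, batch effects across instruments, or
FFPE-specific chemical modifications. Passing tests therefore demonstrate
algorithmic correctness under the stated noise model, not performance on
real raw data.

A lightweight companion (`simulate_paired_cohort_table`) emits
protein-level paired cohorts directly (lognormal noise of 0.8 log2 units
per measurement, patient offsets of 1.0 log2 units that cancel in
pairing) for calibrating the differential statistics at 1000-row scale
without chromatogram simulation.

## Validation problem sizes

The acceptance script and test suite use desk-scale cohorts chosen to make
each property sharp: 100 precursors × 6 runs for the noiseless closed loop
(max relative ratio error vs truth ~1e-15); 200 precursors / 50 proteins /
12 runs at 10% noise, 20% interference and 5% dropout for robust recovery
(median |log2 error| ≈ 0.04, median per-protein profile Spearman 1.0);
25 proteins × 6 runs for the 2×-injection cancellation (residual ≈ 0.3%,
from the analyte share of the TIC); and 1050 rows × 12 patients for
volcano calibration (true-positive rate ≈ 1.0, false-positive rate ≈ 0.5%
under the FC ∧ p rule). All figures are recomputed at run time by
`scripts/acceptance.py` and the test suite, never asserted as constants.

## Configuration

Key defaults (all exposed in `QuantConfig`/TOML): RT extraction half-width
150 s — the 300 s extraction window is read as a full width, and the key
is exposed precisely because the convention is ambiguous; shape threshold
0.8; SNR threshold 3; resample step 1 s; boundary cap 60 s; baseline
fraction 5%; technical-replicate fold-change cut 2; volcano FC 2 and
α 0.05; 48 windows with 0.5 Th overlap margin. Unknown config keys are
rejected rather than ignored.

## Known limitations

- No cross-run chromatographic realignment beyond the linear iRT map;
  strongly nonlinear gradients would need a spline calibration.
- No FDR estimation: m_score is consumed, not computed.
- Best-flier roll-up discards information from concordant sibling
  peptides; it trades variance for robustness to poorly responding ones.
- The window designer optimizes signal balance only, not cycle time or
  accumulation time.
- Protein grouping/parsimony is out of scope; shared peptides are simply
  excluded.
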