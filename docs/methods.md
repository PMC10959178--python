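# Methods

## The signaling-strength statistic

The core readout quantifies antigen-independent ("autonomous") BCR activity
from a single-sample ratiometric calcium-flux acquisition. Cells loaded with
Indo-1 are recorded continuously; the per-event 405/485 signal intensity
ratio (SIR) rises with intracellular calcium. The acquisition has three
phases: baseline (0–90 s), an autonomous window after 4-OHT releases the
SLP65 signal transducer (90–540 s), and a maximal-response window after
anti-Ig crosslinking (540–630 s). The statistic is computed per gated
sample as:

1. **Threshold.** The 95th percentile (linear interpolation between order
   statistics) of baseline SIR. Any event above it during the autonomous
   window counts as a responder; by construction a null sample yields a ~5%
   false-positive responder fraction — the statistic's noise floor.
2. **Unresponsive correction.** The crosslink window is tiled with
   consecutive 20-s bins (a trailing partial bin is dropped); the bin with
   the highest median SIR is the peak of the maximal response. The fraction
   `u` of its events at or below the threshold estimates cells that cannot
   respond at all (failed dye loading, non-functional BCR). The raw
   autonomous responder fraction is divided by `1 − u` and capped at 1,
   giving `Q_aut`. This removes non-functional cells from the denominator —
   the standard transduction-efficiency correction — and makes the score
   independent of expression level. `u = 1` (no event above threshold even
   at crosslink) is an error: the sample is unusable.
3. **Calibration.** `calSIR_aut` is the median SIR of the above-threshold
   autonomous events divided by the median SIR of the peak crosslink bin:
   the amplitude of the autonomous response relative to the maximal one. A
   sample with no above-threshold autonomous events returns 0 by convention
   (nothing to calibrate; the strength is 0 rather than undefined).
4. **Strength.** `strength = Q_aut × calSIR_aut` ∈ [0, ~1]. It is exactly
   invariant to rescaling both Indo-1 channels by a common factor.

Each flow event is treated as one cell; fractions are event fractions
within time windows (flow cytometry samples each cell once, so no per-cell
trajectories exist).

**Replicates and classification.** Strengths are averaged arithmetically
over replicate acquisitions per BCR. A BCR is called signaling when its
mean strength strictly exceeds the maximum strength observed among known
non-signaling control samples; a tie is conservatively non-signaling. The
control set uses *individual replicate* strengths (every control
measurement contributes to the upper limit), while cases are classified on
their replicate means — the asymmetry makes the threshold conservative.

## Synthetic flux generator

`simulate_flux_experiment` emulates the assay's structure, not its
biophysics. Each of `n_cells` events has a uniform arrival time over the
acquisition (constant flow rate; no Poisson jitter). Cells are transduced
with probability `transduced_fraction`; among transduced cells a fraction
`p_aut` responds autonomously and a disjoint fraction `u_true` is totally
unresponsive. The true SIR is a sustained step: baseline `mu0`, rising to
`a_aut·mu0` for autonomous responders after 4-OHT plus a fixed lag, and to
`a_max·mu0` for every non-unresponsive transduced cell after crosslinking.
Transient decay kinetics, oscillations and spectral spillover are not
modeled. Channels carry independent multiplicative lognormal noise
(unit-mean, CV `noise_cv`) — fluorescence is positive and right-skewed.
Untransduced (GFP-negative) cells never respond: they carry no BCR.

Defaults, chosen once: `n_cells = 5000` (per-case acquisition sizes are
not published; `event_rate` is then implied by the 630-s protocol),
`transduced_fraction = 0.6`, `noise_cv = 0.1` (a tight ratiometric dye),
`mu0 = 1`, `a_max = 3`, `a_aut = 2`, `u_true = 0.05` (a small residue of
transduced cells fails to respond even at crosslink), `response_lag_s = 10`.
Cohorts derive per-case, per-replicate seeds from one global seed via
`numpy` `SeedSequence` spawn keys, so each case is individually
reproducible.

A green test on this generator establishes that the statistic recovers
step-responder mixtures under lognormal channel noise; it does not
establish performance on real kinetics (gradual onset, decaying flux,
instrument drift), nor on samples with debris/doublets, which real gating
has to remove.

### The reference cohort and an honest limitation

`autobcr.reference` encodes the 18-case survey (13 signaling, all IgM; 4
IgG and 1 IgM non-signaling; signaling cases simulated at `p_aut = 0.8`,
`a_aut = 0.6·a_max`) plus three non-signaling controls, two replicates
each. Signaling cases score ≈0.49 and are never misclassified. The five
truly non-signaling cases, however, are statistically *exchangeable* with
the controls — all sit at the ~5% false-positive floor — so a null case
exceeds the maximum of six control measurements with probability ≈10%
(measured; heavier-tailed than binomial because the baseline threshold is
itself estimated from a few hundred events). About half of seeded cohort
runs therefore classify 13 exactly, and the rest 14–16; the *modal* count
over 20 runs is robustly 13. No finite exchangeable control set can drive
the per-run error to zero; in the original experimental design the control
cell lines were measured many more times than any case, which shrinks this
error. The per-run count distribution is an inherent property of
threshold-by-finite-controls classification, not a fixable bug.

## Downstream assay models

- **Phospho-flow.** MFI is the arithmetic mean over live, GFP/dTomato
  double-positive cells (a geometric-mean option exists but is off). The
  report is `MFI_unstim / MFI_crosslinked`. Group comparison is a Student
  (equal-variance) two-sample t test by default — the sidedness and Welch
  variant are arguments. Degenerate input (both groups constant and equal)
  returns P = 1. The per-cell SD of the unstimulated sample is reported as
  the dispersion.
- **Dose response.** OD values are normalized to the mean medium-control
  well; the four-parameter logistic `bottom + (top−bottom)/(1+10^(h·(x−x₀)))`
  is fitted on `x = log10(concentration)` by least squares
  (`scipy.optimize.curve_fit`, data-driven start values). The IC50 is the
  fitted midpoint `10^{x₀}`, flagged `extrapolated` when outside the tested
  range. A dynamic range below `flat_epsilon = 0.2` (the
  inhibitor-resistant phenotype) is flagged `indeterminate` instead of
  fitted. The default concentration grid is the twofold series 96 →
  0.1875 μM (10 points, duplicate wells).
- **Growth.** Cell counts are rescaled by expected/observed bead counts
  (beads spiked at a known density calibrate the sampled volume), log2
  transformed and regressed on time; doubling time is the reciprocal slope,
  with a t-based CI mapped through the reciprocal (upper bound ∞ when the
  slope interval touches zero). Non-positive slopes are reported
  `non_growing`, not as a negative time. The log-linear fit over all
  timepoints is exact on noise-free exponential data.

## Genomic classification

- **Variant filter.** A record is retained iff its gene and consequence
  are whitelisted *and* at least one predictor flags it damaging (SIFT
  `deleterious`; PolyPhen `possibly`/`probably damaging`; clinical
  significance `likely pathogenic`/`pathogenic`). Any record annotated
  (likely) benign is discarded unconditionally, before the other rules.
  Labels are normalized (case, spaces/underscores) so VEP- and
  ClinVar-style spellings both work.
- **Cluster assignment.** Naive Bayes over binary locus states:
  conditional independence across loci is an assumption, adopted because
  only marginal cluster-conditional aberration frequencies are published
  for the consensus-cluster scheme. Frequencies are clipped to
  `[ε, 1−ε]`, ε = 0.01, so one discordant locus cannot zero a cluster;
  posteriors are computed in log space and normalized. Priors are uniform
  unless supplied. Unobserved loci are skipped; a vector with no observed
  loci returns the priors with an `uninformative` flag; argmax ties break
  by declared cluster order with an `ambiguous` flag. A case is `assigned`
  only when its top posterior strictly exceeds 0.9. The published
  frequency tables are not bundled — the model is user-supplied JSON, and
  all tests use synthetic models.
- **Hans algorithm.** The CD10/BCL6/MUM1 immunohistochemistry tree:
  CD10+ → GCB; CD10− BCL6− → non-GCB; CD10− BCL6+ MUM1+ → non-GCB;
  CD10− BCL6+ MUM1− → GCB.

## Cohort statistics

Fisher's exact test (scipy; two-sided by probability-mass summation,
cross-checked in the test suite against a full hypergeometric enumeration)
for the isotype × signaling and COO × signaling associations. Wilcoxon
tests come in both flavors — signed-rank (paired) and rank-sum
(independent) — because the source analysis applies a signed-rank test to
groups that appear unpaired; the discrepancy is surfaced, not resolved.
Exact null enumeration is used up to n = 25 when tie/zero-free, the normal
approximation with continuity correction otherwise. IGHV germline homology
is computed positionally on pre-aligned (IMGT-gapped) sequences, skipping
gap/N positions, reported to 0.1%; de novo alignment is out of scope. No
multiple-testing correction is applied anywhere: the reported P values are
unadjusted by design.

The per-case homology vector shipped in `autobcr.reference` is a
**synthetic stand-in** (the study's per-case supplement is not available in
machine-readable form) constructed to be consistent with the published
cohort summary — median 87%, range 68–96% — so tests of the summary
exercise the computation, not independent data.

## I/O and gating

Event tables travel as UTF-8 comma-separated CSV with a header row;
events with a non-positive Indo-1 channel are dropped (SIR undefined) and
counted in a QC report, never imputed. A minimal FCS 3.0/3.1 list-mode
reader (float, double, or linear-scale integer data, both byte orders) is
built in, converting the TIME parameter via the file's `$TIMESTEP`; no FCS
package exists in the supported environment and FCS writing is out of
scope. Gating is by fixed thresholds (GFP ≥, dTomato ≥, viability ≤); a
GFP cutoff can be learned as the 99th percentile of an untransduced
control. Gates are idempotent and zero-retention is an error.

## Known limitations

- The unresponsive-cell correction formula (`raw/(1−u)`, capped) is a
  design choice; the source describes the correction only qualitatively.
- Whole-window autonomous responder fractions are used; a sub-window near
  the end of the 4-OHT phase would weight sustained responses more.
- The 95th-percentile threshold is per-sample, not pooled across samples.
- The flux generator's step-response world makes amplitude recovery exact
  by construction; real kinetics will bias `calSIR_aut` downward relative
  to the step model.
- Classification against finite controls carries the exchangeability
  error described above.
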