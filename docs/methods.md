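# Methods

This note records the models, estimators and numerical choices behind each
module, what the synthetic generators do and do not emulate, and the known
limitations.

## Single-molecule flow-stretching kinetics (`flowstretch`)

**Signal model.** A bead tethered by a ~7.2 kb ssDNA template under ~3 pN
laminar-flow drag reports primer extension as DNA lengthening: ssDNA
converted to dsDNA extends, so bead displacement (nm) is proportional to
nucleotides synthesized via a calibration factor of 3.76 b/nm (set by the
ssDNA/dsDNA extension difference at the applied force; a configurable
constant, not re-derived from polymer elasticity). Sampling is uniform at
0.5 s. A trajectory alternates synthesis phases (slope = single-enzyme
rate) and pauses (no synthesis; interpreted as polymerase exchange, so
phases are treated as independent single-enzyme observations).

**Bead localization.** Each camera frame is fitted with a symmetric 2-D
Gaussian (center, width, amplitude, offset) by least squares
(`scipy.optimize.least_squares`), initialised at the brightest pixel of a
lightly smoothed frame — whole-frame intensity moments are not noise-robust.
A frame whose initial or fitted amplitude is below 5× the robust (MAD)
pixel noise raises a localization failure: the maximum of ~4k noise pixels
alone reaches ~4σ, so a 3σ gate would accept empty frames.

**Drift correction.** Flow instabilities are common-mode across the field,
so the pointwise mean of the mean-centered control traces (tethered,
unreplicated molecules) is subtracted from every reaction trace. Centering
each control first removes drift without disturbing reaction offsets; the
correction adds noise variance σ²/n_controls, which the pipeline's noise
estimate accounts for (factor √(1+1/n)).

**Noise estimate.** `estimate_noise_sd` is the MAD-scaled sd of first
differences divided by √2 — insensitive to slope and to rare jumps. The
pipeline applies it to the control traces rather than per reaction trace:
when the per-sample synthesis step (rate × Δt ≈ 230 b ≈ 61 nm) dwarfs the
noise and pauses occupy roughly half the samples, reaction-trace
differences are strongly bimodal and a per-trace MAD is unstable.

**Pause rule.** A pause is a maximal run of ≥ 6 consecutive samples with
no change in DNA length beyond noise. "No change" is operationalised as
max |x − window mean| ≤ 3 × noise sd over every 6-sample window (union of
qualifying windows). The alternative statistic — total range of the run —
is available (`stat="range"`) but not the default: the expected range of 6
iid normal samples is already 2.53σ, so a 3σ range test rejects a quarter
of genuine minimum-length pauses, and the resulting segment merging
corrupts both population fits. Max deviation from the run mean accepts a
6-sample plateau with probability ≈ 0.997 and admits no false pauses
during synthesis. A marked run that straddles a level step larger than the
threshold (a synthesis burst completed within one sampling interval
between two plateaus) is split at its largest interior jump; split
fragments shorter than 6 samples cannot stand as pauses, and any gap
containing such a fragment is excluded from the rate sample because
plateau samples would dilute its slope. A small absolute epsilon
(10⁻⁹ × signal scale) keeps exactly flat plateaus detectable at zero
noise, where the threshold is zero.

**Segments, rises and the two samples.** Between consecutive pauses the
synthesis event is measured as the difference of the flanking plateau
mean levels ("rise"), not as last-minus-first interior sample: boundary
samples fall mid-step, and the interior-sample difference systematically
loses about one sampling interval of synthesis (~230 b ≈ 11% of the mean
at BR3 conditions). Rises above the 3σ threshold form the length sample —
including rises whose index gap has fewer than 3 samples (even zero:
bursts faster than the sampling interval still leave a measurable level
step; about 11% of an Exp(2000 b) distribution lies below 1.5 samples at
460 b/s, and discarding it truncates the distribution). Rises spanning ≥3
samples additionally carry a least-squares slope and form the rate sample.

**Population fits.** The rate distribution is fitted as a Gaussian by
maximum likelihood — sample mean and (population) sd, uncertainty sd/√n;
binning-free, matching the fitted-mean semantics of a histogram Gaussian.
Segment lengths are fitted as a single exponential. The MLE is the sample
mean; two refinements are available and used by the pipeline:

* *Right-censoring at the template end* (`censor_at`): with a 2 kb mean on
  a 7.25 kb template, roughly one event in four or five is the terminal,
  template-capped one; including it as a completed event biases the mean
  down ~20%. Rises ending within `censor_margin` (50 b ≈ 5σ, covering the
  preserved drift-mean offset and plateau noise) of the template length
  count their mass in the likelihood but not as completed events:
  mean = Σ lengths / n_uncensored.
* *Left-truncation at the detection threshold* (`truncation`): rises are
  only detected above 3σ (~28 b), and by memorylessness each observed
  length is threshold + Exp(mean), so the MLE subtracts the threshold per
  observation.

With both corrections the pipeline estimate tracks the censored MLE
computed on the generator's true segment lengths to within ~±3% per
experiment. What remains, at the study's scale of ~80–90 events per
experiment, is the irreducible sampling scatter of an exponential mean
(relative sd ≈ 1/√n ≈ 10%): the per-experiment event count is Poisson, so
single-experiment processivity estimates scatter by that much around the
nominal mean however good the detection. Rate estimates are far tighter
(sd/√n ≈ 4 b/s).

## Raman decomposition (`raman`)

**Model.** Intensity over 1500–1800 cm⁻¹ is a linear baseline plus six
pseudo-Voigt components — each a Lorentzian/Gaussian pair sharing center
and FWHM, mixed by a fraction in [0,1], area-normalised so the amplitude
parameter is the integrated band area. Assignments by ascending center:
Trp indole (~1550), Ala+Gly (~1580), Tyr/Trp/Phe (~1610), α-helix (1650),
random coil (1670), β-sheet (1680 cm⁻¹). Secondary-structure percentages
normalise the three structural areas to their sum (side-chain bands
excluded); they always sum to 100.

**Fitting.** Nonlinear least squares (lmfit/`leastsq`) with bounds:
centers within ±10 cm⁻¹ of the template, FWHM in [5, 60] cm⁻¹, fractions
in [0, 1], areas ≥ 0; linear baseline co-fitted; five restarts with
jittered areas/widths, best χ² wins. Two stabilising choices matter for
the nearly degenerate 1650/1670/1680 triplet (10 cm⁻¹ apart at FWHM
~15–20 cm⁻¹):

* one Gauss/Lorentz fraction shared across components (per-band free
  fractions let neighbours trade Lorentzian tail mass for area);
* a quadratic restraint pulling each center to its template position with
  scale 0.5 cm⁻¹, weighted by the spectral noise estimated from second
  differences. A Fisher-information analysis at 1%-of-peak noise puts the
  floor on the coil percentage at ~3–4 points when centers float freely
  within their bounds, versus ~0.4 points with centers held — the
  restraint removes that degeneracy while still permitting genuine
  sub-cm⁻¹ shifts, and it vanishes on noiseless data (weight ∝ noise).
  With it, the coil percentage at the 50/30/20 test conditions is
  recovered within 3 points in ≥ 90% of seeds.

**Tyr doublet.** Two pseudo-Voigt peaks (centers bounded 830±8 and
850±8 cm⁻¹) plus a linear baseline over 800–880 cm⁻¹; the ratio uses
integrated areas, not peak heights. Classification: (1.0, 1.5] exposed
(phenolic OH H-bonded to water), [0.7, 0.9) buried (H-bonded to
carboxylates), [0.9, 1.0] ambiguous (literature ranges overlap), outside
[0.7, 1.5] ambiguous. A vanishing 830 cm⁻¹ area raises an
undefined-ratio error.

## Steady-state SPR (`spr`)

Equilibrium responses follow the 1:1 Langmuir isotherm
R(C) = Rmax·C/(Kd + C). The fit is unweighted least squares
(`scipy.optimize.curve_fit`; relative weighting available for
percent-of-signal noise), Rmax bounded at 500 RU by default (immobilization
levels are chosen to keep protein responses below that; overridable). The
fit is flagged non-converged when the Kd estimate exceeds 10× the top
concentration — in that regime the data are linear in C and Rmax and Kd
are not separately identified. Noiseless model series are recovered to
machine precision for any Kd within [Cmin/10, 10·Cmax]. Reference
subtraction is pointwise over matching concentration ladders. No Hill or
bivalent models: the instrument analysis this mirrors uses the 1:1
steady-state mode only.

## Sequence halophilicity (`seqprofile`)

Acidic = {D, E} and basic = {R, K} only — His is excluded and no pKa model
is applied, matching the charge definitions used in comparative polymerase
composition analyses. X is tolerated in sequences but excluded from all
numerators and denominators; percentages are case-insensitive. Domain
coordinates are 1-based inclusive; when domains tile the sequence their
counts sum to the whole-chain counts. "Unique" acidic positions are query
D/E aligned to a non-acidic subject residue; query residues aligned to a
subject gap count as unique by default (acidic inserts have no
counterpart), toggleable. Pairwise alignments are accepted as input (any
global aligner's gapped pair); the module does not choose an alignment
algorithm. Disorder tracks are per-residue probabilities with a 0.5
threshold (the conventional cutoff of neural-network disorder
predictors); the predictor itself is an input, not reimplemented.

## Synthetic data (`synthetic_data`)

The generators define the testbed conditions:

* **Trajectories** — per molecule, alternating synthesis ramps (length ~
  Exp(processivity), slope a fresh Normal(rate) draw) and pause plateaus,
  cumulative synthesis capped at the 7249 b template with a terminal
  plateau appended; one smooth drift waveform (sum of 3 sinusoids, total
  amplitude ≤ 10 nm, periods 30–120 s) shared by all traces of an
  experiment; iid Gaussian bead noise (2 nm default); control traces carry
  drift + noise only. Defaults are the BR3 conditions (460 ± 35 b/s,
  2 kb, 25 molecules + 3 controls); a Pfu preset (305 ± 40 b/s, 1.3 kb,
  13 molecules) matches the comparison dataset's scale (~73 segments).
  Pause durations are a shifted exponential: a 3 s minimum — the
  operational definition of a pause at 0.5 s sampling (6 points) — plus an
  exponential tail to a 5 s mean. Events shorter than 3 s are not pauses
  under that definition; an unshifted exponential would put nearly half
  its mass below detectability and make segment recovery ill-posed by
  construction. Pause frequency/duration are otherwise unreported
  quantities, so both parameters are configurable placeholders.
* **Spectra** — baseline + pseudo-Voigt bands + white noise on a
  0.5 cm⁻¹ grid; default six-band amide layout with structural areas
  50/30/20 and FWHM 12–18 cm⁻¹.
* **Binding** — Langmuir responses on the 10/20/50/100/200/400/600 nM
  ladder with additive (RU) and/or multiplicative (fraction-of-signal)
  noise.
* **Sequences** — planted acidic/basic counts (round(target × length)),
  acidic positions split between disordered segments and the rest
  according to the enrichment parameter, D/E labels assigned in stratified
  halves so both residues realise the enrichment; non-charged positions
  uniform over the remaining 16 amino acids (no further composition is
  analysed); disorder probabilities ≥ 0.5 inside the planted segments,
  < 0.5 outside. Defaults emulate an 818-residue halophilic polymerase:
  17% acidic, 11% basic, ~30% disordered.

All generators are bit-reproducible given (params, seed) and return their
ground truth (segment/pause boundaries in seconds and sample indices, band
tables, Kd/Rmax, planted positions) alongside the data.

**What the generators do not emulate** — and hence what passing tests do
not demonstrate about real data: polymerase rate fluctuations within a
segment (exonuclease switching, force dependence), non-Gaussian camera
noise and tracking artifacts, drift that differs between molecules,
Raman cosmic rays and instrument baseline curvature beyond linear,
SPR mass-transport and surface-regeneration artifacts, and real sequence
composition beyond charge classes.

## Degenerate inputs and tie-breaks

Zero noise makes the pause threshold zero; comparisons use ≤ with a tiny
scale-relative epsilon, so exactly flat plateaus are detected and
noiseless boundaries recover the generator truth exactly. Two pauses
separated by a single outlier sample are not merged (no merging rule is
applied); the gap is recorded as discarded, never fitted. Gaps with
non-significant net lengthening are discarded, so pauses + segments +
discarded always tile a trace. Kd exactly at 10× the top concentration
converges (strict inequality with 10⁻⁹ slack). Empty position sets give
None ("not applicable"), never 0%.

## Problem sizes

Tests and the acceptance script run the study-scale experiments: 25/13
molecules (~90/~73 synthesis segments), 7-point affinity ladders with 50
noise replicates, 601-point spectra with 20 noise replicates, 818-residue
sequences. Everything completes in seconds on one CPU.
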