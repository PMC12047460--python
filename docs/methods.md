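# Methods

## Detection model

The detector treats ventricular-ectopy identification as a two-stage
decision over a stream of beat fiducials on a single sensing vector.

**Stage 1 (trigger).** For each interior beat `i`, prematurity is
`RR_prev(i) / RR_local`, where `RR_local` is the mean of the trailing 8 RR
intervals whose endpoints were both non-candidates and whose length lies
within ±30% of the current local mean — the plausibility band keeps
initial gaps and post-ectopic pauses from inflating the rhythm estimate,
which would otherwise make every normal beat look premature (a
self-reinforcing failure we observed without the band). A beat becomes a
candidate when prematurity ≤ 0.88 or when its peak amplitude ratio to the
mean of its neighbours leaves [0.4, 2.2]; the amplitude path exists
because ventricular ectopy is not strictly premature (escape beats,
interpolated beats). Candidates whose previous-or-next RR interval
overlaps a noise interval are dropped. Consecutive candidates whose
mutual RR is ≤ 0.75 × the local mean merge into blocks: size 1 = single,
2 = couplet, 3 = triplet; larger blocks are emitted untagged and excluded
from PVC counting (sustained runs belong to tachyarrhythmia detection).
The short-mutual-RR requirement is essential: in bigeminy a spuriously
triggered interposed sinus beat would otherwise fuse alternating single
PVCs into a long run and silently drop the whole episode.

**Stage 2 (morphology).** An NSR template — the sample-wise mean of up to
16 recent beats whose adjacent RRs are within ±12.5% of the local median
and whose correlation to the running mean is ≥ 0.95 — is attempted every
2 h (retry 120 s after a failure, 15 s while none has ever formed; at
least 8 qualifying beats are required for validity). Each candidate
window (200 ms, fiducial-centred) yields seven features: 1−CWA, 1−DCWA
(max shift ±10 samples ≈ 39 ms at 256 Hz, overlap correlation, ties to the
smallest then negative shift), prematurity, compensatory ratio
(`RR_next / RR_local`), amplitude ratio, slew ratio (max |dV/dt| vs
template) and width ratio (25%-of-peak span vs template). A separate
L2-regularised logistic regression per sequence type maps standardised
features to a PVC probability; the decision threshold maximises F1 on a
held-out quarter of the training data with ties resolved toward 0.5.
Candidates arising while no valid template exists are labelled non-PVC
and flagged deferred — a conservative choice matching a device that lacks
a reference morphology.

**Burden.** `100 · n_PVC / n_beats` over consecutive windows (default
24 h) anchored at recording start; a window with no beats has *undefined*
burden, never 0%. Alert iff burden ≥ threshold (default 5%, the minimum
configurable level).

## Signal plumbing

Records are converted to μV and seconds on read; the working signal is
band-passed 0.5–40 Hz (zero-phase, order-2 Butterworth sections) and
resampled to 256 Hz. The 40 Hz top edge mirrors the band-limiting of
stored single-vector episodes; the true device front-end is unpublished,
so these are declared, configurable stand-ins. Noise marking runs on the
*raw* signal: the myopotential band it inspects (≥ 45 Hz, power fraction
> 0.5 with an absolute HF-RMS floor of 50 μV, or rail saturation > 50 ms)
is removed by the working band-pass. The amplitude floor exists because a
power *fraction* alone flags quiescent sensor noise. The R-wave detector
is a band-limited-energy scheme (5–30 Hz band — low enough to keep wide,
slow ectopic complexes, whose energy concentrates below 10 Hz — squared
derivative, 150 ms integration, adaptive threshold at 0.35 of the running
peak, 200 ms refractory, search-back at 1.66 × the RR estimate). Records
whose mean |R| within ±50 ms of the fiducials falls below 100 μV fail
amplitude QC.

## Synthetic generator

Beats are sums of Gaussians, giving analytic control of exactly the
quantities the classifier consumes. The sinus prototype is a P-QRS-T
complex (R σ = 9 ms, default 600 μV); wide ectopy is a dominantly
negative, high-amplitude, slow complex (σ = 26 ms, amplitude factor 1.4
with per-record log-normal spread, σ_log = 0.15 — low-amplitude ectopic
foci are a recognised undersensing risk); "narrow-projection" ectopy
reuses a near-sinus shape (CWA to the sinus prototype ≥ 0.9 by
construction, vs ≤ 0.6 for the wide shape). Scheduling is greedy
catch-up: an ectopic event starts whenever the running V fraction is
below target, with event type drawn from the configured mix (singles /
bigeminy episodes of 4 / couplets / triplets) weighted so *beat*
fractions match the mix. Singles couple at 0.72 × the local RR with a
full compensatory pause (2·RR − coupling); sequence members compress to
0.85 × the coupling interval. PACs couple at U(0.70, 0.88) × RR with a
reset of U(1.00, 1.30) × RR — some near-compensatory — and 15% arrive as
pairs/triples. Aberrant conduction is modelled as a continuum: a
per-record severity λ ~ U(0, 0.9), jittered ±0.15 per beat, blends a
perturbed wide-supraventricular shape toward the ventricular prototype.
This continuum (rather than a discrete "looks like a PVC" flag) is what
makes the false-positive failure mode statistically stable: every
aberrant record carries some probability mass near the classifier
boundary. Noise bursts are high-pass-filtered white noise (≥ 45 Hz) with
recorded bounds. RR jitter is Gaussian with CV 0.05, clipped to
[0.6, 1.4] × base.

What the generator does *not* emulate: atrial-fibrillation RR dynamics,
respiration and posture-driven morphology drift, electrode motion
artifact structure, multi-morphology (multifocal) ectopy, and fusion
beats. Passing tests therefore demonstrate the pipeline's mechanics and
its qualitative failure modes, not clinical-grade performance on real
recordings.

## Default models

`scripts/train_default_models.py` builds the committed models from 8
synthetic records (600 s each, 15% burden, mixed sequence types, 3
PACs/min alternating normal/aberrant conduction, one noise burst each,
seeds 2026–2033). Candidates are labelled positive when a true ectopic
fiducial lies within 100 ms. Models are data: JSON files carrying feature
means/scales, weights, intercept, threshold, training seed and a data
hash.

## Scoring

Matching solves the small assignment problem exactly (maximum matched
pairs within ±150 ms, then minimum total |Δt|) rather than scanning
greedily closest-first: a detection whose nearest reference is another
detection's only candidate can strand that detection under the greedy
rule, and the exact solution is what the equivalence-to-optimal property
demands. Fusion-beat references are excluded from both sensitivity and
PPV pools, and detections landing on them are neither TP nor FP.
Modified specificity uses detected beats as the negative universe
(`TN* = n_detected − TP − FP − FN`); the classical form over adjudicated
normals is available behind a flag. GEE adjustment (intercept-only,
binomial link, exchangeable working correlation, robust CIs) is
delegated to statsmodels; the test suite cross-checks it against an
independent fixed-point moment solver. Zero-denominator metrics are
undefined (NaN), never 0 or 100, except F1, which is 0 when there are no
true positives against a non-empty problem. Burden agreement reports
Pearson r, mean bias and 1.96·SD limits of agreement.

## Problem sizes and numerical choices

Test and acceptance runs use 300–1200 s records and cohorts of 20
synthetic patients; these sizes give a few hundred ectopic events per
comparison, enough that the reported rates are stable to a percentage
point or two while a full run stays under a minute. The directional
false-positive comparison uses 10 record pairs because per-record
aberrancy severity makes FP counts clustered; fewer records would make a
sign test flaky. Template, trigger and noise constants are package
defaults (the corresponding device constants are unpublished) and live in
`PipelineConfig`, overridable from YAML. Time is float seconds from
record start throughout; annotation sample indices convert on read, so
all logic is sampling-rate independent.

## Known limitations

Narrow-projection ectopy is essentially invisible to the shipped models
(by design of the stressor, sensitivity approaches zero on pure
narrow-projection records); real devices sit somewhere between, since
projection narrowing is usually partial. The benchmark harness requires a
user-supplied local database copy and refuses partial record sets. The
WFDB layer implements the subset of the format family needed here
(formats 212/16/80, single-segment records, MIT annotation files), not
the full specification. Paced rhythms, atrial-fibrillation discrimination
and episode-level (run) scoring are out of scope.
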