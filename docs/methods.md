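# Methods

This note describes the generative model, the fitting machinery and the
numerical choices behind `tapsync`. Everything stated here is computed by the
package itself; the test suite (`tests/`) and `scripts/acceptance.py`
exercise each claim.

## 1. Task and coordinates

An observer taps in time with one or two auditory metronome streams. The two
streams share a per-trial period drawn uniformly from 470–530 ms. Stream B
lags stream A by a fixed phase offset φ ∈ {0, 50, 100, 150} ms, and each
stream's onsets are independently perturbed around its isochronous grid by
zero-mean Gaussian jitter with s.d. σ_jA, σ_jB ∈ {0, 10, 50} ms.

All quantities are expressed **relative to stream A's pre-jitter grid**, beat
by beat: a tap's asynchrony is `tap − grid_onset_A`, negative when the tap
leads the beat. Trials are 30 beats; analyses use beats 15–28 (14 beats),
after tapping has stabilised.

## 2. Observer model

Per beat *m* the observer receives noisy sensed onsets

- t_A = (onset_A − grid_A) + ε_A, ε_A ~ N(0, σ_A²)
- t_B = (onset_B − grid_A) + ε_B, ε_B ~ N(0, σ_B²)

and carries a prior over the beat time, s ~ N(μ_p, σ_p²). It then performs
Bayesian causal inference over whether the two onsets share a common cause:

p(C=1 | t_A, t_B) = p_s·L₁ / (p_s·L₁ + (1−p_s)·L₂)

where p_s is the prior probability of a single cause and L₁, L₂ are the
marginal likelihoods of the common- and separate-cause models. Both are
closed-form Gaussian integrals:

- L₁ = ∫ N(t_A; s, σ_A²) N(t_B; s, σ_B²) N(s; μ_p, σ_p²) ds
- L₂ = N(t_A; μ_p, σ_A²+σ_p²) · N(t_B; μ_p, σ_B²+σ_p²)

`posterior_common` implements the closed forms; the acceptance suite checks
them against direct numerical quadrature to 10⁻⁶ over a 100-point random
grid of onsets, widths and priors.

**Decision and estimation.** If p(C=1) ≥ 0.5 the observer fuses:
ŝ = precision-weighted mean of (t_A, t_B, μ_p). Otherwise it estimates each
stream separately (precision-weighted mean of t_X and μ_p) and follows
stream A with probability β, else stream B. A model-averaging decision rule
(`decision="average"`) is available as an alternative; the threshold rule is
the default. The tap is emitted at ŝ + d + N(0, σ_M²), with d the usual
negative anticipation bias, and the prior mean for beat m+1 is ŝ(m) (μ_p = 0
on the first beat).

**Variants.**

| variant | p_single | offset handling |
|---------|----------|-----------------|
| MI (mandatory integration) | fixed 1 | — |
| MS (mandatory separation) | fixed 0 | — |
| CI (causal inference) | free | none |
| CI_PA (phase-aware CI) | free | subtracts the known offset from t_B *in the causal judgement only* |

CI with p_single = 1 (0) reproduces MI (MS) bit-for-bit under a shared seed,
and CI_PA with zero offset reproduces CI; the simulator consumes its random
stream in a fixed per-beat order (sensory A, sensory B, selection uniform,
motor) so these equivalences are exact, not just distributional.

**Calibrated reliability (default on).** The observer's *assumed* likelihood
width for each stream in the causal judgement and in estimation is
√(σ_X² + σ_jX²) — sensory registration noise plus the stream's learned
jitter reliability — while the sensing noise itself remains σ_X. Without
this, any jitter larger than a few multiples of σ_X would force separation
even at zero phase offset, and jittering a to-be-ignored stream could not
leave integration intact. With it, an ideal observer discounts unreliable
streams, which is what lets integration shield taps from jitter applied to
one stream. Set `calibrated_reliability=False` to disable.

## 3. Default parameters

| parameter | default | why |
|-----------|---------|-----|
| σ_A, σ_B | 10 ms (`ObserverParams`); 20 ms in the synthetic cohort | 10 ms is a lower-bound auditory registration noise for single clicks; cohort observers use 20 ms so that, with motor noise, unjittered single-metronome tapping s.d. lands in the ~25–30 ms range typical of auditory synchronization, and so that a 50 ms offset is fused whenever the common-cause prior exceeds ½ while ≥100 ms offsets are separated |
| σ_M | 10 ms; cohort range 12–28 ms | motor/timekeeper noise; the cohort range spans typical inter-individual variability |
| σ_p | 100 ms | weakly informative beat prior; fit bounds 10–500 ms |
| p_single | ½ (CI); cohort range 0.5–0.9 | agnostic default; the cohort range produces individual differences in integration (a minority keeps integrating even at large offsets) |
| d | −30 ms | typical anticipation bias; fit bounds ±100 ms |
| β | ½; cohort range 0.25–0.75 | stream preference when separating; calibrated per participant in fitting |
| window | beats 15–28 | discards the initial synchronization transient |

## 4. Synthetic cohort

No tapping dataset accompanies this design, so `generate_cohort` simulates
participants whose ground-truth parameters are drawn from the ranges above
(uniformly, independently), through the full factorial design: 12 dual
conditions × 10 trials plus 3 single-metronome jitter conditions × 10
trials, 30 beats each. Ground truth is written next to the data so recovery
can be audited. The generator emulates: stimulus statistics (period, offset,
jitter), beat-by-beat causal inference with prior carry-over, stream
selection, anticipation and motor noise, and participant heterogeneity. It
does **not** emulate: learning or drift across trials, tap omissions or
double taps, handedness or musicianship effects, and — importantly — the
perceptual merging of physically coincident clicks: at φ = 0 with no jitter
the model still senses two independent noisy copies and gains a √2 precision
benefit from fusing them that a listener who hears a single dyad cannot
obtain. The model's variability in that one cell is therefore biased low;
see §7.

## 5. Fitting

The model has no closed-form likelihood. For a candidate parameter vector θ
the observer is simulated through 2000 fresh windowed asynchronies under the
condition's stimulus statistics, the simulated sample is turned into a
density with a Gaussian KDE, and the data's negative log-likelihood under
that density is the objective (density floored at 10⁻⁹/ms so outliers stay
finite). Common random numbers (one fixed simulation seed per optimizer run)
make the objective deterministic in θ. A seeded differential-evolution
search (Sobol initialisation, no polishing) minimises it over box bounds
(σ_p ∈ [10, 500], p_single ∈ [0, 1], d ∈ [−100, 100], β ∈ [0, 1]); the best
θ is then re-evaluated with three fresh simulation seeds and the median NLL
is reported and used in BIC = 2·NLL + k·ln n, with k counting free
parameters only (MI/MS: 2; CI/CI_PA: 3; +1 when β is being calibrated).

β is calibrated once per participant and variant on the φ = 150 ms,
jitter {0,0} condition — where the asynchrony distribution's two lobes pin
down the stream preference — and then held fixed elsewhere.

**KDE bandwidth.** The improved Sheather–Jones (diffusion) plug-in selector
is implemented directly (DCT-domain fixed point, log-spaced bracket scan +
Brent refinement, 2¹⁰-point mesh), because rule-of-thumb bandwidths
oversmooth the bimodal distributions that large offsets produce; Silverman's
rule is the documented fallback for pathological samples. Densities are
evaluated by binning on a 2¹²-point grid spanning the sample ± 4 bandwidths
followed by Gaussian convolution, then renormalised.

## 6. Model comparison and modality analysis

Per participant, BICs are summed across conditions and differenced against a
reference variant; differences are averaged across participants
(`delta_bic`). A scaled goodness of fit r² places a fit between two anchors:
the data scored against a KDE of itself (r² = 1) and against a featureless
reference density over the support (r² = 0), uniform by default with a
jittered-spline alternative.

Empirical-side modality calls compare 1- versus 2-component Gaussian
mixtures (full covariance, 5 EM restarts, variances floored at 1 ms²) by
BIC; a distribution is bimodal exactly when the 2-component model wins.

## 7. Limitations

- **σ_p is only identifiable when it is small.** Above roughly 100 ms the
  simulated likelihood is flat in σ_p: a weak prior barely moves any beat
  estimate, so weak priors of different widths are behaviourally
  equivalent. Recovery is therefore only tested in the identifiable regime
  (truth 50 ms, factor-of-two tolerance); fitted σ_p values near the upper
  bound should be read as "weak prior", not as a calibrated width.
- **p_single is condition-dependent in its identifiability.** Within a
  condition where the causal posterior never crosses threshold, CI behaves
  exactly like MI or MS and p_single is only interval-identified. It is
  pinned down where jitter makes the posterior straddle the threshold
  (e.g. φ = 100 ms with jitter {50, 10}).
- **The φ = 0 isochronous dual condition is mis-modelled** for the
  perceptual reason in §4: the model's {0,0} baseline variability is
  unrealistically low, so comparisons of jittered dual conditions against
  that baseline overstate the jitter effect. The acceptance suite contains
  one deliberately strict check of this comparison, which fails for exactly
  this reason and is left failing; the companion checks (single-metronome
  jitter ordering, modality flip across offsets) pass.
- Simulated likelihoods carry Monte-Carlo noise (~2000 samples per
  evaluation); tolerances in the tests account for it, but individual fitted
  values move by a few percent across seeds.
- MS with a small fitted σ_p can mimic fusion (the prior smooths selected
  estimates toward the running beat), so CI is only distinguishable from MS
  on data containing genuinely mixed integrate/separate regimes.
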