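# Methods

## Model

`scrdesign` implements closed-population spatially explicit
capture–recapture (SCR) for proximity detectors.  Each animal *i* has a
latent activity centre **x**ᵢ; a survey consists of S occasions over K
detectors, and the data are binary indicators ω᷈ᵢₛₖ of whether animal *i*
was recorded at detector *k* on occasion *s*.  Detectors are
"proximity" type: they record presence without holding the animal, so
several detectors can record the same individual within one occasion,
and all detector-occasion events are conditionally independent given
the centre.

The detection function is hazard-exponential,

    p(d) = 1 − exp(−λ₀ e^(−d/σ)),   λ₀ = −ln(1 − g0),

chosen because area-search data accumulate a cumulative hazard of
detection as the searcher covers ground.  The λ₀↔g0 mapping means the
intercept is reported as g0 = p(0), the familiar probability scale,
while fitting happens on log λ₀ (and log σ).  A half-normal form
(logit-g0 link) is available for comparison.  g0 and σ may each be
constant, occasion-specific ("time", one level per occasion), or
subject to a permanent learned response ("behaviour": one level before
and one after an individual's first capture anywhere — site-specific or
transient responses are deliberately not implemented).

### Conditional likelihood and derived density

Activity centres are integrated over a habitat mask: a grid of M
candidate locations with cell area *c*, extending a buffer beyond the
detectors.  The likelihood conditions on the number n of animals
detected:

    L(θ) = Π_i [ Σₓ Pr(ωᵢ | x; θ) · c ] / a(θ),
    a(θ) = Σₓ p·(x; θ) · c,

where p·(x) = 1 − Π(1 − pₛₖ(x)) over used detector-occasions at the
naive (pre-capture) parameter level, and a(θ) is the effective sampling
area.  Density never enters the likelihood; it is derived afterwards by
Horvitz–Thompson, D̂ = n / a(θ̂) (all detected animals share one
detection class here, so the sum of 1/a over individuals reduces to
n/a).  Reported units are animals per 1,000 km², the convention for
low-density ungulates.  Variance combines the delta method through
a(θ) with Poisson variation in n:

    var(D̂) = ∇D̂ᵀ V ∇D̂ + (1000/a)² · n,

and the 95% CI is lognormal, D̂ · exp(±1.96 √ln(1 + CV²)).  Abundance
over a stated region area A is N̂ = D̂·A/1000 with the same CV.  The
exact var(n) component is an assumption (a parametric choice, not
estimable from one realization); the CI-coverage simulation below is
the check that the overall interval is calibrated.  Candidate parameter
structures are ranked by AICc = −2ℓ + 2K + 2K(K+1)/(n−K−1) with n = the
number of detected individuals (the standard SCR convention for the
effective sample size).

### Numerical choices

- **Optimisation**: BFGS on the link scale with finite-difference
  gradients, gtol 1e−6.  BFGS frequently terminates with "precision
  loss" once the numeric gradient bottoms out below its noise floor;
  the fit is accepted as converged if the Hessian at the stopping point
  (central differences, relative step 1e−4) is positive definite —
  otherwise `converged=False` and no SEs are reported.  A gradient
  tolerance much below 1e−6 is not meaningful with numeric gradients on
  a surface whose values are O(10²–10³).
- **Starting values**: g0 = 0.05; σ from the pooled spread of each
  individual's detections about its own centroid (an RPSV-style
  statistic), falling back to the median nearest-detector spacing when
  no individual moved between detectors.  Simulation experiments start
  at the generating truth, mirroring how reference estimates seed
  follow-up designs in practice.
- **Identifiability guard**: with zero recaptures σ is unidentifiable;
  the fit is abandoned with status "non-identifiable" instead of
  optimising a flat surface.
- **Likelihood evaluation**: detections are sparse, so log p is only
  evaluated at detectors that recorded something; log(1−p) =
  −λ₀e^(−d/σ) is exact (no cancellation) for the hazard-exponential
  form.  An optional far-field cutoff (`cutoff_sigmas`) zeroes
  log(1−p) beyond a distance of several σ for speed at ~1e−5 absolute
  likelihood error; it is off by default because the induced kink adds
  noise to finite-difference gradients.
- **Mask construction**: rectangular grid over the detector bounding
  box plus a buffer (default 15 km, the field protocol's state-space
  buffer; ≥5σ is sufficient for this detection form — a 4σ buffer still
  truncates ~1.3–1.5% of a(θ) because the e^(−d/σ) tail is heavier than
  a half-normal's).  Default spacing is min(σ/2, 1,500 m).
- **Ties in AICc ranking** break toward fewer parameters.

## Synthetic surveys

`survey_synth` emulates the aerial design: parallel north–south
transects at 3-km spacing (midline rule: lines at half-spacing from the
western edge; at least one line always returned), and a 1,500-m grid of
proximity detectors aligned so flight lines pass through cell centres.
Cells whose centres are within half a cell of a line are "searched" and
act as detectors; the rest are excluded by default (the thinning
operations then behave exactly like removing flight lines), or kept
under a flag for a whole-area grid.  Occasion-level usage defaults to
all-on; weather-caused gaps can be expressed through the usage matrix
but are not generated.

Populations are homogeneous Poisson, or Neyman–Scott: Poisson parents
of intensity D/µ, exactly µ offspring per parent (the fixed-cluster-size
reading), isotropic Gaussian scatter with SD `within_cluster_scale`
(metres; default 1 m in the robustness experiment, making cluster mates
essentially co-located).  Both processes share expected intensity D, so
µ varies clustering at fixed truth.  Populations are generated over the
survey region **plus a buffer** (default min(8σ, 15 km)): the estimator
integrates centres over a buffered mask, so animals beyond the surveyed
boundary must exist in the truth — confining them to the survey polygon
produces a large artificial negative bias.  Offspring falling outside
the region are kept for the same reason (a clip flag exists).  Sexes
are i.i.d. Bernoulli at the design's sex ratio.

What the generator does **not** emulate: the sample→individual
resolution pipeline (genotyping error, per-site oversampling),
backtracking along trails, behavioural cohesion during detection
(grouping enters only through activity-centre clustering), open
population dynamics, and real range shapes (regions are rectangles or
user polygons).  Passing simulation tests therefore demonstrates
estimator correctness under the stated model, not robustness to these
field realities.

## Rarefaction engine

Scenarios are the full occasion set plus all 2-subsets, crossed with
keep-every-k transects (k ∈ {1,2,3} ≙ 3/6/9-km spacing) and sex groups
{both, F, M} — 36 scenarios for a 3-occasion survey; "both" includes
unknown-sex individuals, single-sex groups drop them.  Transect
retention starts at the first line (offset configurable).  Each
scenario inherits the reference fit's model structure, is refit, and
scored by CV and |RB| against that sex group's full-data estimate;
non-convergence is recorded, never raised.  Favorable thresholds:
CV < 20% and |RB| < 15%; CV < 30% and |RB| < 20% still acceptable.
Pearson correlations (two-sided t-based p) relate CV and |RB| to the
capture/recapture/spatial-recapture counts over converged scenarios.

Two spatial-recapture definitions exist because the phrase is
ambiguous: the default counts each individual's distinct detectors
beyond the first; the alternative counts detections at any detector
other than the first-capture site.  Neither is asserted against the
published per-population values.

## Reference experiments and problem sizes

`scrdesign.experiments` runs three studies at published truths on
square stand-in regions sized for single-CPU minutes (the empirical
ranges are 1,516–24,737 km²; simulating them at full size changes only
runtime and sample size, and the scaled surveys already detect 90–130
individuals, inside the empirical 42–490 span):

- **Parameter recovery** — ESAR truth (D = 50.6, g0 = 0.024,
  σ = 1,778.8 m), 80 × 80 km region, 100 replicates: median relative
  bias of D̂ and coverage of the 95% CI.  Masks here use 2,500-m
  spacing (moves D̂ by <0.1% vs 1,500 m; measured).
- **Clustering robustness** — Cold Lake truth (D = 61.9, g0 = 0.015,
  σ = 3,363.2 m), 60 × 60 km region, µ ∈ {1, 5, 10}, 50 replicates per
  level: median |RB| per µ and a replicate-level Kendall test for a
  trend of RB in µ.  µ levels are stand-ins; the defaults elsewhere are
  {1, 3, 5, 10, 25}.
- **Small-range thinning** — Slave Lake truth (D = 25.9, g0 = 0.247,
  σ = 1,226 m) with a clustered population (µ = 5), 39 × 39 km region,
  20 replicates: per-sex refits at keep-every-1 and keep-every-3
  transects, comparing non-convergence rates.  σ below the 1,500-m
  detector spacing is what makes spatial recaptures scarce here; at
  this truth outright non-convergence is nonetheless rare, so the
  comparison typically holds with equality.

`scripts/acceptance.py --seed N --out results/acceptance.json` runs all
three plus the exact arithmetic and the likelihood-oracle comparison.

## Known limitations

- Homogeneous density only (no density surfaces or covariates), single
  session, closed population, no Bayesian/data-augmentation variant,
  no count-valued detectors, no telemetry integration.
- D̂ = n/â carries positive small-sample bias (Jensen's inequality in
  1/â) that is material below ~50 detected individuals with
  single-line detector columns; design evaluations on very small
  surveys should read |RB| accordingly.
- The delta-method SE assumes Poisson n; a parametric bootstrap is the
  recommended cross-check when the assumption is in doubt.
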