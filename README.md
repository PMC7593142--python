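# scrdesign

Spatially explicit capture–recapture (SCR) density estimation and
sampling-design assessment for transect-based noninvasive genetic
surveys.

## Who this is for

Wildlife biologists planning or evaluating surveys of low-density,
wide-ranging animals — the motivating system is boreal caribou
(*Rangifer tarandus caribou*) surveyed by winter fecal-DNA collection
along aerial transects — who need to know whether a given combination of
transect spacing, number of sampling occasions, and sex stratification
will deliver a usable density estimate before committing flight hours to
it.

## What it does

1. **Fits SCR models** to proximity-detector capture histories by
   maximising the conditional likelihood.  Each animal has a latent
   activity centre **x**, integrated over a discretized habitat mask;
   the per-occasion probability of recording an animal at a detector a
   distance *d* from its centre is the hazard-exponential form

   p(d) = 1 − exp(−λ₀ e^(−d/σ)),  λ₀ = −ln(1 − g0),

   appropriate for area-search data (search effort accumulates a hazard
   of detection).  g0 is the detection probability at the centre, σ the
   spatial scale of landscape use; both may be constant,
   occasion-specific ("time"), or switch after first capture
   ("behaviour"), with candidate structures ranked by AICc.  Density is
   derived by Horvitz–Thompson, D̂ = n / a(θ̂), where
   a(θ) = ∫ p·(x) dx is the effective sampling area, with a delta-method
   SE, CV = SE/D̂, and lognormal 95% CI.

2. **Simulates populations and surveys**: homogeneous Poisson or
   Neyman–Scott clustered activity centres (Poisson parents, exactly µ
   individuals per cluster, Gaussian within-cluster scatter) on a
   transect survey geometry (parallel lines, default 3 km apart, with a
   1,500-m grid of proximity detectors along the flown lines, 3
   occasions), so estimator calibration and robustness to grouped
   animal distributions can be quantified against known truth.

3. **Rarefies real or synthetic datasets** to score cheaper designs:
   every 2-occasion subset, keep-every-2nd/3rd transect (emulating 6- or
   9-km spacing), and per-sex fits.  Each reduced fit is scored by
   precision (CV) and absolute relative bias |RB| = |(D̂ − D)/D| against
   the full-data estimate, with CV < 20% and |RB| < 15% flagged
   favorable (CV < 30%, |RB| < 20% acceptable for low-density species),
   plus Pearson correlations of CV and |RB| with the capture,
   recapture and spatial-recapture counts.

The package ships the published seven-range Alberta caribou reference
tables (sampling tallies and density estimates) in
`scrdesign.datasets`; they drive the worked examples and provide
realistic simulation truths.

## Worked example

```python
import scrdesign as sd

# a ~1,500 km^2 range surveyed at 3-km spacing, 3 occasions
design = sd.SurveyDesign(region=(0, 0, 39_000, 39_000))
truth = dict(D=25.9, g0=0.247, sigma=1226.0)   # Slave-Lake-like truth
ds = sd.generate_survey_dataset(design, truth, seed=1)
print(len(ds.detectors), ds.population.n, ds.histories.n_individuals)
# 338 87 35   (detectors; animals in the buffered truth; detected)

mask = sd.make_mask(ds.detectors, buffer_m=10_000, spacing_m=1500)
fit = sd.fit(ds.histories, ds.detectors, mask)
print(f"D = {fit.D_hat:.1f} per 1,000 km2, CV = {fit.CV_D:.2f}, "
      f"g0 = {fit.model.g0[0]:.3f}, sigma = {fit.model.sigma[0]:.0f} m")
# D = 27.8 per 1,000 km2, CV = 0.20, g0 = 0.225, sigma = 1173 m

tab = sd.run_design_evaluation(ds.detectors, ds.histories, mask,
                               spacing_factors=(1, 2), sex_groups=("both",))
print(tab[["occasions", "spacing_factor", "CV", "abs_RB", "converged"]])
#   occasions  spacing_factor        CV    abs_RB  converged
# 0     1+2+3               1  0.195107  0.000000       True
# 1     1+2+3               2  0.278443  0.047352       True
# 2       1+2               1  0.256047  0.191930       True
# ...
```

The fitted density (27.8 per 1,000 km²) lands near the simulation truth
(25.9) with a CV of 0.20 — right at the favorable-precision threshold,
as expected for a range this small — and the design-evaluation table
shows precision degrading (CV 0.20 → 0.28) as soon as every second
transect is dropped.

A command-line interface wraps the same steps for TSV inputs
(`detectors.tsv`: detector_id, x, y, transect_id; `captures.tsv`:
session, individual_id, occasion, detector_id, sex) — this is also the
route for fitting archived field datasets once exported to these
dialects:

```sh
scrdesign simulate --config survey.yaml --seed 1 --out-dir data/
scrdesign fit --detectors data/detectors.tsv --captures data/captures.tsv
scrdesign design-eval --detectors data/detectors.tsv --captures data/captures.tsv
scrdesign report --scenarios scenarios.csv
```

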