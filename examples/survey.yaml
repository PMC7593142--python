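# Example survey configuration for `scrdesign simulate`
region:
  width_km: 39
  height_km: 39
spacing_km: 3.0       # transect spacing
cell_m: 1500          # detector cell size
occasions: 3
sex_ratio: 0.5
truth:                # simulation truth
  D: 25.9             # animals per 1,000 km^2
  g0: 0.247           # detection probability at the activity centre
  sigma: 1226.0       # spatial scale, metres
  mu: 5               # individuals per cluster (1 = homogeneous)
  within_cluster_scale: 1.0
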