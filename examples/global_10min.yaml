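# Template for a run on real 10-arc-minute climate rasters (ESRI ASCII
# grids) and a literature-compiled occurrence CSV (lon,lat[,clade]).
# At this scale the background sample is 100,000 cells, the design used
# for a global analysis. Paths are placeholders: point them at your own
# raster stack before running.
outdir: runs/global
seed: 0

env_current:
  - data/current/bio1.asc
  - data/current/bio7.asc
  - data/current/bio12.asc
  - data/current/bio17.asc
env_scenarios:
  a1b:
    - data/a1b_2080/bio1.asc
    - data/a1b_2080/bio7.asc
    - data/a1b_2080/bio12.asc
    - data/a1b_2080/bio17.asc
  b2a:
    - data/b2a_2080/bio1.asc
    - data/b2a_2080/bio7.asc
    - data/b2a_2080/bio12.asc
    - data/b2a_2080/bio17.asc
env_variables: [bio1, bio7, bio12, bio17]
occurrences: data/occurrences.csv

prevalence_grid: [0.1, 0.3, 0.5, 0.7, 0.9]
families: [GAM, GLM, CART, BRT, BIOCLIM, DOMAIN, MAHAL, MAXENT_LIKE]
n_background: 100000
r_max: 0.8
alpha: 0.05
auc_min: 0.9
n_repeats: 10
n_boot: 1000
scenarios: [a1b, b2a]
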