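# Fixture-scale run on a simulated virtual species (no external data).
# Run:  nichecast run-all -c examples/fixture.yaml
outdir: runs/fixture
seed: 0

# synthetic environment: 100x100 grid of 10-arcmin cells, 4 smooth
# standardized layers plus a decoy correlated 0.9 with env1, ~5% sea
n_rows: 100
n_cols: 100
n_env_vars: 4
decoy_r: 0.9
smooth_sigma: 6.0
sea_fraction: 0.05

# modelling design (fixture scale: 5,000 background cells)
prevalence_grid: [0.1, 0.3, 0.5, 0.7, 0.9]
families: [GAM, GLM, CART, BRT, BIOCLIM, DOMAIN, MAHAL, MAXENT_LIKE]
n_background: 5000
r_max: 0.8
alpha: 0.05
auc_min: 0.9
n_repeats: 10
n_boot: 1000
scenarios: [mild, strong]
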