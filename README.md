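# searchshare

Analysis pipeline for geographic disparities in mental-health symptom
searching, built on county-level symptom search-weight panels whose raw
weights are *not* comparable across regions (each county carries an unknown
positive scale factor, plus privacy noise and suppression).

The core statistic is the **share of search**: a symptom's weight divided by
the summed weight of all symptoms in the same county and biweekly period,
expressed as a percentage. Because every weight in a county-period carries
the same unknown scale factor, the share is invariant to it. On top of that
the package provides:

- **data_io** — readers for the wide panel dialect (empty cell = suppressed,
  never zero), shortage-area and urbanization-code files, biweekly
  resampling, and CSV/Parquet writers.
- **synthetic** — a panel generator with latent per-symptom propensities,
  per-county scale factors, multiplicative planted effects by stratum and
  symptom class, temporal steps/trends, log-normal + Laplace noise, and
  cell/county suppression — with closed-form ground-truth shares
  (`GroundTruth`) for recovery testing.
- **taxonomy** — Cohen's kappa for dual-coder agreement, seed-set expansion
  through a co-search affiliation table with a relevance threshold, and
  rule-based exclusions with an audit ledger.
- **shares** — share-of-search, composite symptom-set shares, windowed means.
- **comparison** — Welch/pooled two-sample t tests, Benjamini-Hochberg
  (and Benjamini-Yekutieli) Q values computed per contrast family, named
  stratified contrasts (shortage vs nonshortage; rural/urban/metro slices),
  pre/post temporal contrasts, county rankings, and group time series with
  confidence bands.
- **cli** — a `searchshare` command orchestrating everything from YAML.

Counties designated *partial* shortage areas are excluded from two-group
contrasts but retained in rankings and time series. Missing (suppressed)
cells are excluded from share denominators, not imputed as zero.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance suite:
scale-invariance and conservation oracles, exact equivalence of the BH
implementation with a brute-force step-up oracle, closed-form t/kappa
checks, null (type-I) calibration over 200 simulations, planted-effect
power and temporal-step recovery, qualitative-pattern reproduction, and
suppression/exclusion accounting.

## CLI

```sh
# simulate a panel with planted effects
searchshare simulate --config sim.yaml --out-dir data/

# full pipeline from a config
searchshare run --config run.yaml
```

A minimal `run.yaml`:

```yaml
output_dir: out
seed: 1
simulate:
  n_counties: 100
  n_periods: 26
  symptom_classes: {anxiety: broad, adhd: specific, cough: non_mh}
  base_propensity: {anxiety: 2.0, adhd: 3.0, cough: 5.0}
  lognormal_sd: 0.2
contrasts: [shortage_vs_nonshortage, rural_shortage_vs_rural_nonshortage]
cutoff: 2020-03-11
rank_k: 10
```

Real data goes through `inputs: {panel: ..., designations: ...}` (or
separate `shortage:`/`nchs:` files) plus `symptom_set: path/to/list.csv`.
Individual stages are also available as `taxonomy`, `shares`, `compare`,
`temporal` and `rank` subcommands. Exit codes: 0 success, 2 validation,
3 I/O, 4 statistical degeneracy.

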