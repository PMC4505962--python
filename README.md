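# netmatch

Degree-softmax choice modelling of growing social networks.

Newcomers joining a network choose whom to link to with probability
proportional to `degree**L`, where the real-valued sensitivity `L`
interpolates between popularity avoidance (`L < 0`), value-blind uniform
choice (`L = 0`), classical linear preferential attachment (`L = 1`) and
winner-take-all behaviour (`L >> 1`). This package provides:

- **`netmatch.netgrow`** — the choice rule and a growing-network simulator
  (seed clique of `m+1` nodes, each newcomer adds `m` edges sampled
  sequentially without replacement from the degree softmax), with per-newcomer
  `L` either fixed or drawn from a truncated Gaussian.
- **`netmatch.inference`** — Bayesian estimation of `L` from two-choice data
  on a fixed stimulus graph: per-participant, per-choice, shared-`L` and
  hierarchical (Gaussian individual differences) models fitted by
  Metropolis–Hastings / Metropolis-within-Gibbs with Gelman–Rubin convergence
  checks, plus AICc model comparison with participant effects integrated out
  by quadrature.
- **`netmatch.metrics`** — degree distributions and CCDF tail slopes,
  characteristic path length (exact or source-sampled), mean local clustering.
- **`netmatch.cohort_stats`** — Pearson correlations with percentile-bootstrap
  confidence intervals: first/second-choice consistency of fitted `L` and
  correlations with Big Five trait scores.
- **`netmatch.synthetic_data`** — a generator for stimulus networks and
  simulated cohorts (choices + personality scores with a tunable
  extraversion–`L` correlation), so the entire pipeline runs and is tested
  without any external data.
- **`netmatch.cli_io`** — the `netmatch` command-line interface, the
  (`L` mean, `L` sd) parameter-sweep driver for connectivity metrics, and an
  importer for deposited MATLAB datasets.

## CLI

```bash
netmatch synth-cohort --seed 1 --n-participants 600 --out runs/cohort
netmatch fit hierarchical --cohort runs/cohort --seed 2 --out runs/hier
netmatch fit separate --cohort runs/cohort --seed 3 --n-samples 1000 --out runs/fits
netmatch report --cohort runs/cohort --fits runs/fits/fits.csv --out runs/report
netmatch compare-models --cohort runs/cohort --seed 4 --out runs/aicc
netmatch simulate-network --seed 5 --n-nodes 10000 --l-mean 1 --l-sd 2 --out runs/net
netmatch metrics --network runs/net/network.edgelist --out runs/metrics
netmatch sweep --seed 6 --out runs/sweep            # reduced scale
netmatch sweep --seed 6 --full-scale --out runs/big # 41x13 grid, 10^4 nodes
netmatch import --mat data/s1_dataset.mat --out runs/imported
```

Every subcommand takes `--seed` and `--out`; outputs are deterministic given
the seed, and each output directory contains a manifest of the command and
configuration. Cohort directories hold plain-text artifacts
(`stimulus.edgelist`/`.graphml`, `choices.csv`, `personality.csv`, optional
ground-truth `truth.csv`, `manifest.json`).

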