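# phylogeo

Does geography or morphology predict a molecular phylogeny?

`phylogeo` is a toolkit for testing alternative topological hypotheses
against molecular sequence data, built for systems — such as short-range
endemic millipedes of the Appalachians — where species look alike because of
convergent evolution and live near their relatives because of limited
dispersal. It asks the question quantitatively: given a multi-gene
alignment, is the tree implied by geography (species grouped by ecoregion),
the tree inferred from morphology, or a prior classification any good at
explaining the molecular data?

## What it does

- **Constrained Bayesian inference.** A Metropolis-coupled MCMC sampler over
  topologies, branch lengths and substitution-model parameters (JC/HKY/GTR
  with +I and discrete-Γ; symmetric Mk with the "variable" ascertainment
  correction for morphology). Topological hypotheses enter as hard
  monophyly constraints: proposals violating a constraint receive zero
  prior mass.
- **Stepping-stone marginal likelihoods and Bayes factors.** Each hypothesis
  H is scored by its log marginal likelihood ln p(X | H), estimated by
  stepping-stone sampling along the power posterior p(θ) L(θ)^β with
  β_j = (j/K)^(1/0.3) over K = 50 steps. Hypotheses are compared on the
  doubled-log scale 2Δln = 2[ln p(X|H₁) − ln p(X|H₂)]; values above 10 are
  "very strong" evidence.
- **Stochastic character mapping and homoplasy.** Discrete characters are
  mapped onto the molecular tree by sampling substitution histories
  conditional on tip states (pruning + node-state sampling +
  endpoint-conditioned uniformization). Per character it reports the
  consistency index CI = m/s (m = observed states − 1, s = posterior-mean
  mapped changes), the homoplasy index HI = 1 − CI, per-state dwell times,
  and each gonopod region's (coxa / prefemur / tibiotarsus) share of
  overall homoplasy.
- **Geographic distance trees and endemism.** Species centroids on the
  sphere, point-in-polygon ecoregion assignment, great-circle (haversine,
  R = 6371.0088 km) distance matrices, neighbor joining, convex-hull range
  areas in an equal-area projection, and short-range endemism classes
  (SRE < 10,000 km², MRE < 1,000 km²).
- **Synthetic data.** Yule trees, partitioned sequence simulation, discrete
  characters with a tunable fraction ρ evolved on a decoy tree (known-truth
  convergence), and Brownian-dispersal localities with tunable noise — so
  the entire pipeline is testable without any external download.

## Worked example

```python
import phylogeo as pg
from phylogeo.geo import RegionMap
from phylogeo.pipeline import run_comparison, report_to_text

cfg = pg.SimConfig(n_taxa=8, n_morph_chars=12, partition_lengths=(300,),
                   partition_models=("HKY+G",), convergence_fraction=0.25,
                   dispersal_sigma_km=150.0, geo_noise=0.0,
                   morph_rate=0.4, seed=3)
bundle = pg.simulate_dataset(cfg)
regions = RegionMap.grid(-86, 32, -76, 42, 3, 3)
mcmc = pg.McmcConfig(generations=3000, sample_interval=25, n_runs=2,
                     n_chains=2, seed=11, ss_generations_per_step=60)
report = run_comparison(bundle["sequences"], bundle["scheme"],
                        bundle["morphology"], bundle["localities"],
                        regions, None, cfg=mcmc)
print(report_to_text(report))
```

prints

```
hypothesis  n_constraints  log_ml        2dln_vs_MOT  category
MOT                     6      -2770.03         0.00  none
MRT                     6      -2819.59        99.12  very strong
EDT                     2      -2827.49       114.91  very strong
gonopodal homoplasy shares: coxa: 27%, prefemur: 32%, tibiotarsus: 40%
endemism: 8/8 SRE-qualifying, 8/8 MRE
```

Reading the table: the molecular-consensus hypothesis (MOT) is the
baseline, so its score is 0 by construction. The morphology tree (MRT) and
the ecoregion distance tree (EDT) are both "very strongly" rejected
relative to it (2Δln ≫ 10) — expected here, since a quarter of the
simulated characters evolved convergently and only eight taxa anchor the
geography. The homoplasy shares split the summed per-character HI of the
gonopod-tagged characters across the three podomere regions, and the
endemism line counts species whose convex-hull range falls under the
10,000 km² (SRE) and 1,000 km² (MRE) thresholds.

The same pipeline is available from the shell:

```sh
phylogeo --seed 5 --out-dir demo simulate --taxa 8 --sites 300
phylogeo --out-dir demo geodist demo/localities.csv demo/regions.geojson
phylogeo --seed 5 --out-dir demo compare demo/sequences.fasta \
    --partitions demo/partitions.txt --morphology demo/morphology.nex \
    --localities demo/localities.csv --regions demo/regions.geojson
```

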