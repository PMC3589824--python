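# dcnsim

Notch–Delta mutual inhibition on irregular 3D neuron clusters:
simulation and quantitative anatomy of binary axon-target choice in the
*Drosophila* dorsal cluster neurons (DCNs).

## The problem

The ~38 DCNs per hemisphere (variable: 35–43) send most axons to the
lobula while ~12 regularly spaced axons remain in the medulla.  The
stereotyped pattern despite a variable lineage is explained by
**lateral inhibition among neighboring postmitotic soma**: within
overlapping subclusters of cells closer than 0.17 nad (normalized
units), Notch–Delta feedback amplifies small initial differences, and
the cells ending with the lowest Notch activity keep their axon in the
medulla.  `dcnsim` is for modelers and quantitative anatomists who want
to simulate that selection process on measured or synthetic soma
coordinates and analyze the resulting axon patterns.

## Model

Per cell *i*, with `dl_i` the mean Delta of its graph neighbors
(`dl_i = (1/r_i) Σ_{j~i} Dl_j`, 0 for isolated cells):

    dN_i/dt  = p_n · dl_i² / (a + dl_i²) − μ N_i
    dDl_i/dt = p_d / (1 + b N_i²)        − ρ Dl_i

with `a = 0.01, b = 100, μ = ρ = p_d = 1`; a signal strength
`s ∈ (0, 1]` sets `p_n = s` and the noisy initial levels
(`N(0) = Dl(0) = s(1 + ε), ε ~ U[0, 0.01]`).  The system is integrated
to `t = 1000` with adaptive RK(2,3); each subcluster then nominates its
lowest-Notch cells as medulla-targeting winners (ties at numerical
resolution are resolved along the least-damped spatial mode — see
`docs/methods.md`).

## Worked example

```python
import numpy as np
from dcnsim import (GeneratorConfig, ModelParams, calibrate_scale,
                    generate_cohort, mean_subcluster_size,
                    run_replicates, summarize_replicates)

config = calibrate_scale(GeneratorConfig(), threshold=0.17,
                         target_mean_neighbors=7.0, seed=0)
cohort = generate_cohort(config, 16, seed=0)
print(round(mean_subcluster_size(cohort, 0.17), 2))

for s in (1.0, 0.1):
    table = run_replicates(cohort, 0.17, ModelParams(signal_strength=s),
                           n_reps=20, seed=0)
    out = summarize_replicates(table)
    print(f"s={s}: {out['mean_axon_count']:.2f} "
          f"± {out['sd_axon_count']:.2f} SD (n={out['n']})")
```

prints

```
6.98
s=1.0: 12.55 ± 2.18 SD (n=320)
s=0.1: 17.42 ± 2.69 SD (n=320)
```

i.e. the calibrated cohort has ~7-cell subclusters at the 0.17-nad
threshold; under full Notch signal a ~38-cell cluster produces ~12
spaced medulla axons, and reducing the signal to 10% *increases* the
count to ~17 with the extra axons appearing adjacent to one another —
the in-silico loss-of-Notch phenotype.

The same pipeline is available from a shell:

```
dcnsim generate --n-clusters 16 --seed 0 --out cohort.tsv
dcnsim graph-stats --profile cohort.tsv --threshold 0.17
dcnsim simulate --profile cohort.tsv --signal-strength 0.1 --reps 100 \
    --seed 0 --out replicates.csv
dcnsim analyze --profile measured_profile.tsv
dcnsim experiment --config config.json --out results/
```

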