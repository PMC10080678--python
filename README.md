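# formose-dyn

Tools for studying how *dynamic* environmental conditions shape the
product composition of a model prebiotic reaction network — the formose
reaction run in a continuous stirred-tank reactor (CSTR) under
fluctuating Ca(OH)2 input.

In a CSTR of volume V at total flow F, every species is diluted with
time constant tau = V/F (here 411 uL / 3.425 uL s^-1 = 120 s). The
package generates stepwise-Gaussian CaCl2/NaOH inlet programs
(mean 15 mM, sigma up to 5.75 mM, steps of 30–120 s, NaOH slaved to a
1:2 Ca2+:HO− ratio, a water channel holding tau constant), drives a
schematic formose-like reaction network through them, applies GC–MS
style quantification, and runs the two analyses that expose how
fluctuations propagate:

* **Correlation-distance hierarchical clustering.** Pairwise distances
  d(u,v) = 1 − corr(u,v) between compound concentration time traces,
  agglomerated by average linkage with the proportional-average update
  d(A∪B, Y) = (|A| d(A,Y) + |B| d(B,Y)) / (|A|+|B|) and merge heights
  recorded as d(A,B)/2. Compounds that respond to the environment in
  unison cluster together.
* **Multi-timescale windowed-differential correlation.** The input and
  each compound trace are averaged in consecutive windows of width
  w ∈ {30, 60, 90, 120, 150} s, differenced between windows,
  standardised (v = (x − x̄)/σ_x), and correlated (Pearson r per
  compound per width). Positive r means the compound moves with the
  input on that timescale.

Distribution comparisons between conditions (Welch's t, significance
stars from ns to ****) complete the pipeline.

The reaction-network simulator is the synthetic-data generator for the
whole package: a Breslow-cycle engine with five gated compound
families whose catalyst sensitivities, signs and relaxation lags
differ, so the analyses have known ground truth to recover. See
`docs/methods.md` for the model and its assumptions.

## Worked example

The numbered scripts under `analysis/` run the study end to end at desk
scale. Generating the input programs:

```sh
$ python analysis/01_generate_inputs.py --seed 0
condition   sigma       rate/s    mean     SD clipped
EXP001       0.00            0   15.00   0.00       0
EXP002       2.89           45   15.32   2.68       0
EXP003       5.75           45   15.63   5.33       0
EXP011       5.75          120   16.46   4.83       0
EXP013       5.75 [30, 60, 120]   15.00   5.74       1
```

Each row is one preset condition: the realised mean and SD of the
CaCl2 inlet signal (mM) and the number of steps clipped for
feasibility. EXP013 superimposes three timescales and is rescaled
exactly to its targets; the single-timescale rows show ordinary
finite-sample scatter around theirs (75 steps each).

Simulating EXP013, sampling 50 outlet points at 30.6 s, and clustering
the 28 measured compound traces:

```sh
$ python analysis/02_simulate_network.py --seed 0
$ python analysis/04_cluster_traces.py --seed 0
k=5 flat clusters (dendrogram order):
  cluster 2 (module II): M8c, M8d, M8, M8b, M8e
  cluster 3 (module III): F3b, F3, F4, F4b, F2, F2b
  cluster 1 (module core): Q6, Q6b, Q5, Q4, Q4b
  cluster 5 (module V): W9f, W9c, W9d, W9, W9b, W9e
  cluster 4 (module IV): X9, X9c, X9b, X9f, X9d, X9e
adjusted Rand index vs planted modules: 1.000
```

The k=5 cut of the dendrogram recovers the generator's five planted
modules exactly (adjusted Rand index 1.0): compounds downstream of the
same gating chemistry respond to the environment collectively.
`05_timescale_correlation.py` then shows the per-timescale input
correlations of each family, and `06_compare_conditions.py` the
significance-starred composition shifts between the steady state and
the 45-s / 120-s perturbed conditions.

The same pipeline is scriptable (`formose-dyn run --preset EXP013
--seed 0 --out-dir out/`) and usable as a library:

```python
from formose_dyn import clustering, crn_sim, io_cli

model = crn_sim.build_formose_model()
flows, traces = io_cli.simulate_condition(io_cli.preset("EXP013"), seed=0,
                                          model=model)
dend = clustering.average_linkage(clustering.pairwise_distances(traces))
labels = clustering.cut_clusters(dend, k=5)
```

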