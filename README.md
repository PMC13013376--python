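# netshift

Paired-condition graph-theory analysis of functional brain networks.

`netshift` implements, as a tested and reusable pipeline, the standard
within-subject connectome workflow used to ask how an acute condition (for
example total sleep deprivation versus rested wakefulness) reorganizes
brain network topology: from region-of-interest BOLD time series to
Fisher-z functional connectivity, through proportionally thresholded
binary and weighted graphs swept over a sparsity (cost) range, to global
and nodal topology metrics summarized by their area under the curve over
cost, and finally the full paired statistical battery — normality-routed
paired tests with effect sizes, false-discovery-rate control across nodes,
brain–behavior rank correlations, and covariate-adjusted regression.

Because datasets of this kind are rarely shareable, the package ships a
first-class synthetic generator that produces paired cohorts with the
statistical structure the analysis assumes (modular band-limited signals,
implanted topological condition effects, behavior coupled to network
metrics), so every downstream stage is testable end to end with no
download.

## The model in brief

For each subject and condition, regional time series $x_i(t)$ yield a
$90\times 90$ Pearson matrix $r_{ij}$, Fisher-transformed to
$z_{ij}=\operatorname{arctanh}(r_{ij})$. At each cost
$s \in \{0.10, 0.11, \dots, 0.22\}$ the top
$\operatorname{round}(s\cdot\binom{90}{2})$ connections by $|z|$ form an
undirected graph (binary, or weighted by $|z|$), on which the package
computes:

- clustering coefficient $C_p$, characteristic path length $L_p$;
- $\gamma = C_p/\langle C_p^{rand}\rangle$,
  $\lambda = L_p/\langle L_p^{rand}\rangle$, and the small-world index
  $\sigma = \gamma/\lambda$, with $\langle\cdot\rangle$ over
  degree-preserving Maslov–Sneppen rewired nulls;
- global efficiency $E_{glob}$, local efficiency $E_{loc}$, and the
  hierarchy exponent $b$ of $c_i \propto k_i^{-b}$;
- nodal degree centrality $k_i$ and nodal efficiency $E_i$.

Each metric's trapezoidal AUC over the cost grid is the unit of
between-condition comparison. Differences are tested with paired $t$
(Shapiro–Wilk permitting, otherwise Wilcoxon signed-rank), with
paired-design effect sizes $d_z = t/\sqrt{n}$ and $r = z/\sqrt{n}$,
Benjamini–Hochberg FDR across the 90 nodes per nodal metric and across the
89 targets of the parcel-level seed contrast, Spearman correlations for
brain–behavior associations, and OLS with variance inflation factors for
covariate adjustment.

## Worked example

```python
import netshift as ns

rec = ns.generate_paired_dataset(ns.GeneratorConfig(n_subjects=1, seed=3))[0]
cm = ns.connectivity_from_timeseries(
    ns.ROITimeSeries(rec.ts_A, ns.atlas.AAL90_LABELS, tr=2.0)
)
for sparsity in (0.10, 0.16, 0.22):
    net = ns.threshold_proportional(cm.z, sparsity, mode="binary")
    print(sparsity, net.n_edges, round(ns.clustering_coefficient(net)[0], 3),
          round(ns.global_efficiency(net), 3))
```

prints

```
0.1 400 0.333 0.459
0.16 641 0.33 0.552
0.22 881 0.347 0.605
```

— exactly 400 edges at 10% cost ($\operatorname{round}(0.10 \cdot 4005)$),
with global efficiency rising as the graph densifies while clustering
tracks the modular structure the generator implanted. The scripts in
`examples/` walk through each capability: dataset simulation,
connectivity and thresholding, the metric sweep with null normalization,
the statistical battery, and the full study replica (which, with the
default implanted effects, flags the clustering increase and ranks region
24 — the right superior medial frontal gyrus — first among all 90 nodes by
degree-centrality p-value).

## Command line

```bash
netshift simulate --config run.yaml --out data/ --seed 1
netshift fc --in data/ --out fc/
netshift metrics --in fc/ --out metrics.csv --grid 0.10:0.22:0.01 --mode binary
netshift seedfc --in fc/ --seed-region 24 --out seedfc.csv
netshift run-all --config run.yaml --out report/ --seed 1
netshift calibrate --replicates 200
```

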