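# persnet

Persistent homology of weighted complete networks through order statistics:
birth-death decomposition of graph filtrations, expected persistent barcodes
via order-statistic quantiles, per-rank confidence bands, and group-level
topological inference (expected topological loss, maximum-gap and
area-under-Betti-curve statistics with permutation / rank-sum tests).

A complete network on `p` nodes is a length `q = p(p-1)/2` edge-weight
vector. Thresholding at increasing filtration values deletes edges from the
lowest weight up; the `p - 1` maximum-spanning-tree weights are the birth
values of connected components and the remaining `(p-1)(p-2)/2` weights are
the death values of cycles — together they partition the weight vector. For
iid weights with cdf `F`, the expected value of the k-th smallest weight is
approximately `F⁻¹(k/(q+1))`, which turns observed barcodes into expected
barcodes, confidence bands and fast group-difference statistics.

## Library overview

| Module | Contents |
| --- | --- |
| `persnet.graphcore` | `WeightedNetwork`, `Barcode`, `BettiCurve`, `birth_death_decomposition`, `betti_curves`, `euler_check` |
| `persnet.orderstats` | distribution specs (uniform, beta, empirical + Gaussian KDE), `expected_order_stat`, `order_stat_variance`, `expected_barcode`, `estimate_group_distribution`, `confidence_bands` |
| `persnet.inference` | `wasserstein_0d/1d`, `etl`, `group_statistic`, `max_gap_statistic`, `auc_betti0`, `permutation_test`, `wilcoxon_auc_test` |
| `persnet.synthetic` | `generate_iid_network`, `generate_noisy_group`, `SimulationConfig`, `run_table_experiment` |
| `persnet.io` | adjacency CSV / edge-list TSV / time-series CSV readers, barcode JSON, `correlation_network` |

```python
import persnet as pn

net = pn.generate_iid_network(p=116, dist="beta(2,5)", seed=1)
bar = pn.birth_death_decomposition(net)        # 115 births, 6555 deaths
beta0, beta1 = pn.betti_curves(bar)

groups_a = [pn.generate_iid_network(10, "beta(1,1)", seed=s) for s in range(6)]
groups_b = [pn.generate_iid_network(10, "beta(5,2)", seed=s + 10) for s in range(6)]
result = pn.permutation_test(groups_a, groups_b, statistic="etl",
                             n_perm=10_000, seed=0)
print(result.statistic_observed, result.p_value)
```

## Command line

```sh
persnet decompose network.csv --out barcode.json
persnet betti network.csv --out curves.csv [--plot curves.png]
persnet bands --group subjects/ --alpha 95 --out bands.csv
persnet compare --group-a males/ --group-b females/ --stat etl \
        --n-perm 10000 --seed 1 --out report.json
persnet simulate --config experiment.yaml --out table.csv
```

Group directories contain one dense symmetric adjacency CSV per network
(diagonal ignored). `simulate` reads a YAML config with keys `p`, `pairs`
(list of distribution-name pairs such as `["beta(1,1)", "beta(5,2)"]`),
`group_sizes`, `stat` (`etl` | `maxgap` | `auc`), `n_perm`, `n_repeats`,
`seed`.

## Conventions

- Edge order is row-major over the strict upper triangle (`i < j`, 0-based),
  so weight vectors and barcodes are reproducible across readers.
- Betti curves are right-continuous; an edge with weight exactly equal to
  the threshold is absent (strict `w > eps`).
- Tied weights are resolved deterministically by canonical edge index and
  flagged with a `TieWarning`.
- Permutation p-values use the add-one estimator
  `(1 + #{null >= observed}) / (n_perm + 1)`; `p_value_plain` carries the
  plain proportion.
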