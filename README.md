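# traitnet

Analysis toolkit for plant functional-trait ecology along environmental
gradients, built around the workflow used to compare spring ephemeral and
non-ephemeral understory herbs: rank species by importance value from
quadrat surveys, compare 26 functional traits between plant types with a
normality-gated test choice, ordinate traits by PCA, model each trait on
plant type × elevation, quantify phylogenetic signal with Blomberg's *K*
and a tip-shuffle permutation null, and build thresholded Spearman
correlation networks over the traits ("plant trait networks", PTNs) with
degree, edge density, modularity, average path length and per-category
relative importance.

It is written for ecologists who have per-sample trait tables (CSV), an
optional quadrat survey, an optional per-site environment table, and a
rooted Newick phylogeny — and for methodologists who want to exercise the
whole pipeline on synthetic data with planted, recoverable ground truth.

## The statistics at the core

- **Importance value** per species from a quadrat survey:
  `IV = (relative frequency + relative density + relative coverage) / 3`,
  each component normalized over species so IVs sum to 1.
- **Normality-gated comparisons**: Shapiro–Wilk per group at α = 0.05;
  paired *t* (pairs = per-type means within each elevation × replicate
  cell) when both groups pass, two-sided Mann–Whitney otherwise.
- **Trait models**: OLS `trait ~ type + elevation + type:elevation`
  (elevation continuous, centered; sequential Type-I sums of squares in
  that order), with per-type simple regressions when the interaction is
  significant, and rank-inverse-normal-transformed regressions of each
  trait on each soil/climate variable.
- **Blomberg's K** with phylogenetic covariance `C` (shared root-to-tip
  path lengths) and GLS root estimate `â`:
  `K = [MSE0/MSE] / [(tr C − n/(1ᵀC⁻¹1)) / (n−1)]` where
  `MSE0 = (x−â)ᵀ(x−â)/(n−1)` and `MSE = (x−â)ᵀC⁻¹(x−â)/(n−1)`.
  `K = 1` under Brownian motion; significance from 999 tip shuffles with
  `p = (1 + #{K_null ≥ K_obs}) / 1000`.
- **Trait networks**: edge ⇔ `|ρ_Spearman| > 0.2` and `p < 0.05` (both
  strict); Newman modularity `Q = Σ_c [e_c/m − (d_c/2m)²]` of a
  deterministic community partition (exact enumeration for ≤ 8 nodes,
  greedy agglomeration + refinement beyond); relative importance of a
  trait category = its mean degree / summed degree of all traits.

## Worked example

```python
import traitnet as tn

# synthetic dataset: 8 species (4 ephemeral) x 3 elevation bands x 3
# replicates, 26 traits, with a planted ephemeral offset on leaf N and a
# correlated carbohydrate module
cfg = tn.SyntheticConfig(
    type_offsets={"LN": 2.0},
    module_spec={"carb": ["LSS", "LS", "LNSC", "RSS", "RS", "RNSC"]},
    module_loading=0.8,
    seed=42,
)
table, tree, env, truth = tn.generate_dataset(cfg)

res = tn.compare_trait("LN", table)
print(res.chosen_test, round(res.p_value, 6), res.direction)

net, metrics = tn.build_network(table)   # |rho| > 0.2, p < 0.05
print(metrics.n_edges, round(metrics.edge_density, 3),
      round(metrics.modularity, 3))

k = tn.permutation_test_k(tree, table.species_means()["LN"].to_dict(),
                          n_perm=999, seed=1)
print(round(k.K, 3), k.p_value)
```

prints

```
paired_t 0.0 ephemeral
83 0.255 0.311
0.905 0.076
```

meaning: the planted ephemeral enrichment of leaf nitrogen is detected
(both groups passed the Shapiro–Wilk gate, so a paired *t*-test was used;
p below print precision, ephemerals higher); the trait network has 83
edges (edge density 0.255) and a community partition with modularity
0.311, driven by the planted carbohydrate module; leaf-N species means
carry no significant phylogenetic signal (K = 0.905, permutation
p = 0.076), as expected since none was planted.

The same analyses are scriptable from a shell:

```sh
traitnet simulate --out data/ --seed 42
traitnet network --traits data/traits.csv --stratify type --out nets/
traitnet physig --traits data/traits.csv --tree data/tree.nwk \
    --perms 999 --seed 42 --out k.csv
traitnet pipeline --config cfg.yaml --out run1/
```

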