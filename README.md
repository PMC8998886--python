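# metabnet

Metabolite–transcript co-occurrence networks and transcriptome-based
prediction of metabolite abundance.

## The problem

Metabolite levels and gene expression are mutually coupled in living cells:
the abundance of an enzyme's mRNA constrains the abundance of its product,
transporters track their cargo, and broader cell states move both layers at
once. Metabolomics, however, remains far less standardized and far more
expensive than RNA-Seq. `metabnet` is for systems biologists who have (or can
borrow) one dataset in which metabolites and transcripts were measured in the
same samples, and who want to (1) map which transcripts co-vary directly with
which metabolites and (2) use that map to predict relative metabolite levels
in any other dataset for which only expression is available — sample by
sample, or as a differential contrast between two groups.

## The method

**Network inference.** Given a metabolite matrix and a transcript matrix over
shared samples, every metabolite–transcript pair (and, auxiliarily, every
metabolite–metabolite pair) is scored by Pearson correlation r with the exact
two-sided p-value from t = r·√((n−2)/(1−r²)) on n−2 df. Pairs with
p ≤ 0.001 become candidate edges. Indirect associations are then removed by
the data-processing inequality (DPI): in every triplet (m₁, m₂, t) whose
three correlations all passed the gate, the edge with strictly the lowest |r|
is discarded if it is a metabolite–transcript edge. Finally the samples are
bootstrapped B = 100 times; an edge is *supported* in a bootstrap if it
passes the gate and survives DPI recomputed within that resample. An edge
enters the final network if it survives the full-data DPI **or** is supported
by at least one bootstrap (re-admitting edges the full-data DPI removed), and
carries a likelihood ℓ = k/B, where k is its support count. The network is
strictly bipartite-hubbed: metabolites are the hubs ("centroids"), and
metabolite–metabolite correlations are used only transiently inside DPI.

**Prediction.** A network applied to new expression data scores each
metabolite m by a Normalized Enrichment Score. All G genes of a signature —
per-gene z-scores against the dataset mean (sample mode) or Welch
t-statistics between two groups (contrast mode) — are rank-transformed to
normal quantiles q_g = Φ⁻¹(rank_g/(G+1)), and with per-target weights
w_g = r_g·ℓ_g,

    NES(m) = Σ_{g ∈ targets(m)} w_g·q_g / √(Σ w_g²),

which is standard normal when the signature carries no information, so
two-sided p-values come straight from Φ. A metabolite is only scored when at
least `minsize = 10` of its network targets are measured in the new dataset.

**Validation harness.** Repeated 50/50 split-half validation within one
dataset, cross-dataset evaluation (per-metabolite Pearson r between predicted
NES and measured abundance, BH-FDR, one-tail Wilcoxon signed-rank summary),
and a degree-proportional shuffled-network null that preserves network shape
while destroying edge identity.

**Synthetic data.** A linear-Gaussian generator plants metabolite→transcript
modules with closed-form correlations ρ = s·β/√((1+σ_m²)(β²+1)) and optional
latent coupling between metabolites (which creates exactly the indirect edges
DPI exists to remove), so every stage is testable without external downloads.

## Worked example

```python
import metabnet as mn

# plant 10 metabolites with 15 transcript targets each, 200 background genes
gt = mn.build_ground_truth(n_metabolites=10, targets_per_metabolite=15,
                           beta_range=(1.0, 1.4), n_background=200, seed=11)
train = mn.simulate_dataset(gt, n_samples=300, seed=12)

combined = mn.combine_matrices(train.metabolites, train.transcripts)
cfg = mn.InferenceConfig(p_threshold=0.001, n_bootstraps=100, seed=13)
net = mn.infer_network(combined, cfg)
precision, recall = mn.edge_recovery(net, gt)
print(f"network: {net.n_edges} edges, precision {precision:.3f}, recall {recall:.3f}")

# held-out dataset: predict metabolites from transcripts alone
test = mn.simulate_dataset(gt, n_samples=57, seed=14)
pred = mn.predict(net, test.transcripts, mode="sample", minsize=10)
report = mn.per_metabolite_correlation(pred, test.metabolites)
print(report.table[["r", "p", "fdr", "class_adj"]].head(3))
print(f"mean r = {report.summary['mean_r']:.3f}, "
      f"one-tail Wilcoxon p = {report.summary['wilcoxon_p']:.2g}")
```

Output:

```
network: 152 edges, precision 0.987, recall 1.000
                   r             p           fdr             class_adj
metabolite
M001        0.859293  1.198706e-17  1.712438e-17  positive-significant
M002        0.851115  5.066982e-17  6.333728e-17  positive-significant
M003        0.879951  2.016143e-19  5.040358e-19  positive-significant
mean r = 0.872, one-tail Wilcoxon p = 0.00098
```

The network recovered every planted edge (recall 1.0) with two spurious ones
(precision 0.987). On the 57-sample held-out dataset, predicted NES tracks
the measured abundance of each planted metabolite at r ≈ 0.86–0.88, and the
one-tail Wilcoxon p says the per-metabolite correlations sit significantly
above zero as a family.

The same pipeline is available from the shell:

```sh
metabnet simulate --n-samples 300 --seed 11 --out-prefix sim/
metabnet infer-network --metabolites sim/metabolites.tsv \
    --expression sim/expression.tsv --seed 13 --out net.tsv
metabnet predict --network net.tsv --expression other_expression.tsv \
    --mode sample --out nes.tsv
metabnet evaluate-split --metabolites sim/metabolites.tsv \
    --expression sim/expression.tsv --splits 50 --seed 2 --out split.tsv
metabnet shuffle-null --network net.tsv --seed 3 --out null.tsv
```

Matrices are TSV (features × samples, first column = feature id, `NA` for
missing); networks are 6-column TSV edge tables with a JSON metadata sidecar.

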