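# srbmrank

Energy-based prioritization of disease-progression genes from two-period
gene expression data, using stacked restricted Boltzmann machines (SRBM).

## The problem

In slowly progressing diseases (the motivating case is striatal gene
expression in a Huntington's-disease mouse model, sampled at two ages with
~8 animals per age), the genes most affected by progression are not simply
the most differentially expressed ones: expression is driven by latent
regulatory factors, several of which drift as disease advances. `srbmrank`
models each expression profile with an energy-based network, identifies
hidden units whose activity pattern shifts between the two time periods,
and ranks genes by how much the energy of their circuit through those units
changes.

## The model

A Gaussian-Bernoulli RBM sits on the standardized expression profile
$V \in \mathbb{R}^{n_V}$ (one visible unit per gene, per-gene mean 0,
variance 1) with binary hidden units $H \in \{0,1\}^{n_H}$ and energy

$$E(V,H) = \sum_i \tfrac{(v_i-b_i)^2}{2} - \sum_j c_j h_j
          - \sum_{ij} v_i h_j w_{ji},$$

giving the conditionals $P(h_j{=}1\mid V) = \sigma(c_j + \sum_i w_{ji}v_i)$
and, for binary-visible Gibbs reconstructions,
$P(v_i{=}1\mid H) = \sigma(-\tfrac12 + b_i + \sum_j h_j w_{ji})$. A second,
fully Bernoulli RBM is stacked on the first hidden layer
($-\sum b_i v_i - \sum c_j h_j - \sum h_j w_{ji} v_i$); both layers train
greedily with mini-batch contrastive divergence (CD-k),
$\theta \leftarrow \theta + \eta\,\partial\log p(V)/\partial\theta$.

Ranking then proceeds in two steps. A hidden unit's *activation frequency*
over a sample set is the number of samples with thresholded conditional
probability $\ge 0.5$; units whose frequency difference between the periods
exceeds a threshold (defaults: $>1$ in layer 1, $>5$ in layer 2) are the
*differentially activated* units, and all others are clamped to 0. Each
gene's energy

$$E_g = \tfrac{(v_g-b_{1,g})^2}{2} - \sum_j h_{1,j} w_{1,jg} v_g
        - \sum_i b_{2,i} v_{2,i} - \sum_{ij} h_{2,j} w_{2,ji} v_{2,i}$$

is evaluated per sample through the selected circuit, and genes are ranked
by the absolute change of their mean energy between periods,
$C_g = \lvert \overline{E_g^{s_1}} - \overline{E_g^{s_2}} \rvert$
(by default after centering energies across genes within each sample, so
that contributions shared by all genes cancel; see `docs/methods.md`).
Four variants are provided — SRBM-I/II and the single-layer RBM-I/II,
where the I-variants skip unit selection and instead prune the weakest
third of every unit's outgoing connections — alongside Welch t-test and
fold-change rank-product (FC-RP) baselines and a ROC/PR evaluation suite.

## Worked example

```python
import srbmrank as sr
from srbmrank.synthetic_data import SyntheticSpec, benchmark_protocol

spec = SyntheticSpec(seed=7)              # 500 genes, 8+8 samples,
ds = sr.generate(spec)                    # 3 of 20 latent factors shifted
proto = benchmark_protocol(spec, seed=7)
model = sr.SRBMGeneRanker(
    ds.period1, ds.period2, variant="SRBM-II",
    n_hidden1=proto["n_hidden1"], n_hidden2=proto["n_hidden2"],
    config1=proto["cfg1"], config2=proto["cfg2"], seed=7)
res = model.fit()
print(res.summary(top=5))
ev = res.evaluate(ds.labels)
print(f"label AUC: {ev.auc:.3f}   AUPR: {ev.aupr:.3f}")
```

```
                   Energy-change gene ranking
================================================================
Variant:                SRBM-II
Regime:                 pooled
Genes:                  500
Samples:                8 + 8
Architecture:           500 -> 50 -> 10
Layer trace 1:          energy 237.979 -> -1024.059 over 50 epochs
Layer trace 2:          energy -0.492 -> -78.876 over 400 epochs
Selected units:         25 (layer 1, |dfreq| > 1), 0 (layer 2, |dfreq| > 5)
----------------------------------------------------------------
rank  gene             energy change
   1  g00179                 14.3495
   2  g00240                 14.2499
   3  g00250                 12.1864
   4  g00054                 12.1408
   5  g00238                 11.9357
================================================================
label AUC: 0.769   AUPR: 0.230
```

The trace lines show the mean data energy of each layer falling over
training; 25 first-layer units changed activation frequency by more than 1
between the periods and form the circuit used for scoring. On this seeded
dataset the planted genes (those loaded on a shifted factor, 34 of 500)
are ranked with AUC 0.77 — far above the 0.5 of a label-free ranking —
from only eight samples per period.

The same pipeline is available from the shell:

```bash
srbmrank simulate --n-genes 500 --seed 7 --outdir data/
srbmrank rank --period1 data/period1.tsv --period2 data/period2.tsv \
              --variant SRBM-II --outdir run/
srbmrank evaluate --ranking run/ranking.tsv --labels data/labels.tsv \
              --outdir eval/
srbmrank compare --period1 data/period1.tsv --period2 data/period2.tsv \
              --labels data/labels.tsv --outdir cmp/
```

Expression matrices are genes-by-samples TSV files (gene IDs in the first
column, sample IDs in the header); every command writes a JSON manifest
sufficient to re-run it bit-identically.

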