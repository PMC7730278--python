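# invresist

Analysis pipeline for *inverse resistance* evolution in isogenic cancer
cell-line series: rising resistance to a selecting drug accompanied by
collateral sensitisation to a bystander drug, followed simultaneously in
cytotoxicity assays and in the bulk transcriptome of the ordered series.

The motivating system is the A2780 ovarian-carcinoma line and six sublines
selected by stepwise paclitaxel (PTX) escalation (4 → 128 nM), which
gradually gain PTX resistance while becoming collaterally sensitive to
cisplatin (CDDP). The package is written for researchers who run this kind
of study: it turns raw 96-well plate absorbances into resistance tables,
tests dose-response differences, and mines the ordered-series transcriptome
for the genes that change consistently at every stage — the "scaffold" of
the resistance process.

## What it computes

**Cytotoxicity** (`invresist.cytotox`)

- % viability from paired 570/600 nm absorbances via the two-wavelength
  redox-indicator reduction formula; drug-free controls define 100%.
- The concentration grid at viability levels 90…20% by linear
  interpolation between bracketing points,
  `x = x1 + (x2 − x1)(y − y1)/(y2 − y1)`; IC50 is the 50% entry.
- pIC50 = −log10(IC50 in molar); resistance index RI = IC50_subline /
  IC50_parent (selecting drug); sensitivity index SI = IC50_parent /
  IC50_subline (bystander drug); consecutive fold changes whose unrounded
  product equals the end-to-end index.
- Two dose-response comparisons per line pair: a random-slope model of
  well-level viability (slope varies by plate; exact two-stage t on
  per-plate slopes) and a pooled-variance Student t on replicate pIC50s.

**Differential expression** (`invresist.de`)

- CPM > 5 in ≥ 2 samples filter; log2-CPM transform with optional
  median-of-ratios effective library sizes.
- Moderated t per subline-vs-parent contrast: gene variances shrunk toward
  an empirical-Bayes prior fitted by moment-matching the log-variances;
  Benjamini–Hochberg q-values; DEG sets split by fold-change direction;
  Spearman correlation of DEG counts with resistance-index differences.

**Trend analysis** (`invresist.trend`)

- Five kinetic classes from the sign trajectory of log2FC over the ordered
  contrasts: consistently up, consistently down, rising (one − → +
  reversal), descending (one + → − reversal), variable (≥ 2 reversals);
  |log2FC| < 0.1 counts as sign 0 and inherits its neighbour's sign.
- Scaffold selection: genes with q < 0.001 and |log2FC| > 2 in **every**
  contrast; shared-DEG matrices with an early/late subline partition; PCA
  (centred SVD) and average-linkage hierarchical clustering of samples.

**Network** (`invresist.network`)

- Direction-annotated interaction network induced by the scaffold on a
  scored edge list; hubs = nodes with ≥ 7 interactions; gene-set
  over-representation by the hypergeometric upper tail with BH control.

**Synthetic data** (`invresist.simulate`)

Every stage has a generator with planted ground truth: 96-well plates with
four-parameter-logistic true curves at the series' reported IC50s,
negative-binomial count matrices with planted five-class trend structure,
and edge lists with planted hubs — so the whole pipeline is testable
end-to-end without any external download.

## Worked example

```python
import invresist as ir
from invresist.de import effective_library_sizes

# resistance indices from the series' IC50 values
ptx = {k[0]: v for k, v in ir.DEFAULT_TRUE_IC50.items() if k[1] == "PTX"}
profiles = ir.resistance_profiles(ptx, "PTX", "nM", "A2780", "RI")
for p in profiles:
    print(f"{p.cell_line:>8s}  IC50 {p.ic50:7.2f} nM  pIC50 {p.pic50:5.2f}"
          f"  RI {p.index_rounded:6.2f}")

# synthetic ordered-series transcriptome, analysed end to end
cfg = ir.SimConfig(seed=1, n_genes=2000)
counts, samples, truth = ir.simulate_counts(cfg)
data = ir.filter_low_expression(ir.CountData(counts, samples))
logmat, _ = ir.normalize_log(data, effective_library_sizes(data))
de_list = [ir.fit_de(logmat, samples, c) for c in ir.series_contrasts(data)]
print(de_list[3].summary())
scaffold = ir.select_scaffold(de_list, q_threshold=0.001, fc_threshold=2.0)
print(f"scaffold: {len(scaffold)} genes")
```

prints

```
   A2780  IC50    4.62 nM  pIC50  8.34  RI   1.00
   A4PTX  IC50   11.47 nM  pIC50  7.94  RI   2.48
   A8PTX  IC50   18.71 nM  pIC50  7.73  RI   4.05
  A16PTX  IC50   77.54 nM  pIC50  7.11  RI  16.78
  A32PTX  IC50  148.47 nM  pIC50  6.83  RI  32.14
  A64PTX  IC50  173.86 nM  pIC50  6.76  RI  37.63
 A128PTX  IC50  272.47 nM  pIC50  6.56  RI  58.98
Contrast A32PTX vs A2780: 2000 genes tested; 170 DEGs at q<0.05, 158 at q<0.01; prior df 20.6, prior var 0.0973
scaffold: 155 genes
```

The RI column is each subline's IC50 divided by the parental 4.62 nM —
A/16PTX is 16.78-fold PTX-resistant — and the scaffold is the set of genes
significantly and strongly changed in all six subline-vs-parent contrasts.

A command-line interface mirrors the stages:

```sh
invresist simulate --config cfg.yaml --out run/
invresist cytotox  --plates run/plates --reference A2780 --out run/cyto
invresist de       --counts run/counts.tsv --samples run/samples.tsv --out run/de
invresist trend    --de-dir run/de --order A2780,A4PTX,A8PTX,A16PTX,A32PTX,A64PTX,A128PTX \
                   --early A4PTX,A8PTX --late A16PTX,A32PTX,A64PTX,A128PTX --out run/trend
invresist network  --scaffold run/trend/scaffold.tsv --edges edges.tsv --out run/net
```

## Documentation

`docs/methods.md` describes the statistical model of every stage, the
defaults and why they were chosen, what the synthetic data does and does
not emulate, and known limitations.
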