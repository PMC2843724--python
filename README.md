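# whorlstat

Contrast-based differential expression for floral-whorl microarray
experiments, with parametric gene-set enrichment and cross-species
comparison of expression statistics.

## The problem

Flowers are built from concentric whorls of organs — sepals, petals,
stamens, (in *Aquilegia*, a fifth whorl of staminodia) and carpels. A
single-channel oligonucleotide array hybridized to dissected whorls from
replicate populations asks: which genes are expressed specifically in one
whorl, and which are co-expressed across the whorl groupings predicted by
the ABC model of organ identity (A = SEP+PET, B = PET+STA, C = STA+CAR)?
`whorlstat` implements the full analysis chain for such tissue × block
designs and a synthetic-data generator with planted ground truth so every
stage can be validated end to end.

## The method

**Preprocessing.** Probe-level intensities are log2-transformed, spatially
corrected per array (a window×window two-dimensional moving median of the
residuals from the array median is subtracted), quantile-normalized
(Bolstad), probe-centered (per-probe means subtracted), and averaged into
gene values; genes represented by fewer than 4 probes are dropped.

**Differential expression.** For each gene g and whorl-group contrast c
(a group of whorls against the rest), the coefficient is the mean over
population blocks p of the within-block group difference
d_p = mean(group) − mean(complement), with se = sd(d_p)/√P. The
standardized statistic is

    D = coefficient / (se + s0),    s0 = median se over genes,

a SAM-style moderated effect. Tissue labels are permuted (99 draws by
default), ranked permuted D values are averaged rank-wise, and a gene is
called when its observed ranked D departs from that expectation by more
than a delta threshold (default 4). The FDR estimate is the median
permuted count of D values beyond the call cutoffs divided by the number
of calls. Each gene is assigned a *specific* contrast: the one with the
maximal |D| across all 12 (five-whorl) or 7 (four-whorl) contrasts.

**Enrichment.** GO biological-process categories with ≥ 10 genes on the
array are tested per contrast with the PAGE z statistic
z = (S_m − μ)·√m/σ against the universe of annotated genes, with
Benjamini–Hochberg adjustment within each contrast (significant at
adjusted p < 0.01).

**Cross-species comparison.** Putative homologs between two species are
reciprocal best hits of two directional BLAST-tabular searches (inclusive
E-value thresholds, defaults 5e-6 and 7e-6), and the D statistics of the
paired genes are compared with Spearman rank correlations, per contrast
pair and per whorl pair.

## Worked example

```python
import whorlstat as ws

params = ws.SimulationParams(
    n_genes=2000, probes_per_gene=(4, 8), noise_sd=0.25,
    effect_table={2: (50, 2.0)},   # 50 genes up 2.0 log2 units in petals
    seed=5,
)
tables, design, truth = ws.generate_study(params)
expr = ws.preprocess_study(tables, design, window=9)

an = ws.SAMContrastAnalyzer(delta=4.0, n_perm=99, seed=5).fit(expr)
summary = an.summary()
print(summary[summary["contrast"] == 2])

spec = an.specific_.loc[truth.planted_genes(2)]
print("planted genes assigned petal-specific:",
      (spec["specific_contrast"] == 2).sum(), "of", len(spec))
```

prints

```
   contrast name  n_down  n_up  fdr  n_specific_down  n_specific_up
1         2  PET       0    50  0.0              315             91
planted genes assigned petal-specific: 46 of 50
```

— exactly the 50 planted petal genes are up-called on contrast 2 (PET vs
the rest) at an estimated FDR of 0, and 46 of them also have their
maximal |D| under that contrast (the specificity assignment classifies
*every* gene, called or not, so the n_specific columns count the whole
array's argmax distribution; four planted genes peak at an overlapping
contrast instead). `an.d_` holds the genes × contrasts D table used by
`ws.enrich` and `ws.correlate_d` downstream.

The same pipeline is exposed as a CLI:

```
whorlstat simulate --out-dir sim --n-genes 2000 --effect 2:50:2.0 --seed 5
whorlstat preprocess --pairs-dir sim --design sim/design.tsv --out expr.tsv
whorlstat diffexp --matrix expr.tsv --design sim/design.tsv --out-dir de
whorlstat enrich --dstats de/dstats.tsv --go sim/go_annotations.tsv --out enrich.tsv
whorlstat all --config config.yaml     # orchestrated, with a hashed MANIFEST
```

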