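# clonal-surveil

Single-cell plasma-cell malignancy scoring and B-cell receptor repertoire
surveillance, with the exact small-sample statistics used to compare treated
and untreated animal cohorts.

Immunotherapies for plasma-cell malignancies are judged by whether they
clear the malignant clones while sparing normal plasma cells and ongoing
B-cell development.  Reading that selectivity out of single-cell data takes
two coupled analyses, which this package implements as a tested, reusable
pipeline for anyone analyzing 10x-style expression matrices plus AIRR
heavy-chain rearrangements from such studies:

1. **Malignancy classification.**  Plasma cells are gated by marker
   expression (any of *Sdc1*/*Xbp1*/*Prdm1*, not *Cd19*), scored for a
   malignancy and a nonmalignancy gene signature with expression-binned
   control genes (score = set mean − matched-control mean), and classified
   by a dual-percentile rule: malignant iff the malignant score is in the
   top 20% **and** the nonmalignant score in the bottom 20% (mirror
   condition for nonmalignant).  The compound score M − N puts every cell
   on one axis; its treated-vs-untreated shift (two-tailed Mann–Whitney) is
   the treatment readout.
2. **Repertoire surveillance.**  Clonotypes are sequences sharing V gene,
   J gene and ≥80% CDR3 amino-acid identity (single-linkage); on top of the
   partition the package quantifies somatic hypermutation (% divergence
   from germline), the frequency of highly mutated expanded clonotypes
   (>2% mutation, >10 cells), isotype and V-family spectra, CDR3 length
   distributions with AUC, V–J pairing matrices, canonical-clone tracking
   (VH1-72 usage and the W33L CDR1 mutation at window position 8), clone
   sizes (log10), and signed Kullback–Leibler sequence logos in which
   depleted residues plot below the axis.

Group comparisons use exact tests where the sample sizes permit full
enumeration — Mann–Whitney over all rank assignments (n+m ≤ 12), Wilcoxon
signed rank over all 2^n sign patterns, Fisher's exact by hypergeometric
enumeration — plus Kruskal–Wallis with Dunn follow-up, paired and
ratio-paired t tests, and Benjamini–Hochberg FDR correction.

A synthetic-data generator (`clonal_surveil.synthetic_data`) produces
bone-marrow cohorts with planted ground truth — malignant plasma-cell
subpopulations, expanded class-switched mutated clones, a canonical
VH1-72/W33L clone, and a treatment effect that depletes them by a
configurable factor — so every downstream stage is validated by recovering
what was planted.  See `docs/methods.md` for the model and its limits.

## Worked example

```bash
clonal-surveil run --seed 1 --out results/run1
```

simulates the default cohort (5 untreated / 6 treated samples, 800 cells
and 9,000 heavy chains each), runs every stage, writes all result tables
under `results/run1/` and prints the run summary.  Key lines from seed 1:

```
"n_gated": 1320,
"compound_score_mann_whitney": { "p_value": 1.64e-40, "method": "normal_approx" },
"de_counts": { "0.001": 80, "0.05": 100 },
"vh1_72_usage": { "U1": 0.0222, ..., "T1": 0.00242, ... },
"w33l_fisher": { "p_value": 1.60e-23 },
"clone_size_mann_whitney": { "p_value": 2.27e-10 }
```

Reading: 1,320 plasma cells pass the gate; the treated compound-score
distribution is shifted toward less-malignant values (Mann–Whitney
p ≈ 1.6e-40); 80 genes change between arms at adjusted p < 0.001; VH1-72
usage drops roughly ninefold in treated samples (0.0222 → 0.0024); the
W33L fraction among canonical-clone sequences falls from 56% to 10%
(Fisher p ≈ 1.6e-23); and treated clones are significantly smaller.  All of
these recover the effects the generator planted.

The same stages run separately on files
(`simulate | score | classify | repertoire | stats | report`), e.g.

```bash
clonal-surveil simulate --seed 1 --out sim/
clonal-surveil score --mtx-dir sim/mtx \
    --malignant-genes sim/malignant_genes.txt \
    --nonmalignant-genes sim/nonmalignant_genes.txt --out scores.csv
clonal-surveil repertoire --airr sim/rearrangements.tsv --out clones.csv
```

and everything is available as a library (`clonal_surveil.module_scoring`,
`.malignancy`, `.repertoire`, `.stats_core`, `.synthetic_data`,
`.io_formats`).

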