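# cislink

Cis-regulatory lncRNA–mRNA target screening for two-condition RNA-seq
experiments, with a planted-truth synthetic benchmark.

Long non-coding RNAs often regulate genes near their own locus. A common
screen for such cis action in a case/control transcriptome (for example,
exosomes from UV-photoaged versus control skin) proceeds in four steps:

1. **lncRNA candidates** — transcripts longer than 200 nt that at least 3
   of the 4 coding-potential predictors (CPC2, CNCI, Pfam, FEElnc) call
   non-coding;
2. **differential expression** — features with FDR < 0.05 and
   |log2FC| ≥ 1 between conditions (from DESeq2 or any external table;
   a simple built-in Welch-t/BH test covers synthetic runs);
3. **window pairing** — every (lncRNA, mRNA) pair on the same chromosome
   whose gene bodies lie within 100 kb of each other (closest-edge
   distance, upstream or downstream alike);
4. **correlation screen** — a pair is a significant cis candidate when
   the Pearson correlation *r* of the two TPM profiles across all samples
   satisfies |*r*| ≥ 0.80 with two-sided *p* < 0.05 from
   *t* = *r*·√(n−2)/√(1−*r*²) on n−2 degrees of freedom.

Significant pairs are then split by correlation sign and by DE direction
concordance (both up / both down / discordant), with a unique-gene rollup
of the concordantly upregulated subset.

Because such studies rarely release raw data, `cislink` ships a
generator that plants known structure — negative-binomial counts, a
Gaussian copula coupling each planted pair at latent correlation ρ,
planted log2 fold changes, and a genome layout in which only designated
pairs fall inside the window — so sensitivity and false discovery rate of
the whole screen are measurable against ground truth.

## Worked example

```python
from cislink import SimConfig, run_benchmark

bench = run_benchmark(SimConfig(seed=17))
print(bench.result.summary.to_text())
print(bench.recovery.to_dict())
```

prints

```
window pairs:              200
pairs with both members DE: 61
significant pairs:         106
  positively correlated:   106 (1.000 = 100%)
  negatively correlated:   0
  both up:                 44
  both down:               9
  discordant:              0
unique genes in both-up set: 88

{'sensitivity': 1.0, 'false_discovery_rate': 0.0566..., 'n_planted': 100,
 'n_recovered': 100, 'n_significant': 106}
```

The 200 window pairs are the 100 planted cis couplings plus 100 in-window
decoys; the screen recovers all 100 planted pairs (sensitivity 1.0) and
lets 6 decoys through (FDR ≈ 0.057). All significant pairs correlate
positively — planted couplings share both the latent factor and the DE
shift, which is also why real studies of this design report
overwhelmingly positive cis correlations.

The same analysis runs from files:

```bash
cislink simulate --seed 17 --out data/
cislink run --annotation data/annotation.gtf --expression data/counts.tsv \
            --conditions data/conditions.yaml --coding-calls data/coding_calls.tsv \
            --out results/
cislink benchmark --seed 17 --out bench/
```

`cislink run` accepts any GTF/BED annotation, expression table and
(optionally) an external DE statistics table, so it applies unchanged to
real datasets.

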