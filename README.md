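# strandmeth

Infer genome-wide **absolute DNA methylation levels** (0–1) from MeDIP-seq
enrichment data, with strand-specific processing and a sigmoid model of the
CpG-density bias.

MeDIP-seq immunoprecipitates methylated single-stranded DNA fragments with
an anti-methylcytosine antibody; the read count over a genomic bin measures
*enrichment*, not methylation. Enrichment is confounded by the bin's CpG
density: at fixed methylation, more CpGs mean more antibody binding — up to
a saturation point. `strandmeth` estimates this density effect from the
data itself, corrects for it, and reports per-bin methylation on the same
0–1 scale as bisulfite sequencing, at bin sizes of 25–100 bp.

## Model

Bin reads on one strand are modelled as the methylation signal times a
CpG-density effect:

```
y = M · f(n_CpG),      f(n) = exp(β₀ + β₁·n) / (1 + exp(β₀ + β₁·n))
```

Because sparse-CpG regions of mammalian genomes are almost fully
methylated, the mean bin reads ȳ(n) of bins with exactly *n* CpGs trace
`f` at low *n*. Taking the maximum group mean `y_max` as the empirical
upper asymptote, the parameters come from ordinary least squares on the
logit-transformed group means,

```
log( (ȳ/y_max) / (1 − ȳ/y_max) ) = β₀ + β₁·n_CpG ,
```

fitted over the rising, fully-methylated regime only (groups at and beyond
the argmax of ȳ, and groups too close to the asymptote, are excluded).
Correction then divides each bin's reads by `f(n_CpG)`, log-transforms,
and min–max scales to [0, 1]. The whole procedure runs **separately on the
reads of the plus and the minus strand** — CpG methylation is asymmetric
between strands, and the antibody pulls down single strands — and the two
per-strand tracks are averaged.

A classical linear baseline (straight line through the low-density group
means, extrapolated to all densities) is included for comparison; it lacks
an asymptote and over-corrects dense, saturated bins.

## Worked example

Everything below runs on synthetic data generated by the built-in
simulator (no downloads). Simulate a 200 kb genome (2000 bins of 100 bp)
with known per-CpG, per-strand methylation truth, infer, and evaluate:

```bash
strandmeth simulate --n-bins 2000 --seed 4 --out-dir sim
strandmeth infer --bam sim/reads.sam --fasta sim/reference.fa \
    --bin-size 100 --fragment-extension 50 --out-prefix run
strandmeth evaluate --inferred run.merged.bedGraph \
    --truth sim/cpg_calls.bedgraph.tsv --fasta sim/reference.fa \
    --by-quartile --out-prefix eval
```

which prints

```
     category      pcc      scc  n_bins
          all 0.934328 0.796956    1892
          low 0.703204 0.513128     487
 lower-medium 0.782443 0.604620     497
higher-medium 0.851105 0.723055     491
         high 0.957478 0.922588     417
```

`pcc`/`scc` are Pearson and Spearman correlations between the inferred
track and the binned bisulfite-style truth (bins with ≥ 4 covered CpGs,
each CpG covered by ≥ 10 reads); the four categories stratify bins by
CpG-count quartile from sparse ("low") to dense ("high"). The inferred
tracks are bedGraphs of per-bin values in [0, 1]:

```
track type=bedGraph name="methylation_merged" description="config:9038b489c110"
chrSim	0	100	0.7561
chrSim	100	200	0.0000
```

Strand asymmetry of the (synthetic) bisulfite calls themselves:

```bash
strandmeth strand-concordance --truth sim/cpg_calls.bedgraph.tsv \
    --fasta sim/reference.fa --bin-sizes 25,50,100,200 --out-prefix sc
```

reports the per-chromosome Pearson correlation between plus-only and
minus-only bin methylation at each bin size (0.987 at 25 bp up to 0.997 at
200 bp for the default strand correlation of 0.9).

The same pipeline runs on real data: `--bam` accepts SAM/BAM or BED6
alignments, `--truth` accepts Bismark coverage files (`.cov`) or per-CpG
bedGraphs, and `--chromosomes` defaults to everything except X and Y.

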