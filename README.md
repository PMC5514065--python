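# exomode

Resampled, mode-based calling of **differential exon usage (DEU)** from
exon-level RNA-seq expression matrices — alternative splicing and
alternative transcription detection without transcript assembly.

## The problem

Bulk RNA-seq of tumor cohorts (e.g. ER+HER2−, ER−HER2−, and HER2+ breast
carcinomas against normal breast samples) is usually summarized as an
exons × samples matrix of RPKM-like values. A gene that is merely up- or
down-regulated shifts *all* of its exons by roughly the same log2 fold
change; a gene that is differentially *spliced or transcribed* instead
shows a minority of exons — a skipped exon, an alternative first or last
exon, a transcript with an intronic start — whose fold change departs from
the rest of the gene. `exomode` finds those exons.

## The method

For an ordered comparison of classes A and B:

1. **Normalize**: divide each sample by its median exon value, then map
   `x ↦ log2(1 + c·x)` (scale constant `c` = 1023 for deep cohorts, 127
   for shallow ones), so that the sample median lands exactly at
   `log2(1 + c)`.
2. **Subsample**: draw 100 random 60% subsamples per class.
3. **Mode expression**: in each subsample, estimate each exon's mode as
   the tallest peak of a Gaussian kernel density (R-style `bw.nrd0`
   bandwidth). A mode is valid only if the density is unimodal or the
   tallest peak is ≥ 2× the second tallest (dominance ratio; 1.8 for
   shallow cohorts) — otherwise the exon is ambiguous in that subsample.
4. **Trials**: every A-subsample × B-subsample pair is a trial (10,000
   in the full design). Per exon, log2FC = mode_A − mode_B; exons with
   an invalid mode on either side, or modes near zero on both sides,
   sit the trial out. A gene needs ≥ 5 usable exons per trial.
5. **Label**: within each gene and trial, the KDE of the exon fold
   changes has a tallest peak — the gene-level scaling. Exons in its
   basin are labeled 0; exons in peaks to the right are +1 (relatively
   up-used), to the left −1.
6. **Score and call**: score = (#trials +1) − (#trials −1) per exon.
   Exons whose score lies beyond 3 standard deviations of the mean score
   of all analyzable exons are the final ±1 calls. Per trial the
   location of the gene density's global maximum also records whether
   the gene as a whole is up (>1), down (<−1), or similar, with a
   majority vote over trials.

The consensus over thousands of overlapping subsample pairs is the
method's protection against intra-class heterogeneity; no parametric
test is involved.

## Worked example

```sh
# a synthetic two-class cohort (40 + 40 samples, 100 genes x 12 exons)
# with 20 planted minority-exon events of |delta log2FC| = 3
exomode simulate --events 20 --delta-fc 3.0 --seed 11 --out demo

# call DEU for ER-HER2- vs ER+HER2- with a 10x10 trial design
exomode call --matrix demo.matrix.tsv --classes demo.classes.tsv \
    --annotation demo.annotation.bed --compare "ER-HER2-:ER+HER2-" \
    --n-sub 10 --seed 5 --out demo_run
```

`demo_run.calls.tsv` contains one row per exon:

```
exon_id	gene_id	n_plus	n_minus	n_zero	n_excluded	score	final_call
chrS:1001-1150	G0000	17	5	38	40	12	0
...
chrS:81001-81150	G0007	100	0	0	0	100	1
```

The exon `chrS:81001-81150` was labeled +1 in all 100 trials (score 100,
far beyond the 3-SD line of the score distribution) — a planted
exon-inclusion event recovered as a final `+1` call. On this dataset the
caller recovers the planted events with sensitivity 0.93 and precision
0.97 against the generator's truth table (compare
`evaluate_calls(callset, dataset.truth_labels(...))`). The companion
`demo_run.genes.tsv` holds the per-gene up/down/similar direction with
its trial consistency, and `demo_run.called.bed` the called exons as a
BED track.

`exomode classify` splits tumors into ER/HER2 classes by locating the
two dominant modes of ESR1-like expression and ERBB2-like focal copy
number and cutting at the density minimum between them; `exomode report`
computes overlap summaries, DEU × differential-expression cross-tabs
with chi-square tests, and hypergeometric overlap statistics across
finished call sets.

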