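# Methods

## The model

The package treats each input study as a normalized log2 probe-by-sample
matrix with exactly two phenotype groups (the reference comparison is
malignant MPNST vs. benign NF tissue). Expression values are assumed
approximately Gaussian on the log2 scale within each group; studies are
assumed unpaired, so all cross-group sample pairs are exchangeable. No
attempt is made to model raw-array normalization (RMA/quantile), dye swaps,
batch effects, or multi-factor designs — inputs are expected already
normalized per study.

### Per-study statistics

* **logFC** — difference of group means; its sign defines "direction"
  throughout.
* **logFC_m** — log2 of the median of all |A|×|B| cross-group linear ratios
  2^(a−b). The median of an even pair count is the midpoint on the *linear*
  scale. A consequence worth knowing: the linear midpoint is not exactly
  antisymmetric under swapping the groups (the median of reciprocals is not
  the reciprocal of the midpoint), so exact score antisymmetry holds only
  for odd pair counts; for even counts the discrepancy is bounded by the
  gap between the two central ratios and is negligible in practice.
* **MAD** — unscaled median absolute deviation of the cross-pair log2
  ratios (no 1.4826 consistency constant: the raw MAD is the smaller,
  more conservative penalty).
* **Moderated t and B** — standard empirical-Bayes linear-model
  moderation (Smyth 2004): pooled two-group variances s² with d = n−2 df
  are shrunk toward a prior s0² with d0 df fitted by the method of moments
  on log s² (digamma/trigamma matching); t uses the posterior variance and
  d0+d df; B is the log posterior odds of differential expression with
  prior proportion 0.01 and a coefficient-variance prior moment-matched on
  the top |t| order statistics. The implementation reproduces limma's
  `lmFit`+`eBayes` to ~1e-14 on shared fixtures (one test runs limma via
  Rscript as an independent oracle). When the moments fit has non-positive
  curvature (tiny fixtures), the fallback is d0 = 4 and s0² = median(s²).
* **ANOVA prefilter** — two-group one-way ANOVA (F = t² identity holds) at
  BH-FDR ≤ 0.05, applied per comparison before scoring. A group with a
  single sample makes the equal-variance F undefined; the pipeline then
  demands `skip_prefilter`.

### Scoring

Scores are computed at probe level, where the effect-size normalization
(positives by the study's max positive, negatives by |min negative|) runs
over all probes with non-null effect **before** gating; probes are then
collapsed to genes by the maximum variance across all samples of both
phenotypes (ties broken by lexicographically smallest probe ID), and the
collapsed raw scores are range-standardized by the study's maximum absolute
score. Range standardization (not z-scoring) was chosen because it keeps
null scores at zero, bounds s_ij in [−1,1], and makes final scores
interpretable as "number of fully supporting studies".

The score formula s = n · |logFC_m|/(|logFC_m| + c·MAD) · gate is this
package's own construction of a signal/(signal+noise)-weighted normalized
effect with significance gating; it satisfies, by design: up/down symmetry
through the sign, a median-based effect size, per-study [−1,1]
normalization, a multiplicative MAD penalty ≤ 1 (more dispersion, smaller
score), and the hard B > 0 and adjusted-p gates. It is isolated behind
`scoring.probe_score` so an alternative weighting can be swapped in.

### Integration

Human scores are summed per gene; the mouse study, mapped to human gene IDs
(many-to-one resolved by the same max-variance rule), is added with weight
w (default 1) only when sign-concordant with a non-null human sum.
Genes observed only in the mouse are dropped. Effect-size medians follow
the same sign rule. The BD ratio divides the Bhattacharyya distance between
the gene's per-study |score| shares and the uniform distribution by the
maximum ½·ln n over the n *represented* studies; single-study genes are
forced to 0, while a gene represented in several studies but with one
non-null score reaches 1 — the two cases are deliberately distinct.
Internally the ratio lives in [0,1]; report rendering multiplies by 100.

The consistency screen removes genes whose score sign contradicts their
median logFC (and null scores). The signature filter takes
floor(0.10·N) genes per sign ranked by score (ties by |logFC| descending,
then gene ID) and then keeps those with |logFC| > 0.99. Flooring, the tie
order, and applying the decile to the post-screen candidate list (not the
full gene universe) are determinism/def-inition choices the method text
leaves open.

### Genomics

Region enrichment computes exact binomial upper tails P(X ≥ x) per
chromosome arm or band, with expected frequencies genome-wide at both
levels (configurable; within-chromosome band frequencies would be the
alternative). No multiple-testing correction is applied across regions —
raw tails with star labels are the convention mirrored here. Star
intervals are open; a boundary value takes the less significant label
(0.0001 → \*\*\*, 0.05 → none).

The silencing filter requires, by default, hypermethylation evidence
(methylation logFC > 1.5, adjusted p < 0.1) in **both** the
malignant-vs-benign and malignant-vs-control methylome comparisons, plus
negative MPNST-vs-NF score and logFC < −0.5 in both tumor expression
comparisons; a flag relaxes the methylation condition to either comparison.
When a pipeline run has only the single MPNST-vs-NF expression comparison,
`run_meta_analysis` reuses its meta table for the control-side logFC
condition and logs a warning; the filter itself always demands both tables
and errors naming the absent one. The bundled 10-gene panel
(`nfmeta/data/mpnst_hypermethylation_panel.tsv`) carries the published
nerve-tumor expression and promoter-methylation statistics of RASSF1 and
nine signature genes and serves as a worked-example input.

## Synthetic cohort

`synthdata` emulates what the analysis assumes: per-study probe universes
covering a random `platform_coverage` fraction of a shared gene universe,
1–3 probes per gene sharing the gene's group means plus a probe offset
(s.d. 0.3), baselines uniform in [5,10] log2 units, planted log2 effects
carried entirely by group A, i.i.d. Gaussian replicate noise, and a mouse
study with identical effect magnitudes and a configurable sign-flip
fraction. Defaults — 4 human studies + 1 mouse, 1000 genes, 10% planted
differential with |effects| in [2,4], 5 replicates per group, noise 0.5,
10% mouse sign flips — describe a deliberately clean rare-disease cohort:
moderate arrays, strong effects, no batch structure.

What passing tests on this cohort do **not** show: robustness to
cross-hybridization, batch effects, platform-specific intensity
distributions, annotation-version drift, or correlated noise — all present
in real accessions. The published headline counts (579 signature genes from
7064 scored, 336 up / 243 down) depend on those real inputs and original
annotation versions and are out of reach at desk scale; what is checked
instead is every stated rule and worked value of the method, plus planted
recovery (≥ 90% of signature members correct on the reference cohort) and
full mouse exclusion under 100% sign discordance.

## Numerical choices and problem sizes

Even-count medians use midpoint convention everywhere. Degenerate cases:
r = 0 when logFC_m = 0 (never 0/0); BD ratio 0 when all scores null;
all-zero score vectors standardize to themselves; an empty post-prefilter
study contributes an empty table rather than an error. Seeds: every
generator consumes a single integer seed through `numpy.random.default_rng`;
identical seeds give bit-identical outputs.

Test and example problem sizes (chosen as comfortable desk scale): cohorts
of 300–1000 genes, 2–5 studies, 5+5 samples; BD oracle grids over all
score compositions of ≤ 5 studies; binomial enumeration oracles at n ≤ 25.
The full suite runs in a few seconds.

## Known limitations

* The score formula and the range standardization are reasoned
  reconstructions (see above); both are configurable seams.
* The BD ratio ignores score signs (mass shares only), so a gene scored
  +0.5/−0.5 in two studies looks perfectly balanced.
* Arm/band annotation is consumed as given; genes lacking band labels
  only participate at arm level.
* The methylation stage consumes a pre-computed promoter statistics table;
  read-level methylome processing is out of scope.
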