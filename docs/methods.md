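# Methods

## Model and procedure

The pipeline detects genes whose two transcript isoforms show opposite
expression bias between two cell types (soma vs gonidia). The analysis
unit is the transcript-level FPKM matrix (transcripts × replicated
samples) plus gene models giving each transcript's exon structure.

**Expression floor.** A gene is "expressed" when the mean over all
samples of its per-sample summed transcript FPKM is strictly greater
than `min_mean_fpkm` (default 1 FPKM). The floor is applied at the gene
level; a per-transcript variant (`filter_expressed_transcripts`) is
available as a pre-filter but is off by default. Strict inequality means
a gene at exactly the floor is excluded.

**Census.** Expressed genes are binned by isoform count. Only
two-isoform genes proceed: one isoform cannot switch, and genes with
three or more isoforms would need a different (multi-way) contrast, so
they are counted but not analyzed. The funnel report quotes the share of
multi-isoform genes that have exactly two isoforms as an integer
percentage truncated toward zero (floor), matching how such funnel
percentages are conventionally printed.

**Expression ratio.** For each transcript,
`ER = (mean_soma + ε)/(mean_gonidia + ε)` with pseudocount ε = 0.01
FPKM in both numerator and denominator. ε only matters near zero means;
it is two orders of magnitude below the expression floor, so ratios of
expressed transcripts are essentially unperturbed. ε is configurable
(`Thresholds.pseudocount`); symmetry properties hold exactly at ε = 0.

**Filter cascade.** With iso1 defined as the higher-ER isoform (so the
combined bias B = ER₁/ER₂ ≥ 1 and the cascade is orientation-free):

| stage | criterion | default |
|---|---|---|
| 1 | ER₁ > τ_bias and ER₂ < 1/τ_bias | τ_bias = 2 |
| 2 | B > τ_B | τ_B = 8 |
| 3 | p₁ < τ_p and p₂ < τ_p | τ_p = 0.1 |

All comparisons are strict; ties fail. Stage 1 is algebraically the
requirement |log₂ ER| > log₂ τ_bias with opposite signs (unit-tested
equivalence). The aggregate p-value is the exact product p₁·p₂, with
default threshold τ_p² = 0.01; this treats the two isoform tests as
independent and is per-gene nominal — no FDR control is applied, matching
the screen's role as a candidate generator feeding manual curation.

**Differential test.** `two_group_isoform_test` is a two-sided
pooled-variance t-test on log₂(FPKM + 1), which for two groups equals
the F-test of the cell-type term in a one-way linear model. The log₂
transform stabilizes the strong mean–variance relationship of FPKM; the
+1 offset keeps zeros finite. Degenerate contract: when both groups have
zero within-group variance (exactly replicated values, as in noise-free
simulation), p = 1 if the group means are equal and p = 0 otherwise.
This makes noise-free recovery tests exact. The test requires ≥ 2
replicates per cell type.

## Curation

The curation criteria formalize checks originally applied by eye on
browser coverage tracks; all cutoffs are artifact-chosen and
configurable, not derived quantities.

**Differential regions.** For an isoform pair, exact interval set
differences and intersection of the two exonic unions (0-based half-open
throughout; conversion to/from 1-based inclusive GFF3 happens only at
the format boundary). Verified against per-base set arithmetic.

**RD (read density).** Each isoform's unique regions must, in the cell
type where that isoform is claimed expressed (the sign of its ER), have
mean depth ≥ `min_mean_depth` (default 5; inclusive, since the cutoff is
artifact-defined) and a covered-base fraction ≥ `min_covered_fraction`
(default 0.8). An isoform with *no* unique region fails RD: with no
differential exonic sequence there is no independent evidence for a
distinct transcript structure.

**REL (relative support).** With u₁(c), u₂(c), s(c) the mean depths over
the unique-to-isoform-1, unique-to-isoform-2 and shared regions in cell
type c (pseudodepth 0.5 added to every mean),

```
score = log₂[(u₁(soma)/s(soma)) / (u₁(gonidia)/s(gonidia))]
      − log₂[(u₂(soma)/s(soma)) / (u₂(gonidia)/s(gonidia))]
```

passing iff |score| ≥ `min_rel` (default 2.0) and the two bracketed
terms have strictly opposite signs. Normalizing by the shared region
cancels whole-gene expression differences — scaling one cell type's
entire track by any constant leaves the score unchanged (exactly at
pseudodepth 0) — so REL rejects precisely the artifact it is designed
for: overall transcript-abundance difference masquerading as isoform
switching. An empty shared region leaves the score undefined and REL
fails with that reason.

**CT (convergent transcription).** `detect_convergent_pairs` reports
pairs of distinct genes on opposite strands whose exonic spans overlap
by ≥ `min_overlap` bases where the overlap intersects the 3′-most exon
of *both* partners (divergent 5′ overlaps are excluded). Strand comes
from gene models only — the read data the screen exists for is
unstranded. A candidate is CT-flagged when its span overlaps both
members of a detected pair in the reference annotation; geometric
membership alone excludes it, since a convergent locus is a miscalled
"gene" regardless of whether the pair also shows opposite bias (the
`opposite_bias` field is still reported, requiring one partner ER >
τ_bias and the other < 1/τ_bias). Curation order is RD, REL, CT; the
final status records the first failing criterion, and every candidate
receives exactly one status.

## Comparative sets and the RBP screen

Set merging uses plain set algebra with per-id provenance tags and
inclusion–exclusion bookkeeping. Gene identifiers can be normalized
before comparison — an all-digit trailing dot-suffix (`.1`, `.t2`) and
the legacy `m.g` gene-model suffix are stripped — because annotation
releases mix id styles for the same locus; locus-style segments such as
`.0004s0224` are deliberately not touched. The ortholog overlap counts,
for a 1:1 ortholog map, pairs whose A-member, B-member, or both members
are in their species' alternatively spliced gene set.

RBP genes are identified by PFAM domain content; the default list covers
the four canonical RNA-binding families (RRM PF00076, KH PF00013,
G-patch PF01585, DEAD/helicase-C PF00270 and PF00271) and is extensible
because real annotations include further families. Bias tiers on the
gene-level fold change f = max(ER, 1/ER): *similar* f < 2, *modest*
2 ≤ f ≤ 5, *specific* f > 5 — the boundary values 2 and 5 are assigned
to *modest*, keeping the outer tiers strict.

## Synthetic data

The simulator emulates a replicated two-cell-type bulk comparison:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 200 | genes on one synthetic chromosome |
| `isoform_count_distribution` | (0.89, 0.087, 0.023) | P(1, 2, 3 isoforms) for null genes, matching the observed predominance of single-isoform genes |
| `n_ctsai` | 20 | planted switch genes (always exactly 2 isoforms) |
| `n_convergent_pairs` | 2 | planted overlapping antisense pairs |
| `effect_log2` | 2.0 | per-isoform planted |log₂ ER| (16-fold between isoforms) |
| `baseline_fpkm_log_mean/sd` | 3.0 / 1.0 | natural-log parameters of the log-normal baseline (median ≈ 20 FPKM) |
| `replicate_cv` | 0.2 | multiplicative replicate noise CV |
| `replicates_per_cell_type` | 2 | duplicate samples, as in the motivating study design |
| `convergent_overlap` | 50 bp | 3′ overlap of planted pairs |

Noise is log-normal multiplicative (FPKM are positive and right-skewed),
mean-corrected so the expectation equals the planted mean and CV = 0
reproduces means exactly. Planted switch genes cycle through three
isoform architectures seen among validated switch loci: an extra
3′-terminal exon spliced from an internal site (truncating the shared
last exon so both isoforms keep a unique region), alternative first
exons, and an internal start with a unique alternative 5′ exon.
Convergent pairs are adjacent opposite-strand genes whose 3′-most exons
overlap by `convergent_overlap`. Coverage is idealized: each transcript
deposits `round(cell-type mean FPKM × depth_per_fpkm)` over its exons,
strand-agnostic and additive.

What passing tests on this generator do *not* show: robustness to read-level
artifacts (mapping bias, positional coverage decay, library-size
effects), to incomplete or wrong transcript models, or to the count
noise of lowly expressed transcripts — the simulator plants clean
log-normal signals on correct models.

## Numerical choices and problem sizes

- Internal coordinates are 0-based half-open everywhere; conversion only
  at format boundaries, so interval arithmetic needs no ±1 bookkeeping.
- ER ties between isoforms are broken by transcript id (B = 1, stage 1
  fails regardless).
- Missing FPKM values are hard errors, never imputed.
- The recovery suites run at 200 genes with 4 replicates per cell type
  and CV 0.2 (the planted-effect cohort) and 200 two-isoform null genes
  (the specificity cohort); property suites draw 1,000 random cascade
  inputs and 100 random isoform pairs. These sizes give stable pass/fail
  behaviour at seconds-scale runtime.

## Known limitations

- RD and REL cutoffs formalize visual judgments; they cannot be
  validated against the original manual calls, only characterized by
  their invariances.
- The differential test assumes homoscedastic log-FPKM across groups and
  carries no library-size adjustment; with 2–4 replicates its p-values
  are coarse, which is why the cascade treats them as one filter among
  three rather than the primary evidence.
- Genes with ≥ 3 isoforms are out of analytical scope by design.
- The CT screen needs a strand-aware reference annotation; it cannot
  rescue loci where no reference gene models exist.
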