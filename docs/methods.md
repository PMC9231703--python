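# Methods

This note documents the models and scoring procedures melkquant implements,
the defaults it ships, the synthetic-data generators used for testing, and
the numerical and design choices that were genuinely open.

## Dual-probe FISH interpretation

Input is one integer pair per scored nucleus: MELK probe spots and CEP9
(chromosome-9 centromere) probe spots. Per sample we report:

- **mean_gene, mean_cep** — arithmetic means of the per-cell counts,
  rounded half-up to one decimal (the reporting precision for FISH tables;
  unrounded means are retained on the summary object);
- **ratio** — mean_gene / mean_cep computed, by default, from the *rounded*
  means and rounded to the same precision. This matches how ratios are
  conventionally derivable from a printed summary table; computing from
  unrounded means is available via `RunConfig(ratio_from_rounded_means=False)`;
- **major clones** — distinct (gene, cep) patterns ranked by frequency,
  ties broken by ascending pattern. Ties are classified on the
  lexicographically smallest tied pattern, for determinism.

Classification rules, in order:

1. **Amplification**: reported ratio ≥ 2.0 (`amplification_ratio`). The
   centromere status is still reported alongside ("High ampl; CEP9 high
   polysomy"), because a tumor can be simultaneously amplified and
   polysomic; the "High" qualifier on "ampl" reflects a high-level gene
   count (≥ 4 copies in the dominant clone).
2. **CEP9 hemizygous deletion**: a single centromere signal with ≥ 2 gene
   signals in the dominant clone.
3. Otherwise the dominant clone's **gene** count sets the level — 2 disomy,
   3 low polysomy, ≥ 4 high polysomy (equivalently "copy number > 2 and
   ≤ 3" vs "≥ 4" on integers) — and equality of gene and centromere counts
   sets balanced vs unbalanced. The level is keyed to the gene count
   because the clone patterns 2:3, 3:4 and 3:5 are called disomy, low and
   (unlevelled) polysomy respectively; the centromere count alone cannot
   reproduce that.

Deciding level and balance from the dominant clone's integer pattern,
rather than from the real-valued means, is deliberate: populations with
means 3.8/3.8 but a 4:4 dominant clone are high polysomy, while means
3.2/3.1 with a 3:3 clone are low polysomy — means alone cannot separate
the two.

**Label rendering.** Labels follow the conventional wording ("High
unbalanced polysomy", "Disomy balanced", "SA, unbalanced disomy", "High
ampl; CEP9 high polysomy"). One rendering subtlety: when the gene- and
centromere-based levels disagree *and* the centromere count exceeds the
gene count by ≥ 2 (e.g. a 3:5 clone), the level qualifier is dropped
("Unbalanced polysomy") — a mixed-level polysomy has no single defensible
level word. Structural alterations are an input annotation (they are
identified cytogenetically, not from counts) and prefix the label with
"SA,".

Cells with zero signals are included in scoring; a population whose
centromere counts are all zero has no defined ratio and is rejected, as is
a dominant clone of 0:0.

## ΔΔCt relative quantification

With replicate Ct values in a 2×2 design (condition ∈ {sample, calibrator}
× role ∈ {target, reference}):

ΔCt = mean(Ct_target) − mean(Ct_reference) per condition,
ΔΔCt = ΔCt_sample − ΔCt_calibrator, RQ = 2^(−ΔΔCt).

The reported SD is, by default, the sample standard deviation of
per-replicate RQs formed by pairing replicate *i* across the four cells
(replicates beyond the shortest cell ignored) — the simplest estimator
consistent with a replicate design that reports an SD next to each RQ. A
delta-method alternative (`rq_sd_method="propagated"`) propagates the
per-cell standard errors through the exponential; the two agree to first
order for small Ct scatter.

RQ bands: **high** RQ ≥ 50, **moderate** 20 ≤ RQ < 50, **low**
1 < RQ < 20, **baseline** RQ ≤ 1 (the calibrator itself sits at exactly
1.00; values below 1 share the baseline label). Reported RQ/SD are rounded
half-up to two decimals. Note the band boundaries are evaluated on the
*unrounded* RQ, so a value infinitesimally below a cutoff bands below it;
amplification-efficiency correction and multi-reference normalization are
out of scope.

## ImmunoReactive Score

Percent-positive values are visually estimated integers 0–100; non-integer
input is rejected rather than silently binned. Bins: 0 → 0, 1–10 → 1,
11–50 → 2, 51–80 → 3, 81–100 → 4. Combined score = intensity grade (0–3) ×
percent score, hence always in {0, 1, 2, 3, 4, 6, 8, 9, 12}. Categories:
0 none, 1–3 low (negative), 4–8 moderate, 9–12 high; positive ⇔ ≥ 4 (8 is
moderate; "greater than 8" is high — the two published phrasings agree).

Cores carry both compartments (nuclear, cytoplasmic) with the invariants
that intensity 0 implies 0% staining and cytoplasmic staining occurs only
with nuclear staining. Cohort summaries report per tissue class (benign,
DCIS, IDC, metastasis): n, positivity count/fraction, and mean ± SD of
percent-positive. Metastases are carried through summaries but excluded
from the ordered three-class comparisons. Consensus of two blinded raters
is an upstream concern; the package accepts whatever single score column it
is given.

## Promoter signal area

A signal track is a set of non-overlapping constant-valued half-open
intervals (bedGraph convention, 0-based). The region statistic is

area(region) = Σ_segments max(0, min(end, region_end) − max(start, region_start)) × value.

Clipping partial segments to the region is the only convention under which
the area is independent of how the track is binned; it also makes the
statistic additive over any partition of the region (verified to 1e-9
relative in tests). The default region is the MELK promoter window,
hg19 chr9:36,571,990–36,574,891 in browser coordinates, stored internally
as 0-based half-open; browser-style input is converted with an explicit
flag (`one_based=True`) to avoid silent off-by-one errors.

Per-sample areas are compared across molecular subtypes with the
tie-corrected Kruskal–Wallis test. Methylation beta values (in [0, 1]) are
compared per probe across subtypes the same way, Holm-adjusted across
probes; the default probe subset is the three promoter CpG probes closest
to the transcription start site (cg14552260, cg14339556, cg13912011) and
any probe list is accepted.

## Statistical layer

Implemented directly (scipy supplies only t / chi-square / normal
distribution functions and midranks):

- **Pearson r** with the two-sided t-transform p (df = n − 2); |r| = 1
  returns p = 0; zero-variance input is rejected naming the offending
  variable. Two-sided is assumed throughout.
- **Kendall tau-b** by explicit pair counting with the tie-pair denominator
  and the tie-adjusted normal variance of C − D. Matches O(n²) pair
  counting to 1e-12 and scipy's asymptotic values.
- **Kruskal–Wallis** with tie correction; all observations tied returns
  H = 0, p = 1 by convention (the correction denominator is guarded).
- **Wilcoxon rank-sum**, two-sided. Default `method="auto"`: for total
  n ≤ 16 the exact permutation distribution of the rank sum is enumerated
  on midranks (so ties are handled); larger samples use the tie-corrected
  normal approximation with a 0.5 continuity correction. This small-sample
  exact switch is the convention of standard implementations and keeps
  small-sample p-values honest, where the normal approximation can be off
  by a few hundredths.
- **Welch t** (unequal variances, Welch–Satterthwaite df); pooled-variance
  t is not offered since equal variances are never assumed here.
- **Holm step-down**: sorted ascending, the i-th p is multiplied by
  m − i + 1, a running maximum enforces monotonicity, capped at 1,
  returned in input order.

**Substitution note:** ordinal pairwise group comparisons are performed as
Wilcoxon rank-sum + Holm rather than cumulative link mixed models; every
report carrying such comparisons embeds this note in its output.

The CN/expression driver reports the pooled Pearson correlation of log2 CN
vs log2 expression, Kruskal–Wallis of each variable across subtypes, and
Holm-adjusted pairwise rank-sum tests of basal vs each other subtype.
Pooled (not meta-analytic) correlation is used.

## Synthetic-data generators

All generators are pure functions of (parameters, seed). A global seed is
expanded into per-stage substreams salted with a CRC32 of the stage name,
so adding a stage never perturbs another stage's draws.

- **FISH populations**: cells drawn from a clonal mixture (fractions must
  sum to 1); with probability `miscount_rate` each probe count is perturbed
  by ±1, floored at 0 — the minimal error model that exercises major-clone
  robustness, since no quantitative spot-miscount model is established.
- **qPCR**: reference Cts at `base_ct` (default 20 cycles), target Cts
  offset by +3 cycles, the sample target shifted by −log2(fold change),
  Gaussian replicate noise (default 0.05 cycles), quadruplicate by default.
  Noise-free tables recover the fold change to machine precision.
- **IHC cohorts**: per tissue class, nuclear intensity from a categorical
  distribution over grades 0–3 and percent-positive from a rounded,
  clipped normal. Default class conditions use nuclear percent-positive
  64.85 ± 32.89 (benign), 69.0 ± 41.34 (DCIS), 87.18 ± 24.6 (IDC) and
  cytoplasmic positivity rates 1/33, 4/10 and 17/39. Cytoplasmic-positive
  cores are guaranteed nuclear staining and an IRS ≥ 4 pattern; negative
  cores stay below the positivity threshold, so empirical positivity
  converges to the model rate.
- **Signal tracks**: the region is tiled with bins of width ≤ `bin_width`,
  with breakpoints forced at peak boundaries so bins never straddle a peak
  edge; values are peak height plus truncated-at-zero noise inside peaks,
  truncated noise alone outside. Noise-free tracks make peak areas exact
  rectangle sums.
- **CN/expression**: within each subtype, (log2 CN, log2 expr) is a
  standard bivariate normal with the target correlation; per-subtype
  (CN, expression) shifts are added. Defaults (n = 135, r = 0.5, basal
  carrying the CN gain and expression increase) mirror a cell-line-panel
  scale analysis; tumor-cohort-scale correlations are weaker, and the
  target is a parameter, not a constant.

What the generators do *not* emulate: image-level artifacts (FISH spot
segmentation, stain deconvolution), PCR efficiency drift, batch and array
normalization effects, spatial correlation within tissue cores, and
cohort-level confounding. Tests passing on synthetic data therefore
demonstrate correctness of the scoring/statistics pipeline under its
stated model, not robustness to those real-data artifacts.

## Problem sizes and tolerances

Deterministic identities are asserted at machine precision (1e-12
relative); area additivity at 1e-9 relative. Parameter-recovery checks use
n = 2,000–10,000 draws with tolerances set by sampling theory (Fisher-z SE
for correlations, binomial SE for fractions). The Kruskal–Wallis type-I
calibration uses 2,000 simulated 3×20 null datasets at α = 0.05 — enough
for a ±0.01 acceptance band at roughly two binomial standard errors.

## Known limitations

- The FISH label grammar covers the patterns that occur in practice;
  exotic combinations (e.g. amplification with centromere loss) render
  mechanically from the same rules but have no published exemplar.
- The rank-sum exact enumeration is O(C(n, n1)) and intentionally capped;
  it is a small-sample correctness device, not a general exact test.
- Kendall tau-b p-values use the asymptotic normal approximation at any n;
  at very small n an exact tau distribution would be preferable.
- The ΔΔCt model assumes perfect doubling efficiency; efficiencies below 2
  bias RQ multiplicatively and are out of scope.
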