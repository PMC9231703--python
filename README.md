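# melkquant

Quantification and classification of **MELK gene dosage and expression in
breast cancer**, packaged as a tested, reusable pipeline for the assays a
molecular-pathology study of a candidate amplicon actually runs:

- **Dual-probe FISH interpretation** — per-nucleus MELK and CEP9
  (chromosome-9 centromere) probe counts are aggregated into mean copies per
  cell, the gene:centromere ratio, and the most representative clone; the
  sample is then called as amplification (ratio ≥ 2.0), balanced/unbalanced
  low/high chromosome-9 polysomy, disomy, or CEP9 hemizygous deletion, with
  optional structural-alteration (SA) annotation.
- **ΔΔCt relative expression** — RQ = 2^(−ΔΔCt) against an endogenous
  control transcript and a calibrator sample, banded as high (RQ ≥ 50),
  moderate (20 ≤ RQ < 50), low (1 < RQ < 20) or baseline (RQ ≤ 1).
- **ImmunoReactive Score (IRS)** — intensity grade (0–3) × percent-positive
  bin score (0–4), combined 0–12, positive when ≥ 4, computed per tissue
  core and cellular compartment with per-tissue-class cohort summaries.
- **Promoter signal area** — for a histone-mark signal track (bedGraph), the
  total peak area within a genomic window, Σ segment width × signal value,
  with segments clipped to the region; areas are compared across molecular
  subtypes by Kruskal–Wallis.
- **Copy-number/expression integration** — Pearson correlation of log2 CN
  vs log2 expression, per-subtype Kruskal–Wallis, and Holm-adjusted pairwise
  rank-sum comparisons of the basal-like subtype against the others.

The statistical layer (Pearson r, Kendall's tau-b with tie correction,
Kruskal–Wallis, Wilcoxon rank-sum, Welch t, Holm step-down) is implemented
in the package and verified against independent oracles, and every stage has
a seed-deterministic synthetic-data generator so the whole pipeline is
testable without any external cohort.

## Worked example

Score a simulated high-polysomy cell line (70% of nuclei with a 9:10
MELK:CEP9 pattern, 5% spot-miscount noise), quantify a high expressor, and
compute an IRS:

```python
from melkquant import (ClonePattern, simulate_fish_population, simulate_qpcr,
                       quantify, irs)
from melkquant.fish_scoring import score_table

cells = simulate_fish_population(
    [ClonePattern(9, 10, 0.7), ClonePattern(8, 10, 0.3)],
    n_cells=100, miscount_rate=0.05, seed=7)
print(score_table({"HCC70-like": cells}).to_string(index=False))

res = quantify(simulate_qpcr(381.55, replicate_sd=0.05, n_reps=4, seed=7))
print(res.rounded(2), res.band)

print(irs(2, 90))
```

prints

```
 sample_id  n_cells  mean_gene  mean_cep  ratio major_clone  major_clone_percent           interpretation
HCC70-like      100        8.7      10.0    0.9        9:10                 62.0 High unbalanced polysomy
(404.32, 34.59) high
IRSResult(intensity=2, percent_score=4, combined=8, category='moderate', positive=True)
```

Reading the output: mean MELK and CEP9 copies per cell are 8.7 and 10.0, so
the gene:centromere ratio (0.9) is far below the amplification cutoff — the
copy gain is whole-chromosome, called "High unbalanced polysomy" from the
dominant 9:10 clone. The simulated quadruplicate qPCR recovers an RQ near
the generating fold change (404.32 ± 34.59, band "high"), and moderate (2+)
staining in 90% of cells gives the combined IRS 8 (moderate, positive).

The same stages are available from a shell via the `melkquant` command
(`fish-score`, `rq`, `irs`, `peak-area`, `correlate`, `compare-groups`, and
`simulate` subcommands); every threshold can be overridden with a YAML
config file passed as `--config`.

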