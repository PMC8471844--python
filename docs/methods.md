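# Methods

## Model and assumptions

The toolkit standardizes karyotypes of complements whose homolog pairs are
not individually recognisable. Its operative assumptions are:

1. **The centromeric index is condensation-invariant.** Chromosomes condense
   differently from spread to spread, changing every arm length, but the
   centromere's *relative* position — and hence i = 100·p/(p+q) — is
   unchanged. All identification and classification therefore runs on i;
   lengths are carried along only for tie-breaking and descriptive summaries.
2. **Rank identity stands in for homology.** "chr*k*" is defined as the pair
   at descending-i ranks 2k−1 and 2k within a metaphase. When measurement
   noise is small relative to the gaps between adjacent true indices this
   coincides with true homolog identity; when it is not, chr*k* is still a
   well-defined order statistic and the pooled median remains a stable
   location estimate near the k-th true index. Cross-species "orthology" is
   the same rank matching, no more.
3. **The median is the karyotype-defining statistic.** Category assignment
   uses Q2 of the pooled indices, which the outlier fences can never exclude,
   so category calls are insensitive to the whisker coefficient.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| ploidy (2n) | 100 | chromosomes | expected count per metaphase; strict mode rejects deviants, permissive mode lowers the pair count and logs |
| whisker_coef | 1.5 | IQR multiples | boxplot fence distance for outlier reporting |
| quantile_method | hinge | — | Tukey fivenum hinges (default) or type-7 linear interpolation |
| ploidy_factor | 2 | — | haploid→diploid count multiplier in formulas |
| category cuts | 12.505, 25.005, 37.505, 49.95 | i | Levan boundaries (below) |
| n_metaphases | 10 | spreads | generator: spreads per species (five male + five female, pooled) |
| arm_noise_frac | 0.01 | fraction of arm length | generator: s.d. of additive Gaussian chromatid-arm noise |
| condensation_sigma | 0.1 | log-scale | generator: s.d. of the per-metaphase log-normal length factor |

## Numerical and design choices

**Division-safe index.** i is computed as 100·p/(p+q), algebraically equal to
100/(r+1), so telocentrics (p = 0, r = ∞) need no special case. A one-ulp
clamp keeps i ≤ 50 when p = q, since binary arithmetic can exceed 50 by
~1e−14 and the classifier's domain is exactly [0, 50].

**Category boundaries.** The classical Levan table prints gapped two-decimal
ranges (st up to 25.00, sm from 25.01). Cuts are placed at the midpoints of
the printed gaps (12.505, 25.005, 37.505; M from 49.95) with half-open
intervals — a value on a cut belongs to the more metacentric side — so
[0, 50] is partitioned with no gaps. T and M are reserved for the exact edge
points i = 0 and i = 50. The classical table is internally inconsistent at
arm ratio 3.00 (listed submetacentric although i = 100/(3+1) = 25.00 falls in
the subtelocentric column); classification here is defined on i only, which
is the statistic the procedure is built around, and the r column is never
consulted.

**Hinge semantics.** The five-number summary uses the Tukey fivenum depth
rule (hinge depth d = (⌊(n+1)/2⌋+1)/2), the semantics of R's boxplot
statistics, which differ from linear-interpolation quartiles at most sample
sizes (for 1..6: hinges 2/5 vs quantiles 2.25/4.75). `hinge` is the default;
`linear` is available because published "Q1–Q3" ranges do not always say
which convention produced them. The suite pins the hinge path against values
frozen from R's `fivenum`/`boxplot.stats` and against an independently coded
median-of-halves oracle.

**Outliers are reported, never silently dropped.** Fence elimination affects
only the whiskers Q0/Q4 (the most extreme data values inside the fences —
data values, not the fences); downstream classification uses the median of
the full pool, which fences cannot move.

**Tie-breaking.** Equal i values — pervasive at i = 0 in telocentric-rich
complements — are ranked by descending length, then stable input order. Any
deterministic rule gives identical pooled multisets per chromosome when ties
are confined to equal-i blocks; length is the only other measured quantity,
hence the choice.

**Orientation normalization.** Rows whose p-labelled arm mean exceeds the
q-labelled one are swapped with a warning rather than rejected: manual
measurement tables routinely carry transposed labels, and the q ≥ p
convention must hold downstream. Chromatid pairs differing by more than 3×
are logged as suspect but kept — no principled exclusion rule exists, and
auditability favours flagging over dropping.

**Interval comparison is binary, not inferential.** Two species "share" a
chromosome when the closed Q1–Q3 intervals intersect. No significance test is
part of the standardized procedure; `permutation_median_test` is provided
separately for users who want a p-value on a median difference, and is
labelled as a supplement, not part of the comparison rule.

**Nearest-median assignment.** An externally observed i is assigned to the
entry minimising |Q2 − i|, ties toward the smaller index. When the nearest
median is 0 the observation is equally compatible with every telocentric
identity, so the whole contiguous all-T block is returned as a range rather
than pretending to single-chromosome resolution.

## What the synthetic generator does and does not emulate

The generator draws, per metaphase, one log-normal condensation factor
(affecting lengths, never i) and, per chromatid arm, additive zero-mean
Gaussian noise with s.d. proportional to the true arm length, truncated at
zero. Telocentric templates have a structurally zero short arm at any noise
level. Defaults mirror the bundled study design: 10 metaphases, 50 templates
(2n = 100), 1% arm noise. No published estimate of manual-measurement error
exists for this setting; 1% is the toolkit's benchmark level, exposed in the
spec file.

Not emulated: correlated errors from touching/bent chromosomes, centromere
misplacement (which moves p and q in opposite directions), chromosome-count
deviations (94–104 counts occur in real spreads; the permissive mode handles
them but the generator does not produce them), microchromosomes, and any
image-level artefact. Passing recovery tests therefore demonstrates
robustness to independent metric noise, not to segmentation or
centromere-calling mistakes.

## Problem sizes

The test suite and acceptance checks run the full pipeline on synthetic data
at the bundled study's own scale — 3 species × 10 metaphases × 100
chromosomes — with 100 seeded replicates for the noisy-recovery rate, and
compare the quartile and selection primitives against brute-force oracles on
1,000 and 200 random inputs respectively; the complete suite finishes in
well under a minute.

## Known limitations

- Rank identification cannot separate chromosomes whose true indices are
  closer than the measurement noise; their pooled samples mix, and only the
  block's medians (not individual identities) are meaningful there.
- Category calls sitting very close to a Levan cut (within ~0.1 in i) can
  flip under 1% arm noise; the recovery rate reported by the suite (≥95%
  across seeds) quantifies this at the default conditions.
- The comparison module inherits rank-matching: a reciprocal translocation
  that preserves indices is invisible, and a single shifted index can cascade
  into many flagged "orthologs".
- Units are raw pixels throughout; cross-study length comparisons require a
  shared magnification or an external normalisation (a relative-length
  normalisation is deliberately not applied by default, since all bundled
  statistics are defined on raw pixel values).
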