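# Methods

## Quantification model

The pipeline assumes peptide-ion intensities are, on the log2 scale,
additive in four effects:

    y_{g,i,j} = b_g + sum_{k : g in S(k)} a_{k,c(j)} + d_j + f_i + eps,
    eps ~ Normal(0, sigma^2)

where `b_g` is the baseline abundance of site group `g`, `a_{k,c}` the
activity shift of kinase `k` in condition `c` (applied to its substrate set
`S(k)`), `d_j` a per-sample loading offset, `f_i` a per-fragment response
offset, and `eps` measurement noise. Each stage of the pipeline removes one
nuisance term:

- **Median equalization** shifts each sample by a constant so its median
  log2 intensity equals the median of per-sample medians. This exactly
  removes `d_j` (a constant per sample) and preserves all within-sample
  differences. It is computed on fragment-level evidence, before
  summarization.
- **Median polish** (Tukey) decomposes each site group's fragment × sample
  matrix into overall + row (fragment) + column (sample) effects by
  alternately sweeping row and column medians out of the residuals. The
  per-sample summary is overall + column effect, which absorbs `f_i` into
  the row effects. On an exactly additive matrix the decomposition is exact
  and all residuals vanish.
- **Differential testing** contrasts per-sample summaries between two
  conditions with a pooled-variance Student's t-test; under the model the
  summary difference estimates the planted activity contrast
  `sum_k (a_{k,A} - a_{k,B})` for the group's kinases.
- **The kinase z-score** `Z = (M - mu)/(s/sqrt(m))` compares the mean fold
  change `M` of a kinase's `m` detected substrates against the mean `mu`
  and sample SD `s` (denominator n−1) of *all* detected site-group fold
  changes. Under a null where substrate fold changes are exchangeable with
  the background, `Z` is approximately standard normal and
  `P = 2(1 - Phi(|Z|))` is a calibrated two-tailed test (verified on 2,000
  simulated null kinases: rejection rate ≈ 0.05, KS vs N(0,1) not
  rejected).

No missing value is ever imputed: a (fragment, sample) cell that was not
observed is simply absent from every median; a sample column with no
observation at all propagates as missing through summarization and is
excluded from the t-test counts.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `min_substrates` | 3 | count | below this, `Z` is too unstable to report; kinases are still listed with a reason code |
| `alpha` | 0.05 | — | significance on the *unadjusted* kinase P (BH across kinases available via `adjust=True`) |
| match rule | `any-site` | — | a multiply-phosphorylated group matches a kinase if any site in its set is an annotated substrate; `exact-singleton` restricts to single-site groups |
| polish tolerance / max iterations | 1e-6 / 50 | log2 / count | convergence is on the largest absolute change in any effect; row sweep first; even-length medians are the mean of the central pair |
| outlier threshold / floor | 3.0 robust-z, 0.1 log10 | — | a sample is flagged when its log total intensity or log detection count is > 3 MAD-based z-units **and** ≥ 0.1 log10 units (~25%) from the across-sample median; the floor prevents MAD degeneracy across a handful of well-behaved samples from flagging sampling jitter |
| `noise_sd` (generator) | 0.5 | log2 | typical phosphopeptide-level measurement spread; gives fold-change SD 0.5·√(2/3) ≈ 0.41 at 3 replicates/condition |
| `fragment_offset_sd` (generator) | 0.5 | log2 | fragment response offsets ~ Normal(0, 0.25 variance), so median polish has real work to do |
| `sample_offset_sd` (generator) | 0.1 | log2 | modest loading variation, removed by normalization |
| baselines (generator) | Normal(20, 2) | log2 | typical MS log2-intensity range |
| default simulation scenario | 120 kinases, 10 substrates each, 20 active at ±1 log2, 3 replicates/condition, 2 fragments/group, 5% missing | — | the recovery benchmark the package is validated on |

## Design choices where the design was open

- **`se = s/sqrt(m)` with `s` from all detected fold changes**, not from
  the substrates: the statistic asks whether a substrate *mean* is an
  unusual draw of `m` values from the overall fold-change distribution.
  `mu` is likewise the mean (not median) of all fold changes, pairing
  naturally with a normal-theory test.
- **Pooled-variance t-test** (not Welch) for the site-level contrast;
  groups are summaries of the same site under identical processing, so
  equal variances are the natural default.
- **Zero-variance contrasts** (identical within-condition summaries with
  unequal means) report statistics as undefined with reason
  `zero_variance` rather than P = 0; identical groups with equal means
  report t = 0, P = 1.
- **BH is applied once per contrast** across all testable site groups;
  untestable rows (fewer than 2 observations in a condition) carry reason
  codes and do not enter the correction count m.
- **The t-test operates on per-sample median-polish summaries**, not on a
  joint mixed model of fragment-level data — simpler, transparent, and
  sufficient for calibrated site-level inference in the tested regimes.
- **Rank-correlation reporting.** When most kinases are planted null,
  tie-averaged Spearman between planted effects and Z is capped far below
  1 even for perfect recovery (0.648 for 20 active of 120, since 100 tied
  nulls share one average rank). `RecoveryReport` therefore carries both
  `rank_correlation` (all kinases) and `rank_correlation_active`
  (non-null kinases only, cap 0.867 with ±1 plants), and recovery claims
  are made on the latter.
- **Outlier handling**: flagged samples are excluded by default before
  quantification (`exclude_outliers: false` retains them); flagging and
  removal are separate so the decision is auditable in the run log.

## What the generator does and does not emulate

It emulates: additive log-scale site-group abundances, condition-specific
kinase activity shifts over (optionally overlapping) substrate sets,
multiple fragments per group with fixed response offsets, sample loading
offsets, Gaussian measurement noise, and completely-at-random missingness.
Missingness is completely at random by default; an intensity-dependent mode
(`missing_mode="intensity"`, dropout probability decreasing linearly in
intensity rank) is available but off by default, since the pipeline itself
makes no missingness assumption beyond never imputing. The generator starts
at quantified peptide evidence and deliberately does not model: raw spectra
or spectral search, phosphatase activity or site stoichiometry,
non-phosphorylated background peptides, or correlated noise between sites
on one protein. Passing the recovery and calibration
tests therefore shows the *inference chain* is correct and calibrated under
the stated model — not that real acquisitions satisfy that model.

The generator emits only phosphopeptides; whether non-phosphorylated
peptides should enter normalization in real data is left to the upstream
processing that produces the evidence table.

## Numerical and degenerate-input conventions

- Intensities must be strictly positive; log2 happens at ingestion.
- Medians of even-length sets are the mean of the two central values,
  uniformly in normalization and polish.
- Median polish: row sweep first, then the column sweep, re-centring the
  opposite effect vector after each sweep; a single-fragment group's
  summary is the observed row itself.
- Kinase P values are clamped to the smallest positive double so that
  P ∈ (0, 1] holds even for extreme Z.
- All randomness flows from one integer seed per operation
  (`numpy.random.default_rng`); the pipeline derives per-stage sub-seeds
  from the config seed, making simulate-mode outputs byte-identical across
  runs.

## Problem sizes used in validation

Unit and property tests run on matrices up to 6×6 (200 random instances
against a pure-Python median-polish oracle), 1,000 random P vectors against
a brute-force BH, and 100 random fold-change maps against a hand-arithmetic
z-score oracle. Calibration uses 2,000 simulated null kinases (direct) and
500 null kinases through the full pipeline (5,000 site groups, 6 samples);
the recovery benchmark is the 120-kinase default scenario above. These
sizes give tight Monte-Carlo bands while keeping the full suite fast on a
single CPU.

## Known limitations

- Substrate sets overlapping heavily between kinases make their Z scores
  correlated; the test is per-kinase and does not model that correlation
  (the generator reports the overlap rate so benchmarks can control it).
- `mu` and `s` are computed per contrast; comparisons sharing samples are
  not pooled.
- The MCAR missingness model understates the intensity-dependent dropout
  of real DIA data; calibration under informative missingness is untested.
- The z-test treats site-group fold changes as exchangeable; strong
  global shifts that survive median equalization (e.g. condition-wide
  phosphorylation changes) shift `mu` and are interpreted as background,
  by construction.
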