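# Methods

## Scope and model

`tmtdiff` implements the quantitative analysis chain for a single-plex
isobaric-label (TMT) proteomics and phosphoproteomics experiment in which
one condition serves as the common reference for every contrast — the
motivating design is a doxycycline-inducible DUX4 myoblast time course
(induced 2, 6 and 14 h vs. DMSO-treated cells), but nothing in the code is
specific to that biology.  The chain is:

1. **PSM collapse.**  A peptide ion is identified by (sequence,
   modifications, charge).  When an ion is measured by several PSMs in a
   sample, only the maximum reporter intensity is kept.  Zero intensities
   are treated as missing because log2(0) is undefined.
2. **Median normalization.**  Under the equal-loading assumption, each
   sample's log2 intensities are shifted so that its median over observed
   values equals the global target median, defined as the median of the
   per-sample medians.  Choosing the median of medians (rather than zero)
   preserves the absolute intensity scale, which practitioners expect when
   browsing the matrices; it leaves any common component of the loading
   offsets in place, which is irrelevant to contrasts.
3. **Protein summarization by Tukey's median polish.**  Each protein's
   peptide-by-sample block is decomposed into overall + row (peptide) +
   column (sample) effects + residuals by alternating row-first/column
   median sweeps.  The protein's summary in a sample is overall + column
   effect; peptide-specific ionization offsets land in the row effects and
   are discarded.  A single-peptide protein passes through unchanged (the
   decomposition is exact there).
4. **Feature-wise linear models.**  For each protein (and, for
   phosphoproteomics, each peptide ion), a one-way fixed-effects model over
   all conditions: y_st = β0 + β_condition(t) + ε_st with ε ~ N(0, σ²).
   OLS gives condition means; σ² is pooled over every condition with data,
   with residual df = (observations) − (conditions with data).  A contrast
   against the reference is mean difference, SE = sqrt(σ²(1/n_c + 1/n_r)),
   and a two-sided Student-t p-value; with two conditions this is exactly
   the pooled two-sample t-test.  No empirical-Bayes moderation is applied:
   the method being implemented is plain feature-wise OLS, and moderation
   would change its p-values.
5. **BH FDR.**  Benjamini–Hochberg step-up q-values, computed separately
   per contrast and per data type, via
   `statsmodels.stats.multitest.multipletests`.
6. **Phospho-to-protein normalization.**  adjusted log2FC = raw log2FC −
   parent-protein log2FC for the same contrast.  Peptides whose parent was
   not quantified are kept unadjusted and flagged `unmatched` (their raw
   value may still be real site-level signal); multi-protein peptides are
   flagged `ambiguous` and left unadjusted.  Adjusted values are point
   estimates only — no SE is propagated — because the downstream rule is a
   fold-change threshold, not a re-test.
7. **Classification.**  RNA: q < 0.05 and |log2FC| > 1 (both strict);
   protein: q < 0.1 and |log2FC| > 1 (strict); phosphopeptides:
   |adjusted log2FC| ≥ 1 (inclusive twofold), no FDR gate.  The strict vs.
   inclusive distinction follows the wording of the respective rules.
   Percentages are printed to one decimal of the per-contrast total.
8. **Splicing counting.**  VOILA-style tables supply, per event, E[ΔPSI]
   and the posterior probability that |ΔPSI| ≥ 0.20.  An event is
   significant when that probability exceeds 0.95 *strictly*; an LSV is
   significant when at least one of its events is; a gene is counted once.
   Exon-skip and intron-retention tallies are split by the sign of E[ΔPSI].
   The module consumes the posterior as given — recomputing ΔPSI posteriors
   from junction counts belongs to the upstream inference tool.

## Numerical choices

- **Median convention:** an even count yields the mean of the two middle
  values, everywhere.
- **Median polish:** sweeps rows first, then columns; medians of the
  row/column effect vectors are folded into the overall term after each
  half-sweep; iteration stops when the sum of absolute residuals changes by
  at most `tol` (default 1e-4, CLI-exposed) or after `max_iter` (default
  20) iterations.  Missing cells are skipped by the medians; an all-missing
  row or column is an error.  Reconstruction (fitted + residual = input
  where observed) holds to 1e-9 by construction.
- **Degenerate fits:** residual df = 0 → flagged, contrasts carry missing
  p-values.  σ̂² = 0 with a nonzero difference → p = 0 and the record is
  flagged degenerate; with a zero difference → t = 0, p = 1.
- **Shared peptides** (one ion, several accessions) abort the collapse
  unless explicitly enabled; when enabled they are excluded from protein
  summarization by default to avoid double counting, and phospho ions keep
  a joined accession and are flagged `ambiguous` at adjustment.
- **Missingness:** a protein sample column with no observed peptide is a
  missing summary, not an error; missing summaries propagate as missing
  through the models (conditions without data are dropped from the fit).

## The synthetic generator

The generator emulates the measurement model the pipeline assumes, at a
desk scale, with every planted quantity recorded as ground truth:

- **Design:** one TMTpro 16-plex — the induced line in four conditions
  (reference DMSO 14 h; dox 2, 6, 14 h) × 3 replicates, plus the wild-type
  line (DMSO/dox 14 h) × 2 replicates.  Statistical studies (FDR control,
  recovery) use a 12-channel variant with the four induced-line conditions
  × 3 replicates, matching the replication of the modeled study.
- **Signal:** PSM intensity = 2^(protein base + peptide ionization offset +
  planted log2FC of the sample's condition + per-sample loading offset +
  N(0, noise_sd)).  Bases are Uniform(18, 26) log2 units; ionization
  offsets N(0, 1) by default; loading offsets N(0, 0.3) unless given;
  reporter noise 0.3 log2 units by default — typical magnitudes for TMT
  reporter data.
- **Planted effects are rank-tiered:** up-effects go to the
  highest-abundance features, down-effects to the lowest.  Median
  normalization is only identifiable when the median feature is
  non-differential; tiered planting enforces that assumption exactly, so
  with all noise terms zero the pipeline recovers planted fold changes to
  machine precision.  (With random placement, a feature crossing a sample
  median shifts every estimate by the gap between adjacent order
  statistics, O(range/n), which is small but not zero.)  Changed fractions
  are kept well below one half for the same reason.
- **Phosphopeptides** sample a parent protein uniformly; their true total
  log2FC is parent + site effect.  Site effects (default magnitude 1.5,
  fraction 6.5% — of the order observed in the modeled study) are planted
  only on peptides of *unchanged* parents, which realizes the
  protein/phospho decoupling the adjustment step exists to isolate, and
  keeps the planting median-safe.
- **Splicing tables** plant exactly round(frac × n_genes) genes with one
  event above the 0.95/0.20 thresholds; all other events sit below 0.90
  posterior so counts are deterministic.
- Defaults: 300 proteins × 2–5 peptides × 1–3 PSMs, 500 phosphopeptides,
  5% of proteins changed at ±1 log2 unit.  These are desk-scale stand-ins
  for a dataset of thousands of proteins; all are CLI flags.

What the generator does **not** emulate: co-isolation interference (ratio
compression), isotope-impurity cross-talk, peptide-level missingness that
depends on abundance, retention-time or fractionation structure, and
shared peptides (off by default).  Passing tests therefore demonstrate the
correctness of the estimators under their own model assumptions, not
robustness to these real-data artifacts — in real TMT data, compressed
ratios will attenuate fold changes relative to the planted-truth behavior
seen here.

## Problem sizes in the shipped studies

The test suite and `scripts/acceptance.py` run: oracle equivalence of the
median polish on 200 random 6×8 matrices with 10% missing cells; FDR
calibration on 50 independent global-null simulations of 500 proteins
(25,000 null tests, checked against a two-sided 99% binomial envelope at
the 5% level for raw p, and its upper edge for the BH q fraction);
recovery of 500 planted ±1 effects among 1250 proteins at noise 0.3
(|bias| < 0.05, RMSE < 0.25); and exact zero-noise checks for the phospho
adjustment and splicing counter.  These sizes give tight Monte-Carlo error
(binomial half-width ±0.0036 at n = 25,000) while keeping a full run in
about a minute.

## Known limitations

- Single plex only: no reference-channel bridging or between-plex batch
  terms.
- The within-feature model pools variance across both cell lines; if one
  line were substantially noisier, its contrasts would borrow a misfit σ².
- Median-polish summaries are slightly less efficient than means under
  purely Gaussian noise (the price of robustness to outlier peptides).
- Exon-skip classification trusts the input column; no coordinate-based
  event classifier is included.
- The shift-invariance of normalization ("adding a constant to one sample
  changes nothing") holds when the shifted sample does not carry the median
  of per-sample medians; with very few samples the target itself moves.
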