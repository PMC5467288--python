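# Methods

## Model and assumptions

The package operationalizes a common regulatory-genomics design: a
transcription factor's direct targets are the genes whose expression
responds to loss of the factor *and* that carry a binding site of the
factor. Three ingredients feed the integration:

1. **Loss-of-function differential expression.** Two knockout-vs-control
   array designs are assumed: a single knockout for the lead factor
   (Sox9-null style) and a double knockout for the two partner factors
   (Sox5/Sox6-null style), each with small per-group replication. Probe
   intensities are assumed background-subtracted upstream; the package
   starts at log2 transformation. Per-sample 75th-percentile shift
   normalization assumes most genes are unchanged, so the upper-quartile
   log-intensity is a stable anchor; with a large fraction of balanced
   up/down effects the anchor moves by only a few hundredths of a log2
   unit. The unpaired t-test treats the log2 scale as approximately
   normal; Welch (unequal variance) is the default because it costs almost
   nothing at these group sizes and is robust to variance heterogeneity,
   and the pooled-variance Student form is available via `equal_var=True`.

2. **Binding positions.** Peaks are reduced to their summits. Using a
   point rather than the interval makes the six-class positional taxonomy
   a true partition of the genome around each gene and matches the
   summit-centred windows used for motif work. One TSS per gene is
   assumed (no isoform handling); the TSS of a minus-strand gene is the
   last base of its span.

3. **Motif dimers.** SOX HMG-box proteins homodimerize on inverted motif
   pairs. The scanner reports all opposite-strand hit pairs with a bounded
   spacer rather than imposing one orientation, and labels each pair
   head-to-head or tail-to-tail; the spacer counts the gap between the two
   motif occupancies, so 0 means abutting. This convention is stated
   explicitly because "spacer" origins differ between papers, and the
   modal-spacer analyses here are only reproducible with a fixed origin.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `fc_min` | 1.5 | linear fold change | symmetric threshold applied to `2^{abs(log2fc)}` |
| `p_max` | 0.05 | BH-adjusted p | standard FDR level |
| `min_informative` | 1 | samples | probe kept if present/marginal anywhere |
| motif `p_cutoff` | 1e-4 | exact match p | the classic MAST default |
| `halfwidth` | 50 | bp | ±50 bp summit windows for motif scanning |
| `max_spacer` | 20 | bp | generous bound over reported SOX dimer spacings |
| `top n` peaks | 200 | peaks | tag-count ranked subset for motif work |
| `distance_cap` (flank mode) | 1,000,000 | bp | bounds absurd assignments; configurable |
| enrichment `max_n` | 3000 | genes | highest-fold-change truncation of large lists |
| score `precision` | 1e-3 | log-odds (log2) units | discretization of the exact score distribution |

## Numerical choices

* **Exact motif p-values.** Per-position log-odds scores are rounded to
  integer multiples of `precision`; the null distribution of the total
  score of a background L-mer is the L-fold convolution of the four-point
  column distributions, and the match p-value is the tail `P(score ≥ s)`.
  Window scores use the same discretized integers, so scan results are
  bit-identical to exhaustive enumeration over all 4^L words at the same
  discretization (verified against enumeration for L = 7). Windows
  containing N (repeat-masked) are skipped individually, not per sequence.
* **Degenerate t-tests.** Zero within-group variance in both groups gives
  p = 1 when the group means are equal and p = 0 (t = ±∞, counted and
  logged) when they differ; this makes the noise-free limit of the
  synthetic study well defined.
* **BH step-up.** Implemented via `statsmodels`' `fdr_bh` and checked in
  the tests against a hand-written step-up oracle. Note BH adjustment is
  *not* idempotent in general — re-adjusting `(0, 0.75, 1)` yields
  `(0, 1, 1)` because the step-up factor m/j re-inflates interior values —
  so no code relies on idempotence; it holds (and is tested) only for
  flat-tail vectors like the worked example `(0.01, 0.02, 0.03, 0.04) →
  (0.04, 0.04, 0.04, 0.04)`.
* **Boundary conventions.** Positional classes are evaluated in strict
  precedence (TSS → promoter → intragenic → proximal → distal → other)
  with bounds closed at the near edge and open at the far edge: exactly
  5,000 bp upstream is promoter, exactly 10,000 bp is proximal. The
  promoter class is upstream-only, so a summit 1–5 kb downstream of the
  TSS but outside the gene falls through to proximal. Nearest-gene ties
  are broken by lexicographically smallest gene id; top-N peak selection
  breaks score ties by peak id; conflicting probe directions resolve to
  "up" and are flagged.
* **Flank assignment.** The upstream-side gene of a summit is the nearest
  gene with TSS ≤ summit on the reference, the downstream side the nearest
  with TSS > summit (a gene with TSS exactly at the summit counts as
  upstream); genes whose span contains the summit are flagged intragenic.
* **Enrichment surface.** `term_enrichment` returns *all* tested terms
  ranked by fold enrichment so callers can inspect null terms;
  `significant_terms`/`top_terms` apply the BH `p_adj < 0.05` filter. The
  EASE-style variant substitutes k−1 for k (floored at 0) behind a flag;
  the fold enrichment always uses the observed k.

## The PWM fixture

The field's degenerate SOX consensus 5'-(A/T)(A/T)CAA(A/T)G-3' carries at
most 4·2 + 3·1 = 11 bits of information, so under a uniform background its
best match p-value is 8/4⁷ ≈ 4.9×10⁻⁴ — above the 10⁻⁴ scan cutoff. It
ships as `sox_consensus_pwm()` for reference, but dimer analyses and the
synthetic generator use a non-degenerate core word PWM
(`sox_core_pwm()`, consensus AACAATG, pseudocount 0.25 over 100 idealized
sites), whose consensus reaches p = 4⁻⁷ ≈ 6.1×10⁻⁵ and is therefore
detectable at the default cutoff. Any sufficiently informative JASPAR
matrix can be substituted.

## What the synthetic generator emulates — and what it does not

The generator reproduces the *logic* of the study design with analytically
checkable statistics, not its biology:

* **Geometry.** Each gene owns a fixed-size block with its TSS at the
  centre; all of a gene's peaks are planted inside its block at distances
  realizing the configured positional-class mix, so a peak is always
  nearest to its own gene and the planted target table is exactly
  recoverable in the noise-free limit. The default class mix puts zero
  weight on the >100 kb "other" class: planting it while preserving
  nearest-gene identifiability needs >280 kb blocks (~300 Mb of sequence
  at the default gene count), so "other" is exercised in dedicated tests
  with small gene counts and wide blocks rather than in the default study.
* **Sequence.** Background is i.i.d. uniform over ACGT (no GC structure,
  no repeats), which keeps motif false-positive rates analytically
  predictable (`p_cutoff` × windows). Inverted dimers are written into 70%
  of summit windows at a 4 bp spacer by default.
* **Expression.** 1–3 probes per gene (exercising the probe-collapse
  rule), probe base levels uniform on log2 [6, 12], i.i.d. Gaussian log2
  noise (default sd 0.25), planted shifts of ±1 log2 unit with recorded
  signs, and present/marginal/absent flags sprinkled at 2%/2%. Real
  arrays have correlated probes, intensity-dependent variance and batch
  structure; none of that is modelled, so passing tests demonstrate the
  pipeline's correctness, not robustness to array artefacts.
* **Roles.** Per factor, 20% of the 1,000-gene universe are direct targets
  (200 each), including a 21-gene trio shared by all three factors; 100
  genes per design are DE without binding (indirect); 50 peaks per factor
  sit near non-DE genes (background binding). The two designs' DE sets
  overlap only in the trio, which makes trio recovery a sharp test.

All randomness flows from one seeded `numpy` generator; equal seeds give
byte-identical outputs, including the emitted files.

## Statistical power at the default conditions

With a 2-fold planted effect, per-sample log2 noise sd 0.25 and n = 3 vs
3, the per-probe t statistic is noncentral-t with ncp =
1/(0.25·√(2/3)) ≈ 4.9 at ~4 degrees of freedom; the median raw p-value of
a true-effect probe is ≈ 0.013. Across a ~2,000-probe array with ~30%
true effects, the BH step-up only admits raw p-values around 10⁻³–10⁻²,
so probe-level power is ~0.3–0.5 and end-to-end edge recall settles near
0.5 (the step-up fixed point is bistable at this signal fraction, so
seed-to-seed recall varies in roughly 0.4–0.55). Precision and edge-sign
accuracy are essentially 1.0 throughout, and the noise-free limit
recovers the planted network and trio set exactly. This ceiling is a
property of df = 4 t-tests under FDR correction, not of the
implementation; recovering recall ≥ 0.9 at these settings would require
larger effects, more replicates, or a moderated variance estimator, all
outside the procedure implemented here.

## Problem sizes

Default analyses and checks use: 1,000 genes over 5 chromosomes (~74 Mb
of sequence), 250 peaks per factor, ~2,000 probes per design, 500-window
dimer scans, and 20-seed replication for recovery and calibration
studies; the hypergeometric implementation is verified exhaustively for
every table with background size N ≤ 60.

## Known limitations

* One TSS per gene; no isoforms, no enhancer–promoter looping or TAD
  awareness.
* Uniform-background motif statistics; no higher-order background models
  or heterodimer support.
* The DE module assumes upstream background subtraction and does not model
  batch effects; the optional lower-percentile expression filter of some
  array pipelines is off by default.
* Network construction is overlap-based only — no correlation, dosage or
  causal modelling.
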