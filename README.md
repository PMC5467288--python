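# soxgrn

Tools for reconstructing a transcription-factor-driven gene regulatory
network from loss-of-function expression profiling combined with in vivo
ChIP-seq, modelled on the SOX trio (Sox9, Sox5, Sox6) that drives embryonic
chondrogenesis. The package is aimed at regulatory genomicists who have (a)
knockout-vs-control expression matrices with detection flags and (b) peak
calls for one or more factors, and who want reproducible direct-target
calls and a signed factor→gene network — plus a fully synthetic test-bed
with planted ground truth for validating every stage.

## What it computes

**Differential expression.** Probe intensities are log2-transformed and
percentile-shift normalized at the 75th percentile (per sample,
`x̃ᵢⱼ = log₂ xᵢⱼ − Q₀.₇₅(log₂ x·ⱼ)`), probes without a present/marginal
detection flag in any sample are dropped, and each probe gets an unpaired
two-sided t-test (Welch by default) of knockout vs control with
Benjamini–Hochberg step-up FDR correction
(`p̃₍ᵢ₎ = min_{j≥i} p₍ⱼ₎ · m/j`). A gene is called DE when at least one of
its probes has `p_adj ≤ 0.05` and linear fold change `2^{|log2fc|} ≥ 1.5`;
direction is `down` iff the knockout mean is below control.

**Peak annotation.** Each peak summit is assigned its nearest gene by
|summit − TSS| and the pair is classified into a strict six-way positional
taxonomy (TSS ±1 kb; promoter 1–5 kb upstream; intragenic; proximal
5–10 kb upstream / 1–10 kb downstream outside the gene; distal 10–100 kb;
other >100 kb), with strand-oriented distances.

**Motif dimers.** PWM scanning uses exact match p-values: the null
distribution of the log-odds score of a background L-mer is computed by
per-position convolution of the discretized score distribution, and a
window is a hit when `P(score ≥ s) ≤ 10⁻⁴`. SOX HMG-box factors bind as
homodimers on inverted motif pairs; opposite-strand hit pairs are reported
with their spacer (gap in bp between the two occupancies) and the spacer
histogram over peaks.

**Integration and network.** A gene is a direct target of a factor when it
is DE in that factor's knockout design and is the nearest gene of (or, in
flank mode, adjacent on either side to) at least one of the factor's
peaks; trio targets are DE in both designs with binding of all three
factors. Loss-of-function logic signs the network: genes down in the
knockout are *activated* by the factor (green edges in the classic
layout), genes up are *repressed*. Graphs export to SIF, GraphML and
node-link JSON.

**Enrichment.** Hypergeometric upper-tail tests per annotation term with
fold enrichment `(k/n)/(K/N)`, BH filtering and fold-enrichment ranking,
with the top-3000-by-fold-change rule for oversized gene lists and an
optional EASE-style conservative variant.

## Worked example

```python
from soxgrn import SyntheticConfig, generate, run_pipeline, score_against_truth
from soxgrn.motif_dimer import dimer_fraction_and_spacers
from soxgrn.peak_annotation import class_distribution

ds = generate(SyntheticConfig(seed=0))          # synthetic study with planted truth
res = run_pipeline(ds)                          # DE -> annotate -> targets -> GRN
m = score_against_truth(res, ds)

print(len(res.de_sets["sox9"].table))           # DE genes, Sox9-null design
fractions, _ = class_distribution(res.annotations["Sox9"])
summary = dimer_fraction_and_spacers(ds.peaks["Sox9"], ds.genome, ds.pwm)
```

Output for seed 0:

```
DE genes (Sox9-null design):  63
DE genes (Sox5/6-null):       336
Sox9 direct targets:          49
Sox9 peak classes:            {'TSS': 0.29, 'PROMOTER': 0.21, 'INTRAGENIC': 0.31, 'PROXIMAL': 0.12, 'DISTAL': 0.06}
peaks with inverted dimer:    0.70 (modal spacer 4 bp)
trio targets recovered:       4 of 21 planted
GRN edges: 321   precision 1.00   recall 0.54   sign accuracy 1.00
```

Reading this: the dimer scan recovers the planted 70% planting rate and
4 bp modal spacer exactly, the positional classes match the planted mix,
and every recovered edge is correct (precision and sign accuracy 1.0).
Recall is limited by t-test power: a 2-fold effect with 0.25 log2 noise at
n = 3 vs 3 gives raw p-values around 10⁻², most of which cannot survive BH
correction across a 2,000-probe array — see `docs/methods.md`. In the
noise-free limit (`noise_sd_log2=0`) the pipeline recovers the planted
network and the 21-gene trio set exactly.

The same steps are available from a shell via the `soxgrn` command
(`soxgrn simulate`, `diffexpr`, `annotate`, `motif`, `targets`, `enrich`,
`grn`); each subcommand consumes and emits the standard formats (GTF,
narrowPeak, FASTA, JASPAR, TSV).

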