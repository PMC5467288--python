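"""Synthetic inputs with planted ground truth for the whole pipeline.

The generator emulates the study design that the pipeline analyses: a trio
of transcription factors (Sox9, Sox5, Sox6) profiled by ChIP-seq in a
knockout-vs-control two-array layout (one single-knockout design for the
first factor, one double-knockout design shared by the other two). It
produces a uniform-background genome, non-overlapping gene models, peak
sets whose summit-TSS distances realize a configurable positional-class
mix, summit windows carrying embedded inverted motif dimers at a chosen
spacer, probe-level expression matrices with planted log2 fold changes and
lognormal noise, a term-annotation map with one enriched term planted over
direct targets, and a ground-truth table of direct targets, edge signs,
trio genes and planted dimer spacers.

Geometry: each gene owns one fixed-size block; its TSS sits at the block
centre and all of its peaks are planted within the block. The block is
sized so that a peak is always nearest (by TSS) to its own gene, making the
planted target table exactly recoverable in the noise-free limit.

Everything is driven by one :class:`numpy.random.Generator` seeded from the
config, so equal seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .diffexpr import ExpressionMatrix
from .enrichment import AnnotationMap
from .genome_model import (
    GeneModel,
    GenomeSequence,
    Peak,
    write_fasta,
    write_gene_models,
    write_peaks,
)
from .motif_dimer import PWM, encode, reverse_complement, write_jaspar
from .peak_annotation import PositionClass

_CODE_TO_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_CLASS_MIX = {
    "TSS": 0.30,
    "PROMOTER": 0.20,
    "INTRAGENIC": 0.30,
    "PROXIMAL": 0.10,
    "DISTAL": 0.10,
    "OTHER": 0.0,
}

# maximum |summit - TSS| the per-class distance samplers can produce
_CLASS_MAX_DIST = {
    "TSS": 1000,
    "PROMOTER": 5000,
    "PROXIMAL": 10000,
    "DISTAL": 25000,
    "OTHER": 140000,
}


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_chroms: int = 5
    n_genes: int = 1000
    gene_length: int = 10000
    chrom_length: int | None = None  # derived from the block geometry when None
    factors: tuple[str, ...] = ("Sox9", "Sox5", "Sox6")
    peaks_per_factor: int = 250
    planted_direct_fraction: float = 0.2
    trio_size: int = 21
    n_indirect: int = 100
    effect_log2fc: float = 1.0
    noise_sd_log2: float = 0.25
    samples_per_group: int = 3
    probes_per_gene: tuple[int, int] = (1, 3)
    absent_rate: float = 0.02
    marginal_rate: float = 0.02
    dimer_planting_rate: float = 0.7
    planted_spacer: int = 4
    motif_consensus: str = "AACAATG"
    peak_halfwidth: int = 150
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    planted_term_coverage: float = 0.8
    planted_term_background_rate: float = 0.02
    n_random_terms: int = 20

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.class_mix.values()), 1.0):
            raise ValueError("class_mix must sum to 1")
        unknown = set(self.class_mix) - {c.value for c in PositionClass}
        if unknown:
            raise ValueError(f"unknown position classes in class_mix: {sorted(unknown)}")
        for name in ("n_chroms", "n_genes", "gene_length", "peaks_per_factor",
                     "samples_per_group", "trio_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("planted_direct_fraction", "dimer_planting_rate", "absent_rate",
                     "marginal_rate", "planted_term_coverage"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.gene_length < 1203:
            raise ValueError("gene_length too short for intragenic planting")
        if self.planted_spacer < 0:
            raise ValueError("planted_spacer must be >= 0")

    @property
    def n_targets_per_factor(self) -> int:
        return int(round(self.planted_direct_fraction * self.n_genes))

    @property
    def designs(self) -> tuple[str, str]:
        first = self.factors[0].lower()
        second = "_".join(f.lower() for f in self.factors[1:])
        return first, second

    def design_of_factor(self, factor: str) -> str:
        return self.designs[0] if factor == self.factors[0] else self.designs[1]

    @property
    def block_halfwidth(self) -> int:
        max_d = max(
            (_CLASS_MAX_DIST.get(c, self.gene_length) for c, w in self.class_mix.items() if w > 0),
            default=1000,
        )
        return max(max_d, self.gene_length - 1) + self.gene_length + 2000

    @property
    def block_size(self) -> int:
        return 2 * self.block_halfwidth


@dataclass
class GroundTruth:
    """Planted regulatory truth, keyed exactly like the pipeline's outputs."""

    direct_targets: dict[str, dict[str, str]]  # factor -> gene -> DE direction
    trio_set: frozenset[str]
    de_genes: dict[str, dict[str, str]]  # design -> gene -> DE direction
    dimer_spacers: dict[str, int]  # peak_id -> planted spacer
    peak_gene: dict[str, tuple[str, str]]  # peak_id -> (gene_id, planted class)
    design_of_factor: dict[str, str]
    enriched_term: str

    def edges(self) -> set[tuple[str, str, str]]:
        """(factor, gene, sign): gene down in the knockout => activated by the factor."""
        out = set()
        for factor, genes in self.direct_targets.items():
            for gene, direction in genes.items():
                sign = "activated" if direction == "down" else "repressed"
                out.add((factor, gene, sign))
        return out

    def to_json(self) -> dict:
        return {
            "direct_targets": self.direct_targets,
            "trio_set": sorted(self.trio_set),
            "de_genes": self.de_genes,
            "dimer_spacers": self.dimer_spacers,
            "peak_gene": {k: list(v) for k, v in self.peak_gene.items()},
            "design_of_factor": self.design_of_factor,
            "enriched_term": self.enriched_term,
        }


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: GenomeSequence
    genes: list[GeneModel]
    peaks: dict[str, list[Peak]]
    expression: dict[str, ExpressionMatrix]
    probe_gene_map: dict[str, str]
    annotation: AnnotationMap
    pwm: PWM
    truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        """Emit the exact file formats the pipeline consumes, plus truth.json."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, out / "genome.fa")
        write_gene_models(self.genes, out / "genes.gtf", format="gtf")
        for factor, plist in self.peaks.items():
            write_peaks(plist, out / f"peaks_{factor}.narrowPeak", format="narrowpeak")
        for design, mat in self.expression.items():
            mat.values.to_csv(out / f"expr_{design}_values.tsv", sep="\t", index_label="probe_id")
            mat.flags.to_csv(out / f"expr_{design}_flags.tsv", sep="\t", index_label="probe_id")
            mat.groups.rename("group").to_csv(
                out / f"expr_{design}_samples.tsv", sep="\t", index_label="sample_id"
            )
        pd.Series(self.probe_gene_map, name="gene_id").to_csv(
            out / "probe_map.tsv", sep="\t", index_label="probe_id"
        )
        with open(out / "annotation.tsv", "w") as fh:
            for term_id in sorted(self.annotation.terms):
                for gene in sorted(self.annotation.terms[term_id]):
                    fh.write(f"{gene}\t{term_id}\n")
        with open(out / "background.txt", "w") as fh:
            for gene in sorted(self.annotation.background):
                fh.write(gene + "\n")
        write_jaspar(self.pwm, out / "motif.jaspar")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth.to_json(), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _sample_distance(rng: np.random.Generator, cls: str, gene_length: int) -> int:
    """Strand-oriented summit-TSS distance realizing a positional class."""
    if cls == "TSS":
        return int(rng.integers(-1000, 1001))
    if cls == "PROMOTER":
        return int(rng.integers(-5000, -1000))
    if cls == "INTRAGENIC":
        return int(rng.integers(1001, gene_length - 1))
    if cls == "PROXIMAL":
        return int(rng.integers(-10000, -5000))
    if cls == "DISTAL":
        if rng.random() < 0.5:
            return int(rng.integers(-25000, -10000))
        low = max(gene_length, 10001)
        if low >= 25001:
            return int(rng.integers(-25000, -10000))
        return int(rng.integers(low, 25001))
    if cls == "OTHER":
        sign = -1 if rng.random() < 0.5 else 1
        return sign * int(rng.integers(100001, 140001))
    raise ValueError(f"unknown class {cls}")


def _concrete_word(rng: np.random.Generator, consensus: str) -> str:
    from .motif_dimer import _IUPAC  # letter -> base set mapping (inverted below)

    rev = {v: sorted(k) for k, v in _IUPAC.items()}
    return "".join(rng.choice(rev[letter]) for letter in consensus.upper())


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset with ground truth (see module docs)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    block = cfg.block_size
    half = cfg.block_halfwidth

    # --- gene placement: one block per gene, TSS at the block centre
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    chrom_lengths = {}
    genes: list[GeneModel] = []
    gene_by_id: dict[str, GeneModel] = {}
    gid = 0
    for chrom, n_on_chrom in zip(chrom_names, per_chrom):
        needed = max(n_on_chrom, 1) * block
        length = cfg.chrom_length if cfg.chrom_length is not None else needed
        if length < needed:
            raise ValueError(
                f"infeasible placement: {n_on_chrom} gene blocks of {block} bp "
                f"do not fit in chrom_length {length}"
            )
        chrom_lengths[chrom] = length
        for slot in range(n_on_chrom):
            tss = slot * block + half
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                start, end = tss, tss + cfg.gene_length
            else:
                start, end = tss + 1 - cfg.gene_length, tss + 1
            g = GeneModel(f"g{gid:04d}", chrom, start, end, strand)
            genes.append(g)
            gene_by_id[g.gene_id] = g
            gid += 1

    # --- role assignment: trio, per-factor unique targets, indirect DE, leftovers
    n_targets = cfg.n_targets_per_factor
    if cfg.trio_size > n_targets:
        raise ValueError("trio_size exceeds the number of direct targets per factor")
    unique_per_factor = n_targets - cfg.trio_size
    need = cfg.trio_size + len(cfg.factors) * unique_per_factor + 2 * cfg.n_indirect
    if need > cfg.n_genes:
        raise ValueError(
            f"role assignment needs {need} genes but only {cfg.n_genes} available"
        )
    perm = list(rng.permutation([g.gene_id for g in genes]))
    pos = 0
    trio = frozenset(perm[pos : pos + cfg.trio_size]); pos += cfg.trio_size
    targets: dict[str, set[str]] = {}
    for factor in cfg.factors:
        targets[factor] = set(trio) | set(perm[pos : pos + unique_per_factor])
        pos += unique_per_factor
    indirect_first = set(perm[pos : pos + cfg.n_indirect]); pos += cfg.n_indirect
    indirect_second = set(perm[pos : pos + cfg.n_indirect]); pos += cfg.n_indirect
    leftover = sorted(perm[pos:])

    # --- DE truth per design: one shift sign per (design, gene)
    design_first, design_second = cfg.designs
    de_genes: dict[str, dict[str, str]] = {design_first: {}, design_second: {}}
    for gene in sorted(targets[cfg.factors[0]] | indirect_first):
        de_genes[design_first][gene] = "up" if rng.random() < 0.5 else "down"
    second_union = set().union(*(targets[f] for f in cfg.factors[1:])) | indirect_second
    for gene in sorted(second_union):
        de_genes[design_second][gene] = "up" if rng.random() < 0.5 else "down"
    direct_targets = {
        factor: {g: de_genes[cfg.design_of_factor(factor)][g] for g in sorted(targets[factor])}
        for factor in cfg.factors
    }

    # --- peaks: one per target gene, plus background peaks near non-DE genes
    classes = sorted(c for c, w in cfg.class_mix.items() if w > 0)
    weights = np.array([cfg.class_mix[c] for c in classes])
    weights = weights / weights.sum()
    n_bg = cfg.peaks_per_factor - n_targets
    if n_bg < 0:
        raise ValueError("peaks_per_factor must be >= the number of direct targets")
    if n_bg > len(leftover):
        raise ValueError("not enough non-DE genes to host background peaks")
    peaks: dict[str, list[Peak]] = {}
    peak_gene: dict[str, tuple[str, str]] = {}
    for factor in cfg.factors:
        bg_genes = list(rng.choice(leftover, size=n_bg, replace=False)) if n_bg else []
        host_genes = sorted(targets[factor]) + bg_genes
        plist = []
        for i, gene_id in enumerate(host_genes):
            g = gene_by_id[gene_id]
            cls = str(rng.choice(classes, p=weights))
            d = _sample_distance(rng, cls, cfg.gene_length)
            summit = g.tss + d if g.strand == "+" else g.tss - d
            score = float(int(rng.lognormal(5.0, 1.0)) + 5)
            pk = Peak(
                peak_id=f"{factor}_p{i:04d}",
                factor=factor,
                chrom=g.chrom,
                start=summit - cfg.peak_halfwidth,
                end=summit + cfg.peak_halfwidth + 1,
                summit=summit,
                score=score,
            )
            plist.append(pk)
            peak_gene[pk.peak_id] = (gene_id, cls)
        peaks[factor] = plist

    # --- genome with planted inverted dimers in summit windows
    chrom_codes = {
        c: rng.integers(0, 4, size=chrom_lengths[c], dtype=np.int8) for c in chrom_names
    }
    pwm = PWM.from_consensus(cfg.motif_consensus, name=cfg.motif_consensus)
    L = pwm.length
    arrangement = 2 * L + cfg.planted_spacer
    window = 101  # +/-50 bp summit window, matching the scanning convention
    if arrangement > window:
        raise ValueError("planted dimer does not fit in the 101 bp summit window")
    dimer_spacers: dict[str, int] = {}
    for factor in cfg.factors:
        plist = peaks[factor]
        n_plant = int(round(cfg.dimer_planting_rate * len(plist)))
        chosen = rng.choice(len(plist), size=n_plant, replace=False) if n_plant else []
        for idx in sorted(int(i) for i in chosen):
            pk = plist[idx]
            word = _concrete_word(rng, cfg.motif_consensus)
            offset = int(rng.integers(0, window - arrangement + 1))
            left = pk.summit - 50 + offset
            codes = chrom_codes[pk.chrom]
            codes[left : left + L] = encode(word)
            codes[left + L + cfg.planted_spacer : left + arrangement] = encode(
                reverse_complement(word)
            )
            dimer_spacers[pk.peak_id] = cfg.planted_spacer
    genome = GenomeSequence(
        {c: _CODE_TO_ASCII[chrom_codes[c]].tobytes().decode("ascii") for c in chrom_names}
    )

    # --- expression: probe-level, 1-3 probes per gene, two knockout designs
    gene_ids = [g.gene_id for g in genes]
    lo, hi = cfg.probes_per_gene
    probes_of: dict[str, list[str]] = {}
    probe_gene_map: dict[str, str] = {}
    for gene in gene_ids:
        k = int(rng.integers(lo, hi + 1))
        ids = [f"{gene}.p{j}" for j in range(k)]
        probes_of[gene] = ids
        for pid in ids:
            probe_gene_map[pid] = gene
    probe_ids = [pid for gene in gene_ids for pid in probes_of[gene]]
    mu = rng.uniform(6.0, 12.0, size=len(probe_ids))
    shift_sign = {"up": 1.0, "down": -1.0}
    expression: dict[str, ExpressionMatrix] = {}
    for design in (design_first, design_second):
        shift = np.array(
            [
                shift_sign.get(de_genes[design].get(probe_gene_map[pid], ""), 0.0)
                * cfg.effect_log2fc
                for pid in probe_ids
            ]
        )
        n_s = cfg.samples_per_group
        noise = rng.normal(0.0, cfg.noise_sd_log2, size=(len(probe_ids), 2 * n_s))
        log_means = np.concatenate(
            [np.tile(mu[:, None], (1, n_s)), np.tile((mu + shift)[:, None], (1, n_s))], axis=1
        )
        values = 2.0 ** (log_means + noise)
        sample_ids = [f"{design}_wt{i}" for i in range(n_s)] + [
            f"{design}_ko{i}" for i in range(n_s)
        ]
        groups = pd.Series(["control"] * n_s + ["knockout"] * n_s, index=sample_ids)
        p_present = 1.0 - cfg.absent_rate - cfg.marginal_rate
        flags = rng.choice(
            ["present", "marginal", "absent"],
            size=values.shape,
            p=[p_present, cfg.marginal_rate, cfg.absent_rate],
        )
        expression[design] = ExpressionMatrix(
            pd.DataFrame(values, index=probe_ids, columns=sample_ids),
            pd.DataFrame(flags, index=probe_ids, columns=sample_ids),
            groups,
        )

    # --- annotation map with one planted enriched term
    planted_term = "TERM:planted"
    first_targets = sorted(targets[cfg.factors[0]])
    n_cov = int(round(cfg.planted_term_coverage * len(first_targets)))
    covered = set(rng.choice(first_targets, size=n_cov, replace=False)) if n_cov else set()
    non_targets = sorted(set(gene_ids) - set(first_targets))
    n_noise = int(round(cfg.planted_term_background_rate * len(non_targets)))
    covered |= set(rng.choice(non_targets, size=n_noise, replace=False)) if n_noise else set()
    terms = {planted_term: frozenset(covered)}
    term_names = {planted_term: "cartilage development (planted)"}
    size_lo = min(20, len(gene_ids))
    size_hi = min(100, len(gene_ids))
    for t in range(cfg.n_random_terms):
        size = int(rng.integers(size_lo, size_hi + 1))
        term_id = f"TERM:rand{t:02d}"
        terms[term_id] = frozenset(rng.choice(gene_ids, size=size, replace=False))
        term_names[term_id] = f"random process {t}"
    annotation = AnnotationMap(terms, frozenset(gene_ids), term_names)

    truth = GroundTruth(
        direct_targets=direct_targets,
        trio_set=trio,
        de_genes=de_genes,
        dimer_spacers=dimer_spacers,
        peak_gene=peak_gene,
        design_of_factor={f: cfg.design_of_factor(f) for f in cfg.factors},
        enriched_term=planted_term,
    )
    return SyntheticDataset(
        config=cfg,
        genome=genome,
        genes=genes,
        peaks=peaks,
        expression=expression,
        probe_gene_map=probe_gene_map,
        annotation=annotation,
        pwm=pwm,
        truth=truth,
    )


def generate_dimer_windows(
    n_windows: int = 500,
    planting_rate: float = 0.7,
    spacer: int = 4,
    halfwidth: int = 50,
    seed: int = 0,
    consensus: str = "AACAATG",
) -> tuple[GenomeSequence, list[Peak], dict[str, int], PWM]:
    """Standalone summit windows with inverted dimers planted at a fixed spacer.

    Each window is its own little chromosome with the peak summit at the
    centre; a fraction ``planting_rate`` of windows receives the motif and
    its reverse complement separated by ``spacer`` background bases.
    Returns (genome, peaks, planted spacers by peak id, planting PWM).
    """
    rng = np.random.default_rng(seed)
    pwm = PWM.from_consensus(consensus, name=consensus)
    L = pwm.length
    width = 2 * halfwidth + 1
    arrangement = 2 * L + spacer
    if arrangement > width:
        raise ValueError("dimer arrangement does not fit in the window")
    n_plant = int(round(planting_rate * n_windows))
    plant_idx = set(int(i) for i in rng.choice(n_windows, size=n_plant, replace=False))
    seqs: dict[str, str] = {}
    peaks: list[Peak] = []
    planted: dict[str, int] = {}
    for i in range(n_windows):
        codes = rng.integers(0, 4, size=width, dtype=np.int8)
        name = f"w{i:04d}"
        if i in plant_idx:
            word = _concrete_word(rng, consensus)
            offset = int(rng.integers(0, width - arrangement + 1))
            codes[offset : offset + L] = encode(word)
            codes[offset + L + spacer : offset + arrangement] = encode(reverse_complement(word))
            planted[name] = spacer
        seqs[name] = _CODE_TO_ASCII[codes].tobytes().decode("ascii")
        peaks.append(Peak(name, "Sox9", name, 0, width, halfwidth, 1.0))
    return GenomeSequence(seqs), peaks, planted, pwm


# ---------------------------------------------------------------------------
# Recovery metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryMetrics:
    precision: float
    recall: float
    sign_accuracy: float
    n_called: int
    n_truth: int
    zero_calls: bool


def evaluate_recovery(
    called: Mapping[str, str] | Iterable[str],
    truth: Mapping[str, str] | Iterable[str],
) -> RecoveryMetrics:
    """Set-overlap precision/recall plus sign accuracy over true positives.

    ``called`` and ``truth`` may be plain gene collections or gene->sign
    mappings; sign accuracy is computed over true positives where both sides
    carry signs (1.0 when there is nothing to compare). An empty call set
    reports precision 1.0 with ``zero_calls`` set.
    """
    called_signs = dict(called) if isinstance(called, Mapping) else {g: None for g in called}
    truth_signs = dict(truth) if isinstance(truth, Mapping) else {g: None for g in truth}
    called_set, truth_set = set(called_signs), set(truth_signs)
    tp = called_set & truth_set
    zero_calls = len(called_set) == 0
    precision = 1.0 if zero_calls else len(tp) / len(called_set)
    recall = 1.0 if not truth_set else len(tp) / len(truth_set)
    comparable = [g for g in tp if called_signs[g] is not None and truth_signs[g] is not None]
    sign_accuracy = (
        sum(called_signs[g] == truth_signs[g] for g in comparable) / len(comparable)
        if comparable
        else 1.0
    )
    return RecoveryMetrics(
        precision=precision,
        recall=recall,
        sign_accuracy=sign_accuracy,
        n_called=len(called_set),
        n_truth=len(truth_set),
        zero_calls=zero_calls,
    )
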