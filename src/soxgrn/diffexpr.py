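"""Knockout-vs-control microarray differential expression.

The analysis mirrors the standard two-colour-free array workflow: log2
transform, 75th-percentile shift normalization per sample, detection-flag
filtering (probes kept when flagged present or marginal in enough samples),
an unpaired t-test per probe (Welch by default), Benjamini-Hochberg FDR
correction, and gene-level calls at adjusted p <= 0.05 with a minimum linear
fold change of 1.5.

Fold change is reported on the linear scale as ``2**|log2fc|`` together with
a direction label (``down`` iff the knockout mean is below the control mean),
so the 1.5 cutoff applies symmetrically to up- and down-regulation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

FLAG_VALUES = ("present", "marginal", "absent")
_FLAG_ALIASES = {"p": "present", "m": "marginal", "a": "absent"}

CONTROL = "control"
KNOCKOUT = "knockout"


def _canon_flag(x: str) -> str:
    x = str(x).strip().lower()
    x = _FLAG_ALIASES.get(x, x)
    if x not in FLAG_VALUES:
        raise ValueError(f"invalid detection flag {x!r}")
    return x


@dataclass
class ExpressionMatrix:
    """Probe x sample intensities with detection flags and group labels.

    ``values`` and ``flags`` share index (probe ids) and columns (sample
    ids); ``groups`` maps each sample id to 'control' or 'knockout'.
    """

    values: pd.DataFrame
    flags: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.flags.index) or not self.values.columns.equals(
            self.flags.columns
        ):
            raise ValueError("values and flags must share probes and samples")
        if set(self.groups.index) != set(self.values.columns):
            raise ValueError("groups must label exactly the sample columns")
        bad = set(self.groups) - {CONTROL, KNOCKOUT}
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("intensities must be finite")
        self.flags = self.flags.map(_canon_flag)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    @property
    def n_probes(self) -> int:
        return len(self.values)


def read_expression(
    values_path: str | Path, flags_path: str | Path, samples_path: str | Path
) -> ExpressionMatrix:
    """Read an expression matrix from TSV files.

    ``values``/``flags``: first column probe_id, remaining columns one per
    sample. ``samples``: two columns, sample_id and group.
    """
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    flags = pd.read_csv(flags_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t")
    groups = pd.Series(samples.iloc[:, 1].values, index=samples.iloc[:, 0].values)
    return ExpressionMatrix(values, flags, groups)


def read_probe_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=0)
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


# ---------------------------------------------------------------------------
# Normalization and filtering
# ---------------------------------------------------------------------------

def normalize(matrix: ExpressionMatrix, floor: float | None = 1.0) -> ExpressionMatrix:
    """log2-transform and shift each sample by its 75th log2 percentile.

    After normalization the per-sample 75th percentile is 0. Intensities are
    clipped at ``floor`` before the log; with ``floor=None`` any non-positive
    value is an error.
    """
    vals = matrix.values.to_numpy(dtype=float)
    if floor is None:
        if (vals <= 0).any():
            raise ValueError("non-positive intensity with floor disabled")
    else:
        vals = np.maximum(vals, floor)
    logv = np.log2(vals)
    shifted = logv - np.quantile(logv, 0.75, axis=0, keepdims=True)
    out = pd.DataFrame(shifted, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(out, matrix.flags.copy(), matrix.groups.copy())


def filter_flags(
    matrix: ExpressionMatrix, min_informative: int = 1
) -> tuple[ExpressionMatrix, list[str]]:
    """Keep probes flagged present or marginal in >= ``min_informative`` samples.

    Returns the filtered matrix and the list of removed probe ids.
    """
    informative = matrix.flags.isin(["present", "marginal"]).sum(axis=1)
    keep = informative >= min_informative
    removed = list(matrix.values.index[~keep])
    if removed:
        logger.info("flag filter removed %d/%d probes", len(removed), matrix.n_probes)
    filtered = ExpressionMatrix(
        matrix.values.loc[keep], matrix.flags.loc[keep], matrix.groups.copy()
    )
    return filtered, removed


# ---------------------------------------------------------------------------
# Testing
# ---------------------------------------------------------------------------

def welch_or_student_t(matrix: ExpressionMatrix, equal_var: bool = False) -> pd.DataFrame:
    """Per-probe two-sided unpaired t-test of knockout vs control.

    Returns a DataFrame (probe index) with ``t_stat``, ``p_raw``,
    ``mean_knockout``, ``mean_control`` and ``log2fc`` (knockout - control on
    the normalized log2 scale). Degenerate probes with zero variance in both
    groups get p=1 when the group means are equal and p=0 otherwise (the
    latter are counted and logged).
    """
    ko_cols = matrix.samples_in(KNOCKOUT)
    ctrl_cols = matrix.samples_in(CONTROL)
    if len(ko_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {len(ko_cols)} knockout / {len(ctrl_cols)} control"
        )
    ko = matrix.values[ko_cols].to_numpy(dtype=float)
    ctrl = matrix.values[ctrl_cols].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, p_raw = stats.ttest_ind(ko, ctrl, axis=1, equal_var=equal_var)
    mean_ko = ko.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)
    zero_var = (ko.var(axis=1) == 0) & (ctrl.var(axis=1) == 0)
    equal_means = np.isclose(mean_ko, mean_ctrl)
    deg_equal = zero_var & equal_means
    deg_diff = zero_var & ~equal_means
    t_stat = np.where(deg_equal, 0.0, t_stat)
    p_raw = np.where(deg_equal, 1.0, p_raw)
    with np.errstate(invalid="ignore"):
        t_stat = np.where(deg_diff, np.sign(mean_ko - mean_ctrl) * np.inf, t_stat)
    p_raw = np.where(deg_diff, 0.0, p_raw)
    if deg_diff.any():
        logger.warning(
            "%d probes with zero within-group variance and unequal means (p set to 0)",
            int(deg_diff.sum()),
        )
    return pd.DataFrame(
        {
            "t_stat": t_stat,
            "p_raw": p_raw,
            "mean_knockout": mean_ko,
            "mean_control": mean_ctrl,
            "log2fc": mean_ko - mean_ctrl,
        },
        index=matrix.values.index,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order restored."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def diffexpr_records(matrix: ExpressionMatrix, equal_var: bool = False) -> pd.DataFrame:
    """t-test + BH on a normalized, flag-filtered matrix.

    Adds ``p_adj``, linear ``fold_change`` (>= 1) and ``direction`` columns
    to the per-probe test table.
    """
    rec = welch_or_student_t(matrix, equal_var=equal_var)
    rec["p_adj"] = bh_adjust(rec["p_raw"].to_numpy())
    rec["fold_change"] = 2.0 ** rec["log2fc"].abs()
    rec["direction"] = np.where(rec["log2fc"] < 0, "down", "up")
    return rec


# ---------------------------------------------------------------------------
# Gene-level calls
# ---------------------------------------------------------------------------

@dataclass
class DEGeneSet:
    """Gene-level differential-expression calls.

    ``table`` is indexed by gene_id with columns ``direction``,
    ``fold_change``, ``log2fc``, ``n_probes_passing`` and ``conflict``
    (passing probes disagree in direction). A gene appears at most once.
    """

    table: pd.DataFrame
    n_unmapped_probes: int = 0
    label: str = ""

    @property
    def genes(self) -> set[str]:
        return set(self.table.index)

    def direction_of(self, gene_id: str) -> str:
        return str(self.table.loc[gene_id, "direction"])

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def read(cls, path: str | Path, label: str = "") -> "DEGeneSet":
        return cls(pd.read_csv(path, sep="\t", index_col="gene_id"), label=label)


def call_de_genes(
    records: pd.DataFrame,
    probe_gene_map: Mapping[str, str],
    fc_min: float = 1.5,
    p_max: float = 0.05,
    label: str = "",
) -> DEGeneSet:
    """Collapse per-probe statistics to gene-level DE calls.

    A probe passes iff ``p_adj <= p_max`` and ``fold_change >= fc_min``; a
    gene is DE iff at least one mapped probe passes. The gene direction is
    that of the passing probe with the largest ``|log2fc|`` (ties resolved to
    'up'); genes whose passing probes disagree in direction are flagged as
    conflicts, not dropped. Unmapped probes are excluded and counted.
    """
    rec = records.copy()
    rec["gene_id"] = [probe_gene_map.get(str(p)) for p in rec.index]
    n_unmapped = int(rec["gene_id"].isna().sum())
    if n_unmapped:
        logger.info("%d probes without gene mapping excluded", n_unmapped)
    rec = rec.dropna(subset=["gene_id"])
    passing = rec[(rec["p_adj"] <= p_max) & (rec["fold_change"] >= fc_min)]
    rows = []
    for gene_id, grp in passing.groupby("gene_id", sort=True):
        # best probe: largest |log2fc|, ties resolved toward 'up'
        order = grp.assign(
            _abs=grp["log2fc"].abs(), _up=(grp["direction"] == "up").astype(int)
        ).sort_values(["_abs", "_up"], ascending=False)
        best = order.iloc[0]
        rows.append(
            {
                "gene_id": gene_id,
                "direction": best["direction"],
                "fold_change": float(grp["fold_change"].max()),
                "log2fc": float(best["log2fc"]),
                "n_probes_passing": len(grp),
                "conflict": grp["direction"].nunique() > 1,
            }
        )
    table = pd.DataFrame(
        rows, columns=["gene_id", "direction", "fold_change", "log2fc", "n_probes_passing", "conflict"]
    ).set_index("gene_id")
    return DEGeneSet(table, n_unmapped_probes=n_unmapped, label=label)


def run_diffexpr(
    matrix: ExpressionMatrix,
    probe_gene_map: Mapping[str, str],
    fc_min: float = 1.5,
    p_max: float = 0.05,
    min_informative: int = 1,
    equal_var: bool = False,
    floor: float | None = 1.0,
    label: str = "",
) -> tuple[DEGeneSet, pd.DataFrame]:
    """Full workflow: normalize, flag-filter, test, adjust, call genes."""
    norm = normalize(matrix, floor=floor)
    filtered, _removed = filter_flags(norm, min_informative=min_informative)
    rec = diffexpr_records(filtered, equal_var=equal_var)
    de = call_de_genes(rec, probe_gene_map, fc_min=fc_min, p_max=p_max, label=label)
    return de, rec
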