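"""Normalization, flag filtering, t-tests, BH correction and gene calls."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from soxgrn.diffexpr import (
    ExpressionMatrix,
    bh_adjust,
    call_de_genes,
    filter_flags,
    normalize,
    welch_or_student_t,
)


def make_matrix(values, flags=None, n_ctrl=None):
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    n_ctrl = n_ctrl if n_ctrl is not None else n_samples // 2
    samples = [f"s{i}" for i in range(n_samples)]
    groups = pd.Series(
        ["control"] * n_ctrl + ["knockout"] * (n_samples - n_ctrl), index=samples
    )
    if flags is None:
        flags = np.full(values.shape, "present")
    return ExpressionMatrix(
        pd.DataFrame(values, index=[f"pr{i}" for i in range(n_probes)], columns=samples),
        pd.DataFrame(np.asarray(flags), index=[f"pr{i}" for i in range(n_probes)], columns=samples),
        groups,
    )


class TestNormalize:
    def test_seventy_fifth_percentile_becomes_zero(self):
        m = make_matrix(2.0 ** np.array([[1, 5], [2, 6], [3, 7], [4, 8]], dtype=float))
        norm = normalize(m)
        q75 = np.quantile(norm.values.to_numpy(), 0.75, axis=0)
        assert np.allclose(q75, 0.0, atol=1e-12)

    def test_identical_samples_stay_identical(self):
        col = 2.0 ** np.arange(1, 6)
        m = make_matrix(np.tile(col[:, None], (1, 4)))
        norm = normalize(m).values.to_numpy()
        assert np.allclose(norm, norm[:, [0]])

    def test_single_probe_maps_to_zero(self):
        m = make_matrix([[8.0, 16.0, 4.0, 2.0]])
        assert np.allclose(normalize(m).values.to_numpy(), 0.0)

    def test_nonpositive_without_floor_errors(self):
        m = make_matrix([[1.0, 0.0], [2.0, 3.0]])
        with pytest.raises(ValueError, match="non-positive"):
            normalize(m, floor=None)


class TestFilterFlags:
    def test_all_absent_probe_removed_and_reported(self):
        m = make_matrix(
            np.ones((3, 4)),
            flags=[
                ["absent"] * 4,
                ["present", "absent", "absent", "absent"],
                ["marginal"] * 4,
            ],
        )
        filtered, removed = filter_flags(m, min_informative=1)
        assert removed == ["pr0"]
        assert list(filtered.values.index) == ["pr1", "pr2"]

    def test_marginal_everywhere_survives_strict_threshold(self):
        m = make_matrix(np.ones((1, 4)), flags=[["marginal"] * 4])
        filtered, removed = filter_flags(m, min_informative=4)
        assert not removed and len(filtered.values) == 1


class TestTTest:
    def test_identical_groups_with_nonzero_variance_give_p_one(self):
        m = make_matrix(np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]]))
        rec = welch_or_student_t(m)
        assert rec["p_raw"].iloc[0] == pytest.approx(1.0)
        assert rec["t_stat"].iloc[0] == pytest.approx(0.0)

    def test_zero_variance_degenerate_rules(self):
        flat = make_matrix(np.full((1, 6), 5.0))
        rec = welch_or_student_t(flat)
        assert rec["p_raw"].iloc[0] == 1.0 and rec["t_stat"].iloc[0] == 0.0
        shifted = make_matrix(np.array([[1.0] * 3 + [2.0] * 3]))
        rec = welch_or_student_t(shifted)
        assert rec["p_raw"].iloc[0] == 0.0 and np.isinf(rec["t_stat"].iloc[0])

    def test_too_few_samples_rejected(self):
        m = make_matrix(np.ones((2, 3)), n_ctrl=1)
        with pytest.raises(ValueError, match="2 samples"):
            welch_or_student_t(m)

    def test_planted_shift_detected_and_extreme_under_permutation(self):
        """A 10-sd shift at n=3 vs 3: t-test p < 0.01 and the observed mean
        difference is the most extreme over all 20 relabelings (the exact
        permutation oracle's attainable minimum)."""
        rng = np.random.default_rng(42)
        ctrl = rng.normal(8.0, 1.0, 3)  # log2-scale expression
        ko = rng.normal(18.0, 1.0, 3)
        m = make_matrix(np.concatenate([ctrl, ko])[None, :])
        rec = welch_or_student_t(m)
        assert rec["p_raw"].iloc[0] < 0.01
        values = np.concatenate([ctrl, ko])
        obs = abs(ko.mean() - ctrl.mean())
        diffs = [
            abs(values[list(idx)].mean() - np.delete(values, list(idx)).mean())
            for idx in itertools.combinations(range(6), 3)
        ]
        perm_p = np.mean([d >= obs - 1e-12 for d in diffs])
        assert perm_p == pytest.approx(2 / 20)  # observed split and its mirror


def bh_oracle(p):
    """Hand-applied step-up: p_adj(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


class TestBH:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_fixed_vectors_match_step_up_formula(self, p, expected):
        assert np.allclose(bh_adjust(p), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_matches_oracle_and_is_monotone(self, p):
        adj = bh_adjust(p)
        assert np.allclose(adj, bh_oracle(p))
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-12).all()  # order of p-values preserved

    def test_idempotent_on_flat_adjusted_vector(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(bh_adjust(adj), adj)


def make_records(rows):
    df = pd.DataFrame(rows).set_index("probe_id")
    df["fold_change"] = 2.0 ** df["log2fc"].abs()
    df["direction"] = np.where(df["log2fc"] < 0, "down", "up")
    return df


class TestCallDeGenes:
    def test_fold_change_threshold_blocks_significant_probe(self):
        rec = make_records([{"probe_id": "p1", "log2fc": np.log2(1.2), "p_adj": 0.001}])
        de = call_de_genes(rec, {"p1": "gA"})
        assert de.genes == set()

    def test_strong_down_probe_calls_gene_down(self):
        rec = make_records([{"probe_id": "p1", "log2fc": -2.0, "p_adj": 0.01}])
        de = call_de_genes(rec, {"p1": "gA"})
        assert de.direction_of("gA") == "down"
        assert de.table.loc["gA", "fold_change"] == pytest.approx(4.0)

    def test_conflicting_probes_flagged_and_resolved_up(self):
        rec = make_records(
            [
                {"probe_id": "p1", "log2fc": 1.0, "p_adj": 0.01},
                {"probe_id": "p2", "log2fc": -1.0, "p_adj": 0.01},
            ]
        )
        de = call_de_genes(rec, {"p1": "gA", "p2": "gA"})
        row = de.table.loc["gA"]
        assert bool(row["conflict"]) and row["direction"] == "up"

    def test_unmapped_probes_counted_not_crashing(self):
        rec = make_records([{"probe_id": "p1", "log2fc": 2.0, "p_adj": 0.01}])
        de = call_de_genes(rec, {})
        assert de.n_unmapped_probes == 1 and de.genes == set()
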