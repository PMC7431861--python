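"""LFQ enrichment workflow: reader, preprocessing, statistics, FDR, HCA."""

import io
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import fcluster

from mitochrom import lfq, simulate
from conftest import (
    naive_average_linkage,
    prepared_log_table,
    table_via_tsv,
    textbook_pooled_t,
)

CMAP4 = {
    "LFQ intensity lysate_b1_t1": ("lysate", 1, 1),
    "LFQ intensity lysate_b2_t1": ("lysate", 2, 1),
    "LFQ intensity sorted_b1_t1": ("sorted", 1, 1),
    "LFQ intensity sorted_b2_t1": ("sorted", 2, 1),
}


def tiny_tsv(rows, columns=None):
    columns = columns or (
        ["Protein IDs"] + list(CMAP4) + ["Reverse", "Potential contaminant",
                                         "Only identified by site",
                                         "Razor + unique peptides"]
    )
    buf = io.StringIO()
    pd.DataFrame(rows, columns=columns).to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    return buf


class TestReader:
    def test_reverse_flag_round_trip(self):
        rows = [
            ["P1", 10, 10, 20, 20, "", "", "", 5],
            ["P2", 10, 10, 20, 20, "+", "", "", 5],
            ["P3", 10, 10, 20, 20, "", "", "", 5],
        ]
        table = lfq.read_protein_group_table(tiny_tsv(rows), CMAP4)
        assert table.meta["is_reverse"].tolist() == [False, True, False]

    def test_zero_intensity_becomes_missing(self):
        rows = [["P1", 0, 10, 20, 20, "", "", "", 5]]
        table = lfq.read_protein_group_table(tiny_tsv(rows), CMAP4)
        assert table.intensities.iloc[0].isna().sum() == 1

    def test_empty_file_is_format_error(self):
        with pytest.raises(lfq.FormatError):
            lfq.read_protein_group_table(io.StringIO(""), CMAP4)

    def test_unmapped_intensity_column_is_format_error(self):
        cols = ["Protein IDs"] + list(CMAP4) + ["LFQ intensity extra_run"]
        rows = [["P1", 1, 1, 1, 1, 7]]
        with pytest.raises(lfq.FormatError, match="unmapped"):
            lfq.read_protein_group_table(tiny_tsv(rows, cols), CMAP4)

    def test_duplicate_protein_ids_rejected(self):
        rows = [["P1", 1, 1, 1, 1, "", "", "", 5], ["P1", 2, 2, 2, 2, "", "", "", 5]]
        with pytest.raises(lfq.FormatError, match="duplicate"):
            lfq.read_protein_group_table(tiny_tsv(rows), CMAP4)


class TestFilterAndPreprocess:
    def make_table(self, n=10, n_flagged=3, peptides=5):
        rows = []
        for i in range(n):
            flag = "+" if i < n_flagged else ""
            rows.append([f"P{i}", 8, 8, 16, 16, flag, "", "", peptides])
        return lfq.read_protein_group_table(tiny_tsv(rows), CMAP4)

    def test_flagged_rows_removed(self):
        table = self.make_table(10, 3)
        out = lfq.filter_protein_groups(table, min_peptides=0)
        assert len(out.intensities) == 7

    def test_peptide_threshold(self):
        rows = [["P1", 8, 8, 16, 16, "", "", "", 1],
                ["P2", 8, 8, 16, 16, "", "", "", 2]]
        table = lfq.read_protein_group_table(tiny_tsv(rows), CMAP4)
        out = lfq.filter_protein_groups(table, min_peptides=2)
        assert out.intensities.index.tolist() == ["P2"]

    def test_no_flags_is_identity(self):
        table = self.make_table(6, 0)
        out = lfq.filter_protein_groups(table, min_peptides=0)
        pd.testing.assert_frame_equal(out.intensities, table.intensities)

    def test_averaging_examples(self):
        cmap = {
            "LFQ intensity lysate_b1_t1": ("lysate", 1, 1),
            "LFQ intensity lysate_b1_t2": ("lysate", 1, 2),
            "LFQ intensity sorted_b1_t1": ("sorted", 1, 1),
            "LFQ intensity sorted_b1_t2": ("sorted", 1, 2),
        }
        cols = ["Protein IDs"] + list(cmap)
        rows = [
            ["P1", 4, 6, 5, 0],   # (4,6)->5 ; (5, missing)->5
            ["P2", 0, 0, 3, 3],   # (missing, missing)->missing
        ]
        table = lfq.read_protein_group_table(tiny_tsv(rows, cols), cmap)
        out = lfq.average_technical_replicates(table)
        assert out.intensities.loc["P1", ("lysate", 1)] == 5
        assert out.intensities.loc["P1", ("sorted", 1)] == 5
        assert np.isnan(out.intensities.loc["P2", ("lysate", 1)])

    def test_log2_examples(self):
        rows = [["P1", 8, 1, 2, 0, "", "", "", 5]]
        table = lfq.read_protein_group_table(tiny_tsv(rows), CMAP4)
        out = lfq.log2_transform_table(table)
        vals = out.intensities.loc["P1"]
        assert vals[("lysate", 1, 1)] == 3
        assert vals[("lysate", 2, 1)] == 0
        assert vals[("sorted", 1, 1)] == 1
        assert np.isnan(vals[("sorted", 2, 1)])

    def test_log2_fc_hand_arithmetic(self):
        cmap = {
            f"LFQ intensity {c}_b{b}_t1": (c, b, 1)
            for c in ("lysate", "sorted") for b in (1, 2, 3)
        }
        cols = ["Protein IDs"] + list(cmap)
        # raw intensities chosen so log2 values are integers
        rows = [
            ["E", 4, 4, 4, 8, 8, 8],          # sorted (3,3,3) - lysate (2,2,2) = 1
            ["S", 16, 16, 16, 16, 16, 16],    # equal groups -> 0
            ["H", 2, 4, 8, 16, 32, 64],       # (4,5,6) - (1,2,3) = 3
        ]
        table = lfq.read_protein_group_table(tiny_tsv(rows, cols), cmap)
        log = lfq.log2_transform_table(table)
        assert lfq.compute_log2_fc(log, "E") == pytest.approx(1.0)
        assert lfq.compute_log2_fc(log, "S") == pytest.approx(0.0)
        assert lfq.compute_log2_fc(log, "H") == pytest.approx(3.0)


class TestModeratedStatistic:
    def test_identical_group_means_give_zero(self):
        assert lfq.moderated_t_statistic([2, 3, 4], [4, 3, 2], s0=0.1) == 0.0

    def test_s0_zero_equals_textbook_t_on_random_draws(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.normal(size=rng.integers(3, 8))
            b = rng.normal(size=rng.integers(3, 8))
            d = lfq.moderated_t_statistic(a, b, s0=0.0)
            t, _ = textbook_pooled_t(a, b)
            assert d == pytest.approx(t, rel=1e-12)

    def test_zero_variance_limit_denominator_is_s0(self):
        assert lfq.moderated_t_statistic([2, 2, 2], [0, 0, 0], s0=0.1) == pytest.approx(20.0)

    def test_zero_variance_zero_s0_is_signed_infinity(self):
        assert lfq.moderated_t_statistic([2, 2, 2], [0, 0, 0], s0=0.0) == math.inf
        assert lfq.moderated_t_statistic([0, 0, 0], [2, 2, 2], s0=0.0) == -math.inf

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=4), rng.normal(size=5)
        assert lfq.moderated_t_statistic(a, b, 0.1) == pytest.approx(
            -lfq.moderated_t_statistic(b, a, 0.1)
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_abs_d_nonincreasing_in_s0(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=3), rng.normal(size=3)
        ds = [abs(lfq.moderated_t_statistic(a, b, s0)) for s0 in (0.0, 0.1, 0.5, 2.0)]
        assert all(x >= y - 1e-12 for x, y in zip(ds, ds[1:]))

    def test_insufficient_values_is_nan(self):
        assert math.isnan(lfq.moderated_t_statistic([1.0], [2.0, 3.0], 0.1))


def brute_force_permutation_calls(data_a, data_b, s0, fdr):
    """Fully independent SAM-style permutation-FDR oracle.

    Enumerates every balanced split of the pooled columns (excluding the
    observed labeling and its complement), computes d with the textbook
    pooled-SE formula, and sweeps |d| cutoffs for the largest rejection set
    with estimated FDR <= target.
    """
    def dstat(x, y):
        n1, n2 = len(x), len(y)
        m1, m2 = sum(x) / n1, sum(y) / n2
        ss1 = sum((v - m1) ** 2 for v in x)
        ss2 = sum((v - m2) ** 2 for v in y)
        sp2 = (ss1 + ss2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        if se + s0 == 0:
            return 0.0 if m1 == m2 else math.copysign(math.inf, m1 - m2)
        return (m1 - m2) / (se + s0)

    data = np.hstack([data_a, data_b])
    n_a = data_a.shape[1]
    n_tot = data.shape[1]
    obs = np.array([dstat(row[:n_a], row[n_a:]) for row in data])

    observed_split = frozenset(range(n_a))
    null_by_perm = []
    for combo in itertools.combinations(range(1, n_tot), n_a - 1):
        grp = frozenset((0,) + combo)
        if grp in (observed_split, frozenset(range(n_a, n_tot))):
            continue
        rest = [i for i in range(n_tot) if i not in grp]
        null_by_perm.append(
            [abs(dstat(row[list(grp)], row[rest])) for row in data]
        )
    n_perm = len(null_by_perm)
    null_flat = [v for perm in null_by_perm for v in perm]

    cutoff = None
    for c in sorted(set(abs(obs))):
        n_obs = sum(abs(obs) >= c)
        n_null = sum(v >= c for v in null_flat) / n_perm
        if min(1.0, n_null / max(n_obs, 1)) <= fdr:
            cutoff = c
            break
    if cutoff is None:
        return np.zeros(len(obs), dtype=bool)
    return np.abs(obs) >= cutoff


class TestPermutationFdr:
    def test_exhaustive_matches_independent_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            a = rng.normal(0, 1, size=(20, 3))
            b = rng.normal(0, 1, size=(20, 3))
            a[:3] += 4.0  # a few strong effects
            table = _make_log_table(a, b)
            cfg = lfq.TestConfig(s0=0.1, fdr=0.05, exhaustive=True)
            res = lfq.permutation_fdr_calls(table, cfg)
            expected = brute_force_permutation_calls(a, b, s0=0.1, fdr=0.05)
            np.testing.assert_array_equal(res["significant"].to_numpy(), expected)

    def test_sampled_calls_match_exhaustive(self):
        rng = np.random.default_rng(5)
        mismatches = 0
        for i in range(20):
            a = rng.normal(0, 1, size=(20, 3))
            b = rng.normal(0, 1, size=(20, 3))
            a[:4] += 4.0
            table = _make_log_table(a, b)
            exh = lfq.permutation_fdr_calls(table, lfq.TestConfig(exhaustive=True))
            smp = lfq.permutation_fdr_calls(table, lfq.TestConfig(seed=i))
            mismatches += int(
                not (exh["significant"] == smp["significant"]).all()
            )
        assert mismatches == 0

    def test_high_effect_recovery_with_correct_sign(self):
        cfg = simulate.LfqSimConfig(
            n_proteins=1000, frac_enriched=0.05, frac_depleted=0.05,
            effect_log2=4.0, within_sd_log2=0.3, seed=21,
        )
        table, truth = prepared_log_table(cfg)
        res = lfq.permutation_fdr_calls(table, lfq.TestConfig(seed=2))
        tt = truth.loc[res.index, "class"]
        assert (res.loc[tt == "enriched", "call"] == "enriched").all()
        assert (res.loc[tt == "depleted", "call"] == "depleted").all()

    def test_antisymmetry_under_label_swap(self, planted_log_table):
        table, _ = planted_log_table
        cfg = lfq.TestConfig(exhaustive=True)
        fwd = lfq.permutation_fdr_calls(table, cfg, ("sorted", "lysate"))
        rev = lfq.permutation_fdr_calls(table, cfg, ("lysate", "sorted"))
        np.testing.assert_allclose(fwd["log2_fc"], -rev["log2_fc"], atol=1e-12)
        np.testing.assert_allclose(fwd["d_stat"], -rev["d_stat"], atol=1e-12)
        swapped = rev["call"].map(
            {"enriched": "depleted", "depleted": "enriched",
             "ns": "ns", "not_tested": "not_tested"}
        )
        assert (fwd["call"].astype(str) == swapped.astype(str)).all()

    def test_call_partition_exhaustive_and_disjoint(self, planted_log_table):
        table, _ = planted_log_table
        res = lfq.permutation_fdr_calls(table, lfq.TestConfig(seed=0))
        counts = res["call"].value_counts()
        assert counts.sum() == len(res)
        assert res.loc[res["significant"], "call"].isin(["enriched", "depleted"]).all()
        assert (res.loc[res["call"] == "enriched", "log2_fc"] > 0).all()
        assert (res.loc[res["call"] == "depleted", "log2_fc"] < 0).all()

    def test_rerun_is_bit_identical(self, planted_log_table):
        table, _ = planted_log_table
        r1 = lfq.permutation_fdr_calls(table, lfq.TestConfig(seed=3))
        r2 = lfq.permutation_fdr_calls(table, lfq.TestConfig(seed=3))
        pd.testing.assert_frame_equal(r1, r2)

    def test_single_replicate_rejected(self):
        a = np.random.default_rng(0).normal(size=(5, 1))
        b = np.random.default_rng(1).normal(size=(5, 3))
        with pytest.raises(lfq.InsufficientReplicationError):
            lfq.permutation_fdr_calls(_make_log_table(a, b), lfq.TestConfig())


def _make_log_table(a: np.ndarray, b: np.ndarray) -> lfq.ProteinGroupTable:
    """Assemble a log2-scale table directly from matrices (sorted, lysate)."""
    cols = pd.MultiIndex.from_tuples(
        [("sorted", i + 1) for i in range(a.shape[1])]
        + [("lysate", i + 1) for i in range(b.shape[1])],
        names=["condition", "bio"],
    )
    ids = [f"P{i}" for i in range(a.shape[0])]
    intens = pd.DataFrame(np.hstack([a, b]), index=ids, columns=cols)
    meta = pd.DataFrame(
        {
            "is_reverse": False,
            "is_contaminant": False,
            "only_identified_by_site": False,
            "razor_unique_peptides": 5,
        },
        index=pd.Index(ids),
    )
    return lfq.ProteinGroupTable(intens.sort_index(axis=1), meta, log2_scale=True)


class TestClustering:
    def test_zscore_population_convention(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]])
        z = lfq.zscore_rows(df)
        assert z.to_numpy().mean() == pytest.approx(0.0, abs=1e-12)
        assert z.to_numpy().std() == pytest.approx(1.0, abs=1e-12)  # ddof=0

    def test_planted_blocks_separate_at_two_clusters(self):
        rng = np.random.default_rng(3)
        up = rng.normal(0, 0.1, size=(15, 3)) + 3.0
        down = rng.normal(0, 0.1, size=(15, 3)) - 3.0
        a = np.vstack([up, down])
        b = np.vstack([down, up]) * 0  # lysate flat at 0
        table = _make_log_table(a + 20, b + 20)
        cfg = lfq.ClusterConfig(kmeans_k=None, prefilter_fdr=0.05, seed=0)
        result = lfq.cluster_significant_rows(table, cfg)
        labels = fcluster(result.row_linkage, t=2, criterion="maxclust")
        idx = result.assignments.index
        first = {labels[i] for i, pid in enumerate(idx) if int(pid[1:]) < 15}
        second = {labels[i] for i, pid in enumerate(idx) if int(pid[1:]) >= 15}
        assert first.isdisjoint(second)
        assert len(first) == len(second) == 1

    def test_linkage_heights_match_naive_oracle(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 0.2, size=(8, 3)) + 5.0
        b = rng.normal(0, 0.2, size=(8, 3))
        table = _make_log_table(a + 20, b + 20)
        cfg = lfq.ClusterConfig(kmeans_k=None, prefilter_fdr=0.05, seed=0)
        result = lfq.cluster_significant_rows(table, cfg)
        z = result.zscored.fillna(0.0).to_numpy()
        np.testing.assert_allclose(
            np.sort(result.row_linkage[:, 2]),
            np.sort(naive_average_linkage(z)),
            rtol=1e-10,
        )

    def test_too_few_significant_rows_is_degenerate(self, small_null_log_table):
        table, _ = small_null_log_table
        with pytest.raises(lfq.DegenerateInputError):
            lfq.cluster_significant_rows(table, lfq.ClusterConfig(seed=0))
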