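"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import io
import math

import numpy as np
import pandas as pd
import pytest

from mitochrom import lfq, simulate


def table_via_tsv(df: pd.DataFrame, column_map) -> lfq.ProteinGroupTable:
    """Round-trip a generated table through the TSV reader (the real path)."""
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    return lfq.read_protein_group_table(buf, column_map)


def prepared_log_table(config: simulate.LfqSimConfig):
    """simulate → read → filter → average technical reps → log2."""
    df, truth = simulate.simulate_lfq_table(config)
    table = table_via_tsv(df, simulate.lfq_column_map(config))
    table = lfq.filter_protein_groups(table, min_peptides=2)
    table = lfq.average_technical_replicates(table)
    return lfq.log2_transform_table(table), truth


def textbook_pooled_t(a, b):
    """Independent two-sample pooled-variance Student t and two-sided p.

    Written from the textbook formula (no scipy.stats.ttest_ind) so it can
    serve as an oracle for the package's statistics.
    """
    from scipy.stats import t as t_dist

    a = [float(x) for x in a]
    b = [float(x) for x in b]
    n1, n2 = len(a), len(b)
    m1 = sum(a) / n1
    m2 = sum(b) / n2
    ss1 = sum((x - m1) ** 2 for x in a)
    ss2 = sum((x - m2) ** 2 for x in b)
    sp2 = (ss1 + ss2) / (n1 + n2 - 2)
    t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * t_dist.sf(abs(t), n1 + n2 - 2)
    return t, p


def naive_average_linkage(points: np.ndarray) -> np.ndarray:
    """O(n^3) UPGMA agglomeration, returning merge heights in order.

    Independent of scipy.cluster.hierarchy: clusters are merged greedily by
    the smallest average pairwise euclidean distance between their members.
    Returns the sorted sequence of merge heights (cluster identity of the
    linkage matrix is not compared, only the heights, which determine the
    dendrogram shape up to tie ordering).
    """
    points = np.asarray(points, dtype=float)
    clusters = [[i] for i in range(len(points))]
    heights = []
    while len(clusters) > 1:
        best = (None, None, math.inf)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dists = [
                    math.dist(points[p], points[q])
                    for p in clusters[i]
                    for q in clusters[j]
                ]
                d = sum(dists) / len(dists)
                if d < best[2]:
                    best = (i, j, d)
        i, j, d = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return np.array(heights)


@pytest.fixture
def small_null_log_table():
    cfg = simulate.LfqSimConfig(n_proteins=60, seed=42)
    table, truth = prepared_log_table(cfg)
    return table, truth


@pytest.fixture
def planted_log_table():
    cfg = simulate.LfqSimConfig(
        n_proteins=300, frac_enriched=0.1, frac_depleted=0.1,
        effect_log2=2.0, within_sd_log2=0.3, seed=1,
    )
    table, truth = prepared_log_table(cfg)
    return table, truth
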