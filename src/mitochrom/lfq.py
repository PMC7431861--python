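"""Label-free proteomic enrichment analysis for sorted mitotic chromosomes.

Implements the Perseus-style volcano workflow on a MaxQuant
``proteinGroups.txt``-dialect table: QC filtering, technical-replicate
averaging, log2 transform, an S0-moderated two-sample statistic (SAM-style:
a small constant ``s0`` added to the standard error of the mean difference,
damping significance of low-variance features), permutation-based FDR calls,
and hierarchical clustering of significant rows.

Conditions are conventionally named ``"lysate"`` (mitotic lysate pellet) and
``"sorted"`` (flow-sorted chromosomes); fold changes are reported as
sorted − lysate on the log2 scale, so positive values mean enrichment on
chromosomes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from sklearn.cluster import KMeans

LYSATE = "lysate"
SORTED = "sorted"

FLAG_COLUMNS = {
    "is_reverse": "Reverse",
    "is_contaminant": "Potential contaminant",
    "only_identified_by_site": "Only identified by site",
}
PEPTIDE_COLUMN = "Razor + unique peptides"


class FormatError(ValueError):
    """Input table violates the expected protein-group dialect."""


class ConfigError(ValueError):
    """Invalid analysis configuration."""


class InsufficientReplicationError(ValueError):
    """Fewer than two biological replicates per condition."""


class DegenerateInputError(ValueError):
    """Too few rows survive filtering for the requested analysis."""


@dataclass
class ProteinGroupTable:
    """Protein groups with per-run intensities and QC metadata.

    ``intensities`` is indexed by protein id with a column MultiIndex of
    ``(condition, bio)`` or ``(condition, bio, tech)``; missing measurements
    are NaN.  ``meta`` shares the index and carries the boolean QC flags and
    razor+unique peptide counts.
    """

    intensities: pd.DataFrame
    meta: pd.DataFrame
    log2_scale: bool = False

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.meta.index):
            raise FormatError("intensity and metadata indices differ")
        if self.intensities.index.has_duplicates:
            dupes = self.intensities.index[self.intensities.index.duplicated()]
            raise FormatError(f"duplicate protein ids: {list(dupes[:5])}")
        if self.intensities.columns.has_duplicates:
            raise FormatError("duplicate intensity columns")

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.intensities.columns.get_level_values(0)))

    def condition_matrix(self, condition: str) -> pd.DataFrame:
        return self.intensities.xs(condition, axis=1, level=0, drop_level=False)


@dataclass
class TestConfig:
    """Settings of the volcano significance analysis.

    Defaults mirror the published workflow: S0 = 0.1 on the log2-intensity
    scale, permutation FDR 0.01 with 250 random relabelings, two-sided.
    """

    s0: float = 0.1
    fdr: float = 0.01
    n_randomizations: int = 250
    side: str = "both"
    seed: int = 0
    min_valid_per_group: int = 2
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.fdr < 1:
            raise ConfigError(f"fdr must be in (0, 1), got {self.fdr}")
        if self.s0 < 0:
            raise ConfigError("s0 must be non-negative")
        if self.n_randomizations < 1:
            raise ConfigError("n_randomizations must be >= 1")
        if self.side != "both":
            raise ConfigError("only two-sided testing is supported")


@dataclass
class ClusterConfig:
    """Settings of the hierarchical clustering of significant rows."""

    prefilter_fdr: float = 0.05
    prefilter_s0: float = 0.0
    min_valid_in_one_group: int = 2
    kmeans_k: int | None = 300
    kmeans_max_iter: int = 10
    kmeans_restarts: int = 1
    distance: str = "euclidean"
    linkage: str = "average"
    seed: int = 0
    prefilter_randomizations: int = 250

    def __post_init__(self) -> None:
        if self.kmeans_k is not None and self.kmeans_k < 2:
            raise ConfigError("kmeans_k must be >= 2 (or None to disable)")
        if self.distance != "euclidean" or self.linkage != "average":
            raise ConfigError("only euclidean distance / average linkage supported")


@dataclass
class ClusterResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    assignments: pd.Series
    zscored: pd.DataFrame


# ---------------------------------------------------------------------------
# Reading and preprocessing
# ---------------------------------------------------------------------------

def read_protein_group_table(
    path,
    column_map: dict[str, tuple[str, int, int]],
    id_column: str = "Protein IDs",
) -> ProteinGroupTable:
    """Read a tab-separated protein-group table.

    ``column_map`` assigns each intensity column name to a
    ``(condition, bio_replicate, tech_replicate)`` triple.  Intensity zeros
    are converted to NaN (missing); QC flags use the ``"+"`` convention.
    """
    try:
        raw = pd.read_csv(path, sep="\t", dtype={id_column: str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty protein-group file: {path}") from exc
    if id_column not in raw.columns:
        raise FormatError(f"missing id column {id_column!r}")

    looks_like_intensity = [c for c in raw.columns if c.startswith("LFQ intensity")]
    unmapped = sorted(set(looks_like_intensity) - set(column_map))
    if unmapped:
        raise FormatError(f"unmapped intensity columns: {unmapped}")
    missing_cols = sorted(set(column_map) - set(raw.columns))
    if missing_cols:
        raise FormatError(f"mapped columns absent from file: {missing_cols}")

    raw = raw.set_index(id_column)
    if raw.index.has_duplicates:
        raise FormatError("duplicate protein ids in file")

    cols = pd.MultiIndex.from_tuples(
        [column_map[c] for c in column_map], names=["condition", "bio", "tech"]
    )
    intens = raw[list(column_map)].astype(float)
    intens.columns = cols
    intens = intens.sort_index(axis=1)
    intens = intens.where(intens > 0)  # zeros are missing values

    meta = pd.DataFrame(index=raw.index)
    for key, col in FLAG_COLUMNS.items():
        meta[key] = (
            raw[col].fillna("").astype(str).str.strip().eq("+")
            if col in raw.columns
            else False
        )
    meta["razor_unique_peptides"] = (
        raw[PEPTIDE_COLUMN].fillna(0).astype(int) if PEPTIDE_COLUMN in raw.columns else 0
    )
    if "Gene names" in raw.columns:
        meta["gene_names"] = raw["Gene names"].fillna("")
    return ProteinGroupTable(intens, meta)


def filter_protein_groups(table: ProteinGroupTable, min_peptides: int = 2) -> ProteinGroupTable:
    """Drop decoy/contaminant/site-only rows and low-evidence identifications.

    Rows flagged as reverse decoys, potential contaminants, or "only
    identified by site" are removed, as are rows with fewer than
    ``min_peptides`` razor+unique peptides (when ``min_peptides > 0``).
    Row order is otherwise preserved.
    """
    meta = table.meta
    keep = ~(meta["is_reverse"] | meta["is_contaminant"] | meta["only_identified_by_site"])
    if min_peptides > 0:
        keep &= meta["razor_unique_peptides"] >= min_peptides
    return replace(table, intensities=table.intensities.loc[keep], meta=meta.loc[keep])


def average_technical_replicates(table: ProteinGroupTable) -> ProteinGroupTable:
    """Average technical replicates within each biological replicate.

    A cell is the mean of its valid technical measurements when at least one
    is valid, and missing otherwise ("min. one valid value").  Applied on the
    raw intensity scale, before the log2 transform.
    """
    if table.intensities.columns.nlevels != 3:
        raise FormatError("table has no technical-replicate level to average")
    averaged = table.intensities.T.groupby(level=["condition", "bio"]).mean().T
    return replace(table, intensities=averaged)


def log2_transform_table(table: ProteinGroupTable) -> ProteinGroupTable:
    """log2-transform all valid intensities; missing cells stay missing."""
    if table.log2_scale:
        raise ConfigError("table is already on the log2 scale")
    values = table.intensities
    if (values <= 0).any().any():
        raise ValueError("non-missing intensities must be positive for log2")
    return replace(table, intensities=np.log2(values), log2_scale=True)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def _group_stats(x: np.ndarray):
    """Per-row count, mean and ddof-1 variance, ignoring NaN. x: (n, k)."""
    valid = ~np.isnan(x)
    n = valid.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, np.nansum(x, axis=1) / np.maximum(n, 1), np.nan)
        dev = np.where(valid, x - mean[:, None], 0.0)
        ss = (dev**2).sum(axis=1)
        var = np.where(n > 1, ss / np.maximum(n - 1, 1), np.nan)
    return n, mean, var


def moderated_d_statistics(
    x_a: np.ndarray, x_b: np.ndarray, s0: float, min_valid: int = 2
) -> np.ndarray:
    """Vectorised S0-moderated statistic d = (mean_a − mean_b)/(SE + s0).

    SE is the pooled-variance standard error of the difference in means.
    Rows with fewer than ``min_valid`` valid values in either group are NaN.
    Antisymmetric under swapping the groups.  When both groups have zero
    variance and s0 = 0, the statistic is ±inf with the sign of the mean
    difference (0 if the means agree).
    """
    x_a = np.atleast_2d(np.asarray(x_a, dtype=float))
    x_b = np.atleast_2d(np.asarray(x_b, dtype=float))
    n1, m1, v1 = _group_stats(x_a)
    n2, m2, v2 = _group_stats(x_b)
    testable = (n1 >= max(min_valid, 2)) & (n2 >= max(min_valid, 2))
    diff = m1 - m2
    with np.errstate(invalid="ignore", divide="ignore"):
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / np.maximum(n1 + n2 - 2, 1)
        se = np.sqrt(sp2 * (1.0 / np.maximum(n1, 1) + 1.0 / np.maximum(n2, 1)))
        denom = se + s0
        d = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0),
                     np.sign(diff) * np.inf)
        d = np.where(diff == 0, 0.0, d)
    return np.where(testable, d, np.nan)


def moderated_t_statistic(x_sorted, x_lysate, s0: float) -> float:
    """S0-moderated statistic for one protein (sorted vs lysate)."""
    d = moderated_d_statistics(
        np.asarray(x_sorted, float)[None, :], np.asarray(x_lysate, float)[None, :], s0
    )
    return float(d[0])


def pooled_t_pvalues(x_a: np.ndarray, x_b: np.ndarray) -> np.ndarray:
    """Two-sided Student p-values (pooled variance) per row; NaN if untestable."""
    x_a = np.atleast_2d(np.asarray(x_a, float))
    x_b = np.atleast_2d(np.asarray(x_b, float))
    n1 = (~np.isnan(x_a)).sum(axis=1)
    n2 = (~np.isnan(x_b)).sum(axis=1)
    t = moderated_d_statistics(x_a, x_b, s0=0.0)
    df = n1 + n2 - 2
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
    p = np.where(np.isinf(t), 0.0, p)
    return np.where(np.isnan(t), np.nan, p)


def compute_log2_fc(
    log_table: ProteinGroupTable,
    protein: str,
    condition_pair: tuple[str, str] = (SORTED, LYSATE),
    min_valid_per_group: int = 1,
) -> float:
    """Mean log2 difference (first condition − second) for one protein.

    Returns NaN (not tested) when either condition has fewer than
    ``min_valid_per_group`` valid values.
    """
    if not log_table.log2_scale:
        raise ConfigError("log2_fc requires a log2-transformed table")
    row = log_table.intensities.loc[protein]
    a = row.xs(condition_pair[0], level="condition").to_numpy(float)
    b = row.xs(condition_pair[1], level="condition").to_numpy(float)
    if (~np.isnan(a)).sum() < min_valid_per_group or (~np.isnan(b)).sum() < min_valid_per_group:
        return float("nan")
    return float(np.nanmean(a) - np.nanmean(b))


# ---------------------------------------------------------------------------
# Permutation FDR
# ---------------------------------------------------------------------------

def _balanced_splits_exhaustive(n_total: int, n_group: int):
    """All distinct unordered splits of range(n_total) into two groups.

    With B per group there are C(2B, B)/2 − 1 null splits: index 0 is
    anchored to the first group to avoid counting complements twice, and
    the observed labeling itself (the first ``n_group`` indices) is
    excluded — it reproduces the observed statistics, not a null draw, and
    with small B would bound the estimated FDR away from zero.
    """
    identity = tuple(range(1, n_group))
    rest = range(1, n_total)
    for combo in itertools.combinations(rest, n_group - 1):
        if combo == identity:
            continue
        yield np.array((0,) + combo)


def _sample_split(rng: np.random.Generator, n_total: int, n_group: int) -> np.ndarray:
    """One random balanced relabeling, excluding the observed labeling."""
    identity = frozenset(range(n_group))
    complement = frozenset(range(n_group, n_total))
    while True:
        grp = rng.permutation(n_total)[:n_group]
        key = frozenset(grp.tolist())
        if key != identity and key != complement:
            return grp


def permutation_fdr_calls(
    log_table: ProteinGroupTable,
    config: TestConfig,
    condition_pair: tuple[str, str] = (SORTED, LYSATE),
) -> pd.DataFrame:
    """Observed d statistics and permutation-FDR significance calls.

    The observed |d| is compared to the null distribution of |d| obtained by
    randomly relabeling the 2B biological-replicate columns into two groups
    of B (unrestricted, "preserve grouping: none").  The significance cutoff
    is the smallest |d| at which the estimated FDR

        FDR(c) = mean over permutations of #{null |d| >= c} / #{observed |d| >= c}

    (capped at 1) stays at or below ``config.fdr``; everything at or above
    that cutoff is called significant.  The observed labeling itself is
    excluded from the relabelings: it is not a null draw, and with B = 3 it
    would bound the estimate below by ~1/10.  With ``config.exhaustive`` all
    C(2B, B)/2 distinct relabelings are enumerated instead of sampled.

    Returns a DataFrame indexed by protein id with columns ``log2_fc``,
    ``d_stat``, ``p_raw``, ``minus_log10_p``, ``significant``, ``call``.
    """
    if not log_table.log2_scale:
        raise ConfigError("permutation testing requires a log2-transformed table")
    cond_a, cond_b = condition_pair
    a = log_table.condition_matrix(cond_a)
    b = log_table.condition_matrix(cond_b)
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a < 2 or n_b < 2:
        raise InsufficientReplicationError(
            f"need >= 2 biological replicates per condition, got {n_a} and {n_b}"
        )

    data = np.hstack([a.to_numpy(float), b.to_numpy(float)])  # (n, 2B)
    obs_d = moderated_d_statistics(data[:, :n_a], data[:, n_a:], config.s0,
                                   config.min_valid_per_group)
    p_raw = pooled_t_pvalues(data[:, :n_a], data[:, n_a:])
    testable = ~np.isnan(obs_d)
    obs_abs = np.abs(obs_d[testable])

    if config.exhaustive:
        splits = list(_balanced_splits_exhaustive(n_a + n_b, n_a))
    else:
        rng = np.random.default_rng(config.seed)
        splits = [_sample_split(rng, n_a + n_b, n_a) for _ in range(config.n_randomizations)]

    all_idx = np.arange(n_a + n_b)
    null_abs = []
    for grp in splits:
        other = np.setdiff1d(all_idx, grp)
        d = moderated_d_statistics(data[:, grp], data[:, other], config.s0,
                                   config.min_valid_per_group)
        null_abs.append(np.abs(d[~np.isnan(d)]))
    n_perm = len(splits)
    null_pool = np.sort(np.concatenate(null_abs)) if null_abs else np.array([])

    significant = np.zeros(data.shape[0], dtype=bool)
    if obs_abs.size:
        cuts = np.sort(np.unique(obs_abs))[::-1]  # largest first
        obs_sorted = np.sort(obs_abs)
        n_obs_ge = obs_abs.size - np.searchsorted(obs_sorted, cuts, side="left")
        n_null_ge = null_pool.size - np.searchsorted(null_pool, cuts, side="left")
        fdr_hat = np.minimum(1.0, (n_null_ge / max(n_perm, 1)) / np.maximum(n_obs_ge, 1))
        # SAM rule: reject down to the smallest cutoff whose estimated FDR
        # stays at or below the target
        passing = cuts[fdr_hat <= config.fdr]
        if passing.size:
            cutoff = passing.min()
            with np.errstate(invalid="ignore"):
                significant = testable & (np.abs(np.where(testable, obs_d, 0.0)) >= cutoff)

    fc = np.nanmean(data[:, :n_a], axis=1) - np.nanmean(data[:, n_a:], axis=1)
    fc = np.where(
        ((~np.isnan(data[:, :n_a])).sum(axis=1) >= 1)
        & ((~np.isnan(data[:, n_a:])).sum(axis=1) >= 1),
        fc,
        np.nan,
    )
    with np.errstate(divide="ignore"):
        mlog10p = -np.log10(p_raw)
    result = pd.DataFrame(
        {
            "log2_fc": fc,
            "d_stat": obs_d,
            "p_raw": p_raw,
            "minus_log10_p": mlog10p,
            "significant": significant,
        },
        index=log_table.intensities.index,
    )
    return classify_proteins(result)


def classify_proteins(results: pd.DataFrame) -> pd.DataFrame:
    """Assign each protein to {enriched, depleted, ns, not_tested}.

    Significant with positive log2 fold change → enriched; significant with
    negative → depleted; tested but not significant → ns; untestable →
    not_tested.  The partition is exhaustive and disjoint.
    """
    results = results.copy()
    tested = ~results["d_stat"].isna()
    call = np.where(
        results["significant"] & (results["log2_fc"] > 0), "enriched",
        np.where(
            results["significant"] & (results["log2_fc"] < 0), "depleted",
            np.where(tested, "ns", "not_tested"),
        ),
    )
    results["call"] = pd.Categorical(
        call, categories=["enriched", "depleted", "ns", "not_tested"]
    )
    return results


# ---------------------------------------------------------------------------
# Hierarchical clustering of significant rows
# ---------------------------------------------------------------------------

def zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-score over valid entries (population sd, divide by n)."""
    arr = values.to_numpy(float)
    mean = np.nanmean(arr, axis=1, keepdims=True)
    sd = np.nanstd(arr, axis=1, keepdims=True)  # ddof=0 by convention
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (arr - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    z = np.where(np.isnan(arr), np.nan, z)
    return pd.DataFrame(z, index=values.index, columns=values.columns)


def average_linkage(points: np.ndarray) -> np.ndarray:
    """Average-linkage agglomeration with euclidean distance (UPGMA)."""
    return _scipy_linkage(points, method="average", metric="euclidean")


def cluster_significant_rows(
    log_table: ProteinGroupTable,
    config: ClusterConfig,
    condition_pair: tuple[str, str] = (SORTED, LYSATE),
) -> ClusterResult:
    """Cluster t-test-significant rows, Perseus HCA style.

    Rows are prefiltered to those with at least ``min_valid_in_one_group``
    valid values in one condition and a significant permutation-FDR t-test at
    the prefilter settings; retained rows are z-scored and reduced by k-means
    to at most ``kmeans_k`` centroids before average-linkage trees are built
    over rows (centroids) and columns.  ``kmeans_k=None`` disables the
    k-means reduction.
    """
    if not log_table.log2_scale:
        raise ConfigError("clustering requires a log2-transformed table")
    intens = log_table.intensities
    cond_a, cond_b = condition_pair
    valid_a = intens.xs(cond_a, axis=1, level="condition").notna().sum(axis=1)
    valid_b = intens.xs(cond_b, axis=1, level="condition").notna().sum(axis=1)
    enough = (valid_a >= config.min_valid_in_one_group) | (
        valid_b >= config.min_valid_in_one_group
    )
    sub = replace(log_table, intensities=intens.loc[enough], meta=log_table.meta.loc[enough])

    test_cfg = TestConfig(
        s0=config.prefilter_s0,
        fdr=config.prefilter_fdr,
        n_randomizations=config.prefilter_randomizations,
        seed=config.seed,
    )
    calls = permutation_fdr_calls(sub, test_cfg, condition_pair)
    keep = calls.index[calls["significant"]]
    if len(keep) < 2:
        raise DegenerateInputError(
            f"only {len(keep)} significant rows; need >= 2 for clustering"
        )

    z = zscore_rows(sub.intensities.loc[keep])
    filled = z.fillna(0.0)  # z-scale row mean; only used for distances
    X = filled.to_numpy(float)

    if config.kmeans_k is not None and X.shape[0] > config.kmeans_k:
        km = KMeans(
            n_clusters=config.kmeans_k,
            max_iter=config.kmeans_max_iter,
            n_init=config.kmeans_restarts,
            random_state=config.seed,
        ).fit(X)
        centroids = km.cluster_centers_
        assignments = pd.Series(km.labels_, index=keep, name="cluster")
    else:
        centroids = X
        assignments = pd.Series(np.arange(X.shape[0]), index=keep, name="cluster")

    row_linkage = average_linkage(centroids)
    col_linkage = average_linkage(X.T)
    return ClusterResult(row_linkage, col_linkage, assignments, z)
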