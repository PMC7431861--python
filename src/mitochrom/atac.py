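"""ATAC-seq insertion-site accessibility transforms.

Converts aligned read records into Tn5 insertion centres (5' ends offset by
+4 bp on the plus strand / −5 bp on the minus strand, so positions reflect
the centre of the transposition event), computes chromosome-wide log2
accessibility enrichment in tiled 25 kb windows relative to the genome-wide
average, and builds summit-centred accessibility trend profiles per peak
class (e.g. bookmarking sites retained vs lost in mitosis).

Coordinates are 0-based half-open throughout (BED convention); the minus
strand 5' end of a read [start, end) is ``end − 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PLUS_OFFSET = 4
MINUS_OFFSET = 5


class ConfigError(ValueError):
    """Invalid accessibility-analysis configuration."""


@dataclass
class InsertionSites:
    """Offset-corrected transposase insertion positions with drop counts."""

    sites: pd.DataFrame  # columns: chrom, position
    n_input: int
    n_dropped_strand: int = 0
    n_dropped_bounds: int = 0

    @property
    def n_retained(self) -> int:
        return len(self.sites)


@dataclass
class EnrichmentTrack:
    """Windowed insertion counts and log2 enrichment vs genome-wide average."""

    windows: pd.DataFrame  # chrom, start, end, count, log2_enrichment
    window_size: int
    pseudocount: float
    total_sites: int


@dataclass
class TrendProfile:
    """Relative insertion density around summits of one peak class."""

    peak_class: str
    bin_offsets: np.ndarray  # bin-centre offsets from the summit, bp
    density: np.ndarray      # mean-1-normalised relative density
    n_summits: int
    bin_bp: int


def extract_insertion_centers(
    reads: pd.DataFrame, chrom_sizes: dict[str, int] | None = None
) -> InsertionSites:
    """Tn5 insertion centres from BED-like read records.

    One centre per read: plus-strand centre = start + 4; minus-strand
    centre = (end − 1) − 5.  Reads with unknown strand are skipped, and
    centres falling outside ``chrom_sizes`` (when given) are dropped; both
    counts are recorded.
    """
    n_input = len(reads)
    strand = reads["strand"].astype(str)
    known = strand.isin(["+", "-"])
    n_bad_strand = int((~known).sum())
    if n_bad_strand:
        logger.warning("skipped %d reads with unknown strand", n_bad_strand)
    sub = reads.loc[known]
    pos = np.where(
        sub["strand"].to_numpy() == "+",
        sub["start"].to_numpy() + PLUS_OFFSET,
        sub["end"].to_numpy() - 1 - MINUS_OFFSET,
    )
    sites = pd.DataFrame({"chrom": sub["chrom"].to_numpy(), "position": pos})
    n_oob = 0
    if chrom_sizes is not None:
        limits = sites["chrom"].map(chrom_sizes)
        ok = (sites["position"] >= 0) & (sites["position"] < limits)
        n_oob = int((~ok).sum())
        if n_oob:
            logger.warning("dropped %d out-of-bounds insertion centres", n_oob)
        sites = sites.loc[ok]
    sites = sites.sort_values(["chrom", "position"], kind="mergesort").reset_index(drop=True)
    return InsertionSites(sites, n_input, n_bad_strand, n_oob)


def windowed_log2_enrichment(
    sites: InsertionSites | pd.DataFrame,
    chrom_sizes: dict[str, int],
    window_size: int = 25_000,
    pseudocount: float = 0.5,
) -> EnrichmentTrack:
    """log2 insertion enrichment in tiled windows vs the genome-wide average.

    Windows tile each chromosome without overlap; the final partial window
    uses its true length in the expectation.  The expected count of a
    window is ``total_sites × window_length / genome_length``; zero-count
    windows take ``pseudocount`` before the log2 so the track stays finite.
    """
    if not chrom_sizes:
        raise ConfigError("chrom_sizes must not be empty")
    table = sites.sites if isinstance(sites, InsertionSites) else sites
    total_sites = len(table)
    genome_length = float(sum(chrom_sizes.values()))
    if total_sites == 0:
        logger.warning("empty insertion-site set: enrichment track is all-missing")

    records = []
    for chrom, size in chrom_sizes.items():
        pos = table.loc[table["chrom"] == chrom, "position"].to_numpy()
        edges = np.arange(0, size + window_size, window_size)
        edges[-1] = min(edges[-1], size)
        if edges[-1] == edges[-2]:
            edges = edges[:-1]
        counts, _ = np.histogram(pos, bins=edges)
        lengths = np.diff(edges)
        expected = total_sites * lengths / genome_length
        numer = np.where(counts > 0, counts, pseudocount)
        with np.errstate(divide="ignore", invalid="ignore"):
            log2e = np.where(
                (expected > 0) & (total_sites > 0),
                np.log2(numer / np.where(expected > 0, expected, 1.0)),
                np.nan,
            )
        for i in range(len(counts)):
            records.append(
                (chrom, int(edges[i]), int(edges[i + 1]), int(counts[i]), log2e[i])
            )
    windows = pd.DataFrame(
        records, columns=["chrom", "start", "end", "count", "log2_enrichment"]
    )
    return EnrichmentTrack(windows, window_size, pseudocount, total_sites)


def summit_trend_profile(
    sites: InsertionSites | pd.DataFrame,
    summits_by_class: dict[str, pd.DataFrame],
    extend_bp: int = 25,
    span_bp: int = 2_000,
    bin_bp: int = 10,
) -> dict[str, TrendProfile]:
    """Average relative insertion density around peak summits, per class.

    Each insertion centre is extended to ±``extend_bp`` (smoothing); the
    per-base coverage of these intervals is accumulated over
    [summit − span/2, summit + span/2) for every summit of a class, binned
    at ``bin_bp``, averaged over summits, and normalised so the mean over
    bins is 1.  Classes with no summits are omitted with a warning.

    ``summits_by_class`` maps class label → DataFrame with columns
    ``chrom`` and ``summit`` (0-based positions).
    """
    if span_bp % bin_bp != 0:
        raise ConfigError("span_bp must be a multiple of bin_bp")
    table = sites.sites if isinstance(sites, InsertionSites) else sites
    half = span_bp // 2
    n_bins = span_bp // bin_bp
    by_chrom = {c: g["position"].to_numpy() for c, g in table.groupby("chrom")}

    profiles: dict[str, TrendProfile] = {}
    for cls, summits in summits_by_class.items():
        if len(summits) == 0:
            logger.warning("class %r has no summits; profile omitted", cls)
            continue
        acc = np.zeros(span_bp, dtype=float)
        for chrom, summit in zip(summits["chrom"], summits["summit"]):
            pos = by_chrom.get(chrom)
            if pos is None:
                continue
            lo, hi = summit - half - extend_bp, summit + half + extend_bp
            sel = pos[(pos >= lo) & (pos < hi)]
            # per-base coverage of [site-extend, site+extend] within the span
            cov = np.zeros(span_bp + 1, dtype=float)
            starts = np.clip(sel - extend_bp - (summit - half), 0, span_bp)
            ends = np.clip(sel + extend_bp + 1 - (summit - half), 0, span_bp)
            np.add.at(cov, starts, 1.0)
            np.add.at(cov, ends, -1.0)
            acc += np.cumsum(cov)[:span_bp]
        binned = acc.reshape(n_bins, bin_bp).mean(axis=1) / len(summits)
        mean = binned.mean()
        density = binned / mean if mean > 0 else binned
        offsets = np.arange(n_bins) * bin_bp - half + bin_bp / 2.0
        profiles[cls] = TrendProfile(cls, offsets, density, len(summits), bin_bp)
    return profiles


# ---------------------------------------------------------------------------
# Plain-text I/O (BED6 reads, chrom.sizes, summit BED, bedGraph)
# ---------------------------------------------------------------------------

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed_reads(path) -> pd.DataFrame:
    """Read 6-column BED read records (chrom, start, end, name, score, strand)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ConfigError("read BED must have 6 columns including strand")
    df = df.iloc[:, :6]
    df.columns = BED6_COLUMNS
    return df


def write_bed_reads(reads: pd.DataFrame, path) -> None:
    reads[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column chrom.sizes file."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def read_summits(path) -> dict[str, pd.DataFrame]:
    """Read summit BED (chrom, start, end[, class]) grouped by class label.

    The class is taken from the name field; a 3-column file yields a single
    class ``"all"``.  The summit position is the interval start.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    cls = df[3].astype(str) if df.shape[1] > 3 else pd.Series(["all"] * len(df))
    out: dict[str, pd.DataFrame] = {}
    for label, grp in df.groupby(cls):
        out[str(label)] = pd.DataFrame(
            {"chrom": grp["chrom"].astype(str), "summit": grp["start"].astype(int)}
        ).reset_index(drop=True)
    return out


def write_bedgraph(track: EnrichmentTrack, path) -> None:
    """Write the enrichment track as bedGraph (one window per line)."""
    with open(path, "w") as fh:
        fh.write(
            f"# window_size={track.window_size} pseudocount={track.pseudocount} "
            f"total_sites={track.total_sites}\n"
        )
        for row in track.windows.itertuples(index=False):
            val = "nan" if pd.isna(row.log2_enrichment) else f"{row.log2_enrichment:.6g}"
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{val}\n")
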