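"""Seeded synthetic-data generators with ground truth.

Each generator emulates the statistical structure one analysis stage
assumes — a two-condition LFQ intensity matrix with planted enrichment,
single-chromosome DAPI/Cenpa images with a brighter pericentric sub-domain,
and ATAC insertion-read sets with uniform background plus peaks — and emits
a ground-truth record per generated entity so parameter recovery can be
tested without any deposited raw data.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
configs and seeds give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gamma as _gamma

from .lfq import FLAG_COLUMNS, LYSATE, PEPTIDE_COLUMN, SORTED, ConfigError


# ---------------------------------------------------------------------------
# LFQ intensity tables
# ---------------------------------------------------------------------------

@dataclass
class MissingModel:
    """Missing-value mechanism for the LFQ generator.

    ``kind`` is one of ``"none"``, ``"mcar"`` (each cell missing with
    probability ``rate``) or ``"mnar"`` (cells whose intensity falls below
    the ``threshold_quantile`` quantile of their column are missing with
    probability ``rate`` — left-censoring, the dominant mode in label-free
    data).
    """

    kind: str = "none"
    rate: float = 0.0
    threshold_quantile: float = 0.2

    def __post_init__(self) -> None:
        if self.kind not in {"none", "mcar", "mnar"}:
            raise ConfigError(f"unknown missing model {self.kind!r}")
        if not 0 <= self.rate <= 1:
            raise ConfigError("missing rate must be in [0, 1]")
        if not 0 < self.threshold_quantile < 1:
            raise ConfigError("threshold_quantile must be in (0, 1)")


@dataclass
class LfqSimConfig:
    """Design of a synthetic label-free proteomics experiment.

    Defaults mirror the study design: 2 conditions x 3 biological
    replicates, each measured in technical duplicate.  Planted enriched /
    depleted proteins shift the sorted-condition mean by ±``effect_log2``
    on the log2 scale.
    """

    n_proteins: int = 1000
    frac_enriched: float = 0.0
    frac_depleted: float = 0.0
    effect_log2: float = 2.0
    within_sd_log2: float = 0.3
    base_log2_mean: float = 25.0
    base_log2_sd: float = 2.0
    missing_model: MissingModel = field(default_factory=MissingModel)
    n_bio: int = 3
    n_tech: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.frac_enriched <= 1 and 0 <= self.frac_depleted <= 1):
            raise ConfigError("class fractions must be in [0, 1]")
        if self.frac_enriched + self.frac_depleted > 1:
            raise ConfigError("frac_enriched + frac_depleted must be <= 1")
        if self.n_bio < 2:
            raise ConfigError("n_bio must be >= 2")
        if self.n_tech < 1 or self.n_proteins < 1:
            raise ConfigError("n_tech and n_proteins must be >= 1")
        if min(self.effect_log2, self.within_sd_log2, self.base_log2_sd) < 0:
            raise ConfigError("scale parameters must be non-negative")


def simulate_lfq_table(config: LfqSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a protein-group intensity table plus per-protein truth.

    Returns ``(table, truth)``.  ``table`` is a MaxQuant-dialect DataFrame
    (one ``LFQ intensity <condition>_b<bio>_t<tech>`` column per run, flag
    columns empty, razor+unique peptide counts >= 2, zeros marking missing
    values).  ``truth`` records each protein's planted class in
    {enriched, depleted, null} and its true log2 effect.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    n_enr = int(round(config.frac_enriched * n))
    n_dep = int(round(config.frac_depleted * n))
    classes = np.array(["null"] * n, dtype=object)
    order = rng.permutation(n)
    classes[order[:n_enr]] = "enriched"
    classes[order[n_enr:n_enr + n_dep]] = "depleted"
    effect = np.where(classes == "enriched", config.effect_log2,
                      np.where(classes == "depleted", -config.effect_log2, 0.0))

    base = rng.normal(config.base_log2_mean, config.base_log2_sd, size=n)
    tech_sd = config.within_sd_log2 / 2.0

    columns, log2_cols = [], []
    for cond, shift in ((LYSATE, 0.0), (SORTED, 1.0)):
        for bio in range(1, config.n_bio + 1):
            bio_noise = rng.normal(0.0, config.within_sd_log2, size=n)
            level = base + shift * effect + bio_noise
            for tech in range(1, config.n_tech + 1):
                log2_cols.append(level + rng.normal(0.0, tech_sd, size=n))
                columns.append(f"LFQ intensity {cond}_b{bio}_t{tech}")
    log2_mat = np.column_stack(log2_cols)
    intens = np.power(2.0, log2_mat)

    mm = config.missing_model
    if mm.kind == "mcar" and mm.rate > 0:
        mask = rng.random(intens.shape) < mm.rate
        intens = np.where(mask, 0.0, intens)
    elif mm.kind == "mnar" and mm.rate > 0:
        thr = np.quantile(intens, mm.threshold_quantile, axis=0, keepdims=True)
        mask = (intens < thr) & (rng.random(intens.shape) < mm.rate)
        intens = np.where(mask, 0.0, intens)

    ids = [f"P{i:05d}" for i in range(n)]
    table = pd.DataFrame(intens, columns=columns)
    table.insert(0, "Protein IDs", ids)
    table["Gene names"] = [f"Gene{i}" for i in range(n)]
    for flag_col in FLAG_COLUMNS.values():
        table[flag_col] = ""
    table[PEPTIDE_COLUMN] = rng.integers(2, 30, size=n)

    truth = pd.DataFrame(
        {"protein_id": ids, "class": classes, "effect_log2": effect}
    ).set_index("protein_id")
    return table, truth


def lfq_column_map(config: LfqSimConfig) -> dict[str, tuple[str, int, int]]:
    """Column map pairing generated intensity columns with (condition, bio, tech)."""
    return {
        f"LFQ intensity {cond}_b{bio}_t{tech}": (cond, bio, tech)
        for cond in (LYSATE, SORTED)
        for bio in range(1, config.n_bio + 1)
        for tech in range(1, config.n_tech + 1)
    }


# ---------------------------------------------------------------------------
# Chromosome images
# ---------------------------------------------------------------------------

@dataclass
class ChromImageSimConfig:
    """Single-chromosome fluorescence image generator settings.

    Bodies are rotated super-ellipses (exponent ``shape_exponent``; 2 gives
    an ellipse) with mild zero-mean radial boundary jitter.  A sub-region
    covering ``centromere_area_frac`` of the body at one end is brighter by
    ``centromere_brightness_ratio``, emulating DAPI-bright pericentric
    heterochromatin; an optional second channel holds a Cenpa-like spot
    centred on that sub-region.  Areas are in µm²; truth areas are the
    analytic shape areas before noise.
    """

    n_objects: int = 100
    area_mean_um2: float = 18.4
    area_sd_um2: float = 3.0
    pixel_size_um: float = 0.1
    elongation: float = 2.5
    centromere_area_frac: float = 0.2
    centromere_brightness_ratio: float = 2.0
    background_level: float = 100.0
    noise_sd: float = 20.0
    cenpa_channel: bool = False
    shape_exponent: float = 2.0
    boundary_jitter: float = 0.02
    foreground_level: float = 3000.0
    image_shape: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be positive")
        if not 0 <= self.centromere_area_frac < 1:
            raise ConfigError("centromere_area_frac must be in [0, 1)")
        if self.centromere_area_frac > 0 and self.centromere_brightness_ratio <= 1:
            raise ConfigError("centromere_brightness_ratio must exceed 1")
        if self.elongation < 1:
            raise ConfigError("elongation (aspect ratio) must be >= 1")
        if min(self.area_sd_um2, self.background_level, self.noise_sd) < 0:
            raise ConfigError("sd and level parameters must be non-negative")
        if self.n_objects < 1 or self.area_mean_um2 <= 0:
            raise ConfigError("n_objects >= 1 and area_mean_um2 > 0 required")


@dataclass
class SyntheticChromosomeImage:
    """One generated image: channel grids plus calibration."""

    image_id: str
    dapi: np.ndarray
    pixel_size_um: float
    cenpa: np.ndarray | None = None


def _superellipse_area(a: float, b: float, n: float) -> float:
    """Area of |x/a|^n + |y/b|^n <= 1 (πab when n = 2)."""
    return 4.0 * a * b * _gamma(1 + 1 / n) ** 2 / _gamma(1 + 2 / n)


def simulate_chromosome_image_set(
    config: ChromImageSimConfig,
) -> tuple[list[SyntheticChromosomeImage], pd.DataFrame]:
    """Generate ``n_objects`` single-chromosome images plus truth areas.

    Truth records per object: analytic body area (µm²), centromere area
    (``centromere_area_frac`` × body area) and orientation.  Pixel centres
    inside the analytic boundary form the foreground; the image is 16-bit
    with Poisson shot noise and additive Gaussian noise on top.
    """
    rng = np.random.default_rng(config.seed)
    px = config.pixel_size_um
    n_exp = config.shape_exponent
    images: list[SyntheticChromosomeImage] = []
    records = []
    for i in range(config.n_objects):
        # rejection-sample a positive area
        area = -1.0
        while area <= 0:
            area = rng.normal(config.area_mean_um2, config.area_sd_um2)
        area_px = area / px**2
        unit = _superellipse_area(1.0, 1.0, n_exp)
        b_ax = math.sqrt(area_px / (unit * config.elongation))
        a_ax = b_ax * config.elongation
        theta = rng.uniform(0.0, math.pi)

        margin = int(math.ceil(a_ax * 1.15)) + 4
        shape = config.image_shape or (2 * margin + 1, 2 * margin + 1)
        cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        xr = (xx - cx) * math.cos(theta) + (yy - cy) * math.sin(theta)
        yr = -(xx - cx) * math.sin(theta) + (yy - cy) * math.cos(theta)
        r_norm = (np.abs(xr) / a_ax) ** n_exp + (np.abs(yr) / b_ax) ** n_exp

        if config.boundary_jitter > 0:
            # zero-mean low-order Fourier modulation of the boundary radius;
            # area bias is second order in the amplitude
            phi = np.arctan2(yr / b_ax, xr / a_ax)
            amp = rng.normal(0.0, config.boundary_jitter, size=3)
            pha = rng.uniform(0.0, 2 * math.pi, size=3)
            mod = sum(amp[k] * np.cos((k + 2) * phi + pha[k]) for k in range(3))
            body = r_norm <= (1.0 + mod) ** n_exp
        else:
            body = r_norm <= 1.0

        dapi = np.full(shape, config.background_level, dtype=float)
        dapi[body] = config.foreground_level

        # pericentric sub-domain: the fraction of the body at one major-axis end
        cen_mask = np.zeros(shape, dtype=bool)
        if config.centromere_area_frac > 0 and body.any():
            xr_body = xr[body]
            cut = np.quantile(xr_body, 1.0 - config.centromere_area_frac)
            cen_mask = body & (xr >= cut)
            dapi[cen_mask] *= config.centromere_brightness_ratio

        noisy = rng.poisson(np.maximum(dapi, 0.0)).astype(float)
        if config.noise_sd > 0:
            noisy += rng.normal(0.0, config.noise_sd, size=shape)
        dapi16 = np.clip(np.round(noisy), 0, 65535).astype(np.uint16)

        cenpa16 = None
        if config.cenpa_channel:
            cenpa = np.full(shape, config.background_level / 2.0)
            if cen_mask.any():
                cyx = np.argwhere(cen_mask).mean(axis=0)
                rr = (yy - cyx[0]) ** 2 + (xx - cyx[1]) ** 2
                # keep the thresholded spot inside the pericentric cap
                sigma = max(b_ax * 0.3, 1.0)
                cenpa += config.foreground_level * np.exp(-rr / (2 * sigma**2))
            cenpa = rng.poisson(np.maximum(cenpa, 0.0)).astype(float)
            if config.noise_sd > 0:
                cenpa += rng.normal(0.0, config.noise_sd, size=shape)
            cenpa16 = np.clip(np.round(cenpa), 0, 65535).astype(np.uint16)

        image_id = f"obj{i:04d}"
        images.append(SyntheticChromosomeImage(image_id, dapi16, px, cenpa16))
        records.append(
            {
                "image_id": image_id,
                "area_um2": area,
                "centromere_area_um2": config.centromere_area_frac * area,
                "theta": theta,
            }
        )
    truth = pd.DataFrame(records).set_index("image_id")
    return images, truth


# ---------------------------------------------------------------------------
# ATAC insertion reads
# ---------------------------------------------------------------------------

@dataclass
class AtacPeak:
    """One accessibility peak with per-condition fold over background."""

    chrom: str
    summit: int
    half_width: int
    fold_by_condition: dict[str, float]
    peak_class: str = "retained"  # {retained, lost}


@dataclass
class AtacSimConfig:
    """Insertion-read simulator: uniform background plus peaks.

    ``background_rate`` is insertions per bp per condition.  Peak reads are
    added at rate background_rate × (fold − 1) over the peak span with
    Gaussian density (sd = half_width / 2) around the summit, giving
    ≈fold × background density at the peak.
    """

    chrom_sizes: dict[str, int] = field(default_factory=dict)
    background_rate: float = 0.004
    peaks: list[AtacPeak] = field(default_factory=list)
    conditions: tuple[str, ...] = ("asynchronous", "mitotic")
    read_length: int = 50
    frac_minus_strand: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_sizes:
            raise ConfigError("chrom_sizes must not be empty")
        if self.background_rate < 0:
            raise ConfigError("background_rate must be >= 0")
        if not 0 <= self.frac_minus_strand <= 1:
            raise ConfigError("frac_minus_strand must be in [0, 1]")
        for pk in self.peaks:
            if pk.chrom not in self.chrom_sizes:
                raise ConfigError(f"peak on unknown chromosome {pk.chrom!r}")
            size = self.chrom_sizes[pk.chrom]
            if pk.summit - pk.half_width < 0 or pk.summit + pk.half_width > size:
                raise ConfigError("peak extends beyond chromosome bounds")
            if any(f < 0 for f in pk.fold_by_condition.values()):
                raise ConfigError("fold-accessibility must be >= 0")


def _reads_from_centers(
    centers: np.ndarray, chrom: str, size: int, read_length: int,
    minus: np.ndarray,
) -> pd.DataFrame:
    """Construct BED read intervals whose offset-corrected 5' ends recover
    the given insertion centres (+4 for plus reads, −5 from the 5' end for
    minus reads)."""
    start = np.where(minus, centers + 6 - read_length, centers - 4)
    end = start + read_length
    ok = (start >= 0) & (end <= size)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": start[ok].astype(int),
            "end": end[ok].astype(int),
            "name": ".",
            "score": 0,
            "strand": np.where(minus[ok], "-", "+"),
        }
    )


def simulate_atac_reads(
    config: AtacSimConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate per-condition BED-like read records plus per-peak truth.

    Returns ``(reads_by_condition, truth)``; each read table is sorted by
    (chrom, start) with columns chrom/start/end/name/score/strand, 0-based
    half-open.  Truth records each peak's class and per-condition rate
    multiplier.
    """
    rng = np.random.default_rng(config.seed)
    reads_by_condition: dict[str, pd.DataFrame] = {}
    for cond in config.conditions:
        frames = []
        for chrom, size in config.chrom_sizes.items():
            n_bg = rng.poisson(config.background_rate * size)
            centers = rng.integers(0, size, size=n_bg)
            minus = rng.random(n_bg) < config.frac_minus_strand
            frames.append(_reads_from_centers(centers, chrom, size,
                                              config.read_length, minus))
        for pk in config.peaks:
            fold = pk.fold_by_condition.get(cond, 1.0)
            extra_rate = config.background_rate * max(fold - 1.0, 0.0)
            span = 2 * pk.half_width
            n_pk = rng.poisson(extra_rate * span)
            pos = rng.normal(pk.summit, pk.half_width / 2.0, size=n_pk)
            pos = np.clip(np.round(pos), pk.summit - pk.half_width,
                          pk.summit + pk.half_width - 1).astype(int)
            minus = rng.random(n_pk) < config.frac_minus_strand
            frames.append(_reads_from_centers(pos, pk.chrom,
                                              config.chrom_sizes[pk.chrom],
                                              config.read_length, minus))
        reads = pd.concat(frames, ignore_index=True)
        reads = reads.sort_values(["chrom", "start", "end"], kind="mergesort")
        reads_by_condition[cond] = reads.reset_index(drop=True)

    truth = pd.DataFrame(
        [
            {
                "chrom": pk.chrom,
                "summit": pk.summit,
                "half_width": pk.half_width,
                "class": pk.peak_class,
                **{f"fold_{c}": pk.fold_by_condition.get(c, 1.0)
                   for c in config.conditions},
            }
            for pk in config.peaks
        ]
    )
    return reads_by_condition, truth
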