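"""Pipeline orchestration: validated run configuration, staged execution,
and a consistency-checked run report.

A run is described by one structured-text (YAML) config with a global seed
that propagates to every stochastic component.  Stages (``simulate``,
``enrich``, ``measure``, ``atac``) are executed in dependency order; each
writes its outputs under the run directory and contributes record counts to
the :class:`RunReport`, whose arithmetic consistency (call partitions sum
to row totals, retained + dropped sites equal input reads) is asserted on
every run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, atac as atac_mod, lfq, morphometry, simulate

logger = logging.getLogger(__name__)

STAGES = ("simulate", "enrich", "measure", "atac")


class ConfigValidationError(ValueError):
    """Aggregated configuration errors (never first-failure-only)."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass
class RunConfig:
    """Validated run configuration with embedded stage settings."""

    seed: int = 0
    outdir: Path = Path("mitochrom_run")
    stages: tuple[str, ...] = ("enrich", "measure", "atac")
    lfq_sim: simulate.LfqSimConfig | None = None
    test: lfq.TestConfig = field(default_factory=lfq.TestConfig)
    cluster: lfq.ClusterConfig | None = None
    image_sim: dict[str, simulate.ChromImageSimConfig] = field(default_factory=dict)
    segmentation: morphometry.SegmentationConfig = field(
        default_factory=morphometry.SegmentationConfig
    )
    atac_sim: simulate.AtacSimConfig | None = None
    window_size: int = 25_000
    trend_bin_bp: int = 10
    enrich_input: dict | None = None  # {"table": path, "column_map": path}
    atac_input: dict | None = None  # {"reads": path, "chrom_sizes": path, "summits": path}
    min_peptides: int = 2


@dataclass
class RunReport:
    """Per-stage record counts, settings echo, seed and version."""

    seed: int
    version: str = __version__
    settings: dict = field(default_factory=dict)
    enrich: dict = field(default_factory=dict)
    measure: dict = field(default_factory=dict)
    atac: dict = field(default_factory=dict)

    def check_consistency(self) -> None:
        if self.enrich:
            e = self.enrich
            parts = e["enriched"] + e["depleted"] + e["ns"] + e["not_tested"]
            assert parts == e["rows_tested_total"], (
                f"call partition {parts} != rows after filtering {e['rows_tested_total']}"
            )
            assert e["rows_tested_total"] <= e["rows_read"]
        for cond, rec in self.atac.items():
            assert (
                rec["sites_retained"]
                + rec["dropped_strand"]
                + rec["dropped_bounds"]
                == rec["reads_input"]
            ), f"site conservation violated for {cond}"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)

    def to_text(self) -> str:
        lines = [f"mitochrom {self.version} run report (seed={self.seed})"]
        for name in ("enrich", "measure", "atac"):
            section = getattr(self, name)
            if section:
                lines.append(f"[{name}]")
                for k, v in section.items():
                    lines.append(f"  {k}: {v}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Config parsing / validation
# ---------------------------------------------------------------------------

def _build(cls, mapping, key, errors):
    try:
        return cls(**(mapping or {}))
    except (TypeError, ValueError) as exc:
        errors.append(f"{key}: {exc}")
        return None


def parse_config(raw: dict) -> RunConfig:
    """Build a RunConfig from a plain mapping, aggregating all violations."""
    errors: list[str] = []
    raw = dict(raw or {})
    stages = tuple(raw.get("stages", ("enrich", "measure", "atac")))
    for st in stages:
        if st not in STAGES:
            errors.append(f"stages: unknown stage {st!r}")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append("seed: must be an integer")
        seed = 0

    lfq_sim = None
    if "lfq_sim" in raw:
        sim_raw = dict(raw["lfq_sim"])
        if "missing_model" in sim_raw:
            mm = _build(simulate.MissingModel, sim_raw["missing_model"],
                        "lfq_sim.missing_model", errors)
            sim_raw["missing_model"] = mm or simulate.MissingModel()
        sim_raw.setdefault("seed", seed)
        lfq_sim = _build(simulate.LfqSimConfig, sim_raw, "lfq_sim", errors)

    test_raw = dict(raw.get("test", {}))
    test_raw.setdefault("seed", seed)
    test = _build(lfq.TestConfig, test_raw, "test", errors) or lfq.TestConfig(seed=seed)

    cluster = None
    if "cluster" in raw:
        cl_raw = dict(raw["cluster"])
        cl_raw.setdefault("seed", seed)
        cluster = _build(lfq.ClusterConfig, cl_raw, "cluster", errors)

    image_sim = {}
    for group, cfg in dict(raw.get("image_sim", {})).items():
        cfg = dict(cfg)
        cfg.setdefault("seed", seed)
        built = _build(simulate.ChromImageSimConfig, cfg, f"image_sim.{group}", errors)
        if built is not None:
            image_sim[group] = built

    seg = _build(
        morphometry.SegmentationConfig, raw.get("segmentation", {}), "segmentation", errors
    ) or morphometry.SegmentationConfig()

    atac_sim = None
    if "atac_sim" in raw:
        at_raw = dict(raw["atac_sim"])
        at_raw.setdefault("seed", seed)
        if "peaks" in at_raw:
            at_raw["peaks"] = [
                pk if isinstance(pk, simulate.AtacPeak) else simulate.AtacPeak(**pk)
                for pk in at_raw["peaks"]
            ]
        if "conditions" in at_raw:
            at_raw["conditions"] = tuple(at_raw["conditions"])
        atac_sim = _build(simulate.AtacSimConfig, at_raw, "atac_sim", errors)

    for key in ("enrich_input", "atac_input"):
        if raw.get(key):
            for sub, path in raw[key].items():
                if not Path(path).exists():
                    errors.append(f"{key}.{sub}: path {path!r} does not exist")

    if "enrich" in stages and lfq_sim is None and not raw.get("enrich_input"):
        errors.append("enrich: needs either lfq_sim or enrich_input")
    if "measure" in stages and not image_sim:
        errors.append("measure: needs image_sim group configs")
    if "atac" in stages and atac_sim is None and not raw.get("atac_input"):
        errors.append("atac: needs either atac_sim or atac_input")

    if errors:
        raise ConfigValidationError(errors)
    return RunConfig(
        seed=seed,
        outdir=Path(raw.get("outdir", "mitochrom_run")),
        stages=stages,
        lfq_sim=lfq_sim,
        test=test,
        cluster=cluster,
        image_sim=image_sim,
        segmentation=seg,
        atac_sim=atac_sim,
        window_size=int(raw.get("window_size", 25_000)),
        trend_bin_bp=int(raw.get("trend_bin_bp", 10)),
        enrich_input=raw.get("enrich_input"),
        atac_input=raw.get("atac_input"),
        min_peptides=int(raw.get("min_peptides", 2)),
    )


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML run config; all violations are aggregated."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return parse_config(raw)


# ---------------------------------------------------------------------------
# Stage execution
# ---------------------------------------------------------------------------

def _write_lfq_sim(config: RunConfig, outdir: Path) -> Path:
    table_df, truth = simulate.simulate_lfq_table(config.lfq_sim)
    path = outdir / "protein_groups.tsv"
    table_df.to_csv(path, sep="\t", index=False)
    truth.to_csv(outdir / "protein_groups_truth.csv")
    return path


def _run_enrich(config: RunConfig, outdir: Path, report: RunReport) -> None:
    if config.lfq_sim is not None:
        path = _write_lfq_sim(config, outdir)
        column_map = simulate.lfq_column_map(config.lfq_sim)
    else:
        path = config.enrich_input["table"]
        cm = pd.read_csv(config.enrich_input["column_map"])
        column_map = {
            r["column"]: (r["condition"], int(r["bio"]), int(r["tech"]))
            for _, r in cm.iterrows()
        }
    table = lfq.read_protein_group_table(path, column_map)
    n_read = len(table.intensities)
    table = lfq.filter_protein_groups(table, config.min_peptides)
    table = lfq.average_technical_replicates(table)
    table = lfq.log2_transform_table(table)
    results = lfq.permutation_fdr_calls(table, config.test)
    results.to_csv(outdir / "enrichment_results.csv")
    counts = results["call"].value_counts()
    report.enrich = {
        "rows_read": n_read,
        "rows_after_filter": len(results),
        "rows_tested_total": len(results),
        "enriched": int(counts.get("enriched", 0)),
        "depleted": int(counts.get("depleted", 0)),
        "ns": int(counts.get("ns", 0)),
        "not_tested": int(counts.get("not_tested", 0)),
    }
    if config.cluster is not None:
        try:
            cl = lfq.cluster_significant_rows(table, config.cluster)
            cl.assignments.to_csv(outdir / "cluster_assignments.csv")
            report.enrich["clustered_rows"] = int(len(cl.assignments))
        except lfq.DegenerateInputError as exc:
            logger.warning("clustering skipped: %s", exc)
            report.enrich["clustered_rows"] = 0


def _run_measure(config: RunConfig, outdir: Path, report: RunReport) -> None:
    per_group: dict[str, pd.DataFrame] = {}
    summaries = []
    for group, sim_cfg in config.image_sim.items():
        images, truth = simulate.simulate_chromosome_image_set(sim_cfg)
        chrom_images = [
            morphometry.ChromosomeImage(im.image_id, im.dapi, im.pixel_size_um, im.cenpa)
            for im in images
        ]
        meas = morphometry.measure_image_set(chrom_images, config.segmentation)
        meas.insert(0, "group", group)
        meas.to_csv(outdir / f"measurements_{group}.csv", index=False)
        truth.to_csv(outdir / f"measurements_{group}_truth.csv")
        per_group[group] = meas
        areas = meas["chromosome_area_um2"]
        summaries.append(
            {
                "group": group,
                "n_objects": len(meas),
                "mean_area_um2": areas.mean(),
                "sd_area_um2": areas.std(ddof=1),
                "mean_centromere_um2": meas["centromere_area_um2"].mean(),
            }
        )
    pd.DataFrame(summaries).to_csv(outdir / "group_summaries.csv", index=False)

    comparisons = []
    names = list(per_group)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = per_group[names[i]], per_group[names[j]]
            cmp_res = morphometry.compare_groups(
                a["chromosome_area_um2"], b["chromosome_area_um2"], names[i], names[j]
            )
            comparisons.append(dataclasses.asdict(cmp_res))
    if comparisons:
        pd.DataFrame(comparisons).to_csv(outdir / "group_comparisons.csv", index=False)
    report.measure = {
        "groups": len(per_group),
        "objects_total": int(sum(len(m) for m in per_group.values())),
        "comparisons": len(comparisons),
    }


def _run_atac(config: RunConfig, outdir: Path, report: RunReport) -> None:
    summits_by_class = None
    if config.atac_sim is not None:
        reads_by_cond, truth = simulate.simulate_atac_reads(config.atac_sim)
        chrom_sizes = config.atac_sim.chrom_sizes
        truth.to_csv(outdir / "atac_peaks_truth.csv", index=False)
        for cond, reads in reads_by_cond.items():
            atac_mod.write_bed_reads(reads, outdir / f"reads_{cond}.bed")
        if len(truth):
            summits_by_class = {
                cls: grp[["chrom", "summit"]].reset_index(drop=True)
                for cls, grp in truth.groupby("class")
            }
    else:
        reads = atac_mod.read_bed_reads(config.atac_input["reads"])
        chrom_sizes = atac_mod.read_chrom_sizes(config.atac_input["chrom_sizes"])
        reads_by_cond = {"all": reads}
        if config.atac_input.get("summits"):
            raw = atac_mod.read_summits(config.atac_input["summits"])
            summits_by_class = raw

    for cond, reads in reads_by_cond.items():
        sites = atac_mod.extract_insertion_centers(reads, chrom_sizes)
        track = atac_mod.windowed_log2_enrichment(sites, chrom_sizes, config.window_size)
        atac_mod.write_bedgraph(track, outdir / f"enrichment_{cond}.bedgraph")
        if summits_by_class:
            profiles = atac_mod.summit_trend_profile(
                sites, summits_by_class, bin_bp=config.trend_bin_bp
            )
            rows = [
                {"condition": cond, "class": cls, "offset_bp": off, "relative_density": d}
                for cls, prof in profiles.items()
                for off, d in zip(prof.bin_offsets, prof.density)
            ]
            pd.DataFrame(rows).to_csv(
                outdir / f"trend_profiles_{cond}.csv", index=False
            )
        report.atac[cond] = {
            "reads_input": sites.n_input,
            "sites_retained": sites.n_retained,
            "dropped_strand": sites.n_dropped_strand,
            "dropped_bounds": sites.n_dropped_bounds,
            "windows": int(len(track.windows)),
        }


def run(config: RunConfig) -> RunReport:
    """Execute the configured stages and write the run report.

    Identical config + seed gives identical outputs.  Missing inputs fail
    before any stage executes (validated at parse time); the report's
    internal consistency is asserted before it is written.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    report.settings = {
        "stages": list(config.stages),
        "test": dataclasses.asdict(config.test),
        "window_size": config.window_size,
        "min_peptides": config.min_peptides,
    }
    if "simulate" in config.stages and "enrich" not in config.stages:
        if config.lfq_sim is not None:
            _write_lfq_sim(config, outdir)
        if config.atac_sim is not None:
            reads_by_cond, truth = simulate.simulate_atac_reads(config.atac_sim)
            truth.to_csv(outdir / "atac_peaks_truth.csv", index=False)
            for cond, reads in reads_by_cond.items():
                atac_mod.write_bed_reads(reads, outdir / f"reads_{cond}.bed")
    if "enrich" in config.stages:
        _run_enrich(config, outdir, report)
    if "measure" in config.stages and config.image_sim:
        _run_measure(config, outdir, report)
    if "atac" in config.stages and (config.atac_sim or config.atac_input):
        _run_atac(config, outdir, report)
    report.check_consistency()
    (outdir / "run_report.json").write_text(report.to_json())
    (outdir / "run_report.txt").write_text(report.to_text())
    return report
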