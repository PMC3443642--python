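"""End-to-end orchestration: simulate (or load) -> map -> deletions ->
metrics -> correlations, written as a reproducible, seeded run bundle.

Outputs in the run directory: ``genotypes.tsv``/``markers.tsv``/``bins.tsv``
(simulated runs), ``map.tsv``, ``calls.tsv``, ``metrics.tsv``, ``corr.tsv``
and ``report.md`` with the per-bin table (raw and display-rounded values)
and the correlation suite.  Every random step derives from the single
configured seed, so two runs with the same config are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import deletions as dels
from . import io, mapping, metrics, simulate, stats

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    # either simulate...
    simulate: bool = True
    sim_config: simulate.SimConfig | None = None
    # ...or load from paths
    genotypes: Path | None = None
    markers: Path | None = None
    bins: Path | None = None
    lod_schedule: tuple[float, ...] = mapping.DEFAULT_LOD_SCHEDULE
    centromere_units: str = "mb"
    alpha: float = 0.05
    # wildcard grouping tolerates scattered missing calls inside a
    # co-segregation group (exact-match grouping splits loci on every
    # failed assay)
    missing_wildcard: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        sim_cfg = None
        if raw.get("simulate", True):
            sim_kwargs = raw.get("sim", {})
            sim_kwargs.setdefault("seed", raw.get("seed", 0))
            sim_cfg = simulate.SimConfig(**sim_kwargs)
        return cls(
            out_dir=Path(raw.get("out_dir", "rhmap_run")),
            seed=int(raw.get("seed", 0)),
            simulate=bool(raw.get("simulate", True)),
            sim_config=sim_cfg,
            genotypes=Path(raw["genotypes"]) if raw.get("genotypes") else None,
            markers=Path(raw["markers"]) if raw.get("markers") else None,
            bins=Path(raw["bins"]) if raw.get("bins") else None,
            lod_schedule=tuple(raw.get("lod_schedule", mapping.DEFAULT_LOD_SCHEDULE)),
            centromere_units=raw.get("centromere_units", "mb"),
            alpha=float(raw.get("alpha", 0.05)),
            missing_wildcard=bool(raw.get("missing_wildcard", True)),
        )


@dataclass
class RunResult:
    rh_map: mapping.RHMap
    bin_spans: dict[str, tuple[float, float]]
    bin_metrics: list[metrics.BinMetrics]
    chromosome: metrics.BinMetrics
    calls: list[dels.DeletionCall]
    summaries: dict[str, dels.BinDeletionSummary]
    per_line_counts: dict[str, int]
    mean_deletion_mb: float | None
    correlations: dict[str, stats.CorrelationResult | None]
    out_dir: Path


def _stage(name: str):
    logger.info("stage: %s", name)


def run_pipeline(cfg: RunConfig) -> RunResult:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    _stage("inputs")
    if cfg.simulate:
        sim_cfg = cfg.sim_config or simulate.study_preset(cfg.seed)
        panel = simulate.simulate_panel(sim_cfg)
        matrix, markers, bin_records = panel.matrix, panel.markers, panel.bins
        io.write_genotype_matrix(matrix, out / "genotypes.tsv")
        io.write_marker_table(markers, out / "markers.tsv")
        io.write_bin_table(bin_records, out / "bins.tsv")
    else:
        if not (cfg.genotypes and cfg.markers and cfg.bins):
            raise ValueError("non-simulated runs need genotypes, markers and bins paths")
        matrix = io.read_genotype_matrix(cfg.genotypes)
        markers = io.read_marker_table(cfg.markers)
        bin_records = io.read_bin_table(cfg.bins)

    bin_order = mapping.bin_order_from_records(bin_records)
    arm_of = {b.bin_name: b.arm for b in io.named_bins(bin_records)}

    _stage("framework map")
    rh_map = mapping.build_framework_map(
        matrix,
        markers,
        cfg.lod_schedule,
        bin_order=bin_order,
        missing_wildcard=cfg.missing_wildcard,
    )
    rh_map, bin_spans = mapping.assign_bins(rh_map, markers, bin_order=bin_order)
    rh_map.write_tsv(out / "map.tsv")
    logger.info(
        "map: %d loci, %d markers, %.1f cR", rh_map.n_loci, rh_map.n_markers, rh_map.length_cR
    )

    _stage("bin metrics")
    observed_bins = [
        io.BinRecord(
            bin_name=b.bin_name,
            arm=b.arm,
            frac_start=b.frac_start,
            frac_end=b.frac_end,
            size_mb=b.size_mb,
            map_cR=bin_spans[b.bin_name][1] - bin_spans[b.bin_name][0],
            map_cM=b.map_cM,
            n_markers=b.n_markers,
        )
        for b in io.named_bins(bin_records)
        if b.bin_name in bin_spans
    ]
    per_bin, chrom = metrics.compute_bin_metrics(observed_bins)
    resolutions = {m.bin_name: m.resolution_rh_mb_per_cR for m in per_bin}

    _stage("deletion calls")
    # classify in map order so arm-scale runs are contiguous
    ordered = matrix.subset_markers(rh_map.marker_order())
    arm_by_marker = {}
    for g, b in zip(rh_map.loci, rh_map.bins):
        for mm in g.members:
            arm_by_marker[mm] = arm_of.get(b, "S")
    order_arms = [arm_by_marker[m] for m in ordered.marker_ids]
    classes = mapping.classify_lines(ordered, order_arms)
    calls: list[dels.DeletionCall] = []
    for line_id, cls in zip(matrix.line_ids, classes):
        if cls != io.INFORMATIVE:
            continue
        calls.extend(
            dels.call_deletions(
                line_id,
                matrix,
                rh_map,
                bin_spans=bin_spans,
                resolutions=resolutions,
                line_class=cls,
            )
        )
    if calls:
        summaries, per_line, mean_mb = dels.summarize_deletions(
            calls, bin_spans, matrix=matrix, rh_map=rh_map
        )
    else:
        summaries, per_line, mean_mb = {}, {}, None
    pd.DataFrame(
        [
            {
                "line_id": c.line_id,
                "first_locus": c.first_deleted_locus,
                "last_locus": c.last_deleted_locus,
                "inner_cR": round(c.inner_span_cR, 4),
                "outer_cR": round(c.outer_span_cR, 4),
                "size_cR": round(c.size_cR, 4),
                "size_mb": round(c.size_mb, 4) if c.size_mb is not None else "NA",
                "bins": ";".join(c.bins_touched),
            }
            for c in calls
        ]
    ).to_csv(out / "calls.tsv", sep="\t", index=False)

    _stage("correlations")
    arm_mb = {
        arm: sum(b.size_mb for b in io.named_bins(bin_records) if b.arm == arm)
        for arm in ("S", "L")
    }
    cdist = {
        b.bin_name: stats.centromere_distance(
            b, arm_mb.get(b.arm, 0.0), units=cfg.centromere_units
        )
        for b in io.named_bins(bin_records)
    }
    correlations = stats.correlation_suite(
        per_bin, summaries or None, cdist, alpha=cfg.alpha
    )

    _write_metrics_tsv(per_bin, chrom, out / "metrics.tsv")
    _write_corr_tsv(correlations, out / "corr.tsv")
    _write_report(cfg, per_bin, chrom, correlations, per_line, mean_mb, out / "report.md")
    return RunResult(
        rh_map=rh_map,
        bin_spans=bin_spans,
        bin_metrics=per_bin,
        chromosome=chrom,
        calls=calls,
        summaries=summaries,
        per_line_counts=per_line,
        mean_deletion_mb=mean_mb,
        correlations=correlations,
        out_dir=out,
    )


def _fmt(v, nd=4):
    if v is None:
        return "NA"
    return f"{v:.{nd}f}"


def _write_metrics_tsv(per_bin, chrom, path: Path) -> None:
    rows = []
    for m in [*per_bin, chrom]:
        disp = m.display()
        rows.append(
            {
                "bin_name": m.bin_name,
                "size_mb": m.size_mb,
                "map_cR": _fmt(m.map_cR),
                "map_cM": _fmt(m.map_cM),
                "saturation_raw": _fmt(m.saturation_mb_per_marker),
                "saturation": _fmt(disp["saturation_mb_per_marker"], 1),
                "resolution_rh_raw": _fmt(m.resolution_rh_mb_per_cR),
                "resolution_rh": _fmt(disp["resolution_rh_mb_per_cR"], 1),
                "resolution_gen_raw": _fmt(m.resolution_gen_mb_per_cM),
                "resolution_gen": _fmt(disp["resolution_gen_mb_per_cM"], 1),
                "br_freq_raw": _fmt(m.br_freq),
                "br_freq": _fmt(disp["br_freq"], 1),
                "co_freq_raw": _fmt(m.co_freq),
                "co_freq": _fmt(disp["co_freq"], 1),
                "ratio_cR_per_cM_raw": _fmt(m.ratio_cR_per_cM),
                "ratio_cR_per_cM": _fmt(disp["ratio_cR_per_cM"], 2),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_corr_tsv(correlations, path: Path) -> None:
    rows = []
    for name, res in correlations.items():
        if res is None:
            rows.append({"comparison": name, "r": "NA", "n": 0, "df": "NA",
                         "t": "NA", "p": "NA", "significant": "NA"})
        else:
            rows.append(
                {
                    "comparison": name,
                    "r": _fmt(res.r),
                    "n": res.n,
                    "df": res.df,
                    "t": _fmt(res.t_stat),
                    "p": _fmt(res.p_two_tailed, 6),
                    "significant": res.significant,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_report(cfg, per_bin, chrom, correlations, per_line, mean_mb, path: Path) -> None:
    lines = ["# RH mapping run report", ""]
    lines.append(f"seed: {cfg.seed}")
    lines.append("")
    lines.append("## Per-bin map statistics")
    lines.append("")
    header = (
        "| bin | size (Mb) | map (cR) | map (cM) | res (Mb/cR) | res (Mb/cM) "
        "| BR (cR/2 per Mb) | CO (cM/Mb) | cR/cM |"
    )
    lines.append(header)
    lines.append("|" + "---|" * 9)
    for m in [*per_bin, chrom]:
        d = m.display()
        lines.append(
            f"| {m.bin_name} | {m.size_mb:g} | {_fmt(m.map_cR, 1)} | {_fmt(m.map_cM, 1)} "
            f"| {_fmt(d['resolution_rh_mb_per_cR'], 1)} | {_fmt(d['resolution_gen_mb_per_cM'], 1)} "
            f"| {_fmt(d['br_freq'], 1)} | {_fmt(d['co_freq'], 1)} "
            f"| {_fmt(d['ratio_cR_per_cM'], 2)} |"
        )
    lines.append("")
    if per_line:
        counts = list(per_line.values())
        lines.append(
            f"deletions: {sum(counts)} calls over {len(counts)} informative lines "
            f"(mean {sum(counts) / len(counts):.2f} per line, "
            f"mean size {_fmt(mean_mb, 1)} Mb)"
        )
        lines.append("")
    lines.append("## Correlation suite")
    lines.append("")
    lines.append("| comparison | r | n | p | significant |")
    lines.append("|---|---|---|---|---|")
    for name, res in correlations.items():
        if res is None:
            lines.append(f"| {name} | NA | - | NA | NA |")
        else:
            lines.append(
                f"| {name} | {res.r:.3f} | {res.n} | {res.p_two_tailed:.4f} "
                f"| {res.significant} |"
            )
    lines.append("")
    path.write_text("\n".join(lines))
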