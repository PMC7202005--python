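"""Pipeline configuration, run logging, and the generate → measure → stats chain."""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import CLOSE_PAIRS, SINGLETONS, load_table1, load_table2_pairs
from .measure import measure_oocyte
from .stack import read_stack, write_stack
from .synthetic import SimulationParams, generate_oocyte_stack
from .stats import (
    fdr_evaluate,
    group_mean_comparison,
    pair_averaged_correlation,
    pairwise_contrasts,
    pearson_correlation,
)

__all__ = ["PipelineConfig", "RunLog", "run_pipeline", "run_stats_suite"]


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs.

    ``mode`` selects the entry point: ``synthetic`` generates stacks and
    measures them; ``measure`` measures stacks already on disk;
    ``summary`` runs the statistical layer on the bundled species table.
    """

    mode: str = "summary"  # synthetic | measure | summary
    stack_dir: str | None = None
    out_dir: str = "karyodot_out"
    pixel_size_xy: float = 0.054
    section_thickness_z: float = 0.5
    threshold_policy: str | float = "relative"
    dip_threshold: float = 0.50
    fdr_q: float | None = None  # None -> 1/(2m)
    seed: int = 0
    report_precision: int = 2
    n_stacks: int = 10
    separation_range_um: tuple[float, float] = (5.2, 7.0)
    dot_area_range_um2: tuple[float, float] = (0.25, 1.0)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "measure", "summary"):
            raise ValueError(f"unknown pipeline mode {self.mode!r}")
        if not 0 < self.dip_threshold < 1:
            raise ValueError("dip_threshold must be in (0, 1)")
        if self.pixel_size_xy <= 0 or self.section_thickness_z <= 0:
            raise ValueError("physical scales must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "separation_range_um" in raw:
            raw["separation_range_um"] = tuple(raw["separation_range_um"])
        if "dot_area_range_um2" in raw:
            raw["dot_area_range_um2"] = tuple(raw["dot_area_range_um2"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["separation_range_um"] = list(self.separation_range_um)
        d["dot_area_range_um2"] = list(self.dot_area_range_um2)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


class RunLog:
    """Append-only log of per-oocyte decisions and run parameters.

    Written as plain text; contains no wall-clock timestamps so a rerun
    with the same config and seed is byte-identical.
    """

    def __init__(self, config: PipelineConfig):
        self.lines: list[str] = [
            f"karyodot {__version__}",
            "config: "
            + ", ".join(
                f"{k}={v}" for k, v in sorted(dataclasses.asdict(config).items())
            ),
        ]

    def record(self, message: str) -> None:
        self.lines.append(message)

    def record_oocyte(self, oocyte_id: str, configuration, distance_eligible: bool, notes: str = "") -> None:
        reason = "" if distance_eligible else " [excluded from distance]"
        extra = f" ({notes})" if notes else ""
        self.lines.append(f"{oocyte_id}: {configuration.value}{reason}{extra}")

    def write(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.lines) + "\n")


def _fmt(x: float | None, ndigits: int) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "n.d."
    return f"{x:.{ndigits}f}"


def run_stats_suite(
    summary: pd.DataFrame,
    pairs: pd.DataFrame | None = None,
    Q: float | None = None,
    precision: int = 2,
) -> tuple[pd.DataFrame, list[str]]:
    """All species-level analyses on a summary table; returns (results, report lines).

    Covers the pairwise contrasts (with published p-values when supplied),
    the inversion-group comparison, the correlation set, and the
    pair-averaged correlation.
    """
    lines: list[str] = []
    rows: list[dict] = []
    nd = precision

    grp = group_mean_comparison(summary)
    lines.append(
        f"Group means (species means of dot-dot distance): polymorphic "
        f"{_fmt(grp.mean_a, nd)} um (n={grp.n_a}) vs monomorphic {_fmt(grp.mean_b, nd)} um "
        f"(n={grp.n_b}); Welch t-test P = {grp.p_value:.2f}"
    )
    rows.append({"analysis": "group_means", "value": grp.mean_a, "detail": "polymorphic_mean"})
    rows.append({"analysis": "group_means", "value": grp.mean_b, "detail": "monomorphic_mean"})
    rows.append({"analysis": "group_means", "value": grp.p_value, "detail": "welch_p"})

    if pairs is not None:
        contrasts = pairwise_contrasts(
            summary,
            list(zip(pairs["poly"], pairs["mono"])),
            pvalues=list(pairs["printed_p"]) if "printed_p" in pairs else None,
            Q=Q,
        )
        lines.append("Pairwise contrasts (poly - mono):")
        for c in contrasts:
            star = "*" if c.significant else ""
            lines.append(
                f"  {c.poly} - {c.mono}: delta = {c.delta_printed} um, "
                f"p = {c.p_value}, FDR cutoff = {c.fdr_cutoff:.3f}{star}"
            )
            rows.append(
                {
                    "analysis": "pair_contrast",
                    "value": c.delta_printed,
                    "detail": f"{c.poly}-{c.mono}",
                    "p_value": c.p_value,
                    "fdr_cutoff": c.fdr_cutoff,
                    "significant": c.significant,
                }
            )

    corr_specs = [
        ("pct_heterochromatin", "mean_distance_um", ()),
        ("mean_distance_um", "mean_dot_area_um2", ()),
        ("mean_distance_um", "proportion_out", ()),
        ("proportion_out", "mean_dot_area_um2", ()),
        ("proportion_out", "mean_dot_area_um2", ("sig",)),
    ]
    lines.append("Correlations (Pearson r, regression P):")
    for x, y, excl in corr_specs:
        res = pearson_correlation(summary, x, y, exclude=excl)
        tag = f" excluding {','.join(excl)}" if excl else ""
        lines.append(
            f"  {x} vs {y}{tag}: r = {res.r:.3f} (n = {res.n}, P = {res.p_value:.3g})"
        )
        rows.append(
            {
                "analysis": "correlation",
                "value": res.r,
                "detail": f"{x}~{y}{tag}",
                "p_value": res.p_value,
                "n": res.n,
            }
        )
    pav = pair_averaged_correlation(
        summary, "proportion_out", "mean_dot_area_um2", CLOSE_PAIRS, SINGLETONS
    )
    lines.append(
        f"  proportion_out vs mean_dot_area_um2, pair-averaged: r = {pav.r:.3f} "
        f"(n = {pav.n}, P = {pav.p_value:.3g})"
    )
    rows.append(
        {
            "analysis": "correlation",
            "value": pav.r,
            "detail": "proportion_out~mean_dot_area_um2 pair-averaged",
            "p_value": pav.p_value,
            "n": pav.n,
        }
    )
    return pd.DataFrame(rows), lines


def _measure_stacks(stacks, config: PipelineConfig, log: RunLog) -> pd.DataFrame:
    rows = []
    for oocyte_id, stack in stacks:
        m = measure_oocyte(
            stack,
            oocyte_id=oocyte_id,
            threshold=config.threshold_policy,
            dip_threshold=config.dip_threshold,
        )
        log.record_oocyte(m.oocyte_id, m.configuration, m.configuration.distance_eligible, m.notes)
        rows.append(
            {
                "oocyte_id": m.oocyte_id,
                "out_flag": m.configuration.counts_as_out,
                "configuration": m.configuration.value,
                "d_xy_um": m.d_xy_um,
                "z_sections": m.z_sections,
                "distance_um": m.distance_um,
                "area1_um2": m.dot_areas_um2[0] if len(m.dot_areas_um2) > 0 else None,
                "area2_um2": m.dot_areas_um2[1] if len(m.dot_areas_um2) > 1 else None,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute one configured run; returns the paths of everything written.

    Deterministic under a fixed seed: rerunning the same config yields
    byte-identical CSV outputs. Any stage failure raises before partial
    results are written.
    """
    out = Path(config.out_dir)
    log = RunLog(config)
    outputs: dict[str, Path] = {}

    if config.mode == "summary":
        table1 = load_table1()
        pairs = load_table2_pairs()
        results, lines = run_stats_suite(
            table1, pairs, Q=config.fdr_q, precision=config.report_precision
        )
        out.mkdir(parents=True, exist_ok=True)
        outputs["results"] = out / "stats_results.csv"
        results.to_csv(outputs["results"], index=False)
        outputs["report"] = out / "report.txt"
        outputs["report"].write_text("\n".join(lines) + "\n")
    elif config.mode in ("synthetic", "measure"):
        if config.mode == "synthetic":
            rng = np.random.default_rng(config.seed)
            stacks = []
            truths = []
            for i in range(config.n_stacks):
                params = SimulationParams(
                    pixel_size_xy=config.pixel_size_xy,
                    section_thickness_z=config.section_thickness_z,
                    true_separation_3d=float(rng.uniform(*config.separation_range_um)),
                    dot_area=float(rng.uniform(*config.dot_area_range_um2)),
                    z_offset_sections=int(rng.integers(0, 4)),
                    noise_sd=config.noise_sd,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                stack, truth = generate_oocyte_stack(params)
                stacks.append((f"synthetic_{i:04d}", stack))
                truths.append(truth)
            out.mkdir(parents=True, exist_ok=True)
            stack_dir = out / "stacks"
            stack_dir.mkdir(exist_ok=True)
            for (oid, stack), truth in zip(stacks, truths):
                write_stack(stack_dir / f"{oid}.tif", stack)
                pd.DataFrame(
                    [
                        {
                            "oocyte_id": oid,
                            "true_d_xy_um": truth.d_xy_um,
                            "true_z_um": truth.z_um,
                            "true_separation_um": truth.separation_um,
                            "true_dot_area_um2": truth.dot_areas_um2[0],
                            "configuration": truth.configuration,
                            "seed": truth.seed,
                        }
                    ]
                ).to_csv(stack_dir / f"{oid}_truth.csv", index=False)
            outputs["stacks"] = stack_dir
        else:
            if config.stack_dir is None:
                raise ValueError("measure mode needs stack_dir")
            paths = sorted(Path(config.stack_dir).glob("*.tif*"))
            if not paths:
                raise FileNotFoundError(
                    f"no TIFF stacks found in {config.stack_dir}"
                )
            stacks = [
                (
                    p.stem,
                    read_stack(p, config.pixel_size_xy, config.section_thickness_z),
                )
                for p in paths
            ]
            out.mkdir(parents=True, exist_ok=True)

        measurements = _measure_stacks(stacks, config, log)
        outputs["measurements"] = out / "measurements.csv"
        measurements.to_csv(outputs["measurements"], index=False)

        eligible = measurements["distance_um"].notna()
        n = len(measurements)
        lines = [
            f"Measured {n} stacks; {int(measurements['out_flag'].sum())} with chromosomes out; "
            f"{int(eligible.sum())} distance-eligible.",
        ]
        if eligible.any():
            lines.append(
                f"Mean dot-dot distance: {measurements.loc[eligible, 'distance_um'].mean():.2f} um"
            )
        outputs["report"] = out / "report.txt"
        outputs["report"].write_text("\n".join(lines) + "\n")

    outputs["runlog"] = out / "runlog.txt"
    log.write(outputs["runlog"])
    outputs["config"] = out / "config.yaml"
    config.to_yaml(outputs["config"])
    return outputs
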