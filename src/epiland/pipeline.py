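"""End-to-end orchestration: fitness -> slices -> metrics -> bootstrap -> trends
-> models -> report, with every stage writing a CSV artifact.

All stages are deterministic under a fixed seed; the effective configuration is
echoed into the output directory together with a run log (package version,
config hash, seed).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .core import dye_swap_check, summarize_fitness
from .inference import (
    BootstrapConfig,
    cost_of_resistance,
    environmental_quality,
    quality_mapping,
    trend_vs_environment,
)
from .io import ValidationReport, read_records, validate_frame, write_csv
from .metrics import summarize_epistasis, summary_frame
from .models import model_suite

log = logging.getLogger("epiland")

EXIT_SCHEMA = 2
EXIT_GRID = 3


@dataclass
class PipelineConfig:
    """Settings for a full pipeline run; every field has a default."""

    input: str = ""
    out_dir: str = "epiland_out"
    seed: int = 0
    bootstrap_samples: int = 1000
    alpha: float = 0.01
    ci_level: float = 0.95
    quality_metric: str = "competitor"
    ab_coding: str = "factor"
    pool_orientations: bool = True

    def bootstrap(self) -> BootstrapConfig:
        return BootstrapConfig(
            n_samples=self.bootstrap_samples, seed=self.seed, ci_level=self.ci_level
        )

    def echo(self) -> str:
        return "\n".join(f"{k} = {v}" for k, v in sorted(asdict(self).items()))

    def digest(self) -> str:
        return hashlib.sha256(self.echo().encode()).hexdigest()[:12]


def load_config(path) -> dict:
    """Parse a flat key = value config file ('#' comments, [sections] ignored)."""
    values: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line or line.startswith("["):
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        values[key.replace("-", "_")] = val
    typed = {}
    defaults = PipelineConfig()
    for key, val in values.items():
        if not hasattr(defaults, key):
            raise ValueError(f"unknown config key {key!r}")
        current = getattr(defaults, key)
        if isinstance(current, bool):
            typed[key] = val.lower() in ("1", "true", "yes")
        elif isinstance(current, int):
            typed[key] = int(val)
        elif isinstance(current, float):
            typed[key] = float(val)
        else:
            typed[key] = val
    return typed


class SchemaExit(SystemExit):
    pass


def _trend_rows(summary: pd.DataFrame, quality_map: dict, alpha: float) -> pd.DataFrame:
    metrics = ["gamma_all", "gamma_abr", "gamma_ko", "frac_reciprocal", "frac_simple", "rs_mean"]
    rows = []
    for metric in metrics:
        values = summary.rename(columns={metric: "value"})[
            ["antibiotic", "temperature", "value"]
        ]
        for pred_name, pred in (
            ("antibiotic", "antibiotic"),
            ("temperature", "temperature"),
            ("quality", quality_map),
        ):
            fit = trend_vs_environment(values, pred)
            rows.append(
                {
                    "metric": metric,
                    "predictor": pred_name,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "f_stat": fit.f_stat,
                    "df1": fit.df[0],
                    "df2": fit.df[1],
                    "p_value": fit.p_value,
                    "adj_r2": fit.adj_r2,
                    "significant": fit.p_value < alpha,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run the full analysis; returns the output directory.

    Raises SystemExit(2) on schema violations and SystemExit(3) on an
    incomplete genotype x environment grid.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info(
            "epiland %s | seed=%d | config sha256=%s", __version__, cfg.seed, cfg.digest()
        )
        (out / "run_config.txt").write_text(cfg.echo() + "\n")

        records = read_records(cfg.input)
        report = validate_frame(records)
        _write_validation(report, out)
        if report.schema_errors:
            raise SystemExit(EXIT_SCHEMA)
        if report.grid_errors:
            raise SystemExit(EXIT_GRID)

        fits = summarize_fitness(records, pool_orientations=cfg.pool_orientations)
        write_csv(fits, out / "fitness_estimates.csv")
        log.info("fitness: %d cell estimates", len(fits))

        dye = dye_swap_check(records, ci_level=cfg.ci_level)
        log.info("dye swap: slope=%.4f adjR2=%.4f", dye.slope, dye.adj_r2)

        bcfg = cfg.bootstrap()
        summaries = summarize_epistasis(fits, bcfg)
        summary = summary_frame(summaries)
        write_csv(summary, out / "epistasis_summary.csv")
        pairwise = pd.concat(
            [
                s.pairwise.assign(
                    antibiotic=s.environment.antibiotic,
                    temperature=s.environment.temperature,
                )
                for s in summaries
            ],
            ignore_index=True,
        )
        write_csv(pairwise, out / "pairwise_epistasis.csv")
        rs = pd.concat(
            [
                s.rs_ratios.assign(
                    antibiotic=s.environment.antibiotic,
                    temperature=s.environment.temperature,
                )
                for s in summaries
            ],
            ignore_index=True,
        )
        write_csv(rs, out / "rs_ratio.csv")
        log.info("epistasis: %d environments, B=%d", len(summaries), bcfg.n_samples)

        quality = environmental_quality(records, cfg.quality_metric)
        write_csv(quality, out / "quality.csv")
        trends = _trend_rows(summary, quality_mapping(quality), cfg.alpha)
        write_csv(trends, out / "trends.csv")

        cost = cost_of_resistance(fits, bcfg)
        write_csv(cost, out / "cost_of_resistance.csv")

        suite = model_suite(records, ab_coding=cfg.ab_coding)
        coefs = pd.concat(
            [f.coef_frame().assign(model=name) for name, f in suite.fits.items()],
            ignore_index=True,
        )
        write_csv(coefs, out / "model_fits.csv")
        comps = pd.DataFrame(
            [
                {
                    "reduced": pair[0],
                    "full": pair[1],
                    "f_stat": c.f_stat,
                    "df1": c.df_num,
                    "df2": c.df_den,
                    "p_value": c.p_value,
                    "significant": c.p_value < cfg.alpha,
                }
                for pair, c in suite.comparisons.items()
            ]
        )
        write_csv(comps, out / "model_comparisons.csv")

        _write_report(out, cfg, dye, summary, trends, suite, cost)
        log.info("pipeline complete -> %s", out)
        return out
    finally:
        log.removeHandler(handler)
        handler.close()


def _write_validation(report: ValidationReport, out: Path) -> None:
    (out / "validation.txt").write_text(report.summary() + "\n")


def _write_report(out, cfg, dye, summary, trends, suite, cost) -> None:
    lines = [
        f"epiland {__version__} pipeline report (seed={cfg.seed}, "
        f"B={cfg.bootstrap_samples}, alpha={cfg.alpha})",
        "",
        "Dye-swap marker neutrality:",
        f"  slope={dye.slope:.4f} (CI {dye.slope_ci[0]:.4f}..{dye.slope_ci[1]:.4f}), "
        f"intercept={dye.intercept:.4f}, adjusted R2={dye.adj_r2:.4f}, "
        f"n_pairs={dye.n_pairs}",
        "",
        "Epistasis by environment (gamma_all / reciprocal fraction / mean r/s):",
    ]
    for _, row in summary.iterrows():
        lines.append(
            f"  {row['antibiotic']:>5.1f} ug/ml, {row['temperature']:>4.1f} C: "
            f"gamma={row['gamma_all']:.3f} "
            f"recip={row['frac_reciprocal']:.3f} rs={row['rs_mean']:.3f}"
        )
    lines += ["", "Environment trends (alpha = %.3g):" % cfg.alpha]
    for _, row in trends.iterrows():
        flag = "*" if row["significant"] else " "
        lines.append(
            f" {flag}{row['metric']:<16s} ~ {row['predictor']:<11s} "
            f"slope={row['slope']:+.4f} F({row['df1']},{row['df2']})="
            f"{row['f_stat']:.2f} p={row['p_value']:.3g} adjR2={row['adj_r2']:.3f}"
        )
    lines += ["", "Nested model suite (adjusted R2):"]
    for name, fit in suite.fits.items():
        lines.append(f"  {name:<18s} adjR2={fit.adj_r2:.4f} df_resid={fit.df_resid}")
    for (red, full), comp in suite.comparisons.items():
        lines.append(
            f"  {red} vs {full}: F({comp.df_num},{comp.df_den})={comp.f_stat:.3f} "
            f"p={comp.p_value:.3g}"
        )
    n_cost = int(cost["cost"].sum())
    lines += [
        "",
        f"Cost of resistance: {n_cost}/{len(cost)} contrasts flag a cost "
        "(CI entirely below 0) at 0 ug/ml",
        "",
    ]
    (out / "report.txt").write_text("\n".join(lines))
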