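"""Single-command pipeline: diagnostics -> unit roots -> causality ->
CS-ARDL -> typology, with CSV/text reports and a JSON run manifest.

Stage order mirrors the decision-tree logic of the analysis: dependence
tests decide between first- and second-generation methods, slope
homogeneity decides between pooled and heterogeneous estimators, unit-root
tests fix the lag augmentation ``dmax``, then the heterogeneous causality
tests, the CS-ARDL robustness fit, and the country typology run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .csardl import CSARDLSpec, ect_interpretation, fit_cs_ardl
from .csd import csd_report, slope_homogeneity
from .cips import cips, integration_order
from .ek import CausalityPairResult, run_all_pairs
from .panel import BalancedPanel, read_long_panel
from .synth import (
    DGPConfig,
    FIXTURE_PAIRS,
    fixture_printed_tables,
    generate,
)
from .typology import classify_countries

logger = logging.getLogger("panelcausal")

__all__ = ["PipelineConfig", "run_pipeline", "stars", "causality_table"]

_ALL_STAGES = ("csd", "homogeneity", "unit_root", "causality", "cs_ardl", "typology")


def stars(p: float) -> str:
    """Significance stars: *** <=0.01, ** <=0.05, * <=0.10."""
    return "***" if p <= 0.01 else "**" if p <= 0.05 else "*" if p <= 0.10 else ""


@dataclass
class PipelineConfig:
    input_path: str | None = None  # long CSV; None -> synthetic
    synthetic: DGPConfig | None = None
    from_fixture: bool = False  # typology from the printed p-value fixture only
    variables: tuple[str, str, str] = ("co2", "hexp", "migr")
    unit_col: str = "country"
    period_col: str = "year"
    alpha: float = 0.10
    k_max: int = 3
    dmax: int | str = "auto"  # integer or 'auto' (from integration order)
    B: int = 1000
    seed: int = 42
    cadf_p: int = 1
    out_dir: str = "panelcausal_out"
    stages: tuple[str, ...] = _ALL_STAGES

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must lie in (0, 0.5)")
        if self.B < 100:
            raise ValueError("B must be at least 100")
        bad = set(self.stages) - set(_ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")


def causality_table(res: CausalityPairResult) -> pd.DataFrame:
    """Country rows plus a Fisher row, mirroring the reporting layout of
    heterogeneous panel causality studies (statistic, p-value columns)."""
    rows = [
        {
            "country": r.unit_id,
            "statistic": r.wald,
            "p_value": r.p_value,
            "stars": stars(r.p_value),
        }
        for r in res.per_country
    ]
    rows.append(
        {
            "country": "Fisher test statistic",
            "statistic": res.fisher_lambda,
            "p_value": res.bootstrap_p if res.bootstrap_p is not None else res.asymptotic_p,
            "stars": stars(res.bootstrap_p if res.bootstrap_p is not None else res.asymptotic_p),
        }
    )
    return pd.DataFrame(rows)


def _fmt_table(df: pd.DataFrame, title: str) -> str:
    body = df.to_string(index=False, float_format=lambda v: f"{v:.3f}")
    return f"{title}\n{'=' * len(title)}\n{body}\n"


def _config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(asdict(cfg), default=str, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the result bundle.

    Writes, per stage, one full-precision CSV and one formatted text table
    (3-decimal p-values, star convention) under ``cfg.out_dir``, plus
    ``manifest.json`` recording config, seed, versions, stage wall times and
    collected warnings. A stage failure halts the run with the stage name;
    outputs of completed stages are retained.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    warnings: list[str] = []
    timings: dict[str, float] = {}

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": cfg.seed,
        "config": json.loads(json.dumps(asdict(cfg), default=str)),
        "config_hash": _config_hash(cfg),
    }

    if cfg.from_fixture:
        pvals = fixture_printed_tables()
        profiles, summary = classify_countries(pvals, FIXTURE_PAIRS, cfg.alpha)
        _write_typology(out, profiles, summary)
        bundle["typology"] = (profiles, summary)
        manifest["warnings"] = ["fixture-only mode: printed p-values, no estimation"]
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return bundle

    # ---- load or generate the panel -------------------------------------
    if cfg.input_path is not None:
        panel = read_long_panel(
            cfg.input_path, cfg.unit_col, cfg.period_col, list(cfg.variables)
        )
    else:
        panel = generate(cfg.synthetic or DGPConfig(seed=cfg.seed))
    bundle["panel"] = panel
    if panel.N >= panel.T:
        warnings.append(
            f"N={panel.N} >= T={panel.T}: asymptotic panel inference is "
            "unreliable; bootstrap p-values are the operative ones"
        )

    def _stage(name):
        return name in cfg.stages

    try:
        if _stage("csd"):
            t0 = time.time()
            rep = csd_report(panel, list(cfg.variables))
            rows = [
                {
                    "variable": v,
                    "test": t,
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                }
                for v, tests in rep.items()
                for t, r in tests.items()
            ]
            df = pd.DataFrame(rows)
            df.to_csv(out / "csd_tests.csv", index=False)
            (out / "csd_tests.txt").write_text(
                _fmt_table(df, "Cross-sectional dependence tests")
            )
            bundle["csd"] = rep
            timings["csd"] = time.time() - t0
            logger.info("csd stage done in %.2fs", timings["csd"])

        if _stage("homogeneity"):
            t0 = time.time()
            dep, *regs = cfg.variables
            sh = slope_homogeneity(panel, dep, list(regs))
            df = pd.DataFrame(
                {
                    "test": ["delta_tilde", "delta_tilde_adj"],
                    "statistic": [sh.delta_tilde, sh.delta_tilde_adj],
                    "p_value": list(sh.p_values),
                }
            )
            df.to_csv(out / "slope_homogeneity.csv", index=False)
            (out / "slope_homogeneity.txt").write_text(
                _fmt_table(df, "Slope homogeneity (delta) tests")
            )
            bundle["homogeneity"] = sh
            timings["homogeneity"] = time.time() - t0

        dmax = cfg.dmax
        if _stage("unit_root"):
            t0 = time.time()
            summary = integration_order(panel, list(cfg.variables), p=cfg.cadf_p)
            rows = []
            for v in cfg.variables:
                lvl = cips(panel, v, cfg.cadf_p)
                rows.append(
                    {
                        "variable": v,
                        "sample": "level",
                        "cips": lvl.cips,
                        "cv_5pct": lvl.critical_values[0.05],
                        "decision_5pct": lvl.decision[0.05],
                    }
                )
            df = pd.DataFrame(rows)
            df["order"] = [summary.orders[v] for v in cfg.variables]
            df.to_csv(out / "unit_root_cips.csv", index=False)
            (out / "unit_root_cips.txt").write_text(
                _fmt_table(df, "CIPS panel unit-root tests")
            )
            bundle["unit_root"] = summary
            if dmax == "auto":
                dmax = summary.dmax
            timings["unit_root"] = time.time() - t0
        if dmax == "auto":
            dmax = 1
            warnings.append("unit_root stage skipped with dmax='auto'; using dmax=1")

        if _stage("causality"):
            t0 = time.time()
            results = run_all_pairs(
                panel, cfg.variables, B=cfg.B, seed=cfg.seed,
                k_max=cfg.k_max, dmax=int(dmax),
            )
            for res in results:
                tag = f"causality_{res.direction[0]}_to_{res.direction[1]}"
                df = causality_table(res)
                df.to_csv(out / f"{tag}.csv", index=False)
                (out / f"{tag}.txt").write_text(
                    _fmt_table(df, f"Granger causality: {res.direction[0]} -> {res.direction[1]}")
                )
                warnings.extend(res.notes)
            bundle["causality"] = results
            timings["causality"] = time.time() - t0
            logger.info("causality stage done in %.2fs", timings["causality"])

        if _stage("cs_ardl"):
            t0 = time.time()
            dep, *regs = cfg.variables
            fit = fit_cs_ardl(panel, CSARDLSpec(dep, tuple(regs)))
            rows = [
                {"block": "long_run", "term": k, "coefficient": e.mean,
                 "std_error": e.se, "t": e.t, "p_value": e.p_value}
                for k, e in fit.long_run.items()
            ] + [
                {"block": "short_run", "term": k, "coefficient": e.mean,
                 "std_error": e.se, "t": e.t, "p_value": e.p_value}
                for k, e in fit.short_run.items()
            ] + [
                {"block": "error_correction", "term": "ECT(-1)",
                 "coefficient": fit.ect.mean, "std_error": fit.ect.se,
                 "t": fit.ect.t, "p_value": fit.ect.p_value}
            ]
            df = pd.DataFrame(rows)
            df.to_csv(out / "cs_ardl.csv", index=False)
            (out / "cs_ardl.txt").write_text(
                _fmt_table(df, f"CS-ARDL mean-group estimates (dependent: {dep})")
            )
            bundle["cs_ardl"] = fit
            bundle["ect_summary"] = ect_interpretation(fit)
            warnings.extend(fit.notes)
            timings["cs_ardl"] = time.time() - t0

        if _stage("typology"):
            t0 = time.time()
            if "causality" not in bundle:
                raise RuntimeError("typology stage requires the causality stage")
            pvals: dict[str, dict[tuple[str, str], float]] = {}
            for res in bundle["causality"]:
                for r in res.per_country:
                    pvals.setdefault(r.unit_id, {})[r.direction] = r.p_value
            a, b, c = cfg.variables
            pairs = [(a, c), (b, c), (b, a)]  # (co2,migr), (hexp,migr), (hexp,co2)
            profiles, summary = classify_countries(pvals, pairs, cfg.alpha)
            _write_typology(out, profiles, summary)
            bundle["typology"] = (profiles, summary)
            timings["typology"] = time.time() - t0
    except Exception as exc:
        stage = next((s for s in cfg.stages if s not in timings), "?")
        manifest.update(
            {"failed_stage": stage, "error": str(exc), "timings_s": timings,
             "warnings": warnings}
        )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.update({"timings_s": timings, "warnings": warnings})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    bundle["manifest"] = manifest
    return bundle


def _write_typology(out: Path, profiles, summary) -> None:
    prof_rows = [
        {
            "profile": " | ".join(key),
            "countries": "; ".join(countries),
            "n": len(countries),
        }
        for key, countries in summary.profiles.items()
    ]
    pd.DataFrame(prof_rows).to_csv(out / "typology_profiles.csv", index=False)
    class_rows = [
        {"country": p.unit_id, "class": p.klass, "dominant_group": p.dominant_group}
        for p in profiles
    ]
    pd.DataFrame(class_rows).to_csv(out / "typology_classes.csv", index=False)
    (out / "typology_summary.txt").write_text(
        "Country typology\n================\n"
        + "\n".join(f"{k}: {v}" for k, v in summary.class_counts.items())
        + f"\ndistinct profiles: {summary.n_distinct_profiles}\n"
    )
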