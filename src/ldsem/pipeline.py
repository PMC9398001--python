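"""Reproducible pipeline runs: simulate -> munge -> ldsc -> fit -> report.

A run is driven by a YAML config; the validated config (defaults filled in)
is echoed into the output directory so every estimation decision is visible
per run, and rerunning with the same config and inputs is byte-identical in
all numeric artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .exceptions import ConfigurationError, DataError
from .fit import FitOptions, compare_models, fit_baseline, fit_dwls, fit_indices
from .ldsc import (GeneticCovariance, LdscFitConfig, genetic_correlations,
                   multivariate_ldsc)
from .models import (SemModel, build_factor_model, build_saturated_model,
                     build_simplex_model)
from .qc import QCThresholds, munge, read_sumstats
from .report import render_report
from .simulate import (default_design, default_factor_model,
                       default_simplex_model, implied_genetic_covariance,
                       make_ld_panel, read_ld_panel, simulate_sumstats,
                       write_ld_panel, write_sumstats)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "munge", "ldsc", "fit", "report")

__all__ = ["RunConfig", "run_pipeline", "STAGES"]


@dataclass
class RunConfig:
    """Validated settings for one pipeline run.

    Either ``simulate`` describes a synthetic dataset to generate, or
    ``sumstats`` (list of per-trait files) and ``ld_panel`` (file prefix)
    point at existing inputs. ``models`` is the roster of structural models
    to fit: each entry has ``kind`` (factor | simplex | saturated) and, for
    simplex, optional ``drop`` / ``equal_betas`` / ``equal_thetas``.
    """

    out_dir: str = "ldsem_run"
    seed: int = 0
    simulate: dict | None = None
    sumstats: list[str] = field(default_factory=list)
    ld_panel: str | None = None
    qc: dict = field(default_factory=dict)
    ldsc: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    models: list[dict] = field(default_factory=lambda: [
        {"kind": "factor"},
        {"kind": "simplex"},
        {"kind": "simplex", "drop": [6]},
        {"kind": "simplex", "drop": [2, 3, 4, 5, 6]},
    ])
    report: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path | None = None) -> str:
        payload = yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    # --- validated sub-configs -------------------------------------------
    def qc_thresholds(self) -> QCThresholds:
        q = dict(self.qc)
        if "mhc_interval" in q:
            chrom, lo, hi = q["mhc_interval"]
            q["mhc_interval"] = (str(chrom), int(lo), int(hi))
        return QCThresholds(**q)

    def ldsc_config(self) -> LdscFitConfig:
        return LdscFitConfig(**self.ldsc)

    def fit_options(self) -> FitOptions:
        return FitOptions(seed=self.seed, **self.fit)

    def build_models(self, k: int) -> list[SemModel]:
        out = []
        for spec in self.models:
            spec = dict(spec)
            kind = spec.pop("kind", None)
            if kind == "factor":
                out.append(build_factor_model(k))
            elif kind == "simplex":
                out.append(build_simplex_model(k, **spec))
            elif kind == "saturated":
                out.append(build_saturated_model(k))
            else:
                raise ConfigurationError(f"unknown model kind {kind!r}")
        return out

    def validate(self) -> None:
        """Check everything before any stage runs (exit code 2 territory)."""
        if self.simulate is None:
            if not self.sumstats or self.ld_panel is None:
                raise ConfigurationError(
                    "config needs either a 'simulate' block or both "
                    "'sumstats' and 'ld_panel'")
            for p in self.sumstats:
                if not Path(p).exists():
                    raise ConfigurationError(f"sumstats file not found: {p}")
            if not Path(str(self.ld_panel) + ".l2.ldscore").exists():
                raise ConfigurationError(
                    f"LD panel not found at prefix: {self.ld_panel}")
        else:
            kind = self.simulate.get("kind", "factor")
            if kind not in ("factor", "simplex"):
                raise ConfigurationError(f"unknown generative kind {kind!r}")
        self.qc_thresholds()
        self.ldsc_config()
        self.fit_options()
        self.build_models(k=6)


def _stage_banner(name: str) -> float:
    logger.info("=== stage: %s ===", name)
    return time.perf_counter()


def run_pipeline(config: RunConfig, start_stage: str = "simulate") -> dict:
    """Execute the pipeline from ``start_stage`` on; returns artifact paths.

    Earlier stages' artifacts are loaded from the output directory when the
    run resumes mid-pipeline. Any stage failure aborts with a stage-named
    error.
    """
    if start_stage not in STAGES:
        raise ConfigurationError(f"unknown stage {start_stage!r}")
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("ldsem")
    root.addHandler(handler)
    config.to_yaml(out / "config.yaml")
    artifacts: dict = {"out_dir": str(out)}
    start_idx = STAGES.index(start_stage)
    try:
        panel_prefix = (str(out / "panel") if config.simulate is not None
                        else str(config.ld_panel))

        if start_idx <= STAGES.index("simulate") and config.simulate is not None:
            t0 = _stage_banner("simulate")
            sim = dict(config.simulate)
            kind = sim.get("kind", "factor")
            m_snps = int(sim.get("m_snps", 20_000))
            design = default_design()
            gen = (default_factor_model() if kind == "factor"
                   else default_simplex_model())
            S_true = implied_genetic_covariance(gen, design.k)
            rng = np.random.default_rng(config.seed)
            panel = make_ld_panel(m_snps, seed=int(rng.integers(2**31 - 1)))
            stats = simulate_sumstats(S_true, design, panel,
                                      seed=int(rng.integers(2**31 - 1)))
            write_ld_panel(panel, panel_prefix)
            raw_dir = out / "sumstats"
            raw_dir.mkdir(exist_ok=True)
            config.sumstats = []
            for st in stats:
                p = raw_dir / f"{st.trait}.sumstats.tsv"
                write_sumstats(st, p)
                config.sumstats.append(str(p))
            np.savetxt(out / "S_true.txt", S_true, fmt="%.6f")
            logger.info("simulate done in %.1fs", time.perf_counter() - t0)

        munged_dir = out / "munged"
        if start_idx <= STAGES.index("munge"):
            t0 = _stage_banner("munge")
            paths = list(config.sumstats)
            if not paths and config.simulate is not None:
                paths = sorted(str(p) for p in (out / "sumstats").glob("*.sumstats.tsv"))
            if not paths:
                raise DataError("no raw sumstats to munge")
            stats = [read_sumstats(Path(p),
                                   trait=Path(p).name.replace(".sumstats.tsv", ""))
                     for p in paths]
            thresholds = config.qc_thresholds()
            if config.simulate is not None and "mhc_interval" not in config.qc:
                # synthetic data lives on chromosome "1"; filter the same span
                thresholds = QCThresholds(
                    maf_min=thresholds.maf_min, info_min=thresholds.info_min,
                    mhc_interval=("1", 26_000_000, 34_000_000))
            stats, qc_report = munge(stats, thresholds)
            munged_dir.mkdir(exist_ok=True)
            for st in stats:
                write_sumstats(st, munged_dir / f"{st.trait}.sumstats.tsv")
            qc_report.to_json(out / "qc_report.json")
            artifacts["qc_report"] = str(out / "qc_report.json")
            logger.info("munge done in %.1fs", time.perf_counter() - t0)

        if start_idx <= STAGES.index("ldsc"):
            t0 = _stage_banner("ldsc")
            if start_idx == STAGES.index("ldsc"):
                paths = sorted(munged_dir.glob("*.sumstats.tsv"))
                if not paths:
                    raise DataError(f"no munged sumstats under {munged_dir}")
                stats = [read_sumstats(p, trait=p.name.replace(".sumstats.tsv", ""))
                         for p in paths]
            panel = read_ld_panel(panel_prefix)
            gc = multivariate_ldsc(stats, panel, config.ldsc_config())
            gc.to_json(out / "gc.json")
            np.savetxt(out / "S.txt", gc.S, fmt="%.6f")
            np.savetxt(out / "R.txt", genetic_correlations(gc), fmt="%.4f")
            artifacts["gc"] = str(out / "gc.json")
            logger.info("ldsc done in %.1fs", time.perf_counter() - t0)
        elif start_idx > STAGES.index("ldsc"):
            gc = GeneticCovariance.from_json(out / "gc.json")

        comparison = None
        if start_idx <= STAGES.index("fit") and config.models:
            t0 = _stage_banner("fit")
            opts = config.fit_options()
            base = fit_baseline(gc, opts)
            fit_dir = out / "fits"
            fit_dir.mkdir(exist_ok=True)
            fits = []
            for model in config.build_models(gc.k):
                res = fit_indices(fit_dwls(model, gc, opts), base)
                res.to_json(fit_dir / f"{model.name}.json")
                fits.append(res)
            base.to_json(fit_dir / "independence.json")
            comparison = compare_models(fits)
            comparison.to_csv(out / "comparison.tsv", sep="\t", index=False,
                              float_format="%.6f")
            (out / "comparison.json").write_text(json.dumps({
                "table": json.loads(comparison.to_json(orient="records")),
                "winner": comparison.attrs["winner"],
                "tied": comparison.attrs["tied"]}, indent=2) + "\n")
            artifacts["comparison"] = str(out / "comparison.tsv")
            logger.info("fit done in %.1fs", time.perf_counter() - t0)

        if config.report and start_idx <= STAGES.index("report"):
            text = render_report(gc=gc, comparison=comparison)
            (out / "report.md").write_text(text + "\n")
            artifacts["report"] = str(out / "report.md")
    except Exception as exc:
        logger.error("pipeline failed: %s", exc)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    return artifacts
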