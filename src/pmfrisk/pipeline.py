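"""End-to-end orchestration: data -> contamination -> PMF -> risk -> Monte Carlo.

A single :class:`RunConfig` (loadable from YAML) drives every stage; all
randomness flows from the config's seeds, so a run is replayable
bit-identically from its manifest. Each stage failure aborts with a
stage-named message.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contamination import contamination_report
from .core_data import (
    ELEMENT_ORDER,
    SURVEY_MEAN_PH,
    default_element_registry,
    load_samples,
    write_samples,
)
from .pmf import (
    bootstrap_stability,
    build_uncertainty,
    contribution_shares,
    diagnostics,
    fit_pmf,
    profile_percentages,
    scan_factors,
)
from .prob_risk import (
    ParameterDistribution,
    default_distributions,
    simulate_risk,
    summarize,
)
from .source_risk import (
    ADULTS,
    CHILDREN,
    allocate_concentrations,
    risk_shares,
    risk_table,
)
from .synthetic_data import FACTOR_NAMES, surveylike_dataset

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@contextmanager
def _stage(name: str, timings: dict[str, float]):
    logger.info("stage %s: start", name)
    t0 = time.perf_counter()
    try:
        yield
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(f"stage '{name}' failed: {exc}") from exc
    timings[name] = round(time.perf_counter() - t0, 3)
    logger.info("stage %s: done in %.2fs", name, timings[name])


@dataclass
class RunConfig:
    """Everything needed to replay an analysis run."""

    input_path: str | None = None
    synthetic: Mapping[str, Any] | None = None  # {"n": 500, "seed": 0, ...}
    registry_overrides: Mapping[str, Mapping[str, Any]] | None = None
    background: str = "shandong"
    include_screening: bool = True
    error_fraction: float = 0.10
    n_factors: int | None = 4
    p_range: tuple[int, int] | None = None
    n_starts: int = 20
    robust: bool = False
    pmf_seed: int = 0
    max_iter: int = 5000
    n_boot: int = 0
    exposure_overrides: Mapping[str, Mapping[str, float]] | None = None
    distributions: Mapping[str, list[Mapping[str, Any]]] | None = None
    n_iter: int = 10_000
    mc_seed: int = 0
    outdir: str = "pmfrisk_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "p_range" in raw and raw["p_range"] is not None:
            raw["p_range"] = tuple(raw["p_range"])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = {}
        for k in self.__dataclass_fields__:
            v = getattr(self, k)
            out[k] = list(v) if isinstance(v, tuple) else v
        return out


def _scenarios(cfg: RunConfig) -> dict:
    scen = {"children": CHILDREN, "adults": ADULTS}
    if cfg.exposure_overrides:
        for pop, over in cfg.exposure_overrides.items():
            scen[pop] = scen[pop].with_overrides(**over)
    return scen


def _distributions(cfg: RunConfig, population: str) -> list[ParameterDistribution]:
    if cfg.distributions and population in cfg.distributions:
        return [
            ParameterDistribution(d["name"], d["family"], d["params"])
            for d in cfg.distributions[population]
        ]
    return default_distributions(population)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and write artifacts + a reproducibility manifest.

    Returns the manifest dict (also written to ``<outdir>/manifest.json``).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": cfg.to_dict(),
        "complete": False,
    }
    registry = default_element_registry(cfg.registry_overrides)

    with _stage("load_data", timings):
        if cfg.input_path is not None:
            table = load_samples(cfg.input_path, registry=registry)
            manifest["input_sha256"] = hashlib.sha256(
                Path(cfg.input_path).read_bytes()
            ).hexdigest()
            truth = None
        elif cfg.synthetic is not None:
            syn = dict(cfg.synthetic)
            table, truth = surveylike_dataset(
                n=int(syn.get("n", 500)),
                seed=int(syn.get("seed", 0)),
                sigma=float(syn.get("sigma", 1.0)),
                noise_mult_sd=float(syn.get("noise_mult_sd", 0.10)),
                registry=registry,
            )
            write_samples(table, outdir / "samples.csv")
            truth.to_json(outdir / "truth.json")
            manifest["input_sha256"] = hashlib.sha256(
                (outdir / "samples.csv").read_bytes()
            ).hexdigest()
        else:
            raise ValueError("config must set input_path or synthetic")

    with _stage("contamination", timings):
        report = contamination_report(
            table, registry, background=cfg.background,
            include_screening=cfg.include_screening,
        )
        report.to_csv(outdir / "contamination_summary.csv")

    with _stage("uncertainty", timings):
        unc = build_uncertainty(table, registry, cfg.error_fraction)

    scan = None
    if cfg.p_range is not None:
        with _stage("pmf_scan", timings):
            lo, hi = cfg.p_range
            scan = scan_factors(
                unc.working_conc, unc, p_range=range(lo, hi + 1),
                n_starts=cfg.n_starts, seed=cfg.pmf_seed,
                robust=cfg.robust, max_iter=cfg.max_iter,
            )
            scan.report.to_csv(outdir / "factor_scan.csv")
            manifest["factor_scan"] = {
                "suggested_p": scan.suggested_p,
                "report": scan.report.reset_index().to_dict(orient="records"),
            }

    with _stage("pmf_fit", timings):
        p = cfg.n_factors
        if p is None:
            if scan is None or scan.suggested_p is None:
                raise ValueError("n_factors not set and no factor scan suggestion")
            p = scan.suggested_p
        model = fit_pmf(
            unc.working_conc, unc, p, n_starts=cfg.n_starts,
            seed=cfg.pmf_seed, robust=cfg.robust, max_iter=cfg.max_iter,
        )
        names = list(FACTOR_NAMES) if p == len(FACTOR_NAMES) else [
            f"factor_{k + 1}" for k in range(p)
        ]
        pd.DataFrame(model.g, index=table.conc.index, columns=names).to_csv(
            outdir / "pmf_contributions.csv"
        )
        pd.DataFrame(model.f, index=names, columns=table.elements).to_csv(
            outdir / "pmf_profiles.csv"
        )
        pd.DataFrame(
            profile_percentages(model), index=names, columns=table.elements
        ).to_csv(outdir / "profile_percentages.csv")
        pd.Series(contribution_shares(model), index=names, name="share_pct").to_csv(
            outdir / "contribution_shares.csv"
        )
        diag = diagnostics(model, elements=table.elements)
        manifest["pmf"] = {
            "p": p, "q_true": model.q_true, "q_robust": model.q_robust,
            "q_theoretical": model.q_theoretical, "converged": model.converged,
            "n_starts": model.n_starts, "seed": model.seed,
            "resid_fraction_within_3": diag["overall_fraction_within_3"],
        }

    if cfg.n_boot:
        with _stage("bootstrap", timings):
            rates = bootstrap_stability(
                unc.working_conc, unc, model, n_boot=cfg.n_boot, seed=cfg.pmf_seed
            )
            manifest["bootstrap_mapping_rates"] = dict(zip(names, rates.tolist()))

    with _stage("allocation", timings):
        alloc = allocate_concentrations(table, model, source_names=names)
        alloc.mean_conc_by_source().to_csv(outdir / "mean_conc_by_source.csv")

    scenarios = _scenarios(cfg)
    risk_tables = {}
    with _stage("deterministic_risk", timings):
        for pop, scen in scenarios.items():
            rt = risk_table(alloc, scen, registry)
            rt.to_csv(outdir / f"risk_{pop}.csv")
            risk_shares(rt).to_csv(outdir / f"risk_shares_{pop}.csv")
            risk_tables[pop] = rt
            manifest[f"hi_{pop}"] = float(rt.hi["Total"])
            manifest[f"exposure_{pop}"] = {
                f: getattr(scen, f)
                for f in scen.__dataclass_fields__ if f != "population"
            }

    with _stage("monte_carlo", timings):
        mc_summary = {}
        for pop, scen in scenarios.items():
            dists = _distributions(cfg, pop)
            sims = simulate_risk(
                alloc.mean_conc_by_source(), dists, registry, scen,
                n_iter=cfg.n_iter, seed=cfg.mc_seed,
            )
            mc_summary[pop] = {src: summarize(rd) for src, rd in sims.items()}
            mc_summary[pop]["distributions"] = [
                {"name": d.name, "family": d.family, "params": dict(d.params)}
                for d in dists
            ]
        (outdir / "monte_carlo.json").write_text(json.dumps(mc_summary, indent=2))
        manifest["monte_carlo"] = mc_summary

    manifest["timings_s"] = timings
    manifest["complete"] = True
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
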