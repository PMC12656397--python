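"""Monte Carlo probabilistic health risk.

Exposure parameters are drawn from configured distributions (mutually
independent), propagated through the source-oriented hazard-quotient model,
and summarized as hazard-index (HI) distributions per source and in total,
with the probability of exceeding the HI = 1 safety threshold.

Distribution families: ``point``, ``uniform``, ``triangular``,
``normal_truncated_at_0`` and ``lognormal`` (lognormal is parameterized by
its natural-scale mean and sd, moment-matched to the log scale). All draws
are strictly positive. Percentiles use linear interpolation between order
statistics; the conventional "95% confidence" band is reported as the
5th-95th percentile interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import ElementMeta
from .source_risk import ADULTS, CHILDREN, PATHWAYS, ExposureScenario

FAMILIES: tuple[str, ...] = (
    "point", "uniform", "triangular", "normal_truncated_at_0", "lognormal",
)


@dataclass(frozen=True)
class ParameterDistribution:
    """A named exposure-parameter distribution.

    ``name`` must be an :class:`ExposureScenario` field (e.g. ``bw``,
    ``ir_ing``); ``params`` are family-specific:

    * point: ``value``
    * uniform: ``low``, ``high``
    * triangular: ``left``, ``mode``, ``right``
    * normal_truncated_at_0: ``mean``, ``sd``
    * lognormal: ``mean``, ``sd`` (natural scale)
    """

    name: str
    family: str
    params: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        p = self.params
        if self.family == "uniform" and not p["low"] < p["high"]:
            raise ValueError(f"{self.name}: need low < high")
        if self.family == "triangular" and not p["left"] <= p["mode"] <= p["right"]:
            raise ValueError(f"{self.name}: need left <= mode <= right")
        if self.family in ("normal_truncated_at_0", "lognormal"):
            if not (p["mean"] > 0 and p["sd"] > 0):
                raise ValueError(f"{self.name}: mean and sd must be > 0")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        p = self.params
        if self.family == "point":
            return np.full(size, float(p["value"]))
        if self.family == "uniform":
            return rng.uniform(p["low"], p["high"], size)
        if self.family == "triangular":
            if p["left"] == p["right"]:
                return np.full(size, float(p["mode"]))
            return rng.triangular(p["left"], p["mode"], p["right"], size)
        if self.family == "normal_truncated_at_0":
            a = (0.0 - p["mean"]) / p["sd"]
            return stats.truncnorm.rvs(
                a, np.inf, loc=p["mean"], scale=p["sd"], size=size,
                random_state=rng,
            )
        # lognormal, moment-matched from natural-scale mean/sd
        mu, sigma = lognormal_log_params(p["mean"], p["sd"])
        return rng.lognormal(mu, sigma, size)


def lognormal_log_params(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of a lognormal with given natural-scale moments."""
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - 0.5 * sigma2, float(np.sqrt(sigma2))


def default_distributions(population: str) -> list[ParameterDistribution]:
    """Conventional probabilistic choices: BW lognormal, IR_ing and EF
    triangular, everything else at its deterministic point value."""
    if population == "children":
        bw_mean, bw_sd = 15.0, 2.0
        ir = (100.0, 200.0, 300.0)
    elif population == "adults":
        bw_mean, bw_sd = 70.0, 10.0
        ir = (50.0, 100.0, 150.0)
    else:
        raise ValueError(f"unknown population {population!r}")
    return [
        ParameterDistribution("bw", "lognormal", {"mean": bw_mean, "sd": bw_sd}),
        ParameterDistribution(
            "ir_ing", "triangular", {"left": ir[0], "mode": ir[1], "right": ir[2]}
        ),
        ParameterDistribution(
            "ef", "triangular", {"left": 180.0, "mode": 350.0, "right": 365.0}
        ),
    ]


def sample_parameters(
    dists: Sequence[ParameterDistribution], n_iter: int, seed: int
) -> pd.DataFrame:
    """n_iter independent joint draws, one column per parameter."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    return pd.DataFrame({d.name: d.sample(rng, n_iter) for d in dists})


@dataclass
class RiskDistribution:
    """Simulated hazard-index draws for one source (or the total)."""

    draws: np.ndarray
    n_iter: int
    seed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.draws))

    @property
    def p5(self) -> float:
        return float(np.percentile(self.draws, 5))

    @property
    def p50(self) -> float:
        return float(np.percentile(self.draws, 50))

    @property
    def p95(self) -> float:
        return float(np.percentile(self.draws, 95))

    @property
    def p_exceed(self) -> float:
        return exceedance_probability(self)


def exceedance_probability(rd: RiskDistribution, threshold: float = 1.0) -> float:
    """Fraction of draws strictly above ``threshold``."""
    if rd.draws.size == 0:
        raise ValueError("no draws")
    return float(np.mean(rd.draws > threshold))


def summarize(rd: RiskDistribution) -> dict:
    """Mean, 5/50/95th percentiles and exceedance probability of an HI draw."""
    return {
        "mean": rd.mean, "p5": rd.p5, "p50": rd.p50, "p95": rd.p95,
        "p_exceed": rd.p_exceed, "n_iter": rd.n_iter,
    }


def _scenario_arrays(
    base: ExposureScenario,
    dists: Sequence[ParameterDistribution],
    n_iter: int,
    seed: int,
) -> dict[str, np.ndarray]:
    """Per-iteration parameter arrays: base point values overridden by draws.

    If exposure duration is sampled but averaging time is not, AT tracks
    ED * 365 (the non-carcinogenic convention).
    """
    fields = ("ir_ing", "ir_inh", "sa", "af", "abs_dermal",
              "pef", "ef", "ed", "bw", "at")
    arrays = {f: np.full(n_iter, float(getattr(base, f))) for f in fields}
    draws = sample_parameters(dists, n_iter, seed)
    for name in draws.columns:
        if name not in arrays:
            raise KeyError(f"unknown exposure parameter {name!r}")
        arrays[name] = draws[name].to_numpy()
    sampled = {d.name for d in dists}
    if "ed" in sampled and "at" not in sampled:
        arrays["at"] = arrays["ed"] * 365.0
    return arrays


def simulate_risk(
    conc_by_source: pd.DataFrame,
    dists: Sequence[ParameterDistribution],
    registry: Mapping[str, ElementMeta],
    base_scenario: ExposureScenario,
    n_iter: int = 10_000,
    seed: int = 0,
) -> dict[str, RiskDistribution]:
    """Monte Carlo HI distributions per source and in total.

    ``conc_by_source`` is source x element mean concentrations (mg/kg), e.g.
    from ``SourceAllocation.mean_conc_by_source``. Each iteration draws one
    joint parameter set and evaluates the deterministic hazard model, so the
    total draw equals the sum of the per-source draws iteration-wise, and
    all-point distributions reproduce the deterministic HI exactly.
    """
    a = _scenario_arrays(base_scenario, dists, n_iter, seed)
    elements = list(conc_by_source.columns)
    conc = conc_by_source.to_numpy(dtype=float)  # p x m

    chronic = a["ef"] * a["ed"] / (a["bw"] * a["at"])  # n_iter
    # per-iteration dose coefficient per pathway (multiply by conc for ADD)
    coef = {
        "ing": a["ir_ing"] * chronic * 1e-6,
        "inh": a["ir_inh"] * a["ef"] * a["ed"] / (a["pef"] * a["bw"] * a["at"]),
        "dermal": a["sa"] * a["af"] * a["abs_dermal"] * chronic * 1e-6,
    }
    rfd = {
        pw: np.array([getattr(registry[e], f"rfd_{pw}") for e in elements])
        for pw in PATHWAYS
    }
    # HI per source: sum_j c_lj * sum_pw coef_pw / rfd_pw[j]
    per_conc_hq = sum(
        np.outer(coef[pw], 1.0 / rfd[pw]) for pw in PATHWAYS
    )  # n_iter x m
    hi = per_conc_hq @ conc.T  # n_iter x p

    out = {
        str(src): RiskDistribution(draws=hi[:, l], n_iter=n_iter, seed=seed)
        for l, src in enumerate(conc_by_source.index)
    }
    out["total"] = RiskDistribution(draws=hi.sum(axis=1), n_iter=n_iter, seed=seed)
    return out
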