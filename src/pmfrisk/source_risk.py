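"""Source-oriented non-carcinogenic health risk (USEPA hazard-quotient model).

Measured concentrations are first allocated across the receptor-model sources
cell by cell: the share of source l in sample i, element j is the modelled
term g_il * f_lj divided by the reconstructed total, and the allocated
concentration is that share times the *measured* value, so the sources sum
exactly to the measurement (mass conservation).

Average daily doses (ADD, mg/(kg*day)) for three exposure pathways follow the
USEPA residential-soil model:

    ADD_ing    = C * IRing * EF * ED / (BW * AT) * 1e-6
    ADD_inh    = C * IRinh * EF * ED / (PEF * BW * AT)
    ADD_dermal = C * SA * AF * ABS * EF * ED / (BW * AT) * 1e-6

The hazard quotient is ADD divided by the pathway-specific reference dose,
the element hazard is the sum over pathways, and the hazard index (HI) sums
over elements; HI > 1 flags potential non-carcinogenic risk. Because every
equation is linear in concentration, per-source risks add up exactly to the
total-concentration risk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import ElementMeta, SampleTable
from .pmf import PMFModel

logger = logging.getLogger(__name__)

PATHWAYS: tuple[str, ...] = ("ing", "inh", "dermal")


@dataclass(frozen=True)
class ExposureScenario:
    """Population-specific exposure parameters (USEPA residential soil).

    Units: ir_ing mg/day; ir_inh m3/day; sa cm2; af mg/(cm2*day); abs_dermal
    unitless; pef m3/kg; ef day/year; ed year; bw kg; at day. For
    non-carcinogenic assessment at = ed * 365.
    """

    population: str
    ir_ing: float
    ir_inh: float
    sa: float
    af: float
    abs_dermal: float
    pef: float
    ef: float
    ed: float
    bw: float
    at: float

    def __post_init__(self) -> None:
        for name in ("ir_ing", "ir_inh", "sa", "af", "abs_dermal",
                     "pef", "ef", "ed", "bw", "at"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    def with_overrides(self, **kwargs) -> "ExposureScenario":
        return replace(self, **kwargs)


#: Default child receptor (residential soil exposure).
CHILDREN = ExposureScenario(
    population="children", ir_ing=200.0, ir_inh=7.6, sa=2800.0, af=0.2,
    abs_dermal=0.001, pef=1.36e9, ef=350.0, ed=6.0, bw=15.0, at=2190.0,
)

#: Default adult receptor.
ADULTS = ExposureScenario(
    population="adults", ir_ing=100.0, ir_inh=20.0, sa=5700.0, af=0.07,
    abs_dermal=0.001, pef=1.36e9, ef=350.0, ed=24.0, bw=70.0, at=8760.0,
)


@dataclass
class SourceAllocation:
    """Per-cell split of measured concentrations across sources.

    ``share`` and ``conc_by_source`` are (n samples x m elements x p sources);
    shares sum to 1 and allocated concentrations to the measured value over
    the source axis.
    """

    share: np.ndarray
    conc_by_source: np.ndarray
    elements: list[str]
    source_names: list[str]
    sample_index: pd.Index

    def mean_conc_by_source(self) -> pd.DataFrame:
        """Source x element mean allocated concentration (mg/kg)."""
        return pd.DataFrame(
            self.conc_by_source.mean(axis=0).T,
            index=pd.Index(self.source_names, name="source"),
            columns=self.elements,
        )


def allocate_concentrations(
    table: SampleTable,
    model: PMFModel,
    source_names: Sequence[str] | None = None,
) -> SourceAllocation:
    """Split each measured concentration across the fitted sources.

    share(i, j, l) = g_il * f_lj / sum_l g_il * f_lj. Cells whose
    reconstruction is zero while the measurement is positive fall back to the
    element's factor mass shares (logged, never silent).
    """
    conc = table.conc.to_numpy(dtype=float)
    n, m = conc.shape
    p = model.n_factors
    if model.f.shape[1] != m:
        raise ValueError("model was fitted on a different element set")
    names = list(source_names) if source_names is not None else [
        f"factor_{k + 1}" for k in range(p)
    ]

    parts = model.g[:, None, :] * model.f.T[None, :, :]  # n x m x p
    totals = parts.sum(axis=2)
    share = np.empty_like(parts)
    ok = totals > 0
    share[ok] = parts[ok] / totals[ok, None]
    if (~ok).any():
        # fall back to the element's overall factor mass shares
        # (uniform if those are zero too)
        elem_mass = model.g.sum(axis=0)[None, :] * model.f.T  # m x p
        elem_total = elem_mass.sum(axis=1, keepdims=True)
        elem_share = np.where(
            elem_total > 0, elem_mass / np.maximum(elem_total, 1e-300), 1.0 / p
        )
        bad_i, bad_j = np.nonzero(~ok)
        share[~ok] = elem_share[bad_j]
        n_bad = int((~ok & (conc > 0)).sum())
        if n_bad:
            logger.warning(
                "%d cells had zero reconstruction with positive measurement; "
                "used element-level factor mass shares", n_bad,
            )
    return SourceAllocation(
        share=share,
        conc_by_source=share * conc[:, :, None],
        elements=table.elements,
        source_names=names,
        sample_index=table.conc.index,
    )


def average_daily_dose(conc, scen: ExposureScenario, pathway: str):
    """ADD (mg/(kg*day)) for one pathway; vectorized over ``conc`` (mg/kg)."""
    conc = np.asarray(conc, dtype=float)
    chronic = scen.ef * scen.ed / (scen.bw * scen.at)
    if pathway == "ing":
        add = conc * scen.ir_ing * chronic * 1e-6
    elif pathway == "inh":
        add = conc * scen.ir_inh * scen.ef * scen.ed / (scen.pef * scen.bw * scen.at)
    elif pathway == "dermal":
        add = conc * scen.sa * scen.af * scen.abs_dermal * chronic * 1e-6
    else:
        raise ValueError(f"unknown pathway {pathway!r}; expected one of {PATHWAYS}")
    return add.item() if add.ndim == 0 else add


def hazard_quotient(conc, scen: ExposureScenario, meta: ElementMeta) -> dict:
    """Per-pathway HQs and their sum for one element at concentration ``conc``."""
    rfd = {"ing": meta.rfd_ing, "inh": meta.rfd_inh, "dermal": meta.rfd_dermal}
    out = {pw: average_daily_dose(conc, scen, pw) / rfd[pw] for pw in PATHWAYS}
    out["total"] = sum(out[pw] for pw in PATHWAYS)
    return out


@dataclass
class RiskTable:
    """Per-source x per-element hazard quotients and hazard indices.

    ``hq`` has one row per source plus a ``Total`` row; columns are element
    HQs (summed over pathways) plus ``HI``. ``hq_by_pathway`` keeps the
    pathway-resolved values.
    """

    hq: pd.DataFrame
    hq_by_pathway: dict[str, pd.DataFrame]
    population: str

    @property
    def hi(self) -> pd.Series:
        return self.hq["HI"]

    def to_csv(self, path) -> None:
        self.hq.to_csv(path)


def risk_table(
    alloc: SourceAllocation,
    scen: ExposureScenario,
    registry: Mapping[str, ElementMeta],
) -> RiskTable:
    """Deterministic per-source risk on source-allocated mean concentrations."""
    mean_by_source = alloc.mean_conc_by_source()
    if mean_by_source.empty:
        raise ValueError("empty allocation")
    rows = list(mean_by_source.index) + ["Total"]
    conc = np.vstack([mean_by_source.to_numpy(),
                      mean_by_source.to_numpy().sum(axis=0)])
    hq_path: dict[str, pd.DataFrame] = {}
    total = np.zeros_like(conc)
    for pw in PATHWAYS:
        rfd = np.array([getattr(registry[e], f"rfd_{pw}") for e in alloc.elements])
        hq = average_daily_dose(conc, scen, pw) / rfd
        hq_path[pw] = pd.DataFrame(hq, index=rows, columns=alloc.elements)
        total += hq
    hq_df = pd.DataFrame(total, index=pd.Index(rows, name="source"),
                         columns=alloc.elements)
    hq_df["HI"] = hq_df.sum(axis=1)
    return RiskTable(hq=hq_df, hq_by_pathway=hq_path, population=scen.population)


def risk_shares(rt: RiskTable) -> pd.Series:
    """Each source's percentage of the total hazard index (sums to 100)."""
    hi = rt.hi.drop("Total")
    total = rt.hi["Total"]
    if not total > 0:
        raise ValueError("total HI is zero; shares undefined")
    return 100.0 * hi / total


def element_hazard_quotients(
    mean_conc: Mapping[str, float],
    scen: ExposureScenario,
    registry: Mapping[str, ElementMeta],
) -> pd.Series:
    """Element HQs (summed over pathways) from mean concentrations.

    The deterministic total-concentration view: what the risk table's Total
    row reports, computed directly from the element means.
    """
    return pd.Series(
        {
            e: hazard_quotient(c, scen, registry[e])["total"]
            for e, c in mean_conc.items()
        },
        name=f"HQ_{scen.population}",
    )
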