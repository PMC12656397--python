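"""Contamination indices for topsoil PTE surveys.

Three complementary screens:

* **Contamination factor (CF)** — the ratio of a sample's concentration to a
  regional background value, classified on the Hakanson bands
  (CF < 1 low; 1 <= CF < 3 moderate; 3 <= CF < 6 considerable; CF >= 6 very
  high).
* **Sediment-quality guideline flags** — position of a concentration relative
  to the NOAA Effects Range-Low / Effects Range-Median thresholds.
* **Agricultural screening-value exceedance** — per-element fraction of
  samples strictly above the pH-banded risk screening value (and above three
  times it), GB15618-2018 style.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core_data import ElementMeta, SampleTable

CF_BANDS: tuple[str, ...] = ("low", "moderate", "considerable", "very_high")
_CF_EDGES = np.array([1.0, 3.0, 6.0])

SQG_FLAGS: tuple[str, ...] = ("below_ERL", "ERL_to_ERM", "above_ERM")


def contamination_factor(cs, cbackground):
    """CF = sample concentration / background concentration (both mg/kg).

    Accepts scalars or arrays; homogeneous of degree one in ``cs``.
    """
    cs = np.asarray(cs, dtype=float)
    cb = np.asarray(cbackground, dtype=float)
    if (cb <= 0).any():
        raise ValueError("background concentration must be > 0")
    if (cs < 0).any():
        raise ValueError("sample concentration must be >= 0")
    out = cs / cb
    return out.item() if out.ndim == 0 else out


def classify_cf(cf):
    """Hakanson band for a CF value; boundaries belong to the upper band."""
    cf_arr = np.asarray(cf, dtype=float)
    if (cf_arr < 0).any():
        raise ValueError("CF must be >= 0")
    idx = np.searchsorted(_CF_EDGES, cf_arr, side="right")
    bands = np.array(CF_BANDS, dtype=object)[idx]
    return str(bands) if cf_arr.ndim == 0 else bands


def sqg_flag(conc: float, meta: ElementMeta) -> str:
    """Position of a concentration against the element's ERL/ERM thresholds."""
    if meta.erl is None or meta.erm is None:
        raise ValueError(f"{meta.element}: ERL/ERM not defined")
    if conc < meta.erl:
        return "below_ERL"
    if conc < meta.erm:
        return "ERL_to_ERM"
    return "above_ERM"


def screening_exceedance(
    table: SampleTable, registry: Mapping[str, ElementMeta]
) -> pd.DataFrame:
    """Per-element fraction of samples strictly above the pH-banded SV.

    Returns a frame with columns ``frac_above_sv`` and ``frac_above_3sv``.
    Requires a pH for every sample (the SV depends on the pH band).
    """
    ph = table.require_ph()
    sv = np.empty((table.n_samples, len(table.elements)))
    for i, p in enumerate(ph.to_numpy(dtype=float)):
        sv[i] = [registry[e].screening_value(p) for e in table.elements]
    conc = table.conc.to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "frac_above_sv": (conc > sv).mean(axis=0),
            "frac_above_3sv": (conc > 3.0 * sv).mean(axis=0),
        },
        index=pd.Index(table.elements, name="element"),
    )


@dataclass
class ContaminationReport:
    """Full contamination screen of a survey table.

    ``cf``/``cf_class``/``sqg`` are per-sample-per-element; ``summary`` is the
    per-element view matching how surveys are reported: CF of the mean
    concentration (ratio of means), mean of per-sample CFs, the Hakanson band
    and SQG flag of the mean, and the screening-value exceedance fractions.
    """

    cf: pd.DataFrame
    cf_class: pd.DataFrame
    sqg: pd.DataFrame
    summary: pd.DataFrame

    def to_csv(self, path) -> None:
        self.summary.to_csv(path)


def contamination_report(
    table: SampleTable,
    registry: Mapping[str, ElementMeta],
    background: str = "shandong",
    include_screening: bool = True,
) -> ContaminationReport:
    """Compute CF, Hakanson bands, SQG flags and SV exceedance for a table.

    ``background`` selects the reference set: ``"shandong"`` (provincial,
    default) or ``"national"``.
    """
    if background not in ("shandong", "national"):
        raise ValueError(f"unknown background set {background!r}")
    attr = "bv_shandong" if background == "shandong" else "bv_national"
    bv = np.array([getattr(registry[e], attr) for e in table.elements])
    conc = table.conc.to_numpy(dtype=float)

    cf = pd.DataFrame(
        contamination_factor(conc, bv), index=table.conc.index, columns=table.elements
    )
    cf_class = pd.DataFrame(
        classify_cf(cf.to_numpy()), index=cf.index, columns=cf.columns
    )
    sqg = pd.DataFrame(
        [[sqg_flag(v, registry[e]) for e, v in zip(table.elements, row)] for row in conc],
        index=cf.index,
        columns=cf.columns,
    )

    mean_conc = conc.mean(axis=0)
    cf_of_mean = contamination_factor(mean_conc, bv)
    summary = pd.DataFrame(
        {
            "mean_conc": mean_conc,
            "cf_of_mean": cf_of_mean,
            "cf_band": classify_cf(cf_of_mean),
            "mean_cf": cf.mean(axis=0).to_numpy(),
            "sqg_flag_of_mean": [
                sqg_flag(v, registry[e]) for e, v in zip(table.elements, mean_conc)
            ],
        },
        index=pd.Index(table.elements, name="element"),
    )
    if include_screening:
        exceed = screening_exceedance(table, registry)
        summary = summary.join(exceed)
    return ContaminationReport(cf=cf, cf_class=cf_class, sqg=sqg, summary=summary)
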