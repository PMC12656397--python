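"""Data model, element metadata registry, tabular I/O and validation.

The survey matrix is a set of topsoil samples with measured concentrations
(mg/kg) of eight potentially toxic elements (PTEs) — Cd, Cr, Cu, Ni, Pb, Zn,
As, Hg — plus pH and optional categorical metadata (parent rock, land use,
crop). Per-element constants (method detection limits, regional background
values, NOAA sediment-quality guidelines, pH-banded agricultural screening
values, pathway-specific reference doses) live in :class:`ElementMeta` and the
default registry returned by :func:`default_element_registry`.

Below-detection values are stored exactly as read and only flagged; any
substitution (MDL/2) is the receptor model's business, not the data model's,
so the raw table stays auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed element order used everywhere (survey table column order).
ELEMENT_ORDER: tuple[str, ...] = ("Cd", "Cr", "Cu", "Ni", "Pb", "Zn", "As", "Hg")

#: Optional non-element columns recognised by the loader.
META_COLUMNS: tuple[str, ...] = ("parent_rock", "land_use", "crop")

#: Mean topsoil concentrations (mg/kg) of the Shandong survey these defaults
#: emulate; used as the deterministic-risk input and as the anchor for the
#: synthetic generator's absolute scale.
SURVEY_MEAN_CONC: Mapping[str, float] = {
    "Cd": 0.13, "Cr": 85.0, "Cu": 26.0, "Ni": 36.2,
    "Pb": 26.8, "Zn": 68.4, "As": 7.6, "Hg": 0.03,
}

#: Mean survey pH (used when a scenario needs a representative pH).
SURVEY_MEAN_PH: float = 6.58

#: pH band upper edges for screening-value lookup. Bands are half-open:
#: pH <= 5.5; 5.5 < pH <= 6.5; 6.5 < pH <= 7.5; pH > 7.5.
PH_BAND_EDGES: tuple[float, float, float] = (5.5, 6.5, 7.5)

PH_BAND_LABELS: tuple[str, ...] = ("<=5.5", "5.5-6.5", "6.5-7.5", ">7.5")


@dataclass(frozen=True)
class ElementMeta:
    """Per-element constants.

    Parameters
    ----------
    element : str
        Element symbol.
    mdl : float
        Method detection limit, mg/kg.
    bv_national, bv_shandong : float
        National and Shandong-province soil background values, mg/kg.
    erl, erm : float
        NOAA sediment-quality guidelines: Effects Range-Low / -Median, mg/kg.
    sv_by_ph : tuple of 4 floats
        Agricultural-soil risk screening values (GB15618-2018 style), mg/kg,
        for the four pH bands of :data:`PH_BAND_LABELS`.
    rfd_ing, rfd_inh, rfd_dermal : float
        Pathway-specific non-carcinogenic reference doses, mg/(kg*day).
    """

    element: str
    mdl: float
    bv_national: float
    bv_shandong: float
    erl: float
    erm: float
    sv_by_ph: tuple[float, float, float, float]
    rfd_ing: float
    rfd_inh: float
    rfd_dermal: float

    def validate(self) -> None:
        if not self.mdl > 0:
            raise ValueError(f"{self.element}: MDL must be > 0, got {self.mdl}")
        if not self.erl < self.erm:
            raise ValueError(f"{self.element}: ERL {self.erl} must be < ERM {self.erm}")
        if len(self.sv_by_ph) != 4 or any(v <= 0 for v in self.sv_by_ph):
            raise ValueError(f"{self.element}: four positive screening values required")
        for rfd in (self.rfd_ing, self.rfd_inh, self.rfd_dermal):
            if not rfd > 0:
                raise ValueError(f"{self.element}: reference doses must be > 0")

    def screening_value(self, ph: float) -> float:
        """Screening value (mg/kg) for a sample at the given pH."""
        return self.sv_by_ph[ph_band(ph)]


def ph_band(ph: float) -> int:
    """Index of the pH band (0-3), half-open at the upper edge of each band."""
    if not np.isfinite(ph):
        raise ValueError(f"pH must be finite, got {ph}")
    for i, edge in enumerate(PH_BAND_EDGES):
        if ph <= edge:
            return i
    return 3


# Registry constants: MDLs from the analytical methods; background values,
# ERL/ERM and screening values from the survey's reference table; reference
# doses are the standard USEPA residential-soil set (all overridable).
_REGISTRY_ROWS: tuple[tuple, ...] = (
    # element, mdl, bv_national, bv_shandong, erl, erm, sv(4 bands), rfd_ing, rfd_inh, rfd_dermal
    ("Cd", 0.03, 0.097, 0.132, 1.2, 9.6, (0.3, 0.3, 0.3, 0.6), 1e-3, 1e-3, 1e-5),
    ("Cr", 5.0, 61.0, 62.0, 81.0, 370.0, (150.0, 150.0, 200.0, 250.0), 3e-3, 2.86e-5, 6e-5),
    ("Cu", 1.0, 22.6, 22.6, 34.0, 270.0, (50.0, 50.0, 100.0, 100.0), 4e-2, 4e-2, 1.2e-2),
    ("Ni", 2.0, 26.9, 27.1, 21.0, 52.0, (60.0, 70.0, 100.0, 190.0), 2e-2, 2.06e-2, 5.4e-3),
    ("Pb", 2.0, 26.0, 23.6, 47.0, 218.0, (70.0, 90.0, 120.0, 170.0), 3.5e-3, 3.52e-3, 5.25e-4),
    ("Zn", 4.0, 74.2, 63.3, 150.0, 410.0, (200.0, 200.0, 250.0, 300.0), 3e-1, 3e-1, 6e-2),
    ("As", 1.0, 11.2, 8.6, 8.2, 70.0, (40.0, 40.0, 30.0, 25.0), 3e-4, 3.01e-4, 1.23e-4),
    ("Hg", 0.0005, 0.065, 0.031, 0.15, 0.71, (1.3, 1.8, 2.4, 3.4), 3e-4, 8.57e-5, 2.1e-5),
)


def default_element_registry(
    overrides: Mapping[str, Mapping[str, object]] | None = None,
) -> dict[str, ElementMeta]:
    """The eight-element default registry, optionally with field overrides.

    ``overrides`` maps element symbol -> {field: value}; unknown elements or
    fields raise. The returned dict preserves :data:`ELEMENT_ORDER`.
    """
    registry = {row[0]: ElementMeta(*row) for row in _REGISTRY_ROWS}
    if overrides:
        for elem, fields in overrides.items():
            if elem not in registry:
                raise KeyError(f"unknown element in overrides: {elem!r}")
            fields = {
                k: tuple(v) if k == "sv_by_ph" else float(v)  # type: ignore[arg-type]
                for k, v in fields.items()
            }
            registry[elem] = replace(registry[elem], **fields)
    for meta in registry.values():
        meta.validate()
    return registry


def registry_to_json(registry: Mapping[str, ElementMeta], path: str | Path) -> None:
    payload = {
        e: {
            "mdl": m.mdl, "bv_national": m.bv_national, "bv_shandong": m.bv_shandong,
            "erl": m.erl, "erm": m.erm, "sv_by_ph": list(m.sv_by_ph),
            "rfd_ing": m.rfd_ing, "rfd_inh": m.rfd_inh, "rfd_dermal": m.rfd_dermal,
        }
        for e, m in registry.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class SampleTable:
    """A validated survey table: samples x elements plus pH and metadata.

    ``conc`` holds concentrations exactly as measured/read (mg/kg), indexed by
    sample id; ``below_mdl`` flags cells whose value is below the element's
    method detection limit. ``ph`` and ``meta`` are optional.
    """

    conc: pd.DataFrame
    below_mdl: pd.DataFrame
    ph: pd.Series | None = None
    meta: pd.DataFrame | None = None

    @property
    def elements(self) -> list[str]:
        return list(self.conc.columns)

    @property
    def n_samples(self) -> int:
        return len(self.conc)

    def validate(self, registry: Mapping[str, ElementMeta]) -> None:
        values = self.conc.to_numpy(dtype=float)
        if values.size == 0:
            raise ValueError("empty sample table")
        if not np.isfinite(values).all():
            raise ValueError("non-finite concentration values")
        if (values < 0).any():
            raise ValueError("negative concentration values")
        missing = [e for e in self.elements if e not in registry]
        if missing:
            raise KeyError(f"elements without registry entry: {missing}")
        if self.below_mdl.shape != self.conc.shape:
            raise ValueError("below_mdl shape does not match conc")
        mdl = np.array([registry[e].mdl for e in self.elements])
        expected = values < mdl
        if (self.below_mdl.to_numpy(dtype=bool) != expected).any():
            raise ValueError("below_mdl flags inconsistent with MDLs")
        if self.ph is not None and not self.ph.index.equals(self.conc.index):
            raise ValueError("pH index does not match samples")

    def require_ph(self) -> pd.Series:
        if self.ph is None:
            raise ValueError("operation requires per-sample pH, which is missing")
        bad = self.ph[~np.isfinite(self.ph.to_numpy(dtype=float))]
        if len(bad):
            raise ValueError(f"missing/non-finite pH for samples: {list(bad.index[:5])}")
        return self.ph


def load_samples(
    path: str | Path,
    element_order: Sequence[str] = ELEMENT_ORDER,
    registry: Mapping[str, ElementMeta] | None = None,
) -> SampleTable:
    """Read a delimited-text survey table (comma or tab, header row).

    Column names are matched case-insensitively to element symbols plus the
    optional ``pH``, ``parent_rock``, ``land_use`` and ``crop`` columns; any
    other column is a hard error. Rows with a negative concentration are
    rejected with a logged error; below-MDL values are kept as read and
    flagged.
    """
    registry = registry if registry is not None else default_element_registry()
    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty:
        raise ValueError(f"empty sample table: {path}")

    canon = {e.lower(): e for e in element_order}
    canon.update({"ph": "pH"})
    canon.update({m: m for m in META_COLUMNS})
    renames: dict[str, str] = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in ("sample_id", "id"):
            renames[col] = "sample_id"
        elif key in canon:
            renames[col] = canon[key]
        else:
            raise ValueError(f"unknown column {col!r} in {path}")
    df = df.rename(columns=renames)
    missing = [e for e in element_order if e not in df.columns]
    if missing:
        raise ValueError(f"missing element columns: {missing}")
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    else:
        df.index = pd.RangeIndex(len(df), name="sample_id")

    conc = df[list(element_order)].astype(float)
    bad_rows = conc.index[(conc < 0).any(axis=1) | ~np.isfinite(conc).all(axis=1)]
    for sid in bad_rows:
        logger.error("rejecting sample %r: negative or non-finite concentration", sid)
    keep = ~conc.index.isin(bad_rows)
    conc = conc.loc[keep]
    if conc.empty:
        raise ValueError("no valid rows after rejecting negative concentrations")

    ph = df.loc[keep, "pH"].astype(float) if "pH" in df.columns else None
    meta_cols = [c for c in META_COLUMNS if c in df.columns]
    meta = df.loc[keep, meta_cols] if meta_cols else None

    mdl = np.array([registry[e].mdl for e in element_order])
    below = pd.DataFrame(
        conc.to_numpy() < mdl, index=conc.index, columns=conc.columns
    )
    table = SampleTable(conc=conc, below_mdl=below, ph=ph, meta=meta)
    table.validate(registry)
    return table


def write_samples(table: SampleTable, path: str | Path, sep: str = ",") -> None:
    """Write a table back to delimited text (inverse of :func:`load_samples`)."""
    out = table.conc.copy()
    if table.ph is not None:
        out["pH"] = table.ph
    if table.meta is not None:
        for col in table.meta.columns:
            out[col] = table.meta[col]
    out.to_csv(path, sep=sep, index_label="sample_id")


def from_arrays(
    conc: np.ndarray,
    registry: Mapping[str, ElementMeta],
    elements: Sequence[str] = ELEMENT_ORDER,
    ph: np.ndarray | float | None = None,
    sample_ids: Iterable | None = None,
) -> SampleTable:
    """Build a validated SampleTable from in-memory arrays."""
    conc = np.asarray(conc, dtype=float)
    index = pd.Index(
        list(sample_ids) if sample_ids is not None else range(conc.shape[0]),
        name="sample_id",
    )
    conc_df = pd.DataFrame(conc, index=index, columns=list(elements))
    mdl = np.array([registry[e].mdl for e in elements])
    below = pd.DataFrame(conc < mdl, index=index, columns=list(elements))
    ph_series = None
    if ph is not None:
        ph_series = pd.Series(np.broadcast_to(np.asarray(ph, dtype=float), (len(index),)).copy(),
                              index=index, name="pH")
    table = SampleTable(conc=conc_df, below_mdl=below, ph=ph_series)
    table.validate(registry)
    return table
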