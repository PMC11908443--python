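"""Tree- and plot-level aboveground biomass and carbon accounting.

Six published allometric biomass equations (kg per tree; D in cm, H in m,
wood density ρ in g cm⁻³) are bundled with their printed coefficients:

* ``tf_H``     AGB = exp(−3.04385 + 0.94863·ln(D²H)) × 1.08071
* ``tf_D``     AGB = exp(−1.91172 + 2.45043·lnD) × 1.094052
* ``varzea_H`` AGB = exp(−3.027 + ln(ρD²H)) × 1.051195
* ``varzea_D`` AGB = ρ·exp(−1.349 + 1.980·lnD + 0.207·ln²D − 0.0281·ln³D) × 1.065419
* ``chave_H``  AGB = 0.0673·(ρD²H)^0.976
* ``chave_D``  AGB = exp(−1.8030 − 0.976·E + 0.976·lnρ + 2.673·lnD − 0.0299·ln²D) × 1.089027

The trailing multipliers are log-bias correction factors CF = exp(RSE²/2)
of the generating log-scale regressions.  ``varzea_H`` is printed in some
sources without the exponentiation, which is dimensionally incoherent; the
default here evaluates the exponentiated log-linear moist-forest form, and
``strict=True`` evaluates the literal printed expression for audit.

Biomass is computed for stems ≥5 cm DBH; smaller trees are excluded at
aggregation (with a visible count), not at load, so height modeling can
still use them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model_io import DataError, ForestDataset
from .hd_allometry import HDFit
from .height_prediction import (ErrorSummary, PublishedHeightModel,
                                predict_height, stratified_errors)

__all__ = [
    "BiomassEquation",
    "BIOMASS_EQUATIONS",
    "get_equation",
    "correction_factor",
    "tree_agb",
    "PlotBiomass",
    "plot_biomass",
    "biomass_error_comparison",
    "carbon_accounting",
]

MIN_BIOMASS_DBH = 5.0  # cm


def correction_factor(rse: float) -> float:
    """Log-bias correction CF = exp(RSE²/2) for back-transformed regressions."""
    if rse < 0:
        raise ValueError("rse must be non-negative")
    return math.exp(rse**2 / 2.0)


@dataclass(frozen=True)
class BiomassEquation:
    id: str
    uses_height: bool
    uses_density: bool
    uses_E: bool
    correction_factor: float
    description: str

    def evaluate(self, dbh, height=None, rho=None, E: float | None = None,
                 strict: bool = False) -> np.ndarray:
        D = np.asarray(dbh, dtype=float)
        if self.uses_height:
            if height is None:
                raise DataError(f"{self.id}: height is required")
            H = np.asarray(height, dtype=float)
        if self.uses_density:
            if rho is None:
                raise DataError(f"{self.id}: wood density is required")
            R = np.asarray(rho, dtype=float)
        if self.uses_E and E is None:
            raise DataError(f"{self.id}: the stress index E is required")
        lnD = np.log(D)
        if self.id == "tf_H":
            return np.exp(-3.04385 + 0.94863 * np.log(D**2 * H)) * 1.08071
        if self.id == "tf_D":
            return np.exp(-1.91172 + 2.45043 * lnD) * 1.094052
        if self.id == "varzea_H":
            if strict:
                return -3.027 + np.log(R * D**2 * H) * 1.051195
            return np.exp(-3.027 + np.log(R * D**2 * H)) * 1.051195
        if self.id == "varzea_D":
            return R * np.exp(-1.349 + 1.980 * lnD + 0.207 * lnD**2
                              - 0.0281 * lnD**3) * 1.065419
        if self.id == "chave_H":
            return 0.0673 * (R * D**2 * H) ** 0.976
        if self.id == "chave_D":
            return np.exp(-1.8030 - 0.976 * E + 0.976 * np.log(R)
                          + 2.673 * lnD - 0.0299 * lnD**2) * 1.089027
        raise ValueError(f"unknown biomass equation {self.id!r}")


BIOMASS_EQUATIONS: dict[str, BiomassEquation] = {
    "tf_H": BiomassEquation("tf_H", True, False, False, 1.08071,
                            "terra-firme, with height"),
    "tf_D": BiomassEquation("tf_D", False, False, False, 1.094052,
                            "terra-firme, diameter only"),
    "varzea_H": BiomassEquation("varzea_H", True, True, False, 1.051195,
                                "várzea (moist forest), with height"),
    "varzea_D": BiomassEquation("varzea_D", False, True, False, 1.065419,
                                "várzea (wet mangrove form), diameter only"),
    "chave_H": BiomassEquation("chave_H", True, True, False, 1.0,
                               "pantropical, with height"),
    "chave_D": BiomassEquation("chave_D", False, True, True, 1.089027,
                               "pantropical, diameter only (needs E)"),
}


def get_equation(eq_id: str) -> BiomassEquation:
    try:
        return BIOMASS_EQUATIONS[eq_id]
    except KeyError:
        raise KeyError(f"unknown biomass equation {eq_id!r}; "
                       f"choose from {', '.join(BIOMASS_EQUATIONS)}")


def tree_agb(eq: BiomassEquation | str, dbh, height=None, rho=None,
             E: float | None = None, strict: bool = False) -> np.ndarray:
    """Aboveground biomass (kg) for stems ≥5 cm DBH.

    Raises on dbh < 5; callers aggregating whole inventories should filter
    first (``plot_biomass`` does, and reports the excluded count).
    """
    if isinstance(eq, str):
        eq = get_equation(eq)
    D = np.asarray(dbh, dtype=float)
    if np.any(D < MIN_BIOMASS_DBH):
        raise DataError(f"tree_agb applies to stems ≥{MIN_BIOMASS_DBH:g} cm DBH")
    return eq.evaluate(D, height, rho, E, strict)


def _heights_for(ds: ForestDataset, source, E: float | None,
                 dbh: np.ndarray) -> np.ndarray | None:
    """Resolve the height vector for a height source specifier."""
    if source == "measured":
        h = np.array([float("nan") if r.height is None else r.height
                      for r in ds.records])
        if np.isnan(h).any():
            raise DataError("height_source='measured' but some heights are missing")
        return h
    if source == "none" or source is None:
        return None
    if isinstance(source, (HDFit, PublishedHeightModel)):
        return np.asarray(predict_height(source, dbh, E))
    raise ValueError(f"unresolvable height source {source!r}")


@dataclass
class PlotBiomass:
    plot_id: str
    n_trees: int
    n_excluded: int           # stems below the 5 cm biomass threshold
    agb_total_mg: float       # Mg, unexpanded sum of tree AGB
    agb_per_ha: float         # Mg ha⁻¹ (expansion factors or plot area)
    cumulative: "pd.Series"   # upper class bound (cm) -> cumulative Mg ha⁻¹


def plot_biomass(ds: ForestDataset, eq: BiomassEquation | str,
                 height_source="measured", E: float | None = None,
                 class_width: float = 10.0,
                 strict: bool = False) -> list[PlotBiomass]:
    """Per-plot AGB totals, per-ha values, and cumulative size-class curves.

    Per-ha scaling uses each record's expansion factor when present (the
    size-stratified sampling design), falling back to the plot area.
    """
    if isinstance(eq, str):
        eq = get_equation(eq)
    out = []
    for plot_id in sorted({r.plot_id for r in ds.records}):
        recs = [r for r in ds.records if r.plot_id == plot_id]
        kept = [r for r in recs if r.dbh >= MIN_BIOMASS_DBH]
        excluded = len(recs) - len(kept)
        if not kept:
            out.append(PlotBiomass(plot_id, 0, excluded, 0.0, 0.0,
                                   pd.Series(dtype=float)))
            continue
        sub = ForestDataset(kept, dict(ds.plot_areas), ds.provenance)
        dbh = np.array([r.dbh for r in kept])
        H = _heights_for(sub, height_source, E, dbh)
        rho = None
        if eq.uses_density:
            rho = np.array([float("nan") if r.wood_density is None else r.wood_density
                            for r in kept])
            if np.isnan(rho).any():
                raise DataError(f"plot {plot_id}: wood density missing; "
                                "run assign_wood_density first")
        agb_kg = eq.evaluate(dbh, H, rho, E, strict)
        has_ef = all(r.expansion_factor is not None for r in kept)
        if has_ef:
            per_ha_weights = np.array([r.expansion_factor for r in kept])
        else:
            if plot_id not in ds.plot_areas:
                raise DataError(f"plot {plot_id}: no area entry and no expansion factors")
            per_ha_weights = np.full(len(kept), 1.0 / ds.plot_areas[plot_id])
        per_ha_contrib = agb_kg * per_ha_weights / 1000.0  # Mg ha⁻¹
        total_mg = float(agb_kg.sum()) / 1000.0
        per_ha = float(per_ha_contrib.sum())
        top = math.ceil(dbh.max() / class_width) * class_width
        edges = np.arange(MIN_BIOMASS_DBH, top + class_width, class_width)
        edges[0] = MIN_BIOMASS_DBH
        idx = np.clip(np.searchsorted(edges, dbh, side="right"), 1, len(edges) - 1)
        by_class = np.zeros(len(edges) - 1)
        for i, c in zip(idx, per_ha_contrib):
            by_class[i - 1] += c
        cumulative = pd.Series(np.cumsum(by_class), index=edges[1:])
        out.append(PlotBiomass(plot_id, len(kept), excluded, total_mg, per_ha,
                               cumulative))
    return out


def biomass_error_comparison(
    ds: ForestDataset,
    eq_with_H: BiomassEquation | str,
    eq_without_H: BiomassEquation | str | None,
    height_sources: Mapping[str, object],
    breakpoints: Sequence[float] = (30.0,),
    E: float | None = None,
) -> pd.DataFrame:
    """Per-tree biomass errors of estimated-height (and no-height) biomass
    against measured-height biomass, stratified by DBH class.

    ``height_sources`` maps a label to an HDFit, a PublishedHeightModel,
    or the string "measured".
    """
    if isinstance(eq_with_H, str):
        eq_with_H = get_equation(eq_with_H)
    if isinstance(eq_without_H, str):
        eq_without_H = get_equation(eq_without_H)
    kept = [r for r in ds.records
            if r.dbh >= MIN_BIOMASS_DBH and r.height is not None]
    if not kept:
        raise DataError("no trees ≥5 cm DBH with measured heights")
    sub = ForestDataset(kept, dict(ds.plot_areas), ds.provenance)
    dbh = np.array([r.dbh for r in kept])
    rho = None
    if eq_with_H.uses_density or (eq_without_H is not None and eq_without_H.uses_density):
        rho = np.array([float("nan") if r.wood_density is None else r.wood_density
                        for r in kept])
        if np.isnan(rho).any():
            raise DataError("wood density missing; run assign_wood_density first")
    meas_H = _heights_for(sub, "measured", E, dbh)
    reference = eq_with_H.evaluate(dbh, meas_H, rho, E)
    rows = []

    def add(label, est):
        for summ in stratified_errors(dbh, est, reference, breakpoints):
            row = summ.as_dict()
            row["comparator"] = label
            rows.append(row)

    for label, source in height_sources.items():
        H = _heights_for(sub, source, E, dbh)
        add(label, eq_with_H.evaluate(dbh, H, rho, E))
    if eq_without_H is not None:
        add("no_height", eq_without_H.evaluate(dbh, None, rho, E))
    cols = ["comparator", "size_class", "n", "te", "se", "re", "cvte", "cvse", "cvre"]
    return pd.DataFrame(rows)[cols]


def carbon_accounting(mean_agb: float, area_ha: float, correction: float,
                      carbon_fraction: float = 0.485,
                      price_usd_per_mg_c: float | None = None) -> dict[str, float]:
    """Carbon-stock change from a proportional biomass correction.

    ΔC = area × mean AGB × correction × carbon fraction, reported in Pg C;
    the monetary value is ΔC × price when a price is given.  ``correction``
    may be negative (a downward revision).
    """
    if mean_agb <= 0 or area_ha <= 0 or carbon_fraction <= 0:
        raise ValueError("mean_agb, area_ha and carbon_fraction must be positive")
    delta_mg_c = area_ha * mean_agb * correction * carbon_fraction
    out = {"delta_c_mg": delta_mg_c, "delta_c_pg": delta_mg_c / 1e9}
    if price_usd_per_mg_c is not None:
        out["value_usd"] = delta_mg_c * price_usd_per_mg_c
    return out
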