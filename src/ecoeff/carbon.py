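"""Agricultural carbon accounting and auxiliary indicator construction.

Two accounting identities drive the desired/undesired output side of the
eco-efficiency panel:

* **Carbon sequestration** (desired output): each crop's biological yield is
  recovered from its economic yield through the economic (harvest-index)
  coefficient, dried by its water content and converted to carbon with a
  crop-specific uptake rate,

      CSA = sum_i (1 - r_i) * cs_i * y_i / HI_i        (default, ``divide``)

  A ``multiply`` variant (plain product with HI) is available because the
  economic coefficient's position varies across the applied literature.

* **Carbon emission** (undesired output): six activity sources — pesticides,
  fertilizer, diesel and agricultural film (mass based, kg) plus irrigation
  and tillage (area based, hm²) — each multiplied by a fixed emission factor,

      CE = sum_i beta_i * A_i

The default coefficient tables ship as editable CSV resources
(``data/crop_carbon_uptake.csv``, ``data/emission_coefficients.csv``).

Auxiliary constructions: labor imputation from the primary-industry
employment share, the chemical-input composite, and the four-component
non-point-source pollution sum (COD + NH + TN + TP).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .exceptions import CoefficientLookupError, ValidationError

__all__ = [
    "CropRecord",
    "EmissionActivity",
    "PollutionRecord",
    "load_crop_coefficients",
    "load_emission_coefficients",
    "crop_records_from_yields",
    "activities_from_amounts",
    "sequestration",
    "emission",
    "impute_labor",
    "chemical_composite",
    "nps_pollution",
    "MASS_SOURCES",
    "AREA_SOURCES",
]

#: emission sources whose activity is a mass in kilograms
MASS_SOURCES = frozenset({"pesticides", "fertilizer", "diesel", "agricultural_film"})
#: emission sources whose activity is an area in hm²
AREA_SOURCES = frozenset({"irrigation", "tillage"})

KG_PER_TON = 1000.0


def load_crop_coefficients() -> pd.DataFrame:
    """Crop coefficient table (economic coefficient, water content, uptake rate),
    indexed by crop name."""
    with resources.files("ecoeff.data").joinpath("crop_carbon_uptake.csv").open() as fh:
        return pd.read_csv(fh, index_col="crop")


def load_emission_coefficients() -> pd.DataFrame:
    """Emission factor table (kg CO2-C equivalent per kg or per hm²), indexed by source."""
    with resources.files("ecoeff.data").joinpath("emission_coefficients.csv").open() as fh:
        return pd.read_csv(fh, index_col="source")


@dataclass(frozen=True)
class CropRecord:
    """One crop's economic yield plus its three uptake coefficients."""

    crop_name: str
    yield_y: float          # economic yield, tons
    water_content_r: float  # fraction in [0, 1)
    uptake_rate_cs: float   # carbon uptake rate, > 0
    economic_coeff_HI: float  # harvest-index style economic coefficient, (0, 1]

    def __post_init__(self):
        if self.yield_y < 0:
            raise ValidationError(f"{self.crop_name}: yield must be nonnegative")
        if not 0 <= self.water_content_r < 1:
            raise ValidationError(f"{self.crop_name}: water content must lie in [0, 1)")
        if self.uptake_rate_cs <= 0:
            raise ValidationError(f"{self.crop_name}: uptake rate must be positive")
        if self.economic_coeff_HI <= 0:
            raise ValidationError(f"{self.crop_name}: economic coefficient must be positive")


@dataclass(frozen=True)
class EmissionActivity:
    """One emission source's activity level and its emission factor."""

    source_name: str
    activity_A: float        # kg for mass sources, hm² for area sources
    coefficient_beta: float  # kg emitted per activity unit

    def __post_init__(self):
        if self.activity_A < 0:
            raise ValidationError(f"{self.source_name}: activity must be nonnegative")
        if self.coefficient_beta <= 0:
            raise ValidationError(f"{self.source_name}: coefficient must be positive")


@dataclass(frozen=True)
class PollutionRecord:
    """Non-point-source pollution discharge components, tons."""

    cod: float
    nh: float
    tn: float
    tp: float

    def __post_init__(self):
        for name in ("cod", "nh", "tn", "tp"):
            if getattr(self, name) < 0:
                raise ValidationError(f"pollution component {name} must be nonnegative")


def crop_records_from_yields(
    yields: Mapping[str, float], table: pd.DataFrame | None = None
) -> list[CropRecord]:
    """Attach coefficients to a ``{crop: yield}`` mapping.

    Unknown crop names raise :class:`CoefficientLookupError`; pass a custom
    ``table`` (same columns as the shipped CSV) to extend the vocabulary.
    """
    if table is None:
        table = load_crop_coefficients()
    records = []
    for crop, y in yields.items():
        if crop not in table.index:
            raise CoefficientLookupError(f"no uptake coefficients for crop {crop!r}")
        row = table.loc[crop]
        records.append(
            CropRecord(
                crop_name=crop,
                yield_y=float(y),
                water_content_r=float(row["water_content"]),
                uptake_rate_cs=float(row["uptake_rate"]),
                economic_coeff_HI=float(row["economic_coefficient"]),
            )
        )
    return records


def activities_from_amounts(
    amounts: Mapping[str, float], table: pd.DataFrame | None = None
) -> list[EmissionActivity]:
    """Attach emission factors to a ``{source: activity}`` mapping."""
    if table is None:
        table = load_emission_coefficients()
    activities = []
    for source, amount in amounts.items():
        if source not in table.index:
            raise CoefficientLookupError(f"no emission factor for source {source!r}")
        activities.append(
            EmissionActivity(
                source_name=source,
                activity_A=float(amount),
                coefficient_beta=float(table.loc[source, "coefficient"]),
            )
        )
    return activities


def sequestration(crops: Iterable[CropRecord], hi_mode: str = "divide") -> float:
    """Total crop carbon sequestration CSA, tons.

    ``hi_mode='divide'`` (default) converts economic to biological yield by
    dividing by the economic coefficient; ``'multiply'`` treats the printed
    formula as a plain product.
    """
    if hi_mode not in ("divide", "multiply"):
        raise ValidationError(f"hi_mode must be 'divide' or 'multiply', got {hi_mode!r}")
    total = 0.0
    for crop in crops:
        dry_carbon = (1.0 - crop.water_content_r) * crop.uptake_rate_cs * crop.yield_y
        if hi_mode == "divide":
            total += dry_carbon / crop.economic_coeff_HI
        else:
            total += dry_carbon * crop.economic_coeff_HI
    return total


def emission(activities: Iterable[EmissionActivity], out_unit: str = "kg") -> float:
    """Total agricultural carbon emission CE = Σ β_i A_i.

    Coefficients are expressed in kg per activity unit, so the raw sum is in
    kg; ``out_unit='t'`` converts the aggregate to tons.
    """
    if out_unit not in ("kg", "t"):
        raise ValidationError(f"out_unit must be 'kg' or 't', got {out_unit!r}")
    total_kg = sum(a.coefficient_beta * a.activity_A for a in activities)
    return total_kg / KG_PER_TON if out_unit == "t" else total_kg


def impute_labor(
    primary_employment: float, agri_output: float, total_afah_output: float
) -> float:
    """Agricultural employment imputed as primary-industry employment times the
    share of agriculture in total agriculture/forestry/animal-husbandry/fishery
    output value."""
    if primary_employment < 0:
        raise ValidationError("primary employment must be nonnegative")
    if total_afah_output <= 0:
        raise ValidationError("total AFAH output value must be positive")
    if agri_output < 0:
        raise ValidationError("agricultural output value must be nonnegative")
    share = agri_output / total_afah_output
    if share > 1:
        raise ValidationError(
            f"agricultural output exceeds total AFAH output (share {share:.3f} > 1)"
        )
    return primary_employment * share


def chemical_composite(pesticide: float, fertilizer_pure: float, film: float) -> float:
    """Chemical-input composite: pesticide + pure-nutrient fertilizer + film, tons."""
    for name, v in (("pesticide", pesticide), ("fertilizer", fertilizer_pure), ("film", film)):
        if v < 0:
            raise ValidationError(f"{name} quantity must be nonnegative")
    return pesticide + fertilizer_pure + film


def nps_pollution(p: PollutionRecord) -> float:
    """Non-point-source pollution proxy: COD + NH + TN + TP, tons."""
    return p.cod + p.nh + p.tn + p.tp
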