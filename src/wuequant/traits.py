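"""Whole-plant water-use and biomass-allocation traits from raw measurements.

Raw inputs per plant: dry masses of leaf blades, stems (petioles are always
counted with the stem — the record has no petiole field, so the convention
cannot be broken), optionally roots; leaf area; and a daily pot water-loss
series.  Direct soil evaporation, measured in plant-free control pots, is
subtracted day by day before any water-use quantity is formed.

Derived traits and units:

================  =============================================  ===========
TE_s, TE_wp       transpiration efficiency (shoot / whole plant)  g L-1
SLA               specific leaf area                              cm2 g-1
LMF, SMF, RMF     leaf / stem / root mass fractions               unitless
LAR               leaf area ratio (= SLA x LMF by construction)   cm2 g-1
transpiration     daily water use per unit leaf area              mL cm-2 d-1
wilting index     noon / early-morning projected plant area       unitless
plant water use   evaporation-corrected summed water loss         L
================  =============================================  ===========

Masses are g, areas cm2 and water volumes mL internally; transpiration
efficiency converts to litres (factor 1000) on output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RawPlantRecord",
    "DerivedTraits",
    "compute_plant_water_use",
    "compute_te",
    "compute_allocation",
    "compute_transpiration_rate",
    "compute_wilting_index",
    "derive_plant_traits",
    "derive_trait_table",
]

ML_PER_L = 1000.0


@dataclass
class RawPlantRecord:
    """One harvested plant with its watering record."""

    plant_id: str
    genotype_id: str
    environment_id: str
    replicate_id: str
    leaf_mass: float                     # g, blades only
    stem_mass: float                     # g, stems plus petioles
    leaf_area: float                     # cm2
    daily_water_use: np.ndarray          # mL per day, uncorrected pot loss
    root_mass: float | None = None       # g; None => whole-plant traits undefined
    projected_area_morning: float | None = None  # cm2
    projected_area_noon: float | None = None     # cm2

    def __post_init__(self):
        for name in ("leaf_mass", "stem_mass", "leaf_area"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.root_mass is not None and self.root_mass < 0:
            raise ValueError("root_mass must be non-negative")
        self.daily_water_use = np.asarray(self.daily_water_use, dtype=float)
        if np.any(self.daily_water_use < 0):
            raise ValueError("daily water use must be non-negative")


@dataclass
class DerivedTraits:
    """Trait values for one plant; whole-plant fields are None without roots."""

    TE_s: float
    SLA: float
    LMF_s: float
    SMF_s: float
    LAR_s: float
    plant_water_use: float               # L
    TE_wp: float | None = None
    LMF_wp: float | None = None
    SMF_wp: float | None = None
    RMF_wp: float | None = None
    LAR_wp: float | None = None
    transpiration_rate: float | None = None
    wilting_index: float | None = None
    wilting_flag: bool = False           # True when index > 1 (growth between shots)


def compute_plant_water_use(
    daily_water_use: np.ndarray,
    daily_evaporation: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Evaporation-corrected total plant water use.

    ``daily_evaporation`` is the per-day mean across plant-free control
    pots, on the same calendar as the plant series.  Negative corrected
    days (evaporation exceeding pot loss) are clamped to zero with a
    warning.  Returns the total in litres together with the corrected
    per-day series (mL), which feeds the transpiration-rate computation.
    """
    use = np.asarray(daily_water_use, dtype=float)
    evap = np.asarray(daily_evaporation, dtype=float)
    if use.shape != evap.shape:
        raise ValueError(
            f"series lengths differ ({use.shape} vs {evap.shape})")
    corrected = use - evap
    if np.any(corrected < 0):
        warnings.warn(
            "evaporation exceeded pot water loss on "
            f"{int(np.sum(corrected < 0))} day(s); clamping to zero",
            stacklevel=2)
        corrected = np.clip(corrected, 0.0, None)
    return float(corrected.sum() / ML_PER_L), corrected


def compute_te(shoot_mass: float, root_mass: float | None,
               water_use: float) -> tuple[float, float | None]:
    """Transpiration efficiency: dry mass per litre of water transpired."""
    if water_use <= 0.0:
        raise ValueError("water use must be positive for TE")
    if shoot_mass < 0 or (root_mass is not None and root_mass < 0):
        raise ValueError("masses must be non-negative")
    te_s = shoot_mass / water_use
    te_wp = None if root_mass is None else (shoot_mass + root_mass) / water_use
    return te_s, te_wp


def compute_allocation(leaf_mass: float, stem_mass: float,
                       root_mass: float | None, leaf_area: float) -> dict:
    """SLA, mass fractions and leaf area ratio on shoot and whole-plant bases.

    LAR = SLA x LMF holds exactly by construction on both bases, and the
    whole-plant fractions sum to one.
    """
    if leaf_mass <= 0.0:
        raise ValueError("leaf mass must be positive")
    if stem_mass < 0 or (root_mass is not None and root_mass < 0):
        raise ValueError("masses must be non-negative")
    if leaf_area <= 0.0:
        raise ValueError("leaf area must be positive")
    sla = leaf_area / leaf_mass
    shoot = leaf_mass + stem_mass
    out = {
        "SLA": sla,
        "LMF_s": leaf_mass / shoot,
        "SMF_s": stem_mass / shoot,
        "LAR_s": leaf_area / shoot,
    }
    if root_mass is not None:
        plant = shoot + root_mass
        out.update(
            LMF_wp=leaf_mass / plant,
            SMF_wp=stem_mass / plant,
            RMF_wp=root_mass / plant,
            LAR_wp=leaf_area / plant,
        )
    return out


def compute_transpiration_rate(
    corrected_daily_use: np.ndarray,
    leaf_area: float,
    days: slice | list[int] | None = None,
    average: bool = True,
):
    """Daily water use per unit leaf area (mL cm-2 day-1).

    ``days`` selects a subset of the corrected series (all days by
    default); with ``average=False`` the per-day rates are returned.
    """
    if leaf_area <= 0.0:
        raise ValueError("leaf area must be positive")
    series = np.asarray(corrected_daily_use, dtype=float)
    if days is not None:
        series = series[days]
    rates = series / leaf_area
    return float(rates.mean()) if average else rates


def compute_wilting_index(area_noon: float, area_morning: float) -> tuple[float, bool]:
    """Noon over early-morning projected plant area; flags values > 1.

    The index may legitimately exceed 1 when the plant grew between the
    two images; such values are kept and flagged, not clipped.
    """
    if area_morning <= 0.0:
        raise ValueError("morning projected area must be positive")
    if area_noon < 0.0:
        raise ValueError("noon projected area must be non-negative")
    idx = area_noon / area_morning
    return idx, idx > 1.0


def derive_plant_traits(record: RawPlantRecord,
                        daily_evaporation: np.ndarray) -> DerivedTraits:
    """All derivable traits for one plant."""
    water_l, corrected = compute_plant_water_use(
        record.daily_water_use, daily_evaporation)
    if water_l <= 0.0:
        raise ValueError(
            f"plant {record.plant_id}: corrected water use is zero; "
            "TE undefined")
    shoot = record.leaf_mass + record.stem_mass
    te_s, te_wp = compute_te(shoot, record.root_mass, water_l)
    alloc = compute_allocation(record.leaf_mass, record.stem_mass,
                               record.root_mass, record.leaf_area)
    tr = compute_transpiration_rate(corrected, record.leaf_area)
    wi, wi_flag = (None, False)
    if (record.projected_area_noon is not None
            and record.projected_area_morning is not None):
        wi, wi_flag = compute_wilting_index(
            record.projected_area_noon, record.projected_area_morning)
    return DerivedTraits(
        TE_s=te_s, TE_wp=te_wp, SLA=alloc["SLA"],
        LMF_s=alloc["LMF_s"], SMF_s=alloc["SMF_s"], LAR_s=alloc["LAR_s"],
        LMF_wp=alloc.get("LMF_wp"), SMF_wp=alloc.get("SMF_wp"),
        RMF_wp=alloc.get("RMF_wp"), LAR_wp=alloc.get("LAR_wp"),
        plant_water_use=water_l, transpiration_rate=tr,
        wilting_index=wi, wilting_flag=wi_flag)


def derive_trait_table(
    plants: pd.DataFrame,
    water: pd.DataFrame,
    evaporation: pd.DataFrame,
) -> pd.DataFrame:
    """Long-format phenotype table from the three raw CSV tables.

    ``plants``: one row per plant with columns ``plant_id, genotype,
    environment, replicate, leaf_mass_g, stem_mass_g, root_mass_g`` (blank
    allowed) ``, leaf_area_cm2`` and optionally the two projected areas.
    ``water``: columns ``plant_id, day, water_ml``.  ``evaporation``:
    columns ``pot_id, day, water_ml`` from plant-free pots; pots are
    averaged per day before subtraction.  Evaporation is matched to each
    plant's recorded days, so the two series must share the day labels.
    """
    evap_by_day = evaporation.groupby("day")["water_ml"].mean()
    rows = []
    for _, p in plants.iterrows():
        w = water[water["plant_id"] == p["plant_id"]].sort_values("day")
        if w.empty:
            raise ValueError(f"no water-use series for plant {p['plant_id']}")
        try:
            evap = evap_by_day.loc[w["day"].to_numpy()].to_numpy()
        except KeyError as exc:
            raise ValueError(
                f"evaporation series missing day(s) for plant "
                f"{p['plant_id']}") from exc
        root = p.get("root_mass_g")
        record = RawPlantRecord(
            plant_id=str(p["plant_id"]),
            genotype_id=str(p["genotype"]),
            environment_id=str(p["environment"]),
            replicate_id=str(p["replicate"]),
            leaf_mass=float(p["leaf_mass_g"]),
            stem_mass=float(p["stem_mass_g"]),
            root_mass=None if pd.isna(root) else float(root),
            leaf_area=float(p["leaf_area_cm2"]),
            daily_water_use=w["water_ml"].to_numpy(float),
            projected_area_morning=_opt(p, "projected_area_morning_cm2"),
            projected_area_noon=_opt(p, "projected_area_noon_cm2"),
        )
        derived = derive_plant_traits(record, evap)
        base = {"genotype": record.genotype_id,
                "environment": record.environment_id,
                "replicate": record.replicate_id}
        for trait in ("TE_s", "TE_wp", "SLA", "LMF_s", "SMF_s", "LAR_s",
                      "LMF_wp", "SMF_wp", "RMF_wp", "LAR_wp",
                      "plant_water_use", "transpiration_rate",
                      "wilting_index"):
            value = getattr(derived, trait)
            if value is not None:
                rows.append({**base, "trait": trait, "value": float(value)})
    return pd.DataFrame(rows, columns=["genotype", "environment",
                                       "replicate", "trait", "value"])


def _opt(row, col):
    if col not in row or pd.isna(row[col]):
        return None
    return float(row[col])
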