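"""Soil column discretisation and constitutive relations.

The column mirrors the field setting of West Greenland archaeological sites:
an organic archaeological deposit occupying the upper metre (mean porosity
77.1 vol %, loss-on-ignition 30.3 wt %, bulk density 458 kg m^-3 across
sites) over entisol/cryosol mineral subsoil down to 5 m.  The default grid is
64 layers, 21 of them in the upper 1 m.

Constitutive relations: Brooks–Corey water retention with Mualem hydraulic
conductivity, linear-in-moisture thermal conductivity (matching the strong
positive field correlation of conductivity with water content), volumetric
mixing heat capacity, and a loss-on-ignition to organic-carbon conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "HydraulicParams",
    "ThermalParams",
    "SoilLayer",
    "SoilProfile",
    "build_default_profile",
    "retention",
    "retention_inverse",
    "hydraulic_conductivity",
    "thermal_conductivity",
    "heat_capacity",
    "field_capacity",
    "oc_content",
    "HC_WATER",
    "HC_ICE",
    "LOI_TO_OC",
]

# Volumetric heat capacities, J m^-3 K^-1.
HC_WATER = 4.18e6
HC_ICE = 1.9e6

#: Conventional organic-matter to organic-carbon mass ratio.
LOI_TO_OC = 0.5

#: Matric head (m) defining field capacity in the bucket water scheme.
FIELD_CAPACITY_HEAD = 1.0


@dataclass(frozen=True)
class HydraulicParams:
    """Brooks–Corey / Mualem parameters for one layer."""

    air_entry_m: float  # air-entry (bubbling) pressure head, m
    pore_size_index: float  # Brooks-Corey lambda, dimensionless
    residual_water: float  # theta_r, vol fraction
    ksat_m_per_day: float  # saturated conductivity

    def __post_init__(self) -> None:
        if min(self.air_entry_m, self.pore_size_index,
               self.ksat_m_per_day) <= 0 or self.residual_water < 0:
            raise ValueError("hydraulic parameters must be positive")


@dataclass(frozen=True)
class ThermalParams:
    """Thermal conductivity/heat capacity parameters for one layer.

    Unfrozen conductivity is linear in volumetric water content,
    ``kh = kh_dry + kh_slope * theta``; frozen soil is scaled by
    ``kh_frozen_factor`` at the same total water content.
    """

    kh_dry: float  # W m^-1 K^-1 at theta = 0
    kh_slope: float  # W m^-1 K^-1 per unit vol fraction water
    hc_solids: float  # J m^-3 K^-1 per unit solid volume
    kh_frozen_factor: float = 1.5

    def __post_init__(self) -> None:
        if self.kh_dry <= 0 or self.kh_slope < 0 or self.hc_solids <= 0:
            raise ValueError("thermal parameters must be positive")


# Defaults for the organic archaeological deposit and the mineral subsoil.
ORGANIC_HYDRAULIC = HydraulicParams(0.1, 0.5, 0.08, 1.0)
MINERAL_HYDRAULIC = HydraulicParams(0.3, 0.3, 0.05, 0.1)
ORGANIC_THERMAL = ThermalParams(0.10, 0.9, 2.5e6)
MINERAL_THERMAL = ThermalParams(0.70, 1.8, 2.0e6)


@dataclass(frozen=True)
class SoilLayer:
    top_depth: float  # m, positive downward, 0 at surface
    thickness: float  # m
    porosity: float  # vol fraction
    loi: float  # loss on ignition, weight fraction of dry soil
    bulk_density: float  # kg m^-3
    is_archaeological: bool = False
    hydraulic: HydraulicParams = field(default_factory=lambda: ORGANIC_HYDRAULIC)
    thermal: ThermalParams = field(default_factory=lambda: ORGANIC_THERMAL)

    def __post_init__(self) -> None:
        if not 0.0 < self.porosity < 1.0:
            raise ValueError("porosity must be in (0, 1)")
        if not 0.0 <= self.loi <= 1.0:
            raise ValueError("loi must be in [0, 1]")
        if self.bulk_density <= 0 or self.thickness <= 0:
            raise ValueError("bulk_density and thickness must be > 0")
        if self.hydraulic.residual_water >= self.porosity:
            raise ValueError("residual water must be below porosity")

    @property
    def bottom_depth(self) -> float:
        return self.top_depth + self.thickness

    @property
    def center_depth(self) -> float:
        return self.top_depth + 0.5 * self.thickness


@dataclass(frozen=True)
class SoilProfile:
    """Contiguous stack of layers from the surface down."""

    layers: tuple[SoilLayer, ...]

    def __post_init__(self) -> None:
        z = 0.0
        for lay in self.layers:
            if abs(lay.top_depth - z) > 1e-9:
                raise ValueError("layers must be contiguous from the surface")
            z = lay.bottom_depth

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def total_depth(self) -> float:
        return self.layers[-1].bottom_depth

    def layer_index_at(self, depth: float) -> int:
        """Index of the layer whose depth interval contains ``depth``."""
        for i, lay in enumerate(self.layers):
            if lay.top_depth <= depth < lay.bottom_depth:
                return i
        if abs(depth - self.total_depth) < 1e-9:
            return self.n_layers - 1
        raise ValueError(f"depth {depth} m outside profile")

    def array(self, attr: str) -> np.ndarray:
        """Per-layer array of a layer, hydraulic or thermal attribute."""
        first = self.layers[0]
        if hasattr(first, attr):
            return np.array([getattr(l, attr) for l in self.layers], float)
        for sub in ("hydraulic", "thermal"):
            if hasattr(getattr(first, sub), attr):
                return np.array(
                    [getattr(getattr(l, sub), attr) for l in self.layers], float
                )
        raise AttributeError(attr)

    # -- structured-text round trip -------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lay in self.layers:
            rows.append(
                {
                    "top_depth": lay.top_depth,
                    "thickness": lay.thickness,
                    "porosity": lay.porosity,
                    "loi": lay.loi,
                    "bulk_density": lay.bulk_density,
                    "is_archaeological": lay.is_archaeological,
                    "air_entry_m": lay.hydraulic.air_entry_m,
                    "pore_size_index": lay.hydraulic.pore_size_index,
                    "residual_water": lay.hydraulic.residual_water,
                    "ksat_m_per_day": lay.hydraulic.ksat_m_per_day,
                    "kh_dry": lay.thermal.kh_dry,
                    "kh_slope": lay.thermal.kh_slope,
                    "hc_solids": lay.thermal.hc_solids,
                    "kh_frozen_factor": lay.thermal.kh_frozen_factor,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SoilProfile":
        layers = []
        for _, r in df.iterrows():
            layers.append(
                SoilLayer(
                    top_depth=float(r["top_depth"]),
                    thickness=float(r["thickness"]),
                    porosity=float(r["porosity"]),
                    loi=float(r["loi"]),
                    bulk_density=float(r["bulk_density"]),
                    is_archaeological=bool(r["is_archaeological"]),
                    hydraulic=HydraulicParams(
                        float(r["air_entry_m"]),
                        float(r["pore_size_index"]),
                        float(r["residual_water"]),
                        float(r["ksat_m_per_day"]),
                    ),
                    thermal=ThermalParams(
                        float(r["kh_dry"]),
                        float(r["kh_slope"]),
                        float(r["hc_solids"]),
                        float(r["kh_frozen_factor"]),
                    ),
                )
            )
        return cls(tuple(layers))

    @classmethod
    def from_csv(cls, path) -> "SoilProfile":
        return cls.from_frame(pd.read_csv(path))


def _geometric_thicknesses(t0: float, total: float, n: int) -> np.ndarray:
    """Thicknesses t0*r^i (i=0..n-1) summing to ``total``; solves for r."""

    def total_err(r: float) -> float:
        if abs(r - 1.0) < 1e-12:
            return t0 * n - total
        return t0 * (r**n - 1.0) / (r - 1.0) - total

    r = brentq(total_err, 1.0 + 1e-9, 1.5)
    t = t0 * r ** np.arange(n)
    t[-1] += total - t.sum()  # absorb rounding so the stack closes exactly
    return t


def build_default_profile(
    archaeological_depth: float = 1.0,
    total_depth: float = 5.0,
    n_upper: int = 21,
    n_lower: int = 43,
) -> SoilProfile:
    """Default 5 m column: 64 layers, 21 uniform layers in the upper 1 m.

    The upper metre carries the cross-site mean archaeological-deposit
    properties (porosity 0.771, LOI 0.303, bulk density 458 kg m^-3); below
    1 m, mineral cryosol defaults (porosity 0.40, LOI 0.02, 1500 kg m^-3) on
    a geometrically stretched grid down to 5 m.
    """
    layers: list[SoilLayer] = []
    dz_up = archaeological_depth / n_upper
    z = 0.0
    for _ in range(n_upper):
        layers.append(
            SoilLayer(
                top_depth=z,
                thickness=dz_up,
                porosity=0.771,
                loi=0.303,
                bulk_density=458.0,
                is_archaeological=True,
                hydraulic=ORGANIC_HYDRAULIC,
                thermal=ORGANIC_THERMAL,
            )
        )
        z += dz_up
    lower = _geometric_thicknesses(
        dz_up, total_depth - archaeological_depth, n_lower
    )
    for dz in lower:
        layers.append(
            SoilLayer(
                top_depth=z,
                thickness=float(dz),
                porosity=0.40,
                loi=0.02,
                bulk_density=1500.0,
                is_archaeological=False,
                hydraulic=MINERAL_HYDRAULIC,
                thermal=MINERAL_THERMAL,
            )
        )
        z += dz
    # Rebuild with exact cumulative tops to avoid float drift.
    tops = np.concatenate([[0.0], np.cumsum([l.thickness for l in layers])])
    layers = [replace(l, top_depth=float(tops[i])) for i, l in enumerate(layers)]
    return SoilProfile(tuple(layers))


# ---------------------------------------------------------------------------
# Constitutive relations
# ---------------------------------------------------------------------------

def _effective_saturation(theta: float, layer: SoilLayer) -> float:
    h = layer.hydraulic
    if not h.residual_water <= theta <= layer.porosity + 1e-12:
        raise ValueError(
            f"theta={theta} outside [{h.residual_water}, {layer.porosity}]"
        )
    return (theta - h.residual_water) / (layer.porosity - h.residual_water)


def retention(theta: float, layer: SoilLayer) -> float:
    """Brooks–Corey matric head (m) at water content ``theta``.

    ``head = air_entry * Se**(-1/lambda)``; at saturation the head equals the
    air-entry pressure.  Head grows without bound as theta approaches the
    residual water content.
    """
    se = _effective_saturation(theta, layer)
    h = layer.hydraulic
    if se <= 0.0:
        return np.inf
    return h.air_entry_m * se ** (-1.0 / h.pore_size_index)


def retention_inverse(head: float, layer: SoilLayer) -> float:
    """Water content at matric head ``head`` (m); saturated below air entry."""
    h = layer.hydraulic
    if head <= h.air_entry_m:
        return layer.porosity
    se = (head / h.air_entry_m) ** (-h.pore_size_index)
    return h.residual_water + se * (layer.porosity - h.residual_water)


def field_capacity(layer: SoilLayer, head: float = FIELD_CAPACITY_HEAD) -> float:
    """Water content held against gravity (retention at 1 m head)."""
    return retention_inverse(head, layer)


def hydraulic_conductivity(theta: float, layer: SoilLayer) -> float:
    """Mualem–Brooks–Corey unsaturated conductivity, m d^-1.

    ``K = Ksat * Se**(2.5 + 2/lambda)``.
    """
    se = _effective_saturation(theta, layer)
    h = layer.hydraulic
    return h.ksat_m_per_day * se ** (2.5 + 2.0 / h.pore_size_index)


def thermal_conductivity(
    theta: float, layer: SoilLayer, frozen: bool = False
) -> float:
    """Thermal conductivity, W m^-1 K^-1, linear in total water content."""
    if not 0.0 <= theta <= layer.porosity + 1e-12:
        raise ValueError("theta outside [0, porosity]")
    t = layer.thermal
    kh = t.kh_dry + t.kh_slope * theta
    if frozen:
        kh *= t.kh_frozen_factor
    return kh


def heat_capacity(theta: float, ice: float, layer: SoilLayer) -> float:
    """Volumetric heat capacity by mixing solids, liquid water and ice."""
    if theta + ice > layer.porosity + 1e-9:
        raise ValueError("water + ice exceed porosity")
    t = layer.thermal
    return (1.0 - layer.porosity) * t.hc_solids + theta * HC_WATER + ice * HC_ICE


def oc_content(layer: SoilLayer, loi_to_oc: float = LOI_TO_OC) -> float:
    """Organic-carbon density, kg C m^-3, from bulk density and LOI."""
    return layer.bulk_density * layer.loi * loi_to_oc
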