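"""Vendored photon attenuation data and filter stacks.

Mass attenuation coefficients (and, for air, mass energy-absorption
coefficients) are shipped as package data on 10-150 keV grids for Al, Cu,
W, air and water.  Lookups interpolate log-log, which is exact at grid
nodes and monotone on each segment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "AttenuationTable",
    "FilterStack",
    "MaterialError",
    "EnergyRangeError",
    "get_table",
    "available_materials",
    "mu",
    "mu_rho",
    "mu_en_rho_air",
]


class MaterialError(KeyError):
    """Unknown material identifier."""


class EnergyRangeError(ValueError):
    """Energy outside the vendored table range."""


@dataclass(frozen=True)
class AttenuationTable:
    material: str
    energy_keV: np.ndarray
    mu_rho_cm2_g: np.ndarray
    density_g_cm3: float
    mu_en_rho_cm2_g: np.ndarray | None = None

    def __post_init__(self):
        e = np.asarray(self.energy_keV, float)
        if np.any(np.diff(e) <= 0):
            raise ValueError(f"{self.material}: energy grid not strictly increasing")
        if np.any(np.asarray(self.mu_rho_cm2_g, float) <= 0):
            raise ValueError(f"{self.material}: non-positive coefficients")

    @property
    def e_min(self) -> float:
        return float(self.energy_keV[0])

    @property
    def e_max(self) -> float:
        return float(self.energy_keV[-1])

    def _interp(self, values: np.ndarray, e) -> np.ndarray:
        e = np.asarray(e, dtype=np.float64)
        if np.any(e < self.e_min) or np.any(e > self.e_max):
            raise EnergyRangeError(
                f"energy outside {self.material} table range "
                f"[{self.e_min}, {self.e_max}] keV"
            )
        return np.exp(
            np.interp(np.log(e), np.log(self.energy_keV), np.log(values))
        )

    def mu_rho(self, e) -> np.ndarray:
        """Mass attenuation coefficient (cm^2/g) at energy e (keV)."""
        return self._interp(self.mu_rho_cm2_g, e)

    def mu(self, e) -> np.ndarray:
        """Linear attenuation coefficient in 1/mm at energy e (keV)."""
        return self.mu_rho(e) * self.density_g_cm3 / 10.0

    def mu_en_rho(self, e) -> np.ndarray:
        if self.mu_en_rho_cm2_g is None:
            raise MaterialError(f"no energy-absorption data for {self.material}")
        return self._interp(self.mu_en_rho_cm2_g, e)


def _load() -> dict[str, AttenuationTable]:
    raw = json.loads(
        resources.files("kvphasegen.data").joinpath("attenuation.json").read_text()
    )
    tables = {}
    for name, m in raw["materials"].items():
        tables[name] = AttenuationTable(
            material=name,
            energy_keV=np.asarray(m["energy_keV"], float),
            mu_rho_cm2_g=np.asarray(m["mu_rho_cm2_g"], float),
            density_g_cm3=float(m["density_g_cm3"]),
            mu_en_rho_cm2_g=(
                np.asarray(m["mu_en_rho_cm2_g"], float)
                if "mu_en_rho_cm2_g" in m
                else None
            ),
        )
    return tables


_TABLES: dict[str, AttenuationTable] | None = None


def get_table(material: str) -> AttenuationTable:
    global _TABLES
    if _TABLES is None:
        _TABLES = _load()
    try:
        return _TABLES[material]
    except KeyError:
        raise MaterialError(
            f"unknown material {material!r}; available: {sorted(_TABLES)}"
        ) from None


def available_materials() -> list[str]:
    get_table("Al")
    return sorted(_TABLES)  # type: ignore[arg-type]


def mu(material: str, e) -> np.ndarray:
    """Linear attenuation coefficient (1/mm), log-log interpolated."""
    return get_table(material).mu(e)


def mu_rho(material: str, e) -> np.ndarray:
    return get_table(material).mu_rho(e)


def mu_en_rho_air(e) -> np.ndarray:
    """Mass energy-absorption coefficient of air (cm^2/g): kerma response."""
    return get_table("air").mu_en_rho(e)


class FilterStack:
    """Ordered list of (material, thickness mm) attenuating layers."""

    def __init__(self, layers=()):
        parsed = []
        for mat, t in layers:
            t = float(t)
            if t < 0:
                raise ValueError(f"negative thickness for {mat}: {t}")
            get_table(mat)  # raises MaterialError for unknown materials
            parsed.append((str(mat), t))
        self.layers: tuple[tuple[str, float], ...] = tuple(parsed)

    def __iter__(self):
        return iter(self.layers)

    def __len__(self):
        return len(self.layers)

    def __eq__(self, other):
        return isinstance(other, FilterStack) and self.layers == other.layers

    def __repr__(self):
        if not self.layers:
            return "FilterStack(no filter)"
        return "FilterStack(" + " + ".join(f"{t:g} mm {m}" for m, t in self.layers) + ")"

    def transmission(self, e) -> np.ndarray:
        """exp(-sum_layers mu_m(E) * t_m) at energies e (keV)."""
        e = np.asarray(e, dtype=np.float64)
        tau = np.zeros_like(e, dtype=np.float64)
        for mat, t in self.layers:
            tau += mu(mat, e) * t
        return np.exp(-tau)

    def added(self, material: str, thickness_mm: float) -> "FilterStack":
        return FilterStack(list(self.layers) + [(material, thickness_mm)])

    @classmethod
    def parse(cls, text: str) -> "FilterStack":
        """Parse e.g. '3mmAl+0.5mmCu' or '' (no filter)."""
        text = text.strip()
        if not text or text.lower() in ("none", "no filter"):
            return cls()
        layers = []
        for part in text.split("+"):
            part = part.strip()
            if "mm" not in part:
                raise ValueError(f"cannot parse filter layer {part!r}")
            t, mat = part.split("mm", 1)
            layers.append((mat.strip(), float(t)))
        return cls(layers)
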