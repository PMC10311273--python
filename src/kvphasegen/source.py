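"""Analytic kV X-ray source: focal spot, tube spectrum, heel effect, sampling.

This module is an analytic stand-in for a full Monte-Carlo model of an
X-ray head.  It produces phase spaces with the statistical structure the
downstream modules need:

* focal spot — a 4-component Gaussian mixture horizontally and a single
  Gaussian vertically, calibrated so the full widths at 15% of maximum
  match the measured projections (0.70 mm horizontal, 0.60 mm vertical);
* spectrum — Kramers continuum (kvp - E)/E hardened by the inherent
  filtration, with tungsten K lines above the 69.5 keV K edge;
* heel effect — self-filtration of the angled anode modelled as an
  effective tungsten path that grows toward the anode side, applied by
  rejection sampling so the emitted phase space stays unweighted;
* divergence — directions uniform in tangent inside a rectangular fan,
  positions projected from the focal spot to the scoring plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beam_quality import SpectrumModel
from .materials import FilterStack, mu
from .phasespace import ParticleBatch, PhaseSpace

__all__ = [
    "GaussianMixture1D",
    "FocalSpotModel",
    "SourceConfig",
    "default_focal_spot",
    "build_tube_spectrum",
    "sample_focal_spot",
    "heel_weight",
    "sample_source_phase_space",
    "TUNGSTEN_K_EDGE_KEV",
    "TUNGSTEN_K_LINES",
]

TUNGSTEN_K_EDGE_KEV = 69.5

#: (energy keV, relative intensity) of the tungsten K lines; the
#: Ka1:Ka2:Kb intensity ratio 100:57:33 is a configuration default.
TUNGSTEN_K_LINES = ((59.32, 100.0), (57.98, 57.0), (67.2, 33.0))


@dataclass
class GaussianMixture1D:
    """Weighted superposition of 1-D Gaussian components (mm)."""

    weights: np.ndarray
    means_mm: np.ndarray
    sigmas_mm: np.ndarray

    def __post_init__(self):
        self.weights = np.atleast_1d(np.asarray(self.weights, float))
        self.means_mm = np.atleast_1d(np.asarray(self.means_mm, float))
        self.sigmas_mm = np.atleast_1d(np.asarray(self.sigmas_mm, float))
        if not (self.weights.size == self.means_mm.size == self.sigmas_mm.size):
            raise ValueError("mixture component arrays must align")
        if np.any(self.weights < 0) or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("component weights must be nonnegative and sum to 1")
        if np.any(self.sigmas_mm <= 0):
            raise ValueError("component sigmas must be positive")

    @property
    def k(self) -> int:
        return self.weights.size

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, float)[..., None]
        z = (x - self.means_mm) / self.sigmas_mm
        comp = np.exp(-0.5 * z**2) / (self.sigmas_mm * np.sqrt(2 * np.pi))
        return comp @ self.weights

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(self.k, size=n, p=self.weights)
        return self.means_mm[comp] + self.sigmas_mm[comp] * rng.standard_normal(n)


@dataclass
class FocalSpotModel:
    """Per-axis Gaussian mixtures of the effective emission area."""

    horizontal: GaussianMixture1D
    vertical: GaussianMixture1D


def default_focal_spot() -> FocalSpotModel:
    # Mixture shapes frozen so that FW15(horizontal) = 0.70 mm and
    # FW15(vertical) = 0.60 mm, the measured projected spot widths.
    return FocalSpotModel(
        horizontal=GaussianMixture1D(
            weights=[0.22, 0.28, 0.28, 0.22],
            means_mm=[-0.195950, -0.068582, 0.068582, 0.195950],
            sigmas_mm=[0.088177, 0.117570, 0.117570, 0.088177],
        ),
        vertical=GaussianMixture1D(weights=[1.0], means_mm=[0.0], sigmas_mm=[0.154014]),
    )


@dataclass
class SourceConfig:
    """Geometry and physics knobs of the analytic source."""

    kvp: float
    focal_spot: FocalSpotModel = field(default_factory=default_focal_spot)
    inherent_filtration: FilterStack = field(
        default_factory=lambda: FilterStack([("Al", 2.5)])
    )
    anode_material: str = "W"
    anode_angle_deg: float = 12.0
    heel_enabled: bool = True
    #: effective photon production depth below the anode surface
    heel_depth_mm: float = 0.05
    z_plane: float = 500.0
    fan_half_angle_x_deg: float = 8.0
    fan_half_angle_y_deg: float = 8.0

    def __post_init__(self):
        if not 0.0 < self.anode_angle_deg < 45.0:
            raise ValueError("anode angle must be in (0, 45) degrees")
        if self.fan_half_angle_x_deg <= 0 or self.fan_half_angle_y_deg <= 0:
            raise ValueError("fan half-angles must be positive")
        if self.kvp <= 10.0:
            raise ValueError("tube potential must exceed 10 kV")


def build_tube_spectrum(
    kvp: float,
    inherent_filtration: FilterStack | None = None,
    anode_material: str = "W",
    k_line_fraction: float = 0.08,
) -> SpectrumModel:
    """Filtered Kramers continuum plus tungsten K lines, normalized to 1.

    The continuum is w(E) proportional to (kvp - E)/E on a 1-keV grid from
    10 keV to kvp, multiplied by the inherent-filtration transmission.
    K lines appear iff kvp exceeds the 69.5 keV K edge; their summed
    pre-filtration weight ramps linearly with (kvp - K_edge) and is
    ``k_line_fraction`` of the continuum at 120 kV.
    """
    if kvp <= 10.0:
        raise ValueError("tube potential must exceed 10 keV grid start")
    if kvp > 150.0:
        raise ValueError("tube potential above vendored table range (150 keV)")
    if anode_material != "W":
        raise ValueError("only a tungsten anode is modelled")
    if inherent_filtration is None:
        inherent_filtration = FilterStack()

    grid = np.arange(10.0, np.floor(kvp) + 0.5, 1.0)
    line_indices: list[int] = []
    if kvp > TUNGSTEN_K_EDGE_KEV:
        # replace the nearest continuum bins by the exact line energies so
        # sampled line photons are discrete
        for e_line, _ in TUNGSTEN_K_LINES:
            i = int(np.argmin(np.abs(grid - e_line)))
            grid[i] = e_line
            line_indices.append(i)
        grid = np.sort(grid)
        line_indices = [int(np.argmin(np.abs(grid - e))) for e, _ in TUNGSTEN_K_LINES]

    w = (kvp - grid) / grid
    w[w < 0] = 0.0
    trans = inherent_filtration.transmission(grid)
    continuum_before = w.sum()
    w = w * trans

    if kvp > TUNGSTEN_K_EDGE_KEV and continuum_before > 0:
        ramp = (kvp - TUNGSTEN_K_EDGE_KEV) / (120.0 - TUNGSTEN_K_EDGE_KEV)
        total_line = k_line_fraction * ramp * continuum_before
        intensities = np.array([r for _, r in TUNGSTEN_K_LINES])
        intensities = intensities / intensities.sum()
        for idx, frac in zip(line_indices, intensities):
            w[idx] += total_line * frac * trans[idx]

    return SpectrumModel(
        grid, w, kvp=float(kvp), line_indices=tuple(line_indices)
    ).normalize()


def sample_focal_spot(
    model: FocalSpotModel, n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """(n, 2) i.i.d. draws of (horizontal, vertical) emission positions (mm)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return np.stack(
        [model.horizontal.sample(n, rng), model.vertical.sample(n, rng)], axis=1
    )


def heel_weight(
    emission_angle_deg,
    e_keV,
    anode_angle_deg: float = 12.0,
    anode_material: str = "W",
    depth_mm: float = 0.05,
    return_cutoff: bool = False,
):
    """Transmission weight in [0, 1] of anode self-filtration (heel effect).

    ``emission_angle_deg`` is measured from the central axis, positive
    toward the anode side.  A photon produced at effective depth ``d0``
    below the anode surface leaves through a tungsten path

        t_eff(theta) = d0 * max(sin(alpha)/sin(alpha - theta) - 1, 0)

    where ``alpha`` is the anode (target) angle; the take-off angle is
    alpha - theta.  On the central axis t_eff = 0, so the weight is
    exactly 1 there; toward the anode side the path grows monotonically.
    Rays with take-off <= 0 would exit through the anode face: weight 0,
    flagged when ``return_cutoff``.
    """
    theta = np.deg2rad(np.asarray(emission_angle_deg, float))
    alpha = np.deg2rad(anode_angle_deg)
    takeoff = alpha - theta
    cutoff = takeoff <= 0
    safe = np.where(cutoff, alpha, takeoff)
    t_eff = depth_mm * np.maximum(np.sin(alpha) / np.sin(safe) - 1.0, 0.0)
    weight = np.exp(-mu(anode_material, e_keV) * t_eff)
    weight = np.where(cutoff, 0.0, weight)
    if return_cutoff:
        return weight, cutoff
    return weight


def _sample_energies(
    spec: SpectrumModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw energies; continuum bins are jittered inside their 1-keV width,
    characteristic lines stay discrete."""
    idx = rng.choice(spec.energy_keV.size, size=n, p=spec.weights)
    e = spec.energy_keV[idx].copy()
    is_line = np.isin(idx, np.asarray(spec.line_indices, int))
    jitter = rng.uniform(-0.5, 0.5, n)
    e[~is_line] += jitter[~is_line]
    kvp = spec.kvp if spec.kvp is not None else spec.energy_keV[-1]
    return np.clip(e, 10.0 + 1e-6, kvp)


def sample_source_phase_space(
    cfg: SourceConfig, n: int, seed: int = 0
) -> PhaseSpace:
    """Sample an unweighted phase space at the scoring plane.

    Directions are uniform in tangent inside the rectangular fan, the heel
    effect is applied by rejection on the x (anode-cathode) angle and the
    photon energy, and positions are the focal-spot draw projected along
    the direction to ``cfg.z_plane``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    spec = build_tube_spectrum(cfg.kvp, cfg.inherent_filtration, cfg.anode_material)
    tan_x = np.tan(np.deg2rad(cfg.fan_half_angle_x_deg))
    tan_y = np.tan(np.deg2rad(cfg.fan_half_angle_y_deg))

    cols: list[np.ndarray] = []
    accepted = 0
    proposed = 0
    while accepted < n:
        m = max(2 * (n - accepted), 1024)
        tx = rng.uniform(-tan_x, tan_x, m)
        ty = rng.uniform(-tan_y, tan_y, m)
        spot = sample_focal_spot(cfg.focal_spot, m, rng)
        e = _sample_energies(spec, m, rng)
        if cfg.heel_enabled:
            ang = np.rad2deg(np.arctan(tx))
            w = heel_weight(
                ang, e, cfg.anode_angle_deg, cfg.anode_material, cfg.heel_depth_mm
            )
            keep = rng.random(m) < w
        else:
            keep = np.ones(m, bool)
        proposed += m
        tx, ty, spot, e = tx[keep], ty[keep], spot[keep], e[keep]
        if proposed >= 4096 and (accepted + tx.size) / proposed < 0.01:
            raise ValueError(
                "heel rejection efficiency below 1%: pathological heel parameters"
            )
        norm = np.sqrt(tx**2 + ty**2 + 1.0)
        batch = np.stack(
            [
                spot[:, 0] + tx * cfg.z_plane,
                spot[:, 1] + ty * cfg.z_plane,
                tx / norm,
                ty / norm,
                1.0 / norm,
                e,
            ],
            axis=1,
        )
        cols.append(batch)
        accepted += batch.shape[0]

    arr = np.concatenate(cols, axis=0)[:n]
    ps = PhaseSpace(
        batch=ParticleBatch.from_columns(arr),
        kvp_label=int(cfg.kvp),
        z_plane=cfg.z_plane,
        meta={
            "generator": "kvphasegen.source",
            "seed": int(seed),
            "heel_enabled": bool(cfg.heel_enabled),
            "anode_angle_deg": cfg.anode_angle_deg,
            "fan_half_angle_x_deg": cfg.fan_half_angle_x_deg,
            "fan_half_angle_y_deg": cfg.fan_half_angle_y_deg,
        },
    )
    ps.validate()
    return ps
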