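"""Quantitative comparison machinery for phase spaces and profiles.

The histogram loss compares a generated particle set against a reference
(validation) set, parameter by parameter: with identical bin edges
applied to both sets,

    L_hist = sum_i |counts_gen,i - counts_ref,i|            (per parameter)
    L_total = sum over the six parameters (x, y, dx, dy, dz, e)
    E = L_total / (n_parameters * n_particles) * 100   [percent]

L_hist is the L1 distance between count vectors, hence symmetric and a
metric.  For conditional (multi-energy) models the scalar figure of merit
is the arithmetic mean of L_total across trained energies.

Also provided: full-width-at-fraction profile widths (the focal-spot
FW15 convention), Gaussian-mixture profile fits, and lateral intensity
profiles (the heel-effect observable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .phasespace import COLUMNS, ParticleBatch, PhaseSpace
from .source import FocalSpotModel, GaussianMixture1D

__all__ = [
    "HistogramSpec",
    "HistogramLossReport",
    "ProfileTrace",
    "ProfileShapeError",
    "histogram_loss",
    "conditional_total_loss",
    "fw_at_fraction",
    "fit_gaussian_mixture",
    "lateral_profile",
]

N_PARAMETERS = 6


@dataclass
class HistogramSpec:
    """Shared binning for reference/generated comparisons.

    By default edges span the reference set's min/max per parameter with
    ``n_bins`` equal-width bins; explicit edges may be given instead.
    Values outside the edges are accumulated in the clamped end bins.
    """

    n_bins: int = 100
    n_particles: int = 1_000_000
    edges: dict[str, np.ndarray] | None = None

    def edges_for(self, ref: ParticleBatch) -> dict[str, np.ndarray]:
        if self.edges is not None:
            out = {}
            for c in COLUMNS:
                e = np.asarray(self.edges[c], float)
                if np.any(np.diff(e) <= 0):
                    raise ValueError(f"bin edges for {c!r} not strictly increasing")
                out[c] = e
            return out
        cols = ref.columns()
        out = {}
        for i, c in enumerate(COLUMNS):
            lo, hi = float(cols[:, i].min()), float(cols[:, i].max())
            if hi <= lo:
                hi = lo + 1e-9
            out[c] = np.linspace(lo, hi, self.n_bins + 1)
        return out


@dataclass
class HistogramLossReport:
    per_parameter: dict[str, float]
    l_total: float
    n_particles: int
    n_parameters: int = N_PARAMETERS
    error_percent: float = 0.0

    def __post_init__(self):
        if not self.error_percent:
            self.error_percent = (
                self.l_total / (self.n_parameters * self.n_particles) * 100.0
            )


def _clamped_counts(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    clipped = np.clip(values, edges[0], edges[-1])
    counts, _ = np.histogram(clipped, bins=edges)
    return counts


def histogram_loss(
    ref: ParticleBatch, gen: ParticleBatch, spec: HistogramSpec | None = None
) -> HistogramLossReport:
    """Per-parameter L1 histogram losses, their total, and the percent error.

    Both batches must already be sized to ``spec.n_particles``; the edges
    are derived from the reference unless the spec fixes them explicitly.
    """
    if spec is None:
        spec = HistogramSpec(n_particles=ref.n)
    if ref.n != spec.n_particles or gen.n != spec.n_particles:
        raise ValueError(
            f"batch sizes ({ref.n}, {gen.n}) do not match "
            f"spec.n_particles = {spec.n_particles}"
        )
    edges = spec.edges_for(ref)
    per = {}
    for c in COLUMNS:
        cr = _clamped_counts(np.asarray(getattr(ref, c), float), edges[c])
        cg = _clamped_counts(np.asarray(getattr(gen, c), float), edges[c])
        per[c] = float(np.abs(cg - cr).sum())
    return HistogramLossReport(
        per_parameter=per, l_total=float(sum(per.values())), n_particles=spec.n_particles
    )


def conditional_total_loss(reports: list[HistogramLossReport]) -> float:
    """Mean of L_total across trained energies (conditional-model scalar)."""
    if not reports:
        raise ValueError("need at least one per-energy report")
    return float(np.mean([r.l_total for r in reports]))


@dataclass
class ProfileTrace:
    """Sampled 1-D intensity profile along a spatial axis."""

    positions_mm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.positions_mm = np.asarray(self.positions_mm, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.positions_mm.shape != self.intensity.shape:
            raise ValueError("positions and intensities must align")
        if np.any(np.diff(self.positions_mm) <= 0):
            raise ValueError("positions must be strictly increasing")


class ProfileShapeError(ValueError):
    def __init__(self, message, crossings=None):
        super().__init__(message)
        self.crossings = crossings


def fw_at_fraction(
    p: ProfileTrace, fraction: float = 0.15, strict: bool = False
) -> float:
    """Full width (mm) of the profile at ``fraction`` of its maximum.

    The two crossings are located scanning outward from the peak (first
    sample below threshold on each side) and linearly interpolated.  With
    ``strict`` the profile must cross the threshold exactly once per side
    — noisy sampled profiles can jitter across the threshold, so the
    scan-from-peak convention is the default.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    y = p.intensity
    x = p.positions_mm
    ipk = int(np.argmax(y))
    thr = fraction * y[ipk]
    if ipk == 0 or ipk == y.size - 1:
        raise ProfileShapeError("profile peak lies on the boundary")
    below = y < thr
    if not below[:ipk].any() or not below[ipk + 1 :].any():
        raise ProfileShapeError("profile never falls below the threshold")

    if strict:
        sign = (y >= thr).astype(int)
        crossings = np.flatnonzero(np.diff(sign) != 0)
        left_side = crossings[crossings < ipk]
        right_side = crossings[crossings >= ipk]
        if left_side.size != 1 or right_side.size != 1:
            raise ProfileShapeError(
                f"expected one threshold crossing per side, found "
                f"{left_side.size} left / {right_side.size} right",
                crossings=crossings,
            )

    il = ipk - 1
    while y[il] >= thr:
        il -= 1
    ir = ipk + 1
    while y[ir] >= thr:
        ir += 1

    def interp(i_lo, i_hi):
        y0, y1 = y[i_lo], y[i_hi]
        return x[i_lo] + (thr - y0) * (x[i_hi] - x[i_lo]) / (y1 - y0)

    left = interp(il, il + 1)
    right = interp(ir - 1, ir)
    return float(right - left)


def fit_gaussian_mixture(
    p: ProfileTrace, k: int, n_starts: int = 5, seed: int = 0
) -> tuple[FocalSpotModel | GaussianMixture1D, float]:
    """Nonlinear least-squares fit of k Gaussian components to a profile.

    Multi-start initialisation spreads the component means over the
    intensity-weighted quantiles.  Returns the fitted 1-D mixture (with
    amplitude-normalised weights, components sorted by mean) and the RMS
    residual of the best start.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x, y = p.positions_mm, p.intensity
    if x.size < 3 * k + 1:
        raise ValueError(f"need at least {3 * k + 1} samples to fit k={k}")
    area = np.trapezoid(y, x)
    if area <= 0:
        raise ValueError("profile has no positive area")
    cdf = np.cumsum(y) / y.sum()
    span = x[-1] - x[0]
    rng = np.random.default_rng(seed)

    def model(params):
        amps = params[:k]
        mus = params[k : 2 * k]
        sigs = params[2 * k :]
        z = (x[:, None] - mus) / sigs
        return np.exp(-0.5 * z**2) @ amps

    best = None
    for start in range(n_starts):
        q = np.linspace(0.5 / k, 1 - 0.5 / k, k)
        if start > 0:
            q = np.clip(q + rng.uniform(-0.25 / k, 0.25 / k, k), 0.01, 0.99)
        mus0 = np.interp(q, cdf, x)
        sigs0 = np.full(k, max(span / (4 * k), 1e-3) * (1.0 + 0.3 * start))
        amps0 = np.full(k, y.max() / k)
        p0 = np.concatenate([amps0, mus0, sigs0])
        lb = np.concatenate([np.zeros(k), np.full(k, x[0] - span), np.full(k, 1e-6)])
        ub = np.concatenate(
            [np.full(k, np.inf), np.full(k, x[-1] + span), np.full(k, 10 * span)]
        )
        try:
            sol = least_squares(
                lambda q_: model(q_) - y, p0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14
            )
        except Exception:
            continue
        rms = float(np.sqrt(np.mean((model(sol.x) - y) ** 2)))
        if best is None or rms < best[1]:
            best = (sol.x, rms)
    if best is None:
        raise RuntimeError("gaussian mixture fit failed to converge from any start")
    params, rms = best
    amps, mus, sigs = params[:k], params[k : 2 * k], params[2 * k :]
    order = np.argsort(mus)
    amps, mus, sigs = amps[order], mus[order], sigs[order]
    weights = amps * sigs * np.sqrt(2 * np.pi)
    total = weights.sum()
    if total <= 0:
        raise RuntimeError("degenerate mixture fit (zero total weight)")
    mix = GaussianMixture1D(weights / total, mus, np.abs(sigs))
    return mix, rms


def lateral_profile(ps: PhaseSpace, axis: str = "x", bins: int = 100) -> ProfileTrace:
    """Particle counts per position bin at the scoring plane."""
    if ps.n < 1:
        raise ValueError("empty phase space")
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    if ps.n < bins:
        raise ValueError("need at least one particle per bin on average")
    vals = np.asarray(getattr(ps.batch, axis), float)
    counts, edges = np.histogram(vals, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return ProfileTrace(centers, counts.astype(float))
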