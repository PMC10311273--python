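"""Bundled desk-scale benchmark definitions.

The production-scale study (1e8 particles per energy, batch 1e4, hidden
width 400) is not desk-reproducible, so the package ships one fixed,
scaled-down benchmark family used by the test-suite and the example
workflows:

* 1e5 particles per energy, split 50/50 train/validation;
* 20 epochs, batch 1e3, learning rate 2e-5, RMSProp — the production
  optimiser settings;
* hidden width 48 for generator and discriminator (a scaled-down
  analogue of the 400-wide production networks, sized so a full
  hyper-parameter grid trains on one CPU core in minutes).

These sizes are frozen: they define the conditions under which the
qualitative results (loss-function ordering, interpolation quality,
image agreement) are asserted.
"""

from __future__ import annotations

import numpy as np

from .gan import DiscriminatorSpec, GeneratorSpec, TrainConfig
from .phasespace import PhaseSpace, split_train_validation
from .projector import DetectorGeometry, VoxelPhantom
from .source import SourceConfig, sample_source_phase_space

__all__ = [
    "BENCH_HIDDEN",
    "BENCH_PARTICLES_PER_ENERGY",
    "benchmark_train_config",
    "benchmark_specs",
    "make_benchmark_data",
    "demo_phantom",
    "demo_detector",
]

BENCH_HIDDEN: tuple[int, int, int] = (48, 48, 48)
BENCH_PARTICLES_PER_ENERGY = 100_000


def benchmark_train_config(loss: str, seed: int = 0, **overrides) -> TrainConfig:
    """The frozen scaled-down optimiser settings (batch 1e3, 20 epochs)."""
    cfg = dict(
        loss=loss,
        lr=2e-5,
        batch_size=1000,
        epochs=20,
        ema=True,
        d_steps=2,
        seed=seed,
        val_particles=20_000,
    )
    cfg.update(overrides)
    return TrainConfig(**cfg)


def benchmark_specs(
    labels: tuple[int, ...] | None, spectral_norm: bool
) -> tuple[GeneratorSpec, DiscriminatorSpec]:
    return (
        GeneratorSpec(hidden=BENCH_HIDDEN, labels=labels),
        DiscriminatorSpec(hidden=BENCH_HIDDEN, spectral_norm=spectral_norm),
    )


def make_benchmark_data(
    kvps: tuple[int, ...] = (60, 100),
    n_per_energy: int = BENCH_PARTICLES_PER_ENERGY,
    seed: int = 0,
) -> tuple[dict[int, PhaseSpace], dict[int, PhaseSpace]]:
    """Synthetic multi-energy phase spaces, already split 50/50.

    Returns (train, validation) maps keyed by tube potential.
    """
    train, val = {}, {}
    for i, kvp in enumerate(kvps):
        ps = sample_source_phase_space(
            SourceConfig(kvp=kvp), n_per_energy, seed=seed + 1000 * i
        )
        tr, va = split_train_validation(ps, 0.5, seed=seed + 1000 * i + 1)
        train[kvp], val[kvp] = tr, va
    return train, val


def demo_phantom(n: int = 48, spacing_mm: float = 2.0) -> VoxelPhantom:
    """Water cylinder with an aluminium rod and an air cavity.

    The cylinder axis runs along y; the grid is centred laterally on the
    beam axis and spans z in [550, 550 + n*spacing] mm, i.e. between the
    default source scoring plane (500 mm) and the demo detector.
    """
    names = {1: "water", 2: "Al", 3: "air"}
    mats = np.zeros((n, n, n), dtype=np.int32)
    dens = np.zeros((n, n, n))
    half = n * spacing_mm / 2.0
    coords = (np.arange(n) + 0.5) * spacing_mm - half  # centred axis coords
    xx, zz = np.meshgrid(coords, coords, indexing="ij")
    cyl = xx**2 + zz**2 <= (0.72 * half) ** 2
    rod = (xx - 0.25 * half) ** 2 + (zz - 0.15 * half) ** 2 <= (0.12 * half) ** 2
    hole = (xx + 0.3 * half) ** 2 + (zz + 0.2 * half) ** 2 <= (0.15 * half) ** 2
    for j in range(n):  # extrude along y
        mats[:, j, :][cyl] = 1
        mats[:, j, :][rod] = 2
        mats[:, j, :][hole] = 3
    dens[mats == 1] = 1.0
    dens[mats == 2] = 2.699
    dens[mats == 3] = 0.0012048
    return VoxelPhantom(
        materials=mats,
        densities=dens,
        spacing_mm=(spacing_mm,) * 3,
        origin_mm=(-half, -half, 550.0),
        material_names=names,
    )


def demo_detector() -> DetectorGeometry:
    """16 x 16 pixels of 16 mm: coarse enough that a 1e6-photon image has
    per-pixel counting noise well below the model effects being compared."""
    return DetectorGeometry(z_mm=700.0, nx=16, ny=16, pitch_mm=16.0)
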