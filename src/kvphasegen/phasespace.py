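"""Phase-space data model, on-disk container, normalization and splitting.

A phase space records photons crossing a scoring plane orthogonal to the
beam axis (+z): lateral position (x, y in mm), unit direction cosines
(dx, dy, dz) and energy (e in keV).  Conventions: right-handed axes,
origin on the central axis, dz > 0 (forward-going toward the detector).

The on-disk container is a single HDF5 file with six float32 column
datasets in fixed order and a JSON header attribute; round-trips are
bit-exact for the particle columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import h5py
import numpy as np

FORMAT_VERSION = 1
COLUMNS = ("x", "y", "dx", "dy", "dz", "e")

#: tube potentials with clinical protocols on the modelled system
SUPPORTED_KVPS = (60, 80, 100, 120)

_UNIT_TOL = 1e-6


class PhaseSpaceFormatError(IOError):
    """Missing or corrupt container header / layout."""


class PhaseSpaceValidationError(ValueError):
    """A particle record violates a phase-space invariant."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


@dataclass
class ParticleBatch:
    """Columnar set of particles (the six generated GAN parameters)."""

    x: np.ndarray
    y: np.ndarray
    dx: np.ndarray
    dy: np.ndarray
    dz: np.ndarray
    e: np.ndarray

    def __post_init__(self) -> None:
        cols = [np.asarray(getattr(self, c), dtype=np.float32) for c in COLUMNS]
        n = cols[0].shape[0]
        for name, c in zip(COLUMNS, cols):
            if c.ndim != 1 or c.shape[0] != n:
                raise PhaseSpaceValidationError(
                    f"column {name!r} must be 1-D of common length"
                )
        for name, c in zip(COLUMNS, cols):
            object.__setattr__(self, name, c)

    @property
    def n(self) -> int:
        return int(self.x.shape[0])

    def columns(self) -> np.ndarray:
        """Stack into an (n, 6) float64 array in canonical column order."""
        return np.stack(
            [np.asarray(getattr(self, c), dtype=np.float64) for c in COLUMNS], axis=1
        )

    @classmethod
    def from_columns(cls, arr: np.ndarray) -> "ParticleBatch":
        arr = np.asarray(arr)
        if arr.ndim != 2 or arr.shape[1] != 6:
            raise PhaseSpaceValidationError("expected an (n, 6) array")
        return cls(*(arr[:, i] for i in range(6)))

    def validate(self, kvp: float | None = None) -> None:
        """Check unit directions, forward-going dz and the energy range.

        Raises :class:`PhaseSpaceValidationError` naming the first
        offending row.
        """
        d = self.columns()
        norm2 = d[:, 2] ** 2 + d[:, 3] ** 2 + d[:, 4] ** 2
        bad = np.flatnonzero(np.abs(norm2 - 1.0) > _UNIT_TOL)
        if bad.size:
            raise PhaseSpaceValidationError(
                f"direction not unit length at row {bad[0]} "
                f"(|d|^2 = {norm2[bad[0]]:.8f})",
                row=int(bad[0]),
            )
        bad = np.flatnonzero(d[:, 4] <= 0.0)
        if bad.size:
            raise PhaseSpaceValidationError(
                f"dz <= 0 at row {bad[0]} (dz = {d[bad[0], 4]:.6f})", row=int(bad[0])
            )
        bad = np.flatnonzero(d[:, 5] <= 0.0)
        if bad.size:
            raise PhaseSpaceValidationError(
                f"non-positive energy at row {bad[0]}", row=int(bad[0])
            )
        if kvp is not None:
            bad = np.flatnonzero(d[:, 5] > float(kvp) * (1.0 + 1e-9))
            if bad.size:
                raise PhaseSpaceValidationError(
                    f"energy {d[bad[0], 5]:.3f} keV above tube potential "
                    f"{kvp} kV at row {bad[0]}",
                    row=int(bad[0]),
                )

    def take(self, idx: np.ndarray) -> "ParticleBatch":
        return ParticleBatch(*(getattr(self, c)[idx] for c in COLUMNS))


@dataclass
class PhaseSpace:
    """A particle batch plus the run metadata that produced it."""

    batch: ParticleBatch
    kvp_label: int
    z_plane: float = 500.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if int(self.kvp_label) not in SUPPORTED_KVPS:
            raise PhaseSpaceValidationError(
                f"kvp_label {self.kvp_label} not in declared set {SUPPORTED_KVPS}"
            )
        if self.batch.n < 1:
            raise PhaseSpaceValidationError("phase space must contain >= 1 particle")

    @property
    def n(self) -> int:
        return self.batch.n

    def validate(self) -> None:
        self.batch.validate(kvp=float(self.kvp_label))


def write_phase_space(ps: PhaseSpace, path) -> None:
    """Write the native single-file container (6 float32 columns + header)."""
    header = {
        "format": "kvphasegen-phsp",
        "version": FORMAT_VERSION,
        "kvp_label": int(ps.kvp_label),
        "z_plane_mm": float(ps.z_plane),
        "n": ps.n,
        "columns": list(COLUMNS),
        "meta": ps.meta,
    }
    with h5py.File(path, "w") as f:
        f.attrs["header"] = json.dumps(header)
        for c in COLUMNS:
            f.create_dataset(c, data=np.asarray(getattr(ps.batch, c), np.float32))


def read_phase_space(path, validate: bool = True) -> PhaseSpace:
    """Read the native container; optionally re-check all invariants."""
    with h5py.File(path, "r") as f:
        if "header" not in f.attrs:
            raise PhaseSpaceFormatError(f"{path}: missing header block")
        try:
            header = json.loads(f.attrs["header"])
        except (json.JSONDecodeError, TypeError) as exc:
            raise PhaseSpaceFormatError(f"{path}: corrupt header") from exc
        if header.get("format") != "kvphasegen-phsp":
            raise PhaseSpaceFormatError(f"{path}: not a kvphasegen phase-space file")
        missing = [c for c in COLUMNS if c not in f]
        if missing:
            raise PhaseSpaceFormatError(f"{path}: missing columns {missing}")
        batch = ParticleBatch(*(f[c][...] for c in COLUMNS))
    if batch.n != header.get("n"):
        raise PhaseSpaceFormatError(
            f"{path}: header count {header.get('n')} != stored {batch.n}"
        )
    ps = PhaseSpace(
        batch=batch,
        kvp_label=int(header["kvp_label"]),
        z_plane=float(header["z_plane_mm"]),
        meta=header.get("meta", {}),
    )
    if validate:
        ps.validate()
    return ps


@dataclass
class NormalizationSpec:
    """Per-parameter min/max mapping particle columns onto the unit box.

    The generator's last hidden layer is sigmoid-bounded, so training data
    must live in [0, 1] per parameter; values outside the spec's range are
    clipped (never errored: a trained generator may slightly overshoot)
    and counted.
    """

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        self.lo = np.asarray(self.lo, dtype=np.float64).reshape(6)
        self.hi = np.asarray(self.hi, dtype=np.float64).reshape(6)
        if not np.all(self.hi > self.lo):
            bad = [COLUMNS[i] for i in np.flatnonzero(self.hi <= self.lo)]
            raise ValueError(f"degenerate normalization range for {bad}")

    @classmethod
    def from_batch(cls, b: ParticleBatch, pad: float = 0.0) -> "NormalizationSpec":
        cols = b.columns()
        lo, hi = cols.min(axis=0), cols.max(axis=0)
        span = hi - lo
        span[span == 0] = 1.0
        return cls(lo - pad * span, hi + pad * span)


def normalize_batch(
    b: ParticleBatch, spec: NormalizationSpec
) -> tuple[np.ndarray, int]:
    """Map to the unit box; returns (array (n, 6) in [0,1], clip count)."""
    cols = b.columns()
    clipped = np.clip(cols, spec.lo, spec.hi)
    n_clipped = int(np.sum(np.any(clipped != cols, axis=1)))
    return (clipped - spec.lo) / (spec.hi - spec.lo), n_clipped


def denormalize_batch(arr: np.ndarray, spec: NormalizationSpec) -> ParticleBatch:
    """Inverse of :func:`normalize_batch` (identity within 1e-6 round trip)."""
    arr = np.asarray(arr, dtype=np.float64)
    cols = arr * (spec.hi - spec.lo) + spec.lo
    return ParticleBatch.from_columns(cols)


def split_train_validation(
    ps: PhaseSpace, fraction: float = 0.5, seed: int = 0
) -> tuple[PhaseSpace, PhaseSpace]:
    """Disjoint, exhaustive random split; sizes floor(n*fraction)/remainder."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n = ps.n
    if n < 2:
        raise ValueError("need at least 2 particles to split")
    perm = np.random.default_rng(seed).permutation(n)
    k = int(np.floor(n * fraction))
    if k == 0 or k == n:
        raise ValueError(f"fraction {fraction} leaves an empty portion for n={n}")
    idx_a, idx_b = perm[:k], perm[k:]
    meta_a = dict(ps.meta, split="train", split_seed=seed)
    meta_b = dict(ps.meta, split="validation", split_seed=seed)
    return (
        PhaseSpace(ps.batch.take(idx_a), ps.kvp_label, ps.z_plane, meta_a),
        PhaseSpace(ps.batch.take(idx_b), ps.kvp_label, ps.z_plane, meta_b),
    )
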