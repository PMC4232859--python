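"""Shared in-memory containers: sensor arrays, epoched data, voxel grids, images."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

FACE = "face"
SCRAMBLED = "scrambled"


@dataclass
class SensorArray:
    """MEG sensor geometry: one position and one orientation unit vector per channel.

    Positions are in metres in the head frame.  Channels are modelled as point
    magnetometers measuring the field component along ``ori``; a two-point
    axial-gradiometer option lives in :func:`samface.forward.leadfield_grid`.
    """

    pos: np.ndarray  # (n_channels, 3) m
    ori: np.ndarray  # (n_channels, 3) unit vectors
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        self.ori = np.asarray(self.ori, dtype=float)
        if self.pos.ndim != 2 or self.pos.shape[1] != 3:
            raise ValueError("sensor positions must be (n, 3)")
        if self.ori.shape != self.pos.shape:
            raise ValueError("sensor orientations must match positions in shape")
        norms = np.linalg.norm(self.ori, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("sensor orientations must be unit vectors")
        if not self.names:
            self.names = [f"MEG{i:03d}" for i in range(len(self.pos))]

    @property
    def n_channels(self) -> int:
        return len(self.pos)


@dataclass
class EpochSet:
    """Epoched MEG data: trials x channels x time plus geometry and labels.

    ``time`` is in seconds with stimulus onset at 0; the default acquisition
    span is -1.25 to +1.25 s.  ``labels`` holds one condition string per trial
    (``"face"`` or ``"scrambled"`` in the face paradigm, but arbitrary strings
    are accepted).
    """

    data: np.ndarray  # (n_trials, n_channels, n_times)
    sfreq: float
    time: np.ndarray  # (n_times,) seconds, onset at 0
    labels: np.ndarray  # (n_trials,) condition strings
    sensors: SensorArray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, time)")
        if len(self.time) != self.data.shape[2]:
            raise ValueError("time axis length mismatch")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per trial required")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in epoch data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def time_index(self, t: float) -> int:
        """Index of the sample closest to time ``t`` (seconds)."""
        return int(np.argmin(np.abs(self.time - t)))

    def time_mask(self, t_start: float, t_end: float) -> np.ndarray:
        """Boolean sample mask for the half-open-ish window [t_start, t_end]."""
        if t_start >= t_end:
            raise ValueError("window start must precede end")
        if t_start < self.time[0] - 1e-9 or t_end > self.time[-1] + 1e-9:
            raise ValueError(
                f"window [{t_start}, {t_end}] s outside epoch span "
                f"[{self.time[0]:.3f}, {self.time[-1]:.3f}] s"
            )
        return (self.time >= t_start - 1e-12) & (self.time <= t_end + 1e-12)

    def select(self, condition: str | Sequence[str] | None) -> np.ndarray:
        """Trial mask for a condition (or all trials when ``condition`` is None)."""
        if condition is None:
            return np.ones(self.n_trials, dtype=bool)
        if isinstance(condition, str):
            condition = [condition]
        mask = np.isin(self.labels, list(condition))
        return mask


def default_time_axis(sfreq: float, t_start: float = -1.25, t_end: float = 1.25) -> np.ndarray:
    """Sample times covering [t_start, t_end) with onset exactly on a sample."""
    n_pre = int(round(-t_start * sfreq))
    n_post = int(round(t_end * sfreq))
    return np.arange(-n_pre, n_post) / sfreq


@dataclass
class GridSpec:
    """Regular voxel grid: origin of voxel (0,0,0), isotropic spacing, shape, mask.

    Spacing is in metres (4 mm default in the pipeline).  ``mask`` marks voxels
    inside the brain; statistics are NaN outside it.
    """

    origin: np.ndarray  # (3,) m, centre of voxel (0, 0, 0)
    spacing: float  # m, isotropic
    shape: tuple[int, int, int]
    mask: np.ndarray | None = None  # bool, same shape

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.shape = tuple(int(s) for s in self.shape)
        if self.mask is None:
            self.mask = np.ones(self.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.shape:
            raise ValueError("mask shape must match grid shape")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def voxel_indices(self) -> np.ndarray:
        """(n_masked, 3) integer indices of in-mask voxels, C order."""
        return np.argwhere(self.mask)

    def positions(self, indices: np.ndarray | None = None) -> np.ndarray:
        """Millimetre-free world positions (m) of voxels (default: all in-mask)."""
        if indices is None:
            indices = self.voxel_indices()
        return self.origin + np.asarray(indices, dtype=float) * self.spacing

    def affine(self) -> np.ndarray:
        """NIfTI RAS affine mapping voxel index to millimetres."""
        aff = np.eye(4)
        aff[:3, :3] *= self.spacing * 1000.0
        aff[:3, 3] = self.origin * 1000.0
        return aff

    @classmethod
    def sphere(cls, radius: float, spacing: float, centre=(0.0, 0.0, 0.0)) -> "GridSpec":
        """Grid covering a sphere, masked to voxels inside it."""
        centre = np.asarray(centre, dtype=float)
        n = int(np.ceil(2 * radius / spacing)) + 1
        origin = centre - (n - 1) / 2.0 * spacing
        idx = np.indices((n, n, n)).reshape(3, -1).T
        pos = origin + idx * spacing
        mask = (np.linalg.norm(pos - centre, axis=1) <= radius).reshape(n, n, n)
        return cls(origin=origin, spacing=spacing, shape=(n, n, n), mask=mask)


@dataclass
class VolumetricImage:
    """One scalar per voxel on a grid; NaN outside the mask.

    ``semantics`` tags what the values are: ``power``, ``t``, ``pseudo-t`` or ``p``.
    """

    grid: GridSpec
    values: np.ndarray  # grid.shape
    semantics: str = "power"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("image values must match grid shape")
        if not np.all(np.isfinite(self.values[self.grid.mask])):
            raise ValueError("non-finite values inside mask")

    @classmethod
    def from_flat(cls, grid: GridSpec, flat: np.ndarray, semantics: str = "power") -> "VolumetricImage":
        """Assemble from per-in-mask-voxel values (C order of argwhere)."""
        vol = np.full(grid.shape, np.nan)
        vol[grid.mask] = np.asarray(flat, dtype=float)
        return cls(grid=grid, values=vol, semantics=semantics)

    def flat(self) -> np.ndarray:
        return self.values[self.grid.mask]
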