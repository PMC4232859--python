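"""Spherical-conductor MEG forward model.

The magnetic field of a current dipole inside a homogeneous spherical
conductor has a closed form (Sarvas' formula) that is independent of the
sphere radius and the conductivity profile, and vanishes for radially
oriented dipoles.  The beamformer consumes per-voxel leadfields built from
two tangential unit moments; a multiple local-spheres head model assigns each
channel its own best-fitting sphere of the brain surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from samface.containers import GridSpec, SensorArray

MU0 = 4e-7 * np.pi  # vacuum permeability, T·m/A

__all__ = [
    "Dipole",
    "HeadModel",
    "Leadfield",
    "sphere_field",
    "fit_local_spheres",
    "leadfield_grid",
    "tangential_basis",
]


@dataclass
class Dipole:
    """Equivalent current dipole: position (m) and moment (A·m)."""

    pos: np.ndarray
    moment: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        self.moment = np.asarray(self.moment, dtype=float)
        if self.pos.shape != (3,) or self.moment.shape != (3,):
            raise ValueError("dipole position and moment must be 3-vectors")


@dataclass
class HeadModel:
    """Single-sphere or multiple-local-spheres conductor model.

    ``centres`` is (3,) for a single global sphere or (n_channels, 3) for one
    sphere per channel.  The radius only bounds where sources may sit — the
    external field itself is radius-independent.
    """

    centres: np.ndarray
    radius: float = 0.09

    def __post_init__(self) -> None:
        self.centres = np.asarray(self.centres, dtype=float)
        if self.centres.ndim == 1 and self.centres.shape == (3,):
            pass
        elif self.centres.ndim == 2 and self.centres.shape[1] == 3:
            pass
        else:
            raise ValueError("centres must be (3,) or (n_channels, 3)")
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")

    @property
    def per_channel(self) -> bool:
        return self.centres.ndim == 2

    def centre_for(self, channel: int) -> np.ndarray:
        return self.centres[channel] if self.per_channel else self.centres


def sphere_field(
    dipole: Dipole,
    sensor_pos: np.ndarray,
    sensor_ori: np.ndarray,
    centre: np.ndarray = (0.0, 0.0, 0.0),
) -> float:
    """Field component (tesla) along ``sensor_ori`` at ``sensor_pos``.

    Closed-form solution for a current dipole in a spherical conductor.  With
    positions taken relative to the sphere centre, dipole at r0 with moment q
    and field point r:

        a = r - r0,  F = a (r a + r^2 - r0·r)
        ∇F = (a²/r + a·r/a + 2a + 2r) r - (a + 2r + a·r/a) r0
        B(r) = µ0 / (4π F²) · (F q×r0 - (q×r0 · r) ∇F)

    The result does not depend on the sphere radius, and is exactly zero for
    dipoles whose moment is radial (q parallel to r0).
    """
    r = np.asarray(sensor_pos, dtype=float) - np.asarray(centre, dtype=float)
    r0 = dipole.pos - np.asarray(centre, dtype=float)
    q = dipole.moment
    a_vec = r - r0
    a = np.linalg.norm(a_vec)
    if a < 1e-12:
        raise ValueError("sensor coincides with dipole position")
    rn = np.linalg.norm(r)
    if rn < 1e-12:
        raise ValueError("sensor at sphere centre")
    adotr = float(a_vec @ r)
    F = a * (rn * a + rn**2 - float(r0 @ r))
    gradF = (a**2 / rn + adotr / a + 2.0 * a + 2.0 * rn) * r - (a + 2.0 * rn + adotr / a) * r0
    qxr0 = np.cross(q, r0)
    B = MU0 / (4.0 * np.pi * F**2) * (F * qxr0 - float(qxr0 @ r) * gradF)
    return float(B @ np.asarray(sensor_ori, dtype=float))


def _fit_sphere(points: np.ndarray, weights: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Weighted algebraic least-squares sphere fit (centre, radius).

    Linearizes |p - c|² = R² into 2c·p + (R² - |c|²) = |p|², a weighted linear
    system in (c, R² - |c|²).
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    A = np.hstack([2.0 * points, np.ones((n, 1))])
    b = np.sum(points**2, axis=1)
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        A = A * w[:, None]
        b = b * w
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise ValueError("degenerate (coplanar or collinear) surface points")
    centre = sol[:3]
    r2 = sol[3] + centre @ centre
    if r2 <= 0:
        raise ValueError("sphere fit failed: non-positive squared radius")
    return centre, float(np.sqrt(r2))


def fit_local_spheres(
    surface_points: np.ndarray,
    sensors: SensorArray,
    weight_scale: float = 0.07,
) -> HeadModel:
    """Fit one sphere per channel to brain-surface points, proximity-weighted.

    Each channel's sphere is a least-squares fit of the surface points with
    Gaussian weights exp(-d²/(2·weight_scale²)) on the distance d from the
    point to that channel, so the local curvature under the sensor dominates.
    A uniform-weight global fit determines the stored radius.
    """
    surface_points = np.asarray(surface_points, dtype=float)
    if surface_points.ndim != 2 or surface_points.shape[1] != 3:
        raise ValueError("surface points must be (n, 3)")
    if len(surface_points) < 10:
        raise ValueError("need at least 10 surface points for a sphere fit")
    rank = np.linalg.matrix_rank(surface_points - surface_points.mean(0), tol=1e-10)
    if rank < 3:
        raise ValueError("degenerate (coplanar or collinear) surface points")
    global_centre, global_radius = _fit_sphere(surface_points)
    centres = np.empty((sensors.n_channels, 3))
    for i in range(sensors.n_channels):
        d2 = np.sum((surface_points - sensors.pos[i]) ** 2, axis=1)
        w = np.exp(-d2 / (2.0 * weight_scale**2))
        w = np.maximum(w, 1e-12)  # keep the system full-rank for far channels
        try:
            centres[i], _ = _fit_sphere(surface_points, w)
        except ValueError:
            centres[i] = global_centre
    model = HeadModel(centres=centres, radius=global_radius)
    model.global_centre = global_centre  # type: ignore[attr-defined]
    return model


def tangential_basis(position: np.ndarray, centre: np.ndarray) -> np.ndarray:
    """Two orthonormal tangential moment directions at a source position.

    Gram–Schmidt of the global x axis (falling back to y when the radial
    direction is within ~1e-6 of x) against the local radial direction,
    completed by the cross product.  Deterministic and smooth almost
    everywhere; returns a (3, 2) matrix of column unit vectors.
    """
    radial = np.asarray(position, dtype=float) - np.asarray(centre, dtype=float)
    rn = np.linalg.norm(radial)
    if rn < 1e-12:
        # at the centre every direction is radial (and silent); pick x/y
        return np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
    radial = radial / rn
    seed = np.array([1.0, 0.0, 0.0])
    if abs(radial @ seed) > 1.0 - 1e-6:
        seed = np.array([0.0, 1.0, 0.0])
    t1 = seed - (seed @ radial) * radial
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(radial, t1)
    return np.column_stack([t1, t2])


@dataclass
class Leadfield:
    """Per-voxel forward fields for two tangential unit moments.

    ``lf[v]`` is the (n_channels, 2) field of unit dipoles along the columns of
    ``basis[v]`` at ``positions[v]``.  ``voxel_indices`` ties rows back to the
    grid (C order over in-mask voxels); ``valid`` flags voxels inside their
    governing sphere.
    """

    grid: GridSpec
    positions: np.ndarray  # (n_vox, 3) m
    voxel_indices: np.ndarray  # (n_vox, 3) int
    lf: np.ndarray  # (n_vox, n_channels, 2) tesla per A·m
    basis: np.ndarray  # (n_vox, 3, 2)
    valid: np.ndarray  # (n_vox,) bool
    sensors: SensorArray | None = None

    @property
    def n_voxels(self) -> int:
        return len(self.positions)


def leadfield_grid(
    grid: GridSpec,
    sensors: SensorArray,
    headmodel: HeadModel,
    gradiometer_baseline: float | None = None,
) -> Leadfield:
    """Compute leadfields for every in-mask voxel of ``grid``.

    Point-magnetometer sensors by default; with ``gradiometer_baseline`` set,
    each channel is a two-point axial gradiometer (field at the coil minus the
    field at the coil displaced by the baseline along the channel orientation).
    Voxels outside their governing sphere are flagged invalid and get zero
    leadfields.
    """
    idx = grid.voxel_indices()
    pos = grid.positions(idx)
    n_vox = len(pos)
    n_ch = sensors.n_channels
    basis = np.zeros((n_vox, 3, 2))
    # basis from the channel-mean centre so a per-voxel orientation is unique
    mean_centre = headmodel.centres.mean(axis=0) if headmodel.per_channel else headmodel.centres
    for v in range(n_vox):
        basis[v] = tangential_basis(pos[v], mean_centre)
    # validity: every governing sphere must contain the voxel
    if headmodel.per_channel:
        d = np.linalg.norm(pos[:, None, :] - headmodel.centres[None, :, :], axis=2)
        valid = np.all(d < headmodel.radius, axis=1)
    else:
        valid = np.linalg.norm(pos - headmodel.centres, axis=1) < headmodel.radius
    lf = np.zeros((n_vox, n_ch, 2))
    if valid.any():
        for k in range(2):
            G = forward_matrix(pos[valid], basis[valid, :, k], sensors, headmodel)
            if gradiometer_baseline is not None:
                far = SensorArray(
                    pos=sensors.pos + gradiometer_baseline * sensors.ori,
                    ori=sensors.ori,
                    names=list(sensors.names),
                )
                G = G - forward_matrix(pos[valid], basis[valid, :, k], far, headmodel)
            lf[valid, :, k] = G.T
    return Leadfield(
        grid=grid,
        positions=pos,
        voxel_indices=idx,
        lf=lf,
        basis=basis,
        valid=valid,
        sensors=sensors,
    )


def forward_matrix(
    dipole_positions: np.ndarray,
    dipole_moments: np.ndarray,
    sensors: SensorArray,
    headmodel: HeadModel,
) -> np.ndarray:
    """(n_channels, n_dipoles) gain matrix for fixed-moment dipoles.

    Vectorized Sarvas evaluation used by the simulator; channels may carry
    per-channel sphere centres.
    """
    dipole_positions = np.atleast_2d(np.asarray(dipole_positions, dtype=float))
    dipole_moments = np.atleast_2d(np.asarray(dipole_moments, dtype=float))
    n_dip = len(dipole_positions)
    n_ch = sensors.n_channels
    G = np.empty((n_ch, n_dip))
    for c in range(n_ch):
        centre = headmodel.centre_for(c)
        r = sensors.pos[c] - centre  # (3,)
        rn = np.linalg.norm(r)
        r0 = dipole_positions - centre  # (n_dip, 3)
        q = dipole_moments
        a_vec = r[None, :] - r0
        a = np.linalg.norm(a_vec, axis=1)
        adotr = a_vec @ r
        F = a * (rn * a + rn**2 - r0 @ r)
        grad_r = (a**2 / rn + adotr / a + 2.0 * a + 2.0 * rn)
        grad_r0 = (a + 2.0 * rn + adotr / a)
        gradF = grad_r[:, None] * r[None, :] - grad_r0[:, None] * r0
        qxr0 = np.cross(q, r0)
        B = MU0 / (4.0 * np.pi * F[:, None] ** 2) * (F[:, None] * qxr0 - (qxr0 @ r)[:, None] * gradF)
        G[c] = B @ sensors.ori[c]
    return G
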