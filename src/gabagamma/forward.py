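"""Single-sphere MEG forward model (Sarvas formulation).

The magnetic field of a current dipole inside a homogeneous conducting sphere
has a closed form outside the conductor that is independent of the sphere
radius and of the conductivity; radial dipoles are magnetically silent.
"""

from __future__ import annotations

import numpy as np

from .containers import GeometryError, HeadModel, SourceGrid

MU0_OVER_4PI = 1e-7  # T m / (A m)


def sarvas_field(q: np.ndarray, r0: np.ndarray, sensors: np.ndarray,
                 center: np.ndarray = None) -> np.ndarray:
    """Magnetic field vectors (tesla) of dipole ``q`` (A m) at ``r0`` (m).

    Parameters are in the head frame; ``center`` shifts the sphere origin.
    Returns an ``(n_sensors, 3)`` array.
    """
    q = np.asarray(q, float)
    sensors = np.atleast_2d(np.asarray(sensors, float))
    r0 = np.asarray(r0, float)
    if center is not None:
        sensors = sensors - center
        r0 = r0 - center

    a_vec = sensors - r0                       # (n, 3)
    a = np.linalg.norm(a_vec, axis=1)
    r = np.linalg.norm(sensors, axis=1)
    if np.any(a == 0):
        raise GeometryError("sensor coincides with source")
    ar = np.einsum("ij,ij->i", a_vec, sensors)  # a . r
    r0r = sensors @ r0                          # r0 . r

    F = a * (r * a + r * r - r0r)
    gradF = (
        (a * a / r + ar / a + 2.0 * a + 2.0 * r)[:, None] * sensors
        - (a + 2.0 * r + ar / a)[:, None] * r0[None, :]
    )
    qxr0 = np.cross(q, r0)
    B = MU0_OVER_4PI / F[:, None] ** 2 * (
        F[:, None] * qxr0[None, :] - (sensors @ qxr0)[:, None] * gradF
    )
    return B


def _tangential_basis(u: np.ndarray) -> tuple:
    """Deterministic orthonormal pair perpendicular to radial direction u."""
    u = u / np.linalg.norm(u)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(u @ ref) > 0.99:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(ref, u)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def leadfield(head: HeadModel, grid: SourceGrid) -> np.ndarray:
    """Leadfield tensor, shape (grid points, sensors, 2 tangential orientations).

    Each column is the sensor reading (projection of B onto the sensor
    orientation) for a unit tangential dipole (1 A m); radial components are
    excluded by construction, matching the spherical model's null space.

    Raises :class:`GeometryError` for a source at the sphere centre (no
    tangential plane) or outside the sensor shell.
    """
    pts = grid.points - head.sphere_center
    radii = np.linalg.norm(pts, axis=1)
    sens_r = np.linalg.norm(head.sensor_positions - head.sphere_center, axis=1)
    if np.any(radii < 1e-6):
        raise GeometryError("source at sphere centre: tangential plane undefined")
    if np.any(radii >= sens_r.min()):
        raise GeometryError("source point outside the sensor shell")

    L = np.empty((grid.n_points, head.n_sensors, 2))
    for i, p in enumerate(grid.points):
        e1, e2 = _tangential_basis(p - head.sphere_center)
        for j, e in enumerate((e1, e2)):
            B = sarvas_field(e, p, head.sensor_positions, head.sphere_center)
            L[i, :, j] = np.einsum("ij,ij->i", B, head.sensor_orientations)
    return L


def project_dipole(moment_t: np.ndarray, orientation: np.ndarray,
                   position: np.ndarray, head: HeadModel) -> np.ndarray:
    """Sensor time courses (sensors, samples) for a fixed-orientation dipole."""
    ori = np.asarray(orientation, float)
    ori = ori / np.linalg.norm(ori)
    B = sarvas_field(ori, position, head.sensor_positions, head.sphere_center)
    gain = np.einsum("ij,ij->i", B, head.sensor_orientations)  # per 1 A m
    return gain[:, None] * np.asarray(moment_t, float)[None, :]
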