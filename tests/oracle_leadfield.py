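"""Independent numeric oracle for the spherical-conductor magnetic field.

Brute-force evaluation of the Biot-Savart law for a current dipole plus the
conductor's volume currents, with the volume-current term transformed to the
exact Geselowitz surface integral over the boundary potential:

    B(r) = mu0/4pi [ q x (r - r0) / |r - r0|^3
                     - sigma * surface_int V(r') n(r') x (r - r') / |r-r'|^3 dS' ]

The boundary potential of a dipole on the z-axis of a homogeneous sphere is
evaluated by its Legendre series (Neumann condition dV/dr = 0 at the
surface); sigma cancels between V and the surface term.  Everything here is
independent of the package's Sarvas implementation.
"""

import numpy as np
from scipy.special import eval_legendre, lpmv

MU0_OVER_4PI = 1e-7


def boundary_potential(R, z0, q, theta, phi, n_max=80):
    """sigma * V on the sphere surface for a dipole q at (0, 0, z0)."""
    ct = np.cos(theta)
    qx, qy, qz = q
    V = np.zeros_like(theta)
    for n in range(1, n_max + 1):
        # interior multipole c_n r^-(n+1) plus image A_n r^n from dV/dr=0
        # combine on the surface to c_n R^-(n+1) (2n+1)/n
        fac = (2 * n + 1) / n / (4 * np.pi)
        V += qz * n * z0 ** (n - 1) * R ** (-(n + 1)) * fac * eval_legendre(n, ct)
        V += ((qx * np.cos(phi) + qy * np.sin(phi)) * (-1.0)
              * z0 ** (n - 1) * R ** (-(n + 1)) * fac * lpmv(1, n, ct))
    return V


def dipole_field_numeric(q, z0, sensors, R=0.09, n_theta=200, n_phi=400,
                         n_max=80):
    """Full field (primary + volume currents) at ``sensors``, dipole on z-axis."""
    sensors = np.atleast_2d(np.asarray(sensors, float))
    r0 = np.array([0.0, 0.0, z0])
    a = sensors - r0
    B = MU0_OVER_4PI * np.cross(q, a) / np.linalg.norm(a, axis=1)[:, None] ** 3

    x, wgl = np.polynomial.legendre.leggauss(n_theta)
    theta = np.arccos(x)
    phi = np.arange(n_phi) * 2 * np.pi / n_phi
    TH, PH = np.meshgrid(theta, phi, indexing="ij")
    weights = (np.broadcast_to((wgl * R**2)[:, None], TH.shape)
               * (2 * np.pi / n_phi)).ravel()
    sv = boundary_potential(R, z0, q, TH.ravel(), PH.ravel(), n_max)
    st, ct = np.sin(TH.ravel()), np.cos(TH.ravel())
    normals = np.column_stack([st * np.cos(PH.ravel()),
                               st * np.sin(PH.ravel()), ct])
    surface = R * normals
    w = weights * sv
    for i, s in enumerate(sensors):
        d = s[None, :] - surface
        integrand = np.cross(normals, d) / np.linalg.norm(d, axis=1)[:, None] ** 3
        B[i] -= MU0_OVER_4PI * np.sum(w[:, None] * integrand, axis=0)
    return B
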