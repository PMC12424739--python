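"""Ellipsoidal egg-chamber geometry.

The egg chamber is modeled as a rigid ellipsoid of revolution whose long
(anterior-posterior, AP) axis lies along the body-frame ``z`` axis and whose
equatorial radius sets the unit of length.  A point ``r = (x, y, z)`` on the
surface therefore satisfies ``x**2 + y**2 + (z/e)**2 = 1`` where ``e >= 1`` is
the aspect ratio of the long to the equatorial semi-axis (``e = 1`` is a
sphere).

Each of the ``N`` follicle cells is represented by an anchor point ``r_i`` on
this surface together with a right-handed orthonormal tangent frame
``(t1, t2, n)``:

* ``n``  — outward unit normal,
* ``t1`` — unit tangent along the projection of the AP axis onto the tangent
  plane (meridional, pointing toward the anterior pole),
* ``t2 = t1 x n`` — azimuthal unit tangent.

With this convention a counterclockwise rotation about the AP axis
(``omega3 > 0``) moves every cell along ``+t2``.  Angles ``beta`` in the
tangent plane are measured from ``t1`` toward ``t2``, so the direction of
motion under counterclockwise rotation is ``beta = +pi/2`` and the trailing
direction is ``beta = -pi/2``.

Cells are placed on a deterministic Fibonacci lattice (generalized spiral) on
the unit sphere and then stretched onto the ellipsoid, which gives an
approximately equi-areal, reproducible covering for any ``N``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AP_AXIS",
    "TangentFrame",
    "EggChamberGeometry",
    "make_geometry",
    "drag_coefficient",
    "tangent_unit",
]

#: Body-frame direction of the AP (long) axis, called ``d3`` in the model.
AP_AXIS = np.array([0.0, 0.0, 1.0])

_POLE_TOL = 1e-12


@dataclass(frozen=True)
class TangentFrame:
    """Right-handed orthonormal frame ``(t1, t2, n)`` at one anchor point."""

    t1: np.ndarray
    t2: np.ndarray
    normal: np.ndarray


@dataclass(frozen=True)
class EggChamberGeometry:
    """Anchor points and tangent frames of the follicular epithelium.

    All arrays have shape ``(N, 3)`` and are expressed in body coordinates
    with the AP axis along ``z`` and lengths in units of the equatorial
    radius.
    """

    e: float
    N: int
    positions: np.ndarray
    normals: np.ndarray
    t1: np.ndarray
    t2: np.ndarray
    #: Azimuthal lever arm l_i = (z_hat x r_i) . t2_i of each cell about the
    #: AP axis; the torque of a tangent force b about the AP axis is
    #: sum_i l_i * (b_i . t2_i).
    lever: np.ndarray = field(repr=False, default=None)

    def frame(self, i: int) -> TangentFrame:
        """Return the tangent frame of cell ``i``."""
        return TangentFrame(self.t1[i], self.t2[i], self.normals[i])

    @property
    def frames(self) -> list[TangentFrame]:
        return [self.frame(i) for i in range(self.N)]

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "e": self.e,
            "N": self.N,
            "positions": self.positions.tolist(),
            "normals": self.normals.tolist(),
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text


def drag_coefficient(e: float, N: int) -> float:
    """Rotational drag Pi(e) of the chamber against the basement membrane.

    ``Pi(e) = N * pi * (40 + 26*(e - 1)) / 15`` in the non-dimensional units
    of the model (so ``Pi(1) = 8*N*pi/3``).  The coefficient is linear in the
    cell count ``N`` and increases with elongation ``e``.
    """
    if not np.isfinite(e) or e < 1:
        raise ValueError(f"aspect ratio e must be finite and >= 1, got {e!r}")
    if N < 1:
        raise ValueError(f"cell count N must be >= 1, got {N!r}")
    return N * np.pi * (40.0 + 26.0 * (e - 1.0)) / 15.0


def tangent_unit(frame: TangentFrame, beta: float) -> np.ndarray:
    """Unit tangent ``m(beta) = cos(beta) t1 + sin(beta) t2``."""
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    return np.cos(beta) * frame.t1 + np.sin(beta) * frame.t2


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform points on the unit sphere, shape (n, 3)."""
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    phi = 2.0 * np.pi * k / golden
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def make_geometry(
    e: float,
    N: int,
    seed: int = 0,
    jitter: float = 0.0,
) -> EggChamberGeometry:
    """Build the ellipsoidal surface with ``N`` cell anchor points.

    Parameters
    ----------
    e
        Aspect ratio of long to equatorial semi-axis, ``>= 1``.
    N
        Number of follicle cells, ``>= 4``.
    seed
        Seed for the optional tangential jitter of the lattice; unused when
        ``jitter == 0`` (the default), in which case the construction is
        fully deterministic.
    jitter
        Standard deviation (in radians of arc on the unit sphere) of an
        optional tangential perturbation of each lattice point.
    """
    if not np.isfinite(e) or e < 1:
        raise ValueError(f"aspect ratio e must be finite and >= 1, got {e!r}")
    if not isinstance(N, (int, np.integer)) or N < 4:
        raise ValueError(f"cell count N must be an integer >= 4, got {N!r}")
    if jitter < 0:
        raise ValueError("jitter must be >= 0")

    pts = _fibonacci_sphere(N)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        pts = pts + jitter * rng.standard_normal(pts.shape)
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)

    positions = pts * np.array([1.0, 1.0, e])

    # Outward normal of the implicit surface x^2 + y^2 + (z/e)^2 = 1.
    grad = positions / np.array([1.0, 1.0, e * e])
    normals = grad / np.linalg.norm(grad, axis=1, keepdims=True)

    # t1: AP axis projected onto the tangent plane, normalized.
    proj = AP_AXIS - normals[:, 2:3] * normals
    norms = np.linalg.norm(proj, axis=1)
    polar = norms < _POLE_TOL
    if np.any(polar):
        # At the poles the AP axis is normal to the surface; fall back to the
        # body x axis projected onto the tangent plane.
        fallback = np.array([1.0, 0.0, 0.0]) - normals[polar, 0:1] * normals[polar]
        proj[polar] = fallback
        norms[polar] = np.linalg.norm(fallback, axis=1)
    t1 = proj / norms[:, None]
    t2 = np.cross(t1, normals)

    lever = np.einsum("ij,ij->i", np.cross(AP_AXIS[None, :], positions), t2)

    return EggChamberGeometry(
        e=float(e), N=int(N), positions=positions, normals=normals,
        t1=t1, t2=t2, lever=lever,
    )
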