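"""Cubic B-spline basis utilities and deformation fields.

A deformation field maps points of the training plot (in pixel coordinates)
to points of the target plot.  The displacement is a tensor-product sum of
shifted cubic B-splines on a uniform control grid spanning the plot:

    T(x, y) = (x, y) + sum_ij c_ij * beta3(x/s - i) * beta3(y/s - j)

where ``s`` is the control spacing.  Internally the control grid is indexed
over the normalized plot domain [0, 1]: an axis with ``n`` control intervals
carries ``n + 3`` coefficients (one margin control point beyond each end,
indices -1 .. n+1), so the basis forms a partition of unity everywhere on
the domain and an all-zero coefficient array is exactly the identity map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["cubic_bspline", "cubic_bspline_d1", "basis_matrix", "DeformationField"]


def cubic_bspline(t: np.ndarray) -> np.ndarray:
    """Centred cubic B-spline beta3(t), supported on [-2, 2]."""
    t = np.abs(np.asarray(t, dtype=float))
    out = np.zeros_like(t)
    inner = t < 1.0
    outer = (t >= 1.0) & (t < 2.0)
    ti = t[inner]
    out[inner] = 2.0 / 3.0 - ti * ti + 0.5 * ti ** 3
    to = t[outer]
    out[outer] = (2.0 - to) ** 3 / 6.0
    return out


def cubic_bspline_d1(t: np.ndarray) -> np.ndarray:
    """First derivative of beta3."""
    t = np.asarray(t, dtype=float)
    a = np.abs(t)
    s = np.sign(t)
    out = np.zeros_like(a)
    inner = a < 1.0
    outer = (a >= 1.0) & (a < 2.0)
    ai = a[inner]
    out[inner] = s[inner] * (-2.0 * ai + 1.5 * ai * ai)
    ao = a[outer]
    out[outer] = s[outer] * (-0.5 * (2.0 - ao) ** 2)
    return out


def basis_matrix(u: np.ndarray, n_intervals: int, deriv: int = 0) -> np.ndarray:
    """Dense B-spline collocation matrix.

    Parameters
    ----------
    u : array of normalized coordinates (0..1 covers the plot; values
        outside are extrapolated through the basis support).
    n_intervals : number of control intervals across [0, 1].
    deriv : 0 for values, 1 for d/du (includes the chain factor
        ``n_intervals`` from u to spline argument).

    Returns
    -------
    (len(u), n_intervals + 3) matrix; column ``k`` corresponds to control
    index ``k - 1``.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    t = u * n_intervals
    idx = np.arange(-1, n_intervals + 2)
    arg = t[:, None] - idx[None, :]
    if deriv == 0:
        return cubic_bspline(arg)
    if deriv == 1:
        return cubic_bspline_d1(arg) * n_intervals
    raise ValueError("deriv must be 0 or 1")


@dataclass
class DeformationField:
    """Tensor-product cubic B-spline displacement over a plot.

    Coefficients are displacements in *pixel units* of ``image_size``.
    2-D fields carry ``coeff_x`` and ``coeff_y`` of shape
    ``(ny + 3, nx + 3)``; 1-D fields carry only ``coeff_x`` of shape
    ``(nx + 3,)`` and ``image_size == (W,)``.
    """

    direction: str  # "training->target" or "target->training"
    n_intervals: tuple[int, ...]  # (nx,) or (nx, ny)
    image_size: tuple[int, ...]  # (W,) or (W, H)
    coeff_x: np.ndarray = field(repr=False, default=None)
    coeff_y: np.ndarray | None = field(repr=False, default=None)
    degree: int = 3

    def __post_init__(self) -> None:
        nx = self.n_intervals[0]
        if self.coeff_x is None:
            if self.ndim == 2:
                ny = self.n_intervals[1]
                self.coeff_x = np.zeros((ny + 3, nx + 3))
                self.coeff_y = np.zeros((ny + 3, nx + 3))
            else:
                self.coeff_x = np.zeros(nx + 3)
        self.coeff_x = np.asarray(self.coeff_x, dtype=float)
        if self.coeff_y is not None:
            self.coeff_y = np.asarray(self.coeff_y, dtype=float)

    @property
    def ndim(self) -> int:
        return len(self.image_size)

    @property
    def control_spacing(self) -> tuple[float, ...]:
        return tuple(s / n for s, n in zip(self.image_size, self.n_intervals))

    # -- evaluation ------------------------------------------------------

    def displacement(self, points_px: np.ndarray) -> np.ndarray:
        """Displacement (pixels) at pixel-coordinate points.

        ``points_px`` is (N, 2) for 2-D fields or (N,) for 1-D fields.
        Pixel centre ``p`` corresponds to normalized plot value
        ``(p + 0.5) / size``.
        """
        if self.ndim == 1:
            p = np.atleast_1d(np.asarray(points_px, dtype=float))
            u = (p + 0.5) / self.image_size[0]
            B = basis_matrix(u, self.n_intervals[0])
            return B @ self.coeff_x
        pts = np.atleast_2d(np.asarray(points_px, dtype=float))
        W, H = self.image_size
        ux = (pts[:, 0] + 0.5) / W
        uy = (pts[:, 1] + 0.5) / H
        Bx = basis_matrix(ux, self.n_intervals[0])
        By = basis_matrix(uy, self.n_intervals[1])
        dx = np.einsum("nk,kl,nl->n", By, self.coeff_x, Bx)
        dy = np.einsum("nk,kl,nl->n", By, self.coeff_y, Bx)
        return np.stack([dx, dy], axis=1)

    def evaluate(self, points_px: np.ndarray) -> np.ndarray:
        """Map pixel points through the field: T(p) = p + displacement."""
        if self.ndim == 1:
            p = np.atleast_1d(np.asarray(points_px, dtype=float))
            return p + self.displacement(p)
        pts = np.atleast_2d(np.asarray(points_px, dtype=float))
        return pts + self.displacement(pts)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "direction": self.direction,
            "n_intervals": list(self.n_intervals),
            "image_size": list(self.image_size),
            "degree": self.degree,
            "coeff_x": self.coeff_x.tolist(),
        }
        if self.coeff_y is not None:
            d["coeff_y"] = self.coeff_y.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DeformationField":
        return cls(
            direction=d["direction"],
            n_intervals=tuple(d["n_intervals"]),
            image_size=tuple(d["image_size"]),
            coeff_x=np.asarray(d["coeff_x"], dtype=float),
            coeff_y=(np.asarray(d["coeff_y"], dtype=float) if "coeff_y" in d else None),
            degree=d.get("degree", 3),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "DeformationField":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def checksum(self) -> str:
        import hashlib

        h = hashlib.sha1()
        h.update(self.coeff_x.tobytes())
        if self.coeff_y is not None:
            h.update(self.coeff_y.tobytes())
        return h.hexdigest()[:12]
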