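"""Consistent elastic B-spline registration of density images.

The training (source) image is aligned to the target image with a
free-form deformation parameterised by cubic B-spline coefficients on a
uniform control grid.  Two fields are estimated jointly:

* the *backward* field (target -> training), used to resample the source
  image when measuring similarity, and
* the *forward* field (training -> target), the one later applied to gate
  vertices.

The energy combines a symmetric sum-of-squared-differences similarity, a
divergence + curl quadratic penalty on the displacement, and an inverse
consistency penalty tying the two fields together:

    E = w_sim * [ SSD(S o T_bwd, T) + SSD(T o T_fwd, S) ]
      + w_reg * int (div u)^2 + (curl u)^2            (both fields)
      + w_cons * mean || T_fwd(T_bwd(p)) - p ||^2     (and the reverse)

Optimization is deterministic L-BFGS from a zero (identity) start,
coarse-to-fine: the control grid is refined level by level in lock-step
with a Gaussian image pyramid, carrying the coarse solution forward by a
separable least-squares refit of the spline coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import InterpolatedUnivariateSpline, RectBivariateSpline
from scipy.ndimage import gaussian_filter, gaussian_filter1d, zoom
from scipy.optimize import minimize

from .bspline import DeformationField, basis_matrix
from .errors import InputError
from .imaging import DensityImage

logger = logging.getLogger(__name__)

__all__ = ["RegistrationConfig", "RegistrationResult", "register", "register_1d"]


@dataclass
class RegistrationConfig:
    """Controls the multiresolution schedule and the energy weights."""

    min_intervals: int = 4
    max_intervals: int = 16
    similarity_weight: float = 1.0
    regularization_weight: float = 0.1
    consistency_weight: float = 1.0
    max_iters_per_level: int = 200
    rel_tol: float = 1e-4
    consistency_points: int = 17  # per axis

    def __post_init__(self):
        if self.min_intervals < 1 or self.max_intervals < self.min_intervals:
            raise ValueError("need 1 <= min_intervals <= max_intervals")
        if min(self.similarity_weight, self.regularization_weight, self.consistency_weight) < 0:
            raise ValueError("energy weights must be non-negative")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be > 0")

    @property
    def levels(self) -> int:
        return int(np.round(np.log2(self.max_intervals / self.min_intervals))) + 1

    def intervals_at(self, level: int) -> int:
        return min(self.min_intervals * 2 ** level, self.max_intervals)


@dataclass
class RegistrationResult:
    field: DeformationField  # training -> target
    inverse_field: DeformationField  # target -> training
    final_ssd: float
    initial_ssd: float
    energy_trace: list = field(default_factory=list)  # one list per level
    converged: bool = True


# ---------------------------------------------------------------------------
# shared helpers


def _pyramid_sizes(full: int, levels: int) -> list[int]:
    """Image size per level, coarse to fine; never below 16 px."""
    sizes = []
    for li in range(levels):
        factor = 2 ** (levels - 1 - li)
        sizes.append(max(16, int(np.ceil(full / factor))))
    sizes[-1] = full
    return sizes


def _downsample2(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if img.shape == shape:
        return img
    factor = img.shape[0] / shape[0]
    sm = gaussian_filter(img, sigma=factor / 2.0, mode="nearest")
    return zoom(sm, (shape[0] / img.shape[0], shape[1] / img.shape[1]), order=1)


def _downsample1(vec: np.ndarray, n: int) -> np.ndarray:
    if len(vec) == n:
        return vec
    factor = len(vec) / n
    sm = gaussian_filter1d(vec, sigma=factor / 2.0, mode="nearest")
    return zoom(sm, n / len(vec), order=1)


def _refit_coeffs_2d(C: np.ndarray, n_old: int, n_new: int) -> np.ndarray:
    """Least-squares refit of a tensor-product field onto a finer control grid."""
    m = 8 * n_new + 1
    u = np.linspace(0.0, 1.0, m)
    Bo = basis_matrix(u, n_old)
    Bn = basis_matrix(u, n_new)
    U = Bo @ C @ Bo.T
    P = np.linalg.pinv(Bn)
    return P @ U @ P.T


def _refit_coeffs_1d(c: np.ndarray, n_old: int, n_new: int) -> np.ndarray:
    m = 8 * n_new + 1
    u = np.linspace(0.0, 1.0, m)
    U = basis_matrix(u, n_old) @ c
    return np.linalg.pinv(basis_matrix(u, n_new)) @ U


# ---------------------------------------------------------------------------
# 2-D energy


class _Level2D:
    """Precomputed quantities for one pyramid level (square or rectangular)."""

    def __init__(self, src: np.ndarray, tgt: np.ndarray, n: int, cfg: RegistrationConfig):
        self.cfg = cfg
        self.n = n
        H, W = src.shape
        self.W, self.H = W, H
        self.src, self.tgt = src, tgt
        rows, cols = np.arange(H, dtype=float), np.arange(W, dtype=float)
        self.spl_src = RectBivariateSpline(rows, cols, src, kx=3, ky=3, s=0)
        self.spl_tgt = RectBivariateSpline(rows, cols, tgt, kx=3, ky=3, s=0)
        self.xn = (np.arange(W) + 0.5) / W
        self.yn = (np.arange(H) + 0.5) / H
        self.Bx = basis_matrix(self.xn, n)
        self.By = basis_matrix(self.yn, n)
        self.Bx1 = basis_matrix(self.xn, n, deriv=1)
        self.By1 = basis_matrix(self.yn, n, deriv=1)
        q = cfg.consistency_points
        pc = (np.arange(q) + 0.5) / q
        PX, PY = np.meshgrid(pc, pc)
        self.Px, self.Py = PX.ravel(), PY.ravel()
        self.BxP = basis_matrix(self.Px, n)
        self.ByP = basis_matrix(self.Py, n)
        self.K = n + 3

    def unpack(self, p: np.ndarray):
        K = self.K
        return [c.reshape(K, K) for c in np.split(p, 4)]

    def _sim_term(self, Cx, Cy, spl, fixed):
        """SSD of the moving image resampled through (identity + u) vs fixed."""
        W, H = self.W, self.H
        Ux = self.By @ Cx @ self.Bx.T
        Uy = self.By @ Cy @ self.Bx.T
        col = (self.xn[None, :] + Ux) * W - 0.5
        row = (self.yn[:, None] + Uy) * H - 0.5
        colc = np.clip(col, 0.0, W - 1.0)
        rowc = np.clip(row, 0.0, H - 1.0)
        warped = spl.ev(rowc, colc)
        r = warped - fixed
        E = float(np.sum(r * r))
        mc = ((col > 0.0) & (col < W - 1.0)).astype(float)
        mr = ((row > 0.0) & (row < H - 1.0)).astype(float)
        Gc = spl.ev(rowc, colc, dy=1) * mc
        Gr = spl.ev(rowc, colc, dx=1) * mr
        dCx = 2.0 * self.By.T @ (r * Gc * W) @ self.Bx
        dCy = 2.0 * self.By.T @ (r * Gr * H) @ self.Bx
        return E, dCx, dCy

    def _reg_term(self, Cx, Cy):
        """Divergence + curl quadratic penalty (dimensionless derivatives)."""
        W, H = self.W, self.H
        rxy = W / H  # d(x px)/d(y px) unit conversion for cross-derivatives
        dUxdx = self.By @ Cx @ self.Bx1.T
        dUxdy = (self.By1 @ Cx @ self.Bx.T) * rxy
        dUydx = (self.By @ Cy @ self.Bx1.T) / rxy
        dUydy = self.By1 @ Cy @ self.Bx.T
        div = dUxdx + dUydy
        curl = dUydx - dUxdy
        E = float(np.sum(div * div + curl * curl))
        dCx = 2.0 * (self.By.T @ div @ self.Bx1 - rxy * self.By1.T @ curl @ self.Bx)
        dCy = 2.0 * (self.By1.T @ div @ self.Bx + (1.0 / rxy) * self.By.T @ curl @ self.Bx1)
        return E, dCx, dCy

    def _cons_term(self, Ca_x, Ca_y, Cb_x, Cb_y):
        """|| T_b(T_a(p)) - p ||^2 in pixel units, summed over probe points.

        Returns (E, dCa_x, dCa_y, dCb_x, dCb_y).
        """
        n, W, H = self.n, self.W, self.H
        ua_x = np.einsum("mk,kl,ml->m", self.ByP, Ca_x, self.BxP)
        ua_y = np.einsum("mk,kl,ml->m", self.ByP, Ca_y, self.BxP)
        qx = self.Px + ua_x
        qy = self.Py + ua_y
        Bxq = basis_matrix(qx, n)
        Byq = basis_matrix(qy, n)
        Bxq1 = basis_matrix(qx, n, deriv=1)
        Byq1 = basis_matrix(qy, n, deriv=1)
        ub_x = np.einsum("mk,kl,ml->m", Byq, Cb_x, Bxq)
        ub_y = np.einsum("mk,kl,ml->m", Byq, Cb_y, Bxq)
        ex = (qx + ub_x - self.Px) * W
        ey = (qy + ub_y - self.Py) * H
        E = float(np.sum(ex * ex + ey * ey))
        # outer field (applied second)
        dCb_x = 2.0 * W * (Byq * ex[:, None]).T @ Bxq
        dCb_y = 2.0 * H * (Byq * ey[:, None]).T @ Bxq
        # inner field, through the Jacobian of the outer displacement
        dubx_dqx = np.einsum("mk,kl,ml->m", Byq, Cb_x, Bxq1)
        dubx_dqy = np.einsum("mk,kl,ml->m", Byq1, Cb_x, Bxq)
        duby_dqx = np.einsum("mk,kl,ml->m", Byq, Cb_y, Bxq1)
        duby_dqy = np.einsum("mk,kl,ml->m", Byq1, Cb_y, Bxq)
        wx = ex * W * (1.0 + dubx_dqx) + ey * H * duby_dqx
        wy = ex * W * dubx_dqy + ey * H * (1.0 + duby_dqy)
        dCa_x = 2.0 * (self.ByP * wx[:, None]).T @ self.BxP
        dCa_y = 2.0 * (self.ByP * wy[:, None]).T @ self.BxP
        return E, dCa_x, dCa_y, dCb_x, dCb_y

    def energy(self, p: np.ndarray):
        cfg = self.cfg
        Cfx, Cfy, Cbx, Cby = self.unpack(p)
        E = 0.0
        g = [np.zeros_like(Cfx) for _ in range(4)]
        ws, wr, wc = cfg.similarity_weight, cfg.regularization_weight, cfg.consistency_weight
        if ws > 0:
            e, dx, dy = self._sim_term(Cbx, Cby, self.spl_src, self.tgt)
            E += ws * e
            g[2] += ws * dx
            g[3] += ws * dy
            e, dx, dy = self._sim_term(Cfx, Cfy, self.spl_tgt, self.src)
            E += ws * e
            g[0] += ws * dx
            g[1] += ws * dy
        if wr > 0:
            for i, (Cx, Cy) in enumerate(((Cfx, Cfy), (Cbx, Cby))):
                e, dx, dy = self._reg_term(Cx, Cy)
                E += wr * e
                g[2 * i] += wr * dx
                g[2 * i + 1] += wr * dy
        if wc > 0:
            e, da_x, da_y, db_x, db_y = self._cons_term(Cbx, Cby, Cfx, Cfy)
            E += wc * e
            g[0] += wc * db_x
            g[1] += wc * db_y
            g[2] += wc * da_x
            g[3] += wc * da_y
            e, da_x, da_y, db_x, db_y = self._cons_term(Cfx, Cfy, Cbx, Cby)
            E += wc * e
            g[0] += wc * da_x
            g[1] += wc * da_y
            g[2] += wc * db_x
            g[3] += wc * db_y
        return E, np.concatenate([a.ravel() for a in g])


def _optimize_level(level, p0: np.ndarray, cfg: RegistrationConfig):
    """Scale-normalized deterministic L-BFGS at one level; returns (p, trace, ok)."""
    e0, _ = level.energy(p0)
    if e0 <= 1e-300:
        return p0, [e0], True
    scale = 1.0 / e0

    def fun(p):
        e, g = level.energy(p)
        fun.last = e * scale
        return e * scale, g * scale

    fun.last = 1.0
    trace = [e0]

    def cb(xk):
        trace.append(fun.last / scale)

    res = minimize(
        fun,
        p0,
        jac=True,
        method="L-BFGS-B",
        callback=cb,
        options={"maxiter": cfg.max_iters_per_level, "ftol": cfg.rel_tol, "gtol": 1e-10},
    )
    # keep the trace non-increasing view of accepted iterates
    return res.x, trace, bool(res.success or res.status == 1)


def _check_2d_inputs(source: DensityImage, target: DensityImage):
    if source.gray.shape != target.gray.shape:
        raise InputError(
            f"source {source.gray.shape} and target {target.gray.shape} "
            "images must have identical dimensions"
        )


def register(
    source: DensityImage, target: DensityImage, cfg: RegistrationConfig | None = None
) -> RegistrationResult:
    """Elastically register a training density image onto a target image."""
    cfg = cfg or RegistrationConfig()
    _check_2d_inputs(source, target)
    S = source.as_float()
    T = target.as_float()
    H, W = S.shape

    sizes_h = _pyramid_sizes(H, cfg.levels)
    sizes_w = _pyramid_sizes(W, cfg.levels)

    traces = []
    ok = True
    p = None
    n_prev = None
    for li in range(cfg.levels):
        n = cfg.intervals_at(li)
        shape = (sizes_h[li], sizes_w[li])
        level = _Level2D(_downsample2(S, shape), _downsample2(T, shape), n, cfg)
        K = n + 3
        if p is None:
            p = np.zeros(4 * K * K)
        elif n != n_prev:
            coeffs = [c.reshape(n_prev + 3, n_prev + 3) for c in np.split(p, 4)]
            p = np.concatenate(
                [_refit_coeffs_2d(c, n_prev, n).ravel() for c in coeffs]
            )
        p, trace, lvl_ok = _optimize_level(level, p, cfg)
        traces.append(trace)
        ok = ok and lvl_ok
        n_prev = n
        logger.debug("level %d (n=%d, %sx%s): energy %.4g -> %.4g",
                     li, n, *shape, trace[0], trace[-1])

    n = n_prev
    K = n + 3
    Cfx, Cfy, Cbx, Cby = [c.reshape(K, K) for c in np.split(p, 4)]
    fwd = DeformationField(
        direction="training->target",
        n_intervals=(n, n),
        image_size=(W, H),
        coeff_x=Cfx * W,
        coeff_y=Cfy * H,
    )
    bwd = DeformationField(
        direction="target->training",
        n_intervals=(n, n),
        image_size=(W, H),
        coeff_x=Cbx * W,
        coeff_y=Cby * H,
    )
    final_ssd = resampled_ssd(S, T, bwd)
    initial_ssd = float(np.sum((S - T) ** 2))
    return RegistrationResult(
        field=fwd,
        inverse_field=bwd,
        final_ssd=final_ssd,
        initial_ssd=initial_ssd,
        energy_trace=traces,
        converged=ok,
    )


def resampled_ssd(S: np.ndarray, T: np.ndarray, bwd: DeformationField) -> float:
    """SSD between the source warped through the backward field and the target."""
    H, W = S.shape
    spl = RectBivariateSpline(np.arange(H, dtype=float), np.arange(W, dtype=float), S,
                              kx=3, ky=3, s=0)
    jj, ii = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
    pts = np.stack([jj.ravel(), ii.ravel()], axis=1)
    mapped = bwd.evaluate(pts)
    col = np.clip(mapped[:, 0], 0.0, W - 1.0)
    row = np.clip(mapped[:, 1], 0.0, H - 1.0)
    warped = spl.ev(row, col).reshape(H, W)
    return float(np.sum((warped - T) ** 2))


# ---------------------------------------------------------------------------
# 1-D registration (histograms)


class _Level1D:
    def __init__(self, src: np.ndarray, tgt: np.ndarray, n: int, cfg: RegistrationConfig):
        self.cfg = cfg
        self.n = n
        self.W = len(src)
        self.src, self.tgt = src, tgt
        x = np.arange(self.W, dtype=float)
        self.spl_src = InterpolatedUnivariateSpline(x, src, k=3)
        self.spl_tgt = InterpolatedUnivariateSpline(x, tgt, k=3)
        self.xn = (np.arange(self.W) + 0.5) / self.W
        self.B = basis_matrix(self.xn, n)
        self.B1 = basis_matrix(self.xn, n, deriv=1)
        q = cfg.consistency_points
        self.P = (np.arange(q) + 0.5) / q
        self.BP = basis_matrix(self.P, n)
        self.K = n + 3

    def _sim_term(self, c, spl, fixed):
        W = self.W
        u = self.B @ c
        pos = (self.xn + u) * W - 0.5
        posc = np.clip(pos, 0.0, W - 1.0)
        r = spl(posc) - fixed
        E = float(np.sum(r * r))
        m = ((pos > 0.0) & (pos < W - 1.0)).astype(float)
        G = spl(posc, nu=1) * m
        return E, 2.0 * self.B.T @ (r * G * W)

    def _reg_term(self, c):
        d = self.B1 @ c
        return float(np.sum(d * d)), 2.0 * self.B1.T @ d

    def _cons_term(self, ca, cb):
        n, W = self.n, self.W
        q = self.P + self.BP @ ca
        Bq = basis_matrix(q, n)
        Bq1 = basis_matrix(q, n, deriv=1)
        e = (q + Bq @ cb - self.P) * W
        E = float(np.sum(e * e))
        dcb = 2.0 * W * Bq.T @ e
        dca = 2.0 * self.BP.T @ (e * W * (1.0 + Bq1 @ cb))
        return E, dca, dcb

    def energy(self, p):
        cfg = self.cfg
        cf, cb = np.split(p, 2)
        E = 0.0
        gf = np.zeros_like(cf)
        gb = np.zeros_like(cb)
        ws, wr, wc = cfg.similarity_weight, cfg.regularization_weight, cfg.consistency_weight
        if ws > 0:
            e, g = self._sim_term(cb, self.spl_src, self.tgt)
            E += ws * e
            gb += ws * g
            e, g = self._sim_term(cf, self.spl_tgt, self.src)
            E += ws * e
            gf += ws * g
        if wr > 0:
            e, g = self._reg_term(cf)
            E += wr * e
            gf += wr * g
            e, g = self._reg_term(cb)
            E += wr * e
            gb += wr * g
        if wc > 0:
            e, da, db = self._cons_term(cb, cf)
            E += wc * e
            gb += wc * da
            gf += wc * db
            e, da, db = self._cons_term(cf, cb)
            E += wc * e
            gf += wc * da
            gb += wc * db
        return E, np.concatenate([gf, gb])


def register_1d(
    source: DensityImage, target: DensityImage, cfg: RegistrationConfig | None = None
) -> RegistrationResult:
    """Elastic 1-D registration of histogram count images."""
    cfg = cfg or RegistrationConfig()
    if source.gray.shape != target.gray.shape:
        raise InputError("source and target histograms must have equal length")
    S = source.as_float()
    T = target.as_float()
    W = len(S)
    sizes = _pyramid_sizes(W, cfg.levels)

    traces = []
    ok = True
    p = None
    n_prev = None
    for li in range(cfg.levels):
        n = cfg.intervals_at(li)
        level = _Level1D(_downsample1(S, sizes[li]), _downsample1(T, sizes[li]), n, cfg)
        if p is None:
            p = np.zeros(2 * (n + 3))
        elif n != n_prev:
            cf, cb = np.split(p, 2)
            p = np.concatenate(
                [_refit_coeffs_1d(cf, n_prev, n), _refit_coeffs_1d(cb, n_prev, n)]
            )
        p, trace, lvl_ok = _optimize_level(level, p, cfg)
        traces.append(trace)
        ok = ok and lvl_ok
        n_prev = n

    n = n_prev
    cf, cb = np.split(p, 2)
    fwd = DeformationField("training->target", (n,), (W,), coeff_x=cf * W)
    bwd = DeformationField("target->training", (n,), (W,), coeff_x=cb * W)

    spl = InterpolatedUnivariateSpline(np.arange(W, dtype=float), S, k=3)
    mapped = np.clip(bwd.evaluate(np.arange(W, dtype=float)), 0.0, W - 1.0)
    final_ssd = float(np.sum((spl(mapped) - T) ** 2))
    initial_ssd = float(np.sum((S - T) ** 2))
    return RegistrationResult(fwd, bwd, final_ssd, initial_ssd, traces, ok)
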