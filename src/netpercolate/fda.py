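"""Quality control and smoothing of percolation-point-by-density functions.

Functions live on an ascending density grid.  Because the attack sweep
runs from full density down to the sparsest graphs, the sweep's terminal
value - where percolation estimates become unstable on very few edges -
is the lowest-density grid point (column 0 here).  Preprocessing follows
four steps: drop subjects with a terminal spike (z > 2 on that value);
trim the grid to the informative low-density range where the group-mean
function still varies (its rise has not yet flattened); represent each
function in an order-4 B-spline basis with knots at the grid points
(n_densities + order - 2 basis functions) penalized on the second
derivative, with the weight chosen by generalized cross validation; and
drop subjects whose smoothed fit has an outlying sum of squared
residuals.  Modeling downstream uses the *unsmoothed* trimmed functions;
smoothing here serves outlier detection only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .types import ConfigurationError, FunctionalSample, SmoothedFunction

__all__ = [
    "drop_terminal_spike_outliers",
    "trim_domain",
    "smooth_gcv",
    "drop_ssr_outliers",
    "default_lambda_grid",
    "spline_basis",
    "derivative_dispersion",
    "FunctionalQC",
]


def default_lambda_grid() -> np.ndarray:
    """Exponential grid e^k for integer k in [-5, 12]."""
    return np.exp(np.arange(-5, 13, dtype=float))


def _zscores(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1) if len(x) > 1 else 0.0
    if sd == 0 or not np.isfinite(sd):
        return np.zeros_like(x)  # zero variance: z treated as 0
    return (x - x.mean()) / sd


def drop_terminal_spike_outliers(
    fs: FunctionalSample, z_thresh: float = 2.0
) -> tuple[FunctionalSample, np.ndarray]:
    """Drop subjects whose lowest-density value spikes (z > ``z_thresh``).

    The z-scores are computed once across subjects (no iteration).
    Returns the reduced sample and the retained-subject mask.
    """
    if fs.n_subjects < 3:
        raise ConfigurationError("need at least 3 subjects")
    z = _zscores(fs.values[:, 0])
    keep = z <= z_thresh
    if not keep.any():
        raise ConfigurationError("terminal-spike rule dropped every subject")
    return fs.select(keep), keep


def trim_domain(fs: FunctionalSample, tol: float = 1e-6) -> FunctionalSample:
    """Trim the grid to the low-density range where the mean function varies.

    The group-mean function rises steeply at low densities and then
    flattens; d* is the first grid point (beyond the first) at which its
    finite-difference derivative drops to ``tol`` or below, and the domain
    [d_1, d*] is retained for every subject.  A function that never
    flattens keeps the full domain (with a warning); a near-total trim
    (flat from the start) also warns.
    """
    if fs.n_densities < 2:
        raise ConfigurationError("need at least 2 grid points")
    mean_fn = fs.values.mean(axis=0)
    deriv = np.gradient(mean_fn, fs.densities)
    flat = np.flatnonzero(deriv[1:] <= tol)
    if len(flat) == 0:
        warnings.warn(
            "mean function never flattens; keeping the full density domain",
            stacklevel=2,
        )
        return fs
    m_star = int(flat[0]) + 1
    if m_star <= 1:
        warnings.warn(
            "mean function is flat from the start; near-total domain trim",
            stacklevel=2,
        )
    keep = slice(0, m_star + 1)
    return FunctionalSample(
        densities=fs.densities[keep],
        values=fs.values[:, keep],
        subject_ids=list(fs.subject_ids),
    )


def derivative_dispersion(fs: FunctionalSample) -> np.ndarray:
    """Across-subject SD of the per-subject derivative, for transparency."""
    derivs = np.gradient(fs.values, fs.densities, axis=1)
    return derivs.std(axis=0, ddof=1)


def spline_basis(grid: np.ndarray, order: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Order-``order`` B-spline basis with knots at the grid points.

    Interior knots sit at the interior grid points, so an M-point grid
    yields exactly M + order - 2 basis functions.  Returns (knots, design)
    with design of shape (M, M + order - 2).
    """
    grid = np.asarray(grid, dtype=float)
    m = len(grid)
    k = order - 1  # polynomial degree
    knots = np.concatenate([[grid[0]] * order, grid[1:-1], [grid[-1]] * order])
    design = BSpline.design_matrix(grid, knots, k).toarray()
    assert design.shape == (m, m + order - 2)
    return knots, design


def _roughness_matrix(knots: np.ndarray, n_basis: int, k: int = 3) -> np.ndarray:
    """Gram matrix of second derivatives, R_ij = int B_i'' B_j'' dd.

    Exact: on each knot interval the integrand is a polynomial of degree
    2(k-2) = 2 for cubics, integrated with 2-point Gauss-Legendre.
    """
    spl = BSpline(knots, np.eye(n_basis), k)
    d2 = spl.derivative(2)
    breaks = np.unique(knots)
    gauss_x = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    pts, wts = [], []
    for a, b in zip(breaks[:-1], breaks[1:]):
        half = (b - a) / 2.0
        pts.extend((a + b) / 2.0 + half * gauss_x)
        wts.extend([half, half])
    vals = d2(np.array(pts))  # (n_points, n_basis)
    return (vals * np.asarray(wts)[:, None]).T @ vals


def smooth_gcv(
    y: np.ndarray,
    densities: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    order: int = 4,
    domain_scale: float = 100.0,
) -> SmoothedFunction:
    """Penalized least-squares spline fit with GCV-selected roughness weight.

    Minimizes ``||y - B c||^2 + lambda * c' R c`` with R the
    second-derivative roughness matrix; lambda is chosen from the grid
    (default e^-5..e^12) minimizing ``GCV = M * SSR / (M - edf)^2``.

    The roughness matrix is evaluated with density expressed in percent
    (``domain_scale = 100``): the e^-5..e^12 weight range spans near-
    interpolation to heavy smoothing on that scale, whereas on the
    fractional scale the second-derivative Gram matrix grows like the
    inverse cube of the knot spacing and even the smallest weight would
    oversmooth.  B-spline bases are affine-invariant in the domain, so
    only the penalty is affected; knots and coefficients stay in the
    units of ``densities``.
    """
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if len(lambda_grid) == 0:
        raise ConfigurationError("lambda_grid must be nonempty")
    if np.any(lambda_grid <= 0):
        raise ConfigurationError("lambda must be > 0")
    y = np.asarray(y, dtype=float)
    densities = np.asarray(densities, dtype=float)
    m = len(densities)
    knots, design = spline_basis(densities, order=order)
    n_basis = design.shape[1]
    rough = _roughness_matrix(knots, n_basis, k=order - 1) / domain_scale**3
    btb = design.T @ design
    bty = design.T @ y

    best = None
    for lam in lambda_grid:
        a = btb + lam * rough
        coef = np.linalg.solve(a, bty)
        fitted = design @ coef
        ssr = float(np.sum((y - fitted) ** 2))
        edf = float(np.trace(np.linalg.solve(a, btb)))
        denom = (m - edf) ** 2
        gcv = m * ssr / denom if denom > 0 else (np.inf if ssr > 0 else 0.0)
        if not np.isfinite(gcv):
            gcv = np.inf if ssr > 0 else 0.0
        if best is None or gcv < best[0]:
            best = (gcv, lam, coef, ssr)
    gcv, lam, coef, ssr = best
    return SmoothedFunction(
        knots=knots, coefficients=coef, order=order, lam=float(lam),
        gcv=float(gcv), ssr=ssr,
    )


def drop_ssr_outliers(
    fits: list[SmoothedFunction], z_thresh: float = 2.0
) -> np.ndarray:
    """Retained mask over subjects whose smoothed-fit SSR is not outlying."""
    if len(fits) < 3:
        raise ConfigurationError("need at least 3 fits")
    ssr = np.array([f.ssr for f in fits])
    if np.isinf(z_thresh):
        return np.ones(len(fits), dtype=bool)
    return _zscores(ssr) <= z_thresh


@dataclass
class QCReport:
    spike_mask: np.ndarray
    ssr_mask: np.ndarray
    lambdas: np.ndarray
    gcvs: np.ndarray
    ssrs: np.ndarray
    trimmed_domain: tuple[float, float]
    n_dropped_spike: int
    n_dropped_ssr: int


class FunctionalQC:
    """Transformer applying the full QC chain to a functional sample.

    ``fit_transform`` returns the cleaned, trimmed, *unsmoothed* sample
    (smoothing is used only for SSR-based outlier detection); the per-stage
    masks and per-subject lambda/GCV/SSR land in ``report_``.
    """

    def __init__(
        self,
        spike_z: float = 2.0,
        ssr_z: float = 2.0,
        trim_tol: float = 1e-6,
        lambda_grid: np.ndarray | None = None,
        order: int = 4,
    ):
        self.spike_z = spike_z
        self.ssr_z = ssr_z
        self.trim_tol = trim_tol
        self.lambda_grid = lambda_grid
        self.order = order

    def get_params(self, deep: bool = True) -> dict:
        return {
            "spike_z": self.spike_z,
            "ssr_z": self.ssr_z,
            "trim_tol": self.trim_tol,
            "lambda_grid": self.lambda_grid,
            "order": self.order,
        }

    def set_params(self, **params) -> "FunctionalQC":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, fs: FunctionalSample, y=None) -> "FunctionalQC":
        self.fit_transform(fs)
        return self

    def fit_transform(self, fs: FunctionalSample, y=None) -> FunctionalSample:
        despike, spike_mask = drop_terminal_spike_outliers(fs, z_thresh=self.spike_z)
        trimmed = trim_domain(despike, tol=self.trim_tol)
        fits = [
            smooth_gcv(trimmed.values[i], trimmed.densities,
                       lambda_grid=self.lambda_grid, order=self.order)
            for i in range(trimmed.n_subjects)
        ]
        ssr_mask = drop_ssr_outliers(fits, z_thresh=self.ssr_z)
        cleaned = trimmed.select(ssr_mask)
        self.report_ = QCReport(
            spike_mask=spike_mask,
            ssr_mask=ssr_mask,
            lambdas=np.array([f.lam for f in fits]),
            gcvs=np.array([f.gcv for f in fits]),
            ssrs=np.array([f.ssr for f in fits]),
            trimmed_domain=(float(trimmed.densities[0]), float(trimmed.densities[-1])),
            n_dropped_spike=int((~spike_mask).sum()),
            n_dropped_ssr=int((~ssr_mask).sum()),
        )
        return cleaned
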