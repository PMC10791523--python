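"""Effect-size regression and response-surface media optimization.

Given a handful of culture trials — each a media composition (α:
neuronal-medium fraction, β: serum %), the behaviour metrics measured or
inferred under it, and the resulting quality indicators — this module
(1) estimates standardized effect sizes of each behaviour on each
quality indicator by z-scored ordinary least squares, (2) fits
second-degree polynomial response surfaces z(α, β) over the media space,
locates and classifies their extrema, and (3) blends several surfaces
into a suggested composition for the next trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["SurfaceFit", "Extremum", "standardized_regression",
           "fit_quadratic_surface", "surface_extrema",
           "suggest_next_composition"]

COEF_NAMES = ("c0", "c_a", "c_b", "c_aa", "c_bb", "c_ab")


class CollinearityError(ValueError):
    """The regression design is rank deficient; names the collinear set."""


def standardized_regression(data: pd.DataFrame, response: str,
                            predictors: list[str]) -> pd.DataFrame:
    """Normalized-coefficient OLS of one quality indicator on behaviours.

    Response and predictors are z-scored (sample SD) before fitting, so
    coefficients are directly comparable effect sizes.  Trials with a
    missing value in any used column are dropped from this regression
    only; constant predictors are excluded with a warning.  Returns a
    frame indexed by predictor with columns coef, se, t, p, ci_lo,
    ci_hi.
    """
    cols = [response] + list(predictors)
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    d = data[cols].dropna()
    kept = []
    for name in predictors:
        if d[name].std(ddof=1) == 0:
            warnings.warn(f"predictor {name!r} is constant; excluded",
                          UserWarning, stacklevel=2)
        else:
            kept.append(name)
    if not kept:
        raise ValueError("no non-constant predictors")
    if len(d) <= len(kept) + 1:
        raise ValueError(
            f"need more trials ({len(d)}) than predictors+1 ({len(kept) + 1})")

    def z(s: pd.Series) -> np.ndarray:
        v = s.to_numpy(dtype=float)
        return (v - v.mean()) / v.std(ddof=1)

    X = np.column_stack([z(d[name]) for name in kept])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name a minimal collinear set by greedy elimination
        bad = [name for i, name in enumerate(kept)
               if np.linalg.matrix_rank(np.delete(X, i, axis=1))
               == np.linalg.matrix_rank(X)]
        raise CollinearityError(f"collinear predictors: {bad or kept}")
    y = z(d[response])
    model = sm.OLS(y, sm.add_constant(X)).fit()
    ci = model.conf_int(alpha=0.05)
    return pd.DataFrame({
        "coef": model.params[1:],
        "se": model.bse[1:],
        "t": model.tvalues[1:],
        "p": model.pvalues[1:],
        "ci_lo": ci[1:, 0],
        "ci_hi": ci[1:, 1],
    }, index=pd.Index(kept, name="predictor"))


@dataclass(frozen=True)
class SurfaceFit:
    """Six-coefficient quadratic surface z = c0 + c_a·α + c_b·β + c_aa·α²
    + c_bb·β² + c_ab·α·β over the media space."""

    coeffs: np.ndarray                 # (6,) in COEF_NAMES order
    r2: float
    residuals: np.ndarray = field(repr=False)
    name: str = "z"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("surface coefficients must be finite")

    def __call__(self, alpha, beta):
        a = np.asarray(alpha, dtype=float)
        b = np.asarray(beta, dtype=float)
        c = self.coeffs
        return (c[0] + c[1] * a + c[2] * b + c[3] * a**2 + c[4] * b**2
                + c[5] * a * b)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(COEF_NAMES, map(float, self.coeffs)),
                    r2=float(self.r2))


def _design(alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(alpha), alpha, beta,
                            alpha**2, beta**2, alpha * beta])


def fit_quadratic_surface(points: np.ndarray | pd.DataFrame,
                          name: str = "z") -> SurfaceFit:
    """Least-squares fit of the six-term quadratic to (α, β, z) points.

    Exact (machine-precision) interpolation when the data lie on a true
    quadratic.  Requires at least six points in a non-degenerate design.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (n, 3): alpha, beta, z")
    if pts.shape[0] < 6:
        raise ValueError(f"need >= 6 points to fit a quadratic surface, "
                         f"got {pts.shape[0]}")
    X = _design(pts[:, 0], pts[:, 1])
    if np.linalg.matrix_rank(X) < 6:
        raise ValueError("singular design: media compositions do not span "
                         "the quadratic model (need >= 3 distinct levels "
                         "per axis, not collinear)")
    z = pts[:, 2]
    coeffs, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ coeffs
    ss_tot = float(((z - z.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return SurfaceFit(coeffs=coeffs, r2=r2, residuals=resid, name=name)


@dataclass(frozen=True)
class Extremum:
    location: tuple[float, float]     # (alpha, beta)
    value: float
    kind: str                         # max | min | saddle | boundary


def surface_extrema(fit: SurfaceFit,
                    domain: tuple[tuple[float, float], tuple[float, float]]
                    = ((0.0, 1.0), (0.0, 10.0))) -> list[Extremum]:
    """Stationary point and boundary extrema of a quadratic surface.

    The interior stationary point solves the 2×2 linear system ∇z = 0
    and is classified by the Hessian sign pattern; each of the four
    domain edges is a 1-D quadratic whose stationary point (closed form)
    and corners are boundary candidates.  All candidates inside the
    domain are returned ranked by value (descending).
    """
    (a_lo, a_hi), (b_lo, b_hi) = domain
    c = fit.coeffs
    out: list[Extremum] = []
    H = np.array([[2 * c[3], c[5]], [c[5], 2 * c[4]]])
    det = float(np.linalg.det(H))
    tol_a = 1e-9 * (a_hi - a_lo)
    tol_b = 1e-9 * (b_hi - b_lo)
    if abs(det) > 1e-12 * max(1.0, float(np.abs(H).max()) ** 2):
        sol = np.linalg.solve(H, -np.array([c[1], c[2]]))
        if (a_lo - tol_a <= sol[0] <= a_hi + tol_a
                and b_lo - tol_b <= sol[1] <= b_hi + tol_b):
            sol = np.array([min(max(sol[0], a_lo), a_hi),
                            min(max(sol[1], b_lo), b_hi)])
            ev = np.linalg.eigvalsh(H)
            kind = ("max" if ev[1] < 0 else
                    "min" if ev[0] > 0 else "saddle")
            out.append(Extremum((float(sol[0]), float(sol[1])),
                                float(fit(*sol)), kind))

    def _edge(fixed_axis: int, fixed_val: float, lo: float, hi: float):
        # restrict to the edge: 1-D quadratic A t² + B t + C
        if fixed_axis == 0:     # alpha fixed, t = beta
            A = c[4]
            B = c[2] + c[5] * fixed_val
        else:                   # beta fixed, t = alpha
            A = c[3]
            B = c[1] + c[5] * fixed_val
        cands = [lo, hi]
        if abs(A) > 1e-300:
            t = -B / (2 * A)
            if lo < t < hi:
                cands.append(t)
        for t in cands:
            ab = (fixed_val, t) if fixed_axis == 0 else (t, fixed_val)
            out.append(Extremum((float(ab[0]), float(ab[1])),
                                float(fit(*ab)), "boundary"))

    _edge(0, a_lo, b_lo, b_hi)
    _edge(0, a_hi, b_lo, b_hi)
    _edge(1, b_lo, a_lo, a_hi)
    _edge(1, b_hi, a_lo, a_hi)
    # deduplicate corners visited by both edges
    seen: dict[tuple[float, float], Extremum] = {}
    for e in out:
        key = (round(e.location[0], 12), round(e.location[1], 12))
        if key not in seen:
            seen[key] = e
    return sorted(seen.values(), key=lambda e: e.value, reverse=True)


def suggest_next_composition(
    fits: list[tuple[SurfaceFit, str]],
    domain: tuple[tuple[float, float], tuple[float, float]]
    = ((0.0, 1.0), (0.0, 10.0)),
    tolerance: float = 0.10,
    grid_n: int = 201,
) -> tuple[tuple[float, float], pd.DataFrame]:
    """Blend several response surfaces into one suggested (α, β).

    Each surface (paired with its desired direction, ``"maximize"`` or
    ``"minimize"``) votes for the grid points whose value lies within
    ``tolerance`` × its value range of its own domain optimum.  The
    point with the most votes wins; ties break toward the point nearest
    the centroid of the tied set.  Returns the composition and a
    per-surface audit frame (its optimum value and whether it votes for
    the chosen point).
    """
    if not fits:
        raise ValueError("need at least one fitted surface")
    (a_lo, a_hi), (b_lo, b_hi) = domain
    a = np.linspace(a_lo, a_hi, grid_n)
    b = np.linspace(b_lo, b_hi, grid_n)
    A, B = np.meshgrid(a, b, indexing="ij")
    votes = np.zeros(A.shape, dtype=int)
    audit_rows = []
    desirable_maps = []
    for fit, direction in fits:
        if direction not in ("maximize", "minimize"):
            raise ValueError(f"direction must be maximize|minimize, "
                             f"got {direction!r}")
        Z = fit(A, B)
        z_best = Z.max() if direction == "maximize" else Z.min()
        band = tolerance * (Z.max() - Z.min())
        desirable = np.abs(Z - z_best) <= band
        votes += desirable
        desirable_maps.append(desirable)
        audit_rows.append((fit.name, direction, float(z_best)))
    best = votes.max()
    tied = np.argwhere(votes == best)
    pts = np.column_stack([A[tied[:, 0], tied[:, 1]],
                           B[tied[:, 0], tied[:, 1]]])
    centroid = pts.mean(axis=0)
    pick = int(np.argmin(((pts - centroid) ** 2).sum(axis=1)))
    alpha, beta = float(pts[pick, 0]), float(pts[pick, 1])
    i, j = tied[pick]
    audit = pd.DataFrame(audit_rows,
                         columns=["surface", "direction", "optimum_value"])
    audit["votes_for_choice"] = [bool(m[i, j]) for m in desirable_maps]
    return (alpha, beta), audit
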