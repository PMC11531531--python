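"""Membership functions, fuzzy partitions and fuzzy c-means clustering.

A :class:`MembershipFunction` maps a crisp value to a degree of set
membership in [0, 1].  A :class:`FuzzyPartition` is an ordered bank of
membership functions discretizing one variable into linguistic levels; every
point of the variable's domain is covered by at least one level with
positive membership, and levels are ordered by increasing center.

Supported kinds and parameters:

triangular(a, b, c)
    0 outside [a, c]; rises linearly (x−a)/(b−a) on [a, b]; falls
    (c−x)/(c−b) on [b, c]; apex μ(b) = 1.  Degenerate edges (a == b or
    b == c) are vertical shoulders with the limit value 1.
trapezoidal(a, b, c, d)
    linear rise on [a, b], plateau 1 on [b, c], linear fall on [c, d].
gaussian(c, σ)
    exp(−(x−c)² / (2σ²)) — the standard bell with unit apex.
bell(c, a, b)
    generalized bell 1 / (1 + |(x−c)/a|^{2b}).
piecewise_linear(xs, ys)
    linear interpolation through breakpoints, clipped to [0, 1]; 0 outside
    the breakpoint range when the end ordinates are 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class MembershipFunction:
    kind: str
    params: tuple

    def __post_init__(self) -> None:
        k, p = self.kind, self.params
        if k == "triangular":
            a, b, c = p
            if not (a <= b <= c):
                raise ValueError("triangular requires a <= b <= c")
        elif k == "trapezoidal":
            a, b, c, d = p
            if not (a <= b <= c <= d):
                raise ValueError("trapezoidal requires a <= b <= c <= d")
        elif k == "gaussian":
            _, sigma = p
            if sigma <= 0:
                raise ValueError("gaussian width must be > 0")
        elif k == "bell":
            _, a, b = p
            if a <= 0 or b <= 0:
                raise ValueError("bell requires spread a > 0 and shape b > 0")
        elif k == "piecewise_linear":
            xs, ys = p
            if len(xs) != len(ys) or len(xs) < 2:
                raise ValueError("piecewise_linear needs matching breakpoints")
            if any(np.diff(xs) < 0):
                raise ValueError("piecewise_linear xs must be non-decreasing")
            if min(ys) < 0 or max(ys) > 1:
                raise ValueError("piecewise_linear ordinates must lie in [0,1]")
        else:
            raise ValueError(f"unknown membership kind {k!r}")

    @property
    def center(self) -> float:
        """Representative location (apex / plateau middle / peak)."""
        k, p = self.kind, self.params
        if k == "triangular":
            return float(p[1])
        if k == "trapezoidal":
            return float((p[1] + p[2]) / 2)
        if k in ("gaussian", "bell"):
            return float(p[0])
        xs, ys = p
        return float(np.asarray(xs)[int(np.argmax(ys))])

    def __call__(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        k, p = self.kind, self.params
        if k == "triangular":
            a, b, c = p
            rise = (x - a) / (b - a) if b > a else np.where(x >= a, 1.0, 0.0)
            fall = (c - x) / (c - b) if c > b else np.where(x <= c, 1.0, 0.0)
            mu = np.minimum(rise, fall)
        elif k == "trapezoidal":
            a, b, c, d = p
            rise = (x - a) / (b - a) if b > a else np.where(x >= a, 1.0, 0.0)
            fall = (d - x) / (d - c) if d > c else np.where(x <= d, 1.0, 0.0)
            mu = np.minimum(np.minimum(rise, 1.0), fall)
        elif k == "gaussian":
            c, sigma = p
            mu = np.exp(-((x - c) ** 2) / (2.0 * sigma**2))
        elif k == "bell":
            c, a, b = p
            mu = 1.0 / (1.0 + np.abs((x - c) / a) ** (2.0 * b))
        else:  # piecewise_linear
            xs, ys = p
            mu = np.interp(x, xs, ys, left=ys[0], right=ys[-1])
        out = np.clip(mu, 0.0, 1.0)
        return float(out) if out.ndim == 0 else out


def eval_mf(mf: MembershipFunction, x) -> np.ndarray | float:
    """Evaluate a membership function (total on all finite inputs)."""
    return mf(x)


@dataclass
class FuzzyPartition:
    """Ordered bank of membership functions covering one variable's domain."""

    variable_id: str
    mfs: list[MembershipFunction]
    domain: tuple[float, float]

    def __post_init__(self) -> None:
        centers = [m.center for m in self.mfs]
        if any(np.diff(centers) < 0):
            raise ValueError("membership functions must be ordered by center")

    @property
    def n_levels(self) -> int:
        return len(self.mfs)

    def memberships(self, x) -> np.ndarray:
        """Degrees of x in every level; shape (..., n_levels)."""
        x = np.asarray(x, dtype=float)
        return np.stack([np.asarray(m(x)) for m in self.mfs], axis=-1)

    def best_level(self, x) -> np.ndarray:
        """Index of the maximal-membership level (ties -> lower index)."""
        return np.argmax(self.memberships(x), axis=-1)

    def coverage_ok(self, n_grid: int = 256, tol: float = 1e-9) -> bool:
        grid = np.linspace(*self.domain, n_grid)
        return bool((self.memberships(grid).max(axis=-1) > tol).all())


def fcm_cluster(values, n_clusters: int, m: float = 2.0, tol: float = 1e-6,
                max_iter: int = 300, seed: int = 0,
                return_history: bool = False):
    """1-D fuzzy c-means: minimize Σ_i Σ_j w_ij^m |x_i − μ_j|².

    Alternates membership and center updates; memberships are row-normalized
    and the objective is non-increasing between iterations.  Returns
    ``(centers, memberships)`` with centers sorted ascending and membership
    columns reordered to match (plus the per-iteration objective trajectory
    when ``return_history`` is set).  A point coinciding with a center gets
    crisp membership there.
    """
    x = np.asarray(values, dtype=float).ravel()
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if n_clusters < 1 or n_clusters > len(np.unique(x)):
        raise ValueError("n_clusters must be in [1, number of distinct values]")
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.ones(n_clusters), size=len(x))
    centers = np.empty(n_clusters)
    prev_obj = np.inf
    converged = False
    history: list[float] = []
    for _ in range(max_iter):
        wm = w**m
        centers = (wm * x[:, None]).sum(axis=0) / wm.sum(axis=0)
        d2 = (x[:, None] - centers[None, :]) ** 2
        obj = float((wm * d2).sum())
        history.append(obj)
        # membership update: w_ij = 1 / Σ_k (d_ij/d_ik)^(2/(m-1))
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-1.0 / (m - 1.0))
        crisp = ~np.isfinite(inv).all(axis=1)
        w = inv / inv.sum(axis=1, keepdims=True)
        if crisp.any():  # point exactly on >=1 center: split crisply
            hit = ~np.isfinite(inv[crisp])
            w[crisp] = hit / hit.sum(axis=1, keepdims=True)
        if abs(prev_obj - obj) < tol:
            converged = True
            break
        prev_obj = obj
    if not converged:
        warnings.warn("fuzzy c-means did not converge; returning best iterate",
                      RuntimeWarning, stacklevel=2)
    order = np.argsort(centers)
    if return_history:
        return centers[order], w[:, order], history
    return centers[order], w[:, order]


def _centers_for(column: np.ndarray, n_levels: int, placement: str,
                 seed: int) -> tuple[np.ndarray, float, float]:
    lo, hi = float(column.min()), float(column.max())
    if placement == "uniform":
        centers = np.linspace(lo, hi, n_levels)
    elif placement == "fcm":
        k = min(n_levels, len(np.unique(column)))
        centers, _ = fcm_cluster(column, k, seed=seed)
    else:
        raise ValueError(f"unknown placement {placement!r}")
    return np.asarray(centers, float), lo, hi


def _mf_from_centers(kind: str, centers: np.ndarray, i: int,
                     lo: float, hi: float) -> MembershipFunction:
    """Build level i of a partition whose apexes sit at ``centers``.

    Feet go to the neighboring centers so adjacent triangles cross at 0.5
    under uniform spacing; edge levels extend past the domain bound far
    enough that the bound itself keeps positive (>= ~0.5) membership.
    """
    c = centers[i]
    eps = max(1e-9, 1e-9 * (abs(hi - lo) + abs(c)))
    if i > 0:
        left = centers[i - 1]
    else:
        left = c - max(centers[1] - c if len(centers) > 1 else eps,
                       2 * (c - lo), eps)
    if i < len(centers) - 1:
        right = centers[i + 1]
    else:
        right = c + max(c - centers[-2] if len(centers) > 1 else eps,
                        2 * (hi - c), eps)
    if kind == "triangular":
        return MembershipFunction("triangular", (left, c, right))
    if kind == "trapezoidal":
        hw = 0.25
        return MembershipFunction("trapezoidal", (
            left, c - hw * (c - left), c + hw * (right - c), right))
    if kind == "piecewise_linear":
        xs = (left, (left + c) / 2, c, (c + right) / 2, right)
        ys = (0.0, 0.6, 1.0, 0.6, 0.0)
        return MembershipFunction("piecewise_linear", (xs, ys))
    if kind == "gaussian":
        half = min(c - left, right - c)
        sigma = half / np.sqrt(2 * np.log(2))  # mu = 0.5 at nearest neighbor
        return MembershipFunction("gaussian", (c, sigma))
    if kind == "bell":
        half = min(c - left, right - c)
        return MembershipFunction("bell", (c, half, 2.0))
    raise ValueError(f"unknown membership kind {kind!r}")


def build_partition(column, variable_id: str, n_levels: int = 9,
                    mf_kind: str = "triangular", placement: str = "uniform",
                    seed: int = 0) -> FuzzyPartition:
    """Partition one variable into ``n_levels`` linguistic levels.

    ``placement="uniform"`` spaces apexes evenly over [min, max] (adjacent
    triangular levels then cross at membership 0.5); ``"fcm"`` places apexes
    at fuzzy c-means centers, adapting the levels to the data's modes.  A
    constant column degenerates to a single all-covering level (warning).
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    col = np.asarray(column, dtype=float).ravel()
    lo, hi = float(col.min()), float(col.max())
    if hi <= lo:
        warnings.warn(f"constant column {variable_id!r}: degenerate partition",
                      RuntimeWarning, stacklevel=2)
        span = max(abs(lo), 1.0)
        mf = MembershipFunction("triangular", (lo - span, lo, lo + span))
        return FuzzyPartition(variable_id, [mf], (lo, hi))
    centers, lo, hi = _centers_for(col, n_levels, placement, seed)
    mfs = [_mf_from_centers(mf_kind, centers, i, lo, hi)
           for i in range(len(centers))]
    return FuzzyPartition(variable_id, mfs, (lo, hi))


def build_partitions(X, feature_ids: list[str] | None = None,
                     n_levels: int = 9, mf_kind: str = "triangular",
                     placement: str = "uniform", seed: int = 0
                     ) -> list[FuzzyPartition]:
    """One partition per column of X."""
    X = np.asarray(X, dtype=float)
    ids = feature_ids or [f"f{j}" for j in range(X.shape[1])]
    return [build_partition(X[:, j], ids[j], n_levels, mf_kind, placement, seed)
            for j in range(X.shape[1])]
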