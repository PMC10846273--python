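"""Privatization model of public-good cooperation.

A cooperator secretes an enzyme that hydrolyzes a disaccharide (sucrose)
outside the cell, releasing ``r`` units of monosaccharide per cell.  A
fraction ``alpha`` of those units is captured by the producing cell before
diffusing away (privatization); the remainder enters a common pool shared by
every cell, cooperator and cheater alike.  With ``x`` the cooperator
frequency, the per-cell resource shares are

    R_co = alpha*r + (1 - alpha)*r*x
    R_ch = (1 - alpha)*r*x

Fitness is Monod-saturating in the resource share, and cooperators pay a
production cost ``C``:

    f_co = fmax * R_co / (Km + R_co) - C
    f_ch = fmax * R_ch / (Km + R_ch)

Because the cheater share grows with cooperator frequency, the fitness gap
g(x) = f_co - f_ch is strictly decreasing in x whenever 0 < alpha < 1 and
r > 0, so the equal-fitness coexistence frequency x* is unique when it lies
in (0, 1).  Outside that window the population fixes: g(0) <= 0 means
cheaters exclude cooperators, g(1) >= 0 means cooperators sweep.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelParams",
    "ResourceShares",
    "FitnessPair",
    "BoundaryStatus",
    "CoexistenceResult",
    "SweepGrid",
    "resources",
    "fitness",
    "fitness_gap",
    "solve_coexistence",
    "sweep_alpha_r",
    "write_sweep_tsv",
]

#: Fraction of hydrolysis products the unevolved (ancestral) cooperator
#: retains; roughly 99% of the monosaccharides diffuse into the shared pool.
ANCESTRAL_ALPHA = 0.01

DEFAULT_TOL = 1e-10
_MAX_BISECT_ITER = 200


@dataclass(frozen=True)
class ModelParams:
    """The five constants of the privatization model.

    Parameters
    ----------
    fmax : float
        Maximal per-generation fitness at saturating resource (dimensionless).
    Km : float
        Resource share at which fitness is half-maximal (sugar units, same
        units as ``r``).
    C : float
        Cost of cooperation, i.e. of enzyme production (fitness units).
    r : float
        Sugar molecules released per cooperator cell (sugar units).
    alpha : float
        Fraction of the released sugar retained by the producer, in [0, 1].
    """

    fmax: float = 1.0
    Km: float = 1.0
    C: float = 0.1
    r: float = 1.0
    alpha: float = ANCESTRAL_ALPHA

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.r < 0:
            raise ValueError(f"r must be >= 0, got {self.r}")
        if self.Km <= 0:
            raise ValueError(f"Km must be > 0, got {self.Km}")
        if self.fmax <= 0:
            raise ValueError(f"fmax must be > 0, got {self.fmax}")
        if self.C < 0:
            raise ValueError(f"C must be >= 0, got {self.C}")

    def replace(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        fields = dict(fmax=self.fmax, Km=self.Km, C=self.C, r=self.r, alpha=self.alpha)
        fields.update(kwargs)
        return ModelParams(**fields)


@dataclass(frozen=True)
class ResourceShares:
    """Per-cell resource shares; Rco - Rch = alpha*r regardless of x."""

    Rco: float
    Rch: float

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.Rch) < 0) or np.any(np.asarray(self.Rco) < np.asarray(self.Rch)):
            raise ValueError(f"shares must satisfy Rco >= Rch >= 0, got {self}")


@dataclass(frozen=True)
class FitnessPair:
    """Cooperator and cheater fitness at a given composition."""

    fco: float
    fch: float


class BoundaryStatus(str, enum.Enum):
    """Where the equal-fitness solution lands."""

    INTERIOR = "interior"
    CLAMPED_LOW = "clamped_low"  # cheaters competitively exclude cooperators
    CLAMPED_HIGH = "clamped_high"  # cooperators fix


@dataclass(frozen=True)
class CoexistenceResult:
    """Equilibrium cooperator fraction ``x_star`` with solve diagnostics."""

    x_star: float
    status: BoundaryStatus
    residual: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.x_star <= 1.0):
            raise ValueError(f"x_star must be in [0, 1], got {self.x_star}")


@dataclass(frozen=True)
class SweepGrid:
    """x* over an (alpha, r) grid; X[i, j] pairs alphas[i] with rs[j]."""

    alphas: np.ndarray
    rs: np.ndarray
    X: np.ndarray
    status: np.ndarray  # matching grid of BoundaryStatus values

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.alphas), len(self.rs)):
            raise ValueError("X dimensions must equal |alphas| x |rs|")
        if np.any(self.X < 0) or np.any(self.X > 1):
            raise ValueError("all x_star entries must lie in [0, 1]")


def _check_x(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1) or np.any(~np.isfinite(x)):
        raise ValueError("cooperator fraction x must lie in [0, 1]")
    return x


def resources(params: ModelParams, x):
    """Per-cell resource shares at cooperator fraction ``x``.

    Accepts a scalar or array ``x``; returns a :class:`ResourceShares` for a
    scalar and a ``(Rco, Rch)`` array pair otherwise.
    """
    xa = _check_x(x)
    shared = (1.0 - params.alpha) * params.r * xa
    rco = params.alpha * params.r + shared
    if xa.ndim == 0:
        return ResourceShares(Rco=float(rco), Rch=float(shared))
    return rco, shared


def _monod(params: ModelParams, R):
    return params.fmax * R / (params.Km + R)


def fitness(params: ModelParams, shares: ResourceShares) -> FitnessPair:
    """Monod fitness of each type; the cost C falls on cooperators only."""
    return FitnessPair(
        fco=float(_monod(params, shares.Rco)) - params.C,
        fch=float(_monod(params, shares.Rch)),
    )


def fitness_gap(params: ModelParams, x):
    """Signed fitness difference g(x) = f_co(x) - f_ch(x).

    Strictly decreasing in x for alpha in (0, 1) and r > 0 (the cheater
    share saturates more slowly than the cooperator share).  Vectorized
    over ``x``.
    """
    xa = _check_x(x)
    shared = (1.0 - params.alpha) * params.r * xa
    rco = params.alpha * params.r + shared
    g = _monod(params, rco) - params.C - _monod(params, shared)
    return float(g) if xa.ndim == 0 else g


def solve_coexistence(params: ModelParams, tol: float = DEFAULT_TOL) -> CoexistenceResult:
    """Solve g(x*) = 0 for the equal-fitness cooperator fraction.

    Monotonicity of g makes the interior root unique, so plain bracketing
    bisection on [0, 1] suffices.  When g does not change sign the
    population fixes and x* is clamped to the corresponding boundary.
    """
    if tol <= 0:
        raise ValueError(f"tol must be > 0, got {tol}")
    g0 = fitness_gap(params, 0.0)
    if g0 <= 0.0:
        return CoexistenceResult(0.0, BoundaryStatus.CLAMPED_LOW, abs(g0))
    g1 = fitness_gap(params, 1.0)
    if g1 >= 0.0:
        return CoexistenceResult(1.0, BoundaryStatus.CLAMPED_HIGH, abs(g1))

    lo, hi = 0.0, 1.0
    mid = 0.5
    gm = fitness_gap(params, mid)
    for _ in range(_MAX_BISECT_ITER):
        if hi - lo <= tol and abs(gm) <= tol:
            break
        if gm > 0.0:
            lo = mid
        else:
            hi = mid
        new_mid = 0.5 * (lo + hi)
        if new_mid == mid:  # interval below float resolution
            break
        mid = new_mid
        gm = fitness_gap(params, mid)
    return CoexistenceResult(mid, BoundaryStatus.INTERIOR, abs(gm))


def sweep_alpha_r(
    base: ModelParams,
    alphas,
    rs,
    tol: float = DEFAULT_TOL,
) -> SweepGrid:
    """Equilibrium cooperator fraction over an (alpha, r) grid.

    ``base`` supplies fmax, Km and C; each grid cell replaces (alpha, r).
    Along any column (fixed r) x* is non-decreasing in alpha.
    """
    alphas = np.asarray(list(alphas), dtype=float)
    rs = np.asarray(list(rs), dtype=float)
    if alphas.size == 0 or rs.size == 0:
        raise ValueError("alphas and rs must be non-empty")
    X = np.empty((alphas.size, rs.size))
    status = np.empty((alphas.size, rs.size), dtype=object)
    for i, a in enumerate(alphas):
        for j, r in enumerate(rs):
            res = solve_coexistence(base.replace(alpha=float(a), r=float(r)), tol=tol)
            X[i, j] = res.x_star
            status[i, j] = res.status
    return SweepGrid(alphas=alphas, rs=rs, X=X, status=status)


def write_sweep_tsv(grid: SweepGrid, path) -> None:
    """Write a sweep as TSV (alpha, r, x_star, status), one row per cell.

    Floats are printed with 17 significant digits so the file round-trips
    bit-for-bit.
    """
    with open(path, "w") as fh:
        fh.write("alpha\tr\tx_star\tstatus\n")
        for i, a in enumerate(grid.alphas):
            for j, r in enumerate(grid.rs):
                fh.write(
                    f"{a:.17g}\t{r:.17g}\t{grid.X[i, j]:.17g}\t{grid.status[i, j].value}\n"
                )
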