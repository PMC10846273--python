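"""Serial-transfer dynamics of cooperator frequency.

The experimental unit of time is one batch: cells grow for a day, then the
culture is diluted 1:100 into fresh medium.  Regrowth to the pre-dilution
density takes log2(100) ~ 6.64 doublings, so one transfer advances the
population by about 6.6-6.7 generations.

Frequencies are updated once per transfer with Wrightian (exponential)
fitness weights evaluated at the start-of-batch composition:

    w_co = exp(f_co * dt),   w_ch = exp(f_ch * dt)
    x' = x * w_co / (x * w_co + (1 - x) * w_ch)

equivalently, the log-odds of the cooperator advance by (f_co - f_ch) * dt
per transfer.  The deterministic simulator carries no demographic drift:
with the ~1e5-1e7 cells that survive a 1:100 bottleneck, drift is
negligible next to selection and next to the colony-count observation noise
modelled in :mod:`privgood.synth`.  A finite-N binomial bottleneck is
available for completeness but off by default.

``calibrate`` inverts the simulator: given an observed frequency
trajectory, it fits the privatization fraction alpha and the cooperation
cost C by least squares, holding fmax, Km and r fixed (frequency-only data
cannot identify all five constants).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

from .model import ModelParams, fitness_gap

__all__ = [
    "TransferRegime",
    "FrequencyTrajectory",
    "CalibrationResult",
    "generations_per_transfer",
    "step_frequency",
    "simulate_serial_transfers",
    "assay_transfer_indices",
    "calibrate",
    "write_trajectory_tsv",
    "write_calibration_tsv",
]


def generations_per_transfer(dilution_factor: float) -> float:
    """Doublings needed to regrow a 1:D dilution: log2(D).

    A 1:100 transfer gives log2(100) = 6.64, the 'roughly 6.7 generations
    per day' of a standard yeast serial-dilution experiment.
    """
    if dilution_factor <= 1:
        raise ValueError(f"dilution_factor must be > 1, got {dilution_factor}")
    return math.log2(dilution_factor)


@dataclass(frozen=True)
class TransferRegime:
    """Serial-dilution design: fold dilution, transfer count, assay spacing."""

    dilution_factor: float = 100.0
    n_transfers: int = 30
    assay_interval_generations: float = 50.0

    def __post_init__(self) -> None:
        if self.dilution_factor <= 1:
            raise ValueError(f"dilution_factor must be > 1, got {self.dilution_factor}")
        if self.n_transfers < 1:
            raise ValueError(f"n_transfers must be >= 1, got {self.n_transfers}")
        if self.assay_interval_generations <= 0:
            raise ValueError("assay_interval_generations must be > 0")

    @property
    def generations_per_transfer(self) -> float:
        return generations_per_transfer(self.dilution_factor)

    @property
    def total_generations(self) -> float:
        return self.n_transfers * self.generations_per_transfer


@dataclass(frozen=True)
class FrequencyTrajectory:
    """Cooperator frequency indexed by cumulative generations."""

    generations: np.ndarray
    x: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.generations, dtype=float)
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "generations", g)
        object.__setattr__(self, "x", x)
        if g.shape != x.shape or g.ndim != 1 or g.size < 1:
            raise ValueError("generations and x must be 1-d arrays of equal length")
        if g[0] != 0 or np.any(np.diff(g) <= 0):
            raise ValueError("generations must start at 0 and increase strictly")
        if np.any(x < 0) or np.any(x > 1):
            raise ValueError("frequencies must lie in [0, 1]")


def _check_frequency(x: float) -> float:
    x = float(x)
    if not (0.0 <= x <= 1.0) or not math.isfinite(x):
        raise ValueError(f"frequency must lie in [0, 1], got {x}")
    return x


def step_frequency(params: ModelParams, x: float, dt_generations: float) -> float:
    """One batch of competitive growth: frequency after dt generations.

    Fitness is evaluated at the start-of-batch frequency; x = 0 and x = 1
    are absorbing.  The update is the softmax of exponential growth,
    x'/(1-x') = x/(1-x) * exp((f_co - f_ch) * dt).
    """
    x = _check_frequency(x)
    if dt_generations <= 0:
        raise ValueError(f"dt_generations must be > 0, got {dt_generations}")
    if x == 0.0 or x == 1.0:
        return x
    gap = fitness_gap(params, x)
    # Only the fitness *difference* moves the frequency; factoring out the
    # cheater weight keeps both exponentials tame for large |f * dt|.
    w = math.exp(gap * dt_generations)
    return x * w / (x * w + (1.0 - x))


def simulate_serial_transfers(
    params: ModelParams,
    regime: TransferRegime,
    x0: float,
    bottleneck_cells: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> FrequencyTrajectory:
    """Deterministic frequency trajectory over a serial-transfer experiment.

    Records x at generation 0 and after every transfer.  If
    ``bottleneck_cells`` is given, the frequency is resampled binomially at
    each dilution to emulate a finite transfer volume (requires ``rng``);
    by default the dynamics are purely deterministic.
    """
    x = _check_frequency(x0)
    dt = regime.generations_per_transfer
    if bottleneck_cells is not None and rng is None:
        raise ValueError("a finite bottleneck requires an rng")
    gens = np.empty(regime.n_transfers + 1)
    xs = np.empty(regime.n_transfers + 1)
    gens[0], xs[0] = 0.0, x
    for t in range(1, regime.n_transfers + 1):
        x = step_frequency(params, x, dt)
        if bottleneck_cells is not None:
            x = rng.binomial(bottleneck_cells, x) / bottleneck_cells
        gens[t] = t * dt
        xs[t] = x
    return FrequencyTrajectory(generations=gens, x=xs)


def assay_transfer_indices(regime: TransferRegime) -> np.ndarray:
    """Transfer indices closest to multiples of the assay interval.

    Generations accumulate in steps of log2(dilution), so assays nominally
    scheduled every 50 generations land on the nearest transfer (e.g. the
    8th transfer, at 53.2 generations, for a 1:100 regime).  Generation 0
    is always included.
    """
    dt = regime.generations_per_transfer
    # Half a transfer of slack so a nominal assay just past the final
    # transfer (e.g. generation 200 when 30 transfers reach 199.3) still
    # maps to its nearest transfer.
    n_assays = int(
        math.floor((regime.total_generations + dt / 2) / regime.assay_interval_generations)
    )
    idx = {0}
    for m in range(1, n_assays + 1):
        t = int(round(m * regime.assay_interval_generations / dt))
        idx.add(min(max(t, 0), regime.n_transfers))
    return np.array(sorted(idx), dtype=int)


@dataclass(frozen=True)
class CalibrationResult:
    """Least-squares fit of (alpha, C) to an observed frequency trajectory."""

    alpha: float
    C: float
    objective: float
    converged: bool
    identifiable: bool

    def __post_init__(self) -> None:
        if self.objective < 0:
            raise ValueError("objective must be >= 0")


def _nearest_indices(sim_gens: np.ndarray, obs_gens: np.ndarray) -> np.ndarray:
    return np.array([int(np.argmin(np.abs(sim_gens - g))) for g in obs_gens])


def binomial_weights(p_hat: np.ndarray, n_effective: float) -> np.ndarray:
    """Inverse-variance weights for observed binomial proportions.

    Var(p_hat) = p(1-p)/n shrinks sharply near the boundaries, so
    unweighted least squares over-trusts mid-range points; these weights
    make the fit an approximate binomial maximum-likelihood estimate.  A
    variance floor of 1/(4 n_effective^2) keeps boundary observations from
    acquiring infinite weight.
    """
    p = np.asarray(p_hat, dtype=float)
    if n_effective <= 0:
        raise ValueError("n_effective must be > 0")
    var = np.maximum(p * (1.0 - p), 0.25 / n_effective) / n_effective
    return 1.0 / var


def calibrate(
    observed: FrequencyTrajectory,
    regime: TransferRegime,
    fmax: float = 1.0,
    Km: float = 1.0,
    r: float = 1.0,
    max_cost: float = 2.0,
    weights: Optional[np.ndarray] = None,
    x0: Optional[float] = None,
    fix_C: Optional[float] = None,
) -> CalibrationResult:
    """Fit privatization alpha and cost C to an observed trajectory.

    Sum-of-squared-residuals objective between the deterministic simulator
    and the observed frequencies at their nearest simulated generations;
    multistart from a coarse (alpha, C) grid followed by bounded local
    refinement.  ``weights`` (e.g. :func:`binomial_weights`) turn the
    objective into weighted least squares; ``x0`` overrides the simulator's
    starting frequency when the initial mixture is known by design (the
    default uses the first observed value).

    Privatization and cost are nearly collinear on frequency data — both
    shift the fitness gap almost uniformly over the visited frequency
    window — so the joint fit rides a long (alpha, C) valley that colony-
    count noise can traverse.  When the cost is known from an independent
    measurement (e.g. monoculture growth kinetics), pass ``fix_C`` to hold
    it and fit alpha alone, which is then sharply identified.

    A flat trajectory is flagged non-identifiable (any neutral pair fits)
    and returned unconverged with the neutral fit (alpha = 0, C = 0).
    """
    if observed.x.size < 2:
        raise ValueError("calibration needs at least 2 time points")
    x0 = float(observed.x[0]) if x0 is None else _check_frequency(x0)
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != observed.x.shape or np.any(weights < 0):
            raise ValueError("weights must be non-negative, one per observation")

    sim_gens = np.arange(regime.n_transfers + 1) * regime.generations_per_transfer
    take = _nearest_indices(sim_gens, observed.generations)

    def objective(theta) -> float:
        a, c = theta
        a = min(max(a, 0.0), 1.0)
        c = max(c, 0.0)
        params = ModelParams(fmax=fmax, Km=Km, C=c, r=r, alpha=a)
        traj = simulate_serial_transfers(params, regime, x0)
        resid = traj.x[take] - observed.x
        if weights is not None:
            return float(resid @ (weights * resid))
        return float(resid @ resid)

    if np.ptp(observed.x) < 1e-12:
        neutral = (0.0, 0.0 if fix_C is None else fix_C)
        return CalibrationResult(
            alpha=0.0, C=neutral[1], objective=objective(neutral),
            converged=False, identifiable=False,
        )

    if fix_C is not None:
        if fix_C < 0:
            raise ValueError(f"fix_C must be >= 0, got {fix_C}")
        best = None
        for lo, hi in [(0.0, 0.35), (0.3, 0.65), (0.6, 1.0)]:
            res = optimize.minimize_scalar(
                lambda a: objective((a, fix_C)), bounds=(lo, hi), method="bounded",
            )
            if best is None or res.fun < best.fun:
                best = res
        return CalibrationResult(
            alpha=float(best.x), C=float(fix_C), objective=float(best.fun),
            converged=bool(best.success), identifiable=True,
        )

    starts = [
        (a, c)
        for a in np.linspace(0.0, 0.95, 8)
        for c in np.linspace(0.0, 0.5, 6)
    ]
    coarse = sorted(starts, key=objective)[:3]
    best = None
    for s in coarse:
        res = optimize.minimize(
            objective, s, method="L-BFGS-B",
            bounds=[(0.0, 1.0), (0.0, max_cost)],
            options={"ftol": 1e-16, "gtol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    # derivative-free polish; the finite-difference gradient stalls a few
    # ulps above the floor on noise-free data
    polish = optimize.minimize(
        objective, best.x, method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-16},
    )
    if polish.fun < best.fun:
        best = polish
    best.x = np.clip(best.x, [0.0, 0.0], [1.0, max_cost])
    return CalibrationResult(
        alpha=float(best.x[0]),
        C=float(best.x[1]),
        objective=float(best.fun),
        converged=bool(best.success),
        identifiable=True,
    )


def write_trajectory_tsv(traj: FrequencyTrajectory, path) -> None:
    """Write a trajectory as TSV with columns generation, x."""
    with open(path, "w") as fh:
        fh.write("generation\tx\n")
        for g, x in zip(traj.generations, traj.x):
            fh.write(f"{g:.17g}\t{x:.17g}\n")


def write_calibration_tsv(result: CalibrationResult, path) -> None:
    """Write a calibration report as a two-column parameter/value TSV."""
    with open(path, "w") as fh:
        fh.write("parameter\testimate\n")
        fh.write(f"alpha\t{result.alpha:.17g}\n")
        fh.write(f"C\t{result.C:.17g}\n")
        fh.write(f"objective\t{result.objective:.17g}\n")
        fh.write(f"converged\t{result.converged}\n")
        fh.write(f"identifiable\t{result.identifiable}\n")
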