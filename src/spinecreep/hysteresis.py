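"""Double-Boltzmann parameterization of moment–RoM hysteresis loops.

One loading cycle of a spinal segment under pure moment control traces a
hysteresis loop in the moment (Nm) vs. range-of-motion (degrees) plane.  Each
branch of the loop (loading and unloading sweep) is described by a modified
double Boltzmann sigmoid

    RoM(m) = A / (1 + exp(a1 (m - m1))) - B / (1 + exp(a2 (m - m2))) + B

with shared asymptotes ``A`` (minimum RoM) and ``B`` (maximum RoM) and
branch-specific slopes ``a1, a2`` (1/Nm) and centers ``m1, m2`` (Nm).  A full
loop is therefore captured by ten numbers: A, B plus four shape parameters per
branch.  ``A`` and ``B`` are fixed at the sampled extrema; only the shape
parameters are optimized by nonlinear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "MomentRomLoop",
    "HysteresisParams",
    "FitResult",
    "DegenerateLoopError",
    "eval_boltzmann",
    "split_branches",
    "fit_hysteresis",
    "r_squared",
    "curve_from_params",
]

#: Peak applied moment of the loading protocol, Nm.
MOMENT_LIMIT = 7.5

#: Default fit-quality gate on the pooled coefficient of determination.
R2_THRESHOLD = 0.985

_EXP_CLAMP = 700.0  # exp argument clamp; exp(700) is near the float64 limit


class DegenerateLoopError(ValueError):
    """Raised for loops with a single sweep direction or zero RoM span."""


@dataclass(frozen=True)
class HysteresisParams:
    """Ten-parameter description of one cycle's hysteresis loop.

    ``A``/``B`` are the shared minimum/maximum RoM in degrees; per branch
    (``u`` = upper, ``l`` = lower) the slopes ``a1, a2`` are in 1/Nm and the
    centers ``m1, m2`` in Nm.
    """

    A: float
    B: float
    a1_u: float
    m1_u: float
    a2_u: float
    m2_u: float
    a1_l: float
    m1_l: float
    a2_l: float
    m2_l: float

    #: Parameter order used in CSV files and model feature vectors.
    FIELDS = ("A", "B", "a1_u", "m1_u", "a2_u", "m2_u", "a1_l", "m1_l", "a2_l", "m2_l")

    def __post_init__(self) -> None:
        vec = self.to_vector()
        if not np.all(np.isfinite(vec)):
            raise ValueError("hysteresis parameters must be finite")
        if self.A > self.B:
            raise ValueError(f"A ({self.A}) must not exceed B ({self.B})")

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FIELDS], dtype=float)

    @classmethod
    def from_vector(cls, vec: Sequence[float]) -> "HysteresisParams":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (10,):
            raise ValueError(f"expected 10 parameters, got shape {vec.shape}")
        return cls(*vec)

    def branch(self, which: str) -> tuple[float, float, float, float]:
        """Shape parameters (a1, m1, a2, m2) of one branch."""
        if which == "upper":
            return self.a1_u, self.m1_u, self.a2_u, self.m2_u
        if which == "lower":
            return self.a1_l, self.m1_l, self.a2_l, self.m2_l
        raise ValueError(f"unknown branch {which!r}")

    def rom_at(self, m: float, branch: str = "upper") -> float:
        """Evaluate this loop's RoM at moment ``m`` on one branch."""
        a1, m1, a2, m2 = self.branch(branch)
        return float(eval_boltzmann(self.A, self.B, a1, m1, a2, m2, m))

    def scaled_envelope(self, factor: float) -> "HysteresisParams":
        """Return a copy with the envelope B−A scaled by ``factor`` about its midpoint."""
        mid = 0.5 * (self.A + self.B)
        half = 0.5 * (self.B - self.A) * factor
        return replace(self, A=mid - half, B=mid + half)


@dataclass(frozen=True)
class MomentRomLoop:
    """Sampled moment (Nm) vs. RoM (degrees) trace of one full loading cycle."""

    moment: np.ndarray
    rom: np.ndarray
    cycle_index: int = 1

    def __post_init__(self) -> None:
        m = np.asarray(self.moment, dtype=float)
        r = np.asarray(self.rom, dtype=float)
        object.__setattr__(self, "moment", m)
        object.__setattr__(self, "rom", r)
        if m.ndim != 1 or m.shape != r.shape:
            raise ValueError("moment and rom must be 1-D arrays of equal length")
        if m.size < 8:
            raise ValueError("a loop needs at least 8 samples")
        if not (np.all(np.isfinite(m)) and np.all(np.isfinite(r))):
            raise ValueError("loop samples must be finite")
        if np.max(np.abs(m)) > MOMENT_LIMIT + 0.5:
            raise ValueError(f"moment exceeds the ±{MOMENT_LIMIT} Nm protocol range")
        if self.cycle_index < 1:
            raise ValueError("cycle_index must be ≥ 1")
        d = np.diff(m)
        if not (np.any(d > 0) and np.any(d < 0)):
            raise DegenerateLoopError("loop must contain a rising and a falling moment sweep")


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting one loop: parameters, per-branch and pooled R²."""

    params: HysteresisParams
    r2_upper: float
    r2_lower: float
    r2_total: float
    converged: bool
    accepted: bool


def eval_boltzmann(A, B, a1, m1, a2, m2, m):
    """Evaluate the modified double Boltzmann sigmoid at moment(s) ``m``.

    Vectorized over ``m``.  The exponent is clamped at ±700 so extreme slope ×
    moment products saturate instead of overflowing.
    """
    args = np.asarray([A, B, a1, m1, a2, m2], dtype=float)
    if not np.all(np.isfinite(args)):
        raise ValueError("eval_boltzmann requires finite parameters")
    m = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("eval_boltzmann requires finite moments")
    e1 = np.exp(np.clip(a1 * (m - m1), -_EXP_CLAMP, _EXP_CLAMP))
    e2 = np.exp(np.clip(a2 * (m - m2), -_EXP_CLAMP, _EXP_CLAMP))
    return A / (1.0 + e1) - B / (1.0 + e2) + B


def split_branches(loop: MomentRomLoop):
    """Partition a loop's samples into the upper and lower branch.

    Samples are grouped by the local sweep direction of the moment signal;
    the branch with the larger mean RoM over the overlapping moment range is
    labelled *upper*.  When the branches coincide everywhere the tie is broken
    by acquisition order (first-traversed = upper).

    Returns two ``(moment, rom)`` tuples: ``(upper, lower)``.
    """
    m, r = loop.moment, loop.rom
    d = np.diff(m)
    # assign each sample to the direction of its neighbouring sweep
    direction = np.zeros(m.size)
    direction[1:] += np.sign(d)
    direction[:-1] += np.sign(d)
    rising = direction > 0
    falling = direction < 0
    # plateau samples (direction 0) join the preceding sweep
    last = 1
    for i in range(m.size):
        if rising[i]:
            last = 1
        elif falling[i]:
            last = -1
        else:
            (rising if last > 0 else falling)[i] = True
    if not (rising.any() and falling.any()):
        raise DegenerateLoopError("loop has a single sweep direction")

    branches = [(m[rising], r[rising]), (m[falling], r[falling])]
    lo = max(b[0].min() for b in branches)
    hi = min(b[0].max() for b in branches)
    grid = np.linspace(lo, hi, 32)
    means = []
    for bm, br in branches:
        order = np.argsort(bm, kind="stable")
        means.append(np.interp(grid, bm[order], br[order]).mean())
    if np.isclose(means[0], means[1]):
        # coincident branches: first-traversed sweep becomes the upper branch
        first_is_rising = rising[0] or (not falling[0])
        upper_idx = 0 if first_is_rising else 1
    else:
        upper_idx = int(np.argmax(means))
    return branches[upper_idx], branches[1 - upper_idx]


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot about the observed mean."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size == 0 or obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal nonzero length")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R² is undefined for constant observations")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


_A_STARTS = (0.5, 1.0, 2.0)
_M_STARTS = (-2.0, 0.0, 2.0)


def _fit_branch(moment, rom, A, B):
    """Multi-start NLS for one branch's (a1, m1, a2, m2) with A, B fixed."""

    def residual(theta):
        a1, m1, a2, m2 = theta
        return eval_boltzmann(A, B, a1, m1, a2, m2, moment) - rom

    lower = [1e-4, -3 * MOMENT_LIMIT, 1e-4, -3 * MOMENT_LIMIT]
    upper = [50.0, 3 * MOMENT_LIMIT, 50.0, 3 * MOMENT_LIMIT]
    best = None
    for a0 in _A_STARTS:
        for m0 in _M_STARTS:
            try:
                sol = least_squares(
                    residual,
                    x0=[a0, m0, a0, m0],
                    bounds=(lower, upper),
                    xtol=1e-10,
                    ftol=1e-10,
                    gtol=1e-10,
                    max_nfev=5000,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    return best


def fit_hysteresis(loop: MomentRomLoop, r2_threshold: float = R2_THRESHOLD) -> FitResult:
    """Fit the ten-parameter double Boltzmann description to one sampled loop.

    ``A`` and ``B`` are fixed at the sampled RoM extrema; each branch's four
    shape parameters are optimized independently by bounded multi-start
    nonlinear least squares.  ``r2_total`` pools the residuals of both
    branches; the fit is ``accepted`` when it reaches ``r2_threshold``.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError("r2_threshold must lie in (0, 1]")
    A = float(np.min(loop.rom))
    B = float(np.max(loop.rom))
    if np.isclose(A, B):
        raise DegenerateLoopError("flat loop: RoM span is zero, shape unidentifiable")
    (mu, ru), (ml, rl) = split_branches(loop)

    sol_u = _fit_branch(mu, ru, A, B)
    sol_l = _fit_branch(ml, rl, A, B)
    converged = sol_u is not None and sol_l is not None
    if not converged:
        params = HysteresisParams(A, B, 1, 0, 1, 0, 1, 0, 1, 0)
        return FitResult(params, -np.inf, -np.inf, -np.inf, False, False)

    params = HysteresisParams(A, B, *sol_u.x, *sol_l.x)
    pred_u = eval_boltzmann(A, B, *sol_u.x, mu)
    pred_l = eval_boltzmann(A, B, *sol_l.x, ml)
    r2_u = r_squared(ru, pred_u)
    r2_l = r_squared(rl, pred_l)
    r2_tot = r_squared(np.concatenate([ru, rl]), np.concatenate([pred_u, pred_l]))
    accepted = bool(converged and r2_tot >= r2_threshold)
    return FitResult(params, r2_u, r2_l, r2_tot, converged, accepted)


def curve_from_params(params: HysteresisParams, grid) -> dict[str, np.ndarray]:
    """Reconstruct both branch curves of a loop on a moment grid (Nm)."""
    grid = np.asarray(grid, dtype=float)
    if grid.size and np.max(np.abs(grid)) > MOMENT_LIMIT + 1e-9:
        raise ValueError(f"grid must lie within ±{MOMENT_LIMIT} Nm")
    out = {}
    for branch in ("upper", "lower"):
        a1, m1, a2, m2 = params.branch(branch)
        out[branch] = eval_boltzmann(params.A, params.B, a1, m1, a2, m2, grid)
    return out


def sample_loop(
    params: HysteresisParams,
    n_per_branch: int = 100,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    cycle_index: int = 1,
) -> MomentRomLoop:
    """Sample a loop from known parameters in acquisition order.

    The moment sweeps −7.5 → +7.5 Nm along the lower (loading) branch and back
    along the upper (unloading) branch; optional Gaussian observation noise
    (degrees) is added to the RoM samples.
    """
    m_up = np.linspace(-MOMENT_LIMIT, MOMENT_LIMIT, n_per_branch)
    m_down = m_up[::-1]
    r_load = eval_boltzmann(params.A, params.B, *params.branch("lower"), m_up)
    r_unload = eval_boltzmann(params.A, params.B, *params.branch("upper"), m_down)
    moment = np.concatenate([m_up, m_down])
    rom = np.concatenate([r_load, r_unload])
    if noise_sigma > 0:
        rng = np.random.default_rng() if rng is None else rng
        rom = rom + rng.normal(0.0, noise_sigma, rom.shape)
    return MomentRomLoop(moment=moment, rom=rom, cycle_index=cycle_index)
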