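"""Steady-state integration and dose-response construction.

Steady states are computed by marching the model ODEs from a
conservation-consistent "off" initial condition (all protein in the free,
unmodified forms) until the scaled derivative norm

    max_i |dy_i/dt| / max(|y_i|, floor)

drops below ``steady_tol``.  Two engines are available:

``implicit`` (default)
    a compiled pseudo-transient backward-Euler marcher with analytic
    Jacobians (see :mod:`opposer._kernels`) -- fast enough for Monte-Carlo
    screening of hundreds of thousands of stiff steady-state problems;
``lsoda``
    scipy's LSODA integrator with horizon doubling, kept as an independent
    trajectory-faithful reference.

Dose-response profiles recompute every grid point from the cold initial
condition by default, so verdicts cannot depend on sweep direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from ._kernels import CC_ID, CYCLE_ID, FERRELL_ID, MM_ID
from .models import CC_SPECIES, REDUCED_SPECIES, RateParameters

__all__ = [
    "SteadyStateOptions",
    "SteadyStateResult",
    "DoseResponse",
    "SolverFailureError",
    "initial_state",
    "integrate_to_steady",
    "dose_response",
    "single_cycle_dose_response",
]

_MODEL_IDS = {"complex_complete": CC_ID, "michaelian": MM_ID, "ferrell": FERRELL_ID}

CYCLE_SPECIES = ("A", "A_star", "I", "E", "C1", "C2")


class SolverFailureError(RuntimeError):
    """Integration failed (step-size collapse), as distinct from simply not
    reaching steadiness within the horizon."""


@dataclass(frozen=True)
class SteadyStateOptions:
    """Tolerances and limits for the steady-state march.

    ``steady_tol`` is the scaled derivative norm below which a state counts
    as steady; ``floor`` is the concentration floor used in the scaling.
    ``neg_clamp_frac`` sets the negativity policy: undershoots smaller than
    ``neg_clamp_frac`` x (smallest conserved total) are clamped to zero in
    the reported state, anything larger is a solver failure.
    """

    steady_tol: float = 1e-6
    floor: float = 1e-12
    t_max: float = 1e10
    max_steps: int = 3000
    newton_tol: float = 1e-11
    method: str = "implicit"  # "implicit" | "lsoda"
    rtol: float = 1e-8
    atol: float = 1e-12
    neg_clamp_frac: float = 1e-3

    def halved(self) -> "SteadyStateOptions":
        """The same options with all solve tolerances halved (for the
        scheme-independence check)."""
        return replace(
            self,
            steady_tol=self.steady_tol / 2,
            newton_tol=self.newton_tol / 2,
            rtol=self.rtol / 2,
            atol=self.atol / 2,
        )


DEFAULT_OPTIONS = SteadyStateOptions()


@dataclass(frozen=True)
class SteadyStateResult:
    """A (possibly non-converged) steady state of one model variant."""

    model: str
    state: np.ndarray
    species: tuple
    converged: bool
    residual_norm: float
    t_final: float

    def as_series(self) -> pd.Series:
        return pd.Series(dict(zip(self.species, self.state)))

    def __getitem__(self, name: str) -> float:
        return float(self.state[self.species.index(name)])


@dataclass
class DoseResponse:
    """Steady-state dose-response table over a strictly increasing input grid.

    ``table`` has one row per input with columns for every species, derived
    pools where applicable, and per-point ``converged`` / ``residual`` /
    ``t_final`` diagnostics.
    """

    model: str
    params: RateParameters
    table: pd.DataFrame

    @property
    def inputs(self) -> np.ndarray:
        return self.table["I_tot"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)

    def column(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy()

    def to_csv(self, path, **kwargs) -> None:
        self.table.to_csv(path, index=False, **kwargs)


def initial_state(model: str, params: RateParameters) -> np.ndarray:
    """Conservation-consistent 'off' initial condition.

    Complex-complete: all protein free and unmodified (``A = A_tot``,
    ``B = B_tot``, ``I = I_tot``, ``E1 = E_tot``, everything else zero).
    Reduced models: ``A* = B* = 0``.
    """
    if model == "complex_complete":
        y0 = np.zeros(10)
        y0[0] = params.A_tot
        y0[2] = params.B_tot
        y0[4] = params.I_tot
        y0[5] = params.E_tot
        return y0
    if model in ("michaelian", "ferrell"):
        return np.zeros(2)
    raise ValueError(f"unknown model {model!r}; expected one of {sorted(_MODEL_IDS)}")


def _pack(model: str, params: RateParameters) -> np.ndarray:
    if model == "complex_complete":
        return params.cc_vector()
    return params.mm_vector()


def _totals(model: str, params: RateParameters) -> np.ndarray:
    if model == "complex_complete":
        return np.array([params.A_tot, params.B_tot, max(params.I_tot, 0.0),
                         params.E_tot])
    return np.array([params.A_tot, params.B_tot])


def _lsoda_march(mid: int, y0: np.ndarray, p: np.ndarray,
                 opts: SteadyStateOptions):
    from scipy.integrate import solve_ivp

    n = y0.size
    f = np.empty(n)
    J = np.empty((n, n))

    def fun(t, y):
        _kernels.rhs(mid, y, p, f)
        return f.copy()

    def jfun(t, y):
        _kernels.jac(mid, y, p, J)
        return J.copy()

    y = y0.copy()
    _kernels.jac(mid, y, p, J)
    jmax = max(np.max(np.abs(np.diag(J))), 1e-12)
    t_end = 10.0 / jmax
    t = 0.0
    res = _kernels.residual_norm(mid, y, p, opts.floor)
    while t < opts.t_max:
        sol = solve_ivp(fun, (0.0, t_end), y, method="LSODA", jac=jfun,
                        rtol=opts.rtol, atol=opts.atol, t_eval=(t_end,))
        if not sol.success:
            return y, -1, res, t
        y = sol.y[:, -1]
        t += t_end
        t_end *= 2.0
        res = _kernels.residual_norm(mid, y, p, opts.floor)
        if res <= opts.steady_tol:
            return y, 1, res, t
    return y, 0, res, t


def _solve(model: str, mid: int, y0: np.ndarray, p: np.ndarray,
           totals: np.ndarray, opts: SteadyStateOptions):
    neg_allow = opts.neg_clamp_frac * float(np.min(totals[totals > 0]))
    if opts.method == "implicit":
        y, status, res, t = _kernels.steady_state_kernel(
            mid, np.asarray(y0, dtype=np.float64), p,
            opts.steady_tol, opts.floor, opts.t_max, opts.max_steps,
            opts.newton_tol, neg_allow,
        )
    elif opts.method == "lsoda":
        y, status, res, t = _lsoda_march(mid, np.asarray(y0, float), p, opts)
        if np.min(y) < -neg_allow:
            status = -1
    else:
        raise ValueError(f"unknown method {opts.method!r}")
    # clamp sub-threshold negative undershoots; larger ones already failed
    y = np.where((y < 0) & (y > -neg_allow), 0.0, y)
    return y, status, res, t


def integrate_to_steady(
    model: str,
    params: RateParameters,
    options: SteadyStateOptions | None = None,
    y0: np.ndarray | None = None,
    raise_on_failure: bool = True,
) -> SteadyStateResult:
    """Integrate one model variant from ``y0`` (default: the 'off' state)
    until the steadiness criterion is met.

    A step-size collapse raises :class:`SolverFailureError` (or, with
    ``raise_on_failure=False``, returns a non-converged result), which is
    distinct from an exhausted horizon (``converged=False``).
    """
    opts = options or DEFAULT_OPTIONS
    if model not in _MODEL_IDS:
        raise ValueError(f"unknown model {model!r}; expected one of {sorted(_MODEL_IDS)}")
    mid = _MODEL_IDS[model]
    if y0 is None:
        y0 = initial_state(model, params)
    p = _pack(model, params)
    totals = _totals(model, params)
    y, status, res, t = _solve(model, mid, y0, p, totals, opts)
    if status == -1 and raise_on_failure:
        raise SolverFailureError(
            f"step-size collapse for model {model!r} at I_tot={params.I_tot!r}"
        )
    species = CC_SPECIES if model == "complex_complete" else REDUCED_SPECIES
    return SteadyStateResult(
        model=model,
        state=np.asarray(y, dtype=float),
        species=species,
        converged=status == 1,
        residual_norm=float(res),
        t_final=float(t),
    )


def _validate_grid(input_grid) -> np.ndarray:
    grid = np.asarray(input_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise ValueError("input grid must be a 1-D sequence")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("input grid must be strictly increasing")
    if np.any(grid < 0):
        raise ValueError("input abundances must be non-negative")
    return grid


def default_input_grid(n: int = 60, lo: float = 1e-3, hi: float = 1e4) -> np.ndarray:
    """Logarithmic default input grid used for screening."""
    return np.geomspace(lo, hi, n)


def dose_response(
    model: str,
    params: RateParameters,
    input_grid: Sequence[float],
    options: SteadyStateOptions | None = None,
    warm_start: bool = False,
) -> DoseResponse:
    """One steady state per input abundance.

    Per-point solver failures are recorded (``converged=False``) without
    aborting the profile.  ``warm_start`` continues each solve from the
    previous steady state; it is off by default so that verdicts are
    independent of sweep direction.
    """
    opts = options or DEFAULT_OPTIONS
    grid = _validate_grid(input_grid)
    if model not in _MODEL_IDS:
        raise ValueError(f"unknown model {model!r}; expected one of {sorted(_MODEL_IDS)}")
    mid = _MODEL_IDS[model]
    species = CC_SPECIES if model == "complex_complete" else REDUCED_SPECIES
    n = len(species)
    states = np.empty((grid.size, n))
    conv = np.zeros(grid.size, dtype=bool)
    resid = np.empty(grid.size)
    tfin = np.empty(grid.size)
    prev = None
    for idx, I in enumerate(grid):
        pi = params.with_input(I)
        y0 = prev if (warm_start and prev is not None) else initial_state(model, pi)
        p = _pack(model, pi)
        y, status, res, t = _solve(model, mid, y0, p, _totals(model, pi), opts)
        states[idx] = y
        conv[idx] = status == 1
        resid[idx] = res
        tfin[idx] = t
        if status == 1:
            prev = y
    table = pd.DataFrame(states, columns=list(species))
    table.insert(0, "I_tot", grid)
    if model == "complex_complete":
        table["AS_star"] = table["A_star"] + table["C3"]
        table["BS_star"] = table["B_star"] + table["C2"]
    table["converged"] = conv
    table["residual"] = resid
    table["t_final"] = tfin
    return DoseResponse(model=model, params=params, table=table)


@dataclass(frozen=True)
class CycleParameters:
    """Parameters of the isolated input/output cycle (a single reversible
    covalent-modification cycle, complexes retained)."""

    k_A1: float
    k_A2: float
    K_A1: float
    K_A2: float
    A_tot: float
    d_A1: float = 1.0
    d_A2: float = 1.0

    def vector(self, I_tot: float, enzyme: float) -> np.ndarray:
        a_A1 = (self.d_A1 + self.k_A1) / self.K_A1
        a_A2 = (self.d_A2 + self.k_A2) / self.K_A2
        return np.array([a_A1, a_A2, self.d_A1, self.d_A2,
                         self.k_A1, self.k_A2, self.A_tot, I_tot, enzyme])


def single_cycle_dose_response(
    params: CycleParameters,
    enzyme_abundance: float,
    input_grid: Sequence[float],
    options: SteadyStateOptions | None = None,
) -> pd.DataFrame:
    """Dose-response of the isolated input/output cycle.

    ``enzyme_abundance`` is the total abundance of the deactivating enzyme
    (the role played by the ``BS*`` pool in the full network).  The output
    pool ``AS_star = A* + C2`` reaches half-maximum near
    ``I_tot = (k_A2/k_A1) * enzyme_abundance`` in the zero-order regime.
    """
    if enzyme_abundance < 0:
        raise ValueError("enzyme abundance must be non-negative")
    opts = options or DEFAULT_OPTIONS
    grid = _validate_grid(input_grid)
    rows = np.empty((grid.size, 6))
    conv = np.zeros(grid.size, dtype=bool)
    resid = np.empty(grid.size)
    for idx, I in enumerate(grid):
        p = params.vector(I, enzyme_abundance)
        y0 = np.zeros(6)
        y0[0] = params.A_tot
        y0[2] = I
        y0[3] = enzyme_abundance
        totals = np.array([params.A_tot, max(I, 0.0), max(enzyme_abundance, 0.0)])
        y, status, res, _t = _solve("cycle", CYCLE_ID, y0, p, totals, opts)
        rows[idx] = y
        conv[idx] = status == 1
        resid[idx] = res
    table = pd.DataFrame(rows, columns=list(CYCLE_SPECIES))
    table.insert(0, "I_tot", grid)
    table["AS_star"] = table["A_star"] + table["C2"]
    table["converged"] = conv
    table["residual"] = resid
    return table
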