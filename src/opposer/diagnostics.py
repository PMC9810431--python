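"""Constraint checks and validity diagnostics for sweep outcomes.

Two families of diagnostics explain which sampled parameter sets can and
cannot adapt:

* abundance constraints -- RPA requires ``A_tot > (k_B2/k_B1) E_tot`` (the
  output protein must be able to reach the setpoint at all) and, once
  complexes are retained, ``B_tot > (1 + k_B2/k_B1) E_tot`` (enough opposer
  protein to fill ``C3 = sigma`` and ``C4 = E_tot`` and still leave a
  non-trivial actuator pool ``BS*``);
* the total quasi-steady-state (tQSSA) validity condition
  ``[ES]^2 << [E][S]`` for each enzyme-substrate pair, which the Michaelian
  reduction implicitly assumes.  At RPA steady states the condition fails
  outright for the ``C3`` and ``C4`` pairs (their free-enzyme or
  free-substrate concentrations vanish while the complex does not).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import RateParameters

__all__ = ["ConstraintReport", "TQSSAReport", "check_constraints", "tqssa_check"]

#: enzyme, substrate and complex column names per tQSSA pair
TQSSA_PAIRS = {
    "C1": ("I", "A"),
    "C2": ("B_star", "A_star"),
    "C3": ("A_star", "B"),
    "C4": ("E1", "B_star"),
}


@dataclass(frozen=True)
class ConstraintReport:
    """Abundance constraints evaluated for one parameter set."""

    A_tot_constraint: bool  # A_tot > (k_B2/k_B1) E_tot
    B_tot_constraint: bool  # B_tot > (1 + k_B2/k_B1) E_tot
    BS_star_max: float      # B_tot - E_tot (1 + k_B2/k_B1)


@dataclass
class TQSSAReport:
    """tQSSA validity per enzyme-substrate pair at one steady state."""

    table: pd.DataFrame  # rows C1..C4: E, S, ES, es_squared, e_times_s, ratio, holds

    def holds(self, pair: str) -> bool:
        return bool(self.table.loc[pair, "holds"])

    def ratio(self, pair: str) -> float:
        return float(self.table.loc[pair, "ratio"])


def check_constraints(params: RateParameters) -> ConstraintReport:
    """Evaluate both abundance constraints (strict inequalities)."""
    ratio = params.k_B2 / params.k_B1
    bs_max = params.B_tot - params.E_tot * (1.0 + ratio)
    return ConstraintReport(
        A_tot_constraint=params.A_tot > ratio * params.E_tot,
        B_tot_constraint=params.B_tot > (1.0 + ratio) * params.E_tot,
        BS_star_max=float(bs_max),
    )


def tqssa_check(state, cut: float = 0.1) -> TQSSAReport:
    """Evaluate ``[ES]^2`` against ``[E][S]`` for every pair at one
    (converged) complex-complete steady state.

    The ratio is ``inf`` when the free product vanishes while the complex
    does not -- the maximal failure mode seen inside RPA bands.  ``cut`` is
    the summary threshold operationalizing "much smaller"; raw values are
    always reported so the cut is cosmetic.
    """
    y = np.asarray(getattr(state, "state", state), dtype=float)
    if hasattr(state, "as_array"):
        y = state.as_array()
    if y.shape != (10,):
        raise ValueError("tQSSA check requires a full 10-species state")
    names = ("A", "A_star", "B", "B_star", "I", "E1", "C1", "C2", "C3", "C4")
    v = dict(zip(names, y))
    rows = []
    for pair, (e, s) in TQSSA_PAIRS.items():
        es = v[pair]
        prod = v[e] * v[s]
        sq = es ** 2
        if prod > 0:
            ratio = sq / prod
        else:
            ratio = 0.0 if sq == 0 else np.inf
        rows.append({
            "pair": pair, "E": v[e], "S": v[s], "ES": es,
            "es_squared": sq, "e_times_s": prod, "ratio": ratio,
            "holds": ratio < cut,
        })
    return TQSSAReport(table=pd.DataFrame(rows).set_index("pair"))
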