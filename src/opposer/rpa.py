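"""Operational detection of robust perfect adaptation (RPA) on dose-response
profiles.

A candidate variable exhibits RPA over an input window when, between
successive grid inputs, (a) its steady-state value is unchanging within a
flatness tolerance, (b) it lies within a band around the estimated setpoint
``sigma = (k_B2/k_B1) * E_tot``, and (c) some *other* variable -- the
actuator -- changes by at least a minimum amount across the same inputs.
Criterion (c) separates true adaptation from the 'trivial' flatness that
occurs when a variable is pinned at its conversion potential (the maximum
value the conservation laws allow).

``I_S`` is the smallest grid input satisfying (a)-(c); ``I_F`` is the first
later input violating any of them; ``range = I_F - I_S``.  Both are reported
as grid values -- no sub-grid interpolation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import RateParameters

__all__ = [
    "DetectionTolerances",
    "RPAAssessment",
    "setpoint",
    "conversion_potential",
    "detect_rpa",
    "rpa_state_signature",
    "CANDIDATE_ACTUATOR",
]

#: standard candidate -> actuator pairing per model variant
CANDIDATE_ACTUATOR = {
    "michaelian": (("A_star", "B_star"),),
    "ferrell": (("A_star", "B_star"),),
    "complex_complete": (
        ("A_star", "BS_star"),
        ("AS_star", "BS_star"),
        ("C3", "BS_star"),
    ),
}

#: how close (relatively) the actuator must sit to its conversion potential
#: for a flat actuator to be classified as 'trivial' RPA
_PINNED_RTOL = 1e-3


@dataclass(frozen=True)
class DetectionTolerances:
    """Relative tolerances of the RPA detector (all strict positive fractions).

    ``setpoint_band``: half-width of the tracking band around sigma,
    relative to sigma.  ``flatness_band``: maximum relative change of the
    candidate between successive grid inputs.  ``actuator_min_change``:
    minimum relative change of the actuator across the same inputs.
    """

    setpoint_band: float = 0.01
    flatness_band: float = 0.02
    actuator_min_change: float = 0.01

    def __post_init__(self) -> None:
        for name in ("setpoint_band", "flatness_band", "actuator_min_change"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be a fraction in (0, 1), got {v!r}")


DEFAULT_TOLERANCES = DetectionTolerances()


@dataclass(frozen=True)
class RPAAssessment:
    """Verdict of the RPA detector for one (model, parameter set, candidate)."""

    model: str
    candidate: str
    actuator: str
    sigma: float
    is_rpa: bool
    I_S: float
    I_F: float
    range: float
    failure_reason: str  # none | never-tracks | trivial-only | actuator-flat
    #                      | non-convergence | censored
    censored: bool = False  # detection conditions still held at the last grid point
    n_nonconverged: int = 0


def setpoint(params: RateParameters) -> float:
    """The estimated RPA setpoint ``sigma = (k_B2 / k_B1) * E_tot``.

    Derived from the opposer-cycle steady state in the zero-order limit
    ``K_B1, K_B2 -> 0``, where the balance tends to
    ``0 = k_B1 A* - k_B2 E_tot``.
    """
    return (params.k_B2 / params.k_B1) * params.E_tot


def conversion_potential(variable: str, params: RateParameters) -> float:
    """Maximum steady-state-feasible value of a species or pool, from the
    conservation laws.

    For the opposer output pool ``BS* = B* + C2`` the bound assumes
    RPA-permissive conditions (``C3 = sigma``, ``C4 = E_tot``), giving
    ``B_tot - E_tot (1 + k_B2/k_B1)``; it is positive exactly when the
    abundance constraint on ``B_tot`` holds.
    """
    if variable in ("A_star", "AS_star", "C3"):
        return params.A_tot
    if variable == "B_star":
        return params.B_tot
    if variable == "BS_star":
        return params.B_tot - params.E_tot * (1.0 + params.k_B2 / params.k_B1)
    raise ValueError(f"unknown variable {variable!r}")


def detect_rpa(
    profile,
    candidate: str,
    actuator: str,
    sigma: float | None = None,
    tolerances: DetectionTolerances | None = None,
    actuator_potential: float | None = None,
) -> RPAAssessment:
    """Apply the RPA criteria to one dose-response profile.

    ``profile`` is a :class:`~opposer.steady_state.DoseResponse` (or its
    table).  ``sigma`` and the actuator's conversion potential default to the
    values derived from the profile's parameters.
    """
    tol = tolerances or DEFAULT_TOLERANCES
    table = getattr(profile, "table", profile)
    params = getattr(profile, "params", None)
    model = getattr(profile, "model", "?")
    if sigma is None:
        if params is None:
            raise ValueError("sigma must be given when profile has no parameters")
        sigma = setpoint(params)
    if actuator_potential is None and params is not None:
        actuator_potential = conversion_potential(actuator, params)

    candidate_potential = None
    if params is not None:
        candidate_potential = conversion_potential(candidate, params)

    inputs = table["I_tot"].to_numpy(dtype=float)
    y = table[candidate].to_numpy(dtype=float)
    b = table[actuator].to_numpy(dtype=float)
    conv = (
        table["converged"].to_numpy(dtype=bool)
        if "converged" in table
        else np.ones(inputs.size, dtype=bool)
    )
    m = inputs.size
    if m < 3:
        raise ValueError("profile needs at least 3 grid points")

    def verdict(is_rpa, I_S, I_F, reason, censored=False):
        rng = I_F - I_S if is_rpa else 0.0
        return RPAAssessment(
            model=model, candidate=candidate, actuator=actuator,
            sigma=float(sigma), is_rpa=is_rpa, I_S=float(I_S), I_F=float(I_F),
            range=float(rng), failure_reason=reason, censored=censored,
            n_nonconverged=int(m - conv.sum()),
        )

    if not conv.all():
        return verdict(False, np.nan, np.nan, "non-convergence")
    if sigma <= 0:
        return verdict(False, np.nan, np.nan, "never-tracks")
    if candidate_potential is not None and candidate_potential < sigma:
        # the candidate's conversion potential lies below the setpoint, so it
        # can never truly attain sigma; apparent tracking inside the finite
        # band is a saturation artifact
        return verdict(False, np.nan, np.nan, "never-tracks")

    floor = 1e-12
    if actuator_potential is not None and actuator_potential > 0:
        bfloor = 1e-6 * actuator_potential
    else:
        bfloor = floor

    dy = np.abs(np.diff(y))
    db = np.abs(np.diff(b))
    yscale = np.maximum(np.abs(y[:-1]), floor)
    bscale = np.maximum(np.abs(b[:-1]), bfloor)
    flat = dy <= tol.flatness_band * yscale
    # the candidate must sit inside the setpoint band at BOTH successive
    # inputs: a slow monotone pass-through of the band (e.g. saturation of
    # A* towards A_tot with sigma coincidentally nearby) is not tracking
    in_band = np.abs(y - sigma) <= tol.setpoint_band * sigma
    track = in_band[:-1] & in_band[1:]
    moving = db >= tol.actuator_min_change * bscale
    cond = flat & track & moving

    hits = np.flatnonzero(cond)
    if hits.size == 0:
        ft = np.flatnonzero(flat & track)
        if ft.size == 0:
            return verdict(False, np.nan, np.nan, "never-tracks")
        pinned = (
            actuator_potential is not None
            and actuator_potential > 0
            and bool(
                np.all(
                    np.abs(b[ft] - actuator_potential)
                    <= _PINNED_RTOL * actuator_potential
                )
            )
        )
        return verdict(False, np.nan, np.nan,
                       "trivial-only" if pinned else "actuator-flat")

    s = int(hits[0])
    later = np.flatnonzero(~cond[s + 1:])
    if later.size == 0:
        # conditions still held at the final grid pair, so I_F was never
        # observed: the band is right-censored by the examined input window
        # and the set is not counted as RPA-positive (I_F is required)
        return verdict(False, inputs[s], np.nan, "censored", censored=True)
    e = s + 1 + int(later[0])

    # trivial-RPA exclusions: flatness that merely reflects a protein sitting
    # at its maximum steady-state-feasible value is not adaptation.
    band = slice(s, e)
    if candidate_potential is not None and candidate_potential > 0:
        if np.all(np.abs(y[band] - candidate_potential)
                  <= _PINNED_RTOL * candidate_potential):
            return verdict(False, np.nan, np.nan, "trivial-only")
    if actuator_potential is not None:
        # the actuator must stay below its conversion potential throughout
        # the band (2% headroom for the finite detection tolerances); when
        # the potential is non-positive no non-trivial actuator swing exists
        ceiling = actuator_potential + 0.02 * max(actuator_potential, 0.0)
        if np.any(b[band] > ceiling):
            return verdict(False, np.nan, np.nan, "trivial-only")
    return verdict(True, inputs[s], inputs[e], "none")


def rpa_state_signature(state, params: RateParameters, sigma: float | None = None,
                        band: float = 0.01) -> dict[str, bool]:
    """Flags for the characteristic complex-complete RPA steady state.

    Inside an RPA band the opposer cycle's enzymes are fully saturated:
    ``AS* = C3 = sigma`` with ``A* = 0``, and ``C4 = E_tot`` with
    ``E1 = 0``.  Each flag checks its condition within the relative ``band``.
    """
    y = np.asarray(getattr(state, "state", state), dtype=float)
    if hasattr(state, "as_array"):
        y = state.as_array()
    if y.shape != (10,):
        raise ValueError("signature requires a full 10-species state")
    if sigma is None:
        sigma = setpoint(params)
    A_star, C3, C4, E1 = y[1], y[8], y[9], y[5]
    AS_star = A_star + C3
    E_tot = params.E_tot
    return {
        "AS_star_tracks": bool(abs(AS_star - sigma) <= band * sigma) if sigma > 0 else False,
        "C3_tracks": bool(abs(C3 - sigma) <= band * sigma) if sigma > 0 else False,
        "A_star_zero": bool(A_star <= band * sigma) if sigma > 0 else bool(A_star == 0),
        "C4_saturated": bool(abs(C4 - E_tot) <= band * E_tot),
        "E1_zero": bool(E1 <= band * E_tot),
    }
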