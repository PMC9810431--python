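"""Model definitions for a two-protein negative-feedback (Opposer) module.

The network couples two covalent-modification cycles: an input/output cycle
in which the input enzyme ``I`` activates protein ``A`` (``A -> A*``) and the
active opposer protein ``B*`` deactivates it, and an opposer cycle in which
``A*`` activates ``B`` (``B -> B*``) while a constitutive phosphatase ``E1``
deactivates ``B*``.  Zero-order ultrasensitivity in the opposer cycle turns
the feedback loop into an (approximate) integral controller whose setpoint is
``sigma = (k_B2 / k_B1) * E_tot``.

Three variants of the dynamics are provided:

``complex_complete``
    Full mass-action kinetics retaining every enzyme-substrate complex
    (``C1 = I.A``, ``C2 = A*.B*``, ``C3 = A*.B``, ``C4 = B*.E1``) as an
    explicit species -- ten species in total, with four linear conservation
    laws.
``michaelian``
    The classical two-variable reduction with Michaelis-Menten kinetics on
    both cycles and all complexes neglected.
``ferrell``
    As ``michaelian`` but with simple mass-action kinetics (no saturation)
    on the input/output cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "MODEL_NAMES",
    "CC_SPECIES",
    "REDUCED_SPECIES",
    "RateParameters",
    "FullState",
    "ReducedState",
    "Pools",
    "InvalidStateError",
    "NumericalGuardError",
    "cc_rhs",
    "mm_rhs",
    "ferrell_rhs",
    "conservation_residuals",
    "pools",
]

MODEL_NAMES = ("complex_complete", "michaelian", "ferrell")

#: species order used for every array representation of the full model state
CC_SPECIES = ("A", "A_star", "B", "B_star", "I", "E1", "C1", "C2", "C3", "C4")
REDUCED_SPECIES = ("A_star", "B_star")

_CYCLES = ("A1", "A2", "B1", "B2")


class InvalidStateError(ValueError):
    """Raised when a state vector contains non-finite entries."""


class NumericalGuardError(FloatingPointError):
    """Raised when a Michaelian denominator underflows to (near) zero."""


@dataclass(frozen=True)
class RateParameters:
    """Kinetic constants and total abundances for all model variants.

    Each enzymatic step ``i in {A1, A2, B1, B2}`` carries an association rate
    ``a_i`` (conc^-1 time^-1), a dissociation rate ``d_i`` (time^-1), a
    catalytic rate ``k_i`` (time^-1) and a Michaelis constant
    ``K_i = (d_i + k_i) / a_i`` (conc).  If the ``a_i`` are omitted they are
    derived from the Michaelis constants via ``a_i = (d_i + k_i) / K_i`` --
    the convention used for every printed parameter regime.
    """

    k_A1: float
    k_A2: float
    k_B1: float
    k_B2: float
    K_A1: float
    K_A2: float
    K_B1: float
    K_B2: float
    A_tot: float
    B_tot: float
    E_tot: float
    I_tot: float = 0.0
    d_A1: float = 1.0
    d_A2: float = 1.0
    d_B1: float = 1.0
    d_B2: float = 1.0
    a_A1: float | None = None
    a_A2: float | None = None
    a_B1: float | None = None
    a_B2: float | None = None

    def __post_init__(self) -> None:
        for i in _CYCLES:
            a = getattr(self, f"a_{i}")
            if a is None:
                a = (getattr(self, f"d_{i}") + getattr(self, f"k_{i}")) / getattr(
                    self, f"K_{i}"
                )
                object.__setattr__(self, f"a_{i}", float(a))
        for name in (
            "k_A1", "k_A2", "k_B1", "k_B2",
            "K_A1", "K_A2", "K_B1", "K_B2",
            "d_A1", "d_A2", "d_B1", "d_B2",
            "a_A1", "a_A2", "a_B1", "a_B2",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        for name in ("A_tot", "B_tot", "E_tot"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if not np.isfinite(self.I_tot) or self.I_tot < 0:
            raise ValueError(f"I_tot must be non-negative, got {self.I_tot!r}")

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_dict(cls, record: Mapping[str, float]) -> "RateParameters":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(record) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in record.items()})

    def to_dict(self) -> dict[str, float]:
        return {
            name: float(getattr(self, name))
            for name in self.__dataclass_fields__  # type: ignore[attr-defined]
        }

    def with_input(self, I_tot: float) -> "RateParameters":
        return replace(self, I_tot=float(I_tot))

    # -- derived quantities -------------------------------------------------

    @property
    def sigma(self) -> float:
        """The estimated RPA setpoint ``(k_B2 / k_B1) * E_tot``."""
        return (self.k_B2 / self.k_B1) * self.E_tot

    def michaelis_consistent(self, rtol: float = 1e-12) -> bool:
        """Whether ``a_i == (d_i + k_i) / K_i`` holds for every cycle."""
        for i in _CYCLES:
            a = getattr(self, f"a_{i}")
            want = (getattr(self, f"d_{i}") + getattr(self, f"k_{i}")) / getattr(
                self, f"K_{i}"
            )
            if abs(a - want) > rtol * abs(want):
                return False
        return True

    # -- packed vectors for the numerical kernels ---------------------------

    def cc_vector(self) -> np.ndarray:
        return np.array(
            [
                self.a_A1, self.a_A2, self.a_B1, self.a_B2,
                self.d_A1, self.d_A2, self.d_B1, self.d_B2,
                self.k_A1, self.k_A2, self.k_B1, self.k_B2,
                self.A_tot, self.B_tot, self.I_tot, self.E_tot,
            ],
            dtype=np.float64,
        )

    def mm_vector(self) -> np.ndarray:
        return np.array(
            [
                self.k_A1, self.k_A2, self.k_B1, self.k_B2,
                self.K_A1, self.K_A2, self.K_B1, self.K_B2,
                self.A_tot, self.B_tot, self.E_tot, self.I_tot,
            ],
            dtype=np.float64,
        )


@dataclass(frozen=True)
class FullState:
    """Ten-species state of the complex-complete model (concentrations)."""

    A: float
    A_star: float
    B: float
    B_star: float
    I: float
    E1: float
    C1: float
    C2: float
    C3: float
    C4: float

    @classmethod
    def from_array(cls, y: Iterable[float]) -> "FullState":
        y = np.asarray(y, dtype=float)
        if y.shape != (10,):
            raise ValueError(f"expected 10 species, got shape {y.shape}")
        return cls(*(float(v) for v in y))

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in CC_SPECIES], dtype=np.float64)


@dataclass(frozen=True)
class ReducedState:
    """Two-variable state of the Michaelian / Ferrell models."""

    A_star: float
    B_star: float

    @classmethod
    def from_array(cls, y: Iterable[float]) -> "ReducedState":
        y = np.asarray(y, dtype=float)
        if y.shape != (2,):
            raise ValueError(f"expected 2 species, got shape {y.shape}")
        return cls(float(y[0]), float(y[1]))

    def as_array(self) -> np.ndarray:
        return np.array([self.A_star, self.B_star], dtype=np.float64)


@dataclass(frozen=True)
class Pools:
    """Total active pools: free active protein plus downstream complex."""

    AS_star: float  # A* + C3 -- the total input to the opposer cycle
    BS_star: float  # B* + C2 -- the total output of the opposer cycle


def _as_array(state, n: int) -> np.ndarray:
    if isinstance(state, FullState):
        y = state.as_array()
    elif isinstance(state, ReducedState):
        y = state.as_array()
    else:
        y = np.asarray(state, dtype=np.float64)
    if y.shape != (n,):
        raise ValueError(f"expected state of length {n}, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise InvalidStateError(f"non-finite state: {y!r}")
    return y


def cc_rhs(state, params: RateParameters) -> np.ndarray:
    """Mass-action time derivatives of the complex-complete model.

    Species order follows :data:`CC_SPECIES`.  The returned derivatives
    satisfy the four conservation identities exactly: the sums over the
    A-containing, B-containing, I-containing and E-containing species are
    identically zero.
    """
    y = _as_array(state, 10)
    A, As, B, Bs, I, E1, C1, C2, C3, C4 = y
    p = params
    v1 = p.a_A1 * A * I          # I + A  association
    v2 = p.a_A2 * As * Bs        # B* + A* association
    v3 = p.a_B1 * As * B         # A* + B  association
    v4 = p.a_B2 * Bs * E1        # E1 + B* association
    return np.array(
        [
            p.d_A1 * C1 + p.k_A2 * C2 - v1,
            p.d_A2 * C2 + p.k_A1 * C1 + p.d_B1 * C3 + p.k_B1 * C3 - v2 - v3,
            p.d_B1 * C3 + p.k_B2 * C4 - v3,
            (p.d_A2 + p.k_A2) * C2 + p.d_B2 * C4 + p.k_B1 * C3 - v2 - v4,
            (p.d_A1 + p.k_A1) * C1 - v1,
            (p.d_B2 + p.k_B2) * C4 - v4,
            v1 - (p.d_A1 + p.k_A1) * C1,
            v2 - (p.d_A2 + p.k_A2) * C2,
            v3 - (p.d_B1 + p.k_B1) * C3,
            v4 - (p.d_B2 + p.k_B2) * C4,
        ]
    )


_DENOM_FLOOR = 1e-300


def mm_rhs(state, params: RateParameters, input: float | None = None) -> np.ndarray:
    """Michaelis-Menten time derivatives of the two-variable reduction.

    ``input`` overrides ``params.I_tot`` when given (the reduced models treat
    the input abundance as a fixed parameter, not a dynamic species).
    """
    y = _as_array(state, 2)
    As, Bs = y
    p = params
    I_tot = p.I_tot if input is None else float(input)
    den1 = p.K_A1 + p.A_tot - As
    den2 = p.K_A2 + As
    den3 = p.K_B1 + p.B_tot - Bs
    den4 = p.K_B2 + Bs
    for den in (den1, den2, den3, den4):
        if abs(den) < _DENOM_FLOOR:
            raise NumericalGuardError(f"Michaelian denominator underflow: {den!r}")
    dAs = p.k_A1 * I_tot * (p.A_tot - As) / den1 - p.k_A2 * Bs * As / den2
    dBs = p.k_B1 * As * (p.B_tot - Bs) / den3 - p.k_B2 * p.E_tot * Bs / den4
    return np.array([dAs, dBs])


def ferrell_rhs(state, params: RateParameters, input: float | None = None) -> np.ndarray:
    """Hybrid reduction: mass-action input/output cycle, Michaelian opposer."""
    y = _as_array(state, 2)
    As, Bs = y
    p = params
    I_tot = p.I_tot if input is None else float(input)
    den3 = p.K_B1 + p.B_tot - Bs
    den4 = p.K_B2 + Bs
    for den in (den3, den4):
        if abs(den) < _DENOM_FLOOR:
            raise NumericalGuardError(f"Michaelian denominator underflow: {den!r}")
    dAs = p.k_A1 * I_tot * (p.A_tot - As) - p.k_A2 * Bs * As
    dBs = p.k_B1 * As * (p.B_tot - Bs) / den3 - p.k_B2 * p.E_tot * Bs / den4
    return np.array([dAs, dBs])


def conservation_residuals(state, params: RateParameters) -> np.ndarray:
    """Residuals of the four mass-conservation relations.

    Returns ``(A-sum - A_tot, B-sum - B_tot, I-sum - I_tot, E-sum - E_tot)``
    where the sums run over all species containing the respective protein:
    ``A + A* + C1 + C2 + C3``, ``B + B* + C2 + C3 + C4``, ``I + C1`` and
    ``E1 + C4``.
    """
    y = _as_array(state, 10)
    A, As, B, Bs, I, E1, C1, C2, C3, C4 = y
    return np.array(
        [
            A + As + C1 + C2 + C3 - params.A_tot,
            B + Bs + C2 + C3 + C4 - params.B_tot,
            I + C1 - params.I_tot,
            E1 + C4 - params.E_tot,
        ]
    )


def pools(state) -> Pools:
    """Total active pools ``AS* = A* + C3`` and ``BS* = B* + C2``."""
    y = _as_array(state, 10)
    return Pools(AS_star=float(y[1] + y[8]), BS_star=float(y[3] + y[7]))
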