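"""Monte-Carlo screening of parameter space for RPA capacity.

Parameter sets are sampled log-uniformly: every catalytic constant and
Michaelis constant is ``10**n`` with ``n`` uniform on ``[-3, 4]``, and every
total abundance ``10**n`` with ``n`` uniform on ``[0, 4]``.  Dissociation
constants default to 1 with association constants derived as
``a_i = (d_i + k_i) / K_i`` (the convention of every printed regime); they
can optionally be sampled independently.

For each sampled set both model variants are run over the *same* input grid
(so range comparisons are grid-fair) and assessed with the RPA detector; the
complex-complete model is assessed for each of the candidate variables
``A*``, ``AS* = A* + C3`` and ``C3`` with actuator ``BS* = B* + C2``, the
reduced models for ``A*`` with actuator ``B*``.  Parameter sets whose solver
fails at some grid point are classified non-RPA and logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import RateParameters
from .rpa import (
    DetectionTolerances,
    DEFAULT_TOLERANCES,
    conversion_potential,
    detect_rpa,
    setpoint,
)
from .steady_state import (
    DoseResponse,
    SteadyStateOptions,
    DEFAULT_OPTIONS,
    default_input_grid,
    dose_response,
)

__all__ = [
    "SamplingSpec",
    "SweepSummary",
    "sample_parameters",
    "row_to_params",
    "assess_parameter_set",
    "run_sweep",
    "targeted_sweep",
    "compare_ranges",
]

KINETIC_COLUMNS = ("k_A1", "k_A2", "k_B1", "k_B2", "K_A1", "K_A2", "K_B1", "K_B2")
TOTAL_COLUMNS = ("A_tot", "B_tot", "E_tot")
DISSOCIATION_COLUMNS = ("d_A1", "d_A2", "d_B1", "d_B2")

#: squared-complex vs free-product ratio counted as satisfying the tQSSA
TQSSA_CUT = 0.1


@dataclass(frozen=True)
class SamplingSpec:
    """Specification of the log-uniform Monte-Carlo parameter ensemble."""

    n_sets: int
    seed: int
    kinetic_exponents: tuple[float, float] = (-3.0, 4.0)
    total_exponents: tuple[float, float] = (0.0, 4.0)
    overrides: Mapping[str, float] = field(default_factory=dict)
    sample_dissociation: bool = False
    d_value: float = 1.0

    def __post_init__(self) -> None:
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        for lo, hi in (self.kinetic_exponents, self.total_exponents):
            if not lo < hi:
                raise ValueError("exponent intervals must be well-ordered")
        known = set(KINETIC_COLUMNS) | set(TOTAL_COLUMNS) | set(DISSOCIATION_COLUMNS)
        unknown = set(self.overrides) - known
        if unknown:
            raise ValueError(f"unknown override keys: {sorted(unknown)}")


def sample_parameters(spec: SamplingSpec) -> pd.DataFrame:
    """Draw the ensemble; reproducible under a fixed seed.

    Columns are drawn in a fixed order so the ensemble depends only on the
    seed, never on execution order.  Overridden parameters are held fixed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sets
    data: dict[str, np.ndarray] = {}
    lo, hi = spec.kinetic_exponents
    for col in KINETIC_COLUMNS:
        data[col] = 10.0 ** rng.uniform(lo, hi, size=n)
    lo, hi = spec.total_exponents
    for col in TOTAL_COLUMNS:
        data[col] = 10.0 ** rng.uniform(lo, hi, size=n)
    for col in DISSOCIATION_COLUMNS:
        if spec.sample_dissociation:
            klo, khi = spec.kinetic_exponents
            data[col] = 10.0 ** rng.uniform(klo, khi, size=n)
        else:
            data[col] = np.full(n, spec.d_value)
    for col, value in spec.overrides.items():
        data[col] = np.full(n, float(value))
    df = pd.DataFrame(data)
    df.insert(0, "set_id", np.arange(n))
    return df


def row_to_params(row: Mapping[str, float]) -> RateParameters:
    """Build :class:`RateParameters` from one ensemble row (a_i derived)."""
    kwargs = {c: float(row[c]) for c in KINETIC_COLUMNS + TOTAL_COLUMNS}
    kwargs.update({c: float(row[c]) for c in DISSOCIATION_COLUMNS if c in row})
    return RateParameters(**kwargs)


def _tqssa_fractions(profile: DoseResponse, suffix: str = "",
                     lo: float | None = None,
                     hi: float | None = None) -> dict[str, float]:
    """Per-profile fraction of converged steady states whose enzyme-substrate
    pair satisfies [ES]^2 < TQSSA_CUT x [E][S] (an all-zero pair holds
    trivially).  ``lo``/``hi`` restrict to an input window [lo, hi)."""
    t = profile.table[profile.table["converged"]]
    if lo is not None:
        t = t[(t["I_tot"] >= lo) & (t["I_tot"] < hi)]
    out = {}
    pairs = {
        "c1": ("I", "A", "C1"),
        "c2": ("B_star", "A_star", "C2"),
        "c3": ("A_star", "B", "C3"),
        "c4": ("E1", "B_star", "C4"),
    }
    for key, (e, s, es) in pairs.items():
        prod = t[e].to_numpy() * t[s].to_numpy()
        sq = t[es].to_numpy() ** 2
        ok = (sq < TQSSA_CUT * prod) | ((sq == 0) & (prod == 0))
        out[f"tqssa_{key}{suffix}_frac"] = float(np.mean(ok)) if len(t) else np.nan
    return out


def assess_parameter_set(
    params: RateParameters,
    grid: np.ndarray,
    tolerances: DetectionTolerances = DEFAULT_TOLERANCES,
    models: Sequence[str] = ("michaelian", "complex_complete"),
    options: SteadyStateOptions = DEFAULT_OPTIONS,
    tqssa: bool = False,
) -> dict[str, object]:
    """Run and assess one parameter set for every requested model."""
    rec: dict[str, object] = {"sigma": setpoint(params)}
    prefix = {"michaelian": "mm", "complex_complete": "cc", "ferrell": "fe"}
    for model in models:
        pre = prefix[model]
        profile = dose_response(model, params, grid, options=options)
        if model == "complex_complete":
            a = detect_rpa(profile, "AS_star", "BS_star", tolerances=tolerances)
            rec.update({
                f"{pre}_rpa": a.is_rpa, f"{pre}_IS": a.I_S, f"{pre}_IF": a.I_F,
                f"{pre}_range": a.range, f"{pre}_failure": a.failure_reason,
                f"{pre}_censored": a.censored,
                f"{pre}_nonconv": a.n_nonconverged,
            })
            for cand, tag in (("A_star", "astar"), ("C3", "c3")):
                c = detect_rpa(profile, cand, "BS_star", tolerances=tolerances)
                rec[f"{pre}_{tag}_rpa"] = c.is_rpa
                rec[f"{pre}_{tag}_failure"] = c.failure_reason
            band = profile.table[
                (profile.table["I_tot"] >= a.I_S) & (profile.table["I_tot"] < a.I_F)
            ] if a.is_rpa else None
            rec[f"{pre}_max_BS_star"] = (
                float(band["BS_star"].max()) if band is not None and len(band) else np.nan
            )
            if tqssa:
                rec.update(_tqssa_fractions(profile))
                if a.is_rpa:
                    rec.update(_tqssa_fractions(profile, suffix="_band",
                                                lo=a.I_S, hi=a.I_F))
        else:
            a = detect_rpa(profile, "A_star", "B_star", tolerances=tolerances)
            rec.update({
                f"{pre}_rpa": a.is_rpa, f"{pre}_IS": a.I_S, f"{pre}_IF": a.I_F,
                f"{pre}_range": a.range, f"{pre}_failure": a.failure_reason,
                f"{pre}_censored": a.censored,
                f"{pre}_nonconv": a.n_nonconverged,
            })
    return rec


@dataclass
class SweepSummary:
    """Partition of a sampled ensemble into RPA / non-RPA groups."""

    records: pd.DataFrame
    n_sets: int
    counts: dict[str, int]
    fractions: dict[str, float]
    standard_errors: dict[str, float]

    def summary(self) -> str:
        lines = [f"parameter sets assessed: {self.n_sets}"]
        for key in self.fractions:
            lines.append(
                f"  {key:>18s}: {self.counts[key]:5d}  "
                f"({100 * self.fractions[key]:5.2f}% +/- "
                f"{100 * self.standard_errors[key]:4.2f}%)"
            )
        return "\n".join(lines)

    def range_ratio_table(self) -> pd.DataFrame:
        return compare_ranges(self.records)


def _binomial_se(k: int, n: int) -> float:
    p = k / n
    return float(np.sqrt(p * (1 - p) / n))


def _summarize(records: pd.DataFrame, models: Sequence[str]) -> SweepSummary:
    n = len(records)
    counts: dict[str, int] = {}
    if "michaelian" in models:
        counts["michaelian"] = int(records["mm_rpa"].sum())
    if "complex_complete" in models:
        counts["complex_complete"] = int(records["cc_rpa"].sum())
    if "michaelian" in models and "complex_complete" in models:
        counts["joint"] = int((records["mm_rpa"] & records["cc_rpa"]).sum())
    fractions = {k: v / n for k, v in counts.items()}
    ses = {k: _binomial_se(v, n) for k, v in counts.items()}
    return SweepSummary(records=records, n_sets=n, counts=counts,
                        fractions=fractions, standard_errors=ses)


def run_sweep(
    ensemble: pd.DataFrame,
    grid: np.ndarray | None = None,
    tolerances: DetectionTolerances = DEFAULT_TOLERANCES,
    models: Sequence[str] = ("michaelian", "complex_complete"),
    options: SteadyStateOptions = DEFAULT_OPTIONS,
    grid_n: int = 40,
    n_jobs: int = 1,
    tqssa: bool = False,
) -> SweepSummary:
    """Assess every set of an ensemble for every model.

    Results are independent of ``n_jobs`` (worker count): each set is
    assessed deterministically and reassembled in ensemble order.
    """
    if len(ensemble) == 0:
        raise ValueError("ensemble must be non-empty")
    if grid is None:
        grid = default_input_grid(grid_n)

    def one(row) -> dict[str, object]:
        rec = {"set_id": int(row["set_id"])}
        rec.update(
            assess_parameter_set(
                row_to_params(row), grid, tolerances=tolerances,
                models=models, options=options, tqssa=tqssa,
            )
        )
        return rec

    rows = ensemble.to_dict("records")
    if n_jobs == 1:
        results = [one(r) for r in rows]
    else:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(delayed(one)(r) for r in rows)
    records = ensemble.merge(pd.DataFrame(results), on="set_id")
    return _summarize(records, models)


def targeted_sweep(
    base: RateParameters | Mapping[str, float],
    vary: Sequence[str],
    n_sets: int,
    seed: int,
    exponents: tuple[float, float] = (-3.0, 4.0),
    model: str = "complex_complete",
    grid: np.ndarray | None = None,
    tolerances: DetectionTolerances = DEFAULT_TOLERANCES,
    options: SteadyStateOptions = DEFAULT_OPTIONS,
) -> pd.DataFrame:
    """Targeted search: log-uniformly resample only ``vary``, holding every
    other parameter at its base value.

    Returns per-set records (varied values, verdict, range) for histogramming
    RPA vs non-RPA responses over the varied parameter group.
    """
    if not vary:
        raise ValueError("varied parameter group must be non-empty")
    base_dict = base.to_dict() if isinstance(base, RateParameters) else dict(base)
    for key in ("a_A1", "a_A2", "a_B1", "a_B2", "I_tot"):
        base_dict.pop(key, None)
    rng = np.random.default_rng(seed)
    lo, hi = exponents
    draws = {k: 10.0 ** rng.uniform(lo, hi, size=n_sets) for k in vary}
    if grid is None:
        grid = default_input_grid(40)
    out = []
    for i in range(n_sets):
        d = dict(base_dict)
        d.update({k: float(v[i]) for k, v in draws.items()})
        params = RateParameters.from_dict(d)
        rec = assess_parameter_set(params, grid, tolerances=tolerances,
                                   models=(model,), options=options)
        pre = {"michaelian": "mm", "complex_complete": "cc", "ferrell": "fe"}[model]
        row = {"set_id": i}
        row.update({k: float(v[i]) for k, v in draws.items()})
        row["is_rpa"] = rec[f"{pre}_rpa"]
        row["range"] = rec[f"{pre}_range"]
        row["failure"] = rec[f"{pre}_failure"]
        out.append(row)
    return pd.DataFrame(out)


def compare_ranges(records: pd.DataFrame, grid_min: float | None = None) -> pd.DataFrame:
    """Per-set RPA-range ratio between the two model variants.

    Only sets where both models are RPA-positive with strictly positive
    ranges enter the table; sets where exactly one model shows RPA are
    counted separately by the caller via the record flags.  When ``grid_min``
    is given, sets whose band already extends to the lowest examined input
    (left-censored ``I_S``, hence a truncated measured range) are excluded
    as well.  The ratio is reported as
    ``log10(michaelian range / complex-complete range)``.
    """
    keep = (
        records["mm_rpa"].astype(bool)
        & records["cc_rpa"].astype(bool)
        & (records["mm_range"] > 0)
        & (records["cc_range"] > 0)
    )
    if grid_min is not None:
        keep &= (records["mm_IS"] > grid_min * (1 + 1e-9)) & (
            records["cc_IS"] > grid_min * (1 + 1e-9)
        )
    both = records[keep].copy()
    both["log10_range_ratio"] = np.log10(both["mm_range"] / both["cc_range"])
    cols = ["set_id", "mm_range", "cc_range", "log10_range_ratio"]
    extra = [c for c in ("A_tot", "B_tot", "E_tot") if c in both.columns]
    return both[cols + extra].reset_index(drop=True)
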