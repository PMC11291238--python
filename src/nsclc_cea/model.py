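"""Three-state cohort model (PFS / progressed disease / death) and economics.

State occupancy is derived from the fitted overall-survival and
progression-free-survival curves by the partitioned-survival identity

    PFS(t)  = min(S_pfs(t), S_os(t))
    dead(t) = 1 - S_os(t)
    PD(t)   = 1 - PFS(t) - dead(t)

evaluated at the cycle times t_k = k * cycle_days / 30.4375 months, which is
the standard realization of time-dependent ("dynamic") transition
probabilities from survival functions.  An explicit per-cycle
transition-matrix view is provided and is exactly equivalent.

Costs (drug acquisition, best supportive care, one-time severe adverse-event
treatment) and utility-weighted life-years are accumulated per cycle with
annual discounting, yielding per-arm totals and the incremental
cost-effectiveness ratio (ICER).

Cost-scope conventions
----------------------
``bsc_scope`` controls whether best-supportive-care costs are billed for all
alive patients or in the progressed state only.  ``ArmSpec.drug_scope``
controls whether drug acquisition cost accrues during PFS only or while
alive; the bundled reference configuration bills the checkpoint inhibitor
while alive (treatment beyond progression is permitted for responders) and
the chemotherapy comparator during PFS only.  See docs/methods.md for the
calibration rationale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .curves import DAYS_PER_MONTH
from .fitting import ParametricFit, survival_at

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class AdverseEvent:
    """A grade >=3 adverse event applied once at model entry."""

    name: str
    incidence: float  # probability per patient
    disutility: float  # positive utility decrement
    duration_cycles: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.incidence <= 1.0:
            raise ValueError(f"AE {self.name}: incidence must be in [0, 1]")
        if self.disutility < 0:
            raise ValueError(f"AE {self.name}: disutility is stored as a positive decrement")
        if self.duration_cycles < 1:
            raise ValueError(f"AE {self.name}: duration_cycles must be >= 1")


@dataclass(frozen=True)
class ArmSpec:
    """One treatment arm: survival models, drug cost and AE profile."""

    name: str
    os_fit: ParametricFit
    pfs_fit: ParametricFit
    drug_cost_per_cycle: float
    ae_profile: tuple[AdverseEvent, ...] = ()
    drug_scope: Literal["pfs_only", "all_alive"] = "pfs_only"

    def __post_init__(self) -> None:
        if self.drug_cost_per_cycle < 0:
            raise ValueError("drug cost must be >= 0")
        if self.drug_scope not in ("pfs_only", "all_alive"):
            raise ValueError(f"unknown drug_scope {self.drug_scope!r}")


@dataclass(frozen=True)
class EconomicInputs:
    """Cycle structure, discounting, costs, utilities and thresholds."""

    cycle_days: float = 21.0
    n_cycles: int = 208
    annual_discount_rate: float = 0.05
    bsc_cost_per_cycle: float = 2467.0
    severe_ae_cost: float = 2534.0
    u_pfs: float = 0.804
    u_pd: float = 0.321
    wtp_threshold: float = 257016.0
    bsc_scope: Literal["all_alive", "pd_only"] = "all_alive"
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.u_pd <= 1.0 or not 0.0 <= self.u_pfs <= 1.0:
            raise ValueError("utilities must lie in [0, 1]")
        if self.u_pfs <= self.u_pd:
            raise ValueError("the PFS utility must exceed the PD utility")
        if not 0.0 <= self.annual_discount_rate <= 0.08:
            raise ValueError("annual discount rate must lie in [0, 0.08]")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.bsc_scope not in ("all_alive", "pd_only"):
            raise ValueError(f"unknown bsc_scope {self.bsc_scope!r}")

    @property
    def cycle_months(self) -> float:
        return self.cycle_days / DAYS_PER_MONTH

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / DAYS_PER_YEAR

    def cycle_times_months(self) -> np.ndarray:
        return np.arange(self.n_cycles + 1) * self.cycle_months

    def discount_factors(self) -> np.ndarray:
        """(1 + r)^(-years elapsed) at each cycle boundary."""
        years = np.arange(self.n_cycles + 1) * self.cycle_years
        return (1.0 + self.annual_discount_rate) ** (-years)


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancies (fractions of the cohort)."""

    t_months: np.ndarray
    pfs: np.ndarray
    pd: np.ndarray
    dead: np.ndarray

    def __post_init__(self) -> None:
        rows = self.pfs + self.pd + self.dead
        if np.max(np.abs(rows - 1.0)) > 1e-9:
            raise ValueError("trace rows must sum to 1")
        if np.any(np.diff(self.dead) < -1e-12):
            raise ValueError("dead occupancy must be non-decreasing")

    @property
    def n_cycles(self) -> int:
        return len(self.t_months) - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(len(self.t_months)),
                "t_months": self.t_months,
                "pfs": self.pfs,
                "pd": self.pd,
                "dead": self.dead,
            }
        )


@dataclass(frozen=True)
class CEOutcome:
    arm: str
    total_cost: float
    total_qalys: float


@dataclass(frozen=True)
class ICERResult:
    delta_cost: float
    delta_qalys: float
    icer: float | None
    label: Literal["icer", "dominant", "dominated", "dominated-degenerate"] = "icer"


def occupancy(os_fit: ParametricFit, pfs_fit: ParametricFit, inputs: EconomicInputs) -> CohortTrace:
    """Cohort trace from the partitioned-survival identity at cycle times."""
    t = inputs.cycle_times_months()
    s_os = np.asarray(survival_at(os_fit, t), dtype=float)
    s_pfs = np.asarray(survival_at(pfs_fit, t), dtype=float)
    pfs = np.minimum(s_pfs, s_os)
    dead = 1.0 - s_os
    pd_ = 1.0 - pfs - dead
    return CohortTrace(t_months=t, pfs=pfs, pd=np.maximum(pd_, 0.0), dead=dead)


def transition_matrix_view(
    os_fit: ParametricFit, pfs_fit: ParametricFit, inputs: EconomicInputs
) -> pd.DataFrame:
    """Per-cycle transition probabilities equivalent to :func:`occupancy`.

    For cycle k (from state occupancies at k-1 to k):

    * PFS->PFS  = S_pfs(t_k) / S_pfs(t_{k-1})
    * total deaths this cycle = S_os(t_{k-1}) - S_os(t_k), taken from PD
      first with any overflow from PFS
    * PFS->PD = remainder (clamped at 0)

    Propagating the cohort through these matrices reproduces the
    partitioned-survival trace exactly (up to floating-point round-off).
    """
    t = inputs.cycle_times_months()
    s_os = np.asarray(survival_at(os_fit, t), dtype=float)
    s_pfs = np.asarray(survival_at(pfs_fit, t), dtype=float)
    pfs_prev = np.minimum(s_pfs, s_os)[:-1]
    pd_prev = np.maximum(1.0 - pfs_prev - (1.0 - s_os[:-1]), 0.0)
    pfs_next = np.minimum(s_pfs, s_os)[1:]
    dead_inc = s_os[:-1] - s_os[1:]

    p_pfs_pfs = np.where(pfs_prev > 1e-300, pfs_next / np.maximum(pfs_prev, 1e-300), 1.0)
    p_pfs_pfs = np.clip(p_pfs_pfs, 0.0, 1.0)
    # deaths allocated to PD first; overflow (when PD is too small) from PFS
    deaths_from_pd = np.minimum(dead_inc, pd_prev)
    deaths_from_pfs = np.maximum(dead_inc - deaths_from_pd, 0.0)
    p_pfs_dead = np.where(pfs_prev > 1e-300, deaths_from_pfs / np.maximum(pfs_prev, 1e-300), 0.0)
    p_pfs_pd = np.clip(1.0 - p_pfs_pfs - p_pfs_dead, 0.0, 1.0)
    p_pd_dead = np.where(pd_prev > 1e-300, deaths_from_pd / np.maximum(pd_prev, 1e-300), 0.0)
    p_pd_dead = np.clip(p_pd_dead, 0.0, 1.0)
    return pd.DataFrame(
        {
            "cycle": np.arange(1, inputs.n_cycles + 1),
            "pfs_to_pfs": p_pfs_pfs,
            "pfs_to_pd": p_pfs_pd,
            "pfs_to_dead": p_pfs_dead,
            "pd_to_pd": 1.0 - p_pd_dead,
            "pd_to_dead": p_pd_dead,
        }
    )


def propagate(transitions: pd.DataFrame, inputs: EconomicInputs) -> CohortTrace:
    """Run the cohort through per-cycle transition matrices (for validation)."""
    n = inputs.n_cycles
    pfs = np.zeros(n + 1)
    pd_ = np.zeros(n + 1)
    dead = np.zeros(n + 1)
    pfs[0] = 1.0
    tm = transitions.set_index("cycle")
    for k in range(1, n + 1):
        row = tm.loc[k]
        pfs[k] = pfs[k - 1] * row["pfs_to_pfs"]
        pd_[k] = pd_[k - 1] * row["pd_to_pd"] + pfs[k - 1] * row["pfs_to_pd"]
        dead[k] = dead[k - 1] + pd_[k - 1] * row["pd_to_dead"] + pfs[k - 1] * row["pfs_to_dead"]
    total = pfs + pd_ + dead
    return CohortTrace(
        t_months=inputs.cycle_times_months(), pfs=pfs / total, pd=pd_ / total, dead=dead / total
    )


def accumulate(trace: CohortTrace, arm: ArmSpec, inputs: EconomicInputs) -> CEOutcome:
    """Discounted total cost and QALYs for one arm.

    Per cycle k >= 1, with discount factor (1+r)^(-t_k in years):

    * drug cost accrues on PFS occupancy (or on all alive, per
      ``arm.drug_scope``)
    * BSC cost accrues per ``inputs.bsc_scope``
    * utility = u_pfs * PFS + u_pd * PD, converted to years via
      cycle_days / 365.25

    A one-time adverse-event burden (treatment cost plus a
    duration-limited disutility), weighted by per-AE incidence, is applied at
    cycle 1.  The optional half-cycle correction averages adjacent
    occupancies.
    """
    if trace.n_cycles != inputs.n_cycles:
        raise ValueError("trace and inputs disagree on the number of cycles")
    disc = inputs.discount_factors()
    pfs, pd_ = trace.pfs, trace.pd
    if inputs.half_cycle_correction:
        pfs = np.concatenate([[pfs[0]], (pfs[:-1] + pfs[1:]) / 2.0])
        pd_ = np.concatenate([[pd_[0]], (pd_[:-1] + pd_[1:]) / 2.0])

    drug_occ = pfs + pd_ if arm.drug_scope == "all_alive" else pfs
    bsc_occ = pfs + pd_ if inputs.bsc_scope == "all_alive" else pd_
    cost_per_cycle = drug_occ * arm.drug_cost_per_cycle + bsc_occ * inputs.bsc_cost_per_cycle
    qaly_per_cycle = (pfs * inputs.u_pfs + pd_ * inputs.u_pd) * inputs.cycle_years

    total_cost = float(np.sum(cost_per_cycle[1:] * disc[1:]))
    total_qalys = float(np.sum(qaly_per_cycle[1:] * disc[1:]))

    # one-time AE burden at model entry, discounted at cycle 1
    ae_cost = sum(ae.incidence * inputs.severe_ae_cost for ae in arm.ae_profile)
    ae_qaly_loss = sum(
        ae.incidence * ae.disutility * ae.duration_cycles * inputs.cycle_years
        for ae in arm.ae_profile
    )
    total_cost += float(ae_cost * disc[1])
    total_qalys -= float(ae_qaly_loss * disc[1])
    return CEOutcome(arm=arm.name, total_cost=total_cost, total_qalys=total_qalys)


def run_arm(arm: ArmSpec, inputs: EconomicInputs) -> tuple[CohortTrace, CEOutcome]:
    trace = occupancy(arm.os_fit, arm.pfs_fit, inputs)
    return trace, accumulate(trace, arm, inputs)


def icer(intervention: CEOutcome, comparator: CEOutcome) -> ICERResult:
    """Incremental cost-effectiveness ratio, intervention minus comparator."""
    dc = intervention.total_cost - comparator.total_cost
    de = intervention.total_qalys - comparator.total_qalys
    if abs(de) < 1e-12:
        if dc > 0:
            return ICERResult(dc, de, None, "dominated-degenerate")
        return ICERResult(dc, de, None, "dominant" if dc < 0 else "icer")
    if dc <= 0 and de > 0:
        return ICERResult(dc, de, None, "dominant")
    if dc > 0 and de < 0:
        return ICERResult(dc, de, None, "dominated")
    return ICERResult(dc, de, dc / de, "icer")


def dosing_cost(
    unit_price: float,
    pack_content_mg: float,
    *,
    flat_mg: float | None = None,
    per_m2_mg: float | None = None,
    bsa_m2: float = 1.72,
) -> float:
    """Per-administration drug cost billed at exact milligrams (no vial rounding).

    Either a flat dose in mg or a body-surface-area-based dose (mg per m^2
    with the cohort mean BSA, default 1.72 m^2) must be given.
    """
    if unit_price <= 0 or pack_content_mg <= 0:
        raise ValueError("unit price and pack content must be positive")
    if (flat_mg is None) == (per_m2_mg is None):
        raise ValueError("give exactly one of flat_mg or per_m2_mg")
    if flat_mg is not None:
        if flat_mg < 0:
            raise ValueError("dose must be non-negative")
        total_mg = flat_mg
    else:
        if per_m2_mg < 0 or bsa_m2 <= 0:
            raise ValueError("dose and BSA must be non-negative/positive")
        total_mg = per_m2_mg * bsa_m2
    return unit_price / pack_content_mg * total_mg
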