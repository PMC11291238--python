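"""Deterministic and probabilistic sensitivity analysis.

One-way analysis re-runs the full base case at each parameter's low and high
bound (tornado ordering by ICER swing).  The probabilistic analysis is a
second-order Monte Carlo: each draw samples every non-fixed parameter from a
moment-matched distribution (beta for utilities and disutility magnitudes,
gamma for costs; ranges read as 95% intervals so sigma = (high - low)/3.92),
re-runs both arms and records the incremental cost and QALY pair.  The
cost-effectiveness acceptability curve (CEAC) counts draws with positive net
monetary benefit  lambda * dQALY - dCost  across a willingness-to-pay grid.

Survival-model parameters carry no published ranges and are held fixed in
both analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .model import ArmSpec, CEOutcome, EconomicInputs, icer, run_arm

#: a published low~high range is read as a central 95% interval
RANGE_TO_SD = 3.92

DEFAULT_SEED = 20240718
DEFAULT_N_DRAWS = 5000
DEFAULT_WTP_GRID = np.arange(0, 600_001, 10_000, dtype=float)


@dataclass(frozen=True)
class ParameterSpec:
    """One uncertain model input: base value, range and PSA family."""

    id: str
    base: float
    low: float
    high: float
    psa_family: Literal["beta", "gamma", "fixed"] = "fixed"

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.id}: require low <= base <= high")
        if self.psa_family not in ("beta", "gamma", "fixed"):
            raise ValueError(f"{self.id}: unknown PSA family {self.psa_family!r}")


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    icer_at_low: float
    icer_at_high: float

    @property
    def swing(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


@dataclass(frozen=True)
class PSADraws:
    n_draws: int
    seed: int
    delta_cost: np.ndarray
    delta_qalys: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "draw": np.arange(self.n_draws),
                "delta_cost": self.delta_cost,
                "delta_qalys": self.delta_qalys,
            }
        )


@dataclass(frozen=True)
class CEACCurve:
    wtp_grid: np.ndarray
    prob_cost_effective: np.ndarray

    def at(self, wtp: float) -> float:
        idx = int(np.argmin(np.abs(self.wtp_grid - wtp)))
        if abs(self.wtp_grid[idx] - wtp) > 1e-6:
            raise ValueError(f"WTP {wtp} not on the curve's grid")
        return float(self.prob_cost_effective[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp_grid, "probability": self.prob_cost_effective})


# ---------------------------------------------------------------------------
# Applying parameter overrides to the model configuration
# ---------------------------------------------------------------------------
# Parameter ids are dotted paths:
#   inputs.<field>                        e.g. inputs.bsc_cost_per_cycle
#   arms.<arm name>.drug_cost_per_cycle
#   arms.<arm name>.ae.<ae name>.disutility
#   ae.<ae name>.disutility               (shared across arms)

def apply_overrides(
    inputs: EconomicInputs,
    arms: Sequence[ArmSpec],
    overrides: dict[str, float],
) -> tuple[EconomicInputs, list[ArmSpec]]:
    """Return copies of the configuration with the given parameters replaced."""
    inputs_kwargs: dict[str, float] = {}
    arm_map = {a.name.lower(): a for a in arms}
    arm_updates: dict[str, dict] = {name: {} for name in arm_map}
    for pid, value in overrides.items():
        parts = pid.split(".")
        if parts[0] == "ae" and len(parts) == 3 and parts[2] == "disutility":
            matched = False
            for name, arm in arm_map.items():
                if any(ae.name == parts[1] for ae in arm.ae_profile):
                    arm_updates[name].setdefault("ae", {})[parts[1]] = value
                    matched = True
            if not matched:
                raise KeyError(f"unknown adverse event in parameter id {pid!r}")
        elif parts[0] == "inputs" and len(parts) == 2:
            if not hasattr(inputs, parts[1]):
                raise KeyError(f"unknown parameter id {pid!r}")
            inputs_kwargs[parts[1]] = value
        elif parts[0] == "arms" and len(parts) >= 3:
            arm_name = parts[1].lower()
            if arm_name not in arm_map:
                raise KeyError(f"unknown arm in parameter id {pid!r}")
            if len(parts) == 3 and parts[2] == "drug_cost_per_cycle":
                arm_updates[arm_name]["drug_cost_per_cycle"] = value
            elif len(parts) == 5 and parts[2] == "ae" and parts[4] == "disutility":
                arm_updates[arm_name].setdefault("ae", {})[parts[3]] = value
            else:
                raise KeyError(f"unknown parameter id {pid!r}")
        else:
            raise KeyError(f"unknown parameter id {pid!r}")

    new_inputs = replace(inputs, **inputs_kwargs) if inputs_kwargs else inputs
    new_arms = []
    for arm in arms:
        upd = arm_updates[arm.name.lower()]
        if not upd:
            new_arms.append(arm)
            continue
        kwargs = {}
        if "drug_cost_per_cycle" in upd:
            kwargs["drug_cost_per_cycle"] = upd["drug_cost_per_cycle"]
        if "ae" in upd:
            kwargs["ae_profile"] = tuple(
                replace(ae, disutility=abs(upd["ae"].get(ae.name, -ae.disutility)))
                for ae in arm.ae_profile
            )
        new_arms.append(replace(arm, **kwargs))
    return new_inputs, new_arms


def _base_case(inputs: EconomicInputs, arms: Sequence[ArmSpec]) -> tuple[CEOutcome, CEOutcome]:
    if len(arms) != 2:
        raise ValueError("expected exactly two arms (intervention, comparator)")
    (_, out_i), (_, out_c) = run_arm(arms[0], inputs), run_arm(arms[1], inputs)
    return out_i, out_c


def _icer_value(inputs: EconomicInputs, arms: Sequence[ArmSpec]) -> float:
    out_i, out_c = _base_case(inputs, arms)
    res = icer(out_i, out_c)
    if res.icer is None:
        # dominance: represent as signed infinity for tornado ordering
        return -math.inf if res.label == "dominant" else math.inf
    return res.icer


# ---------------------------------------------------------------------------
# One-way (tornado) sensitivity analysis
# ---------------------------------------------------------------------------

def one_way_sa(
    inputs: EconomicInputs,
    arms: Sequence[ArmSpec],
    specs: Sequence[ParameterSpec],
) -> list[TornadoEntry]:
    """Re-run the base case at each parameter's bounds; sort by ICER swing."""
    entries = []
    for spec in specs:
        icer_low = _icer_value(*apply_overrides(inputs, arms, {spec.id: spec.low}))
        icer_high = _icer_value(*apply_overrides(inputs, arms, {spec.id: spec.high}))
        entries.append(TornadoEntry(spec.id, icer_low, icer_high))
    entries.sort(key=lambda e: (-e.swing, e.parameter))
    return entries


def tornado_table(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "icer_low": [e.icer_at_low for e in entries],
            "icer_high": [e.icer_at_high for e in entries],
            "swing": [e.swing for e in entries],
        }
    )


# ---------------------------------------------------------------------------
# Moment matching and the probabilistic analysis
# ---------------------------------------------------------------------------

def moment_match(spec: ParameterSpec) -> dict[str, float]:
    """Distribution parameters with mean = base and sd = (high - low)/3.92.

    Beta uses the method-of-moments shapes on the magnitude of the base value
    (disutilities are tagged beta with negative ranges; they are sampled on
    their magnitude and re-negated by the caller).  A zero-width range
    degenerates to a point mass.
    """
    if spec.psa_family == "fixed":
        raise ValueError(f"{spec.id}: fixed parameters have no sampling distribution")
    sigma = (spec.high - spec.low) / RANGE_TO_SD
    if sigma == 0.0:
        return {"family": 0.0, "point": spec.base}  # degenerate
    m = abs(spec.base)
    if spec.psa_family == "beta":
        if not 0.0 < m < 1.0:
            raise ValueError(f"{spec.id}: beta requires a base magnitude in (0, 1)")
        if sigma**2 >= m * (1.0 - m):
            raise ValueError(f"{spec.id}: infeasible beta moments (sd {sigma:.4g} too large)")
        nu = m * (1.0 - m) / sigma**2 - 1.0
        return {"shape1": m * nu, "shape2": (1.0 - m) * nu}
    # gamma
    if m <= 0:
        raise ValueError(f"{spec.id}: gamma requires a positive base")
    return {"shape": (m / sigma) ** 2, "scale": sigma**2 / m}


def _sample(spec: ParameterSpec, rng: np.random.Generator) -> float:
    if spec.psa_family == "fixed":
        return spec.base
    params = moment_match(spec)
    if "point" in params:
        return spec.base
    sign = -1.0 if spec.base < 0 else 1.0
    if spec.psa_family == "beta":
        return sign * rng.beta(params["shape1"], params["shape2"])
    return sign * rng.gamma(params["shape"], params["scale"])


def run_psa(
    inputs: EconomicInputs,
    arms: Sequence[ArmSpec],
    specs: Sequence[ParameterSpec],
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = DEFAULT_SEED,
) -> PSADraws:
    """Second-order Monte Carlo over the parameter distributions.

    Every non-fixed parameter is sampled independently each draw; both arms
    are re-run and the incremental (cost, QALY) pair recorded.  Deterministic
    under a fixed seed.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    dc = np.empty(n_draws)
    de = np.empty(n_draws)
    for i in range(n_draws):
        overrides = {}
        for spec in specs:
            value = _sample(spec, rng)
            if spec.psa_family != "fixed":
                overrides[spec.id] = value
        inp_i, arms_i = apply_overrides(inputs, arms, overrides)
        out_i, out_c = _base_case(inp_i, arms_i)
        dc[i] = out_i.total_cost - out_c.total_cost
        de[i] = out_i.total_qalys - out_c.total_qalys
    return PSADraws(n_draws=n_draws, seed=seed, delta_cost=dc, delta_qalys=de)


def ceac(draws: PSADraws, wtp_grid: np.ndarray | Sequence[float] = DEFAULT_WTP_GRID) -> CEACCurve:
    """Fraction of draws with positive net monetary benefit at each WTP."""
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0 or draws.n_draws == 0:
        raise ValueError("ceac requires non-empty draws and WTP grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("WTP grid must be strictly increasing")
    nmb = grid[:, None] * draws.delta_qalys[None, :] - draws.delta_cost[None, :]
    prob = np.mean(nmb > 0, axis=1)
    return CEACCurve(wtp_grid=grid, prob_cost_effective=prob)


def probability_cost_effective(draws: PSADraws, wtp: float) -> float:
    """Fraction of draws with positive NMB at a single WTP threshold."""
    return float(np.mean(wtp * draws.delta_qalys - draws.delta_cost > 0))
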