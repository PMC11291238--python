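"""Synthetic survival data, digitized-curve fixtures and the reference config.

Because the underlying trial deposits no patient-level data, every pipeline
stage is exercised on synthetic inputs: right-censored event times drawn from
the supported parametric families (inverse-CDF sampling), rendered as
digitized step-curve coordinates plus a number-at-risk table exactly as a
manual digitization of a published figure would provide them.

``make_reference_config`` emits the published base-case model inputs
(log-logistic survival parameters per arm and endpoint, per-cycle costs,
utilities and disutilities with their ranges and PSA distribution tags, the
5% discount rate and the 257,016 CNY/QALY willingness-to-pay threshold) as
the package's bundled configuration.  ``make_trial`` emulates the source
trial's design at full scale: 805 subjects randomized 2:1, event times from
the reference log-logistic models, administrative censoring at the data
cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .curves import DigitizedKM, SurvivalRecord, km_estimate
from .fitting import FAMILIES, ParametricFit, loglogistic, quantile
from .model import AdverseEvent, ArmSpec, EconomicInputs
from .sensitivity import ParameterSpec

#: trial scale: 805 subjects randomized 2:1 (intervention:comparator)
TRIAL_N = 805
TRIAL_ALLOCATION = (2, 1)
#: synthetic data cutoff, months (administrative censoring of both endpoints)
TRIAL_CUTOFF_MONTHS = 36.0


@dataclass(frozen=True)
class SimulationSpec:
    """Recipe for one batch of right-censored survival records."""

    family: str
    params: dict[str, float]
    n_subjects: int
    administrative_censor_time: float | None = None
    random_censor_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unsupported family {self.family!r}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 <= self.random_censor_rate < 1.0:
            raise ValueError("random censor rate must be in [0, 1)")


def simulate_ipd(spec: SimulationSpec) -> list[SurvivalRecord]:
    """Draw right-censored records: inverse-CDF event times, exponential dropout.

    The dropout rate is solved numerically so that the expected fraction of
    randomly censored subjects matches ``random_censor_rate`` given the drawn
    event times and the administrative cutoff.
    """
    rng = np.random.default_rng(spec.seed)
    fit = ParametricFit(family=spec.family, params=spec.params)
    u = rng.uniform(size=spec.n_subjects)
    event_times = np.asarray(quantile(fit, u), dtype=float)
    event_times = np.maximum(event_times, 1e-9)
    t_adm = spec.administrative_censor_time if spec.administrative_censor_time is not None else np.inf

    if spec.random_censor_rate > 0.0:
        horizon = np.minimum(event_times, t_adm)

        def expected_censored(rate: float) -> float:
            return float(np.mean(-np.expm1(-rate * horizon))) - spec.random_censor_rate

        rate = optimize.brentq(expected_censored, 1e-12, 1e6)
        dropout = rng.exponential(1.0 / rate, size=spec.n_subjects)
    else:
        dropout = np.full(spec.n_subjects, np.inf)

    censor_times = np.minimum(dropout, t_adm)
    times = np.minimum(event_times, censor_times)
    events = (event_times <= censor_times).astype(int)
    return [SurvivalRecord(float(t), int(e)) for t, e in zip(times, events)]


def make_digitized(
    records: Sequence[SurvivalRecord],
    coord_grid_step: float,
    risk_interval: float,
    *,
    arm_label: str = "synthetic",
    endpoint: str = "OS",
    include_total_events: bool = True,
) -> DigitizedKM:
    """Render records as a digitized curve: KM sampled on a grid + risk table."""
    if coord_grid_step <= 0:
        raise ValueError("coord_grid_step must be positive")
    if risk_interval <= 0:
        raise ValueError("risk_interval must be positive")
    if not len(records):
        raise ValueError("make_digitized requires at least one record")
    km = km_estimate(records)
    t_max = max(r.time for r in records)
    grid = np.arange(0.0, t_max + coord_grid_step / 2.0, coord_grid_step)
    if grid[-1] < t_max:
        grid = np.append(grid, t_max)
    surv = km.survival_at(grid)
    coords = tuple(zip(grid.tolist(), [float(s) for s in surv]))
    times = np.array([r.time for r in records])
    risk_starts = np.arange(0.0, t_max, risk_interval)
    risk_table = tuple((float(s), int(np.sum(times >= s))) for s in risk_starts)
    total_events = int(sum(r.event for r in records)) if include_total_events else None
    return DigitizedKM(
        arm_label=arm_label,
        endpoint=endpoint,
        coords=coords,
        risk_table=risk_table,
        total_events=total_events,
    )


# ---------------------------------------------------------------------------
# Reference configuration (published base-case model inputs)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceConfig:
    inputs: EconomicInputs
    arms: tuple[ArmSpec, ArmSpec]  # (intervention, comparator)
    parameters: tuple[ParameterSpec, ...]

    @property
    def intervention(self) -> ArmSpec:
        return self.arms[0]

    @property
    def comparator(self) -> ArmSpec:
        return self.arms[1]


#: grade >=3 AEs (frequency >= 5% in the trial) with published disutilities;
#: per-arm incidences are not published, so they default to 0 and act only
#: through the sensitivity-analysis ranges
_AE_DISUTILITIES = {
    "neutropenia": (0.200, (0.180, 0.220)),
    "febrile_neutropenia": (0.42, (0.378, 0.462)),
    "anemia": (0.078, (0.070, 0.086)),
    "asthenia": (0.078, (0.070, 0.086)),
}


def _default_ae_profile() -> tuple[AdverseEvent, ...]:
    return tuple(
        AdverseEvent(name=name, incidence=0.0, disutility=d, duration_cycles=1)
        for name, (d, _rng) in _AE_DISUTILITIES.items()
    )


def make_reference_config() -> ReferenceConfig:
    """The bundled base-case configuration (survival models, costs, utilities).

    Cost-scope conventions are frozen as calibrated once against the published
    base case: BSC billed while alive; the checkpoint inhibitor billed while
    alive (treatment beyond progression); chemotherapy billed during PFS only;
    no half-cycle correction.
    """
    inputs = EconomicInputs(
        cycle_days=21.0,
        n_cycles=208,
        annual_discount_rate=0.05,
        bsc_cost_per_cycle=2467.0,
        severe_ae_cost=2534.0,
        u_pfs=0.804,
        u_pd=0.321,
        wtp_threshold=257016.0,
        bsc_scope="all_alive",
        half_cycle_correction=False,
    )
    tislelizumab = ArmSpec(
        name="tislelizumab",
        os_fit=loglogistic(scale=17.43252, shape=1.48925),
        pfs_fit=loglogistic(scale=4.84787, shape=1.42274),
        drug_cost_per_cycle=2675.0,
        ae_profile=_default_ae_profile(),
        drug_scope="all_alive",
    )
    docetaxel = ArmSpec(
        name="docetaxel",
        os_fit=loglogistic(scale=11.7162, shape=1.5699),
        pfs_fit=loglogistic(scale=3.11381, shape=2.12956),
        drug_cost_per_cycle=419.25,
        ae_profile=_default_ae_profile(),
        drug_scope="pfs_only",
    )
    parameters = (
        ParameterSpec("arms.tislelizumab.drug_cost_per_cycle", 2675.0, 2140.0, 2675.0, "gamma"),
        ParameterSpec("arms.docetaxel.drug_cost_per_cycle", 419.25, 419.25, 898.36, "gamma"),
        ParameterSpec("inputs.bsc_cost_per_cycle", 2467.0, 1973.65, 2960.47, "gamma"),
        ParameterSpec("inputs.severe_ae_cost", 2534.0, 2027.2, 3040.8, "gamma"),
        ParameterSpec("inputs.u_pfs", 0.804, 0.724, 0.884, "beta"),
        ParameterSpec("inputs.u_pd", 0.321, 0.289, 0.353, "beta"),
        ParameterSpec("ae.neutropenia.disutility", -0.200, -0.220, -0.180, "beta"),
        ParameterSpec("ae.febrile_neutropenia.disutility", -0.42, -0.462, -0.378, "beta"),
        ParameterSpec("ae.anemia.disutility", -0.078, -0.086, -0.070, "beta"),
        ParameterSpec("ae.asthenia.disutility", -0.078, -0.086, -0.070, "beta"),
        ParameterSpec("inputs.annual_discount_rate", 0.05, 0.0, 0.08, "fixed"),
    )
    return ReferenceConfig(inputs=inputs, arms=(tislelizumab, docetaxel), parameters=parameters)


def make_trial(seed: int = 0, n_total: int = TRIAL_N) -> dict[str, dict[str, list[SurvivalRecord]]]:
    """A synthetic two-arm trial at the source trial's scale (2:1 allocation).

    Event times are drawn from the reference log-logistic models per
    arm/endpoint, with administrative censoring at the data cutoff and a
    small random-dropout fraction.  OS and PFS are simulated marginally
    (per-subject consistency between endpoints is not enforced).
    """
    cfg = make_reference_config()
    w_i, w_c = TRIAL_ALLOCATION
    n_i = round(n_total * w_i / (w_i + w_c))
    n_c = n_total - n_i
    out: dict[str, dict[str, list[SurvivalRecord]]] = {}
    for offset, (arm, n_arm) in enumerate([(cfg.intervention, n_i), (cfg.comparator, n_c)]):
        arm_out = {}
        for j, (endpoint, fit) in enumerate([("OS", arm.os_fit), ("PFS", arm.pfs_fit)]):
            spec = SimulationSpec(
                family=fit.family,
                params=fit.params,
                n_subjects=n_arm,
                administrative_censor_time=TRIAL_CUTOFF_MONTHS,
                random_censor_rate=0.05,
                seed=seed * 4 + offset * 2 + j,
            )
            arm_out[endpoint] = simulate_ipd(spec)
        out[arm.name] = arm_out
    return out


def make_trial_curves(
    seed: int = 0,
    n_total: int = TRIAL_N,
    coord_grid_step: float = 0.1,
    risk_interval: float = 3.0,
) -> dict[str, dict[str, DigitizedKM]]:
    """Digitized-curve fixtures for the synthetic trial (per arm/endpoint)."""
    trial = make_trial(seed=seed, n_total=n_total)
    return {
        arm: {
            endpoint: make_digitized(
                records,
                coord_grid_step,
                risk_interval,
                arm_label=arm,
                endpoint=endpoint,
            )
            for endpoint, records in endpoints.items()
        }
        for arm, endpoints in trial.items()
    }
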