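"""Configuration-driven orchestration of the full analysis.

Stages run in method order: (1) reconstruct pseudo-IPD from digitized curves,
(2) fit the seven parametric families and select by AIC/BIC, (3) base-case
cohort model, (4) one-way sensitivity analysis, (5) probabilistic sensitivity
analysis, (6) CEAC.  When the configuration supplies pre-fitted survival
parameters (the published-table pathway) the reconstruction and fitting
stages are skipped.

The YAML configuration mirrors the published input table; see
``config_from_reference(make_reference_config())`` for a complete example.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import yaml

from . import __version__
from .curves import read_digitized_curve, reconstruct_ipd, write_ipd
from .fitting import ParametricFit, fit_all, fits_table, select_best
from .model import AdverseEvent, ArmSpec, EconomicInputs, icer, run_arm
from .sensitivity import (
    DEFAULT_N_DRAWS,
    DEFAULT_SEED,
    ParameterSpec,
    ceac,
    one_way_sa,
    run_psa,
    tornado_table,
)
from .synthetic import ReferenceConfig

logger = logging.getLogger("nsclc_cea")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    n_draws: int
    stages: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    selected_families: dict[str, str] = field(default_factory=dict)
    package_version: str = __version__
    started_at: str = ""
    finished_at: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def config_hash(config: dict) -> str:
    """Stable hash of the semantic content of a configuration mapping."""
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=float).encode()).hexdigest()


def config_from_reference(cfg: ReferenceConfig) -> dict:
    """Serialize a ReferenceConfig to the YAML-ready configuration mapping."""
    arms = []
    for role, arm in zip(("intervention", "comparator"), cfg.arms):
        arms.append(
            {
                "name": arm.name,
                "role": role,
                "drug_cost_per_cycle": arm.drug_cost_per_cycle,
                "drug_scope": arm.drug_scope,
                "survival": {
                    "os": {"family": arm.os_fit.family, "params": dict(arm.os_fit.params)},
                    "pfs": {"family": arm.pfs_fit.family, "params": dict(arm.pfs_fit.params)},
                },
                "adverse_events": [
                    {
                        "name": ae.name,
                        "incidence": ae.incidence,
                        "disutility": ae.disutility,
                        "duration_cycles": ae.duration_cycles,
                    }
                    for ae in arm.ae_profile
                ],
            }
        )
    return {
        "model": {
            "cycle_days": cfg.inputs.cycle_days,
            "n_cycles": cfg.inputs.n_cycles,
            "discount_rate": cfg.inputs.annual_discount_rate,
            "wtp_threshold": cfg.inputs.wtp_threshold,
            "bsc_scope": cfg.inputs.bsc_scope,
            "half_cycle_correction": cfg.inputs.half_cycle_correction,
        },
        "costs": {
            "bsc_per_cycle": cfg.inputs.bsc_cost_per_cycle,
            "severe_ae": cfg.inputs.severe_ae_cost,
        },
        "utilities": {"pfs": cfg.inputs.u_pfs, "pd": cfg.inputs.u_pd},
        "arms": arms,
        "parameters": [
            {"id": p.id, "base": p.base, "low": p.low, "high": p.high, "psa": p.psa_family}
            for p in cfg.parameters
        ],
        "psa": {"n_draws": DEFAULT_N_DRAWS, "seed": DEFAULT_SEED},
        "ceac": {"wtp_min": 0, "wtp_max": 600_000, "wtp_step": 10_000},
    }


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    validate_config(config)
    return config


def validate_config(config: dict) -> None:
    """Schema check; raises ValueError before any stage runs."""
    if not isinstance(config, dict):
        raise ValueError("configuration must be a mapping")
    for key in ("model", "costs", "utilities", "arms"):
        if key not in config:
            raise ValueError(f"configuration missing required section {key!r}")
    if len(config["arms"]) != 2:
        raise ValueError("configuration must define exactly two arms")
    roles = sorted(a.get("role", "") for a in config["arms"])
    if roles != ["comparator", "intervention"]:
        raise ValueError("arms must carry roles 'intervention' and 'comparator'")
    for arm in config["arms"]:
        if "name" not in arm or "drug_cost_per_cycle" not in arm:
            raise ValueError("each arm needs 'name' and 'drug_cost_per_cycle'")
        if "survival" not in arm and "curves" not in arm:
            raise ValueError(f"arm {arm.get('name')!r} needs 'survival' (pre-fitted) or 'curves' (digitized)")


def _parse_inputs(config: dict) -> EconomicInputs:
    m, c, u = config["model"], config["costs"], config["utilities"]
    return EconomicInputs(
        cycle_days=float(m.get("cycle_days", 21.0)),
        n_cycles=int(m.get("n_cycles", 208)),
        annual_discount_rate=float(m.get("discount_rate", 0.05)),
        bsc_cost_per_cycle=float(c.get("bsc_per_cycle", 2467.0)),
        severe_ae_cost=float(c.get("severe_ae", 2534.0)),
        u_pfs=float(u.get("pfs", 0.804)),
        u_pd=float(u.get("pd", 0.321)),
        wtp_threshold=float(m.get("wtp_threshold", 257016.0)),
        bsc_scope=m.get("bsc_scope", "all_alive"),
        half_cycle_correction=bool(m.get("half_cycle_correction", False)),
    )


def _parse_parameters(config: dict) -> tuple[ParameterSpec, ...]:
    return tuple(
        ParameterSpec(p["id"], float(p["base"]), float(p["low"]), float(p["high"]), p.get("psa", "fixed"))
        for p in config.get("parameters", [])
    )


def run_all(
    config: dict | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
    n_draws: int | None = None,
) -> RunManifest:
    """Execute every applicable stage; write artifacts and a run manifest."""
    if not isinstance(config, dict):
        base_dir = Path(config).parent
        config = load_config(config)
    else:
        validate_config(config)
        base_dir = Path(".")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(seed if seed is not None else config.get("psa", {}).get("seed", DEFAULT_SEED))
    n_draws = int(n_draws if n_draws is not None else config.get("psa", {}).get("n_draws", DEFAULT_N_DRAWS))
    manifest = RunManifest(config_hash=config_hash(config), seed=seed, n_draws=n_draws)
    manifest.started_at = time.strftime("%Y-%m-%dT%H:%M:%S")

    inputs = _parse_inputs(config)
    specs = _parse_parameters(config)

    # --- reconstruction + fitting (digitized pathway) or pre-fitted ---
    arms: list[ArmSpec] = []
    ordered = sorted(config["arms"], key=lambda a: 0 if a["role"] == "intervention" else 1)
    for arm_cfg in ordered:
        fits: dict[str, ParametricFit] = {}
        if "survival" in arm_cfg:
            for endpoint in ("os", "pfs"):
                s = arm_cfg["survival"][endpoint]
                fits[endpoint] = ParametricFit(family=s["family"], params={k: float(v) for k, v in s["params"].items()})
        else:
            for endpoint in ("os", "pfs"):
                paths = arm_cfg["curves"][endpoint]
                curve = read_digitized_curve(
                    base_dir / paths["coords"],
                    base_dir / paths["risk"],
                    arm_label=arm_cfg["name"],
                    endpoint=endpoint.upper(),
                    metadata_path=(base_dir / paths["metadata"]) if "metadata" in paths else None,
                )
                t0 = time.perf_counter()
                records = reconstruct_ipd(curve)
                logger.info(
                    "reconstructed %d records for %s/%s in %.2fs",
                    len(records), arm_cfg["name"], endpoint, time.perf_counter() - t0,
                )
                ipd_path = out / f"ipd_{arm_cfg['name']}_{endpoint}.csv"
                write_ipd(records, ipd_path)
                manifest.outputs.append(ipd_path.name)
                if "reconstruct" not in manifest.stages:
                    manifest.stages.append("reconstruct")
                t0 = time.perf_counter()
                all_fits = fit_all(records)
                best = select_best(all_fits)
                logger.info(
                    "fitted %d families for %s/%s in %.2fs; selected %s",
                    len(all_fits), arm_cfg["name"], endpoint, time.perf_counter() - t0, best,
                )
                table_path = out / f"fits_{arm_cfg['name']}_{endpoint}.csv"
                fits_table(all_fits).to_csv(table_path, index=False)
                manifest.outputs.append(table_path.name)
                for st in ("fit", "select"):
                    if st not in manifest.stages:
                        manifest.stages.append(st)
                manifest.selected_families[f"{arm_cfg['name']}/{endpoint}"] = best
                fits[endpoint] = next(f for f in all_fits if f.family == best)
        arms.append(
            ArmSpec(
                name=arm_cfg["name"],
                os_fit=fits["os"],
                pfs_fit=fits["pfs"],
                drug_cost_per_cycle=float(arm_cfg["drug_cost_per_cycle"]),
                ae_profile=tuple(
                    AdverseEvent(
                        name=ae["name"],
                        incidence=float(ae.get("incidence", 0.0)),
                        disutility=abs(float(ae.get("disutility", 0.0))),
                        duration_cycles=int(ae.get("duration_cycles", 1)),
                    )
                    for ae in arm_cfg.get("adverse_events", [])
                ),
                drug_scope=arm_cfg.get("drug_scope", "pfs_only"),
            )
        )

    # --- base case ---
    t0 = time.perf_counter()
    outcomes = {}
    for arm in arms:
        trace, outcome = run_arm(arm, inputs)
        outcomes[arm.name] = outcome
        trace_path = out / f"trace_{arm.name}.csv"
        trace.to_frame().to_csv(trace_path, index=False)
        manifest.outputs.append(trace_path.name)
    res = icer(outcomes[arms[0].name], outcomes[arms[1].name])
    summary = {
        "arms": {
            name: {"cost": o.total_cost, "qalys": o.total_qalys} for name, o in outcomes.items()
        },
        "icer": {
            "intervention": arms[0].name,
            "comparator": arms[1].name,
            "delta_cost": res.delta_cost,
            "delta_qalys": res.delta_qalys,
            "icer": res.icer,
            "label": res.label,
        },
        "selected_families": manifest.selected_families,
        "wtp_threshold": inputs.wtp_threshold,
        "seed": seed,
        "config_hash": manifest.config_hash,
    }
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    manifest.outputs.append(summary_path.name)
    manifest.stages.append("base_case")
    logger.info("base case in %.2fs: ICER %s", time.perf_counter() - t0, res.icer)

    # --- one-way sensitivity analysis ---
    if specs:
        t0 = time.perf_counter()
        entries = one_way_sa(inputs, arms, specs)
        tornado_path = out / "tornado.csv"
        tornado_table(entries).to_csv(tornado_path, index=False)
        manifest.outputs.append(tornado_path.name)
        manifest.stages.append("owsa")
        logger.info("one-way SA (%d parameters) in %.2fs", len(specs), time.perf_counter() - t0)

        # --- PSA + CEAC ---
        t0 = time.perf_counter()
        draws = run_psa(inputs, arms, specs, n_draws=n_draws, seed=seed)
        psa_path = out / "psa_draws.csv"
        draws.to_frame().to_csv(psa_path, index=False)
        manifest.outputs.append(psa_path.name)
        manifest.stages.append("psa")
        cc = config.get("ceac", {})
        grid = np.arange(
            float(cc.get("wtp_min", 0)),
            float(cc.get("wtp_max", 600_000)) + 1,
            float(cc.get("wtp_step", 10_000)),
        )
        curve = ceac(draws, grid)
        ceac_path = out / "ceac.csv"
        curve.to_frame().to_csv(ceac_path, index=False)
        manifest.outputs.append(ceac_path.name)
        manifest.stages.append("ceac")
        logger.info("PSA (%d draws) + CEAC in %.2fs", n_draws, time.perf_counter() - t0)

    manifest.finished_at = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest_path = out / "manifest.json"
    manifest_path.write_text(manifest.to_json())
    return manifest
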