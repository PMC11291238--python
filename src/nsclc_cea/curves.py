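"""Digitized Kaplan-Meier curves and pseudo-IPD reconstruction.

Published trials report survival as KM figures plus number-at-risk tables
rather than patient-level data.  This module consumes step-curve coordinates
(as produced by manual digitization tools) together with the risk table and
rebuilds pseudo individual patient data (IPD) by the interval-balancing
recursion of Guyot et al.: within each risk-table interval, censoring counts
are iterated until the implied number at risk at the start of the next
interval matches the published one, and events are read off the digitized
survival drops through the product-limit relation.

Times are in months throughout (1 month = 365.25/12 = 30.4375 days).
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from lifelines import KaplanMeierFitter

logger = logging.getLogger("nsclc_cea")

DAYS_PER_MONTH = 365.25 / 12.0  # 30.4375

#: survival at the first coordinate may sit slightly below 1 due to
#: digitization error; anything further off is treated as a bad curve
_T0_TOLERANCE = 0.02
#: small rises between consecutive digitized points are digitization noise
_MONOTONE_TOLERANCE = 1e-9


class SurvivalRecord(NamedTuple):
    """One pseudo-subject: follow-up time in months and event indicator."""

    time: float
    event: int


@dataclass(frozen=True)
class DigitizedKM:
    """A digitized KM step curve plus its number-at-risk table."""

    arm_label: str
    endpoint: str  # "OS" or "PFS"
    coords: tuple[tuple[float, float], ...]  # (time_months, survival)
    risk_table: tuple[tuple[float, int], ...]  # (interval_start, n_at_risk)
    total_events: int | None = None

    def __post_init__(self) -> None:
        if self.endpoint not in ("OS", "PFS"):
            raise ValueError(f"endpoint must be 'OS' or 'PFS', got {self.endpoint!r}")
        if not self.coords:
            raise ValueError("digitized curve has no coordinates")
        if not self.risk_table:
            raise ValueError("digitized curve has an empty risk table")
        times = [t for t, _ in self.coords]
        surv = [s for _, s in self.coords]
        for i, t in enumerate(times):
            if t < 0 or not math.isfinite(t):
                raise ValueError(f"coordinate row {i}: time {t} is not a finite non-negative number")
        for i in range(1, len(times)):
            if times[i] <= times[i - 1]:
                raise ValueError(f"coordinate row {i}: times not strictly increasing ({times[i - 1]} -> {times[i]})")
            if surv[i] > surv[i - 1] + _MONOTONE_TOLERANCE:
                raise ValueError(
                    f"coordinate row {i}: survival rises {surv[i - 1]:.4g} -> {surv[i]:.4g}; "
                    "digitized survival must be non-increasing"
                )
        for i, s in enumerate(surv):
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"coordinate row {i}: survival {s} outside [0, 1]")
        if abs(surv[0] - 1.0) > _T0_TOLERANCE:
            raise ValueError(f"first survival coordinate {surv[0]} is not within {_T0_TOLERANCE} of 1")
        rt_times = [t for t, _ in self.risk_table]
        rt_n = [n for _, n in self.risk_table]
        for i in range(1, len(rt_times)):
            if rt_times[i] <= rt_times[i - 1]:
                raise ValueError(f"risk-table row {i}: interval starts not strictly increasing")
            if rt_n[i] > rt_n[i - 1]:
                raise ValueError(
                    f"risk-table row {i}: n at risk increases {rt_n[i - 1]} -> {rt_n[i]}; "
                    "number at risk must be non-increasing"
                )
        for i, n in enumerate(rt_n):
            if n < 0 or n != int(n):
                raise ValueError(f"risk-table row {i}: n_at_risk must be a non-negative integer")
        if self.total_events is not None and self.total_events < 0:
            raise ValueError("total_events must be non-negative")

    @property
    def n_initial(self) -> int:
        return int(self.risk_table[0][1])


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit estimate: right-continuous step function S(t)."""

    step_times: tuple[float, ...]
    step_survival: tuple[float, ...]
    median: float | None = None

    def survival_at(self, t: float | np.ndarray) -> np.ndarray:
        """S(t) evaluated on the step function (S = 1 before the first step)."""
        times = np.asarray(self.step_times)
        surv = np.asarray(self.step_survival)
        idx = np.searchsorted(times, np.atleast_1d(t), side="right") - 1
        out = np.where(idx >= 0, surv[np.clip(idx, 0, None)], 1.0)
        return out


# ---------------------------------------------------------------------------
# Reading / writing the digitized-curve CSV dialect
# ---------------------------------------------------------------------------

def read_digitized_curve(
    coords_path: str | Path,
    risk_path: str | Path,
    *,
    arm_label: str = "",
    endpoint: str = "OS",
    metadata_path: str | Path | None = None,
) -> DigitizedKM:
    """Read a digitized curve from its coordinate and risk-table CSVs.

    The coordinate CSV has header ``time_months,survival``; the risk-table CSV
    has header ``time_months,n_at_risk``.  An optional JSON sidecar may carry
    ``total_events`` (and override ``arm_label``/``endpoint``).
    """
    coords = []
    for i, row in enumerate(_read_rows(coords_path, ("time_months", "survival"))):
        try:
            coords.append((float(row[0]), float(row[1])))
        except ValueError as exc:
            raise ValueError(f"{coords_path}: malformed coordinate row {i + 1}: {row!r}") from exc
    risk = []
    for i, row in enumerate(_read_rows(risk_path, ("time_months", "n_at_risk"))):
        try:
            risk.append((float(row[0]), int(float(row[1]))))
        except ValueError as exc:
            raise ValueError(f"{risk_path}: malformed risk-table row {i + 1}: {row!r}") from exc
    coords.sort(key=lambda p: p[0])
    total_events = None
    if metadata_path is not None and Path(metadata_path).exists():
        meta = json.loads(Path(metadata_path).read_text())
        total_events = meta.get("total_events")
        arm_label = meta.get("arm_label", arm_label)
        endpoint = meta.get("endpoint", endpoint)
    return DigitizedKM(
        arm_label=arm_label,
        endpoint=endpoint,
        coords=tuple(coords),
        risk_table=tuple(risk),
        total_events=total_events,
    )


def write_digitized_curve(
    curve: DigitizedKM,
    coords_path: str | Path,
    risk_path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Write a curve in the same CSV dialect ``read_digitized_curve`` consumes."""
    with open(coords_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_months", "survival"])
        for t, s in curve.coords:
            w.writerow([repr(t), repr(s)])
    with open(risk_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_months", "n_at_risk"])
        for t, n in curve.risk_table:
            w.writerow([repr(t), n])
    if metadata_path is not None:
        Path(metadata_path).write_text(
            json.dumps(
                {
                    "arm_label": curve.arm_label,
                    "endpoint": curve.endpoint,
                    "total_events": curve.total_events,
                }
            )
        )


def write_ipd(records: Sequence[SurvivalRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_months", "event"])
        for r in records:
            w.writerow([repr(float(r.time)), int(r.event)])


def read_ipd(path: str | Path) -> list[SurvivalRecord]:
    out = []
    for i, row in enumerate(_read_rows(path, ("time_months", "event"))):
        try:
            out.append(SurvivalRecord(float(row[0]), int(float(row[1]))))
        except ValueError as exc:
            raise ValueError(f"{path}: malformed IPD row {i + 1}: {row!r}") from exc
    return out


def _read_rows(path: str | Path, expected_header: tuple[str, ...]) -> list[list[str]]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = [h.strip() for h in next(reader)]
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if header != list(expected_header):
            raise ValueError(f"{path}: expected header {','.join(expected_header)!r}, got {','.join(header)!r}")
        rows = [row for row in reader if row and any(cell.strip() for cell in row)]
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return rows


# ---------------------------------------------------------------------------
# Guyot interval-balancing reconstruction
# ---------------------------------------------------------------------------

def reconstruct_ipd(curve: DigitizedKM) -> list[SurvivalRecord]:
    """Rebuild pseudo individual patient data from a digitized KM curve.

    Within each risk-table interval the number of censorings is iterated
    (spread uniformly over the interval) until the implied number at risk at
    the start of the next interval matches the published count; events at each
    digitized drop follow from the product-limit relation.  Subjects still at
    risk past the last coordinate are administratively censored there.  If the
    published total event count is known, events in the final interval are
    rebalanced to match it.

    The number of returned records always equals the initial number at risk.
    """
    t = np.array([c[0] for c in curve.coords], dtype=float)
    s = np.array([c[1] for c in curve.coords], dtype=float)
    # enforce monotone survival (digitization noise within tolerance)
    s = np.minimum.accumulate(s)
    rt_times = [rt for rt, _ in curve.risk_table]
    rt_n = [n for _, n in curve.risk_table]
    n_int = len(rt_times)
    # lower[i] = index of first coordinate at/after the interval start
    lower = [int(np.searchsorted(t, rt_times[i], side="left")) for i in range(n_int)]
    lower[0] = 0
    upper = [lower[i + 1] for i in range(n_int - 1)] + [len(t)]

    event_counts = np.zeros(len(t), dtype=int)
    censor_times_all: list[float] = []
    n_cur = rt_n[0]
    km_prod = 1.0  # estimated KM at the last processed coordinate
    j_start = 0
    for i in range(n_int):
        j_end = upper[i]
        target_next = rt_n[i + 1] if i + 1 < n_int else None
        t_lo = t[j_start] if j_start < len(t) else rt_times[i]
        t_hi = t[j_end] if j_end < len(t) else t[-1]
        if target_next is not None:
            # initial censoring guess from the survival ratio across the interval
            s_lo = s[j_start]
            s_next = s[j_end] if j_end < len(t) else s[-1]
            guess = int(round(n_cur * (s_next / s_lo if s_lo > 0 else 0.0))) - target_next
            ncensor = max(0, guess)
        else:
            ncensor = 0
        best = None
        for _ in range(60):
            d, c_times, n_end, km_end = _process_interval(
                t, s, j_start, j_end, n_cur, km_prod, ncensor, t_lo, t_hi
            )
            if target_next is None:
                best = (d, c_times, n_end, km_end)
                break
            err = n_end - target_next
            if best is None or abs(err) < abs(best[2] - target_next):
                best = (d, c_times, n_end, km_end)
            if err == 0:
                break
            ncensor_new = ncensor + err
            if ncensor_new < 0:
                logger.warning(
                    "curve %s/%s interval %d implies negative censorings; clamped to 0",
                    curve.arm_label, curve.endpoint, i,
                )
                ncensor_new = 0
            if ncensor_new == ncensor:
                break
            ncensor = ncensor_new
        d, c_times, n_cur, km_prod = best
        event_counts[j_start:j_end] = d
        censor_times_all.extend(c_times)
        j_start = j_end

    records: list[SurvivalRecord] = []
    for j in range(len(t)):
        records.extend([SurvivalRecord(float(t[j]), 1)] * int(event_counts[j]))
    records.extend(SurvivalRecord(float(ct), 0) for ct in censor_times_all)
    # subjects still at risk after the final coordinate: administrative censoring
    records.extend([SurvivalRecord(float(t[-1]), 0)] * int(n_cur))

    if curve.total_events is not None:
        records = _rebalance_total_events(records, curve.total_events)

    records.sort(key=lambda r: (r.time, -r.event))
    if len(records) != curve.n_initial:
        raise AssertionError(
            f"reconstruction produced {len(records)} records for {curve.n_initial} subjects"
        )
    return records


def _process_interval(t, s, j_start, j_end, n_start, km_start, ncensor, t_lo, t_hi):
    """Distribute ``ncensor`` censorings uniformly and infer events per drop."""
    if ncensor > 0 and t_hi > t_lo:
        c_times = list(t_lo + (np.arange(1, ncensor + 1) - 0.5) / ncensor * (t_hi - t_lo))
    elif ncensor > 0:
        c_times = [float(t_lo)] * ncensor
    else:
        c_times = []
    c_times_arr = np.array(c_times)
    n_cur = n_start
    km = km_start
    d = np.zeros(j_end - j_start, dtype=int)
    for j in range(j_start, j_end):
        if km > 0 and n_cur > 0:
            dj = int(round(n_cur * (1.0 - s[j] / km)))
            dj = min(max(dj, 0), n_cur)
        else:
            dj = 0
        d[j - j_start] = dj
        if dj > 0:
            km = km * (1.0 - dj / n_cur)
        n_cur -= dj
        # censorings assigned between this coordinate and the next
        t_next = t[j + 1] if j + 1 < len(t) else np.inf
        n_c = int(np.sum((c_times_arr > t[j]) & (c_times_arr <= t_next))) if ncensor else 0
        n_cur = max(0, n_cur - n_c)
    return d, c_times, n_cur, km


def _rebalance_total_events(records: list[SurvivalRecord], total_events: int) -> list[SurvivalRecord]:
    """Flip late censorings to events (or vice versa) to match the published count."""
    inferred = sum(r.event for r in records)
    if inferred == total_events:
        return records
    records = sorted(records, key=lambda r: (r.time, -r.event))
    if inferred < total_events:
        deficit = total_events - inferred
        # latest censored records become events
        for idx in range(len(records) - 1, -1, -1):
            if deficit == 0:
                break
            if records[idx].event == 0:
                records[idx] = SurvivalRecord(records[idx].time, 1)
                deficit -= 1
        if deficit:
            logger.warning("could not reach published total_events; short by %d", deficit)
    else:
        surplus = inferred - total_events
        for idx in range(len(records) - 1, -1, -1):
            if surplus == 0:
                break
            if records[idx].event == 1:
                records[idx] = SurvivalRecord(records[idx].time, 0)
                surplus -= 1
    return records


# ---------------------------------------------------------------------------
# Product-limit estimator
# ---------------------------------------------------------------------------

def km_estimate(records: Sequence[SurvivalRecord]) -> KMEstimate:
    """Product-limit (Kaplan-Meier) estimate of S(t) from (time, event) records.

    Ties between events and censorings at the same time are handled
    events-first (the standard KM convention).  The median is the earliest
    time at which the estimate reaches 0.5, or None if it never does.
    """
    if not len(records):
        raise ValueError("km_estimate requires at least one record")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    step_times = tuple(float(x) for x in sf.index.to_numpy())
    step_surv = tuple(float(x) for x in sf.iloc[:, 0].to_numpy())
    median = kmf.median_survival_time_
    median_out = None if not math.isfinite(median) else float(median)
    return KMEstimate(step_times=step_times, step_survival=step_surv, median=median_out)


def max_survival_gap(a: KMEstimate, b: KMEstimate, t_max: float, n_grid: int = 2000) -> float:
    """max_t |S_a(t) - S_b(t)| on a dense grid over [0, t_max]."""
    grid = np.linspace(0.0, t_max, n_grid)
    return float(np.max(np.abs(a.survival_at(grid) - b.survival_at(grid))))
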