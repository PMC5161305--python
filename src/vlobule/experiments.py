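"""Executable virtual-experiment protocols with seeded Monte Carlo trials.

A virtual experiment runs one mechanism configuration over ``n_trials``
independent Monte Carlo lobule variants (fresh geometry and event streams
per trial, spawned from one master seed) and aggregates event logs:

* single-pass perfusion -- constant APAP input, measures the hepatic
  extraction ratio of the metabolism-phase configuration;
* bolus toxicity time course -- one dose, 24 h horizon, death log and
  regional band time series;
* dose-response -- dead hepatocytes at 24 h versus dose;
* variant sweep -- total and per-zone deaths for a set of mechanism
  variants, flagged "experimentally indistinguishable" when within +/-20%
  of the reference-mechanism mean.

Death events are measured by a polling observer kept strictly separate from
mechanism state: observation reads logs and never mutates the simulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cellcascade as cc
from . import transport as tp
from .engine import PerfusionTrace, TrialResult, run_bolus_trial, run_perfusion_trial
from .lobule import GeometryConfig, LobuleGraph, build_lobule

__all__ = [
    "PerfusionProtocol",
    "BolusProtocol",
    "ExtractionResult",
    "ExperimentResult",
    "run_single_pass_perfusion",
    "run_bolus_experiment",
    "poll_death_observer",
    "DeathObserver",
    "region_band_indices",
    "region_band_measurements",
    "run_dose_response",
    "run_variant_sweep",
    "trial_seeds",
]

HOUR = 3600.0
DAY = 86400.0

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PerfusionProtocol:
    """Constant-rate single-pass perfusion of one lobule."""

    input_rate: int = 100            # APAP objects per second at the PP entrances
    duration: float = 3000.0         # seconds
    stabilization_window: float = 300.0
    stabilization_tolerance: float = 0.02   # relative variation of windowed mean

    def __post_init__(self):
        if not self.duration > self.stabilization_window > 0:
            raise ValueError("need duration > stabilization_window > 0")


@dataclass(frozen=True)
class BolusProtocol:
    """A bolus-dose toxicity experiment over Monte Carlo lobule variants."""

    dose: tp.DoseSpec
    horizon: float = DAY
    n_trials: int = 12
    poll_interval: float = 60.0
    region_band_width: float = 5.0
    record_interval: float = 60.0

    def __post_init__(self):
        if self.n_trials < 1 or self.poll_interval < 1:
            raise ValueError("need n_trials >= 1 and poll_interval >= 1")


@dataclass
class ExtractionResult:
    """Outcome of a single-pass perfusion run."""

    extraction_ratio: float
    outflow_input_ratio: float
    stabilized: bool
    stabilization_time: float | None
    trace: PerfusionTrace


def trial_seeds(master_seed: int, n_trials: int) -> list[np.random.SeedSequence]:
    """Spawn one independent child seed sequence per Monte Carlo trial."""
    return np.random.SeedSequence(master_seed).spawn(n_trials)


def _lobule_for(child: np.random.SeedSequence, geometry: GeometryConfig | None) -> LobuleGraph:
    lobule_seed = int(child.generate_state(1)[0] % (2**31))
    return build_lobule(lobule_seed, geometry)


def run_single_pass_perfusion(
    proto: PerfusionProtocol,
    cfg: cc.MechanismConfig,
    lobule: LobuleGraph,
    seed: int,
    params: tp.TransportParams | None = None,
) -> ExtractionResult:
    """Measure the hepatic extraction ratio ER = 1 - outflow/input.

    The toxicity phase is disabled (metabolism only).  Outflow is judged
    stabilized at the first time two consecutive non-overlapping windowed
    means agree to within the relative tolerance; ER is then computed from
    the mean outflow over all subsequent steps.  A run that never
    stabilizes is returned with ``stabilized=False`` and the last-window
    ratio.
    """
    params = params or tp.TransportParams()
    rng = np.random.default_rng(seed)
    trace = run_perfusion_trial(
        lobule, cfg, params, proto.input_rate, proto.duration, rng, toxicity=False
    )
    w = int(proto.stabilization_window)
    out = trace.outflow.astype(float)
    stabilized, t_stab = False, None
    for t in range(2 * w, out.size + 1, w):
        m_prev = out[t - 2 * w : t - w].mean()
        m_curr = out[t - w : t].mean()
        ref = max(m_curr, 1e-9)
        if abs(m_curr - m_prev) < proto.stabilization_tolerance * ref:
            stabilized, t_stab = True, float(t)
            break
    if stabilized:
        ratio = out[int(t_stab) - w :].mean() / proto.input_rate
    else:
        ratio = out[-w:].mean() / proto.input_rate
    return ExtractionResult(
        extraction_ratio=1.0 - ratio,
        outflow_input_ratio=ratio,
        stabilized=stabilized,
        stabilization_time=t_stab,
        trace=trace,
    )


def region_band_indices(dpp: np.ndarray, d_max: float, band_width: float) -> dict[str, np.ndarray]:
    """Hepatocyte indices of the three measurement bands.

    PP band: dPP in [0, w); CV band: distance-to-CV in [0, w), i.e.
    dPP in (d_max - w, d_max] (cells beyond d_max count as at the CV);
    Midzonal band: width w centered on d_max / 2.  Bands are disjoint for
    any w <= d_max / 3.
    """
    if band_width > d_max / 3:
        raise ValueError(f"band width {band_width} > d_max/3 = {d_max / 3}")
    mid_lo = d_max / 2 - band_width / 2
    mid_hi = d_max / 2 + band_width / 2
    return {
        "PP": np.nonzero(dpp < band_width)[0],
        "Midzonal": np.nonzero((dpp >= mid_lo) & (dpp < mid_hi))[0],
        "CV": np.nonzero(dpp > d_max - band_width)[0],
    }


def region_band_measurements(
    lobule: LobuleGraph, cells: cc.HepatocyteState, band_width: float = 5.0
) -> pd.DataFrame:
    """Per-band per-hepatocyte means of the cascade counters (current state)."""
    bands = region_band_indices(cells.dpp, lobule.d_max, band_width)
    rows = []
    for name, idx in bands.items():
        rows.append(
            {
                "band": name,
                "n_cells": idx.size,
                "napqi": cells.napqi[idx].mean(),
                "gs_exported": cells.gs_exported[idx].mean(),
                "mitod": cells.mitod[idx].mean(),
                "gsh_depletion_events": cells.gsh_depletion_events[idx].mean(),
                "mitigation_events": cells.mitigation_events[idx].mean(),
            }
        )
    return pd.DataFrame(rows).set_index("band")


@dataclass
class ExperimentResult:
    """Aggregated logs and summary of one bolus experiment."""

    mechanism: str
    protocol: BolusProtocol
    master_seed: int
    trials: list[TrialResult]
    death_log: pd.DataFrame
    summary: dict

    @property
    def d_max_mean(self) -> float:
        return float(np.mean([t.d_max for t in self.trials]))


def _death_log_frame(trials: list[TrialResult], horizon: float) -> pd.DataFrame:
    frames = []
    for i, tr in enumerate(trials):
        frames.append(
            pd.DataFrame(
                {
                    "trial": i,
                    "trigger_time": tr.trigger_times,
                    "death_time": tr.death_times,
                    "dpp": tr.trigger_dpp,
                    "distance_to_cv": tr.trigger_distance,
                    "zone": tr.trigger_zone,
                }
            )
        )
    log = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["trial", "trigger_time", "death_time", "dpp", "distance_to_cv", "zone"]
    )
    return log


def run_bolus_experiment(
    proto: BolusProtocol,
    cfg: cc.MechanismConfig,
    seed: int,
    params: tp.TransportParams | None = None,
    geometry: GeometryConfig | None = None,
    record_regions: bool = True,
    audit_interval: float | None = None,
) -> ExperimentResult:
    """Run ``n_trials`` independent Monte Carlo lobule variants.

    Each trial gets a fresh lobule and a fresh random stream spawned from
    the master seed; (protocol, mechanism, master seed) fully determines
    the result.
    """
    params = params or tp.TransportParams()
    trials: list[TrialResult] = []
    for i, child in enumerate(trial_seeds(seed, proto.n_trials)):
        lobule = _lobule_for(child, geometry)
        rng = np.random.default_rng(child)
        band_idx = (
            region_band_indices(lobule.hepatocyte_dpp(), lobule.d_max, proto.region_band_width)
            if record_regions
            else None
        )
        trials.append(
            run_bolus_trial(
                lobule, cfg, params, proto.dose, proto.horizon, rng,
                record_interval=proto.record_interval, band_idx=band_idx,
                audit_interval=audit_interval, seed_key=(seed, i),
            )
        )
        logger.info(
            "%s trial %d/%d: %d triggers, %d NAPQI created",
            cfg.name, i + 1, proto.n_trials,
            trials[-1].trigger_times.size, trials[-1].cum_napqi_created,
        )
    death_log = _death_log_frame(trials, proto.horizon)
    observed = death_log[death_log.death_time <= proto.horizon]
    dose_total = proto.dose.n_objects * proto.n_trials
    summary = {
        "mechanism": cfg.name,
        "n_trials": proto.n_trials,
        "dose_objects": proto.dose.n_objects,
        "total_deaths": int(len(observed)),
        "deaths_per_zone": {
            z: int((observed.zone == z).sum()) for z in (1, 2, 3)
        },
        "earliest_death_h": (
            float(observed.death_time.min() / HOUR) if len(observed) else None
        ),
        "napqi_dose_fraction": (
            sum(t.cum_napqi_created for t in trials) / dose_total if dose_total else None
        ),
        "total_hepatocytes": 14000 * proto.n_trials,
    }
    return ExperimentResult(
        mechanism=cfg.name, protocol=proto, master_seed=seed,
        trials=trials, death_log=death_log, summary=summary,
    )


class DeathObserver:
    """Polling observer for death events, separate from mechanism state.

    At each poll it reports cells whose death time passed since the prior
    poll.  Observation is read-only: it never mutates simulation state nor
    consumes the mechanism's random stream, so enabling or disabling it
    cannot change a trajectory.
    """

    def __init__(self, poll_interval: float = 60.0):
        self.poll_interval = poll_interval
        self.last_poll = 0.0
        self.observed: list[tuple[float, np.ndarray]] = []

    def poll(self, death_times: np.ndarray, t: float) -> np.ndarray:
        newly = np.nonzero((death_times > self.last_poll) & (death_times <= t))[0]
        self.last_poll = t
        self.observed.append((t, newly))
        return newly


def poll_death_observer(
    death_times: np.ndarray, t: float, poll_interval: float
) -> list[tuple[float, np.ndarray]]:
    """Report deaths at each polling time in (0, t] (each exactly once)."""
    obs = DeathObserver(poll_interval)
    out = []
    poll_t = poll_interval
    while poll_t <= t:
        out.append((poll_t, obs.poll(death_times, poll_t)))
        poll_t += poll_interval
    return out


def run_dose_response(
    cfg: cc.MechanismConfig,
    doses: list[tp.DoseSpec],
    n_trials: int,
    seed: int,
    horizon: float = DAY,
    params: tp.TransportParams | None = None,
    geometry: GeometryConfig | None = None,
) -> pd.DataFrame:
    """Dead hepatocytes at the horizon versus dose (paired Monte Carlo seeds).

    Trials are paired across doses: trial i of every dose shares the same
    lobule geometry and event stream seeds, so dose contrasts are within-
    pair comparisons.  Returns one row per dose with the Monte Carlo mean,
    standard error, and percent reduction relative to the largest dose.
    """
    if len(doses) < 2:
        raise ValueError("need at least two doses")
    params = params or tp.TransportParams()
    children = trial_seeds(seed, n_trials)
    rows = []
    deaths_by_dose = {}
    for dose in doses:
        per_trial = []
        for child in children:
            lobule = _lobule_for(child, geometry)
            rng = np.random.default_rng(child)
            tr = run_bolus_trial(
                lobule, cfg, params, dose, horizon, rng,
                record_interval=3600.0, band_idx=None,
            )
            per_trial.append(tr.deaths_by(horizon))
        deaths_by_dose[dose.n_objects] = np.asarray(per_trial, dtype=float)
    ref = max(deaths_by_dose)
    for dose in doses:
        d = deaths_by_dose[dose.n_objects]
        r = deaths_by_dose[ref]
        with np.errstate(invalid="ignore", divide="ignore"):
            reduction = 100.0 * (1.0 - d / np.where(r > 0, r, np.nan))
        valid = np.isfinite(reduction)
        rows.append(
            {
                "dose_objects": dose.n_objects,
                "mean_deaths": d.mean(),
                "sem_deaths": d.std(ddof=1) / np.sqrt(len(d)) if len(d) > 1 else 0.0,
                "pct_reduction_vs_max_dose": (
                    float(reduction[valid].mean()) if valid.any() else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)


def run_variant_sweep(
    variants: list[cc.MechanismConfig],
    proto: BolusProtocol,
    seed: int,
    reference: str = "MGNZ",
    indistinguishable_band: float = 0.20,
    params: tp.TransportParams | None = None,
    geometry: GeometryConfig | None = None,
) -> pd.DataFrame:
    """Total and per-zone 24-h deaths per mechanism variant.

    Every variant runs the same protocol with the same master seed.  A
    variant is flagged experimentally indistinguishable when its total is
    within +/- ``indistinguishable_band`` (default 20%) of the reference
    mechanism's mean.  The reference is the variant whose name matches
    ``reference``; it must be present in ``variants``.
    """
    results = {}
    for cfg in variants:
        res = run_bolus_experiment(
            proto, cfg, seed, params=params, geometry=geometry, record_regions=False
        )
        results[cfg.name] = res.summary
    if reference not in results:
        raise ValueError(f"reference mechanism {reference!r} not among variants")
    ref_mean = results[reference]["total_deaths"]
    rows = []
    for name, s in results.items():
        total = s["total_deaths"]
        rows.append(
            {
                "variant": name,
                "total_deaths": total,
                "deaths_zone1": s["deaths_per_zone"][1],
                "deaths_zone2": s["deaths_per_zone"][2],
                "deaths_zone3": s["deaths_per_zone"][3],
                "total_hepatocytes": s["total_hepatocytes"],
                "indistinguishable": bool(
                    abs(total - ref_mean) <= indistinguishable_band * ref_mean
                ),
            }
        )
    return pd.DataFrame(rows).sort_values("total_deaths").reset_index(drop=True)
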