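"""Vectorized per-second simulation core for one lobule trial.

This module wires the transport layer (body compartments, column-resolved
percolation) to the hepatocyte cascade kernels and runs the 1 s/step loop,
accumulating event logs and time series.  It is an implementation detail of
the experiment protocols in :mod:`vlobule.experiments`; the scientific
surface (kernels, presets, protocols, metrics) lives in the named modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import cellcascade as cc
from . import transport as tp
from .lobule import LobuleGraph

__all__ = ["TrialResult", "run_bolus_trial", "run_perfusion_trial", "cell_column_map"]


def cell_column_map(lobule: LobuleGraph, contents: tp.SegmentContents):
    """Map hepatocytes to flat sinusoid columns.

    Returns ``(cell_col, cell_start, cell_count)``: the flat column index of
    every cell, and per-column contiguous (start, count) into the cell
    arrays.  Relies on hepatocyte_positions() emitting cells grouped by
    segment and ascending x.
    """
    seg_ids, xs, _ = lobule.hepatocyte_positions()
    cell_col = contents.col_start[seg_ids] + xs
    n_cols = contents.free.size
    cell_count = np.bincount(cell_col, minlength=n_cols).astype(np.int64)
    cell_start = np.concatenate([[0], np.cumsum(cell_count)[:-1]])
    return cell_col, cell_start, cell_count


@dataclass
class TrialResult:
    """Raw logs from one Monte Carlo trial."""

    seed_key: tuple
    d_max: float
    horizon: float
    dose_objects: int
    zone3_mean_length: float = 0.0
    # trigger/death log (one row per triggered cell, in trigger order)
    trigger_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    death_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    trigger_dpp: np.ndarray = field(default_factory=lambda: np.empty(0))
    trigger_distance: np.ndarray = field(default_factory=lambda: np.empty(0))
    trigger_zone: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    # body time series, recorded every record_interval seconds
    series_time: np.ndarray = field(default_factory=lambda: np.empty(0))
    body_series: dict[str, np.ndarray] = field(default_factory=dict)
    regional_series: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    # cumulative totals
    cum_napqi_created: int = 0
    cum_gs_created: int = 0
    cum_depletion_events: int = 0
    cum_mitigation_events: int = 0
    final_cells: object = None

    def deaths_by(self, t: float) -> int:
        return int(np.count_nonzero(self.death_times <= t))

    def napqi_dose_fraction(self) -> float:
        if self.dose_objects == 0:
            raise ZeroDivisionError("NAPQI dose fraction undefined for zero dose")
        return self.cum_napqi_created / self.dose_objects


_REGIONAL_FIELDS = ("napqi", "gs", "depletion", "mitod", "mitigation")


def _regional_record(cells: cc.HepatocyteState, band_idx: dict[str, np.ndarray], sink):
    for name, idx in band_idx.items():
        rec = sink[name]
        rec["napqi"].append(cells.napqi[idx].mean())
        rec["gs"].append(cells.gs_exported[idx].mean())
        rec["depletion"].append(cells.gsh_depletion_events[idx].mean())
        rec["mitod"].append(cells.mitod[idx].mean())
        rec["mitigation"].append(cells.mitigation_events[idx].mean())


def run_bolus_trial(
    lobule: LobuleGraph,
    cfg: cc.MechanismConfig,
    params: tp.TransportParams,
    dose: tp.DoseSpec,
    horizon: float,
    rng: np.random.Generator,
    record_interval: float = 60.0,
    band_idx: dict[str, np.ndarray] | None = None,
    audit_interval: float | None = None,
    toxicity: bool = True,
    seed_key: tuple = (),
) -> TrialResult:
    """Run one bolus-dose trial for ``horizon`` simulated seconds at 1 s/step."""
    contents = tp.SegmentContents.for_lobule(lobule, with_marker=dose.marker_objects > 0)
    body = tp.MouseBodyState.from_dose(dose, params)
    cell_col, cell_start, cell_count = cell_column_map(lobule, contents)
    seg_ids, _, zones = lobule.hepatocyte_positions()
    dpp = lobule.hepatocyte_dpp()
    cells = cc.HepatocyteState.zeros(dpp, segment_id=seg_ids, zone=zones)
    cp = cc.bind_config(cfg, dpp, lobule.d_max)

    res = TrialResult(seed_key=seed_key, d_max=lobule.d_max, horizon=horizon,
                      dose_objects=dose.n_objects,
                      zone3_mean_length=lobule.zone_mean_lengths[3])
    # running count of triggered (necrotizing) cells per column for the
    # necrotic-sink uptake boost
    col_trig_count = np.zeros(contents.free.size, dtype=np.int64)
    col_cells = np.maximum(cell_count, 1).astype(float)
    col_trig_frac = np.zeros(contents.free.size)
    trig_t: list[np.ndarray] = []
    trig_idx: list[np.ndarray] = []
    times: list[float] = []
    body_rec: dict[str, list] = {k: [] for k in ("depot", "body_apap", "body_gs", "body_marker")}
    reg_rec = (
        {name: {f: [] for f in _REGIONAL_FIELDS} for name in band_idx}
        if band_idx else None
    )
    phases = list(cc.CASCADE_PHASES) if toxicity else ["metabolism"]

    for step in range(int(horizon)):
        t = float(step + 1)
        tp.absorption_step(body, rng)
        tp.liver_inflow_step(body, contents, rng)
        tp.cell_release_step(
            contents, params, rng, cells.apap, cell_col, cells.triggered | cells.dead
        )
        tp.percolation_step(
            contents, params, rng, cell_start, cell_count, cells.apap,
            col_triggered_frac=col_trig_frac if toxicity else None,
        )

        order = list(phases)
        rng.shuffle(order)
        for phase in order:
            if phase == "metabolism":
                s = cc.metabolism_step(cells, cp, rng)
                res.cum_napqi_created += s.napqi_created
                res.cum_gs_created += s.gs_created
                body.body_gs += s.gs_created
            elif phase == "napqi_fate":
                s = cc.napqi_fate_step(cells, cp, rng)
                res.cum_depletion_events += s.gsh_depletion_events
            elif phase == "amplification":
                cc.amplification_step(cells, cp, rng)
            elif phase == "mitigation":
                s = cc.mitigation_step(cells, cp, rng)
                res.cum_mitigation_events += s.mitod_mitigated
            else:
                s = cc.death_trigger_check(cells, cp, t, rng)
                if s.triggered_idx.size:
                    trig_t.append(np.full(s.triggered_idx.size, t))
                    trig_idx.append(s.triggered_idx)
                    np.add.at(col_trig_count, cell_col[s.triggered_idx], 1)
                    col_trig_frac = col_trig_count / col_cells

        tp.cv_return_step(body, contents)
        if toxicity:
            cc.apply_deaths(cells, t)

        if audit_interval and step % int(audit_interval) == 0:
            tp.mass_balance_audit(
                body, contents, cells.apap, res.cum_napqi_created,
                res.cum_gs_created, dose.n_objects, dose.marker_objects,
            )
        if step % int(record_interval) == 0:
            times.append(t)
            body_rec["depot"].append(body.depot)
            body_rec["body_apap"].append(body.body_apap)
            body_rec["body_gs"].append(body.body_gs)
            body_rec["body_marker"].append(body.body_marker)
            if reg_rec is not None:
                _regional_record(cells, band_idx, reg_rec)

    if trig_idx:
        idx = np.concatenate(trig_idx)
        res.trigger_times = np.concatenate(trig_t)
        res.death_times = cells.death_time[idx]
        res.trigger_dpp = cells.dpp[idx]
        res.trigger_distance = np.maximum(0.0, lobule.d_max - cells.dpp[idx])
        res.trigger_zone = cells.zone[idx]
    res.series_time = np.asarray(times)
    res.body_series = {k: np.asarray(v) for k, v in body_rec.items()}
    if reg_rec is not None:
        res.regional_series = {
            name: {f: np.asarray(v) for f, v in rec.items()} for name, rec in reg_rec.items()
        }
    res.final_cells = cells
    return res


@dataclass
class PerfusionTrace:
    """Per-second outflow record from a single-pass perfusion run."""

    input_rate: float
    outflow: np.ndarray           # objects returning to CV per second
    metabolized: np.ndarray       # cumulative metabolism events per second
    final_cells: object = None


def run_perfusion_trial(
    lobule: LobuleGraph,
    cfg: cc.MechanismConfig,
    params: tp.TransportParams,
    input_rate: int,
    duration: float,
    rng: np.random.Generator,
    toxicity: bool = False,
) -> PerfusionTrace:
    """Single-pass perfusion: constant APAP input at the PP entrances.

    No body compartment and no recirculation: outflow at the CV is simply
    counted per second.  Used with the toxicity phase disabled to measure
    the hepatic extraction ratio of the metabolism-phase configuration.
    """
    contents = tp.SegmentContents.for_lobule(lobule)
    cell_col, cell_start, cell_count = cell_column_map(lobule, contents)
    dpp = lobule.hepatocyte_dpp()
    cells = cc.HepatocyteState.zeros(dpp)
    cp = cc.bind_config(cfg, dpp, lobule.d_max)
    outflow = np.zeros(int(duration), dtype=np.int64)
    metabolized = np.zeros(int(duration), dtype=np.int64)
    phases = list(cc.CASCADE_PHASES) if toxicity else ["metabolism"]

    for step in range(int(duration)):
        t = float(step + 1)
        alloc = rng.multinomial(input_rate, contents.entrance_probs)
        np.add.at(contents.free, contents.entrance_cols, alloc)
        tp.cell_release_step(contents, params, rng, cells.apap, cell_col)
        tp.percolation_step(contents, params, rng, cell_start, cell_count, cells.apap)
        order = list(phases)
        rng.shuffle(order)
        for phase in order:
            if phase == "metabolism":
                s = cc.metabolism_step(cells, cp, rng)
                metabolized[step] = s.apap_consumed
            elif phase == "napqi_fate":
                cc.napqi_fate_step(cells, cp, rng)
            elif phase == "amplification":
                cc.amplification_step(cells, cp, rng)
            elif phase == "mitigation":
                cc.mitigation_step(cells, cp, rng)
            else:
                cc.death_trigger_check(cells, cp, t, rng)
        outflow[step] = contents.cv_apap
        contents.cv_apap = 0

    return PerfusionTrace(input_rate=float(input_rate), outflow=outflow,
                          metabolized=metabolized, final_cells=cells)
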