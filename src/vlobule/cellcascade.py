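"""Per-hepatocyte stochastic event cascade and the four mechanism hypotheses.

Each simulated second a hepatocyte runs, in pseudo-random order, the five
cascade phases: APAP metabolism (-> NAPQI or inactive G&S), NAPQI fate
(glutathione depletion while below the depletion threshold, otherwise
reaction into damage products), mitoD amplification, damage mitigation, and
the irreversible death-trigger check.  All events are per-object Bernoulli
trials; on integer counters they are implemented as binomial draws, which is
distributionally identical and lets the whole 14,000-cell population run as
a handful of vectorized draws per step.

The four mechanism hypotheses differ only in which features are zonated
(vary along the PP->CV axis):

* NZ    - NAPQI-formation zonation only (metabolism 0.35->0.95 and NAPQI
          fraction 0.33->0.90, both linear); GSH depletion threshold and
          mitoD mitigation are location-independent (3.5 and 0.67).
* GNZ   - NZ plus a linearly decreasing GSH depletion threshold (5 at the
          entrance, endpoint calibrated so the census mean stays 3.5).
* MNZ   - NZ plus reverse-sigmoid mitoD mitigation (0.9 -> 0, inflection
          mid-Zone-2, steepness calibrated so the census mean stays 0.67).
* MGNZ  - both zonations combined.

``HepatocyteState`` is a struct-of-arrays over a whole cell population (a
single cell is simply a population of size one).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .lobule import GradientSpec, calibrate_gradient_mean, canonical_dpp_population, gradient_value

__all__ = [
    "MechanismConfig",
    "HepatocyteState",
    "CellParams",
    "EventRecord",
    "StepStats",
    "bind_config",
    "metabolism_step",
    "napqi_fate_step",
    "amplification_step",
    "mitigation_step",
    "death_trigger_check",
    "hepatocyte_step",
    "mechanism_preset",
    "make_variant",
    "CASCADE_PHASES",
    "VARIANT_KNOBS",
    "HOUR",
]

HOUR = 3600.0

#: Cascade phase names in canonical order (shuffled each step at run time).
CASCADE_PHASES = (
    "metabolism",
    "napqi_fate",
    "amplification",
    "mitigation",
    "trigger",
)

#: The ten influential configuration knobs a mechanism variant may override:
#: the five zonation-capable gradients plus five scalar features.
VARIANT_KNOBS = (
    "p_metabolize",
    "p_napqi",
    "gsh_threshold",
    "p_mitod_mitigation",
    "p_gsh_depletion",
    "p_react",
    "death_delay",
    "p_mitod_split",
    "p_nonmd_mitigation",
    "death_trigger_threshold",
)


@dataclass(frozen=True)
class MechanismConfig:
    """Full parameter set of one mechanism hypothesis.

    Probabilities are per object per 1-second step.  ``death_delay`` is
    ("uniform", lo_s, hi_s) or ("normal", mean_s, sd_s); draws from the
    normal rule are floored at zero.  ``amplification`` is (lo, hi) for the
    discrete-uniform extra-mitoD draw, or None to disable amplification.
    """

    name: str
    p_metabolize: GradientSpec
    p_napqi: GradientSpec
    gsh_threshold: GradientSpec
    p_mitod_mitigation: GradientSpec
    p_gsh_depletion: GradientSpec = field(default_factory=lambda: GradientSpec.constant(0.5))
    p_react: float = 0.5
    p_mitod_split: float = 0.5
    p_nonmd_mitigation: float = 0.5
    death_trigger_threshold: int = 6
    death_delay: tuple = ("uniform", 1.2 * HOUR, 12.0 * HOUR)
    amplification: tuple[int, int] | None = (1, 6)

    def __post_init__(self):
        for p in (self.p_react, self.p_mitod_split, self.p_nonmd_mitigation):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.death_trigger_threshold < 1:
            raise ValueError("death_trigger_threshold must be >= 1")
        kind = self.death_delay[0]
        if kind == "uniform":
            lo, hi = self.death_delay[1:]
            if not 0 < lo < hi:
                raise ValueError(f"uniform death delay bounds {lo},{hi} invalid")
        elif kind != "normal":
            raise ValueError(f"unknown death delay rule {kind!r}")


@dataclass
class HepatocyteState:
    """Struct-of-arrays state for a population of hepatocytes.

    ``mitod_unamplified`` holds mitoD that have not yet had their single
    amplification opportunity; ``mitod_amplified`` holds the absorbing
    post-amplification pool.  ``gs_exported``, ``gsh_depletion_events`` and
    ``mitigation_events`` are cumulative counters used for the regional
    time series.
    """

    dpp: np.ndarray
    segment_id: np.ndarray
    zone: np.ndarray
    apap: np.ndarray
    napqi: np.ndarray
    gs_exported: np.ndarray
    gsh_depletion_events: np.ndarray
    mitod_unamplified: np.ndarray
    mitod_amplified: np.ndarray
    nonmd: np.ndarray
    mitigation_events: np.ndarray
    triggered: np.ndarray
    trigger_time: np.ndarray
    death_time: np.ndarray
    dead: np.ndarray

    @classmethod
    def zeros(cls, dpp, segment_id=None, zone=None) -> "HepatocyteState":
        dpp = np.atleast_1d(np.asarray(dpp, dtype=float))
        n = dpp.size
        z = lambda: np.zeros(n, dtype=np.int64)
        return cls(
            dpp=dpp,
            segment_id=np.zeros(n, dtype=np.int64) if segment_id is None else np.asarray(segment_id),
            zone=np.ones(n, dtype=np.int64) if zone is None else np.asarray(zone),
            apap=z(), napqi=z(), gs_exported=z(), gsh_depletion_events=z(),
            mitod_unamplified=z(), mitod_amplified=z(), nonmd=z(), mitigation_events=z(),
            triggered=np.zeros(n, dtype=bool),
            trigger_time=np.full(n, np.nan),
            death_time=np.full(n, np.nan),
            dead=np.zeros(n, dtype=bool),
        )

    @property
    def n(self) -> int:
        return self.dpp.size

    @property
    def mitod(self) -> np.ndarray:
        """Total mitoD per cell (unamplified + amplified pools)."""
        return self.mitod_unamplified + self.mitod_amplified

    @property
    def active(self) -> np.ndarray:
        """Cells still participating in the cascade (not dead)."""
        return ~self.dead


@dataclass(frozen=True)
class CellParams:
    """Per-cell event probabilities, precomputed from a mechanism's gradients.

    Probabilities are fixed for the duration of an experiment; zonated
    features are evaluated once at each cell's dPP (clipped into
    [0, d_max]: cells in an unusually long Zone-3 segment saturate at the
    CV endpoint).
    """

    p_metabolize: np.ndarray
    p_napqi: np.ndarray
    gsh_threshold: np.ndarray
    p_mitod_mitigation: np.ndarray
    p_gsh_depletion: np.ndarray
    cfg: MechanismConfig


def bind_config(cfg: MechanismConfig, dpp: np.ndarray, d_max: float) -> CellParams:
    d = np.clip(np.atleast_1d(np.asarray(dpp, dtype=float)), 0.0, d_max)
    ev = lambda spec: np.asarray(gradient_value(spec, d, d_max), dtype=float)
    return CellParams(
        p_metabolize=ev(cfg.p_metabolize),
        p_napqi=ev(cfg.p_napqi),
        gsh_threshold=ev(cfg.gsh_threshold),
        p_mitod_mitigation=ev(cfg.p_mitod_mitigation),
        p_gsh_depletion=ev(cfg.p_gsh_depletion),
        cfg=cfg,
    )


@dataclass
class StepStats:
    """Aggregate event counts from one kernel application."""

    apap_consumed: int = 0
    napqi_created: int = 0
    gs_created: int = 0
    gsh_depletion_events: int = 0
    damage_created: int = 0
    mitod_created: int = 0
    nonmd_created: int = 0
    amplification_added: int = 0
    mitod_mitigated: int = 0
    nonmd_mitigated: int = 0
    triggered_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))


@dataclass(frozen=True)
class EventRecord:
    """One logged cascade event (plumbing for the event-log CSV)."""

    time: float
    kind: str
    segment_id: int
    dpp: float
    count: int

    def __post_init__(self):
        if self.time < 0 or self.count < 1:
            raise ValueError("EventRecord requires time >= 0 and count >= 1")


def _binom(rng, n, p):
    """Binomial draw guarded against empty inputs."""
    if np.ndim(n) and len(n) == 0:
        return np.empty(0, dtype=np.int64)
    return rng.binomial(n, p)


def metabolism_step(h: HepatocyteState, params: CellParams, rng) -> StepStats:
    """Metabolize intracellular APAP into NAPQI or G&S.

    Cells that have experienced a death trigger stop metabolizing APAP;
    dead cells are inert.  G&S are exported immediately (cumulative
    ``gs_exported`` counter; the transport layer credits the body pool).
    """
    stats = StepStats()
    idx = np.nonzero((h.apap > 0) & ~h.triggered & ~h.dead)[0]
    if idx.size == 0:
        return stats
    m = _binom(rng, h.apap[idx], params.p_metabolize[idx])
    k = _binom(rng, m, params.p_napqi[idx])
    h.apap[idx] -= m
    h.napqi[idx] += k
    h.gs_exported[idx] += m - k
    stats.apap_consumed = int(m.sum())
    stats.napqi_created = int(k.sum())
    stats.gs_created = stats.apap_consumed - stats.napqi_created
    return stats


def napqi_fate_step(h: HepatocyteState, params: CellParams, rng) -> StepStats:
    """NAPQI destruction: GSH depletion below threshold, damage creation above.

    While a cell's cumulative GSH depletion events are below its depletion
    threshold, each NAPQI may be destroyed (p_gsh_depletion) and counted as
    a depletion event.  Once at/above threshold, each NAPQI may react
    (p_react) into a damage product: mitoD with p_mitod_split, else nonMD.
    Fresh mitoD enter the unamplified pool.
    """
    stats = StepStats()
    live = (h.napqi > 0) & ~h.dead
    if not live.any():
        return stats
    below = np.nonzero(live & (h.gsh_depletion_events < params.gsh_threshold))[0]
    above = np.nonzero(live & (h.gsh_depletion_events >= params.gsh_threshold))[0]
    if below.size:
        d = _binom(rng, h.napqi[below], params.p_gsh_depletion[below])
        h.napqi[below] -= d
        h.gsh_depletion_events[below] += d
        stats.gsh_depletion_events = int(d.sum())
    if above.size:
        r = _binom(rng, h.napqi[above], params.cfg.p_react)
        md = _binom(rng, r, params.cfg.p_mitod_split)
        h.napqi[above] -= r
        h.mitod_unamplified[above] += md
        h.nonmd[above] += r - md
        stats.damage_created = int(r.sum())
        stats.mitod_created = int(md.sum())
        stats.nonmd_created = stats.damage_created - stats.mitod_created
    return stats


def amplification_step(h: HepatocyteState, params: CellParams, rng) -> StepStats:
    """Give each unamplified mitoD its one amplification opportunity.

    Each gains n ~ DiscreteUniform{lo..hi} (default {1..6}) additional
    mitoD and moves to the absorbing amplified pool, so one NAPQI yields at
    most 1 + 6 = 7 mitoD.  Additions are created pre-amplified.
    """
    stats = StepStats()
    if params.cfg.amplification is None:
        # amplification disabled: pool migrates with no additions
        h.mitod_amplified += h.mitod_unamplified
        h.mitod_unamplified[:] = 0
        return stats
    idx = np.nonzero((h.mitod_unamplified > 0) & ~h.dead)[0]
    if idx.size == 0:
        return stats
    counts = h.mitod_unamplified[idx]
    lo, hi = params.cfg.amplification
    draws = rng.integers(lo, hi + 1, size=int(counts.sum()))
    owner = np.repeat(np.arange(idx.size), counts)
    added = np.bincount(owner, weights=draws, minlength=idx.size).astype(np.int64)
    h.mitod_amplified[idx] += counts + added
    h.mitod_unamplified[idx] = 0
    stats.amplification_added = int(added.sum())
    return stats


def mitigation_step(h: HepatocyteState, params: CellParams, rng) -> StepStats:
    """Destroy mitoD/nonMD objects (damage repair); counts cumulative events."""
    stats = StepStats()
    idx = np.nonzero(((h.mitod_unamplified > 0) | (h.mitod_amplified > 0)) & ~h.dead)[0]
    if idx.size:
        p = params.p_mitod_mitigation[idx]
        du = _binom(rng, h.mitod_unamplified[idx], p)
        da = _binom(rng, h.mitod_amplified[idx], p)
        h.mitod_unamplified[idx] -= du
        h.mitod_amplified[idx] -= da
        h.mitigation_events[idx] += du + da
        stats.mitod_mitigated = int(du.sum() + da.sum())
    jdx = np.nonzero((h.nonmd > 0) & ~h.dead)[0]
    if jdx.size:
        dn = _binom(rng, h.nonmd[jdx], params.cfg.p_nonmd_mitigation)
        h.nonmd[jdx] -= dn
        stats.nonmd_mitigated = int(dn.sum())
    return stats


def draw_death_delay(rule: tuple, rng, size: int) -> np.ndarray:
    kind = rule[0]
    if kind == "uniform":
        return rng.uniform(rule[1], rule[2], size=size)
    if kind == "normal":
        return np.maximum(0.0, rng.normal(rule[1], rule[2], size=size))
    raise ValueError(f"unknown death delay rule {kind!r}")


def death_trigger_check(h: HepatocyteState, params: CellParams, t: float, rng) -> StepStats:
    """Trigger irreversible death where total mitoD meets the threshold.

    Triggering records the trigger time and schedules the observable death
    at trigger time + a delay draw (uniform [1.2, 12] h by default).  The
    trigger is irreversible and halts further APAP metabolism.
    """
    stats = StepStats()
    idx = np.nonzero(
        ~h.triggered & ~h.dead & (h.mitod >= params.cfg.death_trigger_threshold)
    )[0]
    if idx.size == 0:
        return stats
    h.triggered[idx] = True
    h.trigger_time[idx] = t
    h.death_time[idx] = t + draw_death_delay(params.cfg.death_delay, rng, idx.size)
    stats.triggered_idx = idx
    return stats


_KERNELS = {
    "metabolism": metabolism_step,
    "napqi_fate": napqi_fate_step,
    "amplification": amplification_step,
    "mitigation": mitigation_step,
}


def hepatocyte_step(
    h: HepatocyteState, params: CellParams, t: float, rng
) -> dict[str, StepStats]:
    """Advance the cascade one simulated second.

    The five phases run in a pseudo-randomly shuffled order drawn once per
    step from the experiment's seeded stream and applied to the whole
    population (the aggregate statistics of a shared per-step order are
    indistinguishable from per-cell orders).
    """
    order = list(CASCADE_PHASES)
    rng.shuffle(order)
    out: dict[str, StepStats] = {}
    for phase in order:
        if phase == "trigger":
            out[phase] = death_trigger_check(h, params, t, rng)
        else:
            out[phase] = _KERNELS[phase](h, params, rng)
    return out


def apply_deaths(h: HepatocyteState, t: float) -> np.ndarray:
    """Flip the dead flag for triggered cells whose death time has passed.

    Dead cells are inert.  Returns the newly dead indices.
    """
    idx = np.nonzero(h.triggered & ~h.dead & (h.death_time <= t))[0]
    h.dead[idx] = True
    return idx


# --------------------------------------------------------------------------
# Mechanism presets

_preset_cache: dict[str, MechanismConfig] = {}

#: Whole-lobule comparability constants: the location-independent mechanisms
#: use the census-mean values of their zonated counterparts.
GSH_THRESHOLD_MEAN = 3.5
MITIGATION_MEAN = 0.67


def _calibrated_gsh_gradient() -> GradientSpec:
    pop, d_max = canonical_dpp_population()
    return calibrate_gradient_mean(
        GradientSpec.linear(5.0, 0.0), pop, GSH_THRESHOLD_MEAN, "v_cv", d_max,
        bounds=(0.0, 5.0),
    )


def _calibrated_mitigation_sigmoid() -> GradientSpec:
    pop, d_max = canonical_dpp_population()
    # inflection midway through Zone 2 (dPP = 23 + 13/2 = 29.5 by default)
    inflection = 23.0 + 13.0 / 2.0
    spec = GradientSpec("reverse_sigmoid", 0.9, 0.0, inflection=inflection, steepness=1.0)
    return calibrate_gradient_mean(
        spec, pop, MITIGATION_MEAN, "steepness", d_max, bounds=(1e-3, 60.0)
    )


def mechanism_preset(name: str) -> MechanismConfig:
    """Return the named mechanism hypothesis (NZ, GNZ, MNZ, or MGNZ)."""
    key = name.upper()
    if key not in ("NZ", "GNZ", "MNZ", "MGNZ"):
        raise ValueError(f"unknown mechanism {name!r}; expected NZ, GNZ, MNZ or MGNZ")
    if key in _preset_cache:
        return _preset_cache[key]
    gsh = (
        _calibrated_gsh_gradient()
        if key in ("GNZ", "MGNZ")
        else GradientSpec.constant(GSH_THRESHOLD_MEAN)
    )
    mit = (
        _calibrated_mitigation_sigmoid()
        if key in ("MNZ", "MGNZ")
        else GradientSpec.constant(MITIGATION_MEAN)
    )
    cfg = MechanismConfig(
        name=key,
        p_metabolize=GradientSpec.linear(0.35, 0.95),
        p_napqi=GradientSpec.linear(0.33, 0.90),
        gsh_threshold=gsh,
        p_mitod_mitigation=mit,
    )
    _preset_cache[key] = cfg
    return cfg


def make_variant(base: MechanismConfig, overrides: dict, label: str | None = None) -> MechanismConfig:
    """Derive a mechanism variant by overriding 1..7 of the ten knobs.

    ``overrides`` maps knob name -> new value (GradientSpec for the five
    gradient knobs, scalars/tuples for the rest).  The base is unchanged;
    the variant carries an identifying label.
    """
    bad = set(overrides) - set(VARIANT_KNOBS)
    if bad:
        raise ValueError(f"not variant knobs: {sorted(bad)}")
    if len(overrides) > 7:
        raise ValueError(f"at most 7 knobs may be overridden, got {len(overrides)}")
    name = label or (base.name + "+" + ",".join(sorted(overrides)) if overrides else base.name)
    return replace(base, name=name, **overrides)
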