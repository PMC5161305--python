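"""Mouse-body compartments and intra-lobule percolation of APAP and marker.

The extrahepatic side is two integer pools: a dose depot (first-order
absorption, bypassed for intravenous dosing) and the body APAP pool, a
fixed fraction of which is metered to the lobule's periportal entrances
each second (maps to hepatic blood flow).  Inside the lobule, objects
percolate column-by-column along each sinusoid segment with a forward-bias
probability, may be bound and released by endothelial binders, and may
enter an adjacent hepatocyte; objects leaving a segment's last column route
uniformly along its outlet edges, and Zone-3 outflow returns to the body
via the central vein.  The extracellular marker behaves exactly like APAP
except that it never binds, never enters cells, and is never eliminated --
the simulation analog of an internal standard.

All transfers are binomial/multinomial draws on integer counts, so
APAP-derived objects and marker obey exact integer conservation, which
``mass_balance_audit`` asserts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lobule import CV_SINK, LobuleGraph

__all__ = [
    "TransportParams",
    "DoseSpec",
    "MouseBodyState",
    "SegmentContents",
    "MassBalanceError",
    "absorption_step",
    "liver_inflow_step",
    "percolation_step",
    "cell_release_step",
    "cv_return_step",
    "mass_balance_audit",
]


@dataclass(frozen=True)
class TransportParams:
    """Flow, binding, and exchange probabilities (per object per second).

    ``p_uptake`` and ``hepatic_fraction`` were calibrated once against the
    metabolism-phase performance targets (hepatic extraction ratio
    0.6 +/- 0.06 in single-pass perfusion; NAPQI dose fraction within
    0.15-0.4 over 24 h) and then frozen; see the methods note.  ``p_bind``
    and ``p_release`` are placeholders for the endothelial binders, exposed
    in configuration because no reference values are printed anywhere.
    """

    p_fwd: float = 0.9
    p_bind: float = 0.1
    p_release: float = 0.5
    p_uptake: float = 0.024
    p_cell_release: float = 0.1
    k_abs: float = 0.001
    hepatic_fraction: float = 1e-4
    #: Exponent for flow-velocity scaling of per-column uptake.  All flow
    #: converges from 45 Zone-1 onto 3 Zone-3 segments, so pericentral
    #: linear velocity is higher and per-column residence (hence capture
    #: opportunity) lower: uptake in zone z is scaled by
    #: (flux multiplier)^-alpha, flux multiplier = n_Z1_nodes / n_z_nodes.
    #: 0 ignores convergence entirely; 1 is full velocity scaling.
    zone_flow_alpha: float = 0.6
    #: Uptake multiplier for cells past their death trigger.  Necrotizing
    #: cells lose membrane integrity, so APAP partitions into them freely
    #: and is retained (the analog of covalent-adduct accumulation in
    #: centrilobular necrotic tissue); the necrotic region thus becomes a
    #: sink that stalls late hepatic clearance.
    necrotic_uptake_scale: float = 12.0


#: Objects per mg/kg of dose: 300 mg/kg (the toxic reference dose) maps to
#: 300,000 APAP objects per mouse analog (~21 per hepatocyte), set during
#: calibration so pericentral cells can pass both damage thresholds while
#: periportal exposure stays near the threshold scale.
DEFAULT_DOSE_SCALE = 1000.0


@dataclass(frozen=True)
class DoseSpec:
    """A dose in discrete APAP objects plus its administration route."""

    n_objects: int
    route: str = "intragastric"
    dose_scale: float = DEFAULT_DOSE_SCALE
    marker_objects: int = 0

    def __post_init__(self):
        if self.n_objects < 0:
            raise ValueError("n_objects must be >= 0")
        if self.route not in ("intravenous", "intraperitoneal", "intragastric"):
            raise ValueError(f"unknown route {self.route!r}")

    @classmethod
    def from_mg_per_kg(
        cls, mg_per_kg: float, route: str = "intragastric",
        dose_scale: float = DEFAULT_DOSE_SCALE, marker_objects: int = 0,
    ) -> "DoseSpec":
        return cls(int(round(mg_per_kg * dose_scale)), route, dose_scale, marker_objects)


@dataclass
class MouseBodyState:
    """Extrahepatic compartment amounts and transfer parameters."""

    depot: int = 0
    body_apap: int = 0
    body_gs: int = 0
    body_marker: int = 0
    k_abs: float = 0.001
    hepatic_fraction: float = 1e-4

    @classmethod
    def from_dose(cls, dose: DoseSpec, params: TransportParams) -> "MouseBodyState":
        body = cls(k_abs=params.k_abs, hepatic_fraction=params.hepatic_fraction)
        if dose.route == "intravenous":
            body.body_apap = dose.n_objects  # depot bypassed entirely at t=0
        else:
            body.depot = dose.n_objects
        body.body_marker = dose.marker_objects
        return body


class MassBalanceError(AssertionError):
    """Exact integer conservation violated (reported with per-compartment diff)."""


@dataclass
class SegmentContents:
    """Column-resolved mobile-object counts for the whole lobule.

    Columns of all segments are flattened into single arrays; per-segment
    slices are ``[col_start[s], col_start[s] + length[s])``.  Marker arrays
    are allocated only when a marker dose is present (marker never enters
    cells, so it has no bound or intracellular pool).
    """

    col_seg: np.ndarray       # owning segment id per column
    col_start: np.ndarray     # first column index per segment
    last_col: np.ndarray      # flat index of each segment's last column
    free: np.ndarray
    bound: np.ndarray
    marker: np.ndarray | None
    cv_apap: int = 0
    cv_marker: int = 0
    entrance_cols: np.ndarray = field(default=None)
    entrance_probs: np.ndarray = field(default=None)
    col_flux_mult: np.ndarray = field(default=None)  # flow-convergence multiplier per column
    outlets: list[list[int]] = field(default_factory=list)   # per segment: outlet segment ids (CV_SINK allowed)

    @classmethod
    def for_lobule(cls, lobule: LobuleGraph, with_marker: bool = False) -> "SegmentContents":
        lengths = np.array([s.length for s in lobule.segments], dtype=np.int64)
        col_start = np.concatenate([[0], np.cumsum(lengths)[:-1]])
        total = int(lengths.sum())
        col_seg = np.repeat(np.arange(len(lengths)), lengths)
        entrance_ids = np.array(lobule.pp_entrance_ids, dtype=np.int64)
        circ = np.array([lobule.segments[i].circumference for i in entrance_ids], dtype=float)
        n_z1 = lobule.zone_node_counts[1]
        seg_flux = np.array(
            [n_z1 / lobule.zone_node_counts[s.zone] for s in lobule.segments], dtype=float
        )
        return cls(
            col_seg=col_seg,
            col_start=col_start,
            last_col=col_start + lengths - 1,
            col_flux_mult=seg_flux[col_seg],
            free=np.zeros(total, dtype=np.int64),
            bound=np.zeros(total, dtype=np.int64),
            marker=np.zeros(total, dtype=np.int64) if with_marker else None,
            entrance_cols=col_start[entrance_ids],
            entrance_probs=circ / circ.sum(),
            outlets=[list(s.outlet_edges) for s in lobule.segments],
        )

    def total_apap(self) -> int:
        return int(self.free.sum() + self.bound.sum())

    def total_marker(self) -> int:
        return 0 if self.marker is None else int(self.marker.sum())


def absorption_step(body: MouseBodyState, rng) -> int:
    """First-order absorption: depot -> body APAP pool.  Returns objects moved."""
    if body.depot == 0:
        return 0
    a = int(rng.binomial(body.depot, body.k_abs))
    body.depot -= a
    body.body_apap += a
    return a


def liver_inflow_step(body: MouseBodyState, contents: SegmentContents, rng) -> int:
    """Meter body APAP (and marker) to the PP entrance columns.

    The metered amount is distributed across entrance segments proportional
    to circumference.  Returns APAP objects transferred.
    """
    moved = 0
    if body.body_apap > 0 and body.hepatic_fraction > 0:
        m = int(rng.binomial(body.body_apap, body.hepatic_fraction))
        if m:
            body.body_apap -= m
            alloc = rng.multinomial(m, contents.entrance_probs)
            np.add.at(contents.free, contents.entrance_cols, alloc)
            moved = m
    if contents.marker is not None and body.body_marker > 0 and body.hepatic_fraction > 0:
        mm = int(rng.binomial(body.body_marker, body.hepatic_fraction))
        if mm:
            body.body_marker -= mm
            alloc = rng.multinomial(mm, contents.entrance_probs)
            np.add.at(contents.marker, contents.entrance_cols, alloc)
    return moved


def _advance(counts: np.ndarray, contents: SegmentContents, p_fwd: float, rng,
             cv_field: str) -> None:
    """Advance one species one grid column with forward bias, routing at branches."""
    nz = np.nonzero(counts)[0]
    if nz.size == 0:
        return
    moved = np.zeros_like(counts)
    moved[nz] = rng.binomial(counts[nz], p_fwd)
    counts -= moved
    # interior columns shift right by one
    interior = np.ones(counts.size, dtype=bool)
    interior[contents.last_col] = False
    src = np.nonzero(interior & (moved > 0))[0]
    np.add.at(counts, src + 1, moved[src])
    # last columns route along outlet edges chosen uniformly per object
    for seg_id in np.nonzero(moved[contents.last_col])[0]:
        n = int(moved[contents.last_col[seg_id]])
        outs = contents.outlets[seg_id]
        alloc = rng.multinomial(n, np.full(len(outs), 1.0 / len(outs)))
        for target, k in zip(outs, alloc):
            if k == 0:
                continue
            if target == CV_SINK:
                setattr(contents, cv_field, getattr(contents, cv_field) + int(k))
            else:
                counts[contents.col_start[target]] += int(k)


def percolation_step(
    contents: SegmentContents,
    params: TransportParams,
    rng,
    cell_start: np.ndarray | None = None,
    cell_count: np.ndarray | None = None,
    cell_apap: np.ndarray | None = None,
    col_triggered_frac: np.ndarray | None = None,
) -> int:
    """One second of intra-lobule flow: bind/release, hepatocyte uptake, advance.

    ``cell_start``/``cell_count`` map each column to its contiguous block of
    hepatocytes (ordered as LobuleGraph.hepatocyte_positions); uptaken
    objects are assigned to a uniformly chosen cell of the column and added
    to ``cell_apap``.  ``col_triggered_frac`` (fraction of each column's
    cells past the death trigger) boosts the column's uptake by the
    necrotic-sink multiplier.  Returns total objects taken up this step.
    """
    free, bound = contents.free, contents.bound
    # endothelial binders: bind then release (snapshot draws on each pool)
    if params.p_bind > 0:
        nz = np.nonzero(free)[0]
        if nz.size:
            b = rng.binomial(free[nz], params.p_bind)
            free[nz] -= b
            bound[nz] += b
    if params.p_release > 0:
        nz = np.nonzero(bound)[0]
        if nz.size:
            r = rng.binomial(bound[nz], params.p_release)
            bound[nz] -= r
            free[nz] += r
    # hepatocyte uptake, damped where converged flow moves faster
    uptake_total = 0
    if params.p_uptake > 0 and cell_apap is not None:
        nz = np.nonzero(free)[0]
        if nz.size:
            p_up = params.p_uptake * contents.col_flux_mult[nz] ** (-params.zone_flow_alpha)
            if col_triggered_frac is not None:
                boost = 1.0 + (params.necrotic_uptake_scale - 1.0) * col_triggered_frac[nz]
                p_up = np.minimum(p_up * boost, 0.95)
            u = rng.binomial(free[nz], p_up)
            take = np.nonzero(u)[0]
            if take.size:
                cols = nz[take]
                free[cols] -= u[take]
                owner_col = np.repeat(cols, u[take])
                offs = rng.integers(0, cell_count[owner_col])
                np.add.at(cell_apap, cell_start[owner_col] + offs, 1)
                uptake_total = int(u[take].sum())
    # axial advance with branch routing
    _advance(free, contents, params.p_fwd, rng, "cv_apap")
    if contents.marker is not None:
        _advance(contents.marker, contents, params.p_fwd, rng, "cv_marker")
    return uptake_total


def cell_release_step(
    contents: SegmentContents,
    params: TransportParams,
    rng,
    cell_apap: np.ndarray,
    cell_col: np.ndarray,
    dead: np.ndarray | None = None,
) -> int:
    """Unmetabolized intracellular APAP leaks back to the cell's sinusoid column.

    Applies to every intact cell holding APAP; with metabolism disabled
    this guarantees 100% long-run recovery of APAP at the CV.  Cells past
    their death trigger release nothing: necrotizing tissue sequesters the
    APAP that diffuses in (the analog of covalent adduct accumulation in
    damaged and necrotic regions), so hepatic clearance stalls as the
    pericentral region dies.  ``dead`` is the sequestration mask (cells at
    or past the trigger).
    """
    if params.p_cell_release <= 0:
        return 0
    holding = cell_apap > 0
    if dead is not None:
        holding &= ~dead
    nz = np.nonzero(holding)[0]
    if nz.size == 0:
        return 0
    r = rng.binomial(cell_apap[nz], params.p_cell_release)
    give = np.nonzero(r)[0]
    if give.size == 0:
        return 0
    idx = nz[give]
    cell_apap[idx] -= r[give]
    np.add.at(contents.free, cell_col[idx], r[give])
    return int(r[give].sum())


def cv_return_step(body: MouseBodyState, contents: SegmentContents) -> tuple[int, int]:
    """Empty the CV buffer back into the body pools (recirculation)."""
    a, m = contents.cv_apap, contents.cv_marker
    body.body_apap += a
    body.body_marker += m
    contents.cv_apap = 0
    contents.cv_marker = 0
    return a, m


def mass_balance_audit(
    body: MouseBodyState,
    contents: SegmentContents,
    cell_apap: np.ndarray,
    cum_napqi_created: int,
    cum_gs_created: int,
    dose_objects: int,
    marker_objects: int = 0,
) -> dict:
    """Assert exact integer conservation of APAP-derived objects and marker.

    depot + body + intralobular (free/bound/intracellular/CV buffer) +
    cumulative NAPQI created + cumulative G&S created must equal the dose
    exactly; marker similarly (with no elimination terms).  Raises
    MassBalanceError with the per-compartment breakdown on any mismatch.
    """
    report = {
        "depot": body.depot,
        "body_apap": body.body_apap,
        "lobule_free": int(contents.free.sum()),
        "lobule_bound": int(contents.bound.sum()),
        "cell_apap": int(cell_apap.sum()),
        "cv_buffer": contents.cv_apap,
        "cum_napqi_created": cum_napqi_created,
        "cum_gs_created": cum_gs_created,
        "dose": dose_objects,
    }
    total = sum(v for k, v in report.items() if k != "dose")
    report["apap_balance"] = total - dose_objects
    if total != dose_objects:
        raise MassBalanceError(f"APAP imbalance {total - dose_objects}: {report}")
    if marker_objects or contents.marker is not None:
        mtotal = body.body_marker + contents.total_marker() + contents.cv_marker
        report["marker_balance"] = mtotal - marker_objects
        if mtotal != marker_objects:
            raise MassBalanceError(f"marker imbalance {mtotal - marker_objects}: {report}")
    return report
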