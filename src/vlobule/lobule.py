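"""Hepatic lobule geometry: the 3-zone sinusoid-segment graph and zonation gradients.

A virtual lobule is a directed graph of Sinusoid Segment (SS) agents through
which blood-borne objects flow from the periportal (PP) entrances toward the
central vein (CV).  The graph has a fixed topology budget -- 68 nodes
(45/20/3 in Zones 1/2/3) wired by 99 directed edges (55 Z1->Z2, 10 within
Z1, 24 Z2->Z3, 10 within Z2, none within Z3) -- while segment dimensions and
the concrete wiring are Monte Carlo drawn per lobule to mimic inter- and
intra-liver variability.  The hepatocyte census is fixed: 9,310 / 3,948 /
742 cells in Zones 1/2/3 (14,000 per lobule); only geometry varies between
Monte Carlo variants.

Each hepatocyte's lobular position is summarized by a single path-length
coordinate ``dPP`` (grid spaces from the PP entrance): its offset along its
own segment plus, for each upstream zone, the mean segment length of that
zone.  Zonated event probabilities (metabolism, NAPQI formation, GSH
depletion threshold, damage mitigation) are functions of dPP with constant,
linear, or reverse-sigmoid shapes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "CANONICAL_CENSUS",
    "ZONE_NODE_COUNTS",
    "EDGE_PARTITION",
    "GeometryConfig",
    "SinusoidSegment",
    "LobuleGraph",
    "HepatocytePosition",
    "GradientSpec",
    "ZoneCensus",
    "build_lobule",
    "dpp",
    "distance_to_cv",
    "gradient_value",
    "calibrate_gradient_mean",
    "zone_census",
    "canonical_dpp_population",
    "export_lobule_csv",
]

#: Fixed per-zone hepatocyte totals (sum 14,000).
CANONICAL_CENSUS: dict[int, int] = {1: 9310, 2: 3948, 3: 742}

#: Sinusoid-segment nodes per zone (sum 68).
ZONE_NODE_COUNTS: dict[int, int] = {1: 45, 2: 20, 3: 3}

#: Directed-edge budget: (zone1->zone2, within-zone1, zone2->zone3, within-zone2, within-zone3).
EDGE_PARTITION: tuple[int, int, int, int, int] = (55, 10, 24, 10, 0)

# Documentation constants retained from the sinusoid interior description:
# cell objects occupy ~99% of endothelial and ~90% of hepatocyte grid
# spaces.  The interior grid is collapsed into per-segment counts here.
ENDOTHELIAL_OCCUPANCY = 0.99
HEPATOCYTE_OCCUPANCY = 0.90


class ConfigurationError(ValueError):
    """Raised when a geometry or gradient configuration cannot satisfy its invariants."""


@dataclass(frozen=True)
class GeometryConfig:
    """Per-zone geometry ranges and the hepatocyte census.

    Lengths and circumferences are integer grid spaces, drawn uniformly
    (inclusive) per segment.  Defaults give mean per-zone lengths 23/13/14,
    so the mean total PP->CV path length is ~50 grid spaces and the "near
    PP" classification (>30 grid spaces from CV) falls inside Zone 1.  The
    relatively long Zone-3 segments represent the converged pericentral
    channels that all flow paths share; their mean length also defines the
    pericentral distance band used by the trigger-location phenomenon
    check.
    """

    length_ranges: dict[int, tuple[int, int]] = field(
        default_factory=lambda: {1: (19, 27), 2: (10, 16), 3: (11, 17)}
    )
    circumference_ranges: dict[int, tuple[int, int]] = field(
        default_factory=lambda: {1: (8, 12), 2: (8, 12), 3: (8, 12)}
    )
    census: dict[int, int] = field(default_factory=lambda: dict(CANONICAL_CENSUS))
    zone_node_counts: dict[int, int] = field(default_factory=lambda: dict(ZONE_NODE_COUNTS))
    edge_partition: tuple[int, int, int, int, int] = EDGE_PARTITION

    def validate(self) -> None:
        for zone in (1, 2, 3):
            lo, hi = self.length_ranges[zone]
            if lo < 1 or hi < lo:
                raise ConfigurationError(
                    f"zone {zone} length range {(lo, hi)} invalid: need 1 <= lo <= hi"
                )
            clo, chi = self.circumference_ranges[zone]
            if clo < 1 or chi < clo:
                raise ConfigurationError(
                    f"zone {zone} circumference range {(clo, chi)} invalid"
                )
            if self.census[zone] < self.zone_node_counts[zone]:
                raise ConfigurationError(
                    f"zone {zone} census {self.census[zone]} smaller than node count"
                )


@dataclass
class SinusoidSegment:
    """One sinusoid-segment agent (a graph node)."""

    id: int
    zone: int
    length: int
    circumference: int
    hepatocyte_count: int
    inlet_edges: list[int] = field(default_factory=list)
    outlet_edges: list[int] = field(default_factory=list)
    dpp_offset: float = 0.0


@dataclass(frozen=True)
class HepatocytePosition:
    """Grid position of a hepatocyte: segment, axial offset x in [0, length), ring index."""

    segment_id: int
    x: int
    ring_index: int = 0


@dataclass(frozen=True)
class ZoneCensus:
    counts: dict[int, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


#: Sentinel id for the central-vein sink (not a SinusoidSegment).
CV_SINK = -1


@dataclass
class LobuleGraph:
    """A Monte Carlo lobule variant: segments, directed edges, path geometry."""

    segments: list[SinusoidSegment]
    edges: list[tuple[int, int]]
    zone_node_counts: dict[int, int]
    pp_entrance_ids: list[int]
    cv_sink: int
    d_max: float
    seed: int
    zone_mean_lengths: dict[int, float] = field(default_factory=dict)

    def segment(self, segment_id: int) -> SinusoidSegment:
        try:
            return self.segments[segment_id]
        except IndexError:
            raise KeyError(f"unknown segment id {segment_id}") from None

    @property
    def n_nodes(self) -> int:
        return len(self.segments)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_partition_counts(self) -> tuple[int, int, int, int, int]:
        """Count edges as (Z1->Z2, within-Z1, Z2->Z3, within-Z2, within-Z3)."""
        z = {s.id: s.zone for s in self.segments}
        c12 = sum(1 for a, b in self.edges if z[a] == 1 and z[b] == 2)
        c11 = sum(1 for a, b in self.edges if z[a] == 1 and z[b] == 1)
        c23 = sum(1 for a, b in self.edges if z[a] == 2 and z[b] == 3)
        c22 = sum(1 for a, b in self.edges if z[a] == 2 and z[b] == 2)
        c33 = sum(1 for a, b in self.edges if z[a] == 3 and z[b] == 3)
        return (c12, c11, c23, c22, c33)

    def hepatocyte_positions(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorized positions for every hepatocyte in the lobule.

        Returns ``(segment_id, x, zone)`` integer arrays of length 14,000
        (canonical census).  Cells in a segment are spread as evenly as
        possible across its axial columns ``x in [0, length)``.
        """
        seg_ids, xs, zones = [], [], []
        for seg in self.segments:
            counts = _spread_counts(seg.hepatocyte_count, seg.length)
            for x, c in enumerate(counts):
                if c:
                    seg_ids.append(np.full(c, seg.id, dtype=np.int64))
                    xs.append(np.full(c, x, dtype=np.int64))
                    zones.append(np.full(c, seg.zone, dtype=np.int64))
        return (np.concatenate(seg_ids), np.concatenate(xs), np.concatenate(zones))

    def hepatocyte_dpp(self) -> np.ndarray:
        """dPP coordinate for every hepatocyte (same order as hepatocyte_positions)."""
        _, xs, zones = self.hepatocyte_positions()
        offsets = np.array(
            [0.0, 0.0, self.zone_mean_lengths[1], self.zone_mean_lengths[1] + self.zone_mean_lengths[2]]
        )
        return xs.astype(float) + offsets[zones]


def _spread_counts(total: int, bins: int) -> np.ndarray:
    """Spread `total` items over `bins` as evenly as possible (largest remainder)."""
    base, rem = divmod(total, bins)
    out = np.full(bins, base, dtype=np.int64)
    out[:rem] += 1
    return out


def _apportion_by_length(census: int, lengths: np.ndarray) -> np.ndarray:
    """Apportion a zone census over its segments proportional to length.

    Deterministic largest-remainder assignment so the zone total is exact.
    """
    quota = census * lengths / lengths.sum()
    counts = np.floor(quota).astype(np.int64)
    short = census - counts.sum()
    # hand leftover cells to the largest fractional remainders (ties by index)
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def _wire_edges(
    rng: np.random.Generator,
    zone_ids: dict[int, list[int]],
    partition: tuple[int, int, int, int, int],
) -> list[tuple[int, int]]:
    """Randomly wire the directed edges under the fixed partition budget.

    Cross-zone edges guarantee that every upstream node has an outlet and
    every downstream node an inlet, so every segment lies on a PP->CV path.
    Within-zone edges follow a random linear order (low rank -> high rank),
    which cannot create a cycle back toward PP.
    """
    edges: list[tuple[int, int]] = []
    n12, n11, n23, n22, n33 = partition

    def cross(src: list[int], dst: list[int], budget: int) -> list[tuple[int, int]]:
        if budget < max(len(src), len(dst)):
            raise ConfigurationError(
                f"edge budget {budget} cannot cover {len(src)} sources and {len(dst)} sinks"
            )
        # every source gets one outlet; targets cycle over a shuffled dst list
        # so every sink is covered, then the remaining budget is random.
        targets = [dst[i % len(dst)] for i in range(len(src))]
        rng.shuffle(targets)
        out = list(zip(src, targets))
        existing = set(out)
        while len(out) < budget:
            e = (src[rng.integers(len(src))], dst[rng.integers(len(dst))])
            if e not in existing:
                existing.add(e)
                out.append(e)
        return out

    def within(ids: list[int], budget: int) -> list[tuple[int, int]]:
        if budget == 0:
            return []
        rank = list(ids)
        rng.shuffle(rank)
        pairs = [
            (rank[i], rank[j]) for i in range(len(rank)) for j in range(i + 1, len(rank))
        ]
        if budget > len(pairs):
            raise ConfigurationError(f"within-zone budget {budget} exceeds {len(pairs)} pairs")
        pick = rng.choice(len(pairs), size=budget, replace=False)
        return [pairs[k] for k in sorted(pick)]

    edges += cross(zone_ids[1], zone_ids[2], n12)
    edges += within(zone_ids[1], n11)
    edges += cross(zone_ids[2], zone_ids[3], n23)
    edges += within(zone_ids[2], n22)
    edges += within(zone_ids[3], n33)
    return edges


def build_lobule(seed: int, geometry: GeometryConfig | None = None) -> LobuleGraph:
    """Construct one Monte Carlo lobule variant.

    Segment lengths/circumferences are drawn uniformly from the per-zone
    ranges; edges are randomly wired under the fixed 55/10/24/10/0 budget;
    the hepatocyte census is apportioned deterministically so zone totals
    are exact for every seed.  Identical seed => identical lobule.
    """
    geometry = geometry or GeometryConfig()
    geometry.validate()
    rng = np.random.default_rng(seed)

    segments: list[SinusoidSegment] = []
    zone_ids: dict[int, list[int]] = {}
    next_id = 0
    for zone in (1, 2, 3):
        ids = []
        lo, hi = geometry.length_ranges[zone]
        clo, chi = geometry.circumference_ranges[zone]
        for _ in range(geometry.zone_node_counts[zone]):
            segments.append(
                SinusoidSegment(
                    id=next_id,
                    zone=zone,
                    length=int(rng.integers(lo, hi + 1)),
                    circumference=int(rng.integers(clo, chi + 1)),
                    hepatocyte_count=0,
                )
            )
            ids.append(next_id)
            next_id += 1
        zone_ids[zone] = ids

    # census: exact zone totals, proportional to segment length
    for zone in (1, 2, 3):
        lengths = np.array([segments[i].length for i in zone_ids[zone]], dtype=float)
        counts = _apportion_by_length(geometry.census[zone], lengths)
        for i, c in zip(zone_ids[zone], counts):
            segments[i].hepatocyte_count = int(c)

    edges = _wire_edges(rng, zone_ids, geometry.edge_partition)
    for a, b in edges:
        segments[a].outlet_edges.append(b)
        segments[b].inlet_edges.append(a)
    for i in zone_ids[3]:
        segments[i].outlet_edges.append(CV_SINK)

    zone_means = {
        z: float(np.mean([segments[i].length for i in zone_ids[z]])) for z in (1, 2, 3)
    }
    offsets = {1: 0.0, 2: zone_means[1], 3: zone_means[1] + zone_means[2]}
    for seg in segments:
        seg.dpp_offset = offsets[seg.zone]

    return LobuleGraph(
        segments=segments,
        edges=edges,
        zone_node_counts=dict(geometry.zone_node_counts),
        pp_entrance_ids=list(zone_ids[1]),
        cv_sink=CV_SINK,
        d_max=sum(zone_means.values()),
        seed=seed,
        zone_mean_lengths=zone_means,
    )


def dpp(pos: HepatocytePosition, lobule: LobuleGraph) -> float:
    """Path-length coordinate: x within the segment plus upstream zone-mean lengths."""
    seg = lobule.segment(pos.segment_id)
    if not 0 <= pos.x < seg.length:
        raise ValueError(f"x={pos.x} outside segment length {seg.length}")
    return pos.x + seg.dpp_offset


def distance_to_cv(pos: HepatocytePosition, lobule: LobuleGraph) -> float:
    """Distance from the CV in grid spaces: d_max - dPP, floored at 0.

    A hepatocyte sitting beyond the mean path length (in an unusually long
    Zone-3 segment) is reported at the CV itself.
    """
    return max(0.0, lobule.d_max - dpp(pos, lobule))


def gradient_value(spec: "GradientSpec", d: float | np.ndarray, d_max: float):
    """Evaluate a PP->CV gradient at path distance(s) ``d`` over span ``d_max``."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0) or np.any(d > d_max):
        raise ValueError(f"d outside [0, {d_max}]")
    if spec.shape == "constant":
        out = np.full_like(d, spec.v_pp)
    elif spec.shape == "linear":
        out = spec.v_pp + (spec.v_cv - spec.v_pp) * d / d_max
    elif spec.shape == "reverse_sigmoid":
        # expit form of v_cv + (v_pp - v_cv) / (1 + exp(s * (d - inflection)))
        out = spec.v_cv + (spec.v_pp - spec.v_cv) * expit(
            -spec.steepness * (d - spec.inflection)
        )
    else:  # pragma: no cover - guarded by GradientSpec.__post_init__
        raise ValueError(f"unknown gradient shape {spec.shape!r}")
    lo, hi = min(spec.v_pp, spec.v_cv), max(spec.v_pp, spec.v_cv)
    out = np.clip(out, lo, hi)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GradientSpec:
    """Shape and endpoint values of one zonated feature.

    ``v_pp`` is the value at dPP = 0 (lobule entrance), ``v_cv`` the value
    at dPP = d_max (central vein).  The reverse sigmoid decays from v_pp
    toward v_cv with the given inflection point (grid spaces) and steepness
    (per grid space); the constant shape requires v_pp == v_cv.
    """

    shape: str
    v_pp: float
    v_cv: float
    inflection: float | None = None
    steepness: float | None = None

    def __post_init__(self):
        if self.shape not in ("constant", "linear", "reverse_sigmoid"):
            raise ConfigurationError(f"unknown gradient shape {self.shape!r}")
        if self.shape == "constant" and self.v_pp != self.v_cv:
            raise ConfigurationError("constant gradient requires v_pp == v_cv")
        if self.shape == "reverse_sigmoid" and (
            self.inflection is None or self.steepness is None
        ):
            raise ConfigurationError("reverse_sigmoid requires inflection and steepness")

    @classmethod
    def constant(cls, value: float) -> "GradientSpec":
        return cls("constant", value, value)

    @classmethod
    def linear(cls, v_pp: float, v_cv: float) -> "GradientSpec":
        return cls("linear", v_pp, v_cv)


class CalibrationError(ValueError):
    """Target mean unreachable within the free parameter's bounds."""


def calibrate_gradient_mean(
    spec: GradientSpec,
    population: np.ndarray,
    target_mean: float,
    free_parameter: str,
    d_max: float,
    bounds: tuple[float, float] | None = None,
) -> GradientSpec:
    """Solve one free parameter so the population-mean gradient value hits a target.

    ``population`` is the array of hepatocyte dPP values the mean is taken
    over (normally the canonical census).  ``free_parameter`` is either
    ``"v_cv"`` (linear family) or ``"steepness"`` (reverse sigmoid).  Solved
    by monotone root finding (Brent) to |mean - target| <= 1e-6.
    """
    population = np.asarray(population, dtype=float)
    if population.size == 0:
        raise ValueError("population must be nonempty")
    if spec.shape == "constant":
        return GradientSpec.constant(target_mean)
    if free_parameter not in ("v_cv", "steepness"):
        raise ValueError(f"free_parameter must be 'v_cv' or 'steepness', got {free_parameter!r}")

    def mean_at(value: float) -> float:
        trial = replace(spec, **{free_parameter: value})
        return float(np.mean(gradient_value(trial, population, d_max)))

    if bounds is None:
        bounds = (-10.0, 10.0) if free_parameter == "v_cv" else (1e-4, 60.0)
    lo, hi = bounds
    f_lo, f_hi = mean_at(lo) - target_mean, mean_at(hi) - target_mean
    if f_lo * f_hi > 0:
        raise CalibrationError(
            f"target mean {target_mean} unreachable; achievable range "
            f"[{min(mean_at(lo), mean_at(hi)):.4f}, {max(mean_at(lo), mean_at(hi)):.4f}] "
            f"over {free_parameter} in {bounds}"
        )
    root = brentq(lambda v: mean_at(v) - target_mean, lo, hi, xtol=1e-12, rtol=8.9e-16)
    solved = replace(spec, **{free_parameter: float(root)})
    if abs(float(np.mean(gradient_value(solved, population, d_max))) - target_mean) > 1e-6:
        raise CalibrationError("root finding did not reach 1e-6 tolerance")
    return solved


def zone_census(lobule: LobuleGraph) -> ZoneCensus:
    """Sum hepatocyte counts per zone."""
    counts = {1: 0, 2: 0, 3: 0}
    for seg in lobule.segments:
        counts[seg.zone] += seg.hepatocyte_count
    return ZoneCensus(counts)


def canonical_dpp_population(
    census: dict[int, int] | None = None,
    zone_mean_lengths: dict[int, float] | None = None,
) -> tuple[np.ndarray, float]:
    """Deterministic reference dPP set used to calibrate mechanism gradients.

    Uses the configured per-zone mean segment lengths (23/13/14 by default,
    d_max = 50) with the canonical census spread evenly over each zone's
    axial columns.  Mechanism presets are calibrated against this population
    once; individual Monte Carlo lobules then evaluate the same gradient
    over their own realized geometry.

    Returns ``(dpp_values, d_max)``.
    """
    census = census or CANONICAL_CENSUS
    means = zone_mean_lengths or {1: 23.0, 2: 13.0, 3: 14.0}
    offsets = {1: 0.0, 2: means[1], 3: means[1] + means[2]}
    values = []
    for zone in (1, 2, 3):
        n_cols = int(round(means[zone]))
        counts = _spread_counts(census[zone], n_cols)
        cols = np.repeat(np.arange(n_cols, dtype=float), counts)
        values.append(cols + offsets[zone])
    return np.concatenate(values), float(sum(means.values()))


def export_lobule_csv(lobule: LobuleGraph) -> tuple[str, str]:
    """Render the lobule as two CSV tables (nodes, edges) for inspection."""
    nodes = io.StringIO()
    nodes.write("id,zone,length,circumference,hepatocyte_count,dpp_offset\n")
    for s in lobule.segments:
        nodes.write(
            f"{s.id},{s.zone},{s.length},{s.circumference},{s.hepatocyte_count},{s.dpp_offset}\n"
        )
    edges = io.StringIO()
    edges.write("from_id,to_id\n")
    for a, b in lobule.edges:
        edges.write(f"{a},{b}\n")
    return nodes.getvalue(), edges.getvalue()
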