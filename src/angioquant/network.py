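"""Stochastic vascular-network generation and the parametric dose-injury model.

A network is a set of segments (polylines in µm coordinates, each with a
uniform diameter) whose shared endpoints define a graph.  Segments are exactly
the graph edges: whenever a growing tip branches, the parent polyline is
closed at the branch point and two child segments start there, so branch and
junction counts of the truth graph match what a topology-preserving
skeletonization of the rendered tubes should recover.

Growth is tip-based: sprouts start on the left field edge and advance in
fixed-length steps with angular jitter; tips branch with a per-step
probability and anastomose (fuse) when they come within a capture radius of
an existing segment, splitting it and creating a junction.  This produces the
branched, partially looped topology of a self-assembled microvascular bed
with very few parameters.

Radiation injury is applied as the simplest monotone dose-response family:
terminal branches are pruned with probability ``1-exp(-pruning_rate*dose)``,
surviving diameters shrink by ``exp(-shrink_rate*dose)``, and surviving
segments are independently flagged *regressed* (basement membrane without
endothelium) or *blocked* (lumen not reachable by tracer) with per-Gy
Bernoulli rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString
from shapely.ops import unary_union

from .config import ConfigurationError, SimulationConfig

_EDGE_TOL_UM = 1e-6


@dataclass
class Segment:
    """One vessel branch: a polyline (N,2) of (x, y) µm points and a diameter."""

    points: np.ndarray
    diameter_um: float
    regressed: bool = False
    blocked: bool = False

    def length_um(self) -> float:
        d = np.diff(self.points, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def tube(self) -> LineString:
        return LineString(self.points).buffer(self.diameter_um / 2.0)

    def copy(self) -> "Segment":
        return Segment(self.points.copy(), self.diameter_um,
                       self.regressed, self.blocked)


@dataclass
class NetworkTruth:
    """Ground-truth network: segments plus the physical domain size (µm)."""

    segments: list[Segment]
    domain_um: tuple[float, float]  # (height, width)
    dose_gy: float = 0.0

    # ------------------------------------------------------------------
    # graph structure (derived from coincident segment endpoints)
    # ------------------------------------------------------------------
    def node_table(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (positions (K,2) µm, degrees (K,)) of the endpoint graph."""
        if not self.segments:
            return np.empty((0, 2)), np.empty((0,), dtype=int)
        ends = []
        for seg in self.segments:
            ends.append(seg.points[0])
            ends.append(seg.points[-1])
        ends = np.asarray(ends)
        positions: list[np.ndarray] = []
        degrees: list[int] = []
        for p in ends:
            for i, q in enumerate(positions):
                if abs(p[0] - q[0]) < _EDGE_TOL_UM and abs(p[1] - q[1]) < _EDGE_TOL_UM:
                    degrees[i] += 1
                    break
            else:
                positions.append(p)
                degrees.append(1)
        return np.asarray(positions), np.asarray(degrees, dtype=int)

    def _node_index(self) -> tuple[np.ndarray, list[tuple[int, int]]]:
        """Node positions and, per segment, its (start_node, end_node)."""
        positions, _ = self.node_table()

        def find(p: np.ndarray) -> int:
            hits = np.nonzero((np.abs(positions - p) < _EDGE_TOL_UM).all(axis=1))[0]
            return int(hits[0])

        pairs = [(find(s.points[0]), find(s.points[-1])) for s in self.segments]
        return positions, pairs

    # ------------------------------------------------------------------
    # truth metrics
    # ------------------------------------------------------------------
    def branch_count(self) -> int:
        return len(self.segments)

    def junction_count(self) -> int:
        _, degrees = self.node_table()
        return int((degrees >= 3).sum())

    def total_length_um(self) -> float:
        return float(sum(s.length_um() for s in self.segments))

    def area_um2(self, which: str = "factin") -> float:
        """Tube-union area of a channel's truth geometry.

        ``factin``: non-regressed segments; ``laminin``: all segments;
        ``dextran``: perfused (reachable, non-blocked, non-regressed) lumens.
        """
        segs = self.channel_segments(which)
        if not segs:
            return 0.0
        return float(unary_union([s.tube() for s in segs]).area)

    def channel_segments(self, which: str) -> list[Segment]:
        if which == "laminin":
            return list(self.segments)
        if which == "factin":
            return [s for s in self.segments if not s.regressed]
        if which == "dextran":
            return self.perfused_segments()
        raise ValueError(f"unknown truth channel {which!r}")

    def perfused_segments(self) -> list[Segment]:
        """Segments reachable from the left field edge through open vessels.

        Tracer enters from one medium channel, modelled as the left image
        edge; blocked or regressed segments do not conduct, and anything only
        reachable through them is unperfused.
        """
        if not self.segments:
            return []
        positions, pairs = self._node_index()
        open_idx = [i for i, s in enumerate(self.segments)
                    if not s.blocked and not s.regressed]
        # adjacency over open segments sharing a node
        node_to_segs: dict[int, list[int]] = {}
        for i in open_idx:
            a, b = pairs[i]
            node_to_segs.setdefault(a, []).append(i)
            node_to_segs.setdefault(b, []).append(i)
        # roots: open segments with an endpoint at (or touching) the left edge
        stack = []
        for i in open_idx:
            a, b = pairs[i]
            if positions[a][0] < _EDGE_TOL_UM or positions[b][0] < _EDGE_TOL_UM:
                stack.append(i)
        seen = set(stack)
        while stack:
            i = stack.pop()
            for node in pairs[i]:
                for j in node_to_segs.get(node, ()):
                    if j not in seen:
                        seen.add(j)
                        stack.append(j)
        return [self.segments[i] for i in sorted(seen)]

    def perfused_area_fraction(self) -> float:
        """Truth share of open (F-actin) vessel area reached by tracer."""
        denom = self.area_um2("factin")
        if denom == 0:
            return float("nan")
        return self.area_um2("dextran") / denom

    def regressed_area_fraction(self) -> float:
        """Truth share of laminin area not covered by F-actin."""
        laminin = self.area_um2("laminin")
        if laminin == 0:
            return float("nan")
        factin_segs = [s.tube() for s in self.segments if not s.regressed]
        if not factin_segs:
            return 1.0
        lam = unary_union([s.tube() for s in self.segments])
        fac = unary_union(factin_segs)
        return float(lam.difference(fac).area) / laminin

    def copy(self) -> "NetworkTruth":
        return NetworkTruth([s.copy() for s in self.segments],
                            self.domain_um, self.dose_gy)


# ----------------------------------------------------------------------
# growth
# ----------------------------------------------------------------------

@dataclass
class _Tip:
    pos: np.ndarray      # current (x, y) µm
    angle: float         # radians, 0 = +x
    points: list = field(default_factory=list)  # polyline so far (incl. start)
    steps: int = 0
    alive: bool = True
    recent_angles: list = field(default_factory=list)


def _all_nodes(segments: list[Segment]) -> np.ndarray:
    if not segments:
        return np.empty((0, 2))
    return np.array([p for s in segments for p in (s.points[0], s.points[-1])])


def _point_polyline_dist(p: np.ndarray, pts: np.ndarray,
                         exclude_near: np.ndarray | None = None,
                         exclude_r: float = 0.0) -> float:
    """Exact distance from a point to a polyline.

    When ``exclude_near`` is given, polyline portions with both endpoints
    within ``exclude_r`` of that point are ignored (used to exempt the
    immediate surroundings of a shared node)."""
    best = math.inf
    for i in range(len(pts) - 1):
        a, b = pts[i], pts[i + 1]
        if exclude_near is not None:
            if (np.hypot(*(a - exclude_near)) < exclude_r
                    and np.hypot(*(b - exclude_near)) < exclude_r):
                continue
        u = b - a
        denom = float(u @ u)
        if denom == 0:
            d = float(np.hypot(*(p - a)))
        else:
            t = float(np.clip((p - a) @ u / denom, 0.0, 1.0))
            d = float(np.hypot(*(p - (a + t * u))))
        best = min(best, d)
    return best


def generate_network(config: SimulationConfig) -> NetworkTruth:
    """Grow a synthetic vascular network by stochastic tip extension.

    Sprouts start on the left edge of the field heading right; each step a
    tip advances ``step_length_um`` with Gaussian angular jitter, may branch
    (closing the current segment and spawning two children), and fuses with
    the first existing segment that comes within ``anastomosis_radius_um``.
    Deterministic for a given ``(seed, config)``.
    """
    config.validate()
    h_um, w_um = config.domain_um
    rng = np.random.default_rng([config.seed, 0x6E65])  # stage tag: network

    segments: list[Segment] = []
    margin = 0.08 * h_um
    ys = np.linspace(margin, h_um - margin, config.sprout_count)
    spread = 0.25 * (ys[1] - ys[0] if len(ys) > 1 else margin)
    ys = ys + rng.normal(0.0, spread, size=len(ys))
    # keep sprout roots clear of the border kill zone
    safe = config.step_length_um
    ys = np.clip(ys, safe, h_um - safe)
    tips = [_Tip(pos=np.array([0.0, float(y)]), angle=0.0,
                 points=[np.array([0.0, float(y)])]) for y in ys]

    jitter = math.radians(config.angle_jitter_deg)
    branch_angle = math.radians(config.branch_angle_deg)

    def draw_diameter() -> float:
        lo, hi = config.diameter_range_um
        d = rng.normal(config.diameter_mean_um, config.diameter_sd_um)
        return float(np.clip(d, lo, hi))

    def close_tip(tip: _Tip) -> np.ndarray | None:
        """Finish a tip's polyline as a Segment; return its end point."""
        tip.alive = False
        pts = np.asarray(tip.points)
        if len(pts) < 2 or np.hypot(*(pts[-1] - pts[0])) < _EDGE_TOL_UM:
            return None
        segments.append(Segment(points=pts, diameter_um=draw_diameter()))
        return pts[-1]

    def try_anastomose(tip: _Tip, all_tips: list[_Tip]) -> bool:
        """Fuse the tip into the nearest segment or other growing tip within
        the capture radius.  Join points close to the tip's own origin are
        exempt so newborn children do not instantly fuse back onto their
        parent or sibling."""
        if tip.steps < config.min_branch_steps:
            return False
        origin = tip.points[0]
        guard = 1.5 * config.anastomosis_radius_um
        node_clearance = 1.5 * config.anastomosis_radius_um
        nodes = _all_nodes(segments)

        def usable(vertex: np.ndarray) -> bool:
            # a join too close to the tip's origin or to an existing node
            # would create junctions an image analysis cannot separate
            if np.hypot(*(vertex - origin)) <= guard:
                return False
            if nodes.size and np.hypot(nodes[:, 0] - vertex[0],
                                       nodes[:, 1] - vertex[1]).min() <= node_clearance:
                return False
            return True

        def shares_origin(end_a, end_b) -> bool:
            # siblings and the parent stump share the tip's origin node;
            # fusing with them would create slivers no image could resolve
            return (np.hypot(*(np.asarray(end_a) - origin)) < _EDGE_TOL_UM
                    or np.hypot(*(np.asarray(end_b) - origin)) < _EDGE_TOL_UM)

        min_sin = math.sin(math.radians(config.min_junction_angle_deg))

        def steep_enough(pts: np.ndarray, k: int) -> bool:
            # a fusion nearly tangent to the target produces a junction no
            # skeleton analysis could separate from the target itself;
            # directions are averaged over ~2 steps to ride out jitter
            join = pts[k]
            back = np.asarray(tip.points[max(len(tip.points) - 3, 0)])
            u = join - back
            nu = np.hypot(*u)
            tangent = (pts[min(k + 2, len(pts) - 1)]
                       - pts[max(k - 2, 0)])
            nt = np.hypot(*tangent)
            if nu < _EDGE_TOL_UM or nt < _EDGE_TOL_UM:
                return True
            un, tn = u / nu, tangent / nt
            return abs(float(un[0] * tn[1] - un[1] * tn[0])) >= min_sin

        best = None  # (dist, kind, obj, vertex_index)
        for si, seg in enumerate(segments):
            if shares_origin(seg.points[0], seg.points[-1]):
                continue
            d = np.hypot(seg.points[:, 0] - tip.pos[0],
                         seg.points[:, 1] - tip.pos[1])
            k = int(np.argmin(d))
            if (d[k] <= config.anastomosis_radius_um and usable(seg.points[k])
                    and steep_enough(seg.points, k)):
                if best is None or d[k] < best[0]:
                    best = (float(d[k]), "segment", si, k)
        for other in all_tips:
            if other is tip or not other.alive or len(other.points) < 2:
                continue
            if shares_origin(other.points[0], other.points[-1]):
                continue
            pts = np.asarray(other.points)
            d = np.hypot(pts[:, 0] - tip.pos[0], pts[:, 1] - tip.pos[1])
            k = int(np.argmin(d))
            if (d[k] <= config.anastomosis_radius_um and usable(pts[k])
                    and steep_enough(pts, k)):
                if best is None or d[k] < best[0]:
                    best = (float(d[k]), "tip", other, k)
        if best is None:
            return False
        _, kind, obj, k = best
        if kind == "segment":
            target = segments[obj]
            join = target.points[k].copy()
            if 0 < k < len(target.points) - 1:
                # split the target at the join vertex so segments stay edges
                left = Segment(target.points[: k + 1].copy(), target.diameter_um)
                right = Segment(target.points[k:].copy(), target.diameter_um)
                segments[obj] = left
                segments.insert(obj + 1, right)
        else:
            other: _Tip = obj
            join = np.asarray(other.points[k]).copy()
            if k > 0:
                # close the other tip's polyline up to the join vertex as a
                # segment; it keeps growing from the join node
                pts = np.asarray(other.points[: k + 1])
                segments.append(Segment(points=pts.copy(),
                                        diameter_um=draw_diameter()))
                other.points = [np.asarray(p) for p in other.points[k:]]
        tip.points.append(join)
        close_tip(tip)
        return True

    clearance = config.diameter_mean_um + config.min_tube_gap_um

    def collides(tip: _Tip, all_tips: list[_Tip]) -> bool:
        """True when the tip head is within the clearance distance of a tube
        it has not fused with.  Only the portion of each tube inside the
        node-clearance disc around the tip's origin (parent stump, sibling
        roots) is exempt, so vessels never blur together away from a shared
        node — not even a tip with its own earlier path."""
        origin = np.asarray(tip.points[0])
        excl = 1.5 * config.anastomosis_radius_um
        for seg in segments:
            if _point_polyline_dist(tip.pos, seg.points,
                                    exclude_near=origin,
                                    exclude_r=excl) < clearance:
                return True
        for other in all_tips:
            if other is not tip and other.alive and len(other.points) >= 2:
                if _point_polyline_dist(tip.pos, np.asarray(other.points),
                                        exclude_near=origin,
                                        exclude_r=excl) < clearance:
                    return True
        # self-collision: ignore the recent path the head is still attached to
        own = np.asarray(tip.points)
        recent = int(math.ceil((clearance + config.step_length_um)
                               / config.step_length_um)) + 1
        if len(own) - recent >= 2:
            if _point_polyline_dist(tip.pos, own[: len(own) - recent],
                                    exclude_near=origin,
                                    exclude_r=excl) < clearance:
                return True
        return False

    for _ in range(config.n_steps):
        if len(segments) >= config.max_segments:
            break
        for tip in tips:
            if not tip.alive:
                continue
            if len(segments) >= config.max_segments:
                close_tip(tip)
                continue
            tip.angle += float(np.clip(rng.normal(0.0, jitter),
                                       -2.5 * jitter, 2.5 * jitter))
            # cap total turning over the last few steps so a tip can never
            # hairpin back onto its own tube
            if tip.recent_angles:
                ref = tip.recent_angles[0]
                delta = (tip.angle - ref + math.pi) % (2 * math.pi) - math.pi
                cap = math.radians(70.0)
                if abs(delta) > cap:
                    tip.angle = ref + math.copysign(cap, delta)
            tip.recent_angles.append(tip.angle)
            if len(tip.recent_angles) > 4:
                tip.recent_angles.pop(0)
            step = config.step_length_um * np.array([math.cos(tip.angle),
                                                     math.sin(tip.angle)])
            new_pos = tip.pos + step
            # approaching the field border ends the branch where it stands:
            # clipping tips along the border would rasterize half-tubes and
            # border-hugging stubs no analysis could score
            border = config.step_length_um / 2.0
            if (new_pos[0] < 0.0 or new_pos[0] > w_um - border
                    or new_pos[1] < border or new_pos[1] > h_um - border):
                close_tip(tip)
                continue
            tip.points.append(new_pos)
            tip.pos = new_pos
            tip.steps += 1
            if try_anastomose(tip, tips):
                continue
            if collides(tip, tips):
                # too close to a tube it may not join: retract and stop, so
                # distinct vessels never blur together in the rendered mask
                tip.points.pop()
                tip.pos = np.asarray(tip.points[-1])
                close_tip(tip)
                continue
            if (tip.steps >= config.min_branch_steps
                    and rng.random() < config.branching_prob):
                node = close_tip(tip)
                if node is None:
                    continue
                for sign in (+1.0, -1.0):
                    tips.append(_Tip(pos=node.copy(),
                                     angle=tip.angle + sign * branch_angle / 2.0,
                                     points=[node.copy()]))
        tips = [t for t in tips if t.alive] + [t for t in tips if not t.alive]
        tips = [t for t in tips if t.alive]
        if not tips:
            break
    for tip in tips:
        if tip.alive:
            close_tip(tip)

    if not segments:
        raise ConfigurationError("growth produced no segments; "
                                 "check domain and step length")
    truth = NetworkTruth(segments=segments, domain_um=(h_um, w_um), dose_gy=0.0)
    _tidy_graph(truth, min_terminal_um=0.4 * config.step_length_um)
    if not truth.segments:
        raise ConfigurationError("growth produced no usable segments")
    return truth


def _tidy_graph(truth: NetworkTruth, min_terminal_um: float) -> None:
    """Normalize the truth graph in place so segments are exactly its edges:
    drop terminal stubs shorter than ``min_terminal_um`` (unresolvable by
    image analysis) and contract degree-2 nodes left behind by stub removal
    or head-on tip fusion."""
    def direction_from(seg: Segment, node_pos: np.ndarray) -> np.ndarray:
        # averaged over ~2 vertices: single steps near fusion joins can be
        # tiny and point anywhere
        pts = seg.points
        if (np.abs(pts[0] - node_pos) < _EDGE_TOL_UM).all():
            v = pts[min(2, len(pts) - 1)] - pts[0]
        else:
            v = pts[max(len(pts) - 3, 0)] - pts[-1]
        n = np.hypot(*v)
        return v / n if n > 0 else v

    def resolvable_length(seg: Segment, node: int, positions, pairs) -> float:
        """Minimum length a terminal branch needs to protrude visibly past
        the tubes it shares its attachment node with: a branch at angle θ to
        a neighbour of similar calibre is swallowed by the joint blob for
        roughly (r1+r2)/sin θ of its run."""
        p = positions[node]
        u = direction_from(seg, p)
        need = min_terminal_um
        for j, (a, b) in enumerate(pairs):
            other = truth.segments[j]
            if other is seg or node not in (a, b):
                continue
            v = direction_from(other, p)
            if float(u @ v) <= 0:
                continue  # leaves the node on the other side: no overlap
            sin_theta = max(abs(float(u[0] * v[1] - u[1] * v[0])), 0.05)
            need = max(need, (seg.diameter_um + other.diameter_um) / 2.0
                       / sin_theta + 4.0)
        return need

    for _ in range(100):
        changed = False
        if len(truth.segments) > 1:
            positions, pairs = truth._node_index()
            _, degrees = truth.node_table()
            h_um, w_um = truth.domain_um
            for i, (seg, (a, b)) in enumerate(zip(truth.segments, pairs)):
                for n in (a, b):
                    x, y = positions[n]
                    on_edge = (x < _EDGE_TOL_UM or y < _EDGE_TOL_UM
                               or x > w_um - _EDGE_TOL_UM
                               or y > h_um - _EDGE_TOL_UM)
                    dangling = degrees[n] == 1 and not on_edge
                    if not dangling:
                        continue
                    attach = b if n == a else a
                    if seg.length_um() < resolvable_length(
                            seg, attach, positions, pairs):
                        del truth.segments[i]
                        changed = True
                        break
                if changed:
                    break
        if not changed and len(truth.segments) > 1:
            positions, pairs = truth._node_index()
            _, degrees = truth.node_table()
            for node in np.nonzero(degrees == 2)[0]:
                incident = [i for i, (a, b) in enumerate(pairs)
                            if node in (a, b)]
                if len(incident) != 2:   # a loop touching the node twice
                    continue
                i, j = incident
                s1, s2 = truth.segments[i], truth.segments[j]
                p = positions[node]
                o1, o2 = direction_from(s1, p), direction_from(s2, p)
                if float(o1 @ o2) > -0.5:
                    # the two runs meet at a sharp corner; merging them
                    # would bake a kink blob into the rendered tube, so
                    # drop the shorter run instead
                    drop = i if s1.length_um() < s2.length_um() else j
                    del truth.segments[drop]
                    changed = True
                    break

                def oriented(seg):
                    # polyline oriented to END at the node
                    if (np.abs(seg.points[-1] - p) < _EDGE_TOL_UM).all():
                        return seg.points
                    return seg.points[::-1]

                merged_pts = np.vstack([oriented(s1), oriented(s2)[::-1][1:]])
                l1, l2 = s1.length_um(), s2.length_um()
                diameter = (s1.diameter_um * l1 + s2.diameter_um * l2) / (l1 + l2)
                merged = Segment(points=merged_pts, diameter_um=diameter)
                for idx in sorted((i, j), reverse=True):
                    del truth.segments[idx]
                truth.segments.append(merged)
                changed = True
                break
        if not changed:
            break


# ----------------------------------------------------------------------
# injury
# ----------------------------------------------------------------------

def apply_dose_injury(truth: NetworkTruth,
                      config: SimulationConfig) -> NetworkTruth:
    """Apply the parametric radiation-injury model at ``config.dose_gy``.

    One pass: every currently terminal branch (a free endpoint not on the
    left-edge inlet) is pruned with probability ``1-exp(-pruning_rate*dose)``;
    surviving diameters are multiplied by ``exp(-shrink_rate*dose)`` (clipped
    to the configured calibre range); surviving segments are flagged
    regressed / blocked with their per-Gy Bernoulli rates.  Dose 0 returns an
    identical copy.
    """
    dose = config.dose_gy
    if dose < 0:
        raise ConfigurationError("dose_gy must be >= 0")
    out = truth.copy()
    out.dose_gy = dose
    if dose == 0.0:
        return out

    rng = np.random.default_rng([config.seed, 0x696E])  # stage tag: injury

    # prune terminal branches (free endpoints away from the inlet edge)
    p_prune = 1.0 - math.exp(-config.pruning_rate * dose)
    positions, pairs = out._node_index()
    _, degrees = out.node_table()
    keep: list[Segment] = []
    for seg, (a, b) in zip(out.segments, pairs):
        terminal = False
        for node in (a, b):
            if degrees[node] == 1 and positions[node][0] > _EDGE_TOL_UM:
                terminal = True
        if terminal and rng.random() < p_prune:
            continue
        keep.append(seg)
    out.segments = keep

    shrink = math.exp(-config.shrink_rate * dose)
    lo, hi = config.diameter_range_um
    p_regress = 1.0 - math.exp(-config.regression_rate * dose)
    p_block = 1.0 - math.exp(-config.blockage_rate * dose)
    for seg in out.segments:
        seg.diameter_um = float(np.clip(seg.diameter_um * shrink, lo, hi))
        seg.regressed = bool(rng.random() < p_regress)
        seg.blocked = bool(rng.random() < p_block)
    return out


def simulate_network(config: SimulationConfig) -> NetworkTruth:
    """Convenience: generate a network and apply the configured dose."""
    return apply_dose_injury(generate_network(config), config)
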