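"""Assemble a VeinNetwork from axis-aligned vein segments.

Both the deterministic fixtures and the loop-subdivision growth model
produce veins as maximal axis-aligned segments whose endpoints lie exactly
on earlier segments (T-junctions).  This helper splits every segment at the
junction points that other segments' endpoints impose on it and emits a
proper planar graph.  Coordinates are matched exactly up to a rounding
tolerance; segments are assumed non-crossing and non-overlapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .network import CM_TO_MM, Edge, VeinNetwork

_ROUND = 9  # decimal places when keying coordinates


@dataclass(frozen=True)
class VeinSegment:
    x1: float
    y1: float
    x2: float
    y2: float
    width: float  # mm

    @property
    def horizontal(self) -> bool:
        return self.y1 == self.y2


def _key(x: float, y: float) -> tuple[float, float]:
    return (round(x, _ROUND), round(y, _ROUND))


def segments_to_network(segments: list[VeinSegment]) -> VeinNetwork:
    """Split segments at T-junctions and build the network.

    Edge ids follow segment order, then position along the segment, so they
    are deterministic; each sub-edge inherits its parent segment's width.
    """
    endpoints = set()
    for s in segments:
        endpoints.add(_key(s.x1, s.y1))
        endpoints.add(_key(s.x2, s.y2))
    by_x: dict[float, list[float]] = {}
    by_y: dict[float, list[float]] = {}
    for x, y in endpoints:
        by_x.setdefault(x, []).append(y)
        by_y.setdefault(y, []).append(x)

    node_ids = {pt: i for i, pt in enumerate(sorted(endpoints))}
    node_rows = {i: pt for pt, i in node_ids.items()}

    edges: dict[int, Edge] = {}
    eid = 0
    for s in segments:
        if s.horizontal:
            y = _key(0.0, s.y1)[1]
            lo, hi = sorted((s.x1, s.x2))
            lo_k, hi_k = round(lo, _ROUND), round(hi, _ROUND)
            cuts = sorted(x for x in by_y.get(y, []) if lo_k <= x <= hi_k)
            pts = [(x, y) for x in cuts]
        else:
            x = _key(s.x1, 0.0)[0]
            lo, hi = sorted((s.y1, s.y2))
            lo_k, hi_k = round(lo, _ROUND), round(hi, _ROUND)
            cuts = sorted(yy for yy in by_x.get(x, []) if lo_k <= yy <= hi_k)
            pts = [(x, yy) for yy in cuts]
        for p1, p2 in zip(pts, pts[1:]):
            a, b = node_ids[p1], node_ids[p2]
            length = math.hypot(p2[0] - p1[0], p2[1] - p1[1]) * CM_TO_MM
            edges[eid] = Edge(a, b, s.width, length)
            eid += 1
    return VeinNetwork(dict(node_rows), edges)
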