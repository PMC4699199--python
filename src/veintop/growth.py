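"""Stochastic loop-subdivision model of minor-venation development.

A single rectangular loop grows; loops whose area approaches a critical
area A_0 subdivide by insertion of a straight new vein perpendicular to the
loop's longer axis, placed near the midline with asymmetry controlled by
rho in [0, 1].  The subdivision probability is a logistic sigmoid of the
loop area with width sigma_A = beta * A_0.  All veins start at a fixed
small width w_0 and widen linearly with time at a rate coupled to the
lamina expansion through alpha, so at the end of growth older veins are
strictly wider.  Finally, multiplicative Gaussian noise of amplitude f_n
perturbs the vein widths; this noise scrambles width ranks and is what
degrades the nesting hierarchy.

The model is governed by the four dimensionless parameters rho,
beta = sigma_A / A_0, alpha and f_n.  With f_n = 0 the nesting tree of the
generated network exactly mirrors the recorded split genealogy, which makes
the simulator double as a ground-truth generator for decomposition tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .metrics import nesting_ratios, topological_lengths
from .decomposition import build_nesting_tree
from .network import Areole, VeinNetwork, extract_facets, prune_to_cycles
from .phenospace import ks_distance
from .segments import VeinSegment, segments_to_network


@dataclass(frozen=True)
class GrowthParams:
    alpha: float = 0.25  # width growth rate relative to length growth
    beta: float = 0.5  # sigmoid width / critical area
    rho: float = 0.2  # split-position asymmetry in [0, 1]
    f_n: float = 0.1  # terminal width-noise amplitude
    A_0: float = 1.0  # critical areole area (model units, cm^2)
    w_0: float = 0.01  # initial vein width, mm
    growth_rate: float = 0.05  # per-step linear expansion of the lamina
    target_areoles: int = 64
    seed: int = 0
    max_steps: int = 100_000

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [0, 1]")
        if self.beta <= 0 or self.A_0 <= 0 or self.w_0 <= 0:
            raise ValueError("beta, A_0, w_0 must be positive")
        if self.f_n < 0:
            raise ValueError("f_n must be >= 0")
        if self.target_areoles < 1:
            raise ValueError("target_areoles must be >= 1")
        if self.growth_rate <= 0:
            raise ValueError("growth_rate must be positive")

    @property
    def sigma_A(self) -> float:
        return self.beta * self.A_0


def split_probability(A: float, A_0: float, sigma_A: float) -> float:
    """Logistic subdivision probability: 1/2 at the critical area A_0."""
    if sigma_A <= 0:
        raise ValueError("sigma_A must be positive")
    return float(expit((A - A_0) / sigma_A))


@dataclass(frozen=True)
class SplitEvent:
    step: int
    parent: int
    child_a: int
    child_b: int
    position: float  # relative position of the new vein along the longer axis
    vein: int  # index of the created segment


@dataclass
class GrowthResult:
    network: VeinNetwork
    events: list[SplitEvent]
    params: GrowthParams
    steps: int
    scale: float
    areole_rects: dict[int, tuple[float, float, float, float]]  # final coords, cm
    children: dict[int, tuple[int, int]] = field(default_factory=dict)

    def genealogy_clades(self) -> set[frozenset[int]]:
        """Final-areole descendant sets of every split, the ground-truth
        counterpart of the nesting tree's clades."""
        desc: dict[int, frozenset[int]] = {}

        def descend(a: int) -> frozenset[int]:
            if a in desc:
                return desc[a]
            if a not in self.children:
                desc[a] = frozenset({a})
            else:
                ca, cb = self.children[a]
                desc[a] = descend(ca) | descend(cb)
            return desc[a]

        return {descend(ev.parent) for ev in self.events}

    def match_facets(self, facets: list[Areole]) -> dict[int, int]:
        """facet_id -> areole id, by locating each facet centroid inside the
        final areole rectangles."""
        out: dict[int, int] = {}
        net = self.network
        for f in facets:
            pts = np.array([net.nodes[n] for n in f.boundary_nodes])
            cx, cy = pts.mean(axis=0)
            for aid, (x0, y0, x1, y1) in self.areole_rects.items():
                if x0 <= cx <= x1 and y0 <= cy <= y1:
                    out[f.facet_id] = aid
                    break
            else:
                raise ValueError(f"facet {f.facet_id} matches no simulated areole")
        return out


def simulate_growth(params: GrowthParams) -> GrowthResult:
    """Run the loop-subdivision model; bit-reproducible for a given seed.

    The lamina starts as a 0.5 cm square (area A_0/4 in the default units)
    and expands by ``growth_rate`` per step; growth is simulated in the
    initial frame with a running scale factor, and final coordinates carry
    the accumulated expansion.
    """
    rng = np.random.default_rng(params.seed)
    side = 0.5
    segments = [
        VeinSegment(0, 0, side, 0, 0.0),
        VeinSegment(side, 0, side, side, 0.0),
        VeinSegment(side, side, 0, side, 0.0),
        VeinSegment(0, side, 0, 0, 0.0),
    ]
    seg_step = [0, 0, 0, 0]  # creation step of each segment
    rects: dict[int, tuple[float, float, float, float]] = {0: (0.0, 0.0, side, side)}
    children: dict[int, tuple[int, int]] = {}
    events: list[SplitEvent] = []
    next_id = 1
    scale = 1.0
    step = 0
    while len(rects) < params.target_areoles:
        step += 1
        if step > params.max_steps:
            raise RuntimeError(
                f"no {params.target_areoles} areoles after {params.max_steps} steps; "
                "parameters give a vanishing split probability"
            )
        scale *= 1.0 + params.growth_rate
        for aid in sorted(rects):
            x0, y0, x1, y1 = rects[aid]
            area = (x1 - x0) * (y1 - y0) * scale**2
            p = split_probability(area, params.A_0, params.sigma_A)
            if rng.random() >= p:
                continue
            pos = 0.5 + params.rho * (rng.random() - 0.5)
            if (x1 - x0) >= (y1 - y0):  # new vein perpendicular to the longer axis
                xc = x0 + pos * (x1 - x0)
                segments.append(VeinSegment(xc, y0, xc, y1, 0.0))
                ra, rb = (x0, y0, xc, y1), (xc, y0, x1, y1)
            else:
                yc = y0 + pos * (y1 - y0)
                segments.append(VeinSegment(x0, yc, x1, yc, 0.0))
                ra, rb = (x0, y0, x1, yc), (x0, yc, x1, y1)
            seg_step.append(step)
            ca, cb = next_id, next_id + 1
            next_id += 2
            del rects[aid]
            rects[ca], rects[cb] = ra, rb
            children[aid] = (ca, cb)
            events.append(SplitEvent(step, aid, ca, cb, pos, len(segments) - 1))
            if len(rects) >= params.target_areoles:
                break

    # widths: linear in age, then multiplicative Gaussian noise per vein
    final = []
    for seg, t in zip(segments, seg_step):
        w = params.w_0 * (1.0 + params.alpha * params.growth_rate * (step - t))
        if params.f_n > 0:
            w *= 1.0 + params.f_n * rng.standard_normal()
        w = max(w, 0.05 * params.w_0)
        final.append(
            VeinSegment(seg.x1 * scale, seg.y1 * scale, seg.x2 * scale, seg.y2 * scale, w)
        )
    network = segments_to_network(final)
    rects_final = {
        aid: (x0 * scale, y0 * scale, x1 * scale, y1 * scale)
        for aid, (x0, y0, x1, y1) in rects.items()
    }
    return GrowthResult(
        network=network,
        events=events,
        params=params,
        steps=step,
        scale=scale,
        areole_rects=rects_final,
        children=children,
    )


def ensemble_nesting_numbers(params: GrowthParams, n_seeds: int, base_seed: int = 0):
    """Unweighted nesting numbers of an ensemble of independent runs."""
    from .metrics import nesting_number

    out = []
    for s in range(n_seeds):
        res = simulate_growth(replace(params, seed=base_seed + s))
        tree = build_nesting_tree(res.network)
        out.append(nesting_number(tree, "unweighted"))
    return np.array(out)


def _distribution_triplet(net: VeinNetwork):
    pruned = prune_to_cycles(net)
    facets = extract_facets(pruned)
    tree = build_nesting_tree(pruned, facets)
    areas = np.array([f.area for f in facets])
    return (
        areas / areas.mean(),
        np.array(list(topological_lengths(pruned).values()), dtype=float),
        np.array(nesting_ratios(tree, max_degree=10**9)),
    )


def model_leaf_comparison(sim_net: VeinNetwork, leaf_net: VeinNetwork) -> tuple[float, float, float]:
    """D_KS between model and leaf for mean-normalized areole areas,
    topological lengths, and nesting ratios (in that order)."""
    sa, sl, sq = _distribution_triplet(sim_net)
    la, ll, lq = _distribution_triplet(leaf_net)
    return (ks_distance(sa, la), ks_distance(sl, ll), ks_distance(sq, lq))
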