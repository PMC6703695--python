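"""Tree-structured ridge tracing.

From each seed maximum the tracer grows a rooted tree of ridge polylines
("ridglets").  Phase 1 sends two ridglets in roughly opposite directions
from the root; phase 2 spawns child ridglets where unclaimed side ridges
leave an existing path (branch points).  Every step moves to the brightest
legal 8-neighbour of the current pixel; a pixel claimed by the tree is
never claimed twice, which both bounds the procedure and records where
paths meet (crossing points).  Each ridglet terminates with exactly one
stop code:

======  ==========================================================
``C``   met another ridglet of its own tree (own path crossing)
``CP``  met a recorded crossing point of its parent
``D``   cumulative path length exceeded the maximum trace distance
``I``   ridge response dropped below a fraction of the root response
``L``   looped back onto its own path (non-origin)
``M``   bookkeeping: seed whose tree produced no accepted shape
``O``   returned to the origin pixel, closing a loop
``P``   met the path between the root and its parent's attach point
``T``   turned more sharply than allowed over the last few steps
======  ==========================================================

``M`` is assigned post hoc by the shape-selection stage, never by the
tracer itself.  The intensity-drop criterion is relative to the response
at the root, so tracing is invariant to global intensity scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .io import SegmentationParams
from .ridge import RidgeResponse
from .seeds import SeedPoint

__all__ = ["StopCode", "Ridglet", "RidgletTree", "TraceState",
           "step_to_brightest_neighbour", "evaluate_stop", "build_tree",
           "render_tree_overlay"]


class StopCode(str, Enum):
    C = "C"    # own tree crossing
    CP = "CP"  # parent crossing point
    D = "D"    # distance stop
    I = "I"    # intensity drop
    L = "L"    # loop to self
    M = "M"    # missed (post hoc)
    O = "O"    # origin closure
    P = "P"    # path to parent node
    T = "T"    # sharp turns


# 8-neighbour offsets (x, y) in clockwise order starting at +x
_DIRS = [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)]
_STEP_LEN = [float(np.hypot(dx, dy)) for dx, dy in _DIRS]
_ANGLES = [float(np.arctan2(dy, dx)) for dx, dy in _DIRS]

ROOT_OWNER = -1

# fraction of the best neighbour response within which straightness decides
_CLOSE_FRAC = 0.8


@dataclass
class Ridglet:
    """One traced ridge polyline.

    ``path`` starts at the ridglet's first own pixel (the root pixel itself
    belongs to the tree, not to any ridglet).  ``attach_index`` is the index
    into the parent's path where this ridglet branched (-1 = attached to the
    root pixel).
    """

    index: int
    path: list[tuple[int, int]] = field(default_factory=list)
    parent: Optional["Ridglet"] = None
    attach_index: int = -1
    children: list["Ridglet"] = field(default_factory=list)
    start_kind: str = "root"  # 'root' | 'branch-point'
    stop_code: Optional[StopCode] = None
    closure_pixel: Optional[tuple[int, int]] = None
    crossing_points: list[tuple[int, int]] = field(default_factory=list)

    @property
    def terminus(self) -> Optional[tuple[int, int]]:
        return self.path[-1] if self.path else None

    def generation(self) -> int:
        g, r = 0, self
        while r.parent is not None:
            g, r = g + 1, r.parent
        return g


@dataclass
class RidgletTree:
    """A rooted tree of ridglets grown from one seed."""

    root_seed: SeedPoint
    root: tuple[int, int]          # snapped root pixel (x, y)
    root_value: float
    ridglets: list[Ridglet] = field(default_factory=list)
    claimed: dict = field(default_factory=dict)  # (x, y) -> ridglet index

    @property
    def leaves(self) -> list[Ridglet]:
        return [r for r in self.ridglets if r.path]

    def path_from_root(self, ridglet: Ridglet) -> list[tuple[int, int]]:
        """Ordered pixels from the root pixel to the ridglet's terminus.

        A child ridglet follows its parent's path only up to the pixel it
        branched from, then continues along its own pixels.
        """
        if ridglet.parent is None:
            return [self.root] + list(ridglet.path)
        parent_full = self.path_from_root(ridglet.parent)
        attach = ridglet.parent.path[ridglet.attach_index]
        prefix = parent_full[: parent_full.index(attach) + 1]
        return prefix + list(ridglet.path)


@dataclass
class TraceState:
    """Mutable per-ridglet tracer state consulted by the stop rules."""

    tree: RidgletTree
    ridglet: Ridglet
    params: SegmentationParams
    total_length: float = 0.0
    dir_history: list[int] = field(default_factory=list)  # direction indices

    @property
    def floor(self) -> float:
        return self.params.intensity_drop_fraction * self.tree.root_value


def _in_bounds(px: tuple[int, int], shape_yx: tuple[int, int]) -> bool:
    x, y = px
    return 0 <= x < shape_yx[1] and 0 <= y < shape_yx[0]


def _resp_at(resp: np.ndarray, px: tuple[int, int]) -> float:
    return float(resp[px[1], px[0]])


def _classify_block(state: TraceState, pixel: tuple[int, int]) -> StopCode:
    """Map the owner of a blocking pixel to a stop code."""
    tree, r = state.tree, state.ridglet
    if pixel == tree.root:
        return StopCode.O if r.parent is None else StopCode.C
    owner = tree.claimed.get(pixel)
    if owner == r.index:
        return StopCode.L
    if r.parent is not None and owner == r.parent.index:
        if pixel in r.parent.crossing_points:
            return StopCode.CP
        attach = r.attach_index
        if attach >= 0 and pixel in r.parent.path[: attach + 1]:
            return StopCode.P
        return StopCode.C
    return StopCode.C


def _turn_over_window(dir_history: list[int], window: int) -> float:
    """Cumulative signed turn (degrees) over the last ``window`` steps."""
    if len(dir_history) < 2:
        return 0.0
    hist = dir_history[-(window + 1):]
    total = 0.0
    for a, b in zip(hist, hist[1:]):
        d = (b - a) % 8
        if d > 4:
            d -= 8
        total += 45.0 * d
    return total


def evaluate_stop(state: TraceState,
                  current: tuple[int, int],
                  response: np.ndarray) -> tuple[Optional[tuple[int, int]], Optional[StopCode]]:
    """One tracer decision: the next pixel, or the stop code.

    Checks, in order: distance stop (D); origin closure (O); the brightest
    unclaimed forward neighbour (ties broken by a fixed clockwise scan from
    the previous step direction); blocked-path classification (C/CP/L/P);
    intensity drop (I); sharp turn (T).
    """
    p = state.params
    if state.total_length > p.max_trace_distance:
        return None, StopCode.D

    tree = state.tree
    shape_yx = response.shape
    prev_dir = state.dir_history[-1] if state.dir_history else None
    steps_taken = len(state.ridglet.path)

    # origin closure: the root pixel is an 8-neighbour again after a real loop
    if steps_taken >= 4:
        cx, cy = current
        rx, ry = tree.root
        if max(abs(cx - rx), abs(cy - ry)) == 1 and state.ridglet.parent is None:
            return None, StopCode.O

    candidates = []       # (resp, turn_mag, scan_offset, dir_index, pixel)
    best_blocked = None   # (resp, pixel) among claimed neighbours
    backward_open = False
    for k, (dx, dy) in enumerate(_DIRS):
        nxt = (current[0] + dx, current[1] + dy)
        if not _in_bounds(nxt, shape_yx):
            continue
        claimed = nxt in tree.claimed or nxt == tree.root
        if claimed:
            r = _resp_at(response, nxt)
            if best_blocked is None or r > best_blocked[0]:
                best_blocked = (r, nxt)
            continue
        if prev_dir is not None:
            dot = dx * _DIRS[prev_dir][0] + dy * _DIRS[prev_dir][1]
            if dot < 0:  # no reversal steps
                backward_open = True
                continue
        r = _resp_at(response, nxt)
        if prev_dir is None:
            turn_mag, offset = 0, 0
        else:
            d = (k - prev_dir) % 8
            turn_mag = min(d, 8 - d)
            offset = d
        candidates.append((r, turn_mag, offset, k, nxt))

    if not candidates:
        if best_blocked is not None:
            return None, _classify_block(state, best_blocked[1])
        if backward_open:
            return None, StopCode.T
        return None, StopCode.D  # dead end at the image border
    # directional hysteresis: among near-equally bright neighbours take the
    # straightest continuation, so the trace crosses ridge junctions instead
    # of turning onto a side wall; ties break by clockwise scan order
    rmax = max(c[0] for c in candidates)
    close = [c for c in candidates if c[0] >= _CLOSE_FRAC * rmax] or candidates
    resp_val, _, _, dir_index, nxt = min(close, key=lambda c: (c[1], c[2], c[3]))
    resp_val = max(c[0] for c in close if c[3] == dir_index)
    if resp_val < state.floor:
        return None, StopCode.I
    turn = _turn_over_window(state.dir_history + [dir_index], p.turn_window)
    if abs(turn) > p.sharp_turn_max_angle:
        return None, StopCode.T
    return nxt, None


def step_to_brightest_neighbour(response: np.ndarray,
                                current: tuple[int, int],
                                state: TraceState) -> tuple[Optional[tuple[int, int]], Optional[StopCode]]:
    """Public stepping primitive: next pixel or stop code (never both)."""
    return evaluate_stop(state, current, response)


def _trace(tree: RidgletTree, ridglet: Ridglet, start: tuple[int, int],
           first_dir: int, response: np.ndarray, params: SegmentationParams) -> None:
    state = TraceState(tree=tree, ridglet=ridglet, params=params,
                       dir_history=[first_dir])
    current = start
    ridglet.path.append(current)
    tree.claimed[current] = ridglet.index
    state.total_length = _STEP_LEN[first_dir]
    while True:
        nxt, stop = evaluate_stop(state, current, response)
        if stop is not None:
            ridglet.stop_code = stop
            if stop in (StopCode.C, StopCode.CP, StopCode.L, StopCode.O, StopCode.P):
                # record where the path met the tree
                blocked = _nearest_claimed_neighbour(tree, current, response)
                ridglet.closure_pixel = blocked
                if blocked is not None and ridglet.parent is not None:
                    ridglet.parent.crossing_points.append(blocked)
            return
        dx, dy = nxt[0] - current[0], nxt[1] - current[1]
        k = _DIRS.index((dx, dy))
        state.dir_history.append(k)
        if len(state.dir_history) > params.turn_window + 2:
            del state.dir_history[0]
        state.total_length += _STEP_LEN[k]
        current = nxt
        ridglet.path.append(current)
        tree.claimed[current] = ridglet.index


def _nearest_claimed_neighbour(tree: RidgletTree, current: tuple[int, int],
                               response: np.ndarray) -> Optional[tuple[int, int]]:
    best = None
    for dx, dy in _DIRS:
        nxt = (current[0] + dx, current[1] + dy)
        if nxt == tree.root or nxt in tree.claimed:
            r = _resp_at(response, nxt) if _in_bounds(nxt, response.shape) else 0.0
            if best is None or r > best[0]:
                best = (r, nxt)
    return best[1] if best else None


def _snap_to_crest(response: np.ndarray, seed: SeedPoint, radius: int = 2) -> tuple[int, int]:
    x0, y0 = seed.position
    ny, nx = response.shape
    y0 = min(max(y0, 0), ny - 1)
    x0 = min(max(x0, 0), nx - 1)
    ys = slice(max(0, y0 - radius), min(ny, y0 + radius + 1))
    xs = slice(max(0, x0 - radius), min(nx, x0 + radius + 1))
    window = response[ys, xs]
    iy, ix = np.unravel_index(int(np.argmax(window)), window.shape)
    return (xs.start + int(ix), ys.start + int(iy))


_MAX_RIDGLETS = 64
_MAX_GENERATIONS = 3


def build_tree(response: RidgeResponse, seed: SeedPoint,
               params: SegmentationParams) -> RidgletTree:
    """Grow the full ridglet tree for one seed.

    The seed is first snapped to the strongest response pixel in a small
    window (seeds are detected on intensity, the crest lives on the ridge
    response).  A seed on zero-response background yields an empty tree.
    Phase 1 grows two opposite ridglets from the root; phase 2 repeatedly
    spawns children where an unclaimed ridge leaves an existing path, for
    at most three branch generations.  Deterministic for fixed inputs.
    """
    resp = response.response
    root = _snap_to_crest(resp, seed)
    root_value = _resp_at(resp, root)
    tree = RidgletTree(root_seed=seed, root=root, root_value=root_value)
    if root_value <= 0:
        return tree
    floor = params.intensity_drop_fraction * root_value

    # phase 1: two opposite starting directions from the root
    shape_yx = resp.shape
    options = []
    for k, (dx, dy) in enumerate(_DIRS):
        nxt = (root[0] + dx, root[1] + dy)
        if _in_bounds(nxt, shape_yx) and nxt not in tree.claimed:
            options.append((k, nxt, _resp_at(resp, nxt)))
    options.sort(key=lambda t: (-t[2], t[0]))
    if not options or options[0][2] < floor:
        return tree
    k1, start1, _ = options[0]
    r1 = Ridglet(index=0, start_kind="root")
    tree.ridglets.append(r1)
    _trace(tree, r1, start1, k1, resp, params)

    opposite = [(k, px, rv) for k, px, rv in options
                if px not in tree.claimed and rv >= floor
                and _DIRS[k][0] * _DIRS[k1][0] + _DIRS[k][1] * _DIRS[k1][1] <= 0]
    opposite.sort(key=lambda t: (-t[2], t[0]))
    if opposite:
        k2, start2, _ = opposite[0]
        r2 = Ridglet(index=1, start_kind="root")
        tree.ridglets.append(r2)
        _trace(tree, r2, start2, k2, resp, params)

    # phase 2: branch children where unclaimed ridges leave existing paths
    frontier = list(tree.ridglets)
    while frontier and len(tree.ridglets) < _MAX_RIDGLETS:
        ridglet = frontier.pop(0)
        if ridglet.generation() >= _MAX_GENERATIONS:
            continue
        for i, q in enumerate(ridglet.path):
            if i < 2 or i > len(ridglet.path) - 3:
                continue
            local = {ridglet.path[j] for j in range(max(0, i - 1), min(len(ridglet.path), i + 2))}
            for k, (dx, dy) in enumerate(_DIRS):
                n = (q[0] + dx, q[1] + dy)
                if not _in_bounds(n, shape_yx) or n in tree.claimed or n == tree.root:
                    continue
                # a branch must carry a ridge of comparable strength
                if _resp_at(resp, n) < max(floor, 0.5 * _resp_at(resp, q)):
                    continue
                # the branch head must lead away from the tree
                clear = True
                for ddx, ddy in _DIRS:
                    nn = (n[0] + ddx, n[1] + ddy)
                    if (nn in tree.claimed or nn == tree.root) and nn not in local:
                        clear = False
                        break
                if not clear:
                    continue
                child = Ridglet(index=len(tree.ridglets), parent=ridglet,
                                attach_index=i, start_kind="branch-point")
                ridglet.children.append(child)
                ridglet.crossing_points.append(q)
                tree.ridglets.append(child)
                _trace(tree, child, n, k, resp, params)
                frontier.append(child)
                if len(tree.ridglets) >= _MAX_RIDGLETS:
                    break
                break  # at most one child per path pixel
            if len(tree.ridglets) >= _MAX_RIDGLETS:
                break
    return tree


def render_tree_overlay(tree: RidgletTree, plane: np.ndarray,
                        path=None) -> np.ndarray:
    """Debug rendering of a ridglet tree over its plane.

    Branches are drawn in red, the root as a red disc, leaf termini in
    green and crossing points in blue, over the grey intensity plane.
    Returns the RGB array; saves it as PNG when ``path`` is given.
    """
    p = np.asarray(plane, dtype=np.float64)
    lo, hi = p.min(), p.max()
    grey = ((p - lo) / (hi - lo + 1e-9) * 255).astype(np.uint8)
    rgb = np.stack([grey, grey, grey], axis=-1)

    def paint(px, colour, radius=0):
        x, y = px
        for dy in range(-radius, radius + 1):
            for dx in range(-radius, radius + 1):
                yy, xx = y + dy, x + dx
                if 0 <= yy < rgb.shape[0] and 0 <= xx < rgb.shape[1]:
                    rgb[yy, xx] = colour

    for r in tree.ridglets:
        for px in r.path:
            paint(px, (255, 64, 64))
        for px in r.crossing_points:
            paint(px, (64, 64, 255))
    for r in tree.leaves:
        paint(r.terminus, (64, 255, 64), radius=1)
    paint(tree.root, (255, 0, 0), radius=2)
    if path is not None:
        from skimage.io import imsave

        imsave(path, rgb, check_contrast=False)
    return rgb
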