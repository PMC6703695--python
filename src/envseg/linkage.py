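"""Linking accepted 2D areas across planes into 3D nucleus volumes.

A directed graph is built from lower to higher plane index: an edge means
"these two areas can be sections of the same nucleus" and requires a small
inter-centroid distance (in micrometres), sufficient mutual overlap, and a
plane gap no larger than ``max_jump``.  Where one area is claimed by
several areas of the same neighbouring plane, the Jaccard index decides
between keeping the single best partner and recognising the area as a
merged section that must be split between the partners — this is how
information from adjacent slices repairs 2D segmentation errors.  Volumes
are then labelled greedily along edges in decreasing Jaccard order and
filtered by the volume constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .io import LabelVolume, SegmentationParams

__all__ = ["Area2D", "NucleusVolume", "jaccard", "build_link_graph",
           "resolve_ambiguities", "label_volumes", "volumes_to_label_image"]


@dataclass(frozen=True)
class Area2D:
    """One accepted 2D area: a pixel set in one plane."""

    plane: int
    index: int
    pixels: frozenset  # of (x, y)

    @property
    def area(self) -> int:
        return len(self.pixels)

    @property
    def centroid_px(self) -> tuple[float, float]:
        pts = np.array(sorted(self.pixels), dtype=float)
        return (float(pts[:, 0].mean()), float(pts[:, 1].mean()))


@dataclass
class NucleusVolume:
    """A labelled 3D instance: one pixel set per occupied plane."""

    id: int
    areas: dict  # plane -> frozenset of (x, y)
    calibration: tuple[float, float, float]
    oversized: bool = False

    @property
    def planes(self) -> list[int]:
        return sorted(self.areas)

    @property
    def n_voxels(self) -> int:
        return sum(len(p) for p in self.areas.values())

    @property
    def volume(self) -> float:
        dx, dy, dz = self.calibration
        return self.n_voxels * dx * dy * dz

    def plane_centroid(self, z: int) -> tuple[float, float]:
        pts = np.array(sorted(self.areas[z]), dtype=float)
        return (float(pts[:, 0].mean()), float(pts[:, 1].mean()))

    @property
    def centroid(self) -> tuple[float, float, float]:
        dx, dy, dz = self.calibration
        n = self.n_voxels
        cx = sum(x for pix in self.areas.values() for x, _ in pix) / n
        cy = sum(y for pix in self.areas.values() for _, y in pix) / n
        cz = sum(z * len(pix) for z, pix in self.areas.items()) / n
        return (cx * dx, cy * dy, cz * dz)

    @property
    def bounding_box(self):
        xs = [x for pix in self.areas.values() for x, _ in pix]
        ys = [y for pix in self.areas.values() for _, y in pix]
        zs = self.planes
        return ((min(xs), min(ys), zs[0]), (max(xs), max(ys), zs[-1]))


def jaccard(mask_a: frozenset, mask_b: frozenset) -> float:
    """|A n B| / |A u B|; 0 when both masks are empty."""
    if not mask_a and not mask_b:
        return 0.0
    inter = len(mask_a & mask_b)
    if inter == 0:
        return 0.0
    return inter / (len(mask_a) + len(mask_b) - inter)


def _edge_attrs(a: Area2D, b: Area2D, params: SegmentationParams,
                calibration) -> Optional[dict]:
    dx, dy, _ = calibration
    ca, cb = a.centroid_px, b.centroid_px
    dist = float(np.hypot((ca[0] - cb[0]) * dx, (ca[1] - cb[1]) * dy))
    if dist > params.max_intercentroid_distance:
        return None
    inter = len(a.pixels & b.pixels)
    if inter == 0:
        return None
    fa, fb = inter / a.area, inter / b.area
    frac = max(fa, fb) if params.overlap_mode == "max" else min(fa, fb)
    if frac < params.overlap_threshold:
        return None
    ji = inter / (a.area + b.area - inter)
    return {"dplanes": b.plane - a.plane, "distance": dist,
            "overlap_source": fa, "overlap_target": fb, "ji": ji}


def build_link_graph(areas_by_plane: dict, params: SegmentationParams,
                     calibration=(1.0, 1.0, 1.0)) -> nx.DiGraph:
    """Directed inter-plane graph over accepted areas.

    Edges always point from lower to higher plane.  Plane gaps are tried in
    increasing order; an area that is already linked to an area in a nearer
    upstream plane does not receive longer-jump edges.
    """
    g = nx.DiGraph()
    planes = sorted(areas_by_plane)
    for z in planes:
        for a in areas_by_plane[z]:
            g.add_node((a.plane, a.index), area=a)
    for dplanes in range(1, params.max_jump + 1):
        # snapshot before the round: an area linked from a nearer upstream
        # plane does not receive longer-jump edges
        blocked = {n for n in g.nodes if g.in_degree(n) > 0} if dplanes > 1 else set()
        for p in planes:
            q = p + dplanes
            if q not in areas_by_plane:
                continue
            for b in areas_by_plane[q]:
                if dplanes > 1 and (b.plane, b.index) in blocked:
                    continue
                for a in areas_by_plane[p]:
                    attrs = _edge_attrs(a, b, params, calibration)
                    if attrs is not None:
                        g.add_edge((a.plane, a.index), (b.plane, b.index), **attrs)
    return g


def _union(pixel_sets) -> frozenset:
    out = set()
    for s in pixel_sets:
        out |= s
    return frozenset(out)


def _split_area(area: Area2D, partners: Sequence[Area2D]) -> list[frozenset]:
    """Partition an area's pixels by the nearest partner's pixel set."""
    pts = np.array(sorted(area.pixels), dtype=float)
    dists = np.empty((len(partners), len(pts)))
    for i, partner in enumerate(partners):
        ppts = np.array(sorted(partner.pixels), dtype=float)
        # nearest distance from every area pixel to this partner
        d2 = ((pts[:, None, :] - ppts[None, :, :]) ** 2).sum(axis=2)
        dists[i] = np.sqrt(d2.min(axis=1))
    owner = np.argmin(dists, axis=0)
    parts = []
    for i in range(len(partners)):
        parts.append(frozenset((int(x), int(y)) for (x, y), o in zip(pts, owner) if o == i))
    return parts


def resolve_ambiguities(graph: nx.DiGraph, params: SegmentationParams,
                        calibration=(1.0, 1.0, 1.0),
                        max_rounds: int = 1000) -> nx.DiGraph:
    """Resolve multi-partner conflicts with the Jaccard index.

    For every area holding several in-edges (or out-edges) from one plane:
    if the union of the competitors matches the area better than the best
    single competitor, the area is a merged section and is split between
    them (nearest-partner pixel assignment); otherwise only the best edge
    survives.  When both sides are ambiguous the side with the higher
    merged Jaccard dictates the outcome.  Repeats until stable.
    """
    g = graph
    next_index = 1 + max((idx for (_, idx) in g.nodes), default=0)
    for _ in range(max_rounds):
        changed = False
        for node in sorted(g.nodes):
            area: Area2D = g.nodes[node]["area"]
            sides = []
            for direction, edges in (("in", list(g.in_edges(node))),
                                     ("out", list(g.out_edges(node)))):
                by_plane: dict[int, list] = {}
                for u, v in edges:
                    other = u if direction == "in" else v
                    by_plane.setdefault(other[0], []).append(other)
                for plane, others in by_plane.items():
                    if len(others) < 2:
                        continue
                    partner_areas = [g.nodes[o]["area"] for o in others]
                    merged = _union(a.pixels for a in partner_areas)
                    merged_ji = jaccard(area.pixels, merged)
                    singles = [(jaccard(area.pixels, a.pixels), o)
                               for a, o in zip(partner_areas, others)]
                    singles.sort(key=lambda t: (-t[0], t[1]))
                    sides.append((merged_ji, singles[0][0], direction, others))
            if not sides:
                continue
            sides.sort(key=lambda t: -t[0])
            merged_ji, best_single, direction, others = sides[0]
            partner_areas = [g.nodes[o]["area"] for o in others]
            if merged_ji > best_single:
                # merged section: split this area between the partners
                parts = _split_area(area, partner_areas)
                preds = [u for u, _ in g.in_edges(node)]
                succs = [v for _, v in g.out_edges(node)]
                g.remove_node(node)
                for part in parts:
                    if not part:
                        continue
                    sub = Area2D(plane=area.plane, index=next_index, pixels=part)
                    next_index += 1
                    sub_node = (sub.plane, sub.index)
                    g.add_node(sub_node, area=sub)
                    for other in set(preds + succs):
                        if other not in g.nodes:
                            continue
                        oa = g.nodes[other]["area"]
                        lo, hi = (oa, sub) if oa.plane < sub.plane else (sub, oa)
                        attrs = _edge_attrs(lo, hi, params, calibration)
                        if attrs is not None:
                            g.add_edge((lo.plane, lo.index), (hi.plane, hi.index), **attrs)
            else:
                keep = min((o for o in others), key=lambda o:
                           (-jaccard(area.pixels, g.nodes[o]["area"].pixels), o))
                for other in others:
                    if other == keep:
                        continue
                    if direction == "in" and g.has_edge(other, node):
                        g.remove_edge(other, node)
                    elif direction == "out" and g.has_edge(node, other):
                        g.remove_edge(node, other)
            changed = True
            break  # graph changed: restart the scan
        if not changed:
            return g
    return g


def label_volumes(graph: nx.DiGraph, params: SegmentationParams,
                  calibration=(1.0, 1.0, 1.0)) -> list[NucleusVolume]:
    """Greedy volume labelling along edges in decreasing Jaccard order.

    Each edge propagates the id of an already-labelled endpoint or mints a
    new one; conflicting propagation (both ends labelled differently) keeps
    the earlier assignment.  Volumes below ``min_volume`` are discarded;
    volumes above ``max_volume`` are kept but flagged for splitting.
    """
    edges = sorted(graph.edges(data=True),
                   key=lambda e: (-e[2]["ji"], e[0], e[1]))
    assignment: dict = {}
    parent: dict = {}
    next_id = 1

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for u, v, _ in edges:
        iu, iv = assignment.get(u), assignment.get(v)
        if iu is None and iv is None:
            parent[next_id] = next_id
            assignment[u] = assignment[v] = next_id
            next_id += 1
        elif iu is None:
            assignment[u] = find(iv)
        elif iv is None:
            assignment[v] = find(iu)
        else:
            # the edge joins two already-labelled runs of the same nucleus
            ru, rv = find(iu), find(iv)
            if ru != rv:
                lo, hi = (ru, rv) if ru < rv else (rv, ru)
                parent[hi] = lo
    for node in sorted(graph.nodes):
        if node not in assignment:
            parent[next_id] = next_id
            assignment[node] = next_id
            next_id += 1
    assignment = {n: find(i) for n, i in assignment.items()}

    grouped: dict[int, dict] = {}
    for node, vid in assignment.items():
        area: Area2D = graph.nodes[node]["area"]
        planes = grouped.setdefault(vid, {})
        planes[area.plane] = frozenset(planes.get(area.plane, frozenset()) | area.pixels)

    volumes = []
    for vid in sorted(grouped):
        areas = _fill_plane_gaps(grouped[vid])
        vol = NucleusVolume(id=vid, areas=areas, calibration=calibration)
        if vol.volume < params.min_volume:
            continue
        if vol.volume > params.max_volume:
            vol.oversized = True
        volumes.append(vol)
    # renumber densely and deterministically
    for new_id, vol in enumerate(volumes, start=1):
        vol.id = new_id
    return volumes


def _dilate_pixels(pixels: frozenset, r: int) -> frozenset:
    out = set(pixels)
    for _ in range(r):
        grown = set()
        for x, y in out:
            grown.update({(x + 1, y), (x - 1, y), (x, y + 1), (x, y - 1),
                          (x + 1, y + 1), (x - 1, y - 1),
                          (x + 1, y - 1), (x - 1, y + 1)})
        out |= grown
    return frozenset(out)


def merge_broken_chains(volumes: list, params: SegmentationParams,
                        calibration=(1.0, 1.0, 1.0)) -> list:
    """Second-chance linking at the volume level.

    A single rejected or badly trimmed 2D area can break an otherwise
    clean chain into two stacked runs.  Two volumes are rejoined when
    their facing terminal areas satisfy the ordinary link criteria.  Any
    genuine stacked pair rejoined by mistake is separated again by the
    intensity-ratio split, which runs after this pass.
    """
    work = sorted(volumes, key=lambda v: (v.planes[0], v.id))
    merged = True
    while merged:
        merged = False
        for i, a in enumerate(work):
            for j, b in enumerate(work):
                if i == j:
                    continue
                za, zb = a.planes[-1], b.planes[0]
                if not 1 <= zb - za <= params.max_jump:
                    continue
                # terminal areas are judged after restoring the envelope
                # half-thickness they exclude (chains usually break where a
                # section came out trimmed)
                grow = max(1, int(params.ridge_scale))
                ta = Area2D(za, 0, _dilate_pixels(a.areas[za], grow))
                tb = Area2D(zb, 1, _dilate_pixels(b.areas[zb], grow))
                if _edge_attrs(ta, tb, params, calibration) is None:
                    continue
                areas = dict(a.areas)
                for z, pix in b.areas.items():
                    areas[z] = frozenset(areas.get(z, frozenset()) | pix)
                joined = NucleusVolume(id=min(a.id, b.id),
                                       areas=_fill_plane_gaps(areas),
                                       calibration=a.calibration)
                if joined.volume > params.max_volume:
                    joined.oversized = True
                work = [v for k, v in enumerate(work) if k not in (i, j)]
                work.append(joined)
                work.sort(key=lambda v: (v.planes[0], v.id))
                merged = True
                break
            if merged:
                break
    return work


def _fill_plane_gaps(areas: dict) -> dict:
    """Interpolate the planes a volume jumped over.

    A max-jump edge asserts that the nucleus is present in the skipped
    plane even though no 2D shape was accepted there; the gap plane is
    filled with the union of the flanking areas eroded by one pixel (a
    coarse shape average).
    """
    from scipy import ndimage as ndi

    planes = sorted(areas)
    out = dict(areas)
    for z0, z1 in zip(planes, planes[1:]):
        if z1 - z0 < 2:
            continue
        a, b = areas[z0], areas[z1]
        pts = a | b
        xs = [p[0] for p in pts]
        ys = [p[1] for p in pts]
        ox, oy = min(xs) - 1, min(ys) - 1
        mask = np.zeros((max(ys) - oy + 2, max(xs) - ox + 2), dtype=bool)
        for x, y in pts:
            mask[y - oy, x - ox] = True
        filled = ndi.binary_erosion(ndi.binary_closing(mask, iterations=2))
        fy, fx = np.nonzero(filled)
        fill = frozenset((int(x + ox), int(y + oy)) for y, x in zip(fy, fx))
        if not fill:
            fill = a & b or min((a, b), key=len)
        for z in range(z0 + 1, z1):
            out[z] = fill
    return out


def volumes_to_label_image(volumes: Sequence[NucleusVolume],
                           shape_zyx: tuple[int, int, int],
                           calibration=(1.0, 1.0, 1.0)) -> LabelVolume:
    """Rasterize volumes into a disjoint 16-bit label image."""
    data = np.zeros(shape_zyx, dtype=np.uint16)
    for vol in volumes:
        for z, pixels in vol.areas.items():
            if not 0 <= z < shape_zyx[0]:
                continue
            for x, y in pixels:
                if 0 <= y < shape_zyx[1] and 0 <= x < shape_zyx[2]:
                    if data[z, y, x] == 0:
                        data[z, y, x] = vol.id
    return LabelVolume(data.astype(np.int64), calibration)
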