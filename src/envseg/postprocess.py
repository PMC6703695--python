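"""Post-hoc refinement of 3D volumes.

Two axial profiles diagnose under-segmentation that the plane-by-plane
stages cannot see.  The intensity ratio (IR) — centre intensity divided by
rim intensity, per plane — is well below 1 inside a shell-labelled nucleus
and rises above 1 at the interface between two nuclei stacked along z,
where envelope material crosses the middle of the area; a prominent IR
peak is therefore a cut plane.  The centroid displacement (CD) — the
lateral shift of consecutive plane centroids in micrometres — spikes at
the junction of two laterally offset nuclei fused into one volume.  A
final morphological smoothing pass removes single-plane spikes and caps
the axial tips.  All operations act on one volume at a time and are
order-independent across volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .io import IntensityVolume, SegmentationParams
from .linkage import NucleusVolume

__all__ = ["AxialProfile", "intensity_ratio_profile", "split_by_intensity",
           "centroid_displacement_profile", "split_by_displacement",
           "smooth_volume", "expand_volumes", "refine_volumes",
           "profiles_to_tsv"]


@dataclass
class AxialProfile:
    """Per-plane profile along a volume's z span; kind 'IR' or 'CD'."""

    kind: str
    planes: list[int]
    values: np.ndarray


def _rim_and_centre(pixels: frozenset):
    pts = np.array(sorted(pixels))
    cx, cy = pts[:, 0].mean(), pts[:, 1].mean()
    r_eq = np.sqrt(len(pts) / np.pi)
    d = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
    centre = pts[d <= 0.5 * r_eq]
    # rim: outline pixels (pixels with a neighbour outside the set)
    pset = pixels
    rim = [p for p in map(tuple, pts)
           if any((p[0] + dx, p[1] + dy) not in pset
                  for dx in (-1, 0, 1) for dy in (-1, 0, 1) if dx or dy)]
    return centre, np.array(rim)


def intensity_ratio_profile(volume: NucleusVolume,
                            intensity: IntensityVolume) -> AxialProfile:
    """IR(z) = mean intensity over the central region / mean over the rim.

    The central region is the set of pixels within half the equivalent
    radius of the area centroid.
    """
    if len(volume.areas) < 3:
        raise ValueError("IR profile needs a volume spanning >= 3 planes")
    planes = volume.planes
    values = []
    for z in planes:
        plane = intensity.plane(z).astype(np.float64)
        centre, rim = _rim_and_centre(volume.areas[z])
        if len(rim) == 0:
            raise ValueError(f"plane {z}: empty rim")
        rim_mean = float(np.mean([plane[y, x] for x, y in rim]))
        if len(centre) == 0:
            centre_mean = rim_mean
        else:
            centre_mean = float(np.mean([plane[y, x] for x, y in centre]))
        values.append(centre_mean / max(rim_mean, 1e-9))
    return AxialProfile("IR", planes, np.array(values))


def centroid_displacement_profile(volume: NucleusVolume) -> AxialProfile:
    """CD(z) = lateral centroid shift (um) between planes z-1 and z."""
    if len(volume.areas) < 3:
        raise ValueError("CD profile needs a volume spanning >= 3 planes")
    dx, dy, _ = volume.calibration
    planes = volume.planes
    values = [0.0]
    for z0, z1 in zip(planes, planes[1:]):
        c0 = volume.plane_centroid(z0)
        c1 = volume.plane_centroid(z1)
        values.append(float(np.hypot((c1[0] - c0[0]) * dx, (c1[1] - c0[1]) * dy)))
    return AxialProfile("CD", planes, np.array(values))


def _cut(volume: NucleusVolume, cut_plane: int, drop_cut: bool,
         params: SegmentationParams):
    """Split at ``cut_plane``; return two children or None if a half would
    fall below the minimum volume."""
    lower = {z: p for z, p in volume.areas.items()
             if z < cut_plane}
    upper = {z: p for z, p in volume.areas.items()
             if (z > cut_plane if drop_cut else z >= cut_plane)}
    if not lower or not upper:
        return None
    a = NucleusVolume(id=volume.id, areas=lower, calibration=volume.calibration)
    b = NucleusVolume(id=-1, areas=upper, calibration=volume.calibration)
    if a.volume < params.min_volume or b.volume < params.min_volume:
        return None
    return [a, b]


def split_by_intensity(volume: NucleusVolume, profile: AxialProfile,
                       params: SegmentationParams) -> list[NucleusVolume]:
    """Cut at a prominent interior IR peak (the envelope interface plane is
    assigned to neither half); unchanged when no peak qualifies."""
    from scipy.signal import find_peaks

    v = profile.values
    if len(v) < 3:
        return [volume]
    peaks, props = find_peaks(v, prominence=1e-6)
    if len(peaks) == 0:
        return [volume]
    best = int(np.argmax(props["prominences"]))
    k = int(peaks[best])
    peak = v[k]
    base = peak - float(props["prominences"][best])
    # a genuine interface plane is envelope material: its centre is at
    # least as bright as its rim, so the peak must also clear IR = 1
    if peak < params.ir_prominence * max(base, 1e-9) or peak < 1.0:
        return [volume]
    children = _cut(volume, profile.planes[k], drop_cut=True, params=params)
    return children if children else [volume]


def split_by_displacement(volume: NucleusVolume, profile: AxialProfile,
                          params: SegmentationParams) -> list[NucleusVolume]:
    """Cut at a CD peak that stands out from the volume's typical drift."""
    v = profile.values
    if len(v) < 3:
        return [volume]
    k = 1 + int(np.argmax(v[1:]))
    peak = v[k]
    dx = volume.calibration[0]
    baseline = max(float(np.median(v[1:])), 0.5 * dx)
    # a genuine junction displaces the centroid by a nucleus-scale step,
    # not by segmentation jitter: require half the linking gate as well
    floor = 0.5 * params.max_intercentroid_distance
    if peak < params.cd_prominence * baseline or peak < floor:
        return [volume]
    children = _cut(volume, profile.planes[k], drop_cut=False, params=params)
    if not children:
        return [volume]
    # a genuine junction separates two laterally offset stacks; a jitter
    # peak cuts one coaxial nucleus.  Compare the halves' median centroids.
    dy = volume.calibration[1]
    med = []
    for child in children:
        cs = np.array([child.plane_centroid(z) for z in child.planes])
        med.append(np.median(cs, axis=0))
    offset = float(np.hypot((med[0][0] - med[1][0]) * dx,
                            (med[0][1] - med[1][1]) * dy))
    if offset < floor:
        return [volume]
    return children


def _volume_to_mask(volume: NucleusVolume):
    (x0, y0, z0), (x1, y1, z1) = volume.bounding_box
    mask = np.zeros((z1 - z0 + 1, y1 - y0 + 1, x1 - x0 + 1), dtype=bool)
    for z, pixels in volume.areas.items():
        for x, y in pixels:
            mask[z - z0, y - y0, x - x0] = True
    return mask, (x0, y0, z0)


def _mask_to_areas(mask: np.ndarray, origin) -> dict:
    x0, y0, z0 = origin
    areas = {}
    for iz in range(mask.shape[0]):
        ys, xs = np.nonzero(mask[iz])
        if len(ys):
            areas[z0 + iz] = frozenset((int(x + x0), int(y + y0))
                                       for y, x in zip(ys, xs))
    return areas


def smooth_volume(volume: NucleusVolume) -> NucleusVolume:
    """Morphological closing-then-opening plus axial tip capping.

    The structuring element is one voxel in x/y and extends along z only
    when the z step is not much coarser than the lateral step (anisotropy
    aware).  A cap area (the terminal area eroded by one pixel) is added at
    each axial tip when the terminal area is more than 60% of its
    neighbour, emulating the rounded top and bottom of a nucleus.  If the
    refinement would change the voxel count by more than 20% the volume is
    returned unchanged.
    """
    dx, dy, dz = volume.calibration
    mask, origin = _volume_to_mask(volume)
    pad = 2
    mask = np.pad(mask, pad)
    if dz <= 2.0 * max(dx, dy):
        structure = ndi.generate_binary_structure(3, 1)  # 6-connected cross
    else:
        structure = np.zeros((3, 3, 3), dtype=bool)
        structure[1] = ndi.generate_binary_structure(2, 1)
    out = ndi.binary_closing(mask, structure=structure)
    out = ndi.binary_opening(out, structure=structure)

    # tip extension
    occ = [iz for iz in range(out.shape[0]) if out[iz].any()]
    if occ:
        lo, hi = occ[0], occ[-1]
        if lo > 0 and hi - lo >= 1:
            a0, a1 = out[lo].sum(), out[lo + 1].sum()
            if a1 > 0 and a0 > 0.6 * a1:
                out[lo - 1] = ndi.binary_erosion(out[lo])
        if hi < out.shape[0] - 1 and hi - lo >= 1:
            a0, a1 = out[hi].sum(), out[hi - 1].sum()
            if a1 > 0 and a0 > 0.6 * a1:
                out[hi + 1] = ndi.binary_erosion(out[hi])

    out = out[pad:-pad, pad:-pad, pad:-pad]
    before = mask.sum()
    after = out.sum()
    if before == 0 or after == 0 or abs(int(after) - int(before)) > 0.2 * before:
        return volume
    areas = _mask_to_areas(out, origin)
    if not areas:
        return volume
    return NucleusVolume(id=volume.id, areas=areas,
                         calibration=volume.calibration,
                         oversized=volume.oversized)


def expand_volumes(volumes, expand_px: int,
                   shape_yx: Optional[tuple[int, int]] = None) -> list:
    """Grow every volume laterally by the envelope half-thickness.

    The traced contour follows the mid-line of the envelope signal, so
    half the envelope lies outside the raw mask; dilating each plane mask
    by ``expand_px`` restores it.  Pixels contested by two volumes are
    assigned to neither, keeping instances disjoint deterministically.
    """
    if expand_px <= 0:
        return list(volumes)
    from collections import defaultdict

    struct = ndi.generate_binary_structure(2, 2)
    grown: dict[int, dict] = {}
    claim: dict = defaultdict(dict)  # plane -> pixel -> claimant indices
    for vi, vol in enumerate(volumes):
        grown[vi] = {}
        for z, pixels in vol.areas.items():
            pts = np.array(sorted(pixels))
            ox, oy = pts[:, 0].min() - expand_px - 1, pts[:, 1].min() - expand_px - 1
            w = pts[:, 0].max() - ox + expand_px + 2
            h = pts[:, 1].max() - oy + expand_px + 2
            mask = np.zeros((h, w), dtype=bool)
            mask[pts[:, 1] - oy, pts[:, 0] - ox] = True
            mask = ndi.binary_dilation(mask, structure=struct,
                                       iterations=expand_px)
            ys, xs = np.nonzero(mask)
            pix = set()
            for y, x in zip(ys, xs):
                px = (int(x + ox), int(y + oy))
                if shape_yx is not None and not (
                        0 <= px[1] < shape_yx[0] and 0 <= px[0] < shape_yx[1]):
                    continue
                pix.add(px)
                claim[z].setdefault(px, []).append(vi)
            grown[vi][z] = pix
    out = []
    for vi, vol in enumerate(volumes):
        areas = {}
        for z, pix in grown[vi].items():
            keep = frozenset(p for p in pix if len(claim[z][p]) == 1
                             or p in vol.areas.get(z, frozenset()))
            if keep:
                areas[z] = keep
        if areas:
            out.append(NucleusVolume(id=vol.id, areas=areas,
                                     calibration=vol.calibration,
                                     oversized=vol.oversized))
    return out


def refine_volumes(volumes, intensity: IntensityVolume,
                   params: SegmentationParams) -> list[NucleusVolume]:
    """Iterated per-volume refinement: IR splits, then CD splits, repeated
    until stable, then optional smoothing.  Only binary splits per pass, so
    a stack of three nuclei resolves over two passes."""
    work = list(volumes)
    for _ in range(6):
        changed = False
        out: list[NucleusVolume] = []
        for vol in work:
            pieces = [vol]
            if params.enable_ir_split and len(vol.areas) >= 3:
                prof = intensity_ratio_profile(vol, intensity)
                pieces = split_by_intensity(vol, prof, params)
            if len(pieces) == 1 and params.enable_cd_split and len(vol.areas) >= 3:
                prof = centroid_displacement_profile(vol)
                pieces = split_by_displacement(vol, prof, params)
            if len(pieces) > 1:
                changed = True
            out.extend(pieces)
        work = out
        if not changed:
            break
    for new_id, vol in enumerate(work, start=1):
        vol.id = new_id
    if params.enable_smoothing:
        work = [smooth_volume(v) for v in work]
    # the traced outline is the envelope mid-line: restore the outer half
    ny, nx = intensity.data.shape[1], intensity.data.shape[2]
    work = expand_volumes(work, max(1, int(params.ridge_scale)), (ny, nx))
    for new_id, vol in enumerate(work, start=1):
        vol.id = new_id
    return work


def profiles_to_tsv(volumes, intensity: IntensityVolume, path):
    """Export per-volume IR and CD profiles as TSV (id, z, IR, CD)."""
    import pandas as pd

    rows = []
    for vol in volumes:
        if len(vol.areas) < 3:
            continue
        ir = intensity_ratio_profile(vol, intensity)
        cd = centroid_displacement_profile(vol)
        for z, ir_v, cd_v in zip(ir.planes, ir.values, cd.values):
            rows.append({"id": vol.id, "z": z, "IR": ir_v, "CD": cd_v})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
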