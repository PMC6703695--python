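"""Axial profiles, under-segmentation splitting and volume smoothing."""

import numpy as np
import pytest

from envseg.io import IntensityVolume, SegmentationParams
from envseg.linkage import NucleusVolume
from envseg.postprocess import (centroid_displacement_profile,
                                intensity_ratio_profile, smooth_volume,
                                split_by_displacement, split_by_intensity)
from envseg.synth import SceneSpec, generate_scene


def disc(cx, cy, r):
    return frozenset((x, y) for x in range(cx - r, cx + r + 1)
                     for y in range(cy - r, cy + r + 1)
                     if (x - cx) ** 2 + (y - cy) ** 2 <= r * r)


def params(**kw):
    base = dict(min_volume=30.0, max_volume=1e6, max_intercentroid_distance=4.0)
    base.update(kw)
    return SegmentationParams(**base)


def shell_nucleus_volume(nz=9, r=10, shell=200.0, interior=40.0, bg=10.0):
    """A spherical shell nucleus rendered into an intensity stack, plus the
    matching crest-level volume (per-plane discs)."""
    n = 40
    data = np.full((nz, n, n), bg)
    areas = {}
    zc = nz // 2
    for z in range(nz):
        dz2 = (z - zc) ** 2
        if dz2 >= r * r / 4:  # ~half-radius z extent per plane spacing 1
            continue
        rz = np.sqrt(r ** 2 - 4 * dz2) / 1.0
        rz = max(rz, 2.0)
        yy, xx = np.mgrid[:n, :n]
        rad = np.hypot(yy - 20, xx - 20)
        data[z][rad <= rz] = interior
        data[z][(rad <= rz) & (rad >= rz - 2)] = shell
        areas[z] = disc(20, 20, int(rz))
    vol = NucleusVolume(1, areas, (1.0, 1.0, 1.0))
    intensity = IntensityVolume(data.astype(np.uint16), (1.0, 1.0, 1.0), 12)
    return vol, intensity


class TestIntensityRatio:
    def test_shell_midplane_ratio_low(self):
        vol, intensity = shell_nucleus_volume()
        prof = intensity_ratio_profile(vol, intensity)
        mid = prof.values[len(prof.values) // 2]
        assert mid == pytest.approx(0.2, abs=0.12)  # interior 40 / rim 200

    def test_uniform_volume_ratio_one(self):
        areas = {z: disc(15, 15, 8) for z in range(5)}
        vol = NucleusVolume(1, areas, (1.0, 1.0, 1.0))
        intensity = IntensityVolume(np.full((5, 30, 30), 500, dtype=np.uint16))
        prof = intensity_ratio_profile(vol, intensity)
        np.testing.assert_allclose(prof.values, 1.0, atol=1e-6)

    def test_interface_plane_ratio_above_one(self):
        """Between two stacked shells, the centre is envelope material."""
        vol, intensity = shell_nucleus_volume()
        zc = vol.planes[len(vol.planes) // 2]
        plane = intensity.data[zc].copy()
        plane[:] = 10
        yy, xx = np.mgrid[:40, :40]
        plane[np.hypot(yy - 20, xx - 20) <= 6] = 200  # bright core = interface
        intensity.data[zc] = plane
        prof = intensity_ratio_profile(vol, intensity)
        k = prof.planes.index(zc)
        assert prof.values[k] > 1.0


class TestIntensitySplit:
    def stacked_pair(self):
        """Two shell nuclei stacked in z, merged into one volume."""
        spec = SceneSpec(n_nuclei=2, field_um=(40.0, 40.0, 40.0),
                         calibration=(1.0, 1.0, 1.0), crowding="stacked",
                         radius_range_um=(6.0, 7.0), axis_ratio_range=(1.0, 1.0),
                         shell_thickness_um=2.0, seed=4)
        vol, gt = generate_scene(spec)
        areas = {}
        for z in range(gt.n_planes):
            lp = gt.plane(z)
            pix = frozenset((int(x), int(y)) for y, x in zip(*np.nonzero(lp > 0)))
            if len(pix) > 20:
                areas[z] = pix
        merged = NucleusVolume(1, areas, spec.calibration)
        # true interface: between the two labelled z-extents
        z1 = np.nonzero((gt.data == 1).any(axis=(1, 2)))[0]
        z2 = np.nonzero((gt.data == 2).any(axis=(1, 2)))[0]
        interface = (min(z1.max(), z2.max()) + max(z1.min(), z2.min())) // 2
        return merged, vol, int(interface)

    def test_stacked_pair_cut_at_interface(self):
        merged, vol, interface = self.stacked_pair()
        prof = intensity_ratio_profile(merged, vol)
        out = split_by_intensity(merged, prof, params())
        assert len(out) == 2
        cut = out[0].planes[-1] + 1  # first plane after the lower half
        assert abs(cut - interface) <= 2

    def test_single_nucleus_unchanged(self):
        vol, intensity = shell_nucleus_volume()
        prof = intensity_ratio_profile(vol, intensity)
        assert split_by_intensity(vol, prof, params()) == [vol]

    def test_split_blocked_by_min_volume(self):
        merged, vol, _ = self.stacked_pair()
        prof = intensity_ratio_profile(merged, vol)
        big = params(min_volume=0.9 * merged.volume)
        assert split_by_intensity(merged, prof, big) == [merged]


class TestDisplacement:
    def test_straight_cylinder_zero(self):
        areas = {z: disc(15, 15, 6) for z in range(6)}
        vol = NucleusVolume(1, areas, (1.0, 1.0, 1.0))
        prof = centroid_displacement_profile(vol)
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-9)

    def test_fused_offset_pair_peak_at_junction(self):
        areas = {z: disc(10, 10, 6) for z in range(5)}
        areas.update({z: disc(18, 10, 6) for z in range(5, 10)})
        vol = NucleusVolume(1, areas, (1.0, 1.0, 1.0))
        prof = centroid_displacement_profile(vol)
        k = int(np.argmax(prof.values))
        assert prof.planes[k] == 5
        assert prof.values[k] == pytest.approx(8.0, abs=0.2)

    def test_helix_constant_drift_no_peak(self):
        areas = {z: disc(10 + z, 10, 6) for z in range(8)}
        vol = NucleusVolume(1, areas, (1.0, 1.0, 1.0))
        prof = centroid_displacement_profile(vol)
        drift = prof.values[1:]
        assert np.all(np.abs(drift - 1.0) < 0.1)

    def test_fused_pair_split_at_junction(self):
        areas = {z: disc(10, 10, 6) for z in range(5)}
        areas.update({z: disc(18, 10, 6) for z in range(5, 10)})
        vol = NucleusVolume(1, areas, (1.0, 1.0, 1.0))
        prof = centroid_displacement_profile(vol)
        out = split_by_displacement(vol, prof, params())
        assert len(out) == 2
        assert out[0].planes == [0, 1, 2, 3, 4]
        assert out[1].planes == [5, 6, 7, 8, 9]

    def test_helix_not_split(self):
        areas = {z: disc(10 + z, 10, 6) for z in range(8)}
        vol = NucleusVolume(1, areas, (1.0, 1.0, 1.0))
        prof = centroid_displacement_profile(vol)
        assert split_by_displacement(vol, prof, params()) == [vol]

    def test_two_plane_volume_rejected_by_profiles(self):
        vol = NucleusVolume(1, {0: disc(5, 5, 3), 1: disc(5, 5, 3)}, (1, 1, 1))
        with pytest.raises(ValueError):
            centroid_displacement_profile(vol)


class TestSmoothing:
    def cylinder(self, nz=6, r=6):
        return NucleusVolume(1, {z: disc(15, 15, r) for z in range(1, nz)},
                             (1.0, 1.0, 1.0))

    def test_lateral_spur_removed(self):
        vol = self.cylinder()
        areas = dict(vol.areas)
        spur = set(areas[3]) | {(15 + 6 + k, 15) for k in range(1, 4)}
        areas[3] = frozenset(spur)
        spiky = NucleusVolume(1, areas, (1.0, 1.0, 1.0))
        out = smooth_volume(spiky)
        for k in range(2, 4):
            assert (15 + 6 + k, 15) not in out.areas[3]

    def test_smooth_volume_near_idempotent(self):
        vol = self.cylinder()
        once = smooth_volume(vol)
        twice = smooth_volume(once)
        diff = sum(len(once.areas.get(z, frozenset()) ^ twice.areas.get(z, frozenset()))
                   for z in set(once.areas) | set(twice.areas))
        assert diff <= 0.01 * once.n_voxels + 1

    def test_smooth_ellipsoid_small_change(self):
        areas = {}
        for z in range(7):
            r = int(np.sqrt(max(9 - (z - 3) ** 2, 1)) * 2)
            areas[z] = disc(15, 15, r)
        vol = NucleusVolume(1, areas, (1.0, 1.0, 1.0))
        out = smooth_volume(vol)
        assert abs(out.n_voxels - vol.n_voxels) < 0.2 * vol.n_voxels


def test_profile_tsv_export(tmp_path):
    """IR/CD profiles export one row per occupied plane."""
    from envseg.postprocess import profiles_to_tsv
    import pandas as pd

    areas = {z: disc(15, 15, 6) for z in range(5)}
    vol = NucleusVolume(3, areas, (1.0, 1.0, 1.0))
    intensity = IntensityVolume(np.full((5, 30, 30), 500, dtype=np.uint16))
    path = profiles_to_tsv([vol], intensity, tmp_path / "prof.tsv")
    df = pd.read_csv(path, sep="\t")
    assert list(df.columns) == ["id", "z", "IR", "CD"]
    assert len(df) == 5
    assert (df["id"] == 3).all()
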