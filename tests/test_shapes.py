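"""Candidate shapes: enumeration, rasterization, features, classifier."""

import numpy as np
import pandas as pd
import pytest

from envseg.io import SegmentationParams
from envseg.ridge import RidgeResponse
from envseg.seeds import SeedPoint
from envseg.shapes import (FEATURE_NAMES, CandidateShape2D, TrainedClassifier,
                           candidate_from_chain, chain_from_mask,
                           compute_features, enumerate_candidates, rasterize,
                           resolve_plane_conflicts, select_winner,
                           train_classifier)
from envseg.tracing import Ridglet, RidgletTree, StopCode


def square_chain(x0, y0, side):
    """Closed pixel chain of an axis-aligned square (outer dimension side)."""
    chain = []
    chain += [(x0 + i, y0) for i in range(side - 1)]
    chain += [(x0 + side - 1, y0 + i) for i in range(side - 1)]
    chain += [(x0 + side - 1 - i, y0 + side - 1) for i in range(side - 1)]
    chain += [(x0, y0 + side - 1 - i) for i in range(side - 1)]
    return chain


def brute_force_interior(chain):
    """Parity (ray casting) interior test over the bounding box."""
    import matplotlib.path as mpath

    path = mpath.Path(np.array(chain, dtype=float))
    xs = [p[0] for p in chain]
    ys = [p[1] for p in chain]
    inside = set()
    for y in range(min(ys), max(ys) + 1):
        for x in range(min(xs), max(xs) + 1):
            if (x, y) in set(chain):
                continue
            if path.contains_point((x, y)):
                inside.add((x, y))
    return inside


def star_tree():
    """A hand-built 4-leaf fan tree in which every leaf pair is closable."""
    from skimage.draw import line as skline

    tree = RidgletTree(root_seed=SeedPoint((32, 32), 0, 1.0),
                       root=(32, 32), root_value=1.0)
    for i, ang in enumerate((0.0, 40.0, 80.0, 120.0)):
        x1 = int(round(32 + 5 * np.cos(np.radians(ang))))
        y1 = int(round(32 + 5 * np.sin(np.radians(ang))))
        rr, cc = skline(32, 32, y1, x1)
        path = list(zip(cc.tolist(), rr.tolist()))[1:]
        r = Ridglet(index=i, path=path, stop_code=StopCode.I)
        tree.ridglets.append(r)
        for p in path:
            tree.claimed[p] = i
    return tree


class TestEnumeration:
    def test_four_leaves_give_six_candidates(self):
        cands = enumerate_candidates(star_tree())
        assert len(cands) == 6

    def test_self_closed_loop_is_single_candidate(self):
        tree = RidgletTree(root_seed=SeedPoint((5, 1), 0, 1.0),
                           root=(5, 1), root_value=1.0)
        chain = square_chain(1, 1, 9)
        start = chain.index((5, 1))
        loop = chain[start + 1:] + chain[:start]
        r = Ridglet(index=0, path=loop, stop_code=StopCode.O)
        tree.ridglets.append(r)
        for p in loop:
            tree.claimed[p] = 0
        cands = enumerate_candidates(tree)
        assert len(cands) == 1
        assert cands[0].leaf_pair is None
        assert len(cands[0].outline_pixels) == 32

    def test_crossing_closure_dropped(self):
        """A leaf pair whose bridge crosses the arm pixels yields nothing."""
        tree = RidgletTree(root_seed=SeedPoint((20, 20), 0, 1.0),
                           root=(20, 20), root_value=1.0)
        # two nearly parallel arms; the bridge between their tips passes
        # straight through the first arm
        p1 = [(20 + k, 20) for k in range(1, 10)]
        p2 = [(20 + k, 21) for k in range(1, 4)] + [(24, 20 - 1 + 0)]
        p2 = [(20 + k, 21) for k in range(1, 10)]
        for i, path in enumerate((p1, p2)):
            r = Ridglet(index=i, path=path, stop_code=StopCode.I)
            tree.ridglets.append(r)
            for p in path:
                tree.claimed[p] = i
        cands = enumerate_candidates(tree)
        # the thin 2-row band encloses no interior -> no candidate
        assert cands == []


class TestRasterize:
    def test_square_pixel_counts(self):
        chain = square_chain(0, 0, 10)
        outline, interior = rasterize(chain)
        assert len(outline) == 36
        assert len(interior) == 64
        assert outline.isdisjoint(interior)

    def test_matches_parity_oracle(self):
        chain = square_chain(2, 3, 8)
        outline, interior = rasterize(chain)
        assert interior == brute_force_interior(chain)

    def test_translation_invariance(self):
        a = rasterize(square_chain(0, 0, 10))
        b = rasterize(square_chain(5, 7, 10))
        assert len(a[0]) == len(b[0]) and len(a[1]) == len(b[1])

    def test_degenerate_chain_dropped(self):
        assert rasterize([(0, 0), (1, 0), (2, 0)]) is None


class TestFeatures:
    def test_disc_is_convex_and_circular(self):
        yy, xx = np.mgrid[:40, :40]
        mask = np.hypot(yy - 20, xx - 20) <= 12
        shape = candidate_from_chain(chain_from_mask(mask))
        fv = compute_features(shape, np.zeros((40, 40)))
        f = dict(zip(FEATURE_NAMES, fv))
        assert f["concave_frac"] < 0.05
        assert 0.85 <= f["circularity"] <= 1.1

    def test_notch_produces_concave_pixels(self):
        yy, xx = np.mgrid[:40, :40]
        mask = np.hypot(yy - 20, xx - 20) <= 12
        mask[:20, 18:23] = False  # rectangular notch cut from the boundary
        shape = candidate_from_chain(chain_from_mask(mask))
        fv = compute_features(shape, np.zeros((40, 40)))
        f = dict(zip(FEATURE_NAMES, fv))
        assert f["concave_frac"] > 0.02

    def test_shell_intensity_statistics(self):
        """Outline on the bright envelope, interior dim: ratio = 5."""
        yy, xx = np.mgrid[:40, :40]
        mask = np.hypot(yy - 20, xx - 20) <= 12
        shape = candidate_from_chain(chain_from_mask(mask))
        plane = np.full((40, 40), 10.0)
        for x, y in shape.interior_pixels:
            plane[y, x] = 40.0
        for x, y in shape.outline_pixels:
            plane[y, x] = 200.0
        fv = compute_features(shape, plane)
        f = dict(zip(FEATURE_NAMES, fv))
        # intensity statistics are relative to the plane's bright scale
        # (the envelope, 200 here), so outline ~ 1 and interior ~ 0.2;
        # the outline/interior ratio is scale-free
        assert f["outline_mean"] == pytest.approx(1.0)
        assert f["interior_mean"] == pytest.approx(0.2)
        assert f["intensity_ratio"] == pytest.approx(5.0, rel=1e-6)


class TestClassifier:
    def make_table(self, rng, n=50):
        """Two well-separated 1-feature classes embedded in the full vector."""
        rows = []
        for label, mu in (("valid", 0.0), ("invalid", 10.0)):
            for _ in range(n):
                fv = {name: 0.0 for name in FEATURE_NAMES}
                fv["area"] = rng.normal(mu, 1.0)
                fv["label"] = label
                rows.append(fv)
        return pd.DataFrame(rows)

    def test_separated_classes_resubstitution_perfect(self):
        table = self.make_table(np.random.default_rng(0))
        clf = train_classifier(table)
        assert clf.resubstitution_accuracy == 1.0

    def test_single_class_rejected(self):
        table = self.make_table(np.random.default_rng(0))
        with pytest.raises(ValueError):
            train_classifier(table[table.label == "valid"])

    def test_symmetric_point_posterior_half(self):
        """1 feature, means 0 and 2, unit variance, equal priors, x=1."""
        clf = TrainedClassifier(
            feature_names=["f"], classes=["valid", "invalid"],
            means=np.array([[0.0], [2.0]]), variances=np.array([[1.0], [1.0]]),
            priors=np.array([0.5, 0.5]))
        assert clf.posterior_valid(np.array([[1.0]]))[0] == pytest.approx(0.5, abs=1e-12)

    def test_posterior_matches_hand_computed_gaussian(self):
        """Exact Bayes posterior for the one-feature Gaussian case."""
        clf = TrainedClassifier(
            feature_names=["f"], classes=["valid", "invalid"],
            means=np.array([[0.0], [3.0]]), variances=np.array([[1.0], [4.0]]),
            priors=np.array([0.4, 0.6]))
        x = 1.7

        def norm(v, mu, var):
            return np.exp(-(v - mu) ** 2 / (2 * var)) / np.sqrt(2 * np.pi * var)

        expect = 0.4 * norm(x, 0, 1) / (0.4 * norm(x, 0, 1) + 0.6 * norm(x, 3, 4))
        got = clf.posterior_valid(np.array([[x]]))[0]
        assert got == pytest.approx(expect, abs=1e-9)

    def test_matches_sklearn_gaussian_nb(self):
        """Independent oracle: sklearn's GaussianNB on the same data."""
        from sklearn.naive_bayes import GaussianNB

        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (80, 4))
        X[40:] += 2.0
        y = np.array(["valid"] * 40 + ["invalid"] * 40)
        table = pd.DataFrame(X, columns=FEATURE_NAMES[:4])
        table["label"] = y
        clf = train_classifier(table, feature_names=FEATURE_NAMES[:4])
        sk = GaussianNB(var_smoothing=0.0).fit(X, y)
        got = clf.posterior_valid(X)
        want = sk.predict_proba(X)[:, list(sk.classes_).index("valid")]
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_tsv_round_trip(self, tmp_path):
        table = self.make_table(np.random.default_rng(2))
        clf = train_classifier(table)
        path = clf.to_tsv(tmp_path / "clf.tsv")
        back = TrainedClassifier.from_tsv(path)
        rng = np.random.default_rng(3)
        X = rng.normal(0, 5, (10, len(FEATURE_NAMES)))
        np.testing.assert_allclose(back.posterior_valid(X),
                                   clf.posterior_valid(X), atol=1e-12)

    def test_posterior_invariant_to_feature_rescaling(self):
        table = self.make_table(np.random.default_rng(4))
        clf1 = train_classifier(table)
        scaled = table.copy()
        scaled["area"] = scaled["area"] * 7.0
        clf2 = train_classifier(scaled)
        X = table[FEATURE_NAMES].to_numpy()
        X2 = scaled[FEATURE_NAMES].to_numpy()
        np.testing.assert_allclose(clf1.posterior_valid(X),
                                   clf2.posterior_valid(X2), atol=1e-9)


def make_shape(x0, y0, side, score=0.0, posterior=0.9):
    chain = square_chain(x0, y0, side)
    shape = candidate_from_chain(chain)
    shape.posterior_valid = posterior
    shape.score = score if score else np.log(posterior / (1 - posterior))
    return shape


class TestSelection:
    def test_single_candidate_above_cut_selected(self):
        clf = TrainedClassifier(
            feature_names=["f"], classes=["valid", "invalid"],
            means=np.array([[0.0], [10.0]]), variances=np.array([[1.0], [1.0]]),
            priors=np.array([0.5, 0.5]))
        shape = make_shape(0, 0, 8)
        shape.features = np.array([0.5])
        assert select_winner([shape], clf) is shape

    def test_no_candidate_above_cut_returns_none(self):
        clf = TrainedClassifier(
            feature_names=["f"], classes=["valid", "invalid"],
            means=np.array([[0.0], [10.0]]), variances=np.array([[1.0], [1.0]]),
            priors=np.array([0.5, 0.5]))
        shape = make_shape(0, 0, 8)
        shape.features = np.array([9.5])  # deep in the invalid class
        assert select_winner([shape], clf) is None

    def test_duplicate_winners_collapse(self):
        a = make_shape(0, 0, 10, posterior=0.9)
        b = make_shape(0, 0, 10, posterior=0.8)
        out = resolve_plane_conflicts([a, b])
        assert len(out) == 1

    def test_disjoint_winners_survive(self):
        a = make_shape(0, 0, 8)
        b = make_shape(20, 20, 8)
        assert len(resolve_plane_conflicts([a, b])) == 2

    def test_partial_overlap_trimmed_to_disjoint(self):
        a = make_shape(0, 0, 10, posterior=0.95)
        b = make_shape(7, 0, 10, posterior=0.9)  # 30% overlap band
        out = resolve_plane_conflicts([a, b])
        assert len(out) == 2
        assert out[0].pixels.isdisjoint(out[1].pixels)
        # the higher-posterior shape keeps the contested pixels
        assert out[0].pixels == a.pixels
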