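"""Candidate nucleus shapes and classifier-driven selection.

Every pair of leaves of a ridglet tree whose two root-to-leaf paths can be
closed into a simple contour is one candidate 2D segmentation of the
nucleus the seed sits on (a loop that closed back on the origin is a
candidate by itself).  Candidates are rasterized into outline and interior
pixel sets, described by intensity and chain-code curvature features, and
ranked by a Gaussian naive Bayes classifier trained on user-annotated
examples; the winning shape per tree is the most probable valid one.
Because the envelope signal makes the inside and the outside of a nucleus
look alike, the classifier is what rejects internuclear-space shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import line as _draw_line
from skimage.measure import find_contours

from .tracing import Ridglet, RidgletTree, StopCode

__all__ = [
    "FEATURE_NAMES",
    "plane_intensity_scale",
    "CandidateShape2D",
    "TrainedClassifier",
    "enumerate_candidates",
    "rasterize",
    "compute_features",
    "train_classifier",
    "select_winner",
    "select_winners",
    "resolve_plane_conflicts",
    "chain_from_mask",
    "candidate_from_chain",
    "training_table_from_labels",
]

FEATURE_NAMES = [
    "outline_mean", "outline_sd", "interior_mean", "interior_sd",
    "intensity_ratio", "area", "perimeter", "circularity",
    "convex_frac", "concave_frac", "curv_low", "curv_med", "curv_high",
    "interior_ridge_frac", "interior_ridge_peak",
]

_MIN_CONTOUR_PIXELS = 8


@dataclass
class CandidateShape2D:
    """A closed candidate contour with its raster and features.

    ``area`` counts interior plus outline pixels — that one convention is
    used everywhere (features, overlaps, volumes).
    """

    contour: list[tuple[int, int]]
    outline_pixels: frozenset
    interior_pixels: frozenset
    plane_index: int = 0
    leaf_pair: Optional[tuple[int, int]] = None  # ridglet indices, None for loops
    features: Optional[np.ndarray] = None
    posterior_valid: Optional[float] = None
    score: float = float("-inf")  # classifier log-odds, used for ranking

    @property
    def area(self) -> int:
        return len(self.interior_pixels) + len(self.outline_pixels)

    @property
    def pixels(self) -> frozenset:
        return self.outline_pixels | self.interior_pixels

    @property
    def centroid(self) -> tuple[float, float]:
        pts = np.array(sorted(self.pixels))
        return (float(pts[:, 0].mean()), float(pts[:, 1].mean()))


# ---------------------------------------------------------------------------
# geometry helpers


def _bridge(a: tuple[int, int], b: tuple[int, int]) -> list[tuple[int, int]]:
    """Shortest pixel segment between two termini, endpoints excluded."""
    rr, cc = _draw_line(a[1], a[0], b[1], b[0])
    pts = list(zip(cc.tolist(), rr.tolist()))
    return pts[1:-1]


def _segments_cross(p1, p2, q1, q2) -> bool:
    """Proper intersection test of segments p1p2 and q1q2."""
    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return (v > 0) - (v < 0)

    o1, o2 = orient(p1, p2, q1), orient(p1, p2, q2)
    o3, o4 = orient(q1, q2, p1), orient(q1, q2, p2)
    return o1 != o2 and o3 != o4 and 0 not in (o1, o2, o3, o4)


def _chain_is_simple(chain: Sequence[tuple[int, int]]) -> bool:
    """A closed pixel chain is simple when its pixels are pairwise distinct
    and no two non-adjacent edges of the closed polyline properly cross."""
    if len(set(chain)) != len(chain):
        return False
    n = len(chain)
    if n < _MIN_CONTOUR_PIXELS:
        return False
    edges = [(chain[i], chain[(i + 1) % n]) for i in range(n)]
    # pixel distinctness already rules out shared vertices; catch diagonal
    # "pass-through" crossings between far-apart edges
    for i in range(n):
        a1, a2 = edges[i]
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            b1, b2 = edges[j]
            if max(abs(a1[0] - b1[0]), abs(a1[1] - b1[1])) > 2:
                continue
            if _segments_cross(a1, a2, b1, b2):
                return False
    return True


def rasterize(contour: Sequence[tuple[int, int]]):
    """Outline and interior pixel sets of a simple closed chain.

    The interior is found by a parity fill (hole filling with 4-connected
    background, the digital-Jordan complement of the 8-connected chain).
    Degenerate chains that enclose nothing are rejected by returning None.
    """
    if len(contour) < _MIN_CONTOUR_PIXELS:
        return None
    xs = [p[0] for p in contour]
    ys = [p[1] for p in contour]
    x0, y0 = min(xs) - 1, min(ys) - 1
    w, h = max(xs) - x0 + 2, max(ys) - y0 + 2
    mask = np.zeros((h, w), dtype=bool)
    for x, y in contour:
        mask[y - y0, x - x0] = True
    filled = ndi.binary_fill_holes(mask)
    interior = filled & ~mask
    if not interior.any():
        return None
    iy, ix = np.nonzero(interior)
    outline = frozenset((int(x), int(y)) for x, y in contour)
    inter = frozenset((int(x + x0), int(y + y0)) for y, x in zip(iy, ix))
    return outline, inter


# ---------------------------------------------------------------------------
# candidate enumeration


def _common_prefix_len(a: Sequence, b: Sequence) -> int:
    n = 0
    for pa, pb in zip(a, b):
        if pa != pb:
            break
        n += 1
    return n


def enumerate_candidates(tree: RidgletTree, plane_index: int = 0,
                         max_pairs: int = 45) -> list[CandidateShape2D]:
    """All closable candidate shapes of one ridglet tree.

    One candidate per unordered leaf pair whose root-to-leaf paths, closed
    by the shortest pixel segment between the termini, form a simple
    contour; origin-closed loops are candidates on their own.  Pairs that
    cannot be closed are dropped silently.
    """
    out: list[CandidateShape2D] = []
    leaves = [r for r in tree.leaves]

    for r in leaves:
        if r.stop_code == StopCode.O and len(r.path) >= _MIN_CONTOUR_PIXELS:
            chain = [tree.root] + list(r.path)
            if _chain_is_simple(chain):
                ras = rasterize(chain)
                if ras is not None:
                    out.append(CandidateShape2D(chain, ras[0], ras[1],
                                                plane_index, leaf_pair=None))

    paths = {r.index: tree.path_from_root(r) for r in leaves}
    n_pairs = 0
    for i, ra in enumerate(leaves):
        for rb in leaves[i + 1:]:
            if n_pairs >= max_pairs:
                break
            pa, pb = paths[ra.index], paths[rb.index]
            k = _common_prefix_len(pa, pb)
            if k == 0 or len(pa) - k < 2 or len(pb) - k < 2:
                continue
            n_pairs += 1
            arm_a = pa[k - 1:]
            arm_b = pb[k - 1:]
            bridge = _bridge(arm_a[-1], arm_b[-1])
            path_set = set(arm_a) | set(arm_b)
            if any(p in path_set for p in bridge):
                continue
            chain = arm_a + bridge + list(reversed(arm_b))[:-1]
            if not _chain_is_simple(chain):
                continue
            ras = rasterize(chain)
            if ras is None:
                continue
            out.append(CandidateShape2D(chain, ras[0], ras[1], plane_index,
                                        leaf_pair=(ra.index, rb.index)))
    return out


# ---------------------------------------------------------------------------
# features

# chain-code turn magnitudes: three equal-width bins over (0, 180] degrees
_CURV_EDGES = (60.0, 120.0)


def plane_intensity_scale(plane: np.ndarray) -> float:
    """Robust per-plane foreground intensity scale.

    Intensity features are expressed relative to this scale, which makes
    them — and hence a trained classifier — invariant to bit depth, gain
    and depth-dependent signal falloff.  The scale is the bright tail of
    the above-background pixels, so it is insensitive to how much of the
    plane the nuclei cover.
    """
    p = np.asarray(plane, dtype=np.float64)
    fg = p[p > 2.0 * np.median(p)]
    if fg.size >= 50:
        scale = float(np.quantile(fg, 0.95))
    else:
        scale = float(np.quantile(p, 0.99))
    return max(scale, 1e-9)


def compute_features(shape: CandidateShape2D, intensity_plane: np.ndarray,
                     response_plane: Optional[np.ndarray] = None,
                     intensity_scale: Optional[float] = None) -> np.ndarray:
    """Populate and return the feature vector of a rasterized shape.

    Intensity statistics come from the two pixel categories (outline vs
    interior); curvature features come from the Freeman chain code of the
    contour: a pixel is convex when the local turn has the same sign as the
    overall traversal orientation, concave when it turns inward.  When the
    ridge response plane is given, two features measure envelope material
    crossing the interior — the signature of a contour spanning more than
    one nucleus (or an internuclear space bounded by walls).
    """
    if not shape.interior_pixels:
        raise ValueError("shape has an empty interior")
    p = np.asarray(intensity_plane, dtype=np.float64)

    if intensity_scale is None:
        intensity_scale = plane_intensity_scale(p)
    scale = intensity_scale

    def stats(pixels):
        vals = np.array([p[y, x] for x, y in pixels])
        return float(vals.mean()), float(vals.std())

    o_mean, o_sd = stats(shape.outline_pixels)
    i_mean, i_sd = stats(shape.interior_pixels)
    ratio = o_mean / (i_mean + 1e-9)
    o_mean, o_sd = o_mean / scale, o_sd / scale
    i_mean, i_sd = i_mean / scale, i_sd / scale

    chain = shape.contour
    n = len(chain)
    # chain-code perimeter with the standard straight/diagonal correction
    # (raw step sums overestimate the length of digitised smooth curves)
    n_straight = n_diag = 0
    for i in range(n):
        dx = abs(chain[(i + 1) % n][0] - chain[i][0])
        dy = abs(chain[(i + 1) % n][1] - chain[i][1])
        if dx + dy == 1:
            n_straight += 1
        elif dx == dy == 1:
            n_diag += 1
        else:
            n_straight += max(dx, dy)  # rare long gap from mask tracing
    perimeter = 0.948 * n_straight + 1.340 * n_diag
    area = float(shape.area)
    circularity = 4.0 * np.pi * area / (perimeter ** 2) if perimeter > 0 else 0.0

    # signed area sign gives the traversal orientation
    shoelace = 0.0
    for i in range(n):
        x1, y1 = chain[i]
        x2, y2 = chain[(i + 1) % n]
        shoelace += x1 * y2 - x2 * y1
    orient = 1.0 if shoelace >= 0 else -1.0

    # chain-code turns, smoothed over a short window so the staircase of a
    # digitised smooth curve does not register as concavities
    k = min(4, max(1, n // 8))
    turns = np.empty(n)
    for i in range(n):
        bx, by = chain[(i + k) % n]
        cx, cy = chain[i]
        ax, ay = chain[(i - k) % n]
        a_in = np.arctan2(cy - ay, cx - ax)
        a_out = np.arctan2(by - cy, bx - cx)
        t = np.degrees(a_out - a_in)
        turns[i] = (t + 180.0) % 360.0 - 180.0

    n_convex = n_concave = 0
    bins = [0, 0, 0]
    straight_tol = 10.0  # degrees
    for t in turns:
        if abs(t) <= straight_tol:
            continue
        if t * orient > 0:
            n_convex += 1
        else:
            n_concave += 1
        mag = abs(t)
        if mag <= _CURV_EDGES[0]:
            bins[0] += 1
        elif mag <= _CURV_EDGES[1]:
            bins[1] += 1
        else:
            bins[2] += 1

    ridge_frac = ridge_peak = 0.0
    if response_plane is not None:
        r = np.asarray(response_plane, dtype=np.float64)
        r_out = np.array([r[y, x] for x, y in shape.outline_pixels])
        r_in = np.array([r[y, x] for x, y in shape.interior_pixels])
        out_mean = float(r_out.mean())
        ridge_frac = float(r_in.mean()) / (out_mean + 1e-9)
        ridge_peak = float(np.quantile(r_in, 0.95)) / \
            (float(np.quantile(r_out, 0.95)) + 1e-9)

    fv = np.array([
        o_mean, o_sd, i_mean, i_sd, ratio,
        area, perimeter, circularity,
        n_convex / n, n_concave / n,
        bins[0] / n, bins[1] / n, bins[2] / n,
        ridge_frac, ridge_peak,
    ])
    shape.features = fv
    return fv


# ---------------------------------------------------------------------------
# Gaussian naive Bayes over shape features


@dataclass
class TrainedClassifier:
    """Per-class, per-feature Gaussian parameters with class priors.

    Variances are floored at ``1e-6 x feature range`` (observed on the
    training data) so near-constant features in small training sets cannot
    produce degenerate likelihoods.  Serialisable to/from TSV so a trained
    classifier can be reused across runs.
    """

    feature_names: list[str]
    classes: list[str]              # ['valid', 'invalid']
    means: np.ndarray               # (n_classes, n_features)
    variances: np.ndarray           # (n_classes, n_features)
    priors: np.ndarray              # (n_classes,)
    training_size: int = 0
    resubstitution_accuracy: float = float("nan")

    def _log_likelihood(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        ll = np.empty((X.shape[0], len(self.classes)))
        for c in range(len(self.classes)):
            var = self.variances[c]
            ll[:, c] = np.sum(
                -0.5 * np.log(2.0 * np.pi * var)
                - 0.5 * (X - self.means[c]) ** 2 / var,
                axis=1,
            ) + np.log(self.priors[c])
        return ll

    def posterior_valid(self, X: np.ndarray) -> np.ndarray:
        """P(valid | features) for each row of X."""
        ll = self._log_likelihood(X)
        ll -= ll.max(axis=1, keepdims=True)
        p = np.exp(ll)
        p /= p.sum(axis=1, keepdims=True)
        return p[:, self.classes.index("valid")]

    def log_odds_valid(self, X: np.ndarray) -> np.ndarray:
        """log P(valid|x) - log P(invalid|x); monotone with the posterior
        but does not saturate, so it ranks confident candidates reliably."""
        ll = self._log_likelihood(X)
        v = self.classes.index("valid")
        i = self.classes.index("invalid")
        return ll[:, v] - ll[:, i]

    # -- persistence ------------------------------------------------------
    def to_tsv(self, path) -> Path:
        path = Path(path)
        rows = []
        for c, cls in enumerate(self.classes):
            for f, name in enumerate(self.feature_names):
                rows.append({"class": cls, "feature": name,
                             "mean": self.means[c, f],
                             "variance": self.variances[c, f],
                             "prior": self.priors[c]})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_tsv(cls, path) -> "TrainedClassifier":
        df = pd.read_csv(path, sep="\t")
        classes = list(dict.fromkeys(df["class"]))
        features = list(dict.fromkeys(df["feature"]))
        means = np.zeros((len(classes), len(features)))
        variances = np.zeros_like(means)
        priors = np.zeros(len(classes))
        for _, row in df.iterrows():
            c = classes.index(row["class"])
            f = features.index(row["feature"])
            means[c, f] = row["mean"]
            variances[c, f] = row["variance"]
            priors[c] = row["prior"]
        return cls(features, classes, means, variances, priors)


def train_classifier(table: pd.DataFrame,
                     feature_names: Sequence[str] = tuple(FEATURE_NAMES)) -> TrainedClassifier:
    """Fit the Gaussian naive Bayes shape classifier.

    ``table`` holds one row per annotated shape: the feature columns plus a
    ``label`` column with values ``valid`` / ``invalid``.  At least two
    examples per class are required.
    """
    feature_names = list(feature_names)
    if "label" not in table.columns:
        raise ValueError("training table needs a 'label' column")
    classes = ["valid", "invalid"]
    counts = table["label"].value_counts()
    for cls in classes:
        if counts.get(cls, 0) < 2:
            raise ValueError(f"need >= 2 training examples of class {cls!r}")
    X = table[feature_names].to_numpy(dtype=np.float64)
    rng_span = X.max(axis=0) - X.min(axis=0)
    # variance floor: proportional to the observed range, but never so
    # small that a near-constant feature can single-handedly veto a shape
    # (a zero-range feature would otherwise produce unbounded log-odds)
    floor = np.maximum(1e-6 * rng_span, (0.01 + 0.05 * rng_span) ** 2)
    means = np.zeros((2, len(feature_names)))
    variances = np.zeros_like(means)
    priors = np.zeros(2)
    for c, cls in enumerate(classes):
        sub = X[(table["label"] == cls).to_numpy()]
        means[c] = sub.mean(axis=0)
        variances[c] = np.maximum(sub.var(axis=0), floor)
        priors[c] = len(sub) / len(X)
    clf = TrainedClassifier(feature_names, classes, means, variances, priors,
                            training_size=len(X))
    post = clf.posterior_valid(X)
    pred = np.where(post > 0.5, "valid", "invalid")
    clf.resubstitution_accuracy = float((pred == table["label"].to_numpy()).mean())
    return clf


def select_winner(candidates: Iterable[CandidateShape2D],
                  classifier: TrainedClassifier,
                  posterior_cut: float = 0.5) -> Optional[CandidateShape2D]:
    """Most probable valid candidate, or None when nothing clears the cut
    (the seed is then recorded with the bookkeeping stop code M)."""
    cut_odds = np.log(posterior_cut / (1.0 - posterior_cut)) \
        if 0 < posterior_cut < 1 else 0.0
    best = None
    for cand in candidates:
        if cand.features is None:
            raise ValueError("candidate features not computed")
        odds = float(classifier.log_odds_valid(cand.features)[0])
        cand.score = odds
        cand.posterior_valid = float(1.0 / (1.0 + np.exp(-min(max(odds, -500), 500))))
        if odds > cut_odds and (best is None or odds > best.score):
            best = cand
    return best


def select_winners(candidates: Iterable[CandidateShape2D],
                   classifier: TrainedClassifier,
                   posterior_cut: float = 0.5,
                   max_winners: int = 3) -> list[CandidateShape2D]:
    """The winner plus mutually disjoint runners-up above the cut.

    A tree rooted near a junction encloses more than one nucleus; its
    candidate set then contains a good shape for each.  The best candidate
    is selected first and further candidates are kept when they clear the
    cut and overlap the already selected ones by less than 30% of their own
    area.
    """
    winner = select_winner(candidates, classifier, posterior_cut)
    if winner is None:
        return []
    kept = [winner]
    pool = sorted((c for c in candidates
                   if c is not winner and c.posterior_valid is not None
                   and c.posterior_valid > posterior_cut),
                  key=lambda c: -c.score)
    for cand in pool:
        if len(kept) >= max_winners:
            break
        taken = set().union(*(k.pixels for k in kept))
        if len(cand.pixels & taken) < 0.3 * len(cand.pixels):
            kept.append(cand)
    return kept


def resolve_plane_conflicts(winners: Sequence[CandidateShape2D]) -> list[CandidateShape2D]:
    """Greedy reconciliation of winners traced independently in one plane.

    Winners are accepted by descending posterior; a winner overlapping the
    accepted set by more than half of its own area is discarded, lesser
    overlaps are trimmed so accepted shapes are pairwise pixel-disjoint.
    """
    order = sorted(winners,
                   key=lambda s: (-s.score, s.plane_index,
                                  s.centroid[1], s.centroid[0]))
    taken: set = set()
    accepted: list[CandidateShape2D] = []
    for cand in order:
        pix = cand.pixels
        overlap = pix & taken
        if len(overlap) > 0.5 * len(pix):
            continue
        if overlap:
            outline = cand.outline_pixels - overlap
            interior = cand.interior_pixels - overlap
            if len(outline) + len(interior) < _MIN_CONTOUR_PIXELS:
                continue
            cand = CandidateShape2D(cand.contour, frozenset(outline),
                                    frozenset(interior), cand.plane_index,
                                    cand.leaf_pair, cand.features,
                                    cand.posterior_valid, cand.score)
        taken |= cand.pixels
        accepted.append(cand)
    return accepted


# ---------------------------------------------------------------------------
# shapes from label masks (training-set construction)


def chain_from_mask(mask: np.ndarray) -> Optional[list[tuple[int, int]]]:
    """Ordered closed pixel chain of the largest boundary of a binary mask."""
    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)
    chain: list[tuple[int, int]] = []
    for ry, rx in np.round(contour).astype(int):
        px = (int(rx), int(ry))
        if not chain or chain[-1] != px:
            chain.append(px)
    if len(chain) > 1 and chain[0] == chain[-1]:
        chain.pop()
    # drop revisited pixels introduced by rounding
    seen = {}
    cleaned: list[tuple[int, int]] = []
    for pxl in chain:
        if pxl in seen:
            continue
        seen[pxl] = True
        cleaned.append(pxl)
    if len(cleaned) < _MIN_CONTOUR_PIXELS:
        return None
    return cleaned


def candidate_from_chain(chain: Sequence[tuple[int, int]],
                         plane_index: int = 0) -> Optional[CandidateShape2D]:
    ras = rasterize(chain)
    if ras is None:
        return None
    return CandidateShape2D(list(chain), ras[0], ras[1], plane_index)


def training_table_from_labels(intensity, labels, rng: np.random.Generator,
                               n_valid: int = 10, n_invalid: int = 10,
                               params=None) -> pd.DataFrame:
    """Mine an annotated training table from a labelled intensity volume.

    The tracer itself proposes the shapes — exactly the population the
    classifier will rank at segmentation time — and the ground-truth
    labels annotate them: a candidate matching a labelled section closely
    (IoU >= 0.75) is a ``valid`` example, a candidate matching nothing
    well (IoU <= 0.4: internuclear space, merged neighbours, fragments)
    is ``invalid``.  This mirrors the interactive workflow in which a user
    labels tracer-proposed shapes before running the method.
    """
    from .io import SegmentationParams
    from .ridge import gaussian_smooth, steerable_ridge_response
    from .seeds import detect_maxima, dog_filter
    from .tracing import build_tree

    if params is None:
        params = SegmentationParams()
    nz = labels.n_planes
    planes = list(range(nz))
    rng.shuffle(planes)

    valid_pool: list[tuple[float, int, int, dict]] = []   # (iou, gt, z, row)
    invalid_pool: list[tuple[float, dict]] = []           # (area, row)
    for z in planes:
        if len(valid_pool) >= 3 * n_valid and len(invalid_pool) >= 5 * n_invalid:
            break
        lp = labels.plane(z)
        # the tracer follows the envelope crest, so the reference section is
        # the labelled solid eroded by the envelope half-thickness
        erode_px = max(1, int(params.ridge_scale))
        gt_masks = {}
        for l in np.unique(lp):
            if l <= 0:
                continue
            m = ndi.binary_erosion(lp == l, iterations=erode_px)
            if int(m.sum()) >= 40:
                gt_masks[int(l)] = frozenset(
                    (int(x), int(y)) for y, x in zip(*np.nonzero(m)))
        if not gt_masks:
            continue
        raw = intensity.plane(z).astype(np.float64)
        work = gaussian_smooth(raw, params.smoothing_sigma) \
            if params.smoothing_sigma > 0 else raw
        response = steerable_ridge_response(work, params.ridge_scale)
        dog = dog_filter(work, params.dog_sigma_small, params.dog_sigma_large)
        seeds = detect_maxima(dog, params.seed_threshold,
                              params.seed_separation, z)
        scale = plane_intensity_scale(raw)
        for seed in seeds[:120]:
            tree = build_tree(response, seed, params)
            if not tree.ridglets:
                continue
            for cand in enumerate_candidates(tree, plane_index=z):
                pix = cand.pixels
                best_iou, best_gt = 0.0, None
                for l, m in gt_masks.items():
                    inter = len(pix & m)
                    if inter == 0:
                        continue
                    iou = inter / (len(pix) + len(m) - inter)
                    if iou > best_iou:
                        best_iou, best_gt = iou, l
                fv = compute_features(cand, raw, response.response,
                                      intensity_scale=scale)
                row = dict(zip(FEATURE_NAMES, fv))
                if best_iou >= 0.7:
                    row["label"] = "valid"
                    valid_pool.append((best_iou, best_gt, z, row))
                elif best_iou <= 0.45:
                    row["label"] = "invalid"
                    invalid_pool.append((float(cand.area), row))
                # 0.45 < IoU < 0.7 is ambiguous and never annotated

    # valid: round-robin across nuclei (best section per nucleus first) so
    # crowded and easy nuclei are both represented
    valid_pool.sort(key=lambda t: (-t[0], t[2], t[1]))
    per_gt: dict = {}
    for iou, gt_id, z, row in valid_pool:
        if (gt_id, z) not in {(g, zz) for g, lst in per_gt.items()
                              for (zz, _) in lst}:
            per_gt.setdefault(gt_id, []).append((z, row))
    valid_rows = []
    rank = 0
    while len(valid_rows) < n_valid:
        added = False
        for gt_id in sorted(per_gt):
            lst = per_gt[gt_id]
            if rank < len(lst):
                valid_rows.append(lst[rank][1])
                added = True
                if len(valid_rows) >= n_valid:
                    break
        if not added:
            break
        rank += 1

    # invalid: spread across the area spectrum so fragments, internuclear
    # gaps and merged-pair contours are all represented
    invalid_pool.sort(key=lambda t: t[0])
    invalid_rows = []
    if invalid_pool:
        idx = np.unique(np.linspace(0, len(invalid_pool) - 1,
                                    num=min(n_invalid, len(invalid_pool))).astype(int))
        invalid_rows = [invalid_pool[i][1] for i in idx]

    if len(valid_rows) < 2 or len(invalid_rows) < 2:
        raise ValueError(
            f"could not mine enough training shapes "
            f"({len(valid_rows)} valid, {len(invalid_rows)} invalid); "
            "check seed_threshold and calibration")
    return pd.DataFrame(valid_rows + invalid_rows)
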