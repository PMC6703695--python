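# Methods

## The problem and the signal model

Nuclei in dense tissue and 3D culture are hard to separate when only the
nuclear content (DNA stains) is imaged: touching nuclei share a blurred
boundary and textured chromatin confounds watershed-style methods.  The
nuclear envelope, by contrast, images as a thin bright shell around each
nucleus that stays visible exactly where nuclei touch.  `envseg` segments
3D stacks of an envelope-labelled channel by treating each 2D plane as a
field of bright ridges (the shell cross-sections), closing candidate
nucleus contours from traced ridges, and assembling the accepted 2D areas
into 3D instances.

## Pipeline

Per plane, in order:

1. **Optional smoothing** (`smoothing_sigma`, px; 0 = off).  Used only for
   very noisy data; all other stages run on the unsmoothed plane by
   default.
2. **Ridge enhancement** (`ridge_scale`, px, set near the envelope
   half-thickness).  Implemented as the rectified most-negative eigenvalue
   of the scale-normalised Hessian of Gaussian; the ridge tangent comes
   from the complementary eigenvector.  This is the standard second-order
   realisation of a steerable ridge detector; it is offset-invariant by
   construction (the plane mean is removed first) and equivariant under
   grid rotations.
3. **Seeding.**  A Difference-of-Gaussian band-pass
   (`dog_sigma_small` < `dog_sigma_large`) of the intensity plane followed
   by strict 8-neighbourhood maxima above `seed_threshold` (the one
   variable that must be rescaled when bit depth changes).  Plateaus
   contribute their lexicographically smallest pixel so detection is fully
   deterministic.  Maxima closer than `2 * dog_sigma_small` are thinned by
   descending score, and at most 300 seeds per plane are traced (ordered
   by score), which bounds the cost on noisy planes without affecting
   clean ones.
4. **Tree-structured ridge tracing.**  From each seed (snapped to the
   strongest response pixel in a 5x5 window) two ridge polylines
   ("ridglets") grow in roughly opposite directions; children spawn where
   an unclaimed ridge of comparable strength leaves an existing path
   (up to three branch generations).  Every step moves to the brightest
   unclaimed 8-neighbour, with two refinements that matter in crowded
   fields: reversal steps are forbidden, and when several neighbours are
   within 80% of the best response the straightest continuation wins.
   The latter carries the trace across shell junctions of touching nuclei
   instead of turning onto the shared wall; without it the recoverable
   fraction of nucleus sections in dense scenes drops from ~0.85 to ~0.5.
   A ridglet stops with exactly one code: cumulative length beyond
   `max_trace_distance` (D); response below
   `intensity_drop_fraction x root response` (I — relative to the root, so
   tracing is invariant to global intensity scaling); cumulative turning
   beyond `sharp_turn_max_angle` over a 5-step window (T); loop closure at
   the origin (O); re-entry into its own path (L), its tree (C), a parent
   crossing point (CP) or the path to its parent (P).  Seeds whose tree
   yields no accepted shape are recorded post hoc as missed (M).  Every
   step claims a fresh pixel from a finite set, so tracing always halts.
5. **Candidate shapes.**  One candidate per closable leaf pair: the two
   root-to-leaf paths plus the shortest pixel segment between the termini,
   kept only if the closed chain is simple (pairwise distinct pixels, no
   proper edge crossings); an origin-closed loop is a candidate by itself.
   The interior is a parity fill of the 8-connected chain (digital Jordan
   complement).  Area is counted as interior plus outline pixels
   everywhere in the package.
6. **Features and ranking.**  Each candidate is described by intensity
   statistics on its two pixel categories (outline vs interior), size and
   shape scalars (area, chain-code-corrected perimeter, circularity),
   chain-code curvature fractions (convex / concave relative to the
   traversal orientation, computed over a 4-pixel secant window so the
   staircase of a digitised smooth curve does not register as curvature,
   plus a three-bin histogram of turn magnitudes over (0, 60], (60, 120],
   (120, 180] degrees), and two ridge-response features — the mean and
   upper-quantile response inside the contour relative to the outline —
   which flag envelope material crossing the interior (the signature of a
   contour spanning two nuclei or an internuclear space).  Intensity
   statistics are expressed relative to a robust per-plane foreground
   scale (the 95th percentile of pixels above twice the plane median),
   which makes the features — and therefore a trained classifier —
   invariant to bit depth, detector gain and depth-dependent falloff.
   A Gaussian naive Bayes classifier trained on annotated examples ranks
   candidates; ranking uses the log-odds (monotone with the posterior but
   not saturated), acceptance uses `posterior_cut` (default 0.5).  Each
   tree contributes its winner plus any mutually disjoint runners-up above
   the cut — a tree rooted near a junction legitimately sees two nuclei.
   Winners from all seeds of a plane are reconciled greedily by descending
   score: heavy overlaps (> 50% of a shape's own area) are discarded,
   light ones trimmed, so accepted areas are pairwise disjoint.
7. **3D linkage.**  Accepted areas become nodes of a directed inter-plane
   graph (edges point to higher planes).  An edge requires a plane gap of
   at most `max_jump`, centroid distance at most
   `max_intercentroid_distance` (um), and an overlap fraction of at least
   `overlap_threshold` (by default the larger of the two per-area
   fractions; a `min` dialect is selectable).  An area already linked from
   a nearer plane receives no longer-jump edges.  Ambiguities (several
   partners in one plane) are resolved by Jaccard index: if the union of
   the competitors matches the area better than any single competitor the
   area is recognised as a merged section and split between them by
   nearest-partner pixel assignment; otherwise only the best edge
   survives.  Volumes are then labelled along edges in decreasing Jaccard
   order with union-find semantics (a chain whose middle edge is processed
   last must still end up as one instance).  Planes jumped over are filled
   with a shape average of the flanking areas.  Volumes below `min_volume`
   are discarded; volumes above `max_volume` are kept and flagged for
   splitting.
8. **Refinement.**  A volume-level second pass rejoins stacked runs whose
   facing terminal areas satisfy the ordinary link criteria (evaluated on
   envelope-expanded areas, since chains usually break where a section came
   out trimmed).  Then two axial profiles split under-segmented volumes:
   the intensity ratio IR(z) (centre mean over rim mean; the centre is the
   inner half of the equivalent radius) peaks above 1 at the interface of
   two nuclei stacked in z, and the volume is cut at the most prominent
   such peak when it exceeds `ir_prominence` (1.5x) times its base — the
   interface plane belongs to neither half.  The centroid displacement
   CD(z) (lateral shift of consecutive plane centroids, um) spikes at the
   junction of two laterally offset nuclei; a cut requires the peak to
   exceed `cd_prominence` (3x) times the volume's median drift *and* half
   the inter-centroid gate, and the two halves' median centroids must
   actually be offset by that much (a coaxial pair of halves indicates
   segmentation jitter, not a junction).  Splits iterate (binary cuts per
   pass) until stable, so triple stacks resolve in two passes.  Optional
   morphological smoothing (closing-then-opening with an anisotropy-aware
   element, plus capping of the axial tips) removes single-plane spikes;
   it never changes a volume by more than 20%.  Finally every volume is
   dilated laterally by the envelope half-thickness: the traced contour
   follows the envelope mid-line, while the nucleus extends to the
   envelope's outer edge; contested pixels go to neither volume, keeping
   instances disjoint.

Planes are processed independently (any worker count gives byte-identical
output) and time-series frames sequentially, so memory stays bounded by
one frame plus per-plane buffers; volumes backed by TIFF files are read
plane by plane.

## Training the classifier

`training_table_from_labels` mines annotated examples the way a user of
the interactive tool would: the tracer proposes candidate shapes on a
labelled volume, and candidates matching a ground-truth section closely
(IoU >= 0.7 against the section eroded by the envelope half-thickness,
since the tracer follows the envelope mid-line) become `valid` examples —
round-robin across nuclei so crowded and easy nuclei are both represented —
while candidates matching nothing well (IoU <= 0.45) become `invalid`
examples, sampled across the area spectrum so fragments, internuclear
gaps and merged-pair contours all appear.  Twenty shapes (10 + 10) suffice
for the synthetic study scenes.  The classifier serialises to TSV and can
be reused across images, bit depths and noise levels.

## The synthetic scene generator

Scenes are rotated tri-axial ellipsoids rendered as a bright shell (the
outermost `shell_thickness_um` of the solid; ray-exact signed distance, no
anti-aliasing) around a dimmer interior on a darker background, with
optional multiplicative axial falloff, additive Gaussian noise (clipped to
the bit range), z-resampling (linear for intensity, nearest for labels)
and linear bit-depth reduction.  Crowding modes: `sparse` (guaranteed
gaps), `touching` (60% of nuclei attach to a previous nucleus at contact
distance, mostly laterally), `stacked` (pairs stacked along z) and
`offset-fused` (pairs offset laterally and nearly stacked axially).
Ground-truth labels mark the full solids and are exact by construction;
where two solids share voxels the more interior nucleus claims them.

Default study conditions (chosen once): 50 nuclei, 80x80x30 um field at
0.5x0.5x1.0 um voxels, nucleus radii 3.7-5.0 um with axis ratios 1.0-1.5,
1.0 um shell, 12-bit intensities 2000/400/100 (shell/interior/background).
The matching segmentation variables are seed_threshold 60, min_volume 100
um^3, max_volume 2000 um^3, max_jump 3, everything else at the package
defaults.  What the generator does **not** emulate: optical blurring (no
PSF; an optional Gaussian stands in), chromatic or stage drift, envelope
invaginations, mitotic envelope breakdown, and debris.  Passing tests on
these scenes therefore demonstrate the geometric and statistical machinery
— ridge closure in dense packings, classifier-based rejection of
internuclear space, 3D repair of 2D errors — not robustness to every
confound of real microscopy.

## Numerical choices and degenerate inputs

* Tie-breaks are fixed everywhere: clockwise neighbour scan from the
  previous step direction in the tracer, lexicographic pixel order in seed
  plateaus, `(plane, shape id)` order for equal Jaccard indices.  The
  whole pipeline is deterministic for fixed inputs.
* Gaussian kernels are truncated at six standard deviations so smoothing
  matches the ideal kernel to 1e-6.
* The naive Bayes variance floor is `max(1e-6 x range, (0.01 + 0.05 x
  range)^2)` per feature: proportional to the observed training range but
  never so small that a near-constant feature in a 20-shape training set
  can single-handedly veto a shape with unbounded log-odds.
* A constant plane yields no seeds (a plateau without an exterior is not a
  maximum) and no ridge response; a seed on zero response yields an empty
  tree; an empty candidate list is valid everywhere downstream.
* Label images are written as 16-bit TIFF (overflow beyond 65535 instances
  raises); missing calibration metadata falls back to 1 um isotropic with
  a warning.

## Known limitations

* Single-scale ridge detection: envelopes much thicker or thinner than
  `ridge_scale` trace poorly; no multi-scale search is attempted.
* The greedy Jaccard-ordered linkage is not a global optimiser; a
  pathological ladder of ambiguities could be resolved suboptimally.
* Nuclei spanning fewer than two planes cannot be linked and are usually
  removed by the volume constraint.
* The classifier is naive Bayes by design (fast, trainable from 20
  examples); strongly correlated features make its posteriors
  overconfident, which is why ranking uses log-odds and acceptance a
  simple cut.
* Very coarse z sampling (about 3 slices per nucleus) degrades accuracy
  only mildly on the synthetic scenes — the gap-filling and volume-merge
  steps compensate — so the method's real-data sensitivity to z-step is
  likely underestimated here.
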