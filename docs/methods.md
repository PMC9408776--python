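# Methods

This note documents the models and conventions behind `ergokit`: how raw
keypoints become posture codes, which choices were genuinely open and how
they were settled, and what the synthetic generators do and do not emulate.

## Coordinate and skeleton conventions

Coordinates are camera-centered millimetres with the image convention —
x right, y down, z toward the scene — so the world up direction is
(0, −1, 0). 2D sources carry pixels in x, y with z absent; operations that
require depth raise a dimensionality error rather than guessing.

Three skeleton dialects ship as versioned JSON configs:

* **coco17** — the standard 17-landmark COCO ordering.
* **dywhse25** — coco17 plus, per side, a thumb tip, a hand (back-of-hand)
  point and a foot (toe) point, plus pelvis and thorax: 25 joints. The hand
  and foot points can be synthesized from richer source data as the
  thumb–ring-finger and big-toe–little-toe midpoints, which is how motion-
  capture dialects with full digit tips are reconciled with this one.
* **h36m17** — a Human3.6M-style 17-joint evaluation set (pelvis, thorax,
  nose, and per side hip/knee/ankle/foot/shoulder/elbow/wrist). Its
  intersection with dywhse25 is exactly 17 joints, the cross-dataset
  evaluation subset.

No authoritative enumeration of the extended 25-joint list exists in print,
so the list here is a documented convention, kept in a config file and
swappable without code changes. Keypoint visibility is a trichotomy:
visible, invisible-but-identifiable (annotated through occlusion), and
absent (no coordinates at all). COCO's 2/1/0 triplet flags map onto these.

## Angle measurement

All posture angles reduce to the three-point vertex angle
θ = arccos(B&#8407;A·B&#8407;C / ‖B&#8407;A‖‖B&#8407;C‖), in degrees, with the
cosine argument clamped to [−1, 1] so round-off near collinear
configurations cannot produce a domain error. Arm vectors shorter than
1e-6 mm make the angle undefined (an explicit error naming the segment).

The three-point primitive is unsigned; flexion vs. extension is recovered
from the sign of the segment's sagittal component. The body frame is built
from the data itself: trunk-up = pelvis→thorax, left = right-hip→left-hip,
forward = left x trunk-up. Trunk flexion is measured against the world
vertical with the horizontal forward direction from the hip line; neck and
upper-arm flexion are measured against the trunk axis with the
trunk-relative forward. This is equivalent to reading the sign from a
side-view projection but needs no intermediate 2D frame.

Wrist kinematics use a forearm frame at the wrist: forearm axis f̂
(elbow→wrist), lateral axis = the elbow hinge axis (f̂ x upper-arm), and
neutral palm normal completing the triad. Flexion is the hand direction's
angle in the (f̂, palm-normal) plane, deviation its arcsine component along
the lateral axis. The frame is undefined at a fully extended elbow (the
hinge axis has no unique direction), in which case wrist items are
uncodable for that frame — honest degradation rather than a guess.

**Wrist twist.** The palm plane is spanned by the wrist, thumb and hand
keypoints; the twist measurement is the angle between that plane's normal
and the forearm axis, folded into [0, 90]°. Geometrically the folded angle
can never drop below 90° minus the total wrist bend, so a *straight* hand
always measures 90° — that is the neutral value, and twist "increases" as
the measurement falls. The twist posture code is therefore 1 (mid-range) at
or above the 45° fold threshold and 2 (near end-range) below it. The
threshold is configuration, not anatomy: no published mapping exists from
this plane construction to the worksheet's "twisted" ranges, so 45° (the
midpoint of the reachable fold range) is the default.

Side views are orthographic — right view (x, y, z) → (z, y), left view
mirrors the horizontal axis — since single-camera deployments provide no
intrinsics for a perspective model.

## RULA scoring

Posture bins follow the McAtamney–Corlett worksheet, implemented as
half-open intervals [lo, hi):

| part | bins (degrees → code) |
|---|---|
| upper arm | [−20, 20)→1; [20, 45) or < −20→2; [45, 90)→3; ≥ 90→4; +1 shoulder raised, +1 abducted, −1 supported |
| lower arm | [60, 100)→1 else 2; +1 across midline / out to side |
| wrist | \|flex\| ≤ 1°→1; ≤ 15°→2; > 15°→3; +1 if deviated (\|dev\| > 10° or flagged) |
| wrist twist | folded angle ≥ 45°→1 else 2 |
| neck | < −1°→4 (extension); [0, 10)→1; [10, 20)→2; ≥ 20→3; +1 twist, +1 side-bend |
| trunk | \|flex\| ≤ 3°→1 (supported upright); < 20→2 (incl. extension); [20, 60)→3; ≥ 60→4; +1 twist, +1 side-bend |
| legs | supported and balanced→1 else 2 |

The 1°/3° neutral tolerances make the "exactly neutral" codes reachable by
measured (not just nominal) angles; both are configurable. Tables A, B and
C are embedded verbatim from the published worksheet; score C = A + muscle
use + force/load (arm/wrist group), score D likewise for the neck/trunk/leg
group, with Table C inputs capped at its last row/column (the "8+" rule).
Grand score 1–2 → action level 1, 3–4 → 2, 5–6 → 3, 7 → 4. The full code
lattice is verified monotone: raising any single code or manual input never
lowers the grand score.

Adjustment items that cannot be read from keypoints alone (shoulder raised,
arm supported, trunk twist, …) are explicit boolean flags, and muscle-use /
force-load points are manual inputs defaulting to 0 — they describe load
and repetition, which no pose frame contains.

**Sides.** Left and right are scored independently; the headline result is
the side with the worse grand score (conservative screening). Both sides
are retained in every report row.

**Occlusion fallback.** Field video often clips the lower body. When leg
joints are absent, carry confidence below 0.3, or a thigh/shank length
falls outside [1/1.3, 1.3] x the sequence median (all configurable), the
frame is scored upper-body-only: legs are assumed supported (code 1) and
the flag is set, so two frames identical above the hips score identically.
Otherwise legs code 1 when both ankle heights agree within 100 mm, else 2.
The plausibility test is necessarily a convention — no published rule
exists for "incorrect leg posture" detection — hence every number sits in
config.

Sequences are subsampled before assessment (default 1 frame/s, stride =
round(fps / sample_fps)), matching how such systems sample stills for
review.

## Evaluation metrics

MPJPE is the mean Euclidean per-joint error over the evaluation subset.
PA-MPJPE first superimposes the estimate on the ground truth with a
similarity Procrustes transform — rotation with det +1 (reflections
excluded), translation, and uniform scale, computed in closed form via the
SVD of the cross-covariance (Umeyama's method). Including scale and
excluding reflections matches standard Protocol-1 practice; alignment
requires ≥ 3 non-collinear reference joints and a non-degenerate estimate,
otherwise an explicit alignment error is raised. Optimality is
cross-checked in tests against a direct numerical optimizer over
(rotation vector, translation, log scale).

Cohen's kappa is computed from exact label matches: p_o the observed match
fraction, p_e the product-of-marginals chance agreement. p_e = 1 (all mass
in one agreeing cell) makes kappa undefined, raised as such. Strength
labels use half-open bins — (−∞, 0] Poor, (0, 0.2] Slight, (0.2, 0.4]
Fair, (0.4, 0.6] Moderate, (0.6, 0.8] Substantial, (0.8, 1] Almost
perfect — which keeps the conventional printed boundaries while making the
function total on (0, 0.01), a gap the printed table leaves unassigned.
Agreement between a system and experts is computed per body part on the
part's posture codes.

## Annotation aggregation

The consensus joint is the componentwise median over the annotators who
tagged it (absent tags excluded). The median uses the lower order statistic
k = ⌈n/2⌉ for even n, so the output is always an observed coordinate; with
2k+1 annotators of whom ≤ k are corrupted arbitrarily, the consensus stays
within the clean tags' range per axis. A mean is available by config for
comparison but is not the default precisely because one gross mis-entry
drags it.

The recommended bounding box defaults to the minimal axis-aligned box over
the aggregated joints, expanded 5% per side; whether the original
dataset-builder derived its box from joints or from the annotators' own
boxes is not documented, so the alternative (per-coordinate median of
annotator boxes) sits behind `bbox_mode: boxes`. Confirm freezes a record
(after optional drag-style joint moves), drop excludes it; exports contain
exactly the confirmed records, and re-deciding a decided record is an
error.

## Synthetic generators

`generate_pose` builds a forward-kinematics skeleton in the 25-joint
dialect from per-part target angles, using a proportional 50th-percentile
adult limb model (trunk 450 mm, upper arm 280 mm, forearm 250 mm, thigh
420 mm, shank 400 mm, …; all in config). Arms are posed symmetrically in
the sagittal plane; the wrist chain is constructed in the same forearm
frame the measurement code uses, so measured angles round-trip to the
recipe targets to better than 1e-6° (verified over 200 random recipes).
The recipe's wrist-twist field is expressed directly on the measurement's
scale (neutral = 90°), and targets below 90° − bend are rejected as
infeasible rather than silently clamped. The seed shifts the skeleton
rigidly (angles unchanged) so distinct seeds give distinct coordinates.

`perturb_pose` adds isotropic Gaussian jitter (per-joint error then follows
a chi distribution with k = 3; its mean σ·2√(2/π) is verified empirically)
and can mark joints absent to exercise the occlusion fallback.
`simulate_annotators` projects the frame to the image plane and adds tag
noise plus, at a configurable rate, 200–500 px gross mis-entries.
`simulate_ratings` has rater B copy rater A with the target probability and
resample uniformly otherwise. All draw from named substreams of one seed.

**What passing synthetic tests does and does not show.** The generators
produce an upright, camera-facing subject with sagittal-plane arm motion,
exact limb proportions, and noise that is Gaussian, isotropic and
independent across joints. Real estimator error is none of those things —
it is pose-dependent, correlated along limbs, and heavy-tailed under
occlusion — and real workers twist out of the sagittal plane, where the
signed-angle decomposition inherits error from the body-frame estimate.
Synthetic recovery therefore validates the *scoring logic* (bins, tables,
fallbacks, statistics) end to end; it does not certify field accuracy of
any upstream pose estimator.

## Numerical choices and degenerate inputs

* cos arguments clamped to [−1, 1]; angle tolerance 1e-6 mm on arm lengths.
* Procrustes degeneracy: second singular value of the centered ground
  truth ≤ 1e-9 x the largest ⇒ collinear ⇒ error; estimate variance
  ≤ 1e-12 ⇒ error.
* Elbow fully extended ⇒ wrist items uncodable (no unique hinge axis).
* Table C inputs capped at 8 (rows) and 7 (columns).
* An unassessable frame (mandatory upper-limb part uncodable on both
  sides) is reported with its reason, never scored partially.
* Problem sizes in the test suite (200-recipe round-trips, 1000-instance
  metric sweeps, ~10,000-joint noise checks, the exhaustive 20,736-point
  code lattice) were chosen as the smallest sizes at which the checked
  statistics are stable.

## Known limitations

* Wrist flexion direction (flexion vs. extension) is coded by magnitude —
  the worksheet bins are symmetric — so the sign convention of the palm
  normal only matters for the deviation flag.
* The trunk "supported upright" distinction for seated work cannot be
  inferred from keypoints; it is a flag.
* Adjustment items (abduction, shoulder raise, midline crossing) are flags
  rather than derived quantities; deriving them robustly needs a torso
  orientation model beyond the scope of this toolkit.
* The action-level mapping and tables are RULA-specific; other worksheets
  (REBA, OWAS) share the architecture but are not implemented.
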