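# ergokit

Automatic ergonomic risk assessment of working postures from 3D human pose
keypoints.

Work-related musculoskeletal disorders (WMSDs) are routinely assessed with
observational worksheets such as RULA (Rapid Upper Limb Assessment), in
which an ergonomist codes the posture of the upper arm, lower arm, wrist,
neck, trunk and legs from video stills, combines the codes through lookup
tables, and reads off an action level describing how urgently the posture
needs intervention. Doing this by hand for hours of video is slow; modern
3D human pose estimators make it automatable. `ergokit` is the assessment
side of such a system: it consumes per-frame 3D keypoints from *any*
upstream pose estimator and turns them into joint angles, RULA posture
codes, table scores, grand scores and action levels — together with the
evaluation statistics used to validate such pipelines and the
multi-annotator aggregation math used to build their training data.

It is aimed at occupational-biomechanics researchers and engineers building
or validating camera-based WMSD screening tools.

## What it computes

**Joint angles.** Every posture item reduces to the three-point angle at a
vertex joint B with arms toward A and C:

&theta; = arccos( (B&#8407;A · B&#8407;C) / (‖B&#8407;A‖ ‖B&#8407;C‖) )

reported in degrees. Wrist twist uses the plane through the wrist, thumb
and hand keypoints: the folded angle between that plane's normal and the
forearm axis (elbow→wrist).

**RULA scoring.** Angles and adjustment flags map to per-part codes
(upper arm 1–6, lower arm 1–3, wrist 1–4 with a twist code 1–2, neck 1–6,
trunk 1–6, legs 1–2), through the published Tables A/B/C with manual
muscle-use and force/load points, to a grand score 1–7 and action level
1–4. Both body sides are scored; the worse side is the headline. When the
lower body is occluded or its estimated leg segments are anatomically
implausible, the scorer assumes the legs and feet are supported and flags
the frame `upper_body_only`.

**Evaluation statistics.** MPJPE (mean per-joint position error, mm),
PA-MPJPE (the same after similarity-Procrustes alignment of the estimate),
and Cohen's kappa &kappa; = (p&#8320; − p&#8324;)/(1 − p&#8324;) with the
conventional strength-of-agreement labels, for comparing automatic posture
codes against expert ratings.

**Dataset-builder math.** Componentwise-median fusion of multi-annotator
keypoint tags (robust to gross mis-entries), minimal-region bounding boxes,
trusted-annotator filtering, and the confirm/drop inspection workflow with
COCO-format export.

**Synthetic data.** A forward-kinematics generator producing 25-joint
skeletons whose measured angles equal their recipe targets to better than
1e-6°, plus estimator-noise, annotator and rating simulators — so the whole
pipeline is testable without any image data.

## Worked example

```python
from ergokit import assess_frame, ManualInputs
from ergokit.synthetic import PoseRecipe, generate_pose

frame = generate_pose(PoseRecipe(
    upper_arm_flexion=95, elbow_flexion=30, wrist_flexion=20,
    neck_flexion=25, trunk_flexion=30, seed=42))
result = assess_frame(frame, manual=ManualInputs(force_load_a=1, force_load_b=1))
h = result.headline
s = h.scores
print(f"side={result.headline_side} upper_arm={s.upper_arm} lower_arm={s.lower_arm} "
      f"wrist={s.wrist} wrist_twist={s.wrist_twist} neck={s.neck} trunk={s.trunk} legs={s.legs}")
print(f"table_a={h.table_a} table_b={h.table_b} score_c={h.score_c} score_d={h.score_d}")
print(f"grand_score={h.grand_score} action_level={h.action_level} upper_body_only={result.upper_body_only}")
```

prints

```
side=right upper_arm=4 lower_arm=2 wrist=3 wrist_twist=1 neck=3 trunk=3 legs=1
table_a=4 table_b=4 score_c=5 score_d=5
grand_score=6 action_level=3 upper_body_only=False
```

Reading it: raising the arm past 90° codes the upper arm 4; an elbow bent
only 30° leaves the forearm outside its comfortable 60–100° band (code 2);
20° of wrist bend codes 3; the forward-leaning neck and trunk each code 3.
Table A combines the arm/wrist group to 4, Table B the neck/trunk/legs
group to 4; one force/load point on each side gives C = D = 5, Table C
grand score 6, action level 3 — "investigation and changes are required
soon".

The same pipeline runs from the shell:

```bash
ergokit simulate pose --n-frames 10 --out poses.json
ergokit assess --input poses.json --sort action_level --out report.csv
ergokit agreement --a expert.csv --b system.csv
```

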