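# hotspot-overlap

Do the high-uptake sub-volumes (*hotspots*) of a pre-radiotherapy
FDG-PET/CT predict where a head-and-neck tumor will locally relapse — and
how much does the answer depend on patient positioning and on the image
registration method used to compare the two scans?

This package implements the full analysis chain for that question and
exercises it end-to-end on synthetic paired PET/CT phantom cohorts with
exact ground truth:

1. **Phantom simulation** (`hotspot_overlap.phantom`) — paired
   baseline/recurrence sessions with a two-compartment lesion (high-uptake
   core in a lower-uptake rim), controllable rigid repositioning error,
   smooth non-rigid deformation, recurrence offset and noise.  Cases come
   in two regimes: treatment position (TP: immobilized, ≤1.5 mm/°, no
   deformation) and non-treatment position (NTP: 5–8 mm/° dominant-axis
   error plus 3–6 mm deformation).
2. **Segmentation** (`hotspot_overlap.segmentation`) — relative-SUVmax
   sub-volumes A_x (x = 30…90 % on the baseline scan) and R_40, R_70 (on
   the recurrence scan), plus SUVmax, SUVmean, MTV = vol(A_40) and
   TLG = SUVmean × MTV.
3. **Registration** (`hotspot_overlap.registration`) — rigid (RR) and
   free-form elastic (ER) CT-to-CT registration (SimpleITK; mean-squares
   metric, multi-resolution, deterministic), returning the map that pulls
   recurrence masks onto the baseline grid.
4. **Overlap indices** (`hotspot_overlap.overlap`) — for every (A_x, R_x)
   pair: Dice 2|A∩R|/(|A|+|R|), Jaccard |A∩R|/|A∪R|, overlap fraction
   OF = |A∩R|/min(|A|,|R|), and the directed fractions |A∩R|/|A| and
   |A∩R|/|R|; agreement bands (poor/fair/moderate/good/very good) at
   0.2-wide cutpoints.
5. **Cohort statistics** (`hotspot_overlap.stats`) — subgroup summaries
   (TP-RR, TP-ER, NTP-RR, NTP-ER), paired Wilcoxon signed-rank tests for
   ER vs RR, Mann-Whitney U for TP vs NTP and for MTV/TLG outcome
   contrasts; raw p-values, significance at p < 0.05.
6. **Pipeline** (`hotspot_overlap.pipeline`) — one reproducible study run
   from a single `StudyConfig` (default: 15 TP + 28 NTP relapse cases,
   7 × 2 thresholds, both methods → 387 VOIs on 86 scans, 6,020 index
   values), writing NIfTI/CSV/JSON artifacts.

The model and its assumptions, parameter defaults, and what phantom
results do and do not show about clinical data are documented in
[docs/methods.md](docs/methods.md).

## Worked example

```python
import numpy as np
from hotspot_overlap import (BoundingBox, PhantomConfig, StudyConfig,
                             generate_case, compute_overlap)
from hotspot_overlap.registration import register_rigid, apply_transform
from hotspot_overlap.segmentation import delineate_all

# one NTP-style case: 5° rotation + 5 mm translation between sessions
case = generate_case(PhantomConfig(rigid_error=(5, 0, 0, 0, 5, 0), seed=22))

# segment baseline and recurrence sub-volumes
region = BoundingBox.around(case.config.lesion_center_mm, (25.0,) * 3)
masks = delineate_all(case.pet_a, case.pet_r, region, region, StudyConfig())

# estimate the session mapping from the CT pair and pull R_40 onto PET_A
focus = BoundingBox.around(case.config.lesion_center_mm, (40.0,) * 3)
rigid = register_rigid(case.ct_a, case.ct_r, focus)
r40_on_a = apply_transform(masks["R_40"], rigid, case.pet_a)

print(compute_overlap(masks["A_40"], r40_on_a).indices())
```

prints

```
{'dice': 0.3793677204658902, 'jaccard': 0.23408624229979466, 'of': 1.0,
 'common_over_a': 0.23408624229979466, 'common_over_r': 1.0}
```

— once the 5 mm / 5° session error is removed by registration, the
recurrence sub-volume falls entirely inside the baseline 40 % sub-volume
(OF = A∩R/R = 1.0), while Dice and A∩R/A stay low simply because the
baseline volume is much larger than the recurrence — exactly why the
overlap fraction, not Dice, is the index this analysis reads.

## Analysis scripts

`analysis/` contains the numbered study drivers; each writes its tables
under `results/`:

| script | what it does |
|---|---|
| `01_simulate_cohort.py` | generate the default 43-case cohort, summarize its geometry/motion |
| `02_run_overlap_study.py` | full study: segment, register (RR+ER), overlap, statistics |
| `03_registration_accuracy.py` | rigid and elastic recovery against known ground truth |
| `04_compare_groups.py` | subgroup tables, ER-vs-RR and TP-vs-NTP tests |
| `05_uptake_prognosis.py` | MTV/TLG contrast between controlled and relapsed synthetic groups |

Representative output (scripts 03 and 04):

```
rigid recovery of (5 mm, 5 deg) misalignment:
  rotation error   0.063 deg (max of 3)
  translation error 0.131 mm (max of 3)
elastic recovery of 4 mm sinusoidal deformation (lesion region):
  mean residual 0.96 mm (max of 3; unregistered 2.77 mm)

ER vs RR, overlap fraction OF(A_X, R_40), x = 30-50%:
  ER-vs-RR within NTP  A_30: ER 0.93 vs RR 0.85  p=0.005*
  ER-vs-RR within NTP  A_40: ER 0.66 vs RR 0.51  p=0.001*
  ER-vs-RR within NTP  A_50: ER 0.60 vs RR 0.37  p=0.000*
TP vs NTP under RR, overlap fraction OF(A_X, R_40):
  A_40: TP 0.72 vs NTP 0.51  p=0.039
  A_50: TP 0.70 vs NTP 0.37  p=0.005
```

Off treatment position, elastic registration recovers most of the
deformation the rigid method cannot, so its overlap fractions are
significantly higher; in treatment position the two methods are
equivalent.  Under rigid registration, treatment-position cases overlap
better than non-treatment-position cases.  Both directions mirror the
clinical motivation for acquiring follow-up PET/CT in the radiotherapy
position.

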