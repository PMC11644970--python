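# mobgait

Community-mobility and gait analysis for older-adult cohorts from raw GPS
trajectories and trunk-accelerometer streams, with non-parametric group
statistics and faller/non-faller classification. A synthetic cohort
generator with known ground truth makes every stage testable end to end
without access to clinical data.

## Pipeline

```
GPS CSV (1 fix/min)  ──► stay detection (100 m / 15 min) ──► DBSCAN places ──► home
                                    │                                           │
                                    └──► 8 life-space metrics ◄─────────────────┘
accel CSV (50 Hz)    ──► 0.5–20 Hz band-pass ──► step peaks (≥0.5, fs/2 apart)
                                    └──► walking bouts (≥30 peaks, GPS < 5 km/h)
                                             └──► 16 gait metrics
                    cohort table ──► Shapiro–Wilk + Mann–Whitney comparison
                                ──► RF / SVM / KNN under gps | accel | combined
```

Modules (under `src/mobgait/`):

| module         | role |
|----------------|------|
| `geo`          | WGS84 geodesic distance (Vincenty) and local planar projection |
| `stays`        | trajectory I/O (CSV/GPX), stay detection, DBSCAN clustering, home detection |
| `lifespace`    | activity space (MCP), SDE compactness, visited places, time outside, max/straight-line distance, turning radius, radius of gyration |
| `bouts`        | band-pass filtering, step-peak detection, GPS speed gating, bout segmentation |
| `gaitmetrics`  | step timing, variability, regularity, symmetry, walking speed (0.7 m step), RMS, harmonic ratio, entropy |
| `stats`        | per-variable normality screen, Mann–Whitney U, median/IQR comparison table |
| `classify`     | grid-searched RF/SVM/KNN with LOOCV scoring, 70/30 stratified evaluation, ROC/AUC |
| `synth`        | faller/non-faller cohort generator with per-subject ground truth |
| `pipeline`     | raw streams → one feature row per subject |

## CLI

```bash
# generate a synthetic cohort (reference = full 8 h day, compact = short day)
simulate-cohort --n-per-group 20 --seed 1 --out cohort/ --preset reference

# stays, life-space features, gait features
extract-stays --in cohort/gps --out stays.csv --radius-km 0.1 --min-minutes 15
extract-gps   --in cohort/gps --out gps_features.csv
extract-gait  --accel cohort/accel --gps cohort/gps --out gait_features.csv

# group comparison and classification on a merged feature table
compare-groups   --features cohort_features.csv --out comparison.csv
classify-fallers --features cohort_features.csv --condition combined --model rf \
                 --seed 42 --out reports.csv
```

CSV dialects: trajectories `subject_id,timestamp,lat,lon` (ISO-8601 or epoch
seconds; GPX 1.1 also read), accelerometer `subject_id,t,vt,ml,ap` (epoch
seconds, m/s²).

## Notes

- The radius of gyration is implemented as the SD of per-fix distances to
  home (as defined upstream); the conventional RMS-distance form is
  available via `k_radius_of_gyration(..., conventional=True)`.
- The activity-space field serves both the "activity space" and "minimum
  convex polygon" notions; they share one area.
- The vertical-axis even:odd energy control in the generator saturates at a
  small odd amplitude so step peaks can never fall below the detection
  threshold; ML/AP axes follow the requested ratio exactly (see
  `synth.py`).
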