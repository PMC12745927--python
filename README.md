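# hemodose

Dynamic estimation of the radiation dose delivered to **circulating
blood** during fractionated external photon radiotherapy, with the
downstream statistics used to relate blood dose to clinical outcomes.

Radiation-induced lymphopenia is common after fractionated radiotherapy
and is associated with worse locoregional control, distant-metastasis-free
survival, and overall survival.  Because blood cannot be dosimetered
directly, its dose must be simulated: `hemodose` transports discrete blood
particles through a compartmental patient model (organs, vessel groups,
tissues, each holding a fixed fraction of blood volume and cardiac output)
while the treatment plan's beam-on/beam-off timeline plays out, then
reduces the per-particle cumulative dose distribution to the standard
metrics

* `D_mean` — mean dose over all particles,
* `D_X%` — minimum dose among the top X% highest-dose particles,
* `V_YGy` — percentage of particles receiving ≥ Y Gy,

alongside three static comparators (mean body dose, mean dose over the
union of all compartment structures, and EDIC, the effective dose to
immune cells).  A survival module (Kaplan–Meier, quartile log-rank, Cox
proportional hazards with per-Gy hazard ratios, proportional-hazards
checks, multiple-testing corrections) and a compartment-relevance module
(Pearson correlation of compartment DVH dose with blood dose across a
cohort) reproduce the analysis stage, and a synthetic phantom/cohort
generator makes the whole pipeline runnable without patient data.

Intended users: medical-physics and outcomes researchers who want a
self-contained, testable implementation of dynamic blood dosimetry and its
statistical downstream at desk scale.

## Worked example

```python
import numpy as np
from hemodose import (
    CirculationParams, CompartmentModel, PatientModel,
    build_schedule, compute_metrics, default_physiology, score_course,
)

# A male patient (ICRP-89: 5.3 L blood, 6.5 L/min cardiac output) with one
# irradiated organ holding 20% of the blood volume and a cold remainder.
model = PatientModel(
    physiology=default_physiology("male"),
    compartments=(
        CompartmentModel(name="target_organ", f_volume=0.2, f_flow=0.3,
                         voxel_doses=np.linspace(30.0, 70.0, 60)),
        CompartmentModel(name="rest", f_volume=0.8, f_flow=0.7,
                         voxel_doses=[0.0]),
    ),
)
# 60 Gy in 30 fractions at 3 Gy/min: 40 s beam-on per fraction.
schedule = build_schedule({"n_fractions": 30, "prescription_gy": 60.0})
dist = score_course(model, CirculationParams(n_particles=10_000, rng_seed=1), schedule)
m = compute_metrics(dist, x_levels=(10.0, 90.0), y_levels=(5.0,))
print(f"D_mean = {m.d_mean:.2f} Gy")
print(f"D_10%  = {m.d_x[10.0]:.2f} Gy")
print(f"D_90%  = {m.d_x[90.0]:.2f} Gy")
print(f"V_5Gy  = {m.v_y[5.0]:.1f} %")
```

Output:

```
D_mean = 9.95 Gy
D_10%  = 14.19 Gy
D_90%  = 6.02 Gy
V_5Gy  = 95.1 %
```

The mean matches the conservation identity
`f_volume × mean(voxel dose) = 0.2 × 50 Gy = 10 Gy` to within Monte-Carlo
error; the D_10%–D_90% spread reflects which particles happened to sit in
the irradiated organ during beam-on, and narrows as the same total dose is
split over more fractions.

End-to-end on synthetic data (writes phantoms, per-patient metrics, Cox /
log-rank / Kaplan–Meier / relevance tables):

```bash
cat > cohort.yaml <<EOF
n_patients: 20
site: hnscc
dose_mode: simulate
n_particles: 2000
seed: 7
EOF
hemodose all --spec cohort.yaml --out run/
```

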