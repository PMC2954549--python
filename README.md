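# pftrace

Multizone **effective air exchange rates** from passive perfluorocarbon
tracer (PFT) surveys.

Indoor air quality surveys need to know not just how fast fresh air enters
each room, but how fast the air between rooms mixes — and they need to
measure it over a full day, cheaply, while the occupants go about their
lives. The PFT method does this by placing passive dosers of a different
perfluorocarbon in each room (at the corners, mimicking the real emission
locations of indoor pollutants) and passively sampling the air at each room
centre for 24 h. `pftrace` implements the computational core of that
method for researchers and survey technicians:

- the **forward model**: steady-state tracer concentrations from a known
  airflow field;
- the **inversion**: all indoor–outdoor and inter-room airflows from
  measured concentrations and dosing rates;
- the **calibration chain**: solvent-extraction recovery, passive sampling
  rates, analytical and 24-h air detection/quantification limits,
  gravimetric dosing rates and their exponential temperature model;
- the **CO₂ concentration-decay** reference method for validation;
- a **synthetic-survey generator** so every step is testable without field
  data.

## Model

Zones are indexed 0 (outdoors) and 1..n (rooms); `Q[i][j]` is the airflow
from zone i to zone j in m³/h. Assuming steady state, perfect mixing per
room and zero outdoor tracer concentration, each tracer T (emitted at
M_T µg/h in its source room) satisfies one mass balance per room i:

    M_T·[i = src(T)] + Σ_j C_Tj·Q_ji − C_Ti·(Q_i0 + Σ_j Q_ij) = 0

and each room satisfies air-volume closure:

    Q_0i + Σ_j Q_ji − Q_i0 − Σ_j Q_ij = 0

For a 3-room dwelling this is 9 tracer equations + 3 air equations in the
12 unknown flows. With measured concentrations the system is **linear in
Q**, so the inversion is solved exactly by nonnegative least squares
(`method="nnls"`, default); a bounded quasi-Newton route (L-BFGS-B,
`method="bounded_quasi_newton"`) is kept as the field-traditional
cross-check. Per-room rates are then

    outdoor ACH_i = Q_0i / V_i        inter-room ACH_i = Σ_j Q_ji / V_i

in h⁻¹. See `docs/methods.md` for assumptions, weighting of the
mixed-unit residuals, and numerical details.

## Worked example

Simulate a noiseless survey day of a 3-room dwelling (dining
room/kitchen 29.04 m³, Japanese-style room 23.54 m³, bedroom 21.78 m³;
tracers HxFBz/OFT/PFABz at 0.23/0.082/0.015 mg/h per doser, four dosers
per room), then invert it:

```sh
pftrace simulate --zones 3 --seed 7 --concentration-cv 0 --out-dir demo
pftrace invert --concentrations-csv demo/concentrations.csv \
               --dosers-csv demo/dosers.csv --zones-csv demo/zones.csv
```

prints (abridged):

```json
{
  "flows": {
    "Q10": 37.584094749618465,
    "Q01": 27.324695179737567,
    "Q12": 27.492331151814753,
    "...": "... 12 flows in total ..."
  },
  "flows_unit": "m3/h",
  "objective": 0.0,
  "per_room_outdoor_ach": [0.9409330296052881, 3.3823527448760915, 0.6971180518377417],
  "per_room_interroom_ach": [4.335558332155568, 1.5951740039531146, 7.001142459660794],
  "ach_unit": "1/h"
}
```

`Q10` is the exhaust from room 1 to outdoors and `Q01` the infiltration
into room 1 (m³/h); `per_room_outdoor_ach[0] = 0.94 h⁻¹` means room 1
receives fresh outdoor air at 0.94 room volumes per hour, and the
`objective` of 0 confirms the 12 mass balances are satisfied exactly
(noiseless data; the recovered flows match `demo/true_flows.json`).

Calibration one-liners work the same way, e.g. the 24-h air detection
limit of a tracer with analytical LOD 0.0030 µg/mL sampled at 10.5 mL/min:

```sh
$ pftrace lod --analytical-lod 0.0030 --sampling-rate 10.5 --duration 1440
0.20 ug/m3
```

Subcommands: `forward`, `invert`, `calibrate`, `lod`, `gravimetry`,
`decay`, `simulate`, `aggregate`. The same functionality is available as a
library (`import pftrace`).

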