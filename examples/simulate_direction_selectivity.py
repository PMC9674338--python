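"""Direction selectivity of a model starburst dendrite from input kinetics.

Builds the ball-and-stick starburst model with sustained bipolar input on
proximal dendrites and transient input distally, sweeps a 400-µm bar in
both directions, and prints the normalized direction-selectivity index
DSi = (CF − CP)/(CF + CP) of peak terminal Ca²⁺. The infinite-vesicle
("deterministic") limit is used so the numbers show the model's expected
timing structure rather than single-trial Poisson noise; stochastic
repeats (see `run_velocity_sweep`) scatter around these values.

With the native arrangement DSi is positive (centrifugal preference);
swapping the kinetics reverses the sign — the space-time wiring effect.
"""

import numpy as np

from sacglu import sacmodel as sm

model = sm.SACModel()

print("normalized DSi of peak terminal Ca (mean over 4 rosters, deterministic limit)")
print()
print(f"{'condition':>12}  {'0.15 mm/s':>10}  {'0.5 mm/s':>10}  {'2.0 mm/s':>10}")
for condition in ("native", "swapped"):
    row = []
    for vel in (0.15, 0.5, 2.0):
        vals = []
        for r in range(4):
            roster = sm.build_roster(model, seed=[0, r], condition=condition)
            cf, cp = sm.run_direction_pair(model, roster, vel, seed=1, deterministic=True)
            vals.append(sm.compute_dsi(cf, cp, mode="normalized"))
        row.append(np.mean(vals))
    print(f"{condition:>12}  {row[0]:>+10.4f}  {row[1]:>+10.4f}  {row[2]:>+10.4f}")

print()
print(
    "positive = centrifugal (soma→tip) preference. Swapping which dendritic\n"
    "zone gets sustained vs transient input flips the preferred direction,\n"
    "and the selectivity collapses for fast bars — both signatures of the\n"
    "space-time wiring mechanism."
)
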