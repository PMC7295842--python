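"""Parameter-recovery study for the cohort simulator.

Simulates 100 replicate rearing experiments (7 temperatures × 10
specimens, 5 % between-specimen CV, midpoint inspection censoring) from
a known linear truth and refits the thermal summation model to each.
The refitted K is unbiased to well under 1 %, showing that the
inspection protocol's discretisation does not distort the fit; the
nominal 95 % intervals cover the truth at a somewhat-below-nominal rate
(the conventional SMA standard errors undercover modestly on a
seven-point design).
"""

from pathlib import Path

import pandas as pd

import thermaldev as td
from thermaldev.dataset import landmark_dataset_from_records
from thermaldev.synthetic import SimulationConfig, simulate_cohort

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

K_TRUE, T_MIN_TRUE = 405.0, 11.7
TEMPS = (15.0, 17.5, 20.0, 22.5, 25.0, 27.5, 30.0)

rows = []
for rep in range(100):
    cfg = SimulationConfig(
        K=K_TRUE, T_min=T_MIN_TRUE, temperatures=TEMPS,
        n_per_temperature=10, cv_duration=0.05, seed=20_000 + rep,
    )
    fit = td.fit_thermal_summation(
        landmark_dataset_from_records(simulate_cohort(cfg), "eclosion")
    )
    rows.append(
        {
            "replicate": rep,
            "K": fit.K,
            "K_se": fit.K_se,
            "T_min": fit.T_min,
            "T_min_se": fit.T_min_se,
            "K_covered": abs(fit.K - K_TRUE) <= 1.96 * fit.K_se,
            "T_min_covered": abs(fit.T_min - T_MIN_TRUE) <= 1.96 * fit.T_min_se,
        }
    )

table = pd.DataFrame(rows)
table.to_csv(OUT / "simulation_recovery.csv", index=False)

print(f"truth: K = {K_TRUE}, T_min = {T_MIN_TRUE}")
print(f"mean refitted K     = {table.K.mean():8.2f}  "
      f"(bias {100 * (table.K.mean() - K_TRUE) / K_TRUE:+.2f} %, sd {table.K.std():.2f})")
print(f"mean refitted T_min = {table.T_min.mean():8.3f}  (sd {table.T_min.std():.3f})")
print(f"95 % interval coverage: K {int(table.K_covered.sum())}/100, "
      f"T_min {int(table.T_min_covered.sum())}/100")
print(f"\nwrote {OUT / 'simulation_recovery.csv'}")
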