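"""Validate each thermal summation model with the relative-error statistic.

For each landmark and rearing temperature, the actual thermal units
D·(T − T_min) computed from the per-temperature mean durations are
compared with the model constant K.  Errors are largest at the cold edge
of the viable range (the linear approximation breaks down there) and
stay below ~10 % through the 20-27.5 °C core; late landmarks
(pupation, eclosion) carry larger errors than early ones, driven by the
high variance of the postfeeding third-instar phase.
"""

from pathlib import Path

import pandas as pd

import thermaldev as td

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

rows = []
for landmark in td.LANDMARKS:
    data = td.cumulative_landmarks()[landmark]
    fit = td.fit_thermal_summation(data)
    for _, r in data.rows.iterrows():
        actual = r.D * (r.temperature_C - fit.T_min)
        rows.append(
            {
                "landmark": landmark,
                "temperature_C": r.temperature_C,
                "actual_ADD": round(actual, 2),
                "model_K": round(fit.K, 2),
                "relative_error": round(abs(actual - fit.K) / actual, 4),
            }
        )

table = pd.DataFrame(rows)
table.to_csv(OUT / "validation_errors.csv", index=False)

core = table[(table.temperature_C >= 20) & (table.temperature_C <= 27.5)]
print("mean relative error, 20-27.5 °C core:")
print(core.groupby("landmark").relative_error.mean().round(4).to_string())
print("\nmean relative error, full range:")
print(table.groupby("landmark").relative_error.mean().round(4).to_string())
print(f"\nwrote {OUT / 'validation_errors.csv'}")
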