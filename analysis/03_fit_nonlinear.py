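"""Fit the Analytis, Brière-2 and Lactin-2 rate curves to every landmark.

Because mortality removed the warm decline of the rate curve (no beetle
completed development at 32.5 °C), the observed rates are nearly linear
in temperature and the empirical nonlinear models push their upper
threshold far beyond anything biologically meaningful — the plausibility
flag fires for most fits.  This is the expected failure mode; the
linear and SSI models are the usable products.
"""

from pathlib import Path

import pandas as pd

import thermaldev as td
from thermaldev.nonlinear import MODELS, cardinal_temperatures, fit_nonlinear

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

rows = []
for landmark in td.LANDMARKS:
    data = td.cumulative_landmarks()[landmark]
    for model in MODELS:
        res = fit_nonlinear(model, data, seed=1)
        t_min, t_opt, t_max = cardinal_temperatures(res)
        rows.append(
            {
                "landmark": landmark,
                "model": model,
                "sse": res.sse,
                "r2": round(res.r2, 4),
                "aicc": round(res.aicc, 2),
                "T_min": None if t_min is None else round(t_min, 2),
                "T_opt": None if t_opt is None else round(t_opt, 2),
                "T_max": None if t_max is None else round(t_max, 2),
                "implausible": res.implausible,
            }
        )
        flag = " [implausible]" if res.implausible else ""
        print(f"{landmark:15s} {model:9s} r2={res.r2:.4f} "
              f"T_min={t_min if t_min is None else round(t_min, 1)} "
              f"T_max={t_max if t_max is None else round(t_max, 1)}{flag}")

pd.DataFrame(rows).to_csv(OUT / "nonlinear_models.csv", index=False)
print(f"\nwrote {OUT / 'nonlinear_models.csv'}")
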