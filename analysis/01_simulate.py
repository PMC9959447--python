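"""Generate the synthetic study inputs: a 30-province x 10-year panel.

Writes the raw activity tables (crop yields, emission activities, input
quantities), the four infrastructure indicator blocks, and the
regression-ready panel with known ground truth to results/data/.
"""

from pathlib import Path

import numpy as np

from ecoeff.synthetic import (SyntheticConfig, config_to_dict,
                              generate_activity_panel, generate_indicator_panel,
                              generate_regression_panel, write_panel_csv)

OUT = Path("results/data")
OUT.mkdir(parents=True, exist_ok=True)

cfg = SyntheticConfig(seed=0, beta_ndi=1.0, gamma_interact=0.0)
activity = generate_activity_panel(cfg)
activity.crops.to_csv(OUT / "crops.csv", index=False)
activity.activities.to_csv(OUT / "activities.csv", index=False)
activity.quantities.to_csv(OUT / "quantities.csv", index=False)

blocks = generate_indicator_panel(cfg)
for name, M in blocks.items():
    import pandas as pd
    df = pd.DataFrame(M.values, columns=M.indicators)
    df.insert(0, "unit", [u for u, _ in M.units])
    df.insert(1, "year", [y for _, y in M.units])
    df.to_csv(OUT / f"indicators_{name}.csv", index=False)

panel = generate_regression_panel(cfg)
write_panel_csv(panel, OUT / "panel.csv")
import json
(OUT / "truth.json").write_text(json.dumps(config_to_dict(cfg), indent=2))

print(f"activity bundles : {len(activity.quantities)} unit-years")
print(f"indicator blocks : {', '.join(f'{k}({M.values.shape[1]})' for k, M in blocks.items())}")
print(f"regression panel : {len(panel)} rows, true NDI effect = {cfg.beta_ndi}")
print(f"outputs under    : {OUT}/")
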