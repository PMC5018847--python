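"""AICc-ranked Cox model selection on a simulated nest study.

Draws per-nest camouflage metrics, simulates interval-checked predation
with a planted 2.9-fold species hazard ratio, enumerates the 19-model
candidate suite (species, each metric alone / additive / interactive,
the significant pair, and the full sets), ranks it by AICc, and averages
the well-supported (delta <= 2) models.
"""

import numpy as np
import pandas as pd

from nestcam.pipeline import RunConfig, survival_stage
from nestcam.synthetic import SurvivalTruth, make_null_metric_table, make_survival_table

metrics = make_null_metric_table(n_plover=30, n_tern=24, seed=1)
truth = SurvivalTruth(baseline_hazard=0.0075, beta_species=np.log(2.9))
fates = make_survival_table(truth, metrics, seed=2)
print(fates.groupby("species")["event"].agg(["sum", "count"]))

# pretend the comparison stage flagged the published significant pair
comparison = pd.DataFrame(
    {"variable": ["PropBgToEggColorMatch", "DisRat"], "p_adjusted": [0.01, 0.04]}
)
out = survival_stage(fates, metrics, RunConfig(), comparison=comparison)

print(f"\n{len(out['ranking'])} models ranked by AICc (n = {len(out['data'])} nests):")
print(out["ranking"].to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print("\nmodel-averaged coefficients over the delta <= 2 set:")
print(out["averaged"].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
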