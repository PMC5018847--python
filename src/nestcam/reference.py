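"""Published model-selection table and fate tallies from the plover/tern
field study this pipeline re-implements.

The field photographs were never released, so the study's per-image
metrics cannot be recomputed; what can be checked is the information-
theoretic arithmetic.  This module records the published 19-model Cox
ranking (model structure, number of coefficients, log-likelihood, AICc,
delta and Akaike weight over 54 nests) and the published predation
tallies, as plain data for cross-checking the ranking machinery.

One published row ("Species + PropBgToEggColorMatch + DisRat") prints a
log-likelihood of -74.38 that is arithmetically inconsistent with its own
printed AICc of 135.2; the AICc/delta/weight columns are consistent with
-64.38 (a single-digit transcription slip).  Both values are kept:
``loglik`` as printed, ``loglik_consistent`` as the value implied by the
rest of the row.
"""

from __future__ import annotations

import pandas as pd

#: Nests per species in the published survival analysis.
N_NESTS = 54
N_PLOVER = 30
N_TERN = 24

#: Predated clutches per species (5/30 plovers = 17%, 14/24 terns = 58%).
N_PREDATED_PLOVER = 5
N_PREDATED_TERN = 14

#: Hazard ratio of tern vs plover predation risk in the species-only model.
SPECIES_HAZARD_RATIO = 2.9

# (model, k, logLik printed, logLik consistent with the row, AICc, delta, weight)
_ROWS = [
    ("Species", 1, -65.26, -65.26, 132.6, 0.00, 0.17),
    ("Species + DisRat", 2, -64.59, -64.59, 133.4, 0.82, 0.11),
    ("Species + CompRat^2", 2, -64.78, -64.78, 133.8, 1.2, 0.09),
    ("Species * DisRat", 3, -63.69, -63.69, 133.8, 1.25, 0.09),
    ("Species + PropBgToEggColorMatch", 2, -64.81, -64.81, 133.9, 1.26, 0.09),
    ("Species * PropBgToEggColorMatch", 3, -63.78, -63.78, 134.0, 1.45, 0.08),
    ("Species + VisRat", 2, -65.23, -65.23, 134.7, 2.1, 0.06),
    ("Species + DeltaE", 2, -65.23, -65.23, 134.7, 2.11, 0.06),
    ("Species + PropBgToEggColorMatch + DisRat", 3, -74.38, -64.38, 135.2, 2.65, 0.05),
    ("Species * CompRat^2", 3, -64.74, -64.74, 136.0, 3.37, 0.03),
    ("Species * VisRat", 3, -64.96, -64.96, 136.4, 3.81, 0.03),
    ("DisRat", 1, -67.2, -67.2, 136.5, 3.89, 0.02),
    ("DeltaE", 1, -67.26, -67.26, 136.6, 4.01, 0.02),
    ("PropBgToEggColorMatch", 1, -67.27, -67.27, 136.6, 4.02, 0.02),
    ("Species * DeltaE", 3, -65.13, -65.13, 136.7, 4.15, 0.02),
    ("CompRat^2", 1, -67.38, -67.38, 136.8, 4.24, 0.02),
    ("VisRat", 1, -67.45, -67.45, 137.0, 4.38, 0.02),
    (
        "Species + PropBgToEggColorMatch + DeltaE + CompRat^2 + VisRat + DisRat",
        6,
        -63.68,
        -63.68,
        141.1,
        8.55,
        0.0,
    ),
    (
        "PropBgToEggColorMatch + DeltaE + CompRat^2 + VisRat + DisRat",
        5,
        -66.82,
        -66.82,
        144.9,
        12.3,
        0.0,
    ),
]


def published_model_table() -> pd.DataFrame:
    """The published 19-model AICc ranking as a DataFrame."""
    return pd.DataFrame(
        _ROWS,
        columns=["model", "k", "loglik", "loglik_consistent", "aicc", "delta", "weight"],
    )


#: The five pruned camouflage predictors of the published candidate suite
#: and the two that differed significantly between species.
PRUNED_METRICS = ["DisRat", "VisRat", "CompRat^2", "DeltaE", "PropBgToEggColorMatch"]
SIGNIFICANT_METRICS = ["PropBgToEggColorMatch", "DisRat"]
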