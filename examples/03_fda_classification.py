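"""Classify host-like vs parasite-like eggs from their trait tables.

Measures a scribbled "host" cohort and a blotched "parasite" cohort,
fits a linear-basis flexible discriminant analysis on the trait table,
and prints per-class assignment rates plus the trait contributions to
the first discriminant (normalised to sum to 100%).
"""

import numpy as np
import pandas as pd

from minkpat import RunConfig
from minkpat.batch import measure_image
from minkpat.classify import assign, coefficient_importance, fit_fda
from minkpat.synth import egg_pair

cfg = RunConfig(invert=False)
rows, labels = [], []
for i in range(15):
    scr, blo = egg_pair(seed=i)
    for label, egg in [("host", scr), ("parasite", blo)]:
        traits, _ = measure_image(egg, cfg, specimen=f"{label}_{i:02d}")
        rows.append(traits)
        labels.append(label)

table = pd.DataFrame(rows).drop(columns=["pole_dispersion"]).dropna(axis=1)
table = table.loc[:, table.std() > 0]
y = np.array(labels)

model = fit_fda(table, y, basis="linear")
rates = assign(model, table, y, scheme="resubstitution")
print("per-class percent correctly assigned (resubstitution):")
print(rates.round(1).to_string())
print("\ntrait contributions to the first discriminant (sum to 100%):")
print(coefficient_importance(model).sort_values(ascending=False).round(1).to_string())
print(
    "\nThe cohorts differ only in marking morphology, so the Minkowski and\n"
    "shape-sensitive traits carry the discrimination."
)
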