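"""Shrink effects, classify ATAC x G4 quadrants, tabulate the FDR ladder."""

import pandas as pd

from common import RESULTS, WORKDIR, config
from g4age.pipeline import stage_integrate

stage_integrate(config(), WORKDIR)
quad = pd.read_csv(WORKDIR / "quadrants.csv")
labels = quad["label"].value_counts().rename_axis("label").reset_index()
labels.to_csv(RESULTS / "06_quadrant_counts.csv", index=False)
print(labels.to_string(index=False))

ladder = pd.concat([
    pd.read_csv(WORKDIR / f"fdr_counts_{a}.csv").assign(assay=a)
    for a in ("ATAC", "G4Q")
])
ladder.to_csv(RESULTS / "06_fdr_ladder.csv", index=False)
print(ladder.to_string(index=False))
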