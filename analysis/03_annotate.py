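"""Annotate peaks hierarchically and flag canonical G4 motifs."""

import pandas as pd

from common import RESULTS, WORKDIR, config
from g4age.pipeline import stage_annotate

stage_annotate(config(), WORKDIR)
ann = pd.read_csv(WORKDIR / "annotation.csv")
table = (ann.groupby("category")
         .agg(n=("peak_id", "size"), canonical=("canonical_g4", "sum"))
         .sort_values("n", ascending=False))
table.to_csv(RESULTS / "03_annotation_categories.csv")
print(table.to_string())
print(f"canonical G4 fraction: {ann['canonical_g4'].mean():.3f}")
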