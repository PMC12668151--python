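"""Refine G4 peak calls through the signal and M/A filters."""

import json

import pandas as pd

from common import RESULTS, WORKDIR, config
from g4age.pipeline import stage_refine

stage_refine(config(), WORKDIR)
stats = json.loads((WORKDIR / "refinement_stats.json").read_text())
pd.DataFrame([stats]).to_csv(RESULTS / "04_refinement_stats.csv",
                             index=False)
print(json.dumps(stats, indent=1))
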