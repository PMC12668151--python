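"""Ordinal-age moderated regression per assay; count FDR discoveries."""

import json

import pandas as pd

from common import RESULTS, WORKDIR, config
from g4age.pipeline import stage_diff

stage_diff(config(), WORKDIR)
rows = []
for assay in ("ATAC", "G4Q"):
    res = pd.read_csv(WORKDIR / f"diff_{assay}.csv")
    info = json.loads((WORKDIR / f"diff_{assay}_info.json").read_text())
    rows.append({
        "assay": assay,
        "n_peaks": len(res),
        "n_fdr10": int((res["fdr"] <= 0.10).sum()),
        "prior_df": float(info["prior_df"]),
        "consensus_correlation": float(info["consensus_correlation"]),
    })
out = pd.DataFrame(rows)
out.to_csv(RESULTS / "05_differential_summary.csv", index=False)
print(out.to_string(index=False))
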