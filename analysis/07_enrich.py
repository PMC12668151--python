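"""Context-split ORA and preranked GSEA over the decoy gene sets."""

import pandas as pd

from common import RESULTS, WORKDIR, config
from g4age.pipeline import stage_enrich

stage_enrich(config(), WORKDIR)
for assay in ("ATAC",):
    ora = pd.read_csv(WORKDIR / f"ora_{assay}.csv")
    gsea = pd.read_csv(WORKDIR / f"gsea_{assay}.csv")
    cols = [c for c in ora.columns if c.startswith(("fisher", "fdr"))]
    top = ora.sort_values("fisher_up")[["set"] + cols].head(10)
    top.to_csv(RESULTS / "07_ora_top.csv", index=False)
    print("top ORA sets (decoys; expect no strong signal):")
    print(top.to_string(index=False))
    g = gsea.sort_values("fisher_up").head(10)
    g.to_csv(RESULTS / "07_gsea_top.csv", index=False)
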