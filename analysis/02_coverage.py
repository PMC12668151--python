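"""Normalize coverage, summarize peaks, call moderate-abundance presence.

Reports per-assay signal levels and how many peaks each culture shares
with the others (the UpSet-style exact-subset counts).
"""

import pandas as pd

from common import RESULTS, WORKDIR, config
from g4age.pipeline import stage_coverage

cfg = config()
stage_coverage(cfg, WORKDIR)

rep = pd.read_csv(WORKDIR / "replicate_summary.csv")
glob = rep.drop_duplicates(["peak_id", "assay"])
signal = glob.groupby("assay")["mean_norm"].describe()[
    ["mean", "50%", "std"]]
signal.to_csv(RESULTS / "02_signal_summary.csv")
print("normalized signal per assay:")
print(signal.to_string())

for assay in ("ATAC", "G4Q"):
    inter = pd.read_csv(WORKDIR / f"intersections_{assay}.csv")
    shared_all = inter.loc[inter["n_cultures"] == 8, "count"].sum()
    print(f"{assay}: peaks present in all 8 cultures: {shared_all}")
    inter.tail(5).to_csv(RESULTS / f"02_intersections_{assay.lower()}.csv",
                         index=False)
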