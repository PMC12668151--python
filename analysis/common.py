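"""Shared paths and config for the numbered analysis scripts.

The heavy per-run files (genome, matrices, per-peak tables) live under
scratch/; only compact summary tables are written to results/.
"""

from pathlib import Path

from g4age.config import PipelineConfig

ROOT = Path(__file__).resolve().parent.parent
WORKDIR = ROOT / "scratch" / "analysis_run"
RESULTS = ROOT / "results"

SEED = 1


def config() -> PipelineConfig:
    return PipelineConfig(seed=SEED, n_perm=500)
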