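"""Shared configuration for the numbered analysis scripts.

Every script recomputes its upstream stages from the same seeded
configuration, so each one is standalone and the whole chain is
reproducible; artifacts land under results/.
"""

from pathlib import Path

from deerdsm.config import PipelineConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"


def get_config(subdir: str, seed: int = 1) -> PipelineConfig:
    out = RESULTS / subdir
    out.mkdir(parents=True, exist_ok=True)
    return PipelineConfig(seed=seed, outdir=str(out))
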