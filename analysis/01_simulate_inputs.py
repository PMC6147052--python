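#!/usr/bin/env python
"""Generate the synthetic study inputs.

Writes flux-study records (mixed daily/seasonal/annual reporting bases at the
published ecozone x class cell means), daily temperature series per ecozone,
a co-registered raster landscape with its rule-oracle class map, validation
points and PCM-style polygons into scratch/pipeline/.
"""

from pathlib import Path

from peatflux.config import PipelineConfig
from peatflux.pipeline import run_stage

OUT = Path(__file__).resolve().parents[1] / "scratch" / "pipeline"

if __name__ == "__main__":
    cfg = PipelineConfig(seed=42)
    artifacts = run_stage("simulate", cfg, OUT)
    print(f"Simulated inputs for seed {cfg.seed}:")
    for a in artifacts:
        print(f"  {a}")
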