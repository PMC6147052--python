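#!/usr/bin/env python
"""Assess map accuracy against validation points and polygon percentages.

Builds the ground-truth confusion matrix (points carry 20% label noise by
construction, so overall accuracy should sit near 80%), reports producer's/
user's accuracies and kappa, and bins per-polygon bog percentages from the
two map products to measure near-1:1-line agreement.
"""

import json
import shutil
from pathlib import Path

import pandas as pd

from peatflux.config import PipelineConfig
from peatflux.pipeline import run_stage

OUT = Path(__file__).resolve().parents[1] / "scratch" / "pipeline"

def publish(*names):
    """Copy the stage's summary tables from the working dir into results/."""
    results = Path(__file__).resolve().parents[1] / "results"
    results.mkdir(exist_ok=True)
    for name in names:
        shutil.copy(OUT / name, results / name)


if __name__ == "__main__":
    cfg = PipelineConfig(seed=42)
    for prereq, stage in (("validation_points.csv", "simulate"),
                          ("class_map.tif", "buildmap")):
        if not (OUT / prereq).exists():
            run_stage(stage, cfg, OUT)
    run_stage("assess", cfg, OUT)

    cm = pd.read_csv(OUT / "confusion_matrix.csv", index_col=0)
    stats = json.loads((OUT / "accuracy.json").read_text())
    print("Confusion matrix (rows = truth, columns = map):")
    print(cm.to_string())
    print(f"\nOverall accuracy {stats['overall_pct']:.1f}% "
          f"(n = {stats['n']}), kappa {stats['kappa']:.2f}")

    agree = json.loads((OUT / "polygon_agreement.json").read_text())
    print(f"Polygon bog-percentage bins within one 10%-category of the 1:1 "
          f"line: {agree['within_one_pct']:.0f}% of {agree['n_polygons']} polygons")
    publish("confusion_matrix.csv", "accuracy.json", "polygon_agreement.json")
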