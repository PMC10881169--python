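"""Resting vs activated comparison through the full pipeline.

Runs the whole workflow (simulate both conditions, transform, segment,
quantify, test) into a temporary directory and prints the statistical
report: the activated condition carries a -0.1 shift in bound fraction
(the glycolytic shift of T-cell activation), which the Welch t-test on
per-cell volume means should flag.
"""

import tempfile
from pathlib import Path

from flimcyte import run_pipeline
from flimcyte.config import config_from_dict

cfg = config_from_dict({
    "acquisition": {"n_time_bins": 64, "frame_shape": [128, 128], "n_z": 6},
    "simulate": {"phantom": {"n_cells": 30, "cell_radius": 5.0,
                             "min_gap": 4.0, "mito_density": 6.0,
                             "mito_radius": 1.2}},
    "segmentation": {"blur_sigma": 1.0, "min_area": 25},
    "seed": 7,
})

with tempfile.TemporaryDirectory() as tmp:
    out = run_pipeline(cfg, Path(tmp) / "run")
    print((out / "stats" / "report.txt").read_text())
    n_rows = sum(1 for line in (out / "cells.csv").open()
                 if not line.startswith("#")) - 1
    print(f"cells.csv rows: {n_rows}")
print("Medians [IQR] per condition; a significant Welch t (p << 0.05) "
      "reflects the\nimposed activation effect. Axial contrasts and the "
      "area correlation follow.")
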