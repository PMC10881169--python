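"""Axial (Z) structure of the metabolic signal.

Mitochondria concentrate at the bottom (coverslip / immune-synapse side)
and top of spread T cells, so the per-plane mean fraction bound is
U-shaped; an activated cell with synapse-side mitochondrial polarisation
shows bottom > top.  Both effects are rendered by the simulator and
recovered by the per-Z quantification.
"""

from dataclasses import replace

from flimcyte import (AcquisitionParams, PhantomSpec, PipelineConfig,
                      render_phantom, z_profile)
from flimcyte.pipeline import process_stack

acq = AcquisitionParams(n_time_bins=64, frame_shape=(128, 128), n_z=6)
cfg = PipelineConfig(acquisition=acq)
cfg = replace(cfg, segmentation=replace(cfg.segmentation, blur_sigma=1.0,
                                        min_area=25))
spec = PhantomSpec(n_cells=30, cell_radius=5.0, min_gap=4.0,
                   mito_density=6.0, mito_radius=1.2, seed=1)

for label, phantom, cond in [
        ("symmetric (control)", spec, "control"),
        ("synapse-polarised (activated)",
         replace(spec, synapse_bias=1.5), "activated")]:
    stack, _ = render_phantom(phantom, acq, cond, 10)
    records, *_ = process_stack(stack, cfg)
    prof = z_profile(records, acq=acq)
    print(f"\n{label}:")
    for _, row in prof.iterrows():
        bar = "#" * int(row["mean"] * 120)
        print(f"  z={row['z_um']:4.0f} um  mean f_bound={row['mean']:.3f} "
              f"+/- {row['sd']:.3f}  {bar}")
print("\nFirst and last planes exceed the nuclear mid-planes (U shape); "
      "with synapse\npolarisation the coverslip-proximal plane dominates "
      "the top one.")
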