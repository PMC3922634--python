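"""Build the synthetic study material and record its ground truth.

Generates the layered glycocalyx section, a blank-resin control block, a
fiducial-decorated section for the pre-shrink measurement, and the
urinary-space phantom; writes the volumes as MRC under results/phantoms and
the ground truth (fibre spacing statistics, bead positions, SPS table) as
CSV/JSON sidecars.
"""

import json
from pathlib import Path

import numpy as np

from gfb3d.io_formats import ImageVolume, write_morphometry_csv, write_volume
from gfb3d.phantom import (GfbPhantomSpec, SpacePhantomSpec, add_fiducials,
                           generate_blank_resin, generate_gfb_phantom,
                           generate_space_phantom, mean_nn_spacing)

OUT = Path(__file__).resolve().parents[1] / "results" / "phantoms"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 1

spec = GfbPhantomSpec()
vol, labels, centres = generate_gfb_phantom(spec, seed=SEED)
write_volume(vol, OUT / "gfb_section.mrc")
write_volume(ImageVolume(labels.labels, labels.voxel_size), OUT / "gfb_labels.mrc")
(OUT / "gfb_legend.json").write_text(json.dumps(labels.legend, indent=2))
np.savetxt(OUT / "fibre_centres_nm.csv", centres, delimiter=",", header="y_nm,x_nm")
nn = mean_nn_spacing(centres)
print(f"GFB section {spec.volume_shape} voxels at {spec.voxel_size[0]} nm: "
      f"{len(centres)} fibres, mean nearest-neighbour spacing {nn:.2f} nm "
      f"(requested {spec.fibre_spacing_mean} nm)")

blank = generate_blank_resin(spec.volume_shape, spec.voxel_size,
                             noise_gaussian_sd=spec.noise_gaussian_sd, seed=SEED + 1)
write_volume(blank, OUT / "blank_resin.mrc")
print("blank resin block written (control areas for threshold calibration)")

section = generate_blank_resin((100, 160, 160), (3.0, 3.0, 3.0),
                               noise_gaussian_sd=0.0, seed=SEED + 2)
section_b, beads = add_fiducials(section, 20, seed=SEED + 3, margin_nm=110.0)
write_volume(section_b, OUT / "fiducial_section.mrc")
rows = [(b["surface"], *b["position"]) for b in beads.beads]
with open(OUT / "beads_nm.csv", "w") as fh:
    fh.write("surface,z_nm,y_nm,x_nm\n")
    for surface, z, y, x in rows:
        fh.write(f"{surface},{z:.1f},{y:.1f},{x:.1f}\n")
print(f"fiducial section: 300 nm thick, {len(beads)} gold beads (10 nm) on two surfaces")

sspec = SpacePhantomSpec()
svol, slabels, truth = generate_space_phantom(sspec, seed=SEED + 4)
write_volume(svol, OUT / "spaces.mrc")
write_volume(ImageVolume(slabels.labels, slabels.voxel_size), OUT / "spaces_labels.mrc")
write_morphometry_csv(truth, OUT / "spaces_truth.csv")
print(f"urinary-space phantom: {len(truth.records)} sub-podocyte spaces "
      f"(exit widths {[r.exit_width_nm for r in truth.records]} nm)")
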