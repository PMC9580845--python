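"""Generate a synthetic thorax phantom and inspect its exact ground truth.

The phantom mimics the contrast of a self-gated bSSFP mouse-thorax stack:
dark lungs inside a brighter body, bright vessel-like tubes (labelled as
lung) and bright spherical metastases (labelled 2), with pure-noise slices
at both stack ends.
"""

from lungmet import PhantomSpec, compute_volumes, generate_phantom

spec = PhantomSpec.random(dims=(32, 64, 64), n_metastases=3, seed=7,
                          radius_range=(2.5, 4.0))
stack, labels = generate_phantom(spec)

report = compute_volumes(labels)
counts = labels.class_counts()
print(f"stack dims            : {stack.shape}")
print(f"voxel volume          : {report.voxel_volume_mm3:.6f} mm^3")
print(f"lung voxels           : {counts[1]}  ({report.lung_volume_mm3:.3f} mm^3)")
print(f"metastasis instances  : {report.met_count}")
for i, v in enumerate(report.met_instance_volumes_mm3, 1):
    print(f"  instance {i}: {v:.4f} mm^3")

# Every number above is exact: labels come from voxel-centre rasterization
# of the generating geometry, so voxel counting reproduces it perfectly.
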