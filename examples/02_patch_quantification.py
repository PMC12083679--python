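"""Tile one image into 50 um patches, scale to the 99th percentile, run QC.

Prints the per-marker scaling references and the QC removal counts. Scaled
values are dimensionless: 1.0 means "as bright as this sample's 99th
percentile of patch means" for that marker.
"""

from imcpatch import (
    SyntheticConfig, analysis_view, extract_patches, flag_low_signal,
    flag_outliers, generate_image, scale_patches,
)

config = SyntheticConfig(seed=3)
image, truth = generate_image("G3", config, seed=11)
image.sample_id = "demo_G3"

table = extract_patches(image, patch_size_um=50.0)   # 10x10 grid on 500x500 px
table = scale_patches(table, percentile=99.0)
table = flag_outliers(table)
table = flag_low_signal(table, dna_threshold=0.05)
view, removed = analysis_view(table)

print(table.scaling_refs.to_string(index=False))
print(f"\npatches extracted: {len(table)}   QC-passing: {len(view)}   removed: {removed}")
print(view.df[["patch_row", "patch_col", "scaled_DNA", "scaled_Shh", "scaled_TGFb"]]
      .head(5).round(3).to_string(index=False))
print("\nEach row is one 50x50 um tile; scaled_TGFb near 1 marks fibrotic "
      "regions, near 0.1 marks background tissue.")
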