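"""Per-cell analysis of a segmented tissue image.

Generates a synthetic 20-cell confluent tissue (seeded Voronoi label
raster standing in for a segmentation), runs the full pipeline on every
cell, and prints the per-cell record table. Cells touching the image
border are flagged: their outlines are clipped, so population summaries
exclude them by default.
"""

from locoefa import analyze_label_image, records_dataframe, synthetic_tissue

img = synthetic_tissue(n_cells=20, field_size=256, seed=1)
results = analyze_label_image(img, n_modes=50)
df = records_dataframe(results, n_modes=50)

cols = ["cell_id", "area_px", "border", "argmax_md_mode", "cd", "entropy", "cutoff"]
print(df[cols].to_string(index=False))
interior = df[~df["border"]]
print(f"\n{len(interior)} interior cells; mean cd = {interior['cd'].mean():.3f}, "
      f"mean entropy = {interior['entropy'].mean():.3f}")
print("-> Voronoi cells are convex polygons: low cd, cutoff well below 50.")
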