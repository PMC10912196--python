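"""Extract canopy traits from rendered RGB + DEM plot tiles.

Renders tiles with known cover and height, then runs the CLAHE -> HSV
segmentation -> trait chain and shows that the known targets come back.
"""

import tempfile

import pandas as pd

from phenoyield import SegmentationConfig, extract_trait_table, write_tile_dataset

records = pd.DataFrame(
    {
        "plot_id": ["p1", "p2", "p3", "p4"],
        "genotype": ["G1", "G2", "G3", "G4"],
        "year": ["2021"] * 4,
        "dap": [20, 45, 70, 95],
        "CC": [0.05, 0.30, 0.65, 0.85],   # known canopy cover per tile
        "CH": [0.02, 0.15, 0.35, 0.45],   # known canopy height (m)
    }
)

with tempfile.TemporaryDirectory() as tmp:
    manifest = write_tile_dataset(records, tmp, seed=0)
    table = extract_trait_table(manifest, SegmentationConfig())

print(table[["plot_id", "dap", "CC", "CH", "CH90", "CV", "ExG"]].round(4).to_string(index=False))
print("\nCC/CH columns should match the rendered targets above to ~1 pixel;")
print("CV = CC x CH by definition; ExG is min-max normalised within the year.")
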