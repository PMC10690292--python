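"""Generate a synthetic multi-plate screen with known ground truth.

The generator emulates the structure of a cytotoxic-compound Cell Painting
screen: DMSO control wells, treatment wells spanning named injury classes,
informative features with class-specific mean shifts, per-plate batch
offsets, and deliberately broken feature columns (near-constant,
duplicated, high-missing) for the selection rules to find.
"""

from collections import Counter

from morphoscreen import ScreenDesign, generate_screen

design = ScreenDesign(
    n_plates=6,
    plate_rows=8,
    plate_cols=12,
    classes=("Cytoskeletal", "Hsp90", "Kinase"),
    treatments_per_class=12,
    seed=0,
)
profiles, platemap, truth = generate_screen(design)

print(f"profiles: {len(profiles)} wells x {len(profiles.feature_columns)} features")
print(f"plate map: {len(platemap)} entries, columns {list(platemap.data.columns)}")
print("wells per class:", dict(Counter(truth.well_classes.values())))
print("feature roles:", dict(Counter(truth.feature_roles.values())))

# Every number above is exact by construction: the class of every well and
# the role of every feature column are recorded in the returned GroundTruth,
# which is what lets downstream operations be tested without real data.
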