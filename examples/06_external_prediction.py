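"""Apply a trained injury model to an external screen matched by InChIKey.

An external dataset carries its own (superset) feature space and its own
compound identifiers; chemical identity is matched across datasets by
InChIKey.  The model's feature list is intersected with the external
features, the wells whose InChIKeys map to a known injury become ground
truth, and the classifier's per-well class probabilities are evaluated on
them.
"""

from morphoscreen import (
    ScreenDesign,
    SearchGrid,
    annotate,
    generate_external_screen,
    generate_screen,
    intersect_features,
    label_scheme,
    label_wells,
    match_treatments,
    predict_injury,
    split_train_test,
    train_classifier,
)

design = ScreenDesign(
    n_plates=8, plate_rows=8, plate_cols=12,
    classes=("Cytoskeletal", "Hsp90", "Kinase"), treatments_per_class=12,
    n_informative=40, n_near_constant=0, n_duplicated=0, n_high_missing=0,
    effect_size=3.0, seed=4,
)
profiles, platemap, truth = generate_screen(design)
annotated, _ = annotate(profiles, platemap)
scheme = label_scheme(truth)
labeled, _ = label_wells(annotated, scheme)
train, _ = split_train_test(labeled, seed=4)
bundle = train_classifier(train, SearchGrid(n_candidates=10), cv_folds=5, seed=4)

ext_design = ScreenDesign(
    n_plates=2, plate_rows=8, plate_cols=12,
    classes=design.classes, treatments_per_class=12,
    n_informative=40, n_near_constant=0, n_duplicated=0, n_high_missing=0,
    effect_size=3.0, nan_rate=0.0, seed=4,
)
external, ext_platemap, ext_truth = generate_external_screen(
    ext_design, scheme, overlap=24, injury_class="Cytoskeletal"
)

matched = match_treatments(scheme, ext_platemap, inchikey_column="inchikey")
print(f"external screen: {len(external)} wells, {len(external.feature_columns)} features")
print(f"{len(matched)} wells share cytoskeletal-injury InChIKeys with the model's catalog")

shared = intersect_features(bundle.shared_features, external.feature_columns)
print(f"feature intersection: {len(shared)} of {len(external.feature_columns)} external features")

proba = predict_injury(bundle, external.subset_features(shared))
by_well = proba.set_index(["Metadata_Plate", "Metadata_Well"])
overlap_wells = [k for k, c in ext_truth.well_classes.items() if c == "Cytoskeletal"]
hits = (by_well.loc[overlap_wells, "Metadata_predicted_injury"] == "Cytoskeletal").sum()
print(f"recovered {hits} of {len(overlap_wells)} ground-truth cytoskeletal wells")

# Probabilities per well sum to 1; the recovery count on the matched wells
# is the synthetic analog of validating a pre-trained model on an external
# public dataset it has never seen.
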