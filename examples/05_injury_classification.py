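"""Train and evaluate the cell-injury classifier on a synthetic screen.

The full demonstration pipeline: label wells from the compound catalog
(DMSO -> Control), carve out plate/treatment/well holdouts in that order,
split the remainder 80/20 stratified by class, train a class-weighted
multinomial logistic regression with a randomized hyperparameter search,
and evaluate every split against a shuffled-label baseline.
"""

from morphoscreen import (
    FeatureSelectionConfig,
    ScreenDesign,
    SearchGrid,
    annotate,
    apply_normalization,
    evaluate,
    feature_select,
    fit_normalization,
    generate_screen,
    label_scheme,
    label_wells,
    make_holdouts,
    split_train_test,
    train_classifier,
)

design = ScreenDesign(
    n_plates=12, plate_rows=8, plate_cols=12,
    classes=("Cytoskeletal", "Hsp90", "Kinase", "Genotoxin"),
    treatments_per_class=12, n_informative=40, n_near_constant=4,
    n_duplicated=4, n_high_missing=4, effect_size=3.0, seed=3,
)
profiles, platemap, truth = generate_screen(design)
annotated, _ = annotate(profiles, platemap)
labeled, n_excluded = label_wells(annotated, label_scheme(truth))
print(f"{len(labeled)} labeled wells ({n_excluded} without a known treatment)")

norm = fit_normalization(labeled, "mad_robustize", reference="Metadata_compound == 'DMSO'")
selected, _ = feature_select(apply_normalization(labeled, norm), FeatureSelectionConfig())

partition = make_holdouts(selected, n_plates=3, seed=3)
splits = partition.splits(selected)
train, test = split_train_test(splits.pop("modeling"), test_fraction=0.2, seed=3)
print("split sizes:", {"train": len(train), "test": len(test),
                       **{k: len(v) for k, v in splits.items()}})

bundle = train_classifier(train, SearchGrid(n_candidates=10), cv_folds=5, seed=3)
print(f"chosen hyperparameters: {bundle.hyperparameters} "
      f"(penalty {bundle.penalty}, cv macro-F1 {bundle.cv_score:.3f})")

report = evaluate(bundle, {"train": train, "test": test, **splits},
                  shuffled_baseline=True, seed=3)
for name in ("test", "plate_holdout", "treatment_holdout", "well_holdout"):
    f1 = report.macro_f1(name)
    null = report.macro_f1(name, shuffled=True)
    print(f"{name:18s} macro-F1 {f1:.3f}  (shuffled baseline {null:.3f})")

# Macro-F1 near 1 on every held-out split at effect size 3 SD, against a
# shuffled baseline near 1/n_classes, shows the classifier recovers the
# injected injury phenotypes rather than memorizing plates or treatments.
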