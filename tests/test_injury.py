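"""Labeling, holdouts, stratified splitting, training, evaluation, prediction."""

import numpy as np
import pandas as pd
import pytest

from morphoscreen import (
    EmptyResultError,
    INJURY_CLASSES,
    InjuryLabelScheme,
    InjuryModelBundle,
    PlateMap,
    ProfileTable,
    SearchGrid,
    ScreenDesign,
    ValidationError,
    annotate,
    evaluate,
    generate_external_screen,
    generate_screen,
    intersect_features,
    label_scheme,
    label_wells,
    make_holdouts,
    match_treatments,
    predict_injury,
    split_train_test,
    train_classifier,
)
from sklearn.linear_model import LogisticRegression


# ----------------------------------------------------------------------
# Feature intersection


def test_intersection_preserves_first_list_order():
    assert intersect_features(["A", "B", "C"], ["D", "C", "B"]) == ["B", "C"]


def test_intersection_of_identical_lists():
    assert intersect_features(["A", "B"], ["A", "B"]) == ["A", "B"]


def test_disjoint_intersection_rejected():
    with pytest.raises(EmptyResultError):
        intersect_features(["A"], ["B"])


# ----------------------------------------------------------------------
# Label scheme and labeling


def test_vocabulary_has_fifteen_classes():
    assert len(INJURY_CLASSES) == 15
    assert len(set(INJURY_CLASSES)) == 15
    assert "Control" in INJURY_CLASSES


def test_scheme_rejects_unknown_injury():
    with pytest.raises(ValidationError):
        InjuryLabelScheme(compound_to_injury={"x": "Sunburn"})


def test_scheme_rejects_noncontrol_control_compound():
    with pytest.raises(ValidationError):
        InjuryLabelScheme(
            compound_to_injury={"DMSO": "Kinase"}, control_compounds={"DMSO"}
        )


def _labeled_profiles():
    df = pd.DataFrame(
        {
            "Metadata_Plate": ["p1"] * 4,
            "Metadata_Well": ["A01", "A02", "A03", "A04"],
            "Metadata_compound": ["DMSO", "staur", "mystery", "tricho"],
            "F": [1.0, 2.0, 3.0, 4.0],
        }
    )
    scheme = InjuryLabelScheme(
        compound_to_injury={"staur": "Kinase", "tricho": "HDAC"}
    )
    return ProfileTable.from_dataframe(df), scheme


def test_dmso_labeled_control_and_unknown_excluded():
    table, scheme = _labeled_profiles()
    labeled, n_excluded = label_wells(table, scheme)
    assert n_excluded == 1
    got = labeled.data.set_index("Metadata_Well")["Metadata_injury"].to_dict()
    assert got == {"A01": "Control", "A02": "Kinase", "A04": "HDAC"}


def test_label_wells_errors_when_nothing_mappable():
    table, _ = _labeled_profiles()
    empty_scheme = InjuryLabelScheme(control_compounds=frozenset())
    with pytest.raises(EmptyResultError):
        label_wells(table, empty_scheme)


def test_synthetic_mapped_well_count(small_design):
    profiles, platemap, truth = generate_screen(small_design)
    annotated, _ = annotate(profiles, platemap)
    scheme = label_scheme(truth)
    # remove one compound from the scheme: its wells must drop out
    victim = next(iter(scheme.compound_to_injury))
    pruned = InjuryLabelScheme(
        compound_to_injury={
            c: i for c, i in scheme.compound_to_injury.items() if c != victim
        }
    )
    labeled, n_excluded = label_wells(annotated, pruned)
    n_victim = (annotated.data["Metadata_compound"] == victim).sum()
    assert n_excluded == n_victim
    assert len(labeled) == len(annotated) - n_victim


# ----------------------------------------------------------------------
# Holdouts


@pytest.fixture(scope="module")
def labeled_screen():
    design = ScreenDesign(
        n_plates=12, plate_rows=4, plate_cols=6,
        classes=("Cytoskeletal", "Hsp90", "Kinase"), treatments_per_class=12,
        n_informative=15, n_near_constant=0, n_duplicated=0, n_high_missing=0,
        effect_size=3.0, seed=31,
    )
    profiles, platemap, truth = generate_screen(design)
    annotated, _ = annotate(profiles, platemap)
    labeled, _ = label_wells(annotated, label_scheme(truth))
    return labeled


def test_partition_disjoint_and_exhaustive(labeled_screen):
    part = make_holdouts(labeled_screen, n_plates=3, seed=0)
    sets = [set(idx) for idx in part.as_dict().values()]
    union = set().union(*sets)
    assert len(union) == sum(len(s) for s in sets) == len(labeled_screen)
    assert len(part.held_plates) == 3


def test_small_injury_contributes_no_treatment_holdout(labeled_screen):
    # every injury has 12 treatments; min_treatments=20 disqualifies all
    part = make_holdouts(labeled_screen, n_plates=3, min_treatments=20, seed=0)
    assert len(part.treatment_holdout) == 0
    assert part.held_treatments == {}


def test_treatment_holdout_holds_out_whole_treatments(labeled_screen):
    part = make_holdouts(labeled_screen, n_plates=3, min_treatments=10, seed=0)
    assert set(part.held_treatments) == {"Cytoskeletal", "Hsp90", "Kinase"}
    df = labeled_screen.data
    held = {c for cs in part.held_treatments.values() for c in cs}
    on_kept_plates = df[~df["Metadata_Plate"].isin(part.held_plates)]
    expected = set(on_kept_plates.index[on_kept_plates["Metadata_compound"].isin(held)])
    assert set(part.treatment_holdout) == expected


def test_holdouts_deterministic_in_seed(labeled_screen):
    p1 = make_holdouts(labeled_screen, n_plates=3, seed=7)
    p2 = make_holdouts(labeled_screen, n_plates=3, seed=7)
    p3 = make_holdouts(labeled_screen, n_plates=3, seed=8)
    assert list(p1.modeling) == list(p2.modeling)
    assert p1.held_plates == p2.held_plates
    assert list(p1.modeling) != list(p3.modeling)


def test_too_few_plates_rejected(labeled_screen):
    with pytest.raises(ValidationError):
        make_holdouts(labeled_screen, n_plates=99)


def test_control_shortfall_recorded(labeled_screen):
    # demanding more controls per plate than exist logs a shortfall
    part = make_holdouts(
        labeled_screen, n_plates=3, control_wells_per_plate=50, seed=0
    )
    assert part.control_shortfalls
    assert all(v > 0 for v in part.control_shortfalls.values())


# ----------------------------------------------------------------------
# Stratified split


def test_split_sizes_ceiling_rule():
    rng = np.random.default_rng(0)
    labels = rng.choice(["a", "b", "c"], size=10, p=[0.4, 0.4, 0.2])
    df = pd.DataFrame({"Metadata_injury": ["a"] * 4 + ["b"] * 6, "F": np.arange(10.0)})
    table = ProfileTable.from_dataframe(df)
    train, test = split_train_test(table, test_fraction=0.2, seed=0)
    assert (len(train), len(test)) == (8, 2)
    assert train.data["Metadata_injury"].value_counts().to_dict() == {"b": 5, "a": 3}
    assert test.data["Metadata_injury"].value_counts().to_dict() == {"b": 1, "a": 1}


def test_split_proportions_within_one_well(labeled_screen):
    train, test = split_train_test(labeled_screen, test_fraction=0.2, seed=3)
    n = len(labeled_screen)
    for cls, total in labeled_screen.data["Metadata_injury"].value_counts().items():
        got = (test.data["Metadata_injury"] == cls).sum()
        expected = total * 0.2
        assert abs(got - expected) <= 1.0


def test_degenerate_split_fractions_rejected(labeled_screen):
    for frac in (0.0, 1.0, -0.1):
        with pytest.raises(ValidationError):
            split_train_test(labeled_screen, test_fraction=frac)


def test_singleton_class_named_in_error():
    df = pd.DataFrame(
        {"Metadata_injury": ["a", "a", "lonely"], "F": [1.0, 2.0, 3.0]}
    )
    with pytest.raises(ValidationError, match="lonely"):
        split_train_test(ProfileTable.from_dataframe(df))


# ----------------------------------------------------------------------
# Search grid


def test_grid_compatibility_enforced():
    SearchGrid.validate_combination("l1", "saga")
    with pytest.raises(ValidationError):
        SearchGrid.validate_combination("elasticnet", "lbfgs")
    with pytest.raises(ValidationError):
        SearchGrid.validate_combination("l1", "newton-cg")


def test_parameter_space_is_penalty_consistent():
    space = SearchGrid().parameter_space()
    assert len(space) == 3
    l1, l2, enet = space
    assert l1["l1_ratio"] == [1.0] and set(l1["solver"]) == {"liblinear", "saga"}
    assert l2["l1_ratio"] == [0.0] and len(l2["solver"]) == 5
    assert enet["solver"] == ["saga"] and len(enet["l1_ratio"]) == 5
    assert l2["C"] == [0.0001, 0.01, 0.1, 1.0, 10.0, 100.0]
    assert l2["tol"] == [1e-6, 1e-3]


# ----------------------------------------------------------------------
# Training


def _gaussian_classes(rng, n_per_class, effect, classes=("A", "B", "C"), n_feat=10):
    rows = []
    for k, cls in enumerate(classes):
        shift = np.zeros(n_feat)
        shift[k % n_feat] = effect
        x = rng.standard_normal((n_per_class, n_feat)) + shift
        frame = pd.DataFrame(x, columns=[f"F{i}" for i in range(n_feat)])
        frame.insert(0, "Metadata_injury", cls)
        rows.append(frame)
    return ProfileTable.from_dataframe(pd.concat(rows, ignore_index=True))


def test_separable_classes_recovered(rng):
    table = _gaussian_classes(rng, 60, effect=5.0)
    train, test = split_train_test(table, seed=0)
    bundle = train_classifier(train, SearchGrid(n_candidates=5), cv_folds=3, seed=0)
    report = evaluate(bundle, {"test": test})
    assert report.macro_f1("test") > 0.95


def test_permuted_labels_score_at_chance(rng):
    table = _gaussian_classes(rng, 60, effect=5.0)
    shuffled = table.copy()
    shuffled.data["Metadata_injury"] = rng.permutation(
        shuffled.data["Metadata_injury"].to_numpy()
    )
    train, test = split_train_test(shuffled, seed=0)
    bundle = train_classifier(train, SearchGrid(n_candidates=5), cv_folds=3, seed=0)
    report = evaluate(bundle, {"test": test})
    assert abs(report.macro_f1("test") - 1 / 3) <= 0.15


def test_single_class_rejected(rng):
    table = _gaussian_classes(rng, 20, effect=1.0, classes=("A",))
    with pytest.raises(ValidationError):
        train_classifier(table)


def test_missing_features_rejected(rng):
    table = _gaussian_classes(rng, 10, effect=1.0, classes=("A", "B"))
    table.data.iloc[0, table.data.columns.get_loc("F0")] = np.nan
    with pytest.raises(ValidationError, match="missing"):
        train_classifier(table, SearchGrid(n_candidates=2), cv_folds=2)


def test_class_weighting_lifts_minority_recall(rng):
    """On a 95/5 imbalanced overlapping problem, balanced class weights give
    strictly better minority recall than unweighted fitting (same data)."""
    n_feat = 4
    x_maj = rng.standard_normal((380, n_feat))
    x_min = rng.standard_normal((20, n_feat)) + 1.0
    x = np.vstack([x_maj, x_min])
    y = np.array(["maj"] * 380 + ["min"] * 20)
    xt_maj = rng.standard_normal((380, n_feat))
    xt_min = rng.standard_normal((20, n_feat)) + 1.0
    xt = np.vstack([xt_maj, xt_min])
    yt = np.array(["maj"] * 380 + ["min"] * 20)

    def minority_recall(weight):
        est = LogisticRegression(class_weight=weight, max_iter=500, random_state=0)
        est.fit(x, y)
        pred = est.predict(xt)
        return ((pred == "min") & (yt == "min")).sum() / 20

    assert minority_recall("balanced") > minority_recall(None)


def test_bundle_round_trip_preserves_predictions(tmp_path, rng):
    table = _gaussian_classes(rng, 30, effect=4.0)
    train, test = split_train_test(table, seed=0)
    bundle = train_classifier(train, SearchGrid(n_candidates=3), cv_folds=3, seed=0)
    bundle.save(tmp_path / "model")
    back = InjuryModelBundle.load(tmp_path / "model")
    p1 = predict_injury(bundle, test)
    p2 = predict_injury(back, test)
    prob_cols = [c for c in p1.columns if c.startswith("prob_")]
    np.testing.assert_allclose(p1[prob_cols].to_numpy(), p2[prob_cols].to_numpy())
    assert back.penalty in {"l1", "l2", "elasticnet"}


# ----------------------------------------------------------------------
# Evaluation


def _hand_bundle():
    """A 1-feature, 2-class model predicting B exactly when F > 0."""
    return InjuryModelBundle(
        classes=["A", "B"],
        coefficients=np.array([[50.0]]),
        intercepts=np.array([0.0]),
        hyperparameters={"solver": "lbfgs", "C": 1.0, "tol": 1e-4, "l1_ratio": 0.0},
        shared_features=["F"],
        seed=0,
        n_train=4,
        cv_score=1.0,
    )


def _split(values, labels):
    df = pd.DataFrame({"Metadata_injury": labels, "F": values})
    return ProfileTable.from_dataframe(df)


def test_hand_computed_precision_recall_f1():
    # truths [A,A,B,B], predictions [A,B,B,B]
    split = _split([-1.0, 1.0, 1.0, 1.0], ["A", "A", "B", "B"])
    report = evaluate(_hand_bundle(), {"test": split})
    row = report.metrics.set_index("class").loc["B"]
    assert row["precision"] == pytest.approx(2 / 3)
    assert row["recall"] == pytest.approx(1.0)
    assert row["f1"] == pytest.approx(0.8)


def test_perfect_predictions_are_diagonal():
    split = _split([-1.0, -1.0, 1.0], ["A", "A", "B"])
    report = evaluate(_hand_bundle(), {"test": split})
    cm = report.confusion["test"]
    assert (report.metrics["f1"] == 1.0).all()
    assert cm.to_numpy().sum() == np.trace(cm.to_numpy())


def test_all_wrong_predictions_score_zero():
    split = _split([1.0, -1.0], ["A", "B"])
    report = evaluate(_hand_bundle(), {"test": split})
    assert (report.metrics["f1"] == 0.0).all()


def test_confusion_rows_sum_to_true_counts():
    split = _split([-1.0, 1.0, 1.0, -1.0, 1.0], ["A", "A", "B", "B", "B"])
    report = evaluate(_hand_bundle(), {"test": split})
    cm = report.confusion["test"]
    truth_counts = split.data["Metadata_injury"].value_counts()
    for cls in ("A", "B"):
        assert cm.loc[cls].sum() == truth_counts[cls]


def test_shuffled_baseline_requires_train_split():
    split = _split([-1.0, 1.0], ["A", "B"])
    with pytest.raises(ValidationError, match="train"):
        evaluate(_hand_bundle(), {"test": split}, shuffled_baseline=True)


def test_shuffled_baseline_rows_flagged(rng):
    table = _gaussian_classes(rng, 40, effect=4.0)
    train, test = split_train_test(table, seed=0)
    bundle = train_classifier(train, SearchGrid(n_candidates=5), cv_folds=3, seed=0)
    report = evaluate(
        bundle, {"train": train, "test": test}, shuffled_baseline=True, seed=0
    )
    assert set(report.metrics["shuffled"].unique()) == {True, False}
    assert "test:shuffled" in report.confusion
    assert report.macro_f1("test") > report.macro_f1("test", shuffled=True)


# ----------------------------------------------------------------------
# Prediction and treatment matching


def test_probabilities_sum_to_one_and_are_deterministic(rng):
    table = _gaussian_classes(rng, 30, effect=3.0)
    train, _ = split_train_test(table, seed=0)
    bundle = train_classifier(train, SearchGrid(n_candidates=2), cv_folds=2, seed=0)
    # duplicate a well: identical probability rows
    two = ProfileTable(
        table.data.iloc[[0, 0]].reset_index(drop=True),
        table.metadata_columns,
        table.feature_columns,
    )
    proba = predict_injury(bundle, two)
    prob_cols = [c for c in proba.columns if c.startswith("prob_")]
    np.testing.assert_allclose(proba[prob_cols].sum(axis=1), 1.0, atol=1e-9)
    assert proba[prob_cols].iloc[0].tolist() == proba[prob_cols].iloc[1].tolist()


def test_predict_rejects_missing_model_features(rng):
    table = _gaussian_classes(rng, 30, effect=3.0)
    train, _ = split_train_test(table, seed=0)
    bundle = train_classifier(train, SearchGrid(n_candidates=2), cv_folds=2, seed=0)
    external = table.subset_features([f for f in table.feature_columns if f != "F0"])
    with pytest.raises(ValidationError, match="F0"):
        predict_injury(bundle, external)


def test_match_treatments_by_inchikey():
    scheme = InjuryLabelScheme(
        inchikey_to_injury={"KEY-AAA-N": "Cytoskeletal"},
    )
    pm = PlateMap(
        pd.DataFrame(
            {
                "plate": ["p1", "p1"],
                "well": ["A01", "A02"],
                "compound": ["x", "y"],
                "inchikey": ["KEY-AAA-N", "KEY-ZZZ-N"],
            }
        )
    )
    matched = match_treatments(scheme, pm)
    assert len(matched) == 1
    assert matched.loc[0, "injury"] == "Cytoskeletal"
    none = match_treatments(
        InjuryLabelScheme(inchikey_to_injury={}), pm
    )
    assert len(none) == 0


def test_external_screen_majority_predicted_as_cytoskeletal(small_design):
    profiles, platemap, truth = generate_screen(small_design)
    annotated, _ = annotate(profiles, platemap)
    scheme = label_scheme(truth)
    labeled, _ = label_wells(annotated, scheme)
    informative = [f for f, r in truth.feature_roles.items() if r == "informative"]
    train, _ = split_train_test(labeled.subset_features(informative), seed=0)
    bundle = train_classifier(train, SearchGrid(n_candidates=5), cv_folds=3, seed=0)

    ext_design = ScreenDesign(
        n_plates=2, plate_rows=4, plate_cols=6, classes=small_design.classes,
        treatments_per_class=small_design.treatments_per_class,
        n_informative=small_design.n_informative,
        n_near_constant=small_design.n_near_constant,
        n_duplicated=small_design.n_duplicated,
        n_high_missing=small_design.n_high_missing,
        effect_size=small_design.effect_size, nan_rate=0.0,
        seed=small_design.seed,
    )
    external, epm, etruth = generate_external_screen(ext_design, scheme, overlap=12)
    matched = match_treatments(scheme, epm, inchikey_column="inchikey")
    assert len(matched) == 12
    shared = intersect_features(bundle.shared_features, external.feature_columns)
    assert shared == bundle.shared_features
    proba = predict_injury(bundle, external.subset_features(shared))
    key = proba.set_index(["Metadata_Plate", "Metadata_Well"])
    overlap_wells = [k for k, c in etruth.well_classes.items() if c == "Cytoskeletal"]
    preds = key.loc[overlap_wells, "Metadata_predicted_injury"]
    assert (preds == "Cytoskeletal").mean() > 0.5
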