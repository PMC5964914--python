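import numpy as np
import pandas as pd
import pytest

from hornpred import (
    HornpredError,
    MarkerModelSpec,
    Pedigree,
    PredictionResult,
    RelationshipMatrix,
    accuracy,
    backsolve_marker_effects,
    build_grm,
    build_nrm,
    family_split,
    family_validation,
    gblup_predict,
    genomic_codings,
    kfold_cv,
    predict_marker_model,
)


# ---------------------------------------------------------------------------
# Accuracy
# ---------------------------------------------------------------------------


def test_accuracy_perfect_and_antiperfect():
    obs = np.array([0.0, 1.0, 1.0, 0.0, 1.0])
    assert accuracy(obs, obs)["pooled"] == pytest.approx(1.0)
    assert accuracy(1 - obs, obs)["pooled"] == pytest.approx(-1.0)


def test_accuracy_hand_computed_pair():
    pred = np.array([0.1, 0.9, 0.4, 0.6, 0.2])
    obs = np.array([0.0, 1.0, 0.0, 1.0, 0.0])
    expected = np.corrcoef(pred, obs)[0, 1]
    assert accuracy(pred, obs)["pooled"] == pytest.approx(expected, abs=1e-12)


def test_accuracy_undefined_cells_are_nan():
    # fewer than 3 pairs
    assert np.isnan(accuracy(np.array([0.1, 0.9]), np.array([0.0, 1.0]))["pooled"])
    # zero variance in the observed trait
    pred = np.array([0.1, 0.5, 0.9, 0.3])
    assert np.isnan(accuracy(pred, np.ones(4))["pooled"])


def test_accuracy_per_sex_split():
    pred = np.array([0.2, 0.8, 0.2, 0.3, 0.7, 0.3])
    obs = np.array([0.0, 1.0, 0.0, 0.0, 1.0, 0.0])
    sex = np.array(["female", "female", "female", "wether", "wether", "wether"],
                   dtype=object)
    out = accuracy(pred, obs, sex)
    assert out["female"] == pytest.approx(1.0)
    assert out["wether"] == pytest.approx(1.0)


def test_prediction_components_must_sum():
    with pytest.raises(ValueError, match="components"):
        PredictionResult(
            animal_ids=np.array(["a"], dtype=object),
            predicted=np.array([1.0]),
            components={"fixed": np.array([0.2])},
        )


# ---------------------------------------------------------------------------
# k-fold cross-validation
# ---------------------------------------------------------------------------


def _oracle_predictor(ids, y):
    lut = dict(zip(ids, y))

    def predict(train_ids, valid_ids):
        return np.array([lut[a] for a in valid_ids])

    return predict


def test_kfold_perfect_predictor_scores_one():
    rng = np.random.default_rng(0)
    n = 100
    ids = [f"a{i}" for i in range(n)]
    y = rng.integers(0, 2, size=n).astype(float)
    sex = np.array(["female"] * n, dtype=object)
    rep = kfold_cv(y, sex, ids, _oracle_predictor(ids, y), k=5, repeats=2, seed=1)
    accs = rep.folds.loc[rep.folds["sex"] == "female", "accuracy"]
    assert np.allclose(accs, 1.0)
    assert len(accs) == 10  # k x repeats fold cells


def test_kfold_partitions_cover_everything_evenly():
    n = 53  # not divisible by 5
    ids = [f"a{i}" for i in range(n)]
    seen = []

    def spy(train_ids, valid_ids):
        assert not set(train_ids) & set(valid_ids)
        assert len(train_ids) + len(valid_ids) == n
        seen.append(list(valid_ids))
        return np.zeros(len(valid_ids)) + np.arange(len(valid_ids)) * 1e-6

    kfold_cv(np.zeros(n), np.array(["female"] * n, dtype=object), ids, spy,
             k=5, repeats=1, seed=2)
    sizes = sorted(len(v) for v in seen)
    assert max(sizes) - min(sizes) <= 1
    assert sorted(sum(seen, [])) == sorted(ids)


def test_kfold_random_predictor_centres_at_zero():
    rng = np.random.default_rng(3)
    n = 400
    ids = [f"a{i}" for i in range(n)]
    y = rng.integers(0, 2, size=n).astype(float)
    sex = np.array(["female"] * n, dtype=object)

    def noise(train_ids, valid_ids):
        return np.random.default_rng(len(valid_ids) + len(train_ids)).normal(
            size=len(valid_ids)
        )

    rep = kfold_cv(y, sex, ids, noise, k=5, repeats=5, seed=4)
    summ = rep.summary()
    row = summ[summ["sex"] == "female"].iloc[0]
    assert abs(row["mean_accuracy"]) < 3 * row["se"] + 0.02


def test_kfold_deterministic_in_seed():
    n = 40
    ids = [f"a{i}" for i in range(n)]
    y = np.random.default_rng(5).integers(0, 2, size=n).astype(float)
    sex = np.array(["female"] * n, dtype=object)
    p = _oracle_predictor(ids, y)
    r1 = kfold_cv(y, sex, ids, p, k=4, repeats=2, seed=7)
    r2 = kfold_cv(y, sex, ids, p, k=4, repeats=2, seed=7)
    pd.testing.assert_frame_equal(r1.folds, r2.folds)


# ---------------------------------------------------------------------------
# Family splits
# ---------------------------------------------------------------------------


def _family_pedigree(sizes: dict[str, int]) -> tuple[Pedigree, list[str]]:
    rows = []
    kids = []
    for s in sizes:
        rows.append((s, None, None, "wether"))
    dam_i = 0
    for s, n in sizes.items():
        for j in range(n):
            d = f"dam{dam_i}"
            dam_i += 1
            rows.append((d, None, None, "female"))
            a = f"{s}_kid{j}"
            rows.append((a, s, d, "female" if j % 2 else "wether"))
            kids.append(a)
    ped = Pedigree(pd.DataFrame(rows, columns=["animal", "sire", "dam", "sex"]))
    return ped, kids


def test_across_family_splits_share_no_sires():
    ped, kids = _family_pedigree({f"s{i}": 20 for i in range(6)})
    splits = family_split(ped, kids, mode="across", n_folds=3, seed=0)
    sire_of = dict(zip(ped.table["animal"], ped.table["sire"]))
    for train, test in splits:
        assert not {sire_of[a] for a in train} & {sire_of[a] for a in test}
        assert sorted(train + test) == sorted(kids)


def test_within_family_splits_put_every_sire_on_both_sides():
    ped, kids = _family_pedigree({f"s{i}": 21 for i in range(4)})
    splits = family_split(ped, kids, mode="within", n_folds=2, seed=1)
    sire_of = dict(zip(ped.table["animal"], ped.table["sire"]))
    for train, test in splits:
        tr_s = {sire_of[a] for a in train}
        te_s = {sire_of[a] for a in test}
        assert tr_s == te_s == {f"s{i}" for i in range(4)}
        # odd family sizes resolve toward training: 11 train / 10 test each
        assert len(train) == 4 * 11
        assert len(test) == 4 * 10


def test_family_size_threshold_is_strictly_greater():
    ped, kids = _family_pedigree({"s_small": 13, "s_big": 14})
    splits = family_split(ped, kids, mode="across", min_offspring=13,
                          n_folds=1, seed=0)
    train, test = splits[0]
    used = set(train) | set(test)
    assert all(a.startswith("s_big") for a in used)
    assert len(used) == 14


def test_no_eligible_families_errors():
    ped, kids = _family_pedigree({"s0": 5, "s1": 8})
    with pytest.raises(HornpredError, match="more than 13"):
        family_split(ped, kids, mode="within")


def test_family_validation_scores_test_side_only():
    ped, kids = _family_pedigree({f"s{i}": 16 for i in range(4)})
    y = np.array([float(a.endswith("0")) for a in kids])
    sex = ped.sex_of(kids)
    splits = family_split(ped, kids, mode="across", n_folds=2, seed=3)
    rep = family_validation(y, sex, kids, _oracle_predictor(kids, y), splits,
                            scheme_name="across")
    assert set(rep.folds["fold"]) == {0, 1}
    accs = rep.folds["accuracy"].dropna()
    assert np.allclose(accs, 1.0)


# ---------------------------------------------------------------------------
# Leakage
# ---------------------------------------------------------------------------


def _marker_setup(small_bundle, n=400):
    b = small_bundle
    ids = b["ids"][:n]
    y = b["pnp"][:n].copy()
    sex = b["sex"][:n]
    dosage = b["causal"][:n].astype(float)
    return ids, y, sex, dosage


def test_marker_prediction_blind_to_validation_phenotypes(small_bundle):
    ids, y, sex, dosage = _marker_setup(small_bundle)
    train, valid = ids[:300], ids[300:]
    spec = MarkerModelSpec(kind="single", marker_id="causal", model_id=2,
                           dosage=dosage)
    p1 = predict_marker_model(spec, y, sex, ids, train, valid)
    y2 = y.copy()
    y2[300:] = 0.0  # censor validation phenotypes entirely
    p2 = predict_marker_model(spec, y2, sex, ids, train, valid)
    assert np.array_equal(p1.predicted, p2.predicted)  # bit-identical


def test_gblup_blind_to_validation_phenotypes(small_bundle):
    b = small_bundle
    n = 300
    ids = b["ids"][:n]
    geno = b["geno"].subset(animals=ids)
    y = b["pnp"][:n].copy()
    sex = b["sex"][:n]
    G = build_grm(geno)
    cod = genomic_codings(geno)
    train, valid = ids[:220], ids[220:]
    p1 = gblup_predict(y, sex, ids, train, valid, G, codings=cod)
    y2 = y.copy()
    y2[220:] = 1.0 - y2[220:]
    p2 = gblup_predict(y2, sex, ids, train, valid, G, codings=cod)
    assert np.array_equal(p1.predicted, p2.predicted)


# ---------------------------------------------------------------------------
# GBLUP routes and back-solving
# ---------------------------------------------------------------------------


def test_covariance_and_backsolve_routes_agree(small_bundle):
    b = small_bundle
    n = 300
    ids = b["ids"][:n]
    geno = b["geno"].subset(animals=ids)
    y = b["pnp"][:n]
    sex = b["sex"][:n]
    G = build_grm(geno)
    cod = genomic_codings(geno)
    train, valid = ids[:240], ids[240:]
    pa = gblup_predict(y, sex, ids, train, valid, G, route="covariance", codings=cod)
    pb = gblup_predict(y, sex, ids, train, valid, G, route="backsolve", codings=cod)
    np.testing.assert_allclose(pa.predicted, pb.predicted, atol=1e-6)


def test_backsolve_reconstructs_genomic_values(small_bundle):
    b = small_bundle
    ids = b["ids"][:150]
    geno = b["geno"].subset(animals=ids)
    G = build_grm(geno)
    cod = genomic_codings(geno)
    rng = np.random.default_rng(6)
    gebv = cod["W"] @ rng.normal(size=cod["W"].shape[1]) * 0.1
    eff = backsolve_marker_effects(gebv, cod["W"], G)
    # reconstruction is exact up to the stabilising ridge in the G inverse
    np.testing.assert_allclose(cod["W"] @ eff, gebv, atol=1e-4)
    # null genomic values back-solve to null effects
    assert np.abs(backsolve_marker_effects(np.zeros(len(ids)), cod["W"], G)).max() == 0.0


def test_backsolve_dimension_and_kind_errors(small_bundle, trio_pedigree):
    b = small_bundle
    ids = b["ids"][:50]
    geno = b["geno"].subset(animals=ids)
    G = build_grm(geno)
    cod = genomic_codings(geno)
    with pytest.raises(HornpredError, match="dimensions"):
        backsolve_marker_effects(np.zeros(49), cod["W"], G)
    A = build_nrm(trio_pedigree)
    with pytest.raises(HornpredError, match="scale constant"):
        backsolve_marker_effects(np.zeros(3), np.zeros((3, 2)), A)


def test_genomic_codings_reproduce_relationship_matrices(small_bundle):
    b = small_bundle
    geno = b["geno"].subset(animals=b["ids"][:100])
    G = build_grm(geno)
    cod = genomic_codings(geno)
    np.testing.assert_allclose(cod["W"] @ cod["W"].T / cod["c_a"], G.values, atol=1e-9)
    assert cod["c_a"] == pytest.approx(G.scale_c)


def test_unrelated_validation_animals_get_zero_polygenic():
    rng = np.random.default_rng(7)
    n_tr, n_va = 30, 5
    ids = [f"t{i}" for i in range(n_tr)] + [f"v{i}" for i in range(n_va)]
    V = np.zeros((n_tr + n_va, n_tr + n_va))
    B = rng.normal(size=(n_tr, n_tr))
    V[:n_tr, :n_tr] = B @ B.T / n_tr + np.eye(n_tr)
    V[n_tr:, n_tr:] = np.eye(n_va)  # zero covariance with training
    K = RelationshipMatrix(kind="pedigree_A", labels=np.array(ids, dtype=object),
                           values=V)
    y = rng.integers(0, 2, size=n_tr + n_va).astype(float)
    sex = np.array(["female", "wether"] * ((n_tr + n_va) // 2) + ["female"],
                   dtype=object)[: n_tr + n_va]
    dosage = rng.integers(0, 3, size=n_tr + n_va).astype(float)
    spec = MarkerModelSpec(kind="single", dosage=dosage)
    p = predict_marker_model(spec, y, sex, ids, ids[:n_tr], ids[n_tr:],
                             polygenic=K)
    np.testing.assert_array_equal(p.components["polygenic"], np.zeros(n_va))


def test_haplotype_design_matches_single_snp_closely(small_bundle):
    # a two-class haplotype design at one SNP spans the same column space as
    # the dosage plus an intercept; predictions should agree almost exactly
    ids, y, sex, dosage = _marker_setup(small_bundle)
    train, valid = ids[:300], ids[300:]
    H = np.column_stack([2.0 - dosage, dosage])
    p_hap = predict_marker_model(
        MarkerModelSpec(kind="haplotype", hap_design=H), y, sex, ids, train, valid
    )
    p_snp = predict_marker_model(
        MarkerModelSpec(kind="single", dosage=dosage, model_id=1),
        y, sex, ids, train, valid,
    )
    r = np.corrcoef(p_hap.predicted, p_snp.predicted)[0, 1]
    assert r > 0.999
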