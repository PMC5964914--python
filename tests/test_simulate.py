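import numpy as np
import pandas as pd
import pytest

from hornpred import (
    HornpredError,
    PenetranceModel,
    SimConfig,
    TagSpec,
    build_grm,
    hill_robertson_r2max,
    simulate_study,
)
from hornpred.simulate import (
    gene_drop,
    simulate_founder_haplotypes,
    simulate_pedigree,
    simulate_polygenic_values,
)


def _pool_r2(pool, id_a, id_b):
    ja = int(np.flatnonzero(pool.marker_ids == id_a)[0])
    jb = int(np.flatnonzero(pool.marker_ids == id_b)[0])
    a = pool.haplotypes[:, ja].astype(float)
    b = pool.haplotypes[:, jb].astype(float)
    return float(np.corrcoef(a, b)[0, 1] ** 2)


# ---------------------------------------------------------------------------
# Determinism and structural invariants
# ---------------------------------------------------------------------------


def test_same_seed_is_bit_identical():
    a = simulate_study(SimConfig(seed=5, n_sires=10))
    b = simulate_study(SimConfig(seed=5, n_sires=10))
    np.testing.assert_array_equal(a.genotypes.dosage, b.genotypes.dosage)
    np.testing.assert_array_equal(a.genotypes.hap1, b.genotypes.hap1)
    pd.testing.assert_frame_equal(a.phenotypes.table, b.phenotypes.table)
    pd.testing.assert_frame_equal(a.pedigree.table, b.pedigree.table)
    assert a.true_polygenic == b.true_polygenic


def test_seed_is_mandatory():
    with pytest.raises(ValueError, match="seed"):
        simulate_study(SimConfig(n_sires=5))


def test_phase_sums_to_dosage(small_study):
    g = small_study.genotypes
    np.testing.assert_array_equal(g.hap1 + g.hap2, g.dosage.astype(np.int8))


def test_zero_polygenic_variance_gives_zero_values():
    study = simulate_study(SimConfig(seed=3, n_sires=10, sigma2_a=0.0))
    assert all(v == 0.0 for v in study.true_polygenic.values())


def test_causal_marker_present_exactly_once(small_study):
    hits = [m for m in small_study.genotypes.marker_ids if m == small_study.causal_id]
    assert len(hits) == 1


# ---------------------------------------------------------------------------
# Founder LD calibration
# ---------------------------------------------------------------------------


def test_zero_switch_rate_gives_perfect_ld():
    cfg = SimConfig(
        seed=1,
        switch_rate=0.0,
        causal_freq=0.3,
        tags=(TagSpec("t1", 29_458_450, 1.0, freq=0.3),),
        n_background_markers=0,
    )
    pool = simulate_founder_haplotypes(cfg, 1, n_haplotypes=4000)
    assert _pool_r2(pool, cfg.causal_id, "t1") == pytest.approx(1.0, abs=1e-12)


def test_half_switch_rate_decorrelates_adjacent_markers():
    cfg = SimConfig(seed=1, switch_rate=0.5, n_background_markers=0)
    pool = simulate_founder_haplotypes(cfg, 2, n_haplotypes=10_000)
    r2 = _pool_r2(pool, pool.marker_ids[0], pool.marker_ids[1])
    assert r2 < 0.01


def test_target_r2_realized_within_tolerance():
    cfg = SimConfig(
        seed=1,
        causal_freq=0.3,
        tags=(TagSpec("t1", 29_458_450, 0.985, freq=0.3),),
        n_background_markers=0,
    )
    pool = simulate_founder_haplotypes(cfg, 3, n_haplotypes=10_000)
    assert _pool_r2(pool, cfg.causal_id, "t1") == pytest.approx(0.985, abs=0.01)


def test_unreachable_ld_target_cites_bound():
    cfg = SimConfig(
        seed=1,
        causal_freq=0.3,
        tags=(TagSpec("t1", 29_458_450, 0.985, freq=0.05),),
        n_background_markers=0,
    )
    with pytest.raises(HornpredError, match="r2max"):
        simulate_founder_haplotypes(cfg, 1, n_haplotypes=100)


def test_hill_robertson_bound_examples():
    assert hill_robertson_r2max(0.3, 0.3) == pytest.approx(1.0)
    # p=0.1 vs q=0.5: bound = 0.1*0.5 / (0.5*0.9)
    assert hill_robertson_r2max(0.1, 0.5) == pytest.approx(0.1 * 0.5 / (0.5 * 0.9))


def test_higher_target_never_lowers_realized_r2():
    realized = []
    for target in (0.5, 0.985):
        vals = []
        for seed in range(5):
            cfg = SimConfig(
                seed=1,
                causal_freq=0.3,
                tags=(TagSpec("t1", 29_458_450, target, freq=0.3),),
                n_background_markers=0,
            )
            pool = simulate_founder_haplotypes(cfg, seed, n_haplotypes=3000)
            vals.append(_pool_r2(pool, cfg.causal_id, "t1"))
        realized.append(np.mean(vals))
    assert realized[1] >= realized[0]


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


def test_family_sizes_and_dam_reuse():
    cfg = SimConfig(seed=9, n_sires=60)
    ped = simulate_pedigree(cfg, 9)
    fam = ped.offspring_by_sire()
    assert len(fam) == 60
    sizes = [len(v) for v in fam.values()]
    assert min(sizes) >= 1 and max(sizes) <= 51
    offspring = ped.table[ped.table["sire"].notna()]
    per_dam = offspring.groupby("dam").size()
    assert per_dam.mean() == pytest.approx(1.5, abs=0.1)


def test_sex_ratio_matches_configuration():
    cfg = SimConfig(seed=2, n_sires=182, female_prop=0.5)
    ped = simulate_pedigree(cfg, 2)
    offspring = ped.table[ped.table["sire"].notna()]
    frac = (offspring["sex"] == "female").mean()
    assert 0.45 <= frac <= 0.55


def test_single_sire_family_is_half_sib():
    cfg = SimConfig(seed=4, n_sires=1, offspring_range=(10, 10))
    ped = simulate_pedigree(cfg, 4)
    fam = ped.offspring_by_sire()
    assert len(fam) == 1
    assert len(next(iter(fam.values()))) == 10


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------


def test_no_recombination_copies_a_parental_haplotype():
    cfg = SimConfig(seed=6, n_sires=5, recomb_rate=0.0, n_background_markers=0)
    study = simulate_study(cfg)
    g = study.genotypes
    ped = study.pedigree.table.set_index("animal")
    lut = {a: i for i, a in enumerate(g.animal_ids)}
    checked = 0
    for a in study.study_animals[:50]:
        i = lut[a]
        si = lut[ped.loc[a, "sire"]]
        parental = [g.hap1[si], g.hap2[si]]
        assert any(np.array_equal(g.hap1[i], h) for h in parental)
        checked += 1
    assert checked > 0


def test_parent_offspring_genomic_relationship_near_half(small_study):
    g = small_study.genotypes
    G = build_grm(g)
    lut = {a: i for i, a in enumerate(G.labels)}
    ped = small_study.pedigree.table
    pairs = [
        (lut[a], lut[s])
        for a, s in zip(ped["animal"], ped["sire"])
        if s is not None
    ]
    vals = [G.values[i, j] for i, j in pairs]
    assert np.mean(vals) == pytest.approx(0.5, abs=0.1)


def test_single_known_parent_rejected(small_study, trio_pedigree):
    import pandas as pd

    from hornpred import Pedigree

    bad = Pedigree(
        pd.DataFrame(
            {
                "animal": ["s1", "o1"],
                "sire": [None, "s1"],
                "dam": [None, "ghost"],
                "sex": ["wether", "female"],
            }
        )
    )
    cfg = SimConfig(seed=1, n_background_markers=0)
    pool = simulate_founder_haplotypes(cfg, 1, n_haplotypes=10)
    with pytest.raises(HornpredError, match="one parent"):
        gene_drop(bad, pool, 0.0, 1)


# ---------------------------------------------------------------------------
# Phenotype assignment
# ---------------------------------------------------------------------------


def test_fully_penetrant_polled_gives_constant_trait():
    pen = PenetranceModel.uniform((1.0, 0.0, 0.0))
    study = simulate_study(SimConfig(seed=8, n_sires=10, penetrance=pen))
    assert set(study.phenotypes.table["horn_score"]) == {"polled"}
    assert study.phenotypes.trait("pnp").var() == 0.0


def test_male_horned_fractions_match_penetrance():
    # no polygenic shift so class fractions are exactly the penetrance
    study = simulate_study(SimConfig(seed=12, sigma2_a=0.0))
    ids = list(study.study_animals)
    sex = study.pedigree.sex_of(ids)
    g = study.causal_genotype()
    hnh = study.phenotypes.trait("hnh")
    expected = {0: 472 / 700, 1: 9 / 728, 2: 0.0}
    for cls, p in expected.items():
        m = (sex == "wether") & (g == cls)
        n = int(m.sum())
        assert n > 100
        frac = hnh[m].mean()
        tol = 4 * np.sqrt(max(p * (1 - p), 1e-4) / n)
        assert frac == pytest.approx(p, abs=tol)


def test_male_polled_fractions_match_penetrance():
    study = simulate_study(SimConfig(seed=12, sigma2_a=0.0))
    ids = list(study.study_animals)
    sex = study.pedigree.sex_of(ids)
    g = study.causal_genotype()
    polled = 1.0 - study.phenotypes.trait("pnp")
    expected = {0: 29 / 704, 1: 385 / 725, 2: 97 / 124}
    for cls, p in expected.items():
        m = (sex == "wether") & (g == cls)
        n = int(m.sum())
        frac = polled[m].mean()
        tol = 4 * np.sqrt(p * (1 - p) / n)
        assert frac == pytest.approx(p, abs=tol)


def test_polygenic_values_follow_pedigree_recursion():
    cfg = SimConfig(seed=7, n_sires=10)
    ped = simulate_pedigree(cfg, 7)
    u = simulate_polygenic_values(ped, 0.5, 7)
    vals = np.array(list(u.values()))
    assert np.std(vals) > 0
    # offspring values correlate with mid-parent
    t = ped.table[ped.table["sire"].notna()]
    kid = np.array([u[a] for a in t["animal"]])
    mid = np.array([0.5 * (u[s] + u[d]) for s, d in zip(t["sire"], t["dam"])])
    assert np.corrcoef(kid, mid)[0, 1] > 0.5
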