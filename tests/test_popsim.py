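"""Population simulator: crossing, meiosis, advancement, traits, masking."""
import numpy as np
import pandas as pd
import pytest

import crossgp as cg
from crossgp import popsim
from crossgp.popsim import (
    Population,
    SimConfig,
    advance,
    make_cross,
    make_ril_population,
    mask_genotypes,
    meiosis,
    simulate_trait,
)


# --- configuration ----------------------------------------------------------


@pytest.mark.parametrize(
    "field,value",
    [
        ("n_f2", 0),
        ("n_chromosomes", -1),
        ("prop_dominant", 1.5),
        ("h2", -0.1),
        ("missing_rate", 1.0),
        ("chrom_length", 0.0),
        ("major_gene", ("C01", 500.0, 1.0)),
    ],
)
def test_config_validation_names_field(field, value):
    with pytest.raises(ValueError, match=field.split("_")[0]):
        SimConfig(**{field: value})


# --- crossing ---------------------------------------------------------------


def test_parents_inbred_and_divergent_f1_heterozygous():
    pop = make_cross(SimConfig(n_chromosomes=2, n_markers=10, n_f2=20, seed=1))
    p1 = pop.of_generation("P1")[0].haplotypes
    p2 = pop.of_generation("P2")[0].haplotypes
    f1 = pop.of_generation("F1")[0].haplotypes
    assert (p1[0] == p1[1]).all() and (p2[0] == p2[1]).all()
    assert (p1[0] != p2[0]).all()  # opposite at every locus
    assert (f1[0] != f1[1]).all()  # F1 heterozygous throughout


def test_f2_count_and_unique_lineages():
    pop = make_cross(SimConfig(seed=3))  # default n_f2 = 194
    f2 = pop.of_generation("F2")
    assert len(f2) == 194
    lineages = {ind.lineage for ind in f2}
    assert len(lineages) == 194


def test_f2_heterozygosity_near_half():
    pop = make_cross(SimConfig(n_chromosomes=5, n_markers=20, n_f2=500, seed=11))
    f2 = Population(pop.of_generation("F2"), pop.gmap)
    assert f2.heterozygosity() == pytest.approx(0.5, abs=0.02)


# --- meiosis ----------------------------------------------------------------


def test_meiosis_haldane_recombination(two_locus_map, rng):
    """Observed recombinant fraction at 10 cM matches 0.5(1-e^-0.2)."""
    parent = np.array([[0, 0], [1, 1]], dtype=np.uint8)  # fully phased het
    n = 10_000
    gametes = np.stack([meiosis(parent, two_locus_map, rng) for _ in range(n)])
    recombinant = (gametes[:, 0] != gametes[:, 1]).mean()
    expected = 0.5 * (1 - np.exp(-2 * 10 / 100))  # 0.0906
    assert recombinant == pytest.approx(expected, abs=0.01)


def test_meiosis_zero_distance_never_recombines(rng):
    gmap = pd.DataFrame(
        {"marker": ["a", "b"], "chrom": ["C01", "C01"], "pos_cm": [5.0, 5.0]}
    )
    parent = np.array([[0, 0], [1, 1]], dtype=np.uint8)
    gametes = np.stack([meiosis(parent, gmap, rng) for _ in range(500)])
    assert (gametes[:, 0] == gametes[:, 1]).all()


def test_meiosis_unlinked_chromosomes_half(rng):
    gmap = pd.DataFrame(
        {"marker": ["a", "b"], "chrom": ["C01", "C02"], "pos_cm": [0.0, 0.0]}
    )
    parent = np.array([[0, 0], [1, 1]], dtype=np.uint8)
    gametes = np.stack([meiosis(parent, gmap, rng) for _ in range(10_000)])
    assert (gametes[:, 0] != gametes[:, 1]).mean() == pytest.approx(0.5, abs=0.02)


def test_meiosis_rejects_unsorted_map(rng):
    gmap = pd.DataFrame(
        {"marker": ["a", "b"], "chrom": ["C01", "C01"], "pos_cm": [10.0, 0.0]}
    )
    parent = np.array([[0, 0], [1, 1]], dtype=np.uint8)
    with pytest.raises(ValueError, match="sorted"):
        meiosis(parent, gmap, rng)


# --- advancement ------------------------------------------------------------


@pytest.fixture(scope="module")
def f2_500():
    cfg = SimConfig(n_chromosomes=2, n_markers=25, n_f2=500, seed=5)
    pop = make_cross(cfg)
    return Population(pop.of_generation("F2"), pop.gmap), cfg


def test_heterozygosity_decay_f3(f2_500, rng):
    f2, _ = f2_500
    f3 = advance(f2, "ssd", "F3", rng=rng)
    assert f3.heterozygosity() == pytest.approx(0.25, abs=0.02)


def test_heterozygosity_decay_f7(f2_500, rng):
    f2, _ = f2_500
    f7 = advance(f2, "ssd", "F7", rng=rng)
    assert f7.heterozygosity() == pytest.approx(0.5**6, abs=0.01)


def test_ssd_preserves_lines_and_lineages(f2_500, rng):
    f2, _ = f2_500
    f7 = advance(f2, "ssd", "F7", rng=rng)
    assert len(f7.individuals) == len(f2.individuals)
    assert {i.lineage for i in f7.individuals} == {i.lineage for i in f2.individuals}


def test_self_bulk_family_sizes(f2_500, rng):
    f2, _ = f2_500
    f3 = advance(f2, "ssd", "F3", rng=rng)
    fam = advance(
        Population(f2.individuals[:10], f2.gmap), "self_bulk", "F4",
        sibs_per_family=6, rng=rng,
    )
    sizes = pd.Series([i.lineage for i in fam.individuals]).value_counts()
    assert (sizes == 6).all()
    assert f3.latest_generation() == "F3"


def test_advance_rejects_bad_target(f2_500, rng):
    f2, _ = f2_500
    with pytest.raises(ValueError, match="not supported"):
        advance(f2, "ssd", "F12", rng=rng)
    with pytest.raises(ValueError, match="not after"):
        advance(f2, "ssd", "F2", rng=rng)


def test_ril_lineage_closure(small_dataset):
    """Every RIL resolves to exactly one F2 lineage; families partition RILs."""
    f2_lineages = {i.lineage for i in small_dataset.f2.individuals}
    ril_lineages = [i.lineage for i in small_dataset.ril.individuals]
    assert set(ril_lineages) <= f2_lineages
    assert len(small_dataset.ril.individuals) == small_dataset.config.n_ril
    # partition: each RIL counted once across families
    counts = pd.Series(ril_lineages).value_counts()
    assert counts.sum() == small_dataset.config.n_ril


def test_ril_expansion_uses_distinct_extra_lineages():
    cfg = SimConfig(n_chromosomes=2, n_markers=10, n_f2=50, n_ril=60, seed=9)
    pop = make_cross(cfg)
    ril = make_ril_population(pop, cfg, np.random.default_rng(1))
    counts = pd.Series([i.lineage for i in ril.individuals]).value_counts()
    assert (counts <= 2).all()  # 10 extras land in 10 distinct lineages
    assert (counts == 2).sum() == 10


# --- segregation ------------------------------------------------------------


def test_mendelian_segregation_1_2_1():
    """Aggregate F2 codominant class counts fit 1:2:1 (chi-square p > 0.001).

    One locus per chromosome so the per-locus statistics are independent
    and their sum is chi-square calibrated.
    """
    cfg = SimConfig(
        n_chromosomes=100, n_markers=1, n_f2=500, prop_dominant=0.0, seed=13
    )
    ds = cg.simulate_dataset(cfg)
    from crossgp.markers import segregation_chisq

    chi2, p = segregation_chisq(ds.genotypes_f2, ds.marker_map)
    assert p > 0.001


# --- markers ----------------------------------------------------------------


def test_dominant_collapse_hides_heterozygote(small_dataset):
    """At a dominant locus the het call equals the detectable homozygote class."""
    gmap = small_dataset.marker_map
    dom = gmap[gmap["type"] == "dominant"]
    calls = small_dataset.calls_f2
    for _, row in dom.head(20).iterrows():
        col = calls[row["marker"]]
        expected = {"AA/AB", "BB"} if row["dominant_phase"] == "A" else {"AA", "AB/BB"}
        assert set(col.unique()) <= expected


def test_prop_dominant_binomial():
    cfg = SimConfig(n_chromosomes=4, n_markers=100, prop_dominant=0.75, seed=21)
    pop = make_cross(cfg)
    f2 = Population(pop.of_generation("F2"), pop.gmap)
    _, gmap = popsim.ascertain_markers(f2, cfg, np.random.default_rng(3))
    n_dom = (gmap["type"] == "dominant").sum()
    # binomial(400, 0.75): 300 +/- 4 sd
    assert abs(n_dom - 300) < 4 * np.sqrt(400 * 0.75 * 0.25)


# --- traits -----------------------------------------------------------------


def test_h2_one_phenotype_equals_breeding_value(rng):
    cfg = SimConfig(
        n_chromosomes=2, n_markers=20, n_f2=50, n_qtl=10, h2=1.0,
        n_environments=1, env_var_fraction=0.0, seed=2,
    )
    pop = make_cross(cfg)
    f2 = Population(pop.of_generation("F2"), pop.gmap)
    pheno, _ = simulate_trait(f2, cfg, rng)
    y = cg.phenotype_means(pheno)
    assert np.allclose(y.sort_index(), f2.true_bv.sort_index())


def test_h2_calibration_variance_ratio(rng):
    cfg = SimConfig(
        n_chromosomes=2, n_markers=30, n_f2=2000, n_qtl=30, h2=0.5, seed=4
    )
    pop = make_cross(cfg)
    f2 = Population(pop.of_generation("F2"), pop.gmap)
    pheno, _ = simulate_trait(f2, cfg, rng)
    y = cg.phenotype_means(pheno)
    ratio = f2.true_bv.var() / y.var()
    assert ratio == pytest.approx(0.5, abs=0.05)


def test_major_gene_classes(rng):
    effect = 3.0
    cfg = SimConfig(
        n_chromosomes=2, n_markers=10, n_f2=60, n_qtl=0, h2=1.0,
        n_environments=1, major_gene=("C01", 50.0, effect), seed=6,
    )
    pop = make_cross(cfg)
    f2 = Population(pop.of_generation("F2"), pop.gmap)
    pheno, _ = simulate_trait(f2, cfg, rng)
    values = np.sort(cg.phenotype_means(pheno).unique())
    assert set(np.round(values, 9)) <= {-effect, 0.0, effect}


def test_h2_zero_is_pure_noise(rng):
    cfg = SimConfig(
        n_chromosomes=2, n_markers=10, n_f2=200, n_qtl=5, h2=0.0, seed=8
    )
    pop = make_cross(cfg)
    f2 = Population(pop.of_generation("F2"), pop.gmap)
    pheno, _ = simulate_trait(f2, cfg, rng)
    y = cg.phenotype_means(pheno)
    assert abs(np.corrcoef(y.sort_index(), f2.true_bv.sort_index())[0, 1]) < 0.2


def test_h2_zero_without_residual_errors(rng):
    cfg = SimConfig(
        n_chromosomes=2, n_markers=10, n_f2=50, n_qtl=5, h2=0.0,
        env_var_fraction=1.0, seed=8,
    )
    pop = make_cross(cfg)
    f2 = Population(pop.of_generation("F2"), pop.gmap)
    with pytest.raises(ValueError, match="residual"):
        simulate_trait(f2, cfg, rng)


def test_family_unit_returns_lineage_means(rng):
    cfg = SimConfig(
        n_chromosomes=2, n_markers=10, n_f2=30, n_qtl=10, h2=0.8,
        sibs_per_family=4, seed=10,
    )
    pop = make_cross(cfg)
    f2 = Population(pop.of_generation("F2"), pop.gmap)
    f4 = advance(f2, "self_bulk", "F4", sibs_per_family=4, rng=rng)
    pheno, _ = simulate_trait(f4, cfg, rng, unit="family")
    assert set(pheno["line"]) == {i.lineage for i in f2.individuals}


# --- masking ----------------------------------------------------------------


def test_mask_rate_zero_is_identity(f2_matrix, rng):
    gm, _ = f2_matrix
    masked, mask = mask_genotypes(gm, 0.0, rng)
    pd.testing.assert_frame_equal(masked, gm)
    assert len(mask) == 0


def test_mask_exact_floor_count(rng):
    gm = pd.DataFrame(
        np.ones((20, 50)), index=[f"L{i}" for i in range(20)],
        columns=[f"M{j}" for j in range(50)],
    )
    masked, mask = mask_genotypes(gm, 0.1, rng)
    assert len(mask) == 100  # floor(0.1 * 1000)
    assert int(masked.isna().sum().sum()) == 100


def test_mask_only_observed_cells(rng):
    gm = pd.DataFrame(np.ones((10, 10)), index=list("abcdefghij"))
    gm.iloc[0, :5] = np.nan
    masked, mask = mask_genotypes(gm, 0.2, rng)
    for line, marker in mask.itertuples(index=False):
        assert not np.isnan(gm.loc[line, marker])


def test_mask_rejects_rate_one(f2_matrix, rng):
    gm, _ = f2_matrix
    with pytest.raises(ValueError, match="rate"):
        mask_genotypes(gm, 1.0, rng)


# --- determinism ------------------------------------------------------------


def test_simulation_is_seed_deterministic(small_config):
    a = cg.simulate_dataset(small_config)
    b = cg.simulate_dataset(small_config)
    pd.testing.assert_frame_equal(a.genotypes_f2, b.genotypes_f2)
    pd.testing.assert_frame_equal(a.genotypes_ril, b.genotypes_ril)
    pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
    pd.testing.assert_frame_equal(a.lineage, b.lineage)
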