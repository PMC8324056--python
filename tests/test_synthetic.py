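"""Synthetic dataset generator: construction guarantees, colonization
dynamics, detection model and determinism."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sedadiv import synthetic as sy
from sedadiv.filtering import rep_cols


def test_reference_db_counts_and_shared_names():
    db = sy.generate_reference_db(50, frac_aquatic=0.1, seed=1)
    taxa = db.taxonomy["taxon"]
    assert taxa.nunique() == 50
    n_aq = (db.taxonomy.drop_duplicates("taxon")["group"].isin(["aquatic", "alga"])).sum()
    assert n_aq == 5
    assert taxa.value_counts().max() >= 2          # some taxa carry two barcodes
    assert db.taxonomy["polya_group"].sum() == 2   # the Vaccinium-like pair
    stems = {s.rstrip("A") for s in db.taxonomy.index[db.taxonomy["polya_group"]]}
    assert len(stems) == 1                         # same stem, different poly-A run


def test_reference_db_all_terrestrial_when_no_aquatics():
    db = sy.generate_reference_db(10, frac_aquatic=0.0, seed=7)
    assert (db.taxonomy["group"] == "terrestrial").all()


def test_reference_db_deterministic_and_validated():
    a = sy.generate_reference_db(30, 0.1, seed=3).taxonomy
    b = sy.generate_reference_db(30, 0.1, seed=3).taxonomy
    pd.testing.assert_frame_equal(a, b)
    with pytest.raises(ValueError):
        sy.generate_reference_db(5, 0.1, seed=1)
    with pytest.raises(ValueError):
        sy.generate_reference_db(20, 1.0, seed=1)


def test_barcode_lengths_within_locus_range():
    db = sy.generate_reference_db(60, 0.1, seed=2)
    lengths = db.taxonomy.index.str.len()
    assert lengths.min() >= 10 and lengths.max() <= 80


def _colonization_config(**kw):
    base = dict(n_lakes=2, samples_per_lake=(5, 6), pool_size=100,
                n_initial_taxa=0, n_ref_taxa=120, seed=5)
    base.update(kw)
    return sy.SimulationConfig(**base)


def test_constant_rate_colonization_is_uniform_in_time():
    cfg = _colonization_config(
        age_range=(10_000, 0), colonization_rate_curve=((10_000, 0, 10.0),))
    col = sy.simulate_regional_colonization(cfg)
    ages = np.array(list(col.values()))
    assert len(ages) == 100
    # approx uniform: Kolmogorov-Smirnov against U(0, 10000)
    assert stats.kstest(ages, "uniform", args=(0, 10_000)).pvalue > 0.01
    # non-decreasing cumulative curve toward the present by construction
    assert (np.diff(sorted(ages, reverse=True)) <= 0).all()


def test_colonization_plateau_after_rate_drops_to_zero():
    cfg = _colonization_config(
        age_range=(10_000, 0),
        colonization_rate_curve=((10_000, 3_000, 10.0), (3_000, 0, 0.0)))
    col = sy.simulate_regional_colonization(cfg)
    assert min(col.values()) >= 3_000


def test_colonization_pool_overflow_rejected():
    cfg = _colonization_config(
        pool_size=30, age_range=(10_000, 0),
        colonization_rate_curve=((10_000, 0, 10.0),))
    with pytest.raises(ValueError):
        sy.simulate_regional_colonization(cfg)


def test_two_phase_rates_recovered_from_accumulation_curve():
    cfg = sy.SimulationConfig(
        n_lakes=2, samples_per_lake=(5, 6), seed=9,
        pool_size=1100, n_initial_taxa=0, n_ref_taxa=10,
        age_range=(11_700, 0),
        colonization_rate_curve=((11_700, 5_000, 130.0), (5_000, 0, 40.0)))
    col = sy.simulate_regional_colonization(cfg)
    ages = np.sort(np.array(list(col.values())))[::-1]
    cum = np.arange(1, ages.size + 1)
    for (old, young), rate in [((11_700, 5_000), 130.0), ((5_000, 0), 40.0)]:
        sel = (ages <= old) & (ages >= young)
        slope = np.polyfit((11_700 - ages[sel]) / 1000, cum[sel], 1)[0]
        assert slope == pytest.approx(rate, rel=0.2)


def test_config_validation():
    with pytest.raises(ValueError):
        sy.SimulationConfig(n_replicates=1)
    with pytest.raises(ValueError):
        sy.SimulationConfig(age_range=(0, 11_700))         # wrong order
    with pytest.raises(ValueError):
        sy.SimulationConfig(age_range=(3_000, 0))          # single period
    with pytest.raises(ValueError):
        sy.SimulationConfig(colonization_rate_curve=((5_000, 0, 10.0),))


def _flat_config(**kw):
    base = dict(n_lakes=2, samples_per_lake=(30, 30), pool_size=150,
                n_initial_taxa=150, n_ref_taxa=200,
                colonization_rate_curve=((11_700, 0, 0.0),),
                beta_temperature=0.0, beta_nutrient=0.0, smooth_amplitude=0.0,
                seed=13)
    base.update(kw)
    return sy.SimulationConfig(**base)


def _record(cfg, lake=None, rng_seed=1):
    proxy = sy.generate_proxy_series(cfg.age_range, seed=2)
    col = sy.simulate_regional_colonization(cfg)
    if lake is None:
        lake = sy.LakeSpec("lakeA", 11_000, 100, cfg.samples_per_lake[0],
                           P=8, K=9, Ca=500, H_min=4)
    rng = np.random.default_rng(rng_seed)
    return sy.simulate_lake_record(lake, col, proxy, cfg, rng=rng)


def test_zero_effect_record_is_stationary():
    coms = _record(_flat_config())
    ages = np.array([c.age for c in coms], dtype=float)
    rich = np.array([len(c.taxa) for c in coms], dtype=float)
    slope, _, _, p, _ = stats.linregress(ages, np.log(rich))
    assert p > 0.01 or abs(slope * 10_000) < 0.3   # no systematic trend


def test_higher_nutrient_lake_is_richer():
    cfg = _flat_config(beta_nutrient=0.12)
    lo = sy.LakeSpec("lo", 11_000, 100, 30, P=3, K=3, Ca=100, H_min=7)
    hi = sy.LakeSpec("hi", 11_000, 100, 30, P=11, K=14, Ca=2_000, H_min=2.5)
    rich_lo = np.mean([len(c.taxa) for c in _record(cfg, lo)])
    rich_hi = np.mean([len(c.taxa) for c in _record(cfg, hi)])
    assert rich_hi > rich_lo


def test_richness_clamped_to_colonized_pool_with_warning():
    cfg = _flat_config(n_initial_taxa=5, pool_size=150,
                       colonization_rate_curve=((11_700, 0, 12.0),))
    with pytest.warns(UserWarning):
        coms = _record(cfg)
    col = sy.simulate_regional_colonization(cfg)
    ages = np.array(sorted(col.values(), reverse=True))
    for c in coms:
        assert len(c.taxa) <= (ages >= c.age).sum()


def test_abundances_form_a_simplex():
    for c in _record(_flat_config()):
        assert c.relative_abundances.sum() == pytest.approx(1.0)
        assert (c.relative_abundances > 0).all()


def _reads_for(cfg, community=None, rng_seed=3):
    db = sy.generate_reference_db(cfg.n_ref_taxa, 0.0, seed=4)
    pool = db.taxonomy["taxon"].drop_duplicates().sort_values().to_numpy()
    if community is None:
        n = 40
        rng0 = np.random.default_rng(0)
        ab = rng0.lognormal(0, 1.2, n)
        community = sy.TrueCommunity("s0", "lakeA", 5_000, pool[:n], ab / ab.sum())
    rng = np.random.default_rng(rng_seed)
    return db, community, sy.simulate_reads(community, db, cfg, rng)


def test_no_dropout_limit_detects_every_taxon_everywhere():
    cfg = _flat_config(dropout_halfsat=0.0, contaminant_rate=0.0,
                       false_positive_rate=0.0, aquatic_rate=0.0,
                       inhibited_rate=0.0)
    db, com, reads = _reads_for(cfg)
    tax = db.taxonomy["taxon"]
    reads = reads.assign(taxon=reads["dna"].map(tax))
    per_taxon = reads.groupby("taxon")[rep_cols(reads)].sum()
    assert set(per_taxon.index) == set(com.taxa)
    assert (per_taxon.to_numpy() > 0).all()


def test_no_contaminants_means_all_sequences_identifiable():
    cfg = _flat_config(contaminant_rate=0.0, false_positive_rate=0.0)
    db, _, reads = _reads_for(cfg)
    assert reads["dna"].isin(db.taxonomy.index).all()


def test_detection_frequency_increases_with_abundance():
    cfg = _flat_config(n_ref_taxa=120, dropout_halfsat=50.0,
                       depth_lognormal_params=(7.0, 1.0),
                       contaminant_rate=0.0, false_positive_rate=0.0,
                       aquatic_rate=0.0, inhibited_rate=0.0)
    db = sy.generate_reference_db(cfg.n_ref_taxa, 0.0, seed=4)
    pool = db.taxonomy["taxon"].drop_duplicates().sort_values().to_numpy()[:100]
    rng0 = np.random.default_rng(1)
    ab = rng0.lognormal(0, 1.5, 100)
    ab = ab / ab.sum()
    det = np.zeros(100)
    rng = np.random.default_rng(2)
    tax = db.taxonomy["taxon"]
    for trial in range(30):
        com = sy.TrueCommunity(f"s{trial}", "lakeA", 5_000, pool, ab)
        reads = sy.simulate_reads(com, db, cfg, rng)
        got = (reads.assign(taxon=reads["dna"].map(tax))
               .groupby("taxon")[rep_cols(reads)].sum() > 0).sum(axis=1)
        det += got.reindex(pool).fillna(0).to_numpy()
    rho = stats.spearmanr(ab, det).statistic
    assert rho > 0.5


def test_negative_controls_are_sparse(small_config):
    db = sy.generate_reference_db(40, 0.1, seed=6)
    rng = np.random.default_rng(8)
    nc = sy.simulate_negative_control("lakeA", "nc0", db, small_config, rng)
    if len(nc):
        assert (nc[rep_cols(nc)] > 0).to_numpy().sum() <= 3 * len(nc)


def test_dataset_generation_is_deterministic(small_config, dataset):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        again = sy.generate_dataset(small_config)
    pd.testing.assert_frame_equal(dataset["counts"], again["counts"])
    pd.testing.assert_frame_equal(dataset["lakes"], again["lakes"])
    pd.testing.assert_frame_equal(dataset["proxy"], again["proxy"])


def test_regional_truth_accumulation_reaches_pool_in_zero_dropout_limit():
    cfg = _flat_config(n_lakes=3, samples_per_lake=(25, 30), pool_size=60,
                       n_initial_taxa=60, n_ref_taxa=80, dropout_halfsat=0.0,
                       richness_intercept=4.5)   # demand exceeds pool: all drawn
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = sy.generate_dataset(cfg)
    truth_taxa = set()
    for t in ds["truth_samples"]["true_taxa"]:
        truth_taxa |= set(t.split(";"))
    assert len(truth_taxa) == 60


def test_proxy_series_shape():
    p = sy.generate_proxy_series((11_700, 0), seed=3)
    assert (np.diff(p["age"]) == 50).all()
    assert p["d18o"].min() < -39          # the cold oscillation to exclude
    early = p[p["age"] >= 8_300]["d18o"].mean()
    middle = p[(p["age"] < 8_300) & (p["age"] >= 4_250)]["d18o"].mean()
    assert middle > early                 # Early Holocene colder on average
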