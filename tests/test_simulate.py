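import numpy as np
import pandas as pd
import pytest

from retroburst import SimConfig, SimulationError, derive_varieties, simulate_reference
from retroburst.simulate import (_k80_substitution_probs, evolve_sequence,
                                 indices_to_str, random_sequence)

FAST = dict(n_chromosomes=1, chrom_length=150_000, n_elements=4,
            ltr_length_range=(300, 600), internal_length_range=(1500, 2500),
            n_genes=4, n_solo_ltrs=2, n_truncated=2, n_varieties=2)


def test_zero_age_elements_have_identical_ltrs():
    cfg = SimConfig(seed=5, age_range_mya=(0.0, 0.0), **FAST)
    genome, truth, _ = simulate_reference(cfg)
    for row in truth.itertuples():
        seq = genome[row.chrom]
        assert seq[row.ltr5_start:row.ltr5_end] == seq[row.ltr3_start:row.ltr3_end]


def test_truth_structure_invariants():
    cfg = SimConfig(seed=7, **FAST)
    genome, truth, genes = simulate_reference(cfg)
    lo, hi = cfg.age_range_mya
    for row in truth.itertuples():
        assert row.ltr5_start == row.start and row.ltr3_end == row.end
        assert row.ltr5_end <= row.ltr3_start  # 5' LTR strictly precedes 3' LTR
        assert lo <= row.true_age_mya <= hi
        seq = genome[row.chrom]
        tsd = row.tsd
        assert seq[row.start - len(tsd):row.start] == tsd
        assert seq[row.end:row.end + len(tsd)] == tsd
    # planted upstream subset matches the configured fraction
    n_upstream = truth.upstream_distance.notna().sum()
    assert n_upstream == min(round(cfg.upstream_fraction * cfg.n_elements), cfg.n_genes)
    assert (truth.upstream_distance.dropna() < 1000).all()


def test_deterministic_for_fixed_seed():
    cfg = SimConfig(seed=11, **FAST)
    g1, t1, genes1 = simulate_reference(cfg)
    g2, t2, genes2 = simulate_reference(cfg)
    assert g1 == g2
    pd.testing.assert_frame_equal(t1, t2)
    assert genes1 == genes2
    v1, t1b = derive_varieties(g1, t1, cfg)
    v2, t2b = derive_varieties(g2, t2, cfg)
    assert v1 == v2
    pd.testing.assert_frame_equal(t1b, t2b)


def test_no_elements_gives_empty_truth():
    cfg = SimConfig(seed=1, n_elements=0, n_solo_ltrs=0, n_truncated=0,
                    upstream_fraction=0.0,
                    **{k: v for k, v in FAST.items()
                       if k not in ("n_elements", "n_solo_ltrs", "n_truncated")})
    genome, truth, _ = simulate_reference(cfg)
    assert truth.empty
    assert len(genome["chr1"]) == cfg.chrom_length


def test_placement_overflow_rejected():
    with pytest.raises(SimulationError, match="exceed"):
        simulate_reference(SimConfig(seed=1, n_chromosomes=1, chrom_length=30_000,
                                     n_elements=10, n_genes=0, n_solo_ltrs=0,
                                     n_truncated=0))


@pytest.mark.parametrize("bad", [
    dict(mutation_rate=0.0),
    dict(gc_content=1.5),
    dict(superfamily_mix={"Gypsy": 0.7, "Copia": 0.7, "Unclassified": 0.1}),
    dict(excision_probability=1.5),
    dict(age_range_mya=(3.0, 1.0)),
])
def test_invalid_config_rejected(bad):
    with pytest.raises(SimulationError):
        SimConfig(**bad)


def test_excision_probability_zero_keeps_reference():
    cfg = SimConfig(seed=13, excision_probability=0.0, **FAST)
    genome, truth, _ = simulate_reference(cfg)
    varieties, truth = derive_varieties(genome, truth, cfg)
    for var_genome in varieties.values():
        assert var_genome == genome
    assert truth[[c for c in truth.columns if c.startswith("present_")]].all().all()


def test_excision_probability_one_removes_every_element():
    cfg = SimConfig(seed=13, excision_probability=1.0, **FAST)
    genome, truth, _ = simulate_reference(cfg)
    varieties, truth = derive_varieties(genome, truth, cfg)
    removed = sum(int(r.end - r.start) + len(r.tsd) for r in truth.itertuples())
    for var_genome in varieties.values():
        assert len(var_genome["chr1"]) == len(genome["chr1"]) - removed


def test_single_excision_reconstructs_preinsertion_allele():
    cfg = SimConfig(seed=2, n_chromosomes=1, chrom_length=60_000, n_elements=1,
                    ltr_length_range=(300, 600), internal_length_range=(1500, 2500),
                    n_genes=0, n_solo_ltrs=0, n_truncated=0, n_varieties=1,
                    upstream_fraction=0.0, excision_probability=1.0)
    genome, truth, _ = simulate_reference(cfg)
    varieties, truth = derive_varieties(genome, truth, cfg)
    row = truth.iloc[0]
    ref = genome["chr1"]
    expected = ref[: row.start] + ref[row.end + len(row.tsd):]
    assert varieties["var1"]["chr1"] == expected
    # background conserved outside the excised locus, one TSD copy remains
    assert expected[row.start - len(row.tsd): row.start] == row.tsd


def test_realized_divergence_is_unbiased_for_2muT():
    """Mean observed LTR mismatch proportion matches the K80 expectation
    derived from the drawn ages, within 3 binomial standard errors."""
    rng = np.random.default_rng(17)
    mu, kappa, L = 7e-9, 2.0, 1000
    n = 250
    observed = expected = var_sum = 0.0
    for _ in range(n):
        age = rng.uniform(0.1, 3.0)
        d = mu * age * 1e6
        anc = random_sequence(L, 0.38, rng)
        a = evolve_sequence(anc, d, kappa, rng)
        b = evolve_sequence(anc, d, kappa, rng)
        p_ts, p_tv = _k80_substitution_probs(2 * d, kappa)
        p = p_ts + p_tv
        observed += np.mean(a != b)
        expected += p
        var_sum += p * (1 - p) / L
    se = np.sqrt(var_sum) / n
    assert abs(observed / n - expected / n) < 3 * se


def test_evolved_distance_zero_is_identity():
    rng = np.random.default_rng(0)
    anc = random_sequence(500, 0.5, rng)
    assert np.array_equal(evolve_sequence(anc, 0.0, 2.0, rng), anc)
    assert len(indices_to_str(anc)) == 500
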