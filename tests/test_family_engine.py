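"""Trio-factorized emissions, the MCMC engine and consensus generation."""

import itertools

import numpy as np
import pytest

from famcall import family_engine as fe
from famcall import ld_hmm, simulator
from famcall.formats_io import Individual, PedigreeGraph
from famcall.ld_hmm import ConditioningSet
from famcall.family_engine import (
    FamilyCaller,
    HaplotypeSampleStore,
    consensus_haplotypes,
    duplicate_parents,
    restrict_offspring,
    transmit,
    trio_emission_father,
    trio_emission_mother,
    trio_father_weights,
)


def make_ped(rows):
    ped = PedigreeGraph()
    for fid, iid, fat, mot in rows:
        ped.individuals[iid] = Individual(iid, fid, fat, mot, 0)
    ped.validate()
    return ped


# ---------------------------------------------------------------------------
# transmit


def test_transmit_reads_first_slots():
    assert transmit((1, 0), (0, 0)) == (1, 0)
    assert transmit((0, 0), (0, 0)) == (0, 0)
    assert transmit((1, 1), (1, 1)) == (1, 1)
    assert transmit((0, 1), (1, 0)) == (0, 1)


# ---------------------------------------------------------------------------
# trio emissions vs exhaustive sums


def brute_father_emission(site, state, Lf, Lm, Lc, q, templ, eps):
    C = ld_hmm.copy_matrix(eps)
    ax = templ.alleles[state[0], site]
    ay = templ.alleles[state[1], site]
    total = 0.0
    for g1, g2 in itertools.product((0, 1), repeat=2):
        inner = 0.0
        for m1, m2 in itertools.product((0, 1), repeat=2):
            prior = (q[site] if m1 else 1 - q[site]) * (
                q[site] if m2 else 1 - q[site]
            )
            child = transmit((g1, g2), (m1, m2))
            inner += (
                Lf[site, g1 + g2]
                * Lm[site, m1 + m2]
                * Lc[site, child[0] + child[1]]
                * prior
            )
        total += inner * C[g1, ax] * C[g2, ay]
    return total


def brute_mother_emission(site, state, Lf, Lm, Lc, fhap, templ, eps):
    C = ld_hmm.copy_matrix(eps)
    ax = templ.alleles[state[0], site]
    ay = templ.alleles[state[1], site]
    gf = (int(fhap[0, site]), int(fhap[1, site]))
    total = 0.0
    for g1, g2 in itertools.product((0, 1), repeat=2):
        child = transmit(gf, (g1, g2))
        total += (
            Lf[site, gf[0] + gf[1]]
            * Lm[site, g1 + g2]
            * Lc[site, child[0] + child[1]]
            * C[g1, ax]
            * C[g2, ay]
        )
    return total


def test_trio_emissions_match_exhaustive_sums(rng):
    M = 4
    Lf, Lm, Lc = (rng.random((M, 3)) for _ in range(3))
    q = rng.uniform(0.1, 0.9, M)
    templ = ConditioningSet(alleles=rng.integers(0, 2, (3, M)).astype(np.uint8))
    fhap = rng.integers(0, 2, (2, M)).astype(np.uint8)
    eps = 0.07
    for site in range(M):
        for state in itertools.product(range(3), repeat=2):
            got = trio_emission_father(state, Lf, Lm, Lc, q, templ, site, eps)
            want = brute_father_emission(site, state, Lf, Lm, Lc, q, templ, eps)
            assert got == pytest.approx(want, rel=1e-12)
            got = trio_emission_mother(state, Lf, Lm, Lc, fhap, templ, site, eps)
            want = brute_mother_emission(site, state, Lf, Lm, Lc, fhap, templ, eps)
            assert got == pytest.approx(want, rel=1e-12)


def test_flat_relatives_reduce_to_single_individual_emission(rng):
    M = 5
    Lf = rng.random((M, 3))
    flat = np.ones((M, 3))
    q = rng.uniform(0.1, 0.9, M)
    W_trio = trio_father_weights(Lf, flat, flat, q)
    W_single = ld_hmm.ordered_genotype_weights(Lf)
    eps = np.full(M, 0.02)
    np.testing.assert_allclose(
        ld_hmm.emission_table(W_trio, eps),
        ld_hmm.emission_table(W_single, eps),
        rtol=1e-12,
    )


def test_mendelian_impossibility_zeroes_father_emission():
    M = 2
    flat = np.ones((M, 3))
    mom_homref = np.tile([1.0, 0.0, 0.0], (M, 1))
    child_homalt = np.tile([0.0, 0.0, 1.0], (M, 1))
    W = trio_father_weights(flat, mom_homref, child_homalt, np.full(M, 0.5))
    np.testing.assert_array_equal(W, np.zeros((M, 2, 2)))


# ---------------------------------------------------------------------------
# pedigree expansion


def test_duplicate_parents_counts():
    rows = []
    for f in range(80):
        rows += [(f"F{f}", f"d{f}", None, None), (f"F{f}", f"m{f}", None, None)]
        rows += [(f"F{f}", f"c{f}_{k}", f"d{f}", f"m{f}") for k in range(4)]
    ped = make_ped(rows)
    index = {iid: j for j, iid in enumerate(ped.individuals)}
    assert len(duplicate_parents(ped, index)) == 320


def test_childless_couple_yields_no_trios():
    ped = make_ped([("F1", "a", None, None), ("F1", "b", None, None)])
    assert duplicate_parents(ped, {"a": 0, "b": 1}) == []
    assert sorted(ped.singletons()) == ["a", "b"]


def test_restrict_offspring_detaches_extra_children():
    rows = [("F1", "d", None, None), ("F1", "m", None, None)]
    rows += [("F1", f"c{k}", "d", "m") for k in range(4)]
    ped = make_ped(rows)
    ped1 = restrict_offspring(ped, 1)
    assert len(ped1.trios()) == 1
    assert len(ped1.singletons()) == 3
    ped4 = restrict_offspring(ped, 4)
    assert len(ped4.trios()) == 4


# ---------------------------------------------------------------------------
# engine behavior


def test_run_is_deterministic_given_seed(tiny_cohort):
    _, truth, _, lik = tiny_cohort
    stores = []
    for _ in range(2):
        caller = FamilyCaller(lik, truth.pedigree, seed=77)
        stores.append(caller.run(3))
    a, b = stores
    assert a.individuals() == b.individuals()
    for iid in a.individuals():
        for (ra, ha), (rb, hb) in zip(a.samples[iid], b.samples[iid]):
            assert ra == rb
            np.testing.assert_array_equal(ha, hb)


def test_store_records_duplicated_parent_samples(tiny_cohort):
    _, truth, _, lik = tiny_cohort
    caller = FamilyCaller(lik, truth.pedigree, seed=3, samples_per_update=1)
    caller.run(2)
    # two children per family: parents sampled once per trio per round
    assert len(caller.store.samples["F0_dad"]) == 4
    assert len(caller.store.samples["F0_kid0"]) == 2
    multi = FamilyCaller(lik, truth.pedigree, seed=3, samples_per_update=3)
    multi.run(1)
    # extra per-update draws multiply the stored votes
    assert len(multi.store.samples["F0_kid0"]) == 3


def test_sampled_rounds_are_mendelian_consistent_at_high_depth():
    pool = simulator.make_pool(80, 60, seed=31)
    truth = simulator.sample_pedigree(pool, 2, 2, seed=32)
    _, lik = simulator.simulate_reads(truth, 30.0, 20, seed=33)
    caller = FamilyCaller(lik, truth.pedigree, seed=34)
    caller.run(3)
    from famcall.evaluation import mendelian_errors

    for r in range(3):
        called = np.stack(
            [dict(caller.store.samples[i])[r].sum(axis=0)
             for i in truth.sample_ids]
        )
        assert mendelian_errors(called, truth.pedigree, truth.sample_ids) < 0.5


def test_three_generation_family_updates_middle_generation(tmp_path):
    pool = simulator.make_pool(100, 50, seed=41)
    truth = simulator.sample_pedigree(pool, 2, 2, seed=42, three_generation=True)
    _, lik = simulator.simulate_reads(truth, 6.0, 20, seed=43)
    caller = FamilyCaller(lik, truth.pedigree, seed=44, samples_per_update=1)
    caller.run(2)
    # the middle generation is sampled both as child (own trio) and as
    # parent (one duplicate per grandchild): 1 + 2 samples per round
    assert len(caller.store.samples["F0_dad"]) == 2 * 3


def test_vcf_samples_missing_from_pedigree_become_singletons(tiny_cohort):
    _, truth, _, lik = tiny_cohort
    ped = PedigreeGraph(dict(truth.pedigree.individuals))
    del ped.individuals["F1_kid1"]  # present in data, absent from pedigree
    # drop the trio rows referencing nothing; F1_kid1 row removed only
    caller = FamilyCaller(lik, ped, seed=9)
    assert "F1_kid1" in caller.singleton_ids


# ---------------------------------------------------------------------------
# consensus


def test_consensus_of_identical_rounds_is_that_sample(rng):
    hap = rng.integers(0, 2, (2, 12)).astype(np.uint8)
    store = HaplotypeSampleStore()
    for r in range(5):
        store.append("x", r, hap)
    cons, post = consensus_haplotypes(store)
    np.testing.assert_array_equal(cons["x"], hap)
    g = hap.sum(axis=0)
    assert (post["x"][np.arange(12), g] == 1.0).all()


def test_consensus_absorbs_global_slot_swaps(rng):
    hap = rng.integers(0, 2, (2, 12)).astype(np.uint8)
    store = HaplotypeSampleStore()
    for r in range(6):
        store.append("x", r, hap if r % 2 == 0 else hap[::-1])
    cons, _ = consensus_haplotypes(store)
    np.testing.assert_array_equal(cons["x"], hap)


def test_consensus_majority_votes_per_site():
    store = HaplotypeSampleStore()
    votes = [0, 0, 1]
    for r, a in enumerate(votes):
        hap = np.array([[a, 1], [a, 1]], dtype=np.uint8)
        store.append("x", r, hap)
    cons, post = consensus_haplotypes(store)
    np.testing.assert_array_equal(cons["x"], [[0, 1], [0, 1]])
    assert post["x"][0, 0] == pytest.approx(2 / 3)


def test_consensus_requires_retained_rounds():
    store = HaplotypeSampleStore()
    store.append("x", 0, np.zeros((2, 3), dtype=np.uint8))
    with pytest.raises(ValueError):
        consensus_haplotypes(store, burn_in=5)


def test_burn_in_and_round_limits_filter_samples():
    store = HaplotypeSampleStore()
    for r in range(4):
        store.append("x", r, np.full((2, 2), r % 2, dtype=np.uint8))
    assert len(list(store.rounds("x", burn_in=2))) == 2
    assert len(list(store.rounds("x", burn_in=0, max_round=1))) == 1
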