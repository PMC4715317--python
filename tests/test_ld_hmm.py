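"""Diploid copying HMM: emissions, transitions, posteriors, sampling."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from famcall import ld_hmm
from famcall.ld_hmm import (
    ConditioningSet,
    ModelParams,
    build_state_space,
    emission_g_given_s,
    emission_r_given_s,
    forward,
    forward_backward,
    genotype_posterior,
    sample_haplotypes_given_path,
    sample_state_path,
    transition_prob,
)


def brute_force_posteriors(L, templ, params):
    """Exhaustive enumeration over all H^(2M) ordered-pair state paths."""
    H, M = templ.alleles.shape
    states = list(itertools.product(range(H), repeat=2))
    post = np.zeros((M, H, H))
    total = 0.0
    for path in itertools.product(states, repeat=M):
        p = 1.0 / (H * H)
        for i, (x, y) in enumerate(path):
            if i > 0:
                p *= transition_prob(path[i - 1], (x, y), params.theta[i - 1], H)
            tab = ld_hmm.genotype_given_state_table(params.epsilon[i])
            t = templ.alleles[x, i] + templ.alleles[y, i]
            p *= float(L[i] @ tab[t])
        total += p
        for i, (x, y) in enumerate(path):
            post[i, x, y] += p
    return post / total


def brute_force_genotype_posterior(post, templ, params):
    M = post.shape[0]
    pg = np.zeros((M, 3))
    for i in range(M):
        tab = ld_hmm.genotype_given_state_table(params.epsilon[i])
        for x in range(templ.alleles.shape[0]):
            for y in range(templ.alleles.shape[0]):
                t = templ.alleles[x, i] + templ.alleles[y, i]
                pg[i] += post[i, x, y] * tab[t]
    return pg / pg.sum(axis=1, keepdims=True)


def random_instance(rng, H, M):
    templ = ConditioningSet(alleles=rng.integers(0, 2, (H, M)).astype(np.uint8))
    L = rng.random((M, 3))
    params = ModelParams(
        theta=rng.random(M - 1) * 0.5, epsilon=rng.random(M) * 0.3
    )
    return templ, L, params


# ---------------------------------------------------------------------------
# emissions and transitions


def test_zero_error_forces_template_genotype():
    templ = ConditioningSet(alleles=np.array([[1], [1]], dtype=np.uint8))
    np.testing.assert_allclose(
        emission_g_given_s((0, 1), templ, 0, epsilon=0.0), [0, 0, 1]
    )


def test_het_state_emission_table():
    templ = ConditioningSet(alleles=np.array([[0], [1]], dtype=np.uint8))
    np.testing.assert_allclose(
        emission_g_given_s((0, 1), templ, 0, epsilon=0.1),
        [0.09, 0.82, 0.09],
        atol=1e-12,
    )


def test_hom_state_emission_table():
    templ = ConditioningSet(alleles=np.array([[0], [0]], dtype=np.uint8))
    np.testing.assert_allclose(
        emission_g_given_s((0, 1), templ, 0, epsilon=0.1),
        [0.81, 0.18, 0.01],
        atol=1e-12,
    )


def test_flat_likelihood_emits_one_for_every_state():
    templ = ConditioningSet(
        alleles=np.array([[0, 1], [1, 0], [1, 1]], dtype=np.uint8)
    )
    for state in itertools.product(range(3), repeat=2):
        assert emission_r_given_s(
            state, np.ones(3), templ, 0, 0.23
        ) == pytest.approx(1.0)


def test_incompatible_certain_data_emits_zero():
    templ = ConditioningSet(alleles=np.array([[1], [1]], dtype=np.uint8))
    assert emission_r_given_s((0, 1), np.array([1.0, 0, 0]), templ, 0, 0.0) == 0.0
    hom_ref = ConditioningSet(alleles=np.array([[0], [0]], dtype=np.uint8))
    assert emission_r_given_s(
        (0, 1), np.array([1.0, 0, 0]), hom_ref, 0, 0.0
    ) == pytest.approx(1.0)


def test_transition_examples():
    assert transition_prob((0, 1), (0, 1), 0.0, 5) == 1.0
    assert transition_prob((0, 1), (0, 2), 0.0, 5) == 0.0
    assert transition_prob((0, 1), (0, 1), 0.1, 10) == pytest.approx(0.8281)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.floats(0, 0.99), st.integers(1, 12), st.integers(0, 10_000))
def test_transition_rows_sum_to_one(theta, H, salt):
    rng = np.random.default_rng(salt)
    src = (int(rng.integers(H)), int(rng.integers(H)))
    total = sum(
        transition_prob(src, (w, v), theta, H)
        for w in range(H)
        for v in range(H)
    )
    assert total == pytest.approx(1.0, abs=1e-9)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.floats(0, 0.499))
def test_genotype_given_state_rows_sum_to_one(eps):
    tab = ld_hmm.genotype_given_state_table(eps)
    np.testing.assert_allclose(tab.sum(axis=1), np.ones(3), atol=1e-12)


# ---------------------------------------------------------------------------
# forward-backward against exhaustive enumeration


@pytest.mark.parametrize("H,M,seed", [(2, 3, 7), (2, 4, 8), (3, 3, 9)])
def test_posteriors_match_exhaustive_enumeration(H, M, seed):
    rng = np.random.default_rng(seed)
    templ, L, params = random_instance(rng, H, M)
    expected = brute_force_posteriors(L, templ, params)
    post = forward_backward(L, templ, params)
    np.testing.assert_allclose(post, expected, atol=1e-10)
    np.testing.assert_allclose(post.sum(axis=(1, 2)), np.ones(M), atol=1e-9)
    pg = genotype_posterior(post, templ, params.epsilon)
    np.testing.assert_allclose(
        pg, brute_force_genotype_posterior(expected, templ, params), atol=1e-10
    )


def test_single_site_posterior_is_normalized_emission():
    rng = np.random.default_rng(5)
    templ, L, params = random_instance(rng, 3, 1)
    post = forward_backward(L, templ, params)
    tab = ld_hmm.genotype_given_state_table(params.epsilon[0])
    expected = np.array(
        [
            [float(L[0] @ tab[templ.alleles[x, 0] + templ.alleles[y, 0]])
             for y in range(3)]
            for x in range(3)
        ]
    )
    np.testing.assert_allclose(post[0], expected / expected.sum(), atol=1e-12)


def test_uninformative_data_gives_uniform_state_posterior():
    templ = ConditioningSet(
        alleles=np.array([[0, 1, 0], [1, 0, 1]], dtype=np.uint8)
    )
    params = ModelParams.constant(3, theta=0.2, epsilon=0.1)
    post = forward_backward(np.ones((3, 3)), templ, params)
    np.testing.assert_allclose(post, np.full((3, 2, 2), 0.25), atol=1e-12)


def test_posteriors_invariant_to_per_site_likelihood_scaling():
    rng = np.random.default_rng(17)
    templ, L, params = random_instance(rng, 3, 4)
    scales = rng.uniform(0.1, 40.0, size=(4, 1))
    a = forward_backward(L, templ, params)
    b = forward_backward(L * scales, templ, params)
    np.testing.assert_allclose(a, b, atol=1e-9)


# ---------------------------------------------------------------------------
# sampling


def test_zero_theta_path_is_constant(rng):
    templ = ConditioningSet(alleles=rng.integers(0, 2, (4, 6)).astype(np.uint8))
    L = rng.random((6, 3))
    params = ModelParams(theta=np.zeros(5), epsilon=np.full(6, 0.1))
    F, _ = forward(L, templ, params)
    path = sample_state_path(F, templ, params, np.random.default_rng(0))
    assert (path == path[0]).all()


def test_path_sampling_is_deterministic_given_seed(rng):
    templ, L, params = random_instance(rng, 3, 5)
    F, _ = forward(L, templ, params)
    p1 = sample_state_path(F, templ, params, np.random.default_rng(42))
    p2 = sample_state_path(F, templ, params, np.random.default_rng(42))
    np.testing.assert_array_equal(p1, p2)


def test_path_sampling_frequencies_match_exact_path_posterior():
    rng = np.random.default_rng(3)
    templ = ConditioningSet(alleles=np.array([[0, 1], [1, 0]], dtype=np.uint8))
    L = rng.random((2, 3))
    params = ModelParams(theta=np.array([0.3]), epsilon=np.array([0.1, 0.2]))
    H = 2
    states = list(itertools.product(range(H), repeat=2))
    exact = {}
    for path in itertools.product(states, repeat=2):
        p = 1.0 / (H * H)
        for i, (x, y) in enumerate(path):
            if i > 0:
                p *= transition_prob(path[i - 1], (x, y), params.theta[0], H)
            tab = ld_hmm.genotype_given_state_table(params.epsilon[i])
            p *= float(L[i] @ tab[templ.alleles[x, i] + templ.alleles[y, i]])
        exact[path] = p
    z = sum(exact.values())
    exact = {k: v / z for k, v in exact.items()}

    F, _ = forward(L, templ, params)
    draw_rng = np.random.default_rng(99)
    n = 10_000
    counts: dict = {}
    for _ in range(n):
        path = tuple(map(tuple, sample_state_path(F, templ, params, draw_rng)))
        counts[path] = counts.get(path, 0) + 1
    for path, p in exact.items():
        emp = counts.get(path, 0) / n
        se = max(np.sqrt(p * (1 - p) / n), 1e-9)
        assert abs(emp - p) < 3 * se + 1e-3


def test_haplotype_sampling_copies_templates_at_zero_error(rng):
    templ = ConditioningSet(alleles=rng.integers(0, 2, (4, 8)).astype(np.uint8))
    path = rng.integers(0, 4, (8, 2))
    hap = sample_haplotypes_given_path(
        path, np.ones((8, 3)), templ, 0.0, np.random.default_rng(1)
    )
    idx = np.arange(8)
    np.testing.assert_array_equal(hap[0], templ.alleles[path[:, 0], idx])
    np.testing.assert_array_equal(hap[1], templ.alleles[path[:, 1], idx])


def test_certain_likelihood_vetoes_templates(rng):
    templ = ConditioningSet(alleles=np.zeros((3, 5), dtype=np.uint8))
    path = np.zeros((5, 2), dtype=np.int64)
    L = np.tile([0.0, 0.0, 1.0], (5, 1))  # certainly hom-alt
    hap = sample_haplotypes_given_path(
        path, L, templ, 0.05, np.random.default_rng(2)
    )
    np.testing.assert_array_equal(hap, np.ones((2, 5), dtype=np.uint8))


def test_haplotype_sampling_marginals_match_closed_form():
    # one site, one template pair (0, 1), epsilon = 0.2, flat likelihood:
    # slot 0 copies allele 0 w.p. 0.8, slot 1 copies allele 1 w.p. 0.8
    templ = ConditioningSet(alleles=np.array([[0], [1]], dtype=np.uint8))
    path = np.array([[0, 1]])
    draws = np.stack(
        [
            sample_haplotypes_given_path(
                path, np.ones((1, 3)), templ, 0.2, rng_
            )[:, 0]
            for rng_ in (np.random.default_rng(s) for s in range(4000))
        ]
    )
    for slot, expected in ((0, 0.2), (1, 0.8)):
        freq = draws[:, slot].mean()
        assert abs(freq - expected) < 3 * np.sqrt(0.16 / 4000)


# ---------------------------------------------------------------------------
# state-space construction


def test_state_space_counts_and_exclusion(rng):
    haps = rng.integers(0, 2, (6, 2, 10)).astype(np.uint8)
    cs = build_state_space(haps, np.array([2, 3]), None, 100, rng)
    assert cs.n_haplotypes == 4
    from famcall.formats_io import PanelMatrix

    panel = PanelMatrix(
        alleles=rng.integers(0, 2, (120, 10)).astype(np.uint8),
        haplotype_ids=[f"p{i}" for i in range(120)],
    )
    cs = build_state_space(haps, np.array([2, 3]), panel, 1000, rng)
    assert cs.n_haplotypes == 124
    assert sum(p.startswith("panel:") for p in cs.provenance) == 120


def test_state_space_capping_is_seeded(rng):
    haps = rng.integers(0, 2, (300, 2, 10)).astype(np.uint8)
    cs1 = build_state_space(
        haps, np.arange(300), None, 100, np.random.default_rng(5)
    )
    cs2 = build_state_space(
        haps, np.arange(300), None, 100, np.random.default_rng(5)
    )
    assert cs1.n_haplotypes == 100
    np.testing.assert_array_equal(cs1.alleles, cs2.alleles)


def test_state_space_requires_two_haplotypes(rng):
    haps = np.zeros((3, 2, 5), dtype=np.uint8)
    with pytest.raises(ValueError):
        build_state_space(haps, np.array([], dtype=int), None, 10, rng)
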