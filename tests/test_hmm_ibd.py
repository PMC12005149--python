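"""36-state founder-IBD HMM: transitions, emissions, Viterbi, blocks."""

import numpy as np
import pytest

from magicmap.pedigree import DesignSpec
from magicmap.simulate import GeneticMapSpec, random_marker_model, simulate_design
from magicmap.hmm_ibd import (
    HMMParams,
    N_STATES,
    blocks_and_recombination,
    emission_matrix,
    forward_backward,
    initial_distribution,
    path_log_probability,
    posteriors_at_positions,
    state_index,
    state_pair,
    transition_matrix,
    viterbi,
)

MP8 = DesignSpec(n_funnels=315, lines_per_funnel=2)


def test_state_indexing_roundtrip():
    seen = set()
    for i in range(8):
        for j in range(i, 8):
            s = state_index(i, j)
            assert state_pair(s) == (i, j)
            seen.add(s)
    assert seen == set(range(N_STATES))
    assert state_index(5, 2) == state_index(2, 5)


def test_transition_identity_at_zero_distance():
    T = transition_matrix(0.0, MP8)
    assert np.allclose(T, np.eye(N_STATES), atol=1e-12)


def test_transition_rows_stochastic_and_stationary_at_large_distance():
    T = transition_matrix(10.0, MP8)
    assert np.allclose(T.sum(axis=1), 1.0)
    T_far = transition_matrix(1e4, MP8)
    pi = initial_distribution(MP8)
    # homozygous rows reach the stationary distribution exactly; under the
    # funnel-averaged model a heterozygous state carries residual funnel
    # information, so its row differs from stationary by a small amount
    assert np.allclose(T_far[:8], np.tile(pi, (8, 1)), atol=1e-9)
    assert np.abs(T_far - pi[None, :]).max() < 2e-3


def test_initial_distribution_heterozygosity():
    pi = initial_distribution(MP8)
    assert pi.sum() == pytest.approx(1.0)
    assert pi[8:].sum() == pytest.approx(2**-5)
    aic = DesignSpec(n_funnels=50, intercross_generations=3)
    assert initial_distribution(aic)[8:].sum() == pytest.approx(7 / 8 * 2**-5)


def test_transition_matches_simulation_conditional_frequencies():
    """10 cM transition row agrees with 100k simulated meiosis products."""
    from magicmap.simulate import founder_at
    from magicmap.twopoint import TwoLocusModel

    d = 10.0
    design = DesignSpec(n_funnels=315, lines_per_funnel=32)  # ~10k lines
    ms = GeneticMapSpec(
        chromosomes=[("c1", 30.0)], markers={"c1": np.array([10.0, 20.0])}
    )
    pop = simulate_design(design, ms, seed=91)
    J_emp = np.zeros((N_STATES, N_STATES))
    for li in range(pop.n_lines):
        s1, s2 = pop.true_states[li]
        J_emp[s1, s2] += 1
    n = J_emp.sum()
    J = TwoLocusModel(design).genotype_joint36(
        float(0.5 * (1 - np.exp(-2 * d / 100)))
    )
    big = J * n >= 10
    z = (J_emp[big] - n * J[big]) / np.sqrt(n * J[big] * (1 - J[big]))
    assert np.abs(z).max() < 4.0


def test_emission_matrix_contract():
    alleles = np.array([0, 1, 0, 1, 0, 1, 0, 1])
    E = emission_matrix(alleles, 0.0)
    # state hom founder 0 (allele 0) emits call 0 with certainty
    assert E[0, 0] == 1.0 and E[1, 0] == 0.0
    E2 = emission_matrix(alleles, 0.1)
    # discordant call probability = error/(n_classes-1) = 0.05
    assert E2[2, 0] == pytest.approx(0.05)
    assert np.allclose(E2.sum(axis=0), 1.0)


def test_missing_calls_carry_no_information():
    positions = np.array([0.0, 5.0, 10.0])
    fa = np.tile(np.arange(8), (3, 1))
    params = HMMParams(design=MP8)
    calls = np.array([[-1, -1, -1]])
    post = forward_backward(calls, fa, positions, params)
    pi = initial_distribution(MP8)
    assert np.allclose(post[0, 0], pi, atol=1e-9)


def test_posteriors_normalized_and_viterbi_exact_on_noiseless_unique():
    ms = GeneticMapSpec.uniform(1, 100.0, 60)
    mm = random_marker_model(ms, seed=1, alleles="unique")
    pop = simulate_design(DesignSpec(n_funnels=60, lines_per_funnel=2), ms, seed=21,
                          marker_model=mm)
    params = HMMParams(design=pop.pedigree.design, error_rate=0.1)
    post = forward_backward(pop.calls, mm.founder_alleles, pop.marker_pos, params)
    assert np.allclose(post.sum(axis=2), 1.0)
    paths = viterbi(pop.calls, mm.founder_alleles, pop.marker_pos, params)
    # founder-unique markers identify the mosaic at the markers exactly
    assert (paths == pop.true_states).mean() >= 0.995
    # forward-backward argmax agrees with Viterbi on identifiable data
    assert (post.argmax(axis=2) == paths).mean() >= 0.99


def test_viterbi_accuracy_benchmarks():
    ms = GeneticMapSpec.uniform(1, 100.0, 100)
    design = DesignSpec(n_funnels=315, lines_per_funnel=2)
    params = HMMParams(design=design, error_rate=0.1)
    mmu = random_marker_model(ms, seed=1, alleles="unique", error_rate=0.01)
    popu = simulate_design(design, ms, seed=21, marker_model=mmu)
    pu = viterbi(popu.calls, mmu.founder_alleles, popu.marker_pos, params)
    assert (pu == popu.true_states).mean() >= 0.95
    mmb = random_marker_model(ms, seed=1, alleles="biallelic", error_rate=0.01)
    popb = simulate_design(design, ms, seed=21, marker_model=mmb)
    pb = viterbi(popb.calls, mmb.founder_alleles, popb.marker_pos, params)
    # biallelic markers leave residual founder ambiguity between
    # discriminating markers; accuracy is correspondingly lower
    assert (pb == popb.true_states).mean() >= 0.90


def test_viterbi_tie_break_lowest_state():
    positions = np.array([0.0, 5.0])
    fa = np.zeros((2, 8), dtype=int)
    fa[:, 4:] = 1  # founders 0-3 vs 4-7
    params = HMMParams(design=MP8, error_rate=0.0)
    calls = np.array([[0, 0]])
    path = viterbi(calls, fa, positions, params)[0]
    assert path[0] == 0 and path[1] == 0  # lowest of the equally likely homs


def test_posterior_founder_marginals_uniform(small_pop):
    params = HMMParams(design=small_pop.pedigree.design, error_rate=0.1)
    fa = small_pop.marker_model.founder_alleles
    post = forward_backward(small_pop.calls, fa, small_pop.marker_pos, params)
    from magicmap.distortion import homozygous_probs

    hom, valid = homozygous_probs(post)
    mean = hom[valid].mean(axis=0)
    se = np.sqrt(0.125 * 0.875 / small_pop.n_lines)
    assert np.abs(mean - 0.125).max() < 4 * se


def test_blocks_constant_path():
    paths = np.full((1, 5), 7, dtype=np.int16)
    pos = np.linspace(0, 40, 5)
    chrom = np.array(["c1"] * 5)
    summ = blocks_and_recombination(paths, pos, chrom)
    assert summ.recombination_counts[0, 0] == 0
    assert len(summ.blocks[0]) == 1
    assert summ.heterozygosity[0] == 0.0


def test_blocks_haplotype_change_counts():
    # hom0 -> het(0,1): one haplotype changed; het(0,1) -> hom2: two
    paths = np.array([[0, state_index(0, 1), 2]], dtype=np.int16)
    pos = np.array([0.0, 10.0, 20.0])
    chrom = np.array(["c1"] * 3)
    summ = blocks_and_recombination(paths, pos, chrom)
    assert summ.recombination_counts[0, 0] == 3
    assert len(summ.blocks[0]) == 3


def test_intercrossing_increases_imputed_recombination():
    ms = GeneticMapSpec.uniform(1, 100.0, 60)
    means = {}
    for ic in (0, 3):
        design = DesignSpec(n_funnels=100, lines_per_funnel=3,
                            intercross_generations=ic)
        mm = random_marker_model(ms, seed=3, alleles="biallelic")
        pop = simulate_design(design, ms, seed=41, marker_model=mm)
        params = HMMParams(design=design, error_rate=0.1)
        paths = viterbi(pop.calls, mm.founder_alleles, pop.marker_pos, params)
        summ = blocks_and_recombination(paths, pop.marker_pos, pop.marker_chrom, ms)
        means[ic] = summ.recombination_counts.mean()
    assert means[3] > means[0]


def test_posteriors_interpolation_endpoints_and_renorm():
    post = np.zeros((1, 2, N_STATES))
    post[0, 0, 0] = 1.0
    post[0, 1, 3] = 1.0
    pos = np.array([10.0, 20.0])
    chrom = np.array(["c1", "c1"])
    gp = posteriors_at_positions(post, pos, chrom, np.array(["c1"] * 3),
                                 np.array([10.0, 15.0, 25.0]))
    assert np.allclose(gp[0, 0], post[0, 0])
    assert gp[0, 1, 0] == pytest.approx(0.5) and gp[0, 1, 3] == pytest.approx(0.5)
    assert np.allclose(gp[0, 2], post[0, 1])  # clamped to nearest marker
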