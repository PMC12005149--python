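"""Exact two-locus distributions and recombination-fraction MLE."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from magicmap.pedigree import DesignSpec
from magicmap.simulate import (
    GeneticMapSpec,
    random_marker_model,
    simulate_design,
)
from magicmap.twopoint import (
    RF_GRID,
    TwoLocusModel,
    distortion_weights,
    estimate_rf,
    estimate_rf_matrix,
    haldane_d,
    haldane_r,
    n_marker_pairs,
)

MP8 = DesignSpec(n_funnels=315, lines_per_funnel=4)


def test_grid_shape():
    assert len(RF_GRID) == 61
    assert RF_GRID[0] == 0.0 and RF_GRID[-1] == 0.5
    assert np.allclose(np.diff(RF_GRID), 1 / 120)


def test_pair_counts():
    assert n_marker_pairs(29566) == 437059395
    assert n_marker_pairs(3) == 3


def test_haldane_roundtrip():
    r = np.array([0.01, 0.1, 0.3, 0.49])
    assert np.allclose(haldane_r(haldane_d(r)), r)


@pytest.mark.parametrize("design", [MP8, DesignSpec(n_funnels=50, intercross_generations=2)])
def test_joint_distribution_properties(design):
    model = TwoLocusModel(design)
    for r in (0.0, 0.1, 0.5):
        D = model.joint(r)
        assert D.min() >= 0
        assert D.sum() == pytest.approx(1.0)
        # single-locus marginal uniform over founders for each haplotype
        D4 = D.reshape(8, 8, 8, 8)
        assert np.allclose(D4.sum(axis=(1, 2, 3)), 0.125)
        assert np.allclose(D4.sum(axis=(0, 1, 3)), 0.125)


def test_r_zero_has_no_recombinant_gametes():
    D = TwoLocusModel(MP8).joint(0.0).reshape(8, 8, 8, 8)
    off = D.sum() - sum(D[a, a, c, c] for a in range(8) for c in range(8))
    assert off == pytest.approx(0.0, abs=1e-12)


def test_r_half_factorizes_given_funnel():
    """Conditionally on the funnel the two loci are independent at r=0.5."""
    D = TwoLocusModel(MP8).joint(0.5, exchangeable=False)
    P = D.reshape(8, 8, 8, 8).transpose(0, 2, 1, 3).reshape(64, 64)
    assert np.abs(P - np.outer(P.sum(axis=1), P.sum(axis=0))).max() < 1e-12


def test_joint_matches_forward_simulation():
    """Exact DP vs 20k-line forward simulation on a single funnel, r=0.1."""
    from magicmap.simulate import founder_at

    r = 0.1
    d = float(haldane_d(r))
    ms = GeneticMapSpec(
        chromosomes=[("c1", 40.0)], markers={"c1": np.array([10.0, 10.0 + d])}
    )
    design = DesignSpec(n_funnels=1, lines_per_funnel=20000)
    pop = simulate_design(design, ms, seed=51)
    fun = pop.pedigree.funnel_of(pop.ril_ids[0])
    inv = np.empty(8, dtype=int)
    for role, f in enumerate(fun):
        inv[f] = role
    counts = np.zeros((64, 64))
    for rid in pop.ril_ids:
        (s1, f1), (s2, f2) = pop.genomes[rid]["c1"]
        a1 = inv[founder_at((s1, f1), 10.0)]
        b1 = inv[founder_at((s1, f1), 10.0 + d)]
        a2 = inv[founder_at((s2, f2), 10.0)]
        b2 = inv[founder_at((s2, f2), 10.0 + d)]
        counts[a1 * 8 + b1, a2 * 8 + b2] += 1
    n = counts.sum()
    D = TwoLocusModel(design).joint(r, exchangeable=False)
    # no mass on structurally impossible cells
    assert counts[D < 1e-15].sum() == 0
    # cells with non-negligible expectation agree within 4 sigma
    big = D * n >= 10
    sd = np.sqrt(D * (1 - D) * n)
    z = (counts[big] - n * D[big]) / sd[big]
    assert np.abs(z).max() < 4.0


def test_estimate_rf_self_pair_and_independence():
    from magicmap.hmm_ibd import initial_distribution
    from magicmap.simulate import state_class_codes

    model = TwoLocusModel(MP8)
    rng = np.random.default_rng(0)
    alleles = np.arange(8)
    codes = state_class_codes(alleles)  # state -> observable class
    pi = initial_distribution(MP8)  # realistic single-locus state law
    calls = codes[rng.choice(36, size=800, p=pi)]
    est = estimate_rf(calls, calls, alleles, alleles, model)
    assert est.rf == 0.0  # a marker against itself
    other = codes[rng.choice(36, size=800, p=pi)]
    est2 = estimate_rf(calls, other, alleles, alleles, model)
    assert est2.rf == 0.5  # statistically independent calls


def test_estimate_rf_symmetric_and_monomorphic_flag(small_pop):
    model = TwoLocusModel(small_pop.pedigree.design)
    fa = small_pop.marker_model.founder_alleles
    a = estimate_rf(small_pop.calls[:, 0], small_pop.calls[:, 1], fa[0], fa[1], model)
    b = estimate_rf(small_pop.calls[:, 1], small_pop.calls[:, 0], fa[1], fa[0], model)
    assert a.rf == b.rf
    mono = np.zeros(8, dtype=int)
    est = estimate_rf(small_pop.calls[:, 0], small_pop.calls[:, 0], fa[0], mono, model)
    assert est.uninformative and est.rf == 0.5


@pytest.mark.parametrize("r_true", [0.05, 0.1, 0.2])
def test_rf_recovery_founder_unique(r_true):
    """Grid MLE recovers the true meiotic r within 0.02 at ~1,260 lines."""
    d = float(haldane_d(r_true))
    ms = GeneticMapSpec(
        chromosomes=[("c1", 50.0)], markers={"c1": np.array([10.0, 10.0 + d])}
    )
    mm = random_marker_model(ms, seed=5, alleles="unique")
    pop = simulate_design(MP8, ms, seed=11, marker_model=mm)
    model = TwoLocusModel(MP8)
    est = estimate_rf(
        pop.calls[:, 0], pop.calls[:, 1], mm.founder_alleles[0], mm.founder_alleles[1], model
    )
    assert abs(est.rf - r_true) <= 0.02


def test_funnel_conditioned_likelihood_agrees_on_mp8ril():
    r_true = 0.1
    d = float(haldane_d(r_true))
    ms = GeneticMapSpec(
        chromosomes=[("c1", 50.0)], markers={"c1": np.array([10.0, 10.0 + d])}
    )
    design = DesignSpec(n_funnels=60, lines_per_funnel=6)
    mm = random_marker_model(ms, seed=5, alleles="unique")
    pop = simulate_design(design, ms, seed=23, marker_model=mm)
    model = TwoLocusModel(design)
    fa = mm.founder_alleles
    funnels = np.array([pop.pedigree.funnel_of(r) for r in pop.ril_ids])
    avg = estimate_rf(pop.calls[:, 0], pop.calls[:, 1], fa[0], fa[1], model)
    cond = estimate_rf(
        pop.calls[:, 0], pop.calls[:, 1], fa[0], fa[1], model, funnels=funnels
    )
    assert abs(avg.rf - r_true) <= 0.02
    assert abs(cond.rf - r_true) <= 0.02


def test_rf_matrix_biallelic_fast_path_matches_generic(small_pop):
    model = TwoLocusModel(small_pop.pedigree.design)
    fa = small_pop.marker_model.founder_alleles
    calls = small_pop.calls[:, :6]
    rf = estimate_rf_matrix(calls, fa[:6], model)
    assert np.allclose(rf, rf.T) and np.all(np.diag(rf) == 0)
    for i in range(6):
        for j in range(i + 1, 6):
            est = estimate_rf(calls[:, i], calls[:, j], fa[i], fa[j], model)
            assert rf[i, j] == pytest.approx(est.rf)


def test_rf_matrix_permutation_consistency(small_pop):
    model = TwoLocusModel(small_pop.pedigree.design)
    fa = small_pop.marker_model.founder_alleles[:8]
    calls = small_pop.calls[:, :8]
    rf = estimate_rf_matrix(calls, fa, model)
    perm = np.array([3, 1, 4, 0, 7, 2, 6, 5])
    rf_p = estimate_rf_matrix(calls[:, perm], fa[perm], model)
    assert np.allclose(rf_p, rf[np.ix_(perm, perm)])


def test_likelihood_consistency_at_scale():
    """The grid-snapped true r is within one grid step of the MLE at n=2000."""
    r_true = 0.15
    d = float(haldane_d(r_true))
    ms = GeneticMapSpec(
        chromosomes=[("c1", 50.0)], markers={"c1": np.array([10.0, 10.0 + d])}
    )
    design = DesignSpec(n_funnels=315, lines_per_funnel=7)
    mm = random_marker_model(ms, seed=6, alleles="unique")
    pop = simulate_design(design, ms, seed=31, marker_model=mm)
    model = TwoLocusModel(design)
    est = estimate_rf(
        pop.calls[:, 0], pop.calls[:, 1], mm.founder_alleles[0], mm.founder_alleles[1], model
    )
    assert abs(est.rf - r_true) <= 1 / 120 + 1e-12


# -- distortion weights -----------------------------------------------------


def test_weights_neutral_when_frequency_at_expectation():
    carrier = np.zeros(80, dtype=bool)
    carrier[:10] = True  # exactly 1/8
    w = distortion_weights(carrier, 0)
    assert np.allclose(w, 1.0)


def test_weights_quarter_frequency_ratio():
    """Carrier frequency 1/4 -> carrier/non-carrier weight ratio 3/7."""
    carrier = np.zeros(100, dtype=bool)
    carrier[:25] = True
    w = distortion_weights(carrier, 0)
    ratio = w[carrier][0] / w[~carrier][0]
    assert ratio == pytest.approx(3 / 7)
    assert (w * carrier).sum() / w.sum() == pytest.approx(1 / 8)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(1, 199), st.sampled_from([0, 2, 3]))
def test_weights_restore_expected_frequency(n_carriers, gens):
    carrier = np.zeros(200, dtype=bool)
    carrier[:n_carriers] = True
    w = distortion_weights(carrier, gens)
    assert (w * carrier).sum() / w.sum() == pytest.approx(1 / 8)
    assert w.mean() == pytest.approx(1.0)


def test_weights_zero_carriers_neutral():
    assert np.allclose(distortion_weights(np.zeros(50, dtype=bool), 0), 1.0)


def test_weighted_rf_less_biased_across_drive_locus():
    from magicmap.simulate import DistortionSpec, founder_at

    r_true = 0.1
    d = float(haldane_d(r_true))
    ms = GeneticMapSpec(
        chromosomes=[("c1", 40.0)], markers={"c1": np.array([10.0, 10.0 + d])}
    )
    design = DesignSpec(n_funnels=315, lines_per_funnel=6)
    drive = DistortionSpec(
        kind="drive", chrom="c1", pos=10.0 + d / 2, founder=2, strength=0.8
    )
    mm = random_marker_model(ms, seed=5, alleles="unique")
    pop = simulate_design(design, ms, seed=77, marker_model=mm, distortions=[drive])
    carrier = np.array(
        [
            2
            in (
                founder_at(pop.genomes[r]["c1"][0], 10.0 + d / 2),
                founder_at(pop.genomes[r]["c1"][1], 10.0 + d / 2),
            )
            for r in pop.ril_ids
        ]
    )
    w = distortion_weights(carrier, 0)
    model = TwoLocusModel(design)
    fa = mm.founder_alleles
    un = estimate_rf(pop.calls[:, 0], pop.calls[:, 1], fa[0], fa[1], model)
    we = estimate_rf(pop.calls[:, 0], pop.calls[:, 1], fa[0], fa[1], model, weights=w)
    assert abs(we.rf - r_true) <= abs(un.rf - r_true)
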