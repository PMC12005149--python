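"""Chi-squared segregation-distortion scans and their calibration."""

import numpy as np
import pytest

from magicmap.pedigree import DesignSpec
from magicmap.simulate import DistortionSpec, GeneticMapSpec, simulate_design
from magicmap.hmm_ibd import posteriors_at_positions, state_index
from magicmap.distortion import (
    STRICT_P_THRESHOLD,
    bonferroni_alpha,
    composition_scan,
    funnel_effect_scan,
    g1_partners_for,
    homozygous_probs,
    interaction_scan,
    interaction_test,
    position_grid,
    probs_from_states,
    sex_effect_scan,
    sex_roles_for,
)


def test_bonferroni_arithmetic():
    assert bonferroni_alpha(22992937) == pytest.approx(0.0073, abs=5e-5)
    assert STRICT_P_THRESHOLD == pytest.approx(10**-9.5)


def test_position_grid_spacing():
    ms = GeneticMapSpec(chromosomes=[("c1", 10.0), ("c2", 4.5)], markers={})
    chrom, pos = position_grid(ms)
    assert np.allclose(pos[chrom == "c1"], np.arange(11.0))
    assert np.allclose(pos[chrom == "c2"], np.arange(5.0))


def test_homozygous_renormalization_excludes_het_lines():
    probs = np.zeros((2, 1, 36))
    probs[0, 0, 3] = 0.6
    probs[0, 0, 5] = 0.4
    probs[1, 0, state_index(0, 1)] = 1.0  # pure heterozygote
    hom, valid = homozygous_probs(probs)
    assert valid[0, 0] and not valid[1, 0]
    assert hom[0, 0].sum() == pytest.approx(1.0)
    assert hom[0, 0, 3] == pytest.approx(0.6)


def test_composition_statistic_zero_iff_uniform():
    probs = np.zeros((80, 1, 36))
    probs[:, 0, :8] = 1.0 / 8
    scan = composition_scan(probs, np.array(["c1"]), np.array([0.0]))
    assert scan["statistic"][0] == pytest.approx(0.0)
    assert scan["p"][0] == pytest.approx(1.0)
    probs[0, 0, :8] = 0
    probs[0, 0, 0] = 1.0
    scan2 = composition_scan(probs, np.array(["c1"]), np.array([0.0]))
    assert scan2["statistic"][0] > 0


def test_interaction_statistic_zero_for_outer_product_joint():
    """When every line's joint is the same product p x c the averaged
    matrix equals its margins' outer product and the statistic is 0."""
    rng = np.random.default_rng(0)
    p1 = rng.dirichlet(np.ones(8))
    p2 = rng.dirichlet(np.ones(8))
    q1 = np.tile(p1, (400, 1))
    q2 = np.tile(p2, (400, 1))
    stat, df, pval, M = interaction_test(q1, q2)
    assert stat == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(M, np.outer(p1, p2))


def test_interaction_degenerate_margin_handled():
    """A locus fixed for one founder yields no testable interaction."""
    probs = np.zeros((100, 8))
    probs[:, 2] = 1.0
    stat, df, pval, _ = interaction_test(probs, np.tile(np.full(8, 1 / 8), (100, 1)))
    assert df == 0 and np.isnan(stat)


def test_scans_invariant_to_line_order(small_pop):
    probs = probs_from_states(small_pop.true_states)
    chrom, pos = small_pop.marker_chrom, small_pop.marker_pos
    g = np.array(["chr1"]), np.array([50.0])
    gp = posteriors_at_positions(probs, pos, chrom, *g)
    rng = np.random.default_rng(1)
    perm = rng.permutation(small_pop.n_lines)
    s1 = composition_scan(gp, *g)
    s2 = composition_scan(gp[perm], *g)
    assert s1["statistic"][0] == pytest.approx(s2["statistic"][0])
    roles = sex_roles_for(small_pop.pedigree, small_pop.ril_ids, 0)
    t1 = sex_effect_scan(gp, *g, roles, 0)
    t2 = sex_effect_scan(gp[perm], *g, roles[perm], 0)
    assert t1["statistic"][0] == pytest.approx(t2["statistic"][0])


def test_drive_detection_peak_near_locus():
    design = DesignSpec(n_funnels=315, lines_per_funnel=6)
    ms = GeneticMapSpec.uniform(1, 100.0, 21)
    drive = DistortionSpec(kind="drive", chrom="chr1", pos=43.0, founder=2,
                           strength=0.75)
    pop = simulate_design(design, ms, seed=13, distortions=[drive])
    probs = probs_from_states(pop.true_states)
    gchrom, gpos = position_grid(ms)
    gp = posteriors_at_positions(probs, pop.marker_pos, pop.marker_chrom, gchrom, gpos)
    scan = composition_scan(gp, gchrom, gpos)
    peak = scan.loc[scan["statistic"].idxmax()]
    assert abs(peak["pos"] - 43.0) <= 5.0
    assert peak["founder2"] > 0.125  # the driven founder is in excess


def test_interaction_depletion_cell_is_minimum():
    """A x0.2 penalized combination shows up as the most depleted cell."""
    design = DesignSpec(n_funnels=315, lines_per_funnel=6)
    ms = GeneticMapSpec.uniform(2, 100.0, 11)
    inter = DistortionSpec(kind="interaction", chrom="chr1", pos=30.0, founder=1,
                           chrom2="chr2", pos2=60.0, founder2=4, strength=0.2)
    pop = simulate_design(design, ms, seed=17, distortions=[inter])
    probs = probs_from_states(pop.true_states)
    gchrom = np.array(["chr1", "chr2"])
    gpos = np.array([30.0, 60.0])
    gp = posteriors_at_positions(probs, pop.marker_pos, pop.marker_chrom, gchrom, gpos)
    hom, _ = homozygous_probs(gp)
    _, _, _, M = interaction_test(hom[:, 0, :], hom[:, 1, :])
    ratio = M / np.outer(M.sum(axis=1), M.sum(axis=0))
    assert np.unravel_index(np.argmin(ratio), ratio.shape) == (1, 4)


def test_interaction_scan_rejects_same_chromosome_pairs(small_pop):
    probs = probs_from_states(small_pop.true_states)[:, :2, :]
    with pytest.raises(ValueError):
        interaction_scan(probs, np.array(["c1", "c1"]), np.array([0.0, 1.0]),
                         pairs=[(0, 1)])


def test_sex_scan_equal_carriage_zero_statistic():
    probs = np.zeros((40, 1, 36))
    probs[:, 0, :8] = 1 / 8
    roles = np.array(["maternal"] * 20 + ["paternal"] * 20)
    scan = sex_effect_scan(probs, np.array(["c1"]), np.array([0.0]), roles, 3)
    assert scan["statistic"][0] == pytest.approx(0.0, abs=1e-9)


def test_sex_specific_drive_detected():
    design = DesignSpec(n_funnels=315, lines_per_funnel=10)
    ms = GeneticMapSpec.uniform(1, 100.0, 11)
    sex = DistortionSpec(kind="sex", chrom="chr1", pos=40.0, founder=5,
                         strength=0.85, role="maternal")
    pop = simulate_design(design, ms, seed=23, distortions=[sex])
    probs = probs_from_states(pop.true_states)
    gchrom, gpos = position_grid(ms, spacing=10.0)
    gp = posteriors_at_positions(probs, pop.marker_pos, pop.marker_chrom, gchrom, gpos)
    roles = sex_roles_for(pop.pedigree, pop.ril_ids, 5)
    scan = sex_effect_scan(gp, gchrom, gpos, roles, 5)
    best = scan.loc[scan["p"].idxmin()]
    assert abs(best["pos"] - 40.0) <= 10.0
    assert best["maternal_carriage"] > best["paternal_carriage"]
    assert best["p"] < 1e-4


def test_funnel_effect_detected_and_group_depleted():
    design = DesignSpec(n_funnels=315, lines_per_funnel=8)
    ms = GeneticMapSpec.uniform(1, 100.0, 11)
    fun = DistortionSpec(kind="funnel", chrom="chr1", pos=40.0, founder=3,
                         partner=6, strength=0.02)
    pop = simulate_design(design, ms, seed=29, distortions=[fun])
    probs = probs_from_states(pop.true_states)
    gchrom, gpos = position_grid(ms, spacing=20.0)
    gp = posteriors_at_positions(probs, pop.marker_pos, pop.marker_chrom, gchrom, gpos)
    partners = g1_partners_for(pop.pedigree, pop.ril_ids, 3)
    scan = funnel_effect_scan(gp, gchrom, gpos, partners, 3)
    assert scan["p"].min() < 1e-6
    hom, _ = homozygous_probs(gp)
    k = int(np.argmin(np.abs(gpos - 40.0)))
    carriage = {g: hom[partners == g, k, 3].mean() for g in range(8) if g != 3}
    assert min(carriage, key=carriage.get) == 6
    assert carriage[6] < 0.02


def test_funnel_scan_identical_carriage_zero():
    probs = np.zeros((70, 1, 36))
    probs[:, 0, :8] = 1 / 8
    partners = np.array(([0] * 10 + [1] * 10 + [2] * 10 + [4] * 10 + [5] * 10
                         + [6] * 10 + [7] * 10))
    scan = funnel_effect_scan(probs, np.array(["c1"]), np.array([0.0]), partners, 3)
    assert scan["statistic"][0] == pytest.approx(0.0, abs=1e-9)
    assert scan["df"][0] == 6
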