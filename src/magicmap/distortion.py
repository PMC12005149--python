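"""Chi-squared segregation-distortion scans on founder-IBD probabilities.

All four scans operate on per-line IBD state probabilities evaluated on a
1 cM grid of positions (interpolated from marker posteriors, or derived
from known mosaics). Marker heterozygotes are ignored throughout: each
line's 8 homozygous-state probabilities are renormalized, and lines with no
homozygous mass at a position drop out of that position's test.

``composition_scan``
    founder-composition vector vs the uniform 1/8 expectation; df 7.
``interaction_scan``
    8x8 joint founder matrix at two positions on *different* chromosomes vs
    independence; df 49; pairs flagged at p < 10^-9.5.
``sex_effect_scan``
    carriage of one founder between lines with that founder as an
    all-maternal vs all-paternal contribution; 2x2 table, df 1.
``funnel_effect_scan``
    carriage of one founder between the seven groups defined by its G1
    crossing partner; 7x2 table, df 6.

The "contingency tables" have non-integer entries (sums of probabilities);
the chi-squared reference distribution remains valid by the central limit
theorem.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import N_FOUNDERS, Pedigree
from .hmm_ibd import N_STATES

#: per-test significance threshold used to flag pairwise interactions
STRICT_P_THRESHOLD = 10.0 ** -9.5


def bonferroni_alpha(n_tests: int, per_test_p: float = STRICT_P_THRESHOLD) -> float:
    """Family-wise error level implied by a per-test threshold."""
    return n_tests * per_test_p


def position_grid(mapspec, spacing: float = 1.0):
    """(chrom array, position array) of grid points per chromosome.

    Positions run from 0 to the chromosome length at exactly ``spacing`` cM.
    """
    chroms, pos = [], []
    for c, length in mapspec.chromosomes:
        p = np.arange(0.0, length + 1e-9, spacing)
        chroms.extend([c] * len(p))
        pos.extend(p)
    return np.array(chroms), np.array(pos)


def homozygous_probs(probs, eps: float = 1e-12):
    """Renormalize the 8 homozygous-state probabilities per line.

    ``probs`` is (..., 36); returns (renormalized (..., 8), valid mask) where
    invalid entries (no homozygous mass) are zeroed and excluded.
    """
    probs = np.asarray(probs)
    hom = probs[..., :N_FOUNDERS]
    mass = hom.sum(axis=-1)
    valid = mass > eps
    out = np.zeros_like(hom)
    np.divide(hom, mass[..., None], out=out, where=valid[..., None])
    return out, valid


def probs_from_states(states: np.ndarray) -> np.ndarray:
    """Degenerate IBD probabilities (0/1) from known state codes."""
    states = np.asarray(states)
    out = np.zeros(states.shape + (N_STATES,))
    np.put_along_axis(out, states[..., None], 1.0, axis=-1)
    return out


def _chi2_result(stat, df):
    return float(stat), int(df), float(stats.chi2.sf(stat, df)) if df > 0 else np.nan


def composition_scan(probs, chrom, positions) -> pd.DataFrame:
    """Founder-composition test at every supplied position.

    ``probs`` is (n_lines, n_positions, 36) evaluated at the grid points.
    The statistic at each position is ``n_eff * sum_f (p_f - 1/8)^2 / (1/8)``
    with p the average renormalized homozygous probabilities over the
    ``n_eff`` contributing lines.
    """
    hom, valid = homozygous_probs(probs)
    rows = []
    for k in range(hom.shape[1]):
        n_eff = int(valid[:, k].sum())
        if n_eff == 0:
            continue
        p = hom[valid[:, k], k, :].mean(axis=0)
        stat = n_eff * np.sum((p - 1.0 / N_FOUNDERS) ** 2 / (1.0 / N_FOUNDERS))
        stat, df, pval = _chi2_result(stat, N_FOUNDERS - 1)
        rows.append((chrom[k], positions[k], n_eff, stat, df, pval, *p))
    cols = ["chrom", "pos", "n_eff", "statistic", "df", "p"] + [
        f"founder{i}" for i in range(N_FOUNDERS)
    ]
    return pd.DataFrame(rows, columns=cols)


def _pool_axis(M, margins, floor_mass):
    """Merge the two smallest categories along an axis until all margins
    carry at least ``floor_mass``; returns grouping lists."""
    groups = [[i] for i in range(len(margins))]
    margins = list(margins)
    while len(groups) > 2 and min(margins) < floor_mass:
        order = np.argsort(margins)
        i, j = sorted((order[0], order[1]))
        margins[i] += margins[j]
        groups[i] = groups[i] + groups[j]
        del margins[j], groups[j]
    return groups


def interaction_test(q1, q2, expected_floor: float = 0.5):
    """Independence test for the joint founder distribution at two loci.

    ``q1``/``q2`` are (n_lines, 8) renormalized homozygous probabilities at
    the two positions (zero rows for excluded lines). The per-line joint is
    the outer product (independence across chromosomes given the design);
    the averaged 8x8 matrix is tested against the product of its margins.
    Cells with expected count below ``expected_floor`` are pooled, reducing
    the degrees of freedom, with a warning.

    Returns (statistic, df, p, M) where M is the averaged joint matrix.
    """
    v1 = q1.sum(axis=1) > 0
    v2 = q2.sum(axis=1) > 0
    sel = v1 & v2
    n_eff = int(sel.sum())
    if n_eff == 0:
        return np.nan, 0, np.nan, np.full((8, 8), np.nan)
    M = np.einsum("li,lj->ij", q1[sel], q2[sel]) / n_eff
    r = M.sum(axis=1)
    c = M.sum(axis=0)
    # categories with no mass at all carry no information: drop before pooling
    rkeep = np.where(r > 0)[0]
    ckeep = np.where(c > 0)[0]
    if len(rkeep) < 2 or len(ckeep) < 2:
        return np.nan, 0, np.nan, M
    Mk = M[np.ix_(rkeep, ckeep)]
    rg = _pool_axis(Mk, n_eff * Mk.sum(axis=1), expected_floor)
    cg = _pool_axis(Mk.T, n_eff * Mk.sum(axis=0), expected_floor)
    if len(rg) < len(rkeep) or len(cg) < len(ckeep) or len(rkeep) < N_FOUNDERS \
            or len(ckeep) < N_FOUNDERS:
        warnings.warn("sparse expected cells pooled/dropped; df reduced")
    Mp = np.array([[Mk[np.ix_(g1, g2)].sum() for g2 in cg] for g1 in rg])
    rp = Mp.sum(axis=1)
    cp = Mp.sum(axis=0)
    E = np.outer(rp, cp)
    stat = n_eff * np.sum((Mp - E) ** 2 / E)
    df = (len(rg) - 1) * (len(cg) - 1)
    stat, df, pval = _chi2_result(stat, df)
    return stat, df, pval, M


def interaction_scan(
    probs, chrom, positions, pairs=None, threshold: float = STRICT_P_THRESHOLD
) -> pd.DataFrame:
    """Pairwise scan over position pairs on different chromosomes.

    ``pairs`` restricts the scan to an iterable of (index1, index2) into
    the position arrays; by default all cross-chromosome pairs are tested.
    """
    hom, _ = homozygous_probs(probs)
    chrom = np.asarray(chrom)
    if pairs is None:
        m = len(positions)
        pairs = [
            (i, j) for i in range(m) for j in range(i + 1, m) if chrom[i] != chrom[j]
        ]
    rows = []
    for i, j in pairs:
        if chrom[i] == chrom[j]:
            raise ValueError("interaction pairs must be on different chromosomes")
        stat, df, pval, _ = interaction_test(hom[:, i, :], hom[:, j, :])
        rows.append(
            (chrom[i], positions[i], chrom[j], positions[j], stat, df, pval,
             bool(pval < threshold))
        )
    return pd.DataFrame(
        rows,
        columns=["chrom1", "pos1", "chrom2", "pos2", "statistic", "df", "p",
                 "significant"],
    )


def _pearson_table(table):
    """Pearson chi-squared for a (groups x 2) expected-count table."""
    table = np.asarray(table, dtype=float)
    keep = table.sum(axis=1) > 0
    dropped = int((~keep).sum())
    table = table[keep]
    if table.shape[0] < 2 or table.sum() == 0:
        return np.nan, 0, np.nan, dropped
    E = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        cells = (table - E) ** 2 / E
    stat = np.nansum(cells)
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    s, df, p = _chi2_result(stat, df)
    return s, df, p, dropped


def sex_effect_scan(probs, chrom, positions, roles, founder: int) -> pd.DataFrame:
    """Sex-of-founder effect on the inheritance of ``founder``.

    ``roles`` assigns each line 'maternal' (founder f contributed maternally
    at every mixing cross), 'paternal', or 'mixed'; mixed lines are
    excluded. At each position the 2x2 table of probability-sum counts
    (subset x carries-f / not) is tested with df 1.
    """
    roles = np.asarray(roles)
    hom, valid = homozygous_probs(probs)
    rows = []
    for k in range(hom.shape[1]):
        tab = []
        for role in ("maternal", "paternal"):
            sel = (roles == role) & valid[:, k]
            pf = hom[sel, k, founder]
            tab.append((pf.sum(), (1.0 - pf).sum()))
        if min(t[0] + t[1] for t in tab) == 0:
            continue
        stat, df, pval, _ = _pearson_table(tab)
        rows.append((chrom[k], positions[k], stat, df, pval,
                     tab[0][0] / sum(tab[0]), tab[1][0] / sum(tab[1])))
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "statistic", "df", "p",
                 "maternal_carriage", "paternal_carriage"],
    )


def funnel_effect_scan(probs, chrom, positions, partners, founder: int) -> pd.DataFrame:
    """G1-partner (funnel) effect on the inheritance of ``founder``.

    ``partners`` gives, per line, the founder crossed with ``founder`` in
    the first generation of its funnel (-1 to exclude). The seven partner
    groups are tested for differences in expected carriage of ``founder``;
    empty groups are dropped with the df reduced accordingly.
    """
    partners = np.asarray(partners)
    hom, valid = homozygous_probs(probs)
    others = [f for f in range(N_FOUNDERS) if f != founder]
    rows = []
    for k in range(hom.shape[1]):
        tab = []
        for g in others:
            sel = (partners == g) & valid[:, k]
            pf = hom[sel, k, founder]
            tab.append((pf.sum(), (1.0 - pf).sum()))
        stat, df, pval, dropped = _pearson_table(tab)
        rows.append((chrom[k], positions[k], stat, df, pval, dropped))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "statistic", "df", "p", "groups_dropped"]
    )


def sex_roles_for(pedigree: Pedigree, line_ids, founder: int) -> np.ndarray:
    """Per-line maternal/paternal/mixed role of ``founder`` (MP8RIL lines)."""
    return np.array(
        [pedigree.maternal_founder_roles(l)[founder] for l in line_ids]
    )


def g1_partners_for(pedigree: Pedigree, line_ids, founder: int) -> np.ndarray:
    """Per-line G1 partner founder of ``founder`` (MP8RIL lines)."""
    return np.array([pedigree.g1_partner(l, founder) for l in line_ids])
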