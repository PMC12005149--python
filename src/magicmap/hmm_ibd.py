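"""Hidden-Markov founder-IBD imputation along chromosomes.

The hidden state of a line at a locus is its IBD genotype: an unordered
pair of founders, giving 8 homozygous + 28 heterozygous = 36 states,
indexed consistently with the founder order. Transition matrices between
adjacent loci are built from the exact two-locus design distribution at the
Haldane recombination fraction of the inter-locus distance, conditioned on
the first-locus state — an approximation to the full multipoint
probabilities that is known to be highly accurate at moderate marker
spacing. Emissions compare observed marker calls to the call expected under
the state's founder alleles, with a symmetric error parameter (default
0.1) confined to the emission layer.

Forward-backward gives per-locus posterior state probabilities; Viterbi
gives the most likely state path, from which haplotype blocks,
recombination-event counts and residual heterozygosity are derived.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .pedigree import DesignSpec, N_FOUNDERS
from .simulate import state_class_codes
from .twopoint import TwoLocusModel, haldane_r

N_STATES = 36
DEFAULT_ERROR_RATE = 0.1

_PAIRS = [(i, i) for i in range(N_FOUNDERS)] + list(
    itertools.combinations(range(N_FOUNDERS), 2)
)
_INDEX = {p: s for s, p in enumerate(_PAIRS)}


def state_index(fa: int, fb: int) -> int:
    """State code of an unordered founder pair."""
    return _INDEX[(fa, fb) if fa <= fb else (fb, fa)]


def state_pair(state: int) -> tuple:
    """Founder pair (i <= j) of a state code."""
    return _PAIRS[state]


HOM_STATES = np.arange(N_FOUNDERS)
HET_STATES = np.arange(N_FOUNDERS, N_STATES)


@dataclass(frozen=True)
class HMMParams:
    """Design, genotyping-error rate and candidate grid for the HMM."""

    design: DesignSpec
    error_rate: float = DEFAULT_ERROR_RATE

    def __post_init__(self):
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")


@lru_cache(maxsize=None)
def _transition_cached(design_key, d: float):
    design = DesignSpec(
        n_funnels=design_key[0],
        intercross_generations=design_key[1],
        selfing_generations=design_key[2],
    )
    model = TwoLocusModel(design)
    r = float(haldane_r(d))
    J = model.genotype_joint36(min(r, 0.5))
    marg = J.sum(axis=1, keepdims=True)
    T = np.divide(J, marg, out=np.full_like(J, 1.0 / N_STATES), where=marg > 0)
    return T


def _design_key(design: DesignSpec):
    return (
        design.n_funnels,
        design.intercross_generations,
        design.selfing_generations,
    )


def transition_matrix(d: float, design: DesignSpec) -> np.ndarray:
    """36x36 stochastic matrix for adjacent loci ``d`` cM apart.

    Rows condition on the first-locus state of the exact two-locus joint at
    the Haldane recombination fraction of ``d``. ``d = 0`` gives the
    identity; ``d -> inf`` gives rows equal to the stationary single-locus
    distribution.
    """
    if d < 0:
        raise ValueError("distance must be >= 0")
    return _transition_cached(_design_key(design), round(float(d), 9))


def initial_distribution(design: DesignSpec) -> np.ndarray:
    """Single-locus IBD state distribution for the design."""
    model = TwoLocusModel(design)
    return model.single_locus36()


def emission_matrix(alleles_row, error_rate: float) -> np.ndarray:
    """E[call code, state]: probability of each observable call per state.

    The call expected under the state's founder alleles receives
    ``1 - error_rate``; the remainder is spread uniformly over the other
    observable classes. Missing calls are handled separately (no
    information).
    """
    codes = state_class_codes(alleles_row)
    n_classes = int(codes.max()) + 1
    if n_classes == 1:
        return np.ones((1, N_STATES))
    E = np.full((n_classes, N_STATES), error_rate / (n_classes - 1))
    E[codes, np.arange(N_STATES)] = 1.0 - error_rate
    return E


def _emissions(calls, founder_alleles, error_rate):
    """(n_lines, n_loci, 36) emission likelihoods; missing -> all ones."""
    calls = np.atleast_2d(np.asarray(calls))
    n, m = calls.shape
    em = np.ones((n, m, N_STATES))
    for j in range(m):
        E = emission_matrix(np.asarray(founder_alleles)[j], error_rate)
        obs = calls[:, j]
        ok = obs >= 0
        em[ok, j, :] = E[obs[ok]]
    return em


def _chain_matrices(positions, design):
    d = np.diff(np.asarray(positions, dtype=float))
    if np.any(d < 0):
        raise ValueError("positions must be non-decreasing")
    return [transition_matrix(float(x), design) for x in d]


def forward_backward(calls, founder_alleles, positions, params: HMMParams):
    """Posterior state probabilities, shape (n_lines, n_loci, 36).

    ``calls`` is (n_lines, n_loci) observable-class codes with -1 missing;
    all lines share the design (funnel-averaged transitions) but have
    individual emissions. Posteriors are normalized per locus.
    """
    em = _emissions(calls, founder_alleles, params.error_rate)
    n, m, _ = em.shape
    Ts = _chain_matrices(positions, params.design)
    pi = initial_distribution(params.design)

    alpha = np.empty((n, m, N_STATES))
    a = pi[None, :] * em[:, 0, :]
    a = _normalize_rows(a)
    alpha[:, 0] = a
    for t in range(1, m):
        a = (a @ Ts[t - 1]) * em[:, t, :]
        a = _normalize_rows(a)
        alpha[:, t] = a

    beta = np.ones((n, N_STATES))
    post = np.empty((n, m, N_STATES))
    post[:, m - 1] = _normalize_rows(alpha[:, m - 1] * beta)
    for t in range(m - 2, -1, -1):
        beta = (beta * em[:, t + 1, :]) @ Ts[t].T
        beta = _normalize_rows(beta)
        post[:, t] = _normalize_rows(alpha[:, t] * beta)
    return post


def _normalize_rows(a):
    s = a.sum(axis=-1, keepdims=True)
    bad = ~(s > 0)
    if np.any(bad):
        warnings.warn("zero-probability observation sequence; applying floor")
        a = np.where(bad, 1.0, a)
        s = a.sum(axis=-1, keepdims=True)
    return a / s


def viterbi(calls, founder_alleles, positions, params: HMMParams) -> np.ndarray:
    """Most likely state path per line, shape (n_lines, n_loci).

    Ties are broken toward the lowest state index.
    """
    em = _emissions(calls, founder_alleles, params.error_rate)
    n, m, _ = em.shape
    Ts = _chain_matrices(positions, params.design)
    with np.errstate(divide="ignore"):
        log_pi = np.log(initial_distribution(params.design))
        log_em = np.log(np.maximum(em, 1e-300))
        log_T = [np.log(np.maximum(T, 1e-300)) for T in Ts]

    delta = log_pi[None, :] + log_em[:, 0, :]
    psi = np.empty((n, m, N_STATES), dtype=np.int8)
    for t in range(1, m):
        cand = delta[:, :, None] + log_T[t - 1][None, :, :]
        psi[:, t] = np.argmax(cand, axis=1)
        delta = np.max(cand, axis=1) + log_em[:, t, :]
    path = np.empty((n, m), dtype=np.int16)
    path[:, m - 1] = np.argmax(delta, axis=1)
    for t in range(m - 2, -1, -1):
        path[:, t] = psi[np.arange(n), t + 1, path[:, t + 1]]
    return path


def path_log_probability(path, calls, founder_alleles, positions, params) -> float:
    """Log probability of one explicit state path (for oracle checks)."""
    em = _emissions(calls, founder_alleles, params.error_rate)[0]
    Ts = _chain_matrices(positions, params.design)
    pi = initial_distribution(params.design)
    with np.errstate(divide="ignore"):
        lp = np.log(pi[path[0]]) + np.log(em[0, path[0]])
        for t in range(1, len(path)):
            lp += np.log(Ts[t - 1][path[t - 1], path[t]]) + np.log(em[t, path[t]])
    return float(lp)


# ---------------------------------------------------------------------------
# blocks, recombination counts, heterozygosity


@dataclass
class BlockSummary:
    """Viterbi-path derived quantities for a set of lines."""

    #: list over lines of lists of (chrom, start, end, state)
    blocks: list
    #: (n_lines, n_chromosomes) recombination-event counts
    recombination_counts: np.ndarray
    #: per-line residual heterozygosity (map-length-weighted)
    heterozygosity: np.ndarray


def _haplotype_changes(s1: int, s2: int) -> int:
    a = list(state_pair(s1))
    b = list(state_pair(s2))
    inter = 0
    for x in a:
        if x in b:
            b.remove(x)
            inter += 1
    return 2 - inter


def blocks_and_recombination(paths, positions, chrom, mapspec=None) -> BlockSummary:
    """Haplotype blocks, recombination counts and residual heterozygosity.

    ``paths`` is (n_lines, n_loci) Viterbi states; ``positions`` and
    ``chrom`` give each locus's chromosome-relative position and chromosome.
    Block boundaries are the midpoints between adjacent markers; the
    recombination count of a state change is the number of haplotypes that
    changed founder (1 for hom -> het sharing a founder, 2 for a full
    switch). Heterozygosity is the map-length-weighted fraction of the path
    in heterozygous states; with ``mapspec`` given, chromosome ends extend
    the terminal blocks.
    """
    paths = np.atleast_2d(paths)
    positions = np.asarray(positions, dtype=float)
    chrom = np.asarray(chrom)
    chrom_names = list(dict.fromkeys(chrom.tolist()))
    n = paths.shape[0]
    rec = np.zeros((n, len(chrom_names)), dtype=int)
    het_len = np.zeros(n)
    tot_len = 0.0
    all_blocks = [[] for _ in range(n)]

    for ci, c in enumerate(chrom_names):
        sel = chrom == c
        pos = positions[sel]
        sub = paths[:, sel]
        if mapspec is not None:
            lo, hi = 0.0, mapspec.length(c)
        else:
            lo, hi = pos[0], pos[-1]
        mids = 0.5 * (pos[:-1] + pos[1:])
        bounds = np.concatenate([[lo], mids, [hi]])
        seg_len = np.diff(bounds)
        tot_len += hi - lo
        is_het = sub >= N_FOUNDERS
        het_len += (is_het * seg_len[None, :]).sum(axis=1)
        for li in range(n):
            states = sub[li]
            start = bounds[0]
            for k in range(1, len(states)):
                if states[k] != states[k - 1]:
                    rec[li, ci] += _haplotype_changes(states[k - 1], states[k])
                    all_blocks[li].append((c, start, bounds[k], int(states[k - 1])))
                    start = bounds[k]
            all_blocks[li].append((c, start, bounds[-1], int(states[-1])))
    return BlockSummary(
        blocks=all_blocks,
        recombination_counts=rec,
        heterozygosity=het_len / tot_len if tot_len else het_len,
    )


def posteriors_at_positions(post, positions, chrom, grid_chrom, grid_pos):
    """Interpolate marker posteriors to arbitrary (chrom, position) points.

    Linear interpolation in distance between flanking markers, renormalized;
    points outside the marker span take the nearest marker's posteriors.
    Returns (n_lines, n_grid, 36).
    """
    post = np.asarray(post)
    positions = np.asarray(positions, dtype=float)
    chrom = np.asarray(chrom)
    grid_chrom = np.asarray(grid_chrom)
    grid_pos = np.asarray(grid_pos, dtype=float)
    n = post.shape[0]
    out = np.empty((n, len(grid_pos), N_STATES))
    for c in np.unique(grid_chrom):
        gsel = grid_chrom == c
        msel = chrom == c
        mp = positions[msel]
        sub = post[:, msel, :]
        gp = np.clip(grid_pos[gsel], mp[0], mp[-1])
        hi = np.clip(np.searchsorted(mp, gp, side="left"), 1, len(mp) - 1)
        lo = hi - 1
        span = mp[hi] - mp[lo]
        w = np.where(span > 0, (gp - mp[lo]) / np.where(span > 0, span, 1.0), 0.0)
        vals = (1 - w)[None, :, None] * sub[:, lo, :] + w[None, :, None] * sub[:, hi, :]
        out[:, gsel, :] = vals / vals.sum(axis=2, keepdims=True)
    return out
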