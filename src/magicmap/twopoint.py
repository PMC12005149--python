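"""Two-locus probabilities and recombination-fraction maximum likelihood.

The central object is the exact joint distribution of founder-IBD genotypes
at two loci separated by meiotic recombination fraction ``r`` in a line
from a given MAGIC design. It is computed by propagating the two-locus
gamete distribution generation by generation — each meiosis recombines the
two loci with probability ``r`` — through the three mixing generations, any
advanced-intercross generations, and the selfing rounds. No Monte Carlo is
involved.

Representation: a gamete is a pair of founder labels (a at locus 1, b at
locus 2), coded ``8*a + b`` (64 gametes); a diploid line is an ordered pair
of gametes (64 x 64 matrix of probabilities). The canonical funnel is
((0 x 1) x (2 x 3)) x ((4 x 5) x (6 x 7)); distributions for other funnels
follow by relabelling founders, and the *funnel-averaged* distribution —
the exact marginal when every line's funnel is uniformly random, as in the
generator — follows by symmetrizing over founder permutations (which
reduces to averaging over the 15 equality patterns of the label 4-tuple).

Recombination fractions are estimated by numerical maximum likelihood over
a fixed grid of 61 candidate values on [0, 0.5], with optional per-line
weights correcting for known segregation distorters.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .pedigree import DesignSpec, N_FOUNDERS
from .simulate import marker_classes

#: the 61-value candidate grid: equally spaced on [0, 0.5] (step 1/120)
RF_GRID = np.linspace(0.0, 0.5, 61)

_N_GAM = N_FOUNDERS * N_FOUNDERS  # 64


def haldane_d(r):
    """Haldane map distance (cM) from recombination fraction."""
    r = np.asarray(r, dtype=float)
    return -50.0 * np.log1p(-2.0 * np.minimum(r, 0.5 - 1e-12))


def haldane_r(d):
    """Haldane recombination fraction from map distance (cM)."""
    d = np.asarray(d, dtype=float)
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


def n_marker_pairs(m: int) -> int:
    """Number of unordered marker pairs, m*(m-1)/2."""
    return m * (m - 1) // 2


# ---------------------------------------------------------------------------
# exact two-locus dynamic program


def _meiosis_matrix(r: float) -> np.ndarray:
    """Linear map from a diploid distribution (4096) to a gamete one (64)."""
    M = np.zeros((_N_GAM, _N_GAM * _N_GAM))
    g1 = np.repeat(np.arange(_N_GAM), _N_GAM)
    g2 = np.tile(np.arange(_N_GAM), _N_GAM)
    a1, b1 = g1 // 8, g1 % 8
    a2, b2 = g2 // 8, g2 % 8
    idx = np.arange(_N_GAM * _N_GAM)
    np.add.at(M, (g1, idx), (1 - r) / 2)
    np.add.at(M, (g2, idx), (1 - r) / 2)
    np.add.at(M, (a1 * 8 + b2, idx), r / 2)
    np.add.at(M, (a2 * 8 + b1, idx), r / 2)
    return M


def _symmetrize_gamete(g: np.ndarray) -> np.ndarray:
    """Average a gamete distribution over uniform founder relabelling."""
    s = g[np.arange(N_FOUNDERS) * 9].sum()  # non-recombinant (a == b) mass
    out = np.full(_N_GAM, (1.0 - s) / (_N_GAM - N_FOUNDERS))
    out[np.arange(N_FOUNDERS) * 9] = s / N_FOUNDERS
    return out


def _tuple_patterns() -> tuple:
    """Equality-pattern id of each (a1, b1, a2, b2) label 4-tuple."""
    pats = {}
    ids = np.empty(_N_GAM * _N_GAM, dtype=np.int64)
    k = 0
    for flat in range(_N_GAM * _N_GAM):
        g1, g2 = divmod(flat, _N_GAM)
        t = (g1 // 8, g1 % 8, g2 // 8, g2 % 8)
        canon = []
        seen = {}
        for x in t:
            seen.setdefault(x, len(seen))
            canon.append(seen[x])
        canon = tuple(canon)
        if canon not in pats:
            pats[canon] = k
            k += 1
        ids[flat] = pats[canon]
    return ids, k


_PATTERN_IDS, _N_PATTERNS = _tuple_patterns()
_PATTERN_COUNTS = np.bincount(_PATTERN_IDS, minlength=_N_PATTERNS)


def _symmetrize_diploid(D: np.ndarray) -> np.ndarray:
    """Average a diploid distribution over uniform founder relabelling."""
    sums = np.bincount(_PATTERN_IDS, weights=D.ravel(), minlength=_N_PATTERNS)
    return (sums / _PATTERN_COUNTS)[_PATTERN_IDS].reshape(_N_GAM, _N_GAM)


@lru_cache(maxsize=None)
def _diploid_dist_cached(design_key, r: float, exchangeable: bool):
    n_funnels, aic, selfs = design_key
    M = _meiosis_matrix(r)

    def gam(D):
        return M @ D.ravel()

    def self_once(D):
        MD = M * D.ravel()[None, :]
        return MD @ M.T

    def outer_cross(gm, gf):
        return np.outer(gm, gf)

    def delta_g1(a, b):
        D = np.zeros((_N_GAM, _N_GAM))
        D[a * 9, b * 9] = 1.0
        return D

    g2_left = outer_cross(gam(delta_g1(0, 1)), gam(delta_g1(2, 3)))
    g2_right = outer_cross(gam(delta_g1(4, 5)), gam(delta_g1(6, 7)))
    D = outer_cross(gam(g2_left), gam(g2_right))  # canonical-funnel G3 line

    if aic > 0:
        for _ in range(aic):
            g = _symmetrize_gamete(gam(D))
            D = outer_cross(g, g)
    for _ in range(selfs):
        D = self_once(D)
    if exchangeable and aic == 0:
        D = _symmetrize_diploid(D)
    return D


@dataclass(frozen=True)
class TwoLocusModel:
    """Exact two-locus IBD distributions for one MAGIC design.

    ``joint(r)`` returns the 64x64 ordered-gamete-pair distribution. With
    ``exchangeable=True`` (the default) it is the marginal over a uniformly
    random funnel; otherwise it is conditional on the canonical funnel
    (founder k in canonical role k), from which any specific funnel follows
    by relabelling.
    """

    design: DesignSpec

    def _key(self):
        return (
            self.design.n_funnels,
            self.design.intercross_generations,
            self.design.selfing_generations,
        )

    def joint(self, r: float, exchangeable: bool = True) -> np.ndarray:
        if not 0.0 <= r <= 0.5:
            raise ValueError("r must be in [0, 0.5]")
        return _diploid_dist_cached(self._key(), float(r), bool(exchangeable))

    def joint_grid(self, grid=RF_GRID, exchangeable: bool = True) -> np.ndarray:
        """Stack of joints, shape (len(grid), 64, 64)."""
        return np.stack([self.joint(r, exchangeable) for r in grid])

    def genotype_joint36(self, r: float, exchangeable: bool = True) -> np.ndarray:
        """36x36 joint over unordered IBD genotype states at the two loci."""
        from .hmm_ibd import state_index

        D = self.joint(r, exchangeable)
        J = np.zeros((36, 36))
        for g1 in range(_N_GAM):
            a1, b1 = divmod(g1, 8)
            for g2 in range(_N_GAM):
                a2, b2 = divmod(g2, 8)
                J[state_index(a1, a2), state_index(b1, b2)] += D[g1, g2]
        return J

    def single_locus36(self, exchangeable: bool = True) -> np.ndarray:
        """Marginal distribution over the 36 IBD genotype states."""
        return self.genotype_joint36(0.5, exchangeable).sum(axis=1)


# ---------------------------------------------------------------------------
# marker classes and likelihood tables


def _class_indicator(alleles_row) -> tuple:
    """(classes, A) where A[c, a1, a2] indicates founder pair -> class c."""
    classes = marker_classes(alleles_row)
    lookup = {c: k for k, c in enumerate(classes)}
    A = np.zeros((len(classes), N_FOUNDERS, N_FOUNDERS))
    for a1 in range(N_FOUNDERS):
        for a2 in range(N_FOUNDERS):
            c = lookup[tuple(sorted({alleles_row[a1], alleles_row[a2]}))]
            A[c, a1, a2] = 1.0
    return classes, A


def _pair_class_table(D_grid, A1, A2) -> np.ndarray:
    """P(class1, class2 | r) for each grid r; shape (n_r, C1, C2).

    ``D_grid`` is the (n_r, 64, 64) gamete-pair joint; the 64x64 layout is
    (a1, b1) x (a2, b2), so it is transposed to group locus-1 labels.
    """
    n_r = D_grid.shape[0]
    D4 = D_grid.reshape(n_r, 8, 8, 8, 8)  # a1, b1, a2, b2
    Dt = D4.transpose(0, 1, 3, 2, 4).reshape(n_r, 64, 64)  # (a1,a2) x (b1,b2)
    A1f = A1.reshape(-1, 64)
    A2f = A2.reshape(-1, 64)
    tmp = np.einsum("rij,ci->rcj", Dt, A1f)
    return np.einsum("rcj,dj->rcd", tmp, A2f)


@dataclass
class RFEstimate:
    rf: float
    max_loglik: float
    uninformative: bool = False


def _count_table(calls_i, calls_j, n_ci, n_cj, weights=None):
    ok = (calls_i >= 0) & (calls_j >= 0)
    w = np.ones(ok.sum()) if weights is None else np.asarray(weights)[ok]
    C = np.zeros((n_ci, n_cj))
    np.add.at(C, (calls_i[ok], calls_j[ok]), w)
    return C


def estimate_rf(
    calls_i,
    calls_j,
    alleles_i,
    alleles_j,
    model: TwoLocusModel,
    weights=None,
    grid=RF_GRID,
    funnels=None,
) -> RFEstimate:
    """Grid maximum-likelihood recombination fraction for one marker pair.

    ``calls_*`` are observable-class codes (see
    :func:`magicmap.simulate.marker_classes`), -1 for missing; missing calls
    contribute no likelihood term. Heterozygote classes are their own
    observable category. Ties are broken toward smaller r.

    With ``funnels`` (a per-line ordered funnel array) the likelihood is
    conditioned on each line's funnel; by default the funnel-averaged
    distribution is used, which is the exact marginal under uniform funnel
    sampling.
    """
    calls_i = np.asarray(calls_i)
    calls_j = np.asarray(calls_j)
    classes_i, A1 = _class_indicator(alleles_i)
    classes_j, A2 = _class_indicator(alleles_j)
    if len(classes_i) < 2 or len(classes_j) < 2:
        return RFEstimate(0.5, np.nan, uninformative=True)

    if funnels is None:
        D_grid = model.joint_grid(grid, exchangeable=True)
        P = _pair_class_table(D_grid, A1, A2)
        C = _count_table(calls_i, calls_j, len(classes_i), len(classes_j), weights)
        ll = np.einsum("cd,rcd->r", C, np.log(np.maximum(P, 1e-300)))
    else:
        D_grid = model.joint_grid(grid, exchangeable=False)
        funnels = np.asarray(funnels)
        ll = np.zeros(len(grid))
        uniq, inverse = np.unique(funnels, axis=0, return_inverse=True)
        for k, fun in enumerate(uniq):
            sel = inverse == k
            # founder fun[c] plays canonical role c: permute allele maps
            a_i = np.asarray(alleles_i)[list(fun)]
            a_j = np.asarray(alleles_j)[list(fun)]
            ci, A1k = _class_indicator(a_i)
            cj, A2k = _class_indicator(a_j)
            # class codes must be re-expressed in the permuted class list
            remap_i = np.array([ci.index(c) for c in classes_i])
            remap_j = np.array([cj.index(c) for c in classes_j])
            ii = np.where(calls_i[sel] >= 0, remap_i[calls_i[sel]], -1)
            jj = np.where(calls_j[sel] >= 0, remap_j[calls_j[sel]], -1)
            P = _pair_class_table(D_grid, A1k, A2k)
            w = None if weights is None else np.asarray(weights)[sel]
            C = _count_table(ii, jj, len(ci), len(cj), w)
            ll += np.einsum("cd,rcd->r", C, np.log(np.maximum(P, 1e-300)))

    if np.allclose(ll, ll[0]):
        return RFEstimate(0.5, float(ll[0]), uninformative=True)
    best = int(np.argmax(ll))
    return RFEstimate(float(grid[best]), float(ll[best]))


def estimate_rf_matrix(
    calls,
    founder_alleles,
    model: TwoLocusModel,
    weights=None,
    grid=RF_GRID,
) -> np.ndarray:
    """Symmetric matrix of grid-MLE recombination fractions.

    Uses a vectorized path for all-biallelic panels: the class table of a
    pair depends on the two allele maps only through (#allele-1 founders at
    each marker, overlap), so tables are precomputed per signature and the
    per-pair work reduces to weighted 3x3 count tables obtained by matrix
    products. Other panels fall back to per-pair estimation.
    """
    calls = np.asarray(calls)
    fa = np.asarray(founder_alleles)
    n, m = calls.shape
    if fa.shape != (m, N_FOUNDERS):
        raise ValueError("founder_alleles must be (n_markers, 8)")
    rf = np.zeros((m, m))
    biallelic = fa.max() <= 1
    if not biallelic:
        for i in range(m):
            for j in range(i + 1, m):
                est = estimate_rf(
                    calls[:, i], calls[:, j], fa[i], fa[j], model, weights, grid
                )
                rf[i, j] = rf[j, i] = est.rf
        return rf

    D_grid = model.joint_grid(grid, exchangeable=True)
    k = fa.sum(axis=1)  # allele-1 founder count per marker

    @lru_cache(maxsize=None)
    def table(k1, k2, k12):
        u = np.zeros(N_FOUNDERS, dtype=int)
        u[:k1] = 1
        v = np.zeros(N_FOUNDERS, dtype=int)
        v[:k12] = 1
        v[k1 : k1 + (k2 - k12)] = 1
        _, A1 = _class_indicator(u)
        _, A2 = _class_indicator(v)
        P = _pair_class_table(D_grid, A1, A2)  # (n_r, C1, C2)
        # embed into dosage coding 0/1/2 (monomorphic never reaches here)
        full = np.full((len(grid), 3, 3), 1e-300)
        ci = [c for c in range(3) if _dosage_class_exists(k1, c)]
        cj = [c for c in range(3) if _dosage_class_exists(k2, c)]
        full[np.ix_(range(len(grid)), ci, cj)] = np.maximum(P, 1e-300)
        return np.log(full).reshape(len(grid), 9)

    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    X = [((calls == c) * w[:, None]) for c in range(3)]
    Xu = [(calls == c).astype(float) for c in range(3)]
    counts = np.empty((3, 3, m, m))
    for c1 in range(3):
        for c2 in range(3):
            counts[c1, c2] = X[c1].T @ Xu[c2]
    counts = counts.reshape(9, m, m)

    k12 = (fa @ fa.T).astype(int)
    iu, ju = np.triu_indices(m, 1)
    sig = np.stack([k[iu], k[ju], k12[iu, ju]], axis=1)
    pair_counts = counts[:, iu, ju].T  # (n_pairs, 9)
    uniq, inverse = np.unique(sig, axis=0, return_inverse=True)
    best = np.empty(len(iu), dtype=int)
    for s, (k1, k2, kk) in enumerate(uniq):
        sel = inverse == s
        logP = table(int(k1), int(k2), int(kk))  # (n_r, 9)
        ll = pair_counts[sel] @ logP.T  # (n_sel, n_r)
        best[sel] = np.argmax(ll, axis=1)
    rf[iu, ju] = rf[ju, iu] = np.asarray(grid)[best]
    return rf


def _dosage_class_exists(k1, c):
    # dosage classes present for a biallelic marker with k1 allele-1 founders
    if c == 0:
        return k1 < N_FOUNDERS
    if c == 2:
        return k1 > 0
    return 0 < k1 < N_FOUNDERS


# ---------------------------------------------------------------------------
# distortion weights


def distortion_weights(carrier, intercross_generations, target_freq=None):
    """Per-line weights restoring the expected carrier frequency.

    Lines carrying the over-transmitted allele are down-weighted so that the
    weighted carrier frequency equals its neutral expectation (1/8 for a
    founder-specific allele) within each subpopulation, defined by the
    number of intercross generations. Weights are normalized to mean 1 per
    subpopulation; with carriers at the neutral frequency all weights are 1.
    """
    carrier = np.asarray(carrier, dtype=bool)
    gens = np.broadcast_to(np.asarray(intercross_generations), carrier.shape)
    target = 1.0 / N_FOUNDERS if target_freq is None else float(target_freq)
    w = np.ones(len(carrier))
    for g in np.unique(gens):
        sel = gens == g
        q = carrier[sel].mean()
        if q in (0.0, 1.0):
            continue
        ratio = (target * (1 - q)) / ((1 - target) * q)
        wk = np.where(carrier[sel], ratio, 1.0)
        w[sel] = wk / wk.mean()
    return w
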