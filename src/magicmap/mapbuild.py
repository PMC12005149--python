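"""Linkage groups, marker ordering and map-distance estimation.

Groups are formed by average-linkage hierarchical clustering of the
recombination-fraction matrix, cut into many small groups which are then
aggregated automatically (groups whose median inter-group recombination
fraction is below a threshold are merged).

Ordering within a group is two-stage anti-Robinson seriation. A matrix is
anti-Robinson when entries increase with distance from the diagonal; the
loss used here is the magnitude of monotonicity violations along each row,
moving away from the diagonal in both directions. The coarse stage
(:func:`cluster_order_cross`) seriates ~30 subgroups on their mean-RF
matrix; the fine stage (:func:`order_cross`) makes windowed local moves
(segment reversals and single-marker relocations) accepted when the loss
decreases.

Map distances come from an over-determined linear system: each informative
pair's Haldane distance equals the sum of the inter-marker gaps it spans;
the gaps are solved by non-negative least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.optimize import nnls
from scipy.spatial.distance import squareform

from .twopoint import haldane_d


@dataclass
class LinkageGroups:
    labels: np.ndarray  # group id per marker (0-based, relabelled contiguous)
    sizes: np.ndarray
    #: markers with suspicious low RF to a *different* group (e.g. duplicated
    #: markers linking two chromosomes)
    flagged_markers: np.ndarray


def _prep_rf(rf):
    rf = np.array(rf, dtype=float)
    rf[np.isnan(rf)] = 0.5
    np.fill_diagonal(rf, 0.0)
    return np.clip(rf, 0.0, 0.5)


def form_groups(
    rf,
    n_initial_groups: int,
    aggregate_threshold: float = 0.35,
    min_group_size: int = 10,
) -> LinkageGroups:
    """Average-linkage clustering into groups, then automatic aggregation.

    The initial cut produces ``n_initial_groups``; groups whose median
    inter-group recombination fraction is below ``aggregate_threshold`` are
    merged iteratively. Missing entries are treated as unlinked (0.5).
    """
    rf = _prep_rf(rf)
    m = rf.shape[0]
    if n_initial_groups > m:
        raise ValueError("n_initial_groups exceeds the number of markers")
    Z = hierarchy.linkage(squareform(rf, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=n_initial_groups, criterion="maxclust") - 1
    # tied merge heights can leave fewer clusters than requested (e.g. a
    # constant matrix); split the largest clusters deterministically
    while len(np.unique(labels)) < n_initial_groups:
        ids, counts = np.unique(labels, return_counts=True)
        big = ids[np.argmax(counts)]
        members = np.where(labels == big)[0]
        if len(members) < 2:
            break
        labels[members[len(members) // 2 :]] = labels.max() + 1

    def medians(labels):
        ids = np.unique(labels)
        med = {}
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                block = rf[np.ix_(labels == ids[a], labels == ids[b])]
                med[(ids[a], ids[b])] = np.median(block)
        return ids, med

    while True:
        ids, med = medians(labels)
        if not med:
            break
        (a, b), val = min(med.items(), key=lambda kv: kv[1])
        if val >= aggregate_threshold:
            break
        labels[labels == b] = a

    # relabel contiguously by first occurrence
    _, labels = np.unique(labels, return_inverse=True)
    sizes = np.bincount(labels)

    flagged = []
    ids = np.unique(labels)
    for i in range(m):
        g = labels[i]
        for h in ids:
            if h == g or (labels == h).sum() == 0:
                continue
            mine = np.median(rf[i, labels == h])
            group = np.median(rf[np.ix_(labels == g, labels == h)])
            if mine < aggregate_threshold <= group:
                flagged.append(i)
                break
    return LinkageGroups(labels, sizes, np.array(flagged, dtype=int))


# ---------------------------------------------------------------------------
# anti-Robinson seriation

DEFAULT_BAND = 15

try:  # numba accelerates the local search ~50x; a pure fallback is kept
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally installed
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def wrap(f):
            return f

        return wrap


def anti_robinson_loss(D, order=None, band: int | None = None) -> float:
    """Magnitude-weighted anti-Robinson violations of an ordered matrix.

    For every row, entries should be non-decreasing moving away from the
    diagonal. Each violated comparison between two positions on the same
    side of the diagonal contributes the magnitude of the decrease;
    comparisons are taken between positions up to ``band`` apart (all
    separations when ``band`` is None). A perfect Robinson matrix has loss
    zero for any band.
    """
    D = np.asarray(D, dtype=float)
    A = D if order is None else D[np.ix_(order, order)]
    n = A.shape[0]
    band = n - 1 if band is None else min(band, n - 1)
    return float(_banded_loss(A, band))


@_njit(cache=True)
def _banded_loss(A, band):
    n = A.shape[0]
    loss = 0.0
    for i in range(n):
        for g in range(1, band + 1):
            for k in range(i + 1, n - g):  # right side: (k closer, k+g further)
                d = A[i, k] - A[i, k + g]
                if d > 0:
                    loss += d
            for k in range(0, i - g):  # left side: (k+g closer, k further)
                d = A[i, k + g] - A[i, k]
                if d > 0:
                    loss += d
    return loss


@_njit(cache=True)
def _perm_matrix(A, order):
    n = len(order)
    B = np.empty_like(A)
    for p in range(n):
        for q in range(n):
            B[p, q] = A[order[p], order[q]]
    return B


@_njit(cache=True)
def _search_kernel(D, order0, window, band, max_passes):
    n = len(order0)
    order = order0.copy()
    best = _banded_loss(_perm_matrix(D, order), band)
    for _ in range(max_passes):
        improved = False
        for i in range(n - 1):
            jmax = min(n, i + 1 + window)
            for j in range(i + 1, jmax):
                cand = order.copy()
                cand[i : j + 1] = cand[i : j + 1][::-1]
                loss = _banded_loss(_perm_matrix(D, cand), band)
                if loss < best - 1e-12:
                    order, best, improved = cand, loss, True
                    continue
                moved = order.copy()
                x = moved[i]
                moved[i:j] = moved[i + 1 : j + 1]
                moved[j] = x
                loss = _banded_loss(_perm_matrix(D, moved), band)
                if loss < best - 1e-12:
                    order, best, improved = moved, loss, True
        if not improved:
            break
    return order, best


def _canonical_orientation(order):
    order = list(order)
    rev = order[::-1]
    return rev if rev < order else order


def _local_search(D, order, window=None, band=None, max_passes=60):
    """Segment reversals + single relocations accepted on loss decrease."""
    n = len(order)
    window = n if window is None else window
    band = n - 1 if band is None else min(band, n - 1)
    out, best = _search_kernel(
        np.ascontiguousarray(D, dtype=float),
        np.asarray(order, dtype=np.int64),
        window,
        band,
        max_passes,
    )
    return [int(x) for x in out], float(best)


def _spectral_order(D):
    """Initial order from the Fiedler vector of the similarity graph."""
    S = D.max() - D
    np.fill_diagonal(S, 0.0)
    deg = S.sum(axis=1)
    L = np.diag(deg) - S
    vals, vecs = np.linalg.eigh(L)
    fiedler = vecs[:, np.argsort(vals)[1]]
    return list(np.lexsort((np.arange(len(fiedler)), fiedler)))


def seriate(D) -> list:
    """Anti-Robinson seriation of a small dissimilarity matrix.

    Spectral initialization followed by unwindowed local search; the
    orientation (order vs its reversal, which have equal loss) is
    canonicalized to the lexicographically smaller sequence.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n <= 2:
        return list(range(n))
    starts = [_spectral_order(D), list(range(n))]
    best_order, best_loss = None, np.inf
    for s in starts:
        order, loss = _local_search(D, s)
        if loss < best_loss - 1e-12:
            best_order, best_loss = order, loss
        elif abs(loss - best_loss) <= 1e-12 and best_order is not None:
            cand = _canonical_orientation(order)
            if list(cand) < list(_canonical_orientation(best_order)):
                best_order = cand
    return list(_canonical_orientation(best_order))


def cluster_order_cross(rf_group, n_subgroups: int = 30, seed: int = 0):
    """Coarse ordering: seriate hierarchical subgroups by their mean RF.

    The group is divided into ``n_subgroups`` by average-linkage
    clustering; the subgroups are ordered by anti-Robinson seriation of the
    n x n matrix of mean recombination fractions between subgroups. The
    order of markers *within* a subgroup is left as given (arbitrary).
    Groups smaller than ``n_subgroups`` are returned in input order
    (deferring entirely to :func:`order_cross`).
    """
    rf = _prep_rf(rf_group)
    m = rf.shape[0]
    if m < n_subgroups:
        return list(range(m))
    Z = hierarchy.linkage(squareform(rf, checks=False), method="average")
    sub = hierarchy.fcluster(Z, t=n_subgroups, criterion="maxclust") - 1
    ids = np.unique(sub)
    G = len(ids)
    M = np.zeros((G, G))
    for a in range(G):
        for b in range(a + 1, G):
            M[a, b] = M[b, a] = rf[np.ix_(sub == ids[a], sub == ids[b])].mean()
    sub_order = seriate(M)
    order = []
    for s in sub_order:
        order.extend(np.where(sub == ids[s])[0].tolist())
    return order


def order_cross(rf_group, initial_order=None, window: int = 12,
                band: int = DEFAULT_BAND):
    """Fine ordering: windowed local anti-Robinson search over markers.

    Only local changes (segment reversals and single-marker relocations
    within ``window`` positions) are considered, making the step fast;
    iterates to a local optimum, deterministically. The loss compares
    entries up to ``band`` positions apart, pooling ordering evidence
    across nearby marker pairs while ignoring comparisons between
    effectively unlinked ones.
    """
    rf = _prep_rf(rf_group)
    m = rf.shape[0]
    order = list(range(m)) if initial_order is None else list(initial_order)
    order, _ = _local_search(rf, order, window=window, band=band)
    return _canonical_orientation(order)


# ---------------------------------------------------------------------------
# map distance estimation


def estimate_map(rf_group, order=None, max_rf: float = 0.4):
    """Marker positions (cM) from pairwise RF via non-negative least squares.

    Every pair with estimated recombination fraction <= ``max_rf`` yields
    one equation: the Haldane distance of the pair equals the sum of the
    inter-marker gaps between them in the given order. The gap vector
    (constrained >= 0: negative gaps are physically meaningless) is solved
    by NNLS; positions are its cumulative sums starting at 0.

    Returns (positions array in the given order, residual norm).
    """
    rf = _prep_rf(rf_group)
    m = rf.shape[0]
    order = list(range(m)) if order is None else list(order)
    A_rows, d = [], []
    R = rf[np.ix_(order, order)]
    for i in range(m):
        for j in range(i + 1, m):
            rij = R[i, j]
            if rij > max_rf or rij >= 0.5:
                continue
            row = np.zeros(m - 1)
            row[i:j] = 1.0
            A_rows.append(row)
            d.append(float(haldane_d(rij)))
    if not A_rows:
        raise ValueError("no informative pairs below max_rf")
    A = np.array(A_rows)
    d = np.array(d)
    covered = A.sum(axis=0) > 0
    gaps, resid = nnls(A, d)
    if not covered.all():
        warnings.warn("gaps not covered by any informative pair; using "
                      "adjacent-pair distances")
        for k in np.where(~covered)[0]:
            rk = R[k, k + 1]
            gaps[k] = float(haldane_d(rk)) if rk < 0.5 else 0.0
    positions = np.concatenate([[0.0], np.cumsum(gaps)])
    return positions, float(resid)
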