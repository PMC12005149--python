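"""Genotype calling from two-channel array intensities.

Intensities are converted to polar coordinates — theta = (2/pi)*atan2(y, x)
in [0, 1] and r = x + y (Manhattan magnitude) — and markers are called by
clustering in theta:

* :func:`fit_hbc` — a hierarchical-Bayes-style finite mixture of truncated
  Gaussians (two homozygote components plus an optional heterozygote
  component) fitted by MAP expectation-maximization with a Dirichlet prior
  that inflates the heterozygote weight, producing deliberately aggressive
  heterozygote calling. Supports monomorphic detection and convergence
  flagging, but at most two marker alleles.
* :func:`fit_dbscan` — density-based clustering in (theta, scaled r); can
  recover any number of marker alleles but calls no heterozygotes.

:func:`call_panel` applies the two-pass review procedure: fit every marker,
drop monomorphic markers and high-error lines, re-fit, and flag markers for
review (non-convergence, heterozygote rate above 0.06, or more than two
marker alleles — the latter re-called with DBSCAN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN

from ._rng import rng_for

HET_RATE_FLAG_THRESHOLD = 0.06


def to_polar(x, y):
    """(theta, r) from channel intensities; theta in [0, 1], r = x + y.

    Points with x = y = 0 are failed assays: theta is NaN there.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("intensities must be finite")
    r = x + y
    with np.errstate(invalid="ignore"):
        theta = (2.0 / np.pi) * np.arctan2(y, x)
    theta = np.where((x == 0) & (y == 0), np.nan, theta)
    return theta, r


@dataclass(frozen=True)
class HBCConfig:
    """Priors and numerical settings for the mixture caller."""

    het_prior: float = 8.0  # Dirichlet pseudo-count on the het component
    hom_prior: float = 1.0
    max_iter: int = 500
    tol: float = 1e-9
    min_points: int = 10
    min_separation: float = 0.2  # hom theta centers closer -> monomorphic
    mono_weight: float = 0.02  # minor hom weight below -> monomorphic
    null_r_fraction: float = 0.3  # r below this fraction of median -> missing
    sigma_floor: float = 0.015
    gap: float = 0.12  # theta gap defining raw clusters (multiallelic check)


@dataclass
class MixtureFit:
    """Fitted theta-mixture for one marker."""

    means: np.ndarray
    sigmas: np.ndarray
    weights: np.ndarray
    posteriors: np.ndarray  # (n_points, 3) for non-null points
    converged: bool
    n_iterations: int
    het_cluster_index: int = 1


@dataclass
class MarkerCalls:
    """Per-line calls for one marker.

    ``calls``: 0 / 2 homozygote classes, 1 = heterozygote, -1 = missing;
    ``quality``: posterior probability of the assigned class.
    """

    calls: np.ndarray
    quality: np.ndarray
    flags: set = field(default_factory=set)
    n_alleles: int = 2

    @property
    def het_rate(self):
        ok = self.calls >= 0
        return float((self.calls[ok] == 1).mean()) if ok.any() else 0.0


def _truncnorm_pdf(x, mu, sigma):
    from scipy.stats import norm

    z = norm.pdf(x, mu, sigma)
    denom = norm.cdf(1.0, mu, sigma) - norm.cdf(0.0, mu, sigma)
    return z / np.maximum(denom, 1e-12)


def _count_theta_clusters(theta, gap, min_pts):
    ts = np.sort(theta)
    if len(ts) == 0:
        return 0
    breaks = np.where(np.diff(ts) > gap)[0]
    sizes = np.diff(np.concatenate([[0], breaks + 1, [len(ts)]]))
    return int((sizes >= min_pts).sum())


def fit_hbc(theta, r=None, config: HBCConfig = HBCConfig(), seed: int = 0):
    """Fit the two-homozygote + heterozygote theta mixture for one marker.

    Returns (MixtureFit, MarkerCalls). Null points (failed assays, or r
    below the per-marker threshold) are called MISSING. Flags raised:
    ``monomorphic``, ``nonconvergence``, ``high_het_rate``, ``multiallelic``.
    """
    theta = np.asarray(theta, dtype=float)
    n = len(theta)
    null = np.isnan(theta)
    if r is not None:
        r = np.asarray(r, dtype=float)
        null |= r < config.null_r_fraction * np.nanmedian(r)
    obs = theta[~null]
    calls = np.full(n, -1, dtype=np.int16)
    quality = np.zeros(n)
    if len(obs) < config.min_points:
        fit = MixtureFit(np.full(3, np.nan), np.full(3, np.nan), np.full(3, np.nan),
                         np.empty((0, 3)), False, 0)
        return fit, MarkerCalls(calls, quality, flags={"nonconvergence"})

    rng = rng_for(seed, "hbc")
    alpha = np.array([config.hom_prior, config.het_prior, config.hom_prior])
    mu = np.array([np.quantile(obs, 0.05), 0.5, np.quantile(obs, 0.95)])
    mu += rng.normal(0, 1e-3, 3)  # break exact symmetry deterministically
    sigma = np.full(3, 0.05)
    w = np.array([0.45, 0.10, 0.45])
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        dens = np.stack([_truncnorm_pdf(obs, mu[k], sigma[k]) for k in range(3)], axis=1)
        num = dens * w[None, :]
        norm_c = num.sum(axis=1, keepdims=True)
        norm_c = np.maximum(norm_c, 1e-300)
        resp = num / norm_c
        ll = np.log(norm_c).sum()
        Nk = resp.sum(axis=0)
        w = (Nk + alpha - 1.0) / (len(obs) + alpha.sum() - 3.0)
        w = np.maximum(w, 1e-8)
        w /= w.sum()
        for k in range(3):
            if Nk[k] > 1e-8:
                mu[k] = (resp[:, k] * obs).sum() / Nk[k]
                var = (resp[:, k] * (obs - mu[k]) ** 2).sum() / Nk[k]
                sigma[k] = max(np.sqrt(var), config.sigma_floor)
        order = np.argsort(mu)
        mu, sigma, w = mu[order], sigma[order], w[order]
        if abs(ll - ll_old) < config.tol * max(1.0, abs(ll)):
            converged = True
            break
        ll_old = ll

    dens = np.stack([_truncnorm_pdf(obs, mu[k], sigma[k]) for k in range(3)], axis=1)
    num = dens * w[None, :]
    resp = num / np.maximum(num.sum(axis=1, keepdims=True), 1e-300)
    assign = np.argmax(resp, axis=1)
    calls[~null] = assign
    quality[~null] = resp[np.arange(len(obs)), assign]

    flags = set()
    if not converged:
        flags.add("nonconvergence")
    hom_w = np.array([w[0], w[2]])
    if hom_w.min() < config.mono_weight or (mu[2] - mu[0]) < config.min_separation:
        flags.add("monomorphic")
        major = 0 if w[0] >= w[2] else 2
        calls[~null] = major
        quality[~null] = 1.0
    n_clusters = _count_theta_clusters(obs, config.gap, max(3, int(0.01 * len(obs))))
    if n_clusters >= 4:
        flags.add("multiallelic")
    mc = MarkerCalls(calls, quality, flags=flags)
    if "monomorphic" not in flags and mc.het_rate > HET_RATE_FLAG_THRESHOLD:
        flags.add("high_het_rate")
    fit = MixtureFit(mu, sigma, w, resp, converged, it)
    return fit, mc


@dataclass
class DBSCANFit:
    labels: np.ndarray
    n_clusters: int


def fit_dbscan(theta, r, min_pts: int = 5, eps: float = 0.05, r_weight: float = 0.3):
    """Density-based calling for markers with more than two alleles.

    Clusters (theta, scaled r) with DBSCAN; each non-noise cluster becomes a
    marker-allele class, numbered by ascending mean theta. No heterozygote
    calls are produced; noise points are MISSING.
    """
    if min_pts < 1 or eps <= 0:
        raise ValueError("minPts >= 1 and eps > 0 required")
    theta = np.asarray(theta, dtype=float)
    r = np.asarray(r, dtype=float)
    ok = ~np.isnan(theta)
    calls = np.full(len(theta), -1, dtype=np.int16)
    if ok.sum() == 0:
        return DBSCANFit(calls.copy(), 0), MarkerCalls(calls, np.zeros(len(theta)))
    r_med = np.median(r[ok])
    feats = np.column_stack([theta[ok], r_weight * r[ok] / max(r_med, 1e-12)])
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(feats)
    uniq = [u for u in np.unique(labels) if u >= 0]
    order = np.argsort([theta[ok][labels == u].mean() for u in uniq])
    remap = {uniq[o]: rank for rank, o in enumerate(order)}
    mapped = np.array([remap.get(l, -1) for l in labels], dtype=np.int16)
    calls[ok] = mapped
    quality = np.where(calls >= 0, 1.0, 0.0)
    mc = MarkerCalls(calls, quality, n_alleles=len(uniq))
    if len(uniq) > 2:
        mc.flags.add("multiallelic")
    return DBSCANFit(calls.copy(), len(uniq)), mc


@dataclass
class PanelCalls:
    """Result of the two-pass panel calling procedure."""

    calls: np.ndarray  # (n_kept_lines, n_polymorphic_markers)
    quality: np.ndarray
    kept_lines: np.ndarray  # indices into the input line axis
    polymorphic_markers: np.ndarray  # indices into the input marker axis
    monomorphic_markers: np.ndarray
    review_flags: list  # (marker index, reason)
    het_rates: np.ndarray


def call_panel(
    intensities,
    config: HBCConfig = HBCConfig(),
    line_error_threshold: float = 0.05,
    dbscan_params: dict | None = None,
    seed: int = 0,
) -> PanelCalls:
    """Two-pass calling of an (n_lines, n_markers, 2) intensity panel.

    Pass 1 fits every marker with the mixture caller, identifies
    monomorphic markers and lines whose mean posterior uncertainty exceeds
    ``line_error_threshold``; those lines are removed and the polymorphic
    markers re-fitted. Markers flagged multiallelic are re-called with
    DBSCAN (parameters from ``dbscan_params``).
    """
    intensities = np.asarray(intensities, dtype=float)
    n, m, _ = intensities.shape
    theta = np.empty((n, m))
    r = np.empty((n, m))
    for j in range(m):
        theta[:, j], r[:, j] = to_polar(intensities[:, j, 0], intensities[:, j, 1])

    mono = np.zeros(m, dtype=bool)
    err = np.zeros((n, m))
    counted = np.zeros((n, m), dtype=bool)
    for j in range(m):
        _, mc = fit_hbc(theta[:, j], r[:, j], config, seed=seed + j)
        mono[j] = "monomorphic" in mc.flags
        ok = mc.calls >= 0
        err[ok, j] = 1.0 - mc.quality[ok]
        counted[:, j] = ok & ~mono[j]
    with np.errstate(invalid="ignore"):
        line_err = np.where(
            counted.sum(axis=1) > 0,
            (err * counted).sum(axis=1) / np.maximum(counted.sum(axis=1), 1),
            0.0,
        )
    kept = np.where(line_err <= line_error_threshold)[0]
    poly = np.where(~mono)[0]

    calls = np.full((len(kept), len(poly)), -1, dtype=np.int16)
    quality = np.zeros((len(kept), len(poly)))
    flags = []
    het_rates = np.zeros(len(poly))
    dbp = dbscan_params or {}
    for jj, j in enumerate(poly):
        _, mc = fit_hbc(theta[kept, j], r[kept, j], config, seed=seed + m + j)
        if "multiallelic" in mc.flags:
            _, mc_db = fit_dbscan(
                theta[kept, j], r[kept, j],
                min_pts=dbp.get("min_pts", 5), eps=dbp.get("eps", 0.05),
            )
            mc_db.flags |= mc.flags
            mc = mc_db
        calls[:, jj] = mc.calls
        quality[:, jj] = mc.quality
        het_rates[jj] = mc.het_rate
        for reason in mc.flags & {"nonconvergence", "high_het_rate", "multiallelic"}:
            flags.append((int(j), reason))
    return PanelCalls(
        calls=calls,
        quality=quality,
        kept_lines=kept,
        polymorphic_markers=poly,
        monomorphic_markers=np.where(mono)[0],
        review_flags=flags,
        het_rates=het_rates,
    )
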