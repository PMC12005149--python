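"""Forward simulation of MAGIC genomes, marker genotypes and intensities.

Genomes are founder-labelled mosaics: each haplotype of each chromosome is a
list of segments ``(start position in cM, founder index)`` tiling the
chromosome. Meiosis follows the Haldane model — crossover counts are
Poisson(length/100) with uniform positions and no interference — which is
consistent with the Haldane map function used for all distance conversions
in the mapping modules.

Four distortion mechanisms can be injected, mirroring the phenomena a
segregation-distortion analysis is designed to detect:

``drive``
    gametic transmission bias at one locus: a gamete carrying the target
    founder is transmitted with probability ``strength`` instead of 1/2
    whenever the parent is heterozygous carrier/non-carrier there;
``sex``
    the same bias, active only through maternal (or paternal) meioses;
``interaction``
    zygotic viability weight on offspring carrying a specific two-locus
    founder combination;
``funnel``
    transmission bias restricted to meioses of the G1 individual from a
    named founder pair, depleting that founder's alleles in the
    corresponding funnel group.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from ._rng import rng_for
from .pedigree import (
    DesignSpec,
    FounderSet,
    N_FOUNDERS,
    Pedigree,
    build_pedigree,
)

# ---------------------------------------------------------------------------
# genetic map


@dataclass(frozen=True)
class GeneticMapSpec:
    """Chromosome lengths (cM) and marker positions used for simulation.

    ``chromosomes`` is a tuple of (name, length); ``markers`` maps each
    chromosome name to a sorted array of positions within [0, length].
    """

    chromosomes: tuple
    markers: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))
        markers = {c: np.asarray(p, dtype=float) for c, p in self.markers.items()}
        lengths = dict(self.chromosomes)
        for chrom, pos in markers.items():
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"marker positions on {chrom} must be sorted")
            if len(pos) and (pos[0] < 0 or pos[-1] > lengths[chrom]):
                raise ValueError(f"marker positions on {chrom} outside [0, length]")
        object.__setattr__(self, "markers", markers)

    @classmethod
    def uniform(cls, n_chromosomes=1, length=100.0, n_markers=50, prefix="chr"):
        """Equally spaced markers spanning each chromosome."""
        chroms = tuple((f"{prefix}{i+1}", float(length)) for i in range(n_chromosomes))
        markers = {
            name: np.linspace(0.0, length, n_markers) for name, length in chroms
        }
        return cls(chromosomes=chroms, markers=markers)

    @property
    def chrom_names(self):
        return [c for c, _ in self.chromosomes]

    def length(self, chrom):
        return dict(self.chromosomes)[chrom]

    def marker_table(self):
        """Flattened (chrom array, position array, name list) over all markers."""
        chroms, pos, names = [], [], []
        for c, _ in self.chromosomes:
            p = self.markers.get(c, np.empty(0))
            chroms.extend([c] * len(p))
            pos.extend(p)
            names.extend(f"{c}_m{i+1}" for i in range(len(p)))
        return np.array(chroms), np.array(pos, dtype=float), names


# ---------------------------------------------------------------------------
# genomes and meiosis

#: a haplotype is (starts, founders): segment start positions (first is 0.0)
#: and the founder index of each segment.
Haplotype = tuple

#: a diploid genome maps chromosome name -> (haplotype, haplotype)
DiploidGenome = dict


def founder_genome(founder: int, mapspec: GeneticMapSpec) -> DiploidGenome:
    g = {}
    for chrom, _ in mapspec.chromosomes:
        hap = (np.array([0.0]), np.array([founder], dtype=np.int8))
        g[chrom] = (hap, hap)
    return g


def founder_at(hap: Haplotype, pos: float) -> int:
    starts, founders = hap
    return int(founders[np.searchsorted(starts, pos, side="right") - 1])


def _crossover(hap_a: Haplotype, hap_b: Haplotype, length: float, rng) -> Haplotype:
    """One recombinant haplotype from a pair, Haldane model."""
    n_x = rng.poisson(length / 100.0)
    source = int(rng.integers(2))
    if n_x == 0:
        return (hap_a, hap_b)[source]
    xpos = np.sort(rng.uniform(0.0, length, size=n_x))
    haps = (hap_a, hap_b)
    starts, founders = [], []
    seg_start = 0.0
    for bp in np.append(xpos, np.inf):
        s, f = haps[source]
        i0 = np.searchsorted(s, seg_start, side="right") - 1
        i1 = np.searchsorted(s, bp, side="left") if np.isfinite(bp) else len(s)
        seg_s = s[i0:i1].copy()
        seg_s[0] = seg_start
        starts.append(seg_s)
        founders.append(f[i0:i1])
        seg_start = bp
        source ^= 1
    starts = np.concatenate(starts)
    founders = np.concatenate(founders)
    # drop zero-length / redundant segments
    keep = np.ones(len(starts), dtype=bool)
    keep[1:] = (np.diff(starts) > 0) & (np.diff(founders) != 0)
    # a founder change at identical position: keep the later entry
    same_pos = np.diff(starts) == 0
    for i in np.where(same_pos)[0]:
        keep[i] = False
        keep[i + 1] = True
    starts, founders = starts[keep], founders[keep]
    keep = np.ones(len(starts), dtype=bool)
    keep[1:] = np.diff(founders) != 0
    return starts[keep], founders[keep]


def simulate_meiosis(parent: DiploidGenome, mapspec: GeneticMapSpec, seed=None, rng=None):
    """One gamete (haplotype per chromosome) from a diploid parent.

    Crossover counts per chromosome are Poisson(length/100), positions
    uniform, no interference; the starting haplotype is chosen with
    probability 1/2.
    """
    if rng is None:
        rng = rng_for(0 if seed is None else seed, "meiosis")
    gamete = {}
    for chrom, length in mapspec.chromosomes:
        if length < 0:
            raise ValueError(f"chromosome {chrom} has negative length")
        hap_a, hap_b = parent[chrom]
        gamete[chrom] = _crossover(hap_a, hap_b, length, rng)
    return gamete


# ---------------------------------------------------------------------------
# markers, distortions, intensities


@dataclass(frozen=True)
class MarkerModel:
    """Founder -> marker-allele maps plus error model.

    ``founder_alleles`` has shape (n_markers, 8) with small-integer allele
    symbols (0/1 for biallelic SNPs; 0..7 for fully informative markers).
    ``duplicate_of`` optionally maps a marker index to a second genomic
    location (chrom, position, secondary founder_alleles row) whose signal
    is additively mixed into that marker's intensities, emulating markers
    polymorphic at multiple genomic locations.
    """

    founder_alleles: np.ndarray
    error_rate: float = 0.0
    missing_rate: float = 0.0
    duplicate_of: dict = field(default_factory=dict)

    def __post_init__(self):
        fa = np.asarray(self.founder_alleles, dtype=np.int16)
        object.__setattr__(self, "founder_alleles", fa)
        if fa.ndim != 2 or fa.shape[1] != N_FOUNDERS:
            raise ValueError("founder_alleles must have shape (n_markers, 8)")

    @property
    def n_markers(self):
        return self.founder_alleles.shape[0]


def random_marker_model(
    mapspec: GeneticMapSpec,
    seed=0,
    alleles: str = "biallelic",
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
) -> MarkerModel:
    """Draw founder alleles for every marker of ``mapspec``.

    Biallelic alleles are i.i.d. Bernoulli(1/2) per founder, redrawn until
    polymorphic; ``alleles='unique'`` makes every founder distinguishable.
    """
    rng = rng_for(seed, "marker-model")
    _, pos, _ = mapspec.marker_table()
    m = len(pos)
    if alleles == "unique":
        fa = np.tile(np.arange(N_FOUNDERS, dtype=np.int16), (m, 1))
    elif alleles == "biallelic":
        fa = rng.integers(0, 2, size=(m, N_FOUNDERS)).astype(np.int16)
        for i in range(m):
            while fa[i].min() == fa[i].max():
                fa[i] = rng.integers(0, 2, size=N_FOUNDERS)
    else:
        raise ValueError(f"unknown allele scheme {alleles!r}")
    return MarkerModel(fa, error_rate=error_rate, missing_rate=missing_rate)


@dataclass(frozen=True)
class DistortionSpec:
    """One injectable distortion mechanism; see module docstring.

    ``strength`` is a transmission probability for drive/sex/funnel kinds
    (0.5 = Mendelian) and a viability weight in (0, 1] for ``interaction``
    (1 = no selection).
    """

    kind: str
    chrom: str
    pos: float
    founder: int
    strength: float
    # interaction: second locus and founder
    chrom2: str | None = None
    pos2: float | None = None
    founder2: int | None = None
    # sex: which parental role the bias acts through
    role: str = "maternal"
    # funnel: the G1 partner founder defining the affected crosses
    partner: int | None = None
    # interaction: apply the viability weight at every cross ("all", lines
    # resampled within their family, as when a breeder replaces a failed
    # plant) or to the final lines ("final": carriers are *culled* with
    # probability 1 - strength, e.g. selection acting on the inbred lines;
    # resampling would be neutralized in lineages already fixed for the
    # combination)
    stage: str = "all"

    def __post_init__(self):
        if self.kind not in ("drive", "sex", "interaction", "funnel"):
            raise ValueError(f"unknown distortion kind {self.kind!r}")
        if self.kind == "interaction" and (self.chrom2 is None or self.pos2 is None):
            raise ValueError("interaction distortion needs a second locus")
        if self.kind == "funnel" and self.partner is None:
            raise ValueError("funnel distortion needs a partner founder")
        if not 0.0 < self.strength <= 1.0:
            raise ValueError("strength must be in (0, 1]")


def _check_distortions(distortions, mapspec):
    lengths = dict(mapspec.chromosomes)
    for d in distortions:
        for c, p in ((d.chrom, d.pos), (d.chrom2, d.pos2)):
            if c is None:
                continue
            if c not in lengths or not 0 <= p <= lengths[c]:
                raise ValueError(f"distortion locus {c}:{p} outside the map")


@dataclass(frozen=True)
class IntensityModel:
    """Gaussian intensity clusters in polar coordinates per genotype class.

    For each marker, each observable genotype class has a theta center in
    [0, 1]; the radial magnitude is shared. Cartesian channels are
    x = rho*cos(theta*pi/2), y = rho*sin(theta*pi/2). A ``null_rate``
    fraction of assays fail and cluster near the origin.
    """

    theta_centers: list  # per marker: array over that marker's classes
    rho_center: float = 1.0
    sd_theta: float = 0.03
    sd_rho: float = 0.08
    null_rate: float = 0.0
    #: relative hybridization weight of the primary locus for duplicated markers
    duplicate_weight: float = 2.0 / 3.0


# ---------------------------------------------------------------------------
# IBD state coding (shared with hmm_ibd)

_HET_PAIRS = list(itertools.combinations(range(N_FOUNDERS), 2))
_HET_INDEX = {p: 8 + k for k, p in enumerate(_HET_PAIRS)}


def ibd_state(fa: int, fb: int) -> int:
    """36-state code of an unordered founder pair (8 hom + 28 het)."""
    if fa == fb:
        return fa
    i, j = (fa, fb) if fa < fb else (fb, fa)
    return _HET_INDEX[(i, j)]


#: vectorized founder-pair -> state lookup
_STATE_OF = np.empty((N_FOUNDERS, N_FOUNDERS), dtype=np.int16)
for _i in range(N_FOUNDERS):
    for _j in range(N_FOUNDERS):
        _STATE_OF[_i, _j] = ibd_state(_i, _j)


def marker_classes(alleles_row) -> list:
    """Observable genotype classes for one marker, deterministically ordered.

    A class is the allele content of an unordered founder pair: a hom class
    ``(a,)`` or a het class ``(a, b)``. Sorted lexicographically, so for a
    biallelic marker the class codes 0/1/2 coincide with allele-1 dosage.
    """
    classes = set()
    for fa in range(N_FOUNDERS):
        for fb in range(fa, N_FOUNDERS):
            classes.add(tuple(sorted({alleles_row[fa], alleles_row[fb]})))
    return sorted(classes)


def state_class_codes(alleles_row) -> np.ndarray:
    """Map each of the 36 IBD states to its observable class code."""
    classes = marker_classes(alleles_row)
    lookup = {c: k for k, c in enumerate(classes)}
    codes = np.empty(36, dtype=np.int16)
    for f in range(N_FOUNDERS):
        codes[f] = lookup[tuple(sorted({alleles_row[f]}))]
    for (i, j), s in _HET_INDEX.items():
        codes[s] = lookup[tuple(sorted({alleles_row[i], alleles_row[j]}))]
    return codes


# ---------------------------------------------------------------------------
# population simulation


@dataclass
class SimulatedPopulation:
    """Everything the downstream modules consume, plus the ground truth."""

    pedigree: Pedigree
    mapspec: GeneticMapSpec
    marker_model: MarkerModel | None
    ril_ids: list
    genomes: dict  # line id -> DiploidGenome (RILs only)
    #: (n_lines, n_markers) true 36-state IBD codes at marker positions
    true_states: np.ndarray | None = None
    #: (n_lines, n_markers) observed class codes, -1 = missing
    calls: np.ndarray | None = None
    #: per-marker list of observable classes (see marker_classes)
    call_classes: list | None = None
    marker_chrom: np.ndarray | None = None
    marker_pos: np.ndarray | None = None
    marker_names: list | None = None

    @property
    def n_lines(self):
        return len(self.ril_ids)


def _apply_transmission_bias(gamete_draw, biases, rng):
    """Rejection-sample a gamete under multiplicative transmission biases.

    ``biases`` is a list of (chrom, pos, target founder, strength) active for
    this meiosis *and* for which the parent is heterozygous
    carrier/non-carrier at the locus, so acceptance never degenerates.
    """
    if not biases:
        return gamete_draw()
    for _ in range(10000):
        g = gamete_draw()
        p = 1.0
        for chrom, pos, target, s in biases:
            carrier = founder_at(g[chrom], pos) == target
            p *= s if carrier else 1.0 - s
        if rng.random() < p:
            return g
    raise RuntimeError("transmission-bias rejection sampling did not terminate")


def simulate_population(
    pedigree: Pedigree,
    mapspec: GeneticMapSpec,
    marker_model: MarkerModel | None = None,
    distortions=(),
    seed: int = 0,
    keep_genomes: bool = True,
) -> SimulatedPopulation:
    """Drop genomes through the pedigree and genotype the RILs.

    Deterministic given ``seed``. Distortions are applied as described in
    the module docstring; with all strengths at their neutral values the
    founder composition at every locus is uniform (1/8 each) up to Monte
    Carlo error.
    """
    _check_distortions(distortions, mapspec)
    rng = rng_for(seed, "population")
    fnames = pedigree.founders.names
    findex = {n: i for i, n in enumerate(fnames)}

    drive_like = [d for d in distortions if d.kind in ("drive", "sex", "funnel")]
    interactions = [d for d in distortions if d.kind == "interaction"]

    genomes = {n: founder_genome(i, mapspec) for i, n in enumerate(fnames)}

    def gamete(parent_id: str, role: str):
        parent_genome = genomes[parent_id]
        rec = pedigree.record(parent_id) if parent_id in pedigree else None
        biases = []
        for d in drive_like:
            if d.kind == "sex" and d.role != role:
                continue
            if d.kind == "funnel":
                if rec is None or rec.generation != "G1":
                    continue
                cross = {findex[rec.mother], findex[rec.father]}
                if cross != {d.founder, d.partner}:
                    continue
            fa = founder_at(parent_genome[d.chrom][0], d.pos)
            fb = founder_at(parent_genome[d.chrom][1], d.pos)
            if (fa == d.founder) != (fb == d.founder):  # het carrier/non-carrier
                biases.append((d.chrom, d.pos, d.founder, d.strength))
        return _apply_transmission_bias(
            lambda: simulate_meiosis(parent_genome, mapspec, rng=rng), biases, rng
        )

    def carries_combo(genome, d):
        at1 = d.founder in (
            founder_at(genome[d.chrom][0], d.pos),
            founder_at(genome[d.chrom][1], d.pos),
        )
        at2 = d.founder2 in (
            founder_at(genome[d.chrom2][0], d.pos2),
            founder_at(genome[d.chrom2][1], d.pos2),
        )
        return at1 and at2

    every_cross = [d for d in interactions if d.stage == "all"]
    final_stage = [d for d in interactions if d.stage == "final"]

    for rec in pedigree.records:
        rec_interactions = every_cross
        for _ in range(10000):
            child = {}
            gm = gamete(rec.mother, "maternal")
            gp = gamete(rec.father, "paternal")
            for chrom, _ in mapspec.chromosomes:
                child[chrom] = (gm[chrom], gp[chrom])
            ok = True
            for d in rec_interactions:
                if carries_combo(child, d) and rng.random() > d.strength:
                    ok = False
                    break
            if ok:
                break
        else:
            raise RuntimeError("viability rejection sampling did not terminate")
        genomes[rec.id] = child

    ril_ids = list(pedigree.ril_ids)
    if final_stage:
        survivors = []
        for rid in ril_ids:
            alive = True
            for d in final_stage:
                if carries_combo(genomes[rid], d) and rng.random() > d.strength:
                    alive = False
                    break
            if alive:
                survivors.append(rid)
        ril_ids = survivors
    ril_genomes = {rid: genomes[rid] for rid in ril_ids}

    pop = SimulatedPopulation(
        pedigree=pedigree,
        mapspec=mapspec,
        marker_model=marker_model,
        ril_ids=ril_ids,
        genomes=ril_genomes if keep_genomes else {},
    )

    chroms, pos, names = mapspec.marker_table()
    pop.marker_chrom, pop.marker_pos, pop.marker_names = chroms, pos, names
    if len(pos) == 0:
        return pop

    n, m = len(ril_ids), len(pos)
    true_states = np.empty((n, m), dtype=np.int16)
    for li, rid in enumerate(ril_ids):
        g = ril_genomes[rid]
        col = 0
        for chrom, _ in mapspec.chromosomes:
            mp = mapspec.markers.get(chrom, np.empty(0))
            if len(mp) == 0:
                continue
            (s1, f1), (s2, f2) = g[chrom]
            fa = f1[np.searchsorted(s1, mp, side="right") - 1]
            fb = f2[np.searchsorted(s2, mp, side="right") - 1]
            true_states[li, col : col + len(mp)] = _STATE_OF[fa, fb]
            col += len(mp)
    pop.true_states = true_states

    if marker_model is not None:
        if marker_model.n_markers != m:
            raise ValueError("marker model size does not match map")
        call_rng = rng_for(seed, "calls")
        calls = np.empty((n, m), dtype=np.int16)
        classes = []
        for j in range(m):
            codes = state_class_codes(marker_model.founder_alleles[j])
            classes.append(marker_classes(marker_model.founder_alleles[j]))
            calls[:, j] = codes[true_states[:, j]]
            n_classes = len(classes[-1])
            if marker_model.error_rate > 0 and n_classes > 1:
                err = call_rng.random(n) < marker_model.error_rate
                shift = call_rng.integers(1, n_classes, size=n)
                calls[err, j] = (calls[err, j] + shift[err]) % n_classes
            if marker_model.missing_rate > 0:
                miss = call_rng.random(n) < marker_model.missing_rate
                calls[miss, j] = -1
        pop.calls = calls
        pop.call_classes = classes
    return pop


def simulate_design(
    design: DesignSpec,
    mapspec: GeneticMapSpec,
    seed: int = 0,
    founders: FounderSet | None = None,
    **kwargs,
) -> SimulatedPopulation:
    """Convenience wrapper: build the pedigree, then simulate through it."""
    ped = build_pedigree(design, founders=founders, seed=seed)
    return simulate_population(ped, mapspec, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# intensities


def default_intensity_model(
    marker_model: MarkerModel,
    sd_theta: float = 0.03,
    sd_rho: float = 0.08,
    null_rate: float = 0.0,
) -> IntensityModel:
    """Well-separated theta clusters for each marker's observable classes.

    Biallelic markers get hom/het/hom centers (0.08, 0.5, 0.92); markers
    with more classes spread them evenly over [0.08, 0.92].
    """
    centers = []
    for j in range(marker_model.n_markers):
        classes = marker_classes(marker_model.founder_alleles[j])
        k = len(classes)
        if k == 1:
            centers.append(np.array([0.5]))
        elif k == 3:
            centers.append(np.array([0.08, 0.5, 0.92]))
        else:
            centers.append(np.linspace(0.08, 0.92, k))
    return IntensityModel(
        theta_centers=centers, sd_theta=sd_theta, sd_rho=sd_rho, null_rate=null_rate
    )


def emit_intensities(
    pop: SimulatedPopulation,
    model: IntensityModel,
    seed: int = 0,
) -> np.ndarray:
    """Two-channel intensities (n_lines, n_markers, 2) for the population.

    Each line/marker draws (theta, rho) from its true genotype class's
    bivariate Gaussian; failed assays (``null_rate``) land near the origin.
    For duplicated markers the theta center is the hybridization-weighted
    mix of the allele-1 dosages at the two locations, so the emitted data
    shows more than three clusters.
    """
    if pop.true_states is None or pop.marker_model is None:
        raise ValueError("population has no genotyped markers")
    rng = rng_for(seed, "intensities")
    mm = pop.marker_model
    n, m = pop.true_states.shape
    theta = np.empty((n, m))
    for j in range(m):
        if j in mm.duplicate_of:
            chrom2, pos2, alleles2 = mm.duplicate_of[j]
            dos1 = _dosage_at_marker(pop, j)
            dos2 = _dosage_at_locus(pop, chrom2, pos2, np.asarray(alleles2))
            w = model.duplicate_weight
            center = (w * dos1 + (1 - w) * dos2) / 2.0
        else:
            class_codes = state_class_codes(mm.founder_alleles[j])[pop.true_states[:, j]]
            center = model.theta_centers[j][class_codes]
        theta[:, j] = np.clip(
            center + rng.normal(0.0, model.sd_theta, size=n), 0.0, 1.0
        )
    rho = np.maximum(rng.normal(model.rho_center, model.sd_rho, size=(n, m)), 0.05)
    if model.null_rate > 0:
        null = rng.random((n, m)) < model.null_rate
        theta[null] = rng.uniform(0, 1, size=null.sum())
        rho[null] = np.abs(rng.normal(0.0, 0.02, size=null.sum()))
    x = rho * np.cos(theta * np.pi / 2)
    y = rho * np.sin(theta * np.pi / 2)
    return np.stack([x, y], axis=-1)


def _dosage_at_marker(pop, j):
    alleles = pop.marker_model.founder_alleles[j]
    states = pop.true_states[:, j]
    from .hmm_ibd import state_pair  # local import to avoid a cycle

    pairs = np.array([state_pair(s) for s in range(36)])
    dos = alleles[pairs[:, 0]] + alleles[pairs[:, 1]]
    return dos[states].astype(float)


def _dosage_at_locus(pop, chrom, pos, alleles):
    dos = np.empty(pop.n_lines)
    for li, rid in enumerate(pop.ril_ids):
        g = pop.genomes[rid]
        fa = founder_at(g[chrom][0], pos)
        fb = founder_at(g[chrom][1], pos)
        dos[li] = alleles[fa] + alleles[fb]
    return dos


# ---------------------------------------------------------------------------
# heterozygosity


def ibd_heterozygosity(genome: DiploidGenome, mapspec: GeneticMapSpec) -> float:
    """Map-length-weighted fraction of the genome heterozygous by descent."""
    het_len = 0.0
    total = 0.0
    for chrom, length in mapspec.chromosomes:
        if length == 0:
            continue
        (s1, f1), (s2, f2) = genome[chrom]
        cuts = np.unique(np.concatenate([s1, s2, [length]]))
        for a, b in zip(cuts[:-1], cuts[1:]):
            mid = 0.5 * (a + b)
            if founder_at((s1, f1), mid) != founder_at((s2, f2), mid):
                het_len += b - a
        total += length
    return het_len / total if total else 0.0


def expected_residual_heterozygosity(design: DesignSpec) -> float:
    """Exact expected IBD heterozygosity of a RIL under the design.

    Propagates the single-locus heterozygosity through the pedigree stages:
    a complete funnel line is heterozygous with probability 1 (its two
    gametes come from founder-disjoint 4-way parents); an intercrossed line
    carries two independent uniform founders, heterozygous with probability
    7/8; every selfing generation halves the expectation.
    """
    if design.intercross_generations == 0:
        h = 1.0
    else:
        h = (N_FOUNDERS - 1) / N_FOUNDERS
    for _ in range(design.selfing_generations):
        h *= 0.5
    return h
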