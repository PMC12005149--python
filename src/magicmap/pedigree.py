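"""Eight-founder MAGIC crossing designs: funnels, pedigrees, combinatorics.

A *funnel* is the balanced three-generation crossing tree that combines all
eight founders into a single line::

    ((a x b) x (c x d)) x ((e x f) x (g x h))

Within each cross the two parents can be swapped (reciprocal cross) without
changing the genetic content of the offspring, so funnels are counted up to
the 2^4 * 2^2 * 2 = 128-element symmetry group of the tree, giving
8!/128 = 315 distinct funnels.

A :class:`Pedigree` holds the full record list for a simulated population:
the mixing generations G1-G3, optional advanced-intercross (AIC) generations
between funnels, and five generations of selfing producing recombinant
inbred lines (RILs).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from ._rng import rng_for

N_FOUNDERS = 8

#: Founder names of the population the design emulates (three Australian
#: cultivars plus five lines of global origin).
DEFAULT_FOUNDER_NAMES = (
    "AC-Barrie",
    "Alsen",
    "Baxter",
    "Pastor",
    "Volcani",
    "Westonia",
    "Xiaoyan",
    "Yitpi",
)

MIXING_GENERATIONS = ("G1", "G2", "G3")
SELFING_LABELS = ("S1", "S2", "S3", "S4", "S5")


class DesignError(ValueError):
    """Raised for structurally invalid crossing designs."""


@dataclass(frozen=True)
class FounderSet:
    """Ordered set of exactly eight founder names.

    The order is fixed and defines founder/state indexing everywhere
    downstream (IBD states, composition vectors, allele tables).
    """

    names: tuple = DEFAULT_FOUNDER_NAMES

    def __post_init__(self):
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(names) != N_FOUNDERS or len(set(names)) != N_FOUNDERS:
            raise DesignError(
                f"a founder set needs exactly {N_FOUNDERS} distinct names, "
                f"got {names!r}"
            )

    def index(self, name: str) -> int:
        return self.names.index(name)

    def __iter__(self):
        return iter(self.names)

    def __len__(self):
        return N_FOUNDERS


#: A funnel is an ordered 8-tuple of founder indices in tree order
#: (a, b, c, d, e, f, g, h) == ((a x b) x (c x d)) x ((e x f) x (g x h)),
#: with the maternal parent written first at every internal node.
Funnel = tuple


def canonical_key(funnel: Funnel) -> tuple:
    """Canonical representative of a funnel's reciprocal-equivalence class.

    Invariant under swapping the two founders of any first cross, the two
    pairs within either 4-way cross, and the two 4-way parents.
    """
    if len(funnel) != N_FOUNDERS or len(set(funnel)) != N_FOUNDERS:
        raise DesignError(f"funnel must use all 8 founders once, got {funnel!r}")
    pairs = [tuple(sorted(funnel[i : i + 2])) for i in (0, 2, 4, 6)]
    quads = (tuple(sorted(pairs[0:2])), tuple(sorted(pairs[2:4])))
    return tuple(sorted(quads))


def enumerate_funnels(founders: FounderSet | None = None) -> list:
    """All distinct funnels (canonical keys) for eight founders.

    Exhausts the 8! orderings of the balanced crossing tree and collapses
    them to equivalence classes; returns the sorted list of 315 keys.
    """
    if founders is not None and len(FounderSet(tuple(founders)).names) != N_FOUNDERS:
        raise DesignError("exactly 8 founders required")
    keys = {canonical_key(p) for p in itertools.permutations(range(N_FOUNDERS))}
    return sorted(keys)


def first_cross_pairs(funnels=None) -> set:
    """Distinct unordered founder pairs appearing as first (G1) crosses."""
    funnels = enumerate_funnels() if funnels is None else funnels
    return {pair for key in funnels for quad in key for pair in quad}


def four_way_combinations(funnels=None) -> set:
    """Distinct unordered pairs of disjoint founder pairs (4-way crosses)."""
    funnels = enumerate_funnels() if funnels is None else funnels
    return {quad for key in funnels for quad in key}


def funnel_from_key(key: tuple) -> Funnel:
    """Ordered funnel realizing a canonical key (canonical arrangement)."""
    (p1, p2), (p3, p4) = key
    return tuple(p1) + tuple(p2) + tuple(p3) + tuple(p4)


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of a MAGIC crossing design.

    Parameters
    ----------
    n_funnels:
        Number of distinct funnels used (max 315, sampled uniformly without
        replacement when fewer).
    intercross_generations:
        Advanced-intercross generations between mixing and selfing; must be
        0, 2 or 3 (subpopulations MP8RIL, AIC2RIL, AIC3RIL).
    selfing_generations:
        Consecutive selfing generations applied to each terminal line.
    lines_per_funnel:
        Independent G3 individuals (hence RIL lineages) per funnel.
    reciprocal_fraction:
        Probability that an individual G3 cross is performed in the
        reciprocal direction (4-way parents swapped) relative to its
        funnel's realized orientation, creating reciprocal crosses within a
        funnel. The orientation of every cross (which parent is maternal)
        is itself uniform random per funnel — the historical directions are
        not part of the design — so every founder appears in all-maternal
        and all-paternal roles in ~1/8 of lines each.
    """

    n_funnels: int = 315
    intercross_generations: int = 0
    selfing_generations: int = 5
    lines_per_funnel: int = 1
    reciprocal_fraction: float = 0.0

    def __post_init__(self):
        if self.intercross_generations not in (0, 2, 3):
            raise DesignError(
                "intercross_generations must be one of {0, 2, 3}, got "
                f"{self.intercross_generations}"
            )
        if not 1 <= self.n_funnels <= 315:
            raise DesignError("n_funnels must be in 1..315 (no replacement)")
        if self.selfing_generations < 0:
            raise DesignError("selfing_generations must be >= 0")
        if self.lines_per_funnel < 1:
            raise DesignError("lines_per_funnel must be >= 1")

    @property
    def subpopulation(self) -> str:
        return {0: "MP8RIL", 2: "AIC2RIL", 3: "AIC3RIL"}[self.intercross_generations]


@dataclass(frozen=True)
class CrossRecord:
    """One cross in the pedigree. Selfing records have mother == father."""

    id: str
    mother: str
    father: str
    generation: str

    def __post_init__(self):
        selfing = self.generation.startswith("S")
        if not selfing and self.mother == self.father:
            raise DesignError(f"{self.id}: mother == father outside selfing")


@dataclass
class Pedigree:
    """A validated DAG of crosses from founders to RILs."""

    founders: FounderSet
    design: DesignSpec
    records: list = field(default_factory=list)
    #: ids of the final (RIL) lines, in creation order
    ril_ids: list = field(default_factory=list)
    #: ordered funnel (8-tuple of founder indices, with realized reciprocal
    #: swaps) for every record that descends from a single funnel
    _funnel: dict = field(default_factory=dict)
    _by_id: dict = field(default_factory=dict)

    def __post_init__(self):
        self._by_id = {r.id: r for r in self.records}

    def record(self, line_id: str) -> CrossRecord:
        return self._by_id[line_id]

    def __contains__(self, line_id):
        return line_id in self._by_id

    def validate(self) -> None:
        """Check acyclicity/forward references and selfing-chain lengths."""
        seen = set(self.founders.names)
        for rec in self.records:
            for parent in (rec.mother, rec.father):
                if parent not in seen:
                    raise DesignError(
                        f"record {rec.id}: parent {parent!r} not defined earlier"
                    )
            if rec.id in seen:
                raise DesignError(f"duplicate id {rec.id}")
            seen.add(rec.id)
        s = self.design.selfing_generations
        for rid in self.ril_ids:
            rec = self._by_id[rid]
            for k in range(s, 0, -1):
                if rec.generation != f"S{k}":
                    raise DesignError(f"RIL {rid}: broken selfing chain at {rec.id}")
                rec = self._by_id[rec.mother]

    # -- funnel queries ----------------------------------------------------

    def funnel_of(self, line_id: str) -> Funnel:
        """Ordered funnel of a single-funnel line (MP8RIL ancestry).

        Raises ``DesignError`` for intercrossed lines, whose ancestry spans
        several funnels.
        """
        fun = self._funnel.get(line_id)
        if fun is None:
            raise DesignError(f"{line_id} has multi-funnel (intercrossed) ancestry")
        return fun

    def maternal_founder_roles(self, line_id: str) -> dict:
        """Per-founder contribution path of an MP8RIL line.

        Returns a mapping founder index -> 'maternal' (contributed through
        the maternal parent at every mixing cross), 'paternal', or 'mixed'.
        """
        fun = self.funnel_of(line_id)
        roles = {}
        for pos, founder in enumerate(fun):
            # role at G1: even tree positions are maternal
            path = (pos % 2, (pos // 2) % 2, (pos // 4) % 2)
            if all(p == 0 for p in path):
                roles[founder] = "maternal"
            elif all(p == 1 for p in path):
                roles[founder] = "paternal"
            else:
                roles[founder] = "mixed"
        return roles

    def g1_partner(self, line_id: str, founder: int) -> int:
        """The founder crossed with ``founder`` in G1 of this line's funnel."""
        fun = self.funnel_of(line_id)
        pos = fun.index(founder)
        return fun[pos ^ 1]

    def funnel_keys_used(self) -> set:
        return {canonical_key(f) for f in self._funnel.values()}


def build_pedigree(
    design: DesignSpec,
    founders: FounderSet | None = None,
    seed: int = 0,
) -> Pedigree:
    """Construct a full MAGIC pedigree for ``design``.

    G1 crosses founder pairs, G2 crosses the resulting 2-way lines, G3
    completes each funnel; AIC generations (if any) cross lines from
    different funnels at random; the terminal lines are then selfed.
    Deterministic given ``seed``.
    """
    founders = founders or FounderSet()
    rng = rng_for(seed, "pedigree")
    keys = enumerate_funnels()
    if design.n_funnels < len(keys):
        idx = rng.choice(len(keys), size=design.n_funnels, replace=False)
        keys = [keys[i] for i in sorted(idx)]

    ped = Pedigree(founders=founders, design=design)
    records = ped.records
    fnames = founders.names

    terminal = []  # (line_id, ordered funnel or None)
    g3_pool = []  # (line_id, funnel_index) for intercrossing
    for fi, key in enumerate(keys):
        arranged = list(funnel_from_key(key))
        # realized maternal/paternal orientation is uniform at every node
        for lo in (0, 2, 4, 6):
            if rng.random() < 0.5:
                arranged[lo], arranged[lo + 1] = arranged[lo + 1], arranged[lo]
        for base in (0, 4):
            if rng.random() < 0.5:
                arranged[base : base + 4] = (
                    arranged[base + 2 : base + 4] + arranged[base : base + 2]
                )
        if rng.random() < 0.5:
            arranged = arranged[4:] + arranged[:4]
        fun = tuple(arranged)

        g1_ids = []
        for j, lo in enumerate((0, 2, 4, 6)):
            rid = f"f{fi}.G1.{j}"
            records.append(
                CrossRecord(rid, fnames[fun[lo]], fnames[fun[lo + 1]], "G1")
            )
            ped._funnel[rid] = fun
            g1_ids.append(rid)
        fun_reciprocal = tuple(arranged[4:] + arranged[:4])
        for l in range(design.lines_per_funnel):
            # each G3 line descends from its own G2 individuals: a G1 plant
            # is genetically determined (inbred parents), a G2 plant is not,
            # and sharing realized G2 genomes across a funnel's lines would
            # collapse the funnel to ~4 founders
            g2_ids = []
            for j in range(2):
                rid = f"f{fi}.{l}.G2.{j}"
                records.append(
                    CrossRecord(rid, g1_ids[2 * j], g1_ids[2 * j + 1], "G2")
                )
                ped._funnel[rid] = fun
                g2_ids.append(rid)
            rid = f"f{fi}.G3.{l}"
            if rng.random() < design.reciprocal_fraction:
                records.append(CrossRecord(rid, g2_ids[1], g2_ids[0], "G3"))
                line_fun = fun_reciprocal
            else:
                records.append(CrossRecord(rid, g2_ids[0], g2_ids[1], "G3"))
                line_fun = fun
            ped._funnel[rid] = line_fun
            g3_pool.append((rid, fi))
            if design.intercross_generations == 0:
                terminal.append((rid, line_fun))

    if design.intercross_generations > 0:
        n_lines = len(g3_pool)
        if len({fi for _, fi in g3_pool}) < 2:
            raise DesignError("intercrossing requires at least 2 funnels")
        # funnel-ancestry sets, to pair lines from different funnels
        current = [(rid, frozenset([fi])) for rid, fi in g3_pool]
        for gen in range(1, design.intercross_generations + 1):
            nxt = []
            for l in range(n_lines):
                for _ in range(200):
                    i, j = rng.choice(len(current), size=2, replace=False)
                    if current[i][1].isdisjoint(current[j][1]):
                        break
                rid = f"AIC{gen}.{l}"
                records.append(
                    CrossRecord(rid, current[i][0], current[j][0], f"AIC{gen}")
                )
                nxt.append((rid, current[i][1] | current[j][1]))
            current = nxt
        terminal = [(rid, None) for rid, _ in current]

    for l, (tid, fun) in enumerate(terminal):
        prev = tid
        for s in range(1, design.selfing_generations + 1):
            rid = f"L{l}.S{s}"
            records.append(CrossRecord(rid, prev, prev, f"S{s}"))
            if fun is not None:
                ped._funnel[rid] = fun
            prev = rid
        ped.ril_ids.append(prev)

    ped._by_id = {r.id: r for r in records}
    return ped
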