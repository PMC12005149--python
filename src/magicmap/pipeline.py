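"""End-to-end pipeline driver: simulate -> call -> rf -> map -> impute -> scan.

A :class:`RunConfig` (constructible from YAML) fully determines a run; the
same config and seed give byte-identical artifacts. All randomness flows
from the single root seed through named substreams.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .pedigree import DesignSpec, build_pedigree
from .simulate import (
    GeneticMapSpec,
    DistortionSpec,
    default_intensity_model,
    emit_intensities,
    random_marker_model,
    simulate_population,
)
from .calling import call_panel
from .twopoint import TwoLocusModel, estimate_rf_matrix
from .mapbuild import cluster_order_cross, estimate_map, form_groups, order_cross
from .hmm_ibd import (
    HMMParams,
    blocks_and_recombination,
    forward_backward,
    posteriors_at_positions,
    viterbi,
)
from .distortion import composition_scan, position_grid
from . import io as mio

ALL_STAGES = ("pedigree", "simulate", "call", "rf", "map", "impute", "scan")


class DependencyError(RuntimeError):
    """A stage was requested without its upstream artifact."""


@dataclass
class RunConfig:
    seed: int = 0
    design: dict = field(default_factory=dict)
    map: dict = field(default_factory=lambda: {"n_chromosomes": 3, "length": 100.0,
                                               "n_markers": 100})
    marker: dict = field(default_factory=dict)
    distortions: list = field(default_factory=list)
    stages: tuple = ALL_STAGES
    call_from_intensities: bool = False
    error_rate: float = 0.1  # HMM emission error parameter
    n_initial_groups: int = 20

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if "seed" not in raw:
            raise ValueError("config must set a seed (stochastic steps require it)")
        return cfg

    def design_spec(self) -> DesignSpec:
        return DesignSpec(**self.design)

    def map_spec(self) -> GeneticMapSpec:
        return GeneticMapSpec.uniform(**self.map)

    def distortion_specs(self):
        return [DistortionSpec(**d) for d in self.distortions]


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the requested stages in dependency order under ``outdir``.

    Returns a manifest dict (also written as ``manifest.json``) recording
    the package version, seed and a hash of the configuration.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = tuple(config.stages)
    for s in stages:
        if s not in ALL_STAGES:
            raise ValueError(f"unknown stage {s!r}")
    done = {}

    design = config.design_spec()
    mapspec = config.map_spec()

    if "pedigree" in stages:
        ped = build_pedigree(design, seed=config.seed)
        mio.write_pedigree_csv(ped, outdir / "pedigree.csv")
        done["pedigree"] = ped

    pop = None
    if "simulate" in stages:
        ped = done.get("pedigree")
        if ped is None:
            raise DependencyError("simulate requires the pedigree stage")
        mm = random_marker_model(
            mapspec,
            seed=config.seed,
            alleles=config.marker.get("alleles", "biallelic"),
            error_rate=config.marker.get("error_rate", 0.0),
            missing_rate=config.marker.get("missing_rate", 0.0),
        )
        pop = simulate_population(
            ped, mapspec, mm, distortions=config.distortion_specs(), seed=config.seed
        )
        mio.write_genotype_csv(
            pop.calls, pop.ril_ids, pop.marker_names, outdir / "genotypes.csv"
        )
        done["simulate"] = pop

    calls = None
    if "call" in stages:
        if pop is None:
            raise DependencyError("call requires the simulate stage")
        if config.call_from_intensities:
            model = default_intensity_model(pop.marker_model)
            inten = emit_intensities(pop, model, seed=config.seed)
            mio.write_intensity_csv(
                inten, pop.ril_ids, pop.marker_names, outdir / "intensities.csv"
            )
            panel = call_panel(inten, seed=config.seed)
            calls = np.full_like(pop.calls, -1)
            calls[np.ix_(panel.kept_lines, panel.polymorphic_markers)] = panel.calls
        else:
            calls = pop.calls
        mio.write_genotype_csv(
            calls, pop.ril_ids, pop.marker_names, outdir / "calls.csv"
        )
        done["call"] = calls

    rf = None
    if "rf" in stages:
        if calls is None:
            raise DependencyError("rf requires the call stage")
        model = TwoLocusModel(design)
        rf = estimate_rf_matrix(calls, pop.marker_model.founder_alleles, model)
        np.savetxt(outdir / "rf.csv", rf, delimiter=",")
        done["rf"] = rf

    est_map = None
    if "map" in stages:
        if rf is None:
            raise DependencyError("map requires the rf stage")
        groups = form_groups(rf, min(config.n_initial_groups, rf.shape[0]))
        rows = []
        for g in np.unique(groups.labels):
            idx = np.where(groups.labels == g)[0]
            sub = rf[np.ix_(idx, idx)]
            order = order_cross(sub, cluster_order_cross(sub))
            pos, _ = estimate_map(sub, order)
            for k, o in enumerate(order):
                rows.append((f"LG{g+1}", pop.marker_names[idx[o]], pos[k]))
        est_map = pd.DataFrame(rows, columns=["chromosome", "marker", "position_cM"])
        mio.write_map_csv(est_map, outdir / "map.csv")
        done["map"] = est_map

    post = None
    if "impute" in stages:
        if calls is None:
            raise DependencyError("impute requires the call stage")
        params = HMMParams(design=design, error_rate=config.error_rate)
        post = forward_backward(
            calls, pop.marker_model.founder_alleles, _positions_for(pop), params
        )
        paths = viterbi(
            calls, pop.marker_model.founder_alleles, _positions_for(pop), params
        )
        summary = blocks_and_recombination(
            paths, pop.marker_pos, pop.marker_chrom, mapspec
        )
        rows = []
        for li, blocks in enumerate(summary.blocks):
            for c, a, b, s in blocks:
                rows.append((pop.ril_ids[li], c, a, b, s))
        pd.DataFrame(
            rows, columns=["line", "chromosome", "start", "end", "state"]
        ).to_csv(outdir / "viterbi_blocks.csv", index=False)
        done["impute"] = post

    if "scan" in stages:
        if post is None:
            raise DependencyError("scan requires the impute stage")
        gchrom, gpos = position_grid(mapspec)
        gp = posteriors_at_positions(
            post, pop.marker_pos, pop.marker_chrom, gchrom, gpos
        )
        scan = composition_scan(gp, gchrom, gpos)
        mio.write_scan_csv(scan, outdir / "scan_main.csv")
        done["scan"] = scan

    cfg_hash = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": cfg_hash,
        "stages": list(stages),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _positions_for(pop):
    """Concatenated marker coordinates for a single HMM chain.

    Chromosomes are laid end to end with a large (effectively unlinked)
    spacer between them, so one forward-backward pass covers the genome.
    """
    out = np.empty_like(pop.marker_pos)
    shift = 0.0
    last = None
    start = 0.0
    for k, (c, p) in enumerate(zip(pop.marker_chrom, pop.marker_pos)):
        if c != last:
            if last is not None:
                shift = out[k - 1] + 1e4  # ~ unlinked gap
            last = c
            start = p
        out[k] = shift + (p - start)
    return out
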