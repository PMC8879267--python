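"""End-to-end survey analysis: statistics, networks, cliques, superimposition.

``run_pipeline`` executes the whole workflow on either a survey CSV pair or
a synthetic study configuration:

1. read or generate the survey and species metadata;
2. per-site abundance matrices, rank abundance and rarefaction curves;
3. Bray-Curtis site dissimilarities and a UPGMA dendrogram;
4. per-site bipartite networks (SIF/GraphML export);
5. community partitioning (greedy modularity by default, MCODE optionally)
   and species-clique extraction with hubs;
6. the focal-pair Pearson exclusion test on relative abundances;
7. cross-site superimposition of focal associations, classification into
   shared/exclusive modules and MCL clustering of the combined graph.

All outputs are deterministic: identical config and seed produce a
byte-identical output bundle, and ``manifest.json`` records the config
hash, seed and package version needed to re-execute the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .ecostats import (
    CorrelationResult,
    bray_curtis_matrix,
    pearson_exclusion_test,
    rank_abundance,
    rarefaction_curve,
    upgma,
)
from .io import (
    AbundanceMatrix,
    SpeciesMetadata,
    SurveyTable,
    read_species_metadata,
    read_survey,
    to_abundance_matrix,
    write_sif,
    write_species_metadata,
    write_survey,
)
from .mcl import MclParams
from .mcode import McodeParams, mcode_clusters
from .network import build_bipartite, simplify, species_projection
from .partition import Clique, extract_species_cliques, greedy_modularity_partition, identify_hubs
from .superimpose import (
    FocalAssociationGraph,
    cluster_combined,
    extract_focal_edges,
    merge_and_classify,
    site_exclusion_check,
)
from .synthetic import SyntheticConfig, generate_study

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "cliques_from_mcode"]

ALGORITHMS = ("greedy_modularity", "mcode")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    survey_path: str | None = None
    species_path: str | None = None
    synthetic: SyntheticConfig | None = None
    focal: tuple[str, str] = ("LC", "PJ")
    algorithm: str = "greedy_modularity"
    mcode_params: McodeParams = field(default_factory=McodeParams)
    mcl_params: MclParams = field(default_factory=MclParams)
    pearson_unit: str = "transect"  # or "site"
    weight_by: str = "cliques"  # or "transects" (projection weights)
    rarefaction_points: int = 20
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.pearson_unit not in ("transect", "site"):
            raise ValueError("pearson_unit must be 'transect' or 'site'")
        if self.weight_by not in ("cliques", "transects"):
            raise ValueError("weight_by must be 'cliques' or 'transects'")
        if (self.survey_path is None) == (self.synthetic is None):
            raise ValueError("provide either survey/species paths or a synthetic config")
        if self.survey_path is not None and self.species_path is None:
            raise ValueError("a species metadata path is required with a survey path")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)  # where a bundle lands is not part of its identity
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory bundle of everything one run computed."""

    config: PipelineConfig
    survey: SurveyTable
    meta: SpeciesMetadata
    matrices: dict[str, AbundanceMatrix]
    rank_abundances: dict[str, pd.DataFrame]
    rarefaction: pd.DataFrame
    bray_curtis: pd.DataFrame
    dendrogram_newick: str
    networks: dict[str, nx.Graph]
    cliques: list[Clique]
    correlation: CorrelationResult
    focal_graph: FocalAssociationGraph
    modules: list[dict]
    exclusion_per_site: dict[str, bool]
    exclusion_global: bool
    association_events: int
    association_pairs: int
    truth: object | None = None

    def cliques_frame(self) -> pd.DataFrame:
        rows = [
            {
                "site": c.site_id,
                "clique_rank": c.rank,
                "species_code": s,
                "is_hub": s in c.hubs,
                "status": self.meta.status_of(s) if s in self.meta else "",
            }
            for c in self.cliques
            for s in c.members
        ]
        return pd.DataFrame(
            rows, columns=["site", "clique_rank", "species_code", "is_hub", "status"]
        )


def cliques_from_mcode(
    g: nx.Graph,
    meta: SpeciesMetadata,
    params: McodeParams,
    *,
    min_species: int = 2,
) -> list[Clique]:
    """Species cliques from MCODE clusters of a bipartite site network.

    MCODE clusters need not cover the graph; species outside every cluster
    simply belong to no clique.
    """
    site = g.graph.get("site_id", "")
    raw = []
    for cl in mcode_clusters(g, params):
        members = sorted(
            n for n in cl.members if g.nodes[n].get("partite") == "species"
        )
        if len(members) >= min_species:
            raw.append((members, set(cl.members)))
    raw.sort(key=lambda ms: (-len(ms[0]), ms[0]))
    out = []
    for rank, (members, community) in enumerate(raw, start=1):
        clique = Clique(site_id=site, rank=rank, members=members)
        clique.hubs = identify_hubs(clique, g, community=community)
        invasive_hubs = [h for h in clique.hubs if meta.status_of(h) == "invasive"]
        clique.dominant_invasive = invasive_hubs[0] if invasive_hubs else None
        out.append(clique)
    return out


def _focal_relative_abundances(
    matrices: dict[str, AbundanceMatrix], focal: tuple[str, str], unit: str
) -> tuple[np.ndarray, np.ndarray]:
    f1, f2 = focal
    xs, ys = [], []
    if unit == "transect":
        for m in matrices.values():
            totals = m.counts.sum(axis=1)
            c1 = (
                m.counts[:, m.species.index(f1)]
                if f1 in m.species
                else np.zeros(len(m.transects), dtype=np.int64)
            )
            c2 = (
                m.counts[:, m.species.index(f2)]
                if f2 in m.species
                else np.zeros(len(m.transects), dtype=np.int64)
            )
            keep = totals > 0
            xs.extend(c1[keep] / totals[keep])
            ys.extend(c2[keep] / totals[keep])
    else:
        for m in matrices.values():
            total = m.total
            v = m.species_vector()
            xs.append(float(v.get(f1, 0)) / total)
            ys.append(float(v.get(f2, 0)) / total)
    return np.asarray(xs), np.asarray(ys)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; write the output bundle if out_dir is set."""
    truth = None
    if config.synthetic is not None:
        survey, meta, truth = generate_study(config.synthetic)
    else:
        if not Path(config.survey_path).exists():
            raise FileNotFoundError(f"survey file not found: {config.survey_path}")
        if not Path(config.species_path).exists():
            raise FileNotFoundError(f"species file not found: {config.species_path}")
        meta = read_species_metadata(config.species_path)
        survey = read_survey(config.survey_path, meta)

    f1, f2 = config.focal
    for f in (f1, f2):
        if f not in meta:
            raise ValueError(f"focal species {f!r} not present in species metadata")

    sites = survey.sites
    if not sites:
        raise ValueError("survey contains no records")
    matrices = {s: to_abundance_matrix(survey, s) for s in sites}

    rank_tables = {s: rank_abundance(matrices[s], meta).table for s in sites}

    rare_rows = []
    for s in sites:
        total = matrices[s].total
        sizes = sorted(
            {
                int(round(n))
                for n in np.linspace(1, total, min(config.rarefaction_points, total))
            }
        )
        curve = rarefaction_curve(matrices[s].species_totals, sizes)
        curve.insert(0, "site", s)
        rare_rows.append(curve)
    rarefaction = pd.concat(rare_rows, ignore_index=True)

    if len(sites) >= 2:
        bc = bray_curtis_matrix(list(matrices.values()))
        newick = upgma(bc).to_newick()
    else:
        bc = pd.DataFrame([[0.0]], index=sites, columns=sites)
        newick = f"{sites[0]};"

    networks = {s: simplify(build_bipartite(matrices[s])) for s in sites}
    from .network import count_associations

    events = pairs = 0
    for g in networks.values():
        e, p = count_associations(g)
        events += e
        pairs += p

    cliques: list[Clique] = []
    for s in sites:
        g = networks[s]
        if config.algorithm == "greedy_modularity":
            part = greedy_modularity_partition(g)
            cliques.extend(extract_species_cliques(part, g, meta))
        else:
            cliques.extend(cliques_from_mcode(g, meta, config.mcode_params))

    correlation = pearson_exclusion_test(
        *_focal_relative_abundances(matrices, config.focal, config.pearson_unit)
    )

    if config.weight_by == "cliques":
        edges1 = extract_focal_edges(cliques, f1)
        edges2 = extract_focal_edges(cliques, f2)
    else:
        edges1, edges2 = {}, {}
        for s in sites:
            proj = species_projection(networks[s])
            for focal, edges in ((f1, edges1), (f2, edges2)):
                if focal in proj:
                    for partner in proj.neighbors(focal):
                        edges[partner] = (
                            edges.get(partner, 0) + proj[focal][partner]["weight"]
                        )
    focal_graph = merge_and_classify(edges1, edges2, f1, f2)
    _, modules = cluster_combined(focal_graph, config.mcl_params, meta)
    exclusion_per_site, exclusion_global = site_exclusion_check(cliques, config.focal)

    result = PipelineResult(
        config=config,
        survey=survey,
        meta=meta,
        matrices=matrices,
        rank_abundances=rank_tables,
        rarefaction=rarefaction,
        bray_curtis=bc,
        dendrogram_newick=newick,
        networks=networks,
        cliques=cliques,
        correlation=correlation,
        focal_graph=focal_graph,
        modules=modules,
        exclusion_per_site=exclusion_per_site,
        exclusion_global=exclusion_global,
        association_events=events,
        association_pairs=pairs,
        truth=truth,
    )
    if config.out_dir is not None:
        write_bundle(result, Path(config.out_dir))
    return result


def write_bundle(result: PipelineResult, out_dir: Path) -> None:
    """Write every artifact of a run to ``out_dir`` (deterministic bytes)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = result.config

    write_survey(result.survey, out_dir / "survey.csv")
    write_species_metadata(result.meta, out_dir / "species.csv")

    rank = pd.concat(
        [df.assign(site=s) for s, df in sorted(result.rank_abundances.items())],
        ignore_index=True,
    )[["site", "species_code", "status", "relative_abundance", "rank"]]
    rank.to_csv(out_dir / "rank_abundance.csv", index=False)
    result.rarefaction.to_csv(out_dir / "rarefaction.csv", index=False)
    result.bray_curtis.to_csv(out_dir / "bray_curtis.csv")
    (out_dir / "dendrogram.nwk").write_text(result.dendrogram_newick + "\n")

    net_dir = out_dir / "networks"
    net_dir.mkdir(exist_ok=True)
    for site, g in sorted(result.networks.items()):
        write_sif(g, net_dir / f"{site}.sif")
        nx.write_graphml(g, net_dir / f"{site}.graphml")

    result.cliques_frame().to_csv(out_dir / "cliques.csv", index=False)

    corr = result.correlation
    (out_dir / "correlation.json").write_text(
        json.dumps(
            {
                "focal": list(cfg.focal),
                "unit": cfg.pearson_unit,
                "r": corr.r,
                "p_value": corr.p_value,
                "n": corr.n,
                "alpha": corr.alpha,
                "significant": corr.significant,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )

    fg = result.focal_graph
    rows = []
    for focal, edges in ((fg.focal1, fg.edges1), (fg.focal2, fg.edges2)):
        for partner in sorted(edges):
            rows.append(
                {
                    "focal": focal,
                    "partner": partner,
                    "partner_status": (
                        result.meta.status_of(partner) if partner in result.meta else ""
                    ),
                    "weight": edges[partner],
                    "class": fg.partner_class(partner),
                }
            )
    pd.DataFrame(
        rows, columns=["focal", "partner", "partner_status", "weight", "class"]
    ).to_csv(out_dir / "focal_associations.csv", index=False)

    (out_dir / "modules.json").write_text(
        json.dumps(
            {
                "modules": result.modules,
                "module_strengths": {
                    k: list(v) for k, v in fg.module_strengths().items()
                },
                "exclusion_per_site": result.exclusion_per_site,
                "exclusion_global": result.exclusion_global,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )

    manifest = {
        "vegnet_version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": cfg.content_hash(),
        "sites": sorted(result.networks),
        "association_events": result.association_events,
        "association_pairs": result.association_pairs,
        "n_cliques": len(result.cliques),
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
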