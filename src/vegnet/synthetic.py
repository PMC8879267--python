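"""Seeded generator of synthetic multi-site transect surveys.

Real vegetation-survey data of the kind this package analyses is rarely
deposited, so the generator emulates its statistical structure and serves
as the test bed for the whole pipeline:

* several sites, each sampled by line transects;
* species organised into planted co-occurrence **blocks** per site: a
  species occurs on a transect of its own block with probability ``p_in``
  (default 0.8) and elsewhere with background probability ``p_out``
  (default 0.05) — a planted partition analogue on the bipartite graph;
  each block is defined by an **anchor** (a focal invader or a native hub)
  that occupies every own-block transect, making it the block's planted
  hub;
* two **focal invaders** (LC and PJ by default), each anchoring one block
  at every site; with exclusion strength ``gamma = 1`` a focal-block
  species never occurs on the other focal's transects, so the two planted
  partner sets are disjoint — the clique-level exclusion the analysis is
  meant to recover;
* site-level **abundance anti-correlation**: each site has a dominance
  weight ``w`` tilting the two focals' mean abundances in opposite
  directions (sites alternate between the endpoints of
  ``focal_dominance_range``, a mosaic of LC-dominated and PJ-dominated
  fragments), so the focals' relative abundances are negatively
  correlated across sampling units — the abundance-level exclusion
  signature;
* per-occurrence counts are overdispersed (shifted negative binomial),
  the norm for clumped vegetation data.

All draws come from one master seed; per-site substreams are derived
deterministically, so adding a site never perturbs the others.  The
planted structure is returned as :class:`SyntheticGroundTruth` for
recovery scoring.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ecostats import CorrelationResult
from .io import SpeciesMetadata, SpeciesRecord, SurveyRecord, SurveyTable
from .partition import Clique
from .superimpose import FocalAssociationGraph, site_exclusion_check

__all__ = [
    "SyntheticConfig",
    "SyntheticGroundTruth",
    "generate_study",
    "recovery_metrics",
]

_SITE_CODES = ["SA", "SB", "SC", "SD", "SE", "SF", "SG", "SH", "SI", "SJ"]


@dataclass
class SyntheticConfig:
    """Study design parameters for the synthetic survey generator.

    Defaults mirror a six-fragment urban-woodland survey: 6 sites of 15
    transects, ~50 species (45 native, 2 focal invasive, 3 introduced),
    four co-occurrence blocks per site, dense within-block occupancy and
    sparse background, full focal exclusion, and site dominance weights
    alternating between 0.85 and 0.15.
    """

    n_sites: int = 6
    transects_per_site: int = 15
    n_native: int = 45
    n_invasive: int = 2
    n_introduced: int = 3
    blocks_per_site: int = 4
    p_in: float = 0.8
    p_out: float = 0.05
    abundance_dispersion: float = 4.0
    mean_abundance: float = 6.0
    exclusion_strength: float = 1.0  # gamma
    focal_dominance_range: tuple[float, float] = (0.15, 0.85)
    dominance_boost: float = 12.0
    focal_codes: tuple[str, str] = ("LC", "PJ")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_in", "p_out", "exclusion_strength"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if min(self.n_native, self.n_invasive, self.n_introduced) < 0:
            raise ValueError("species counts must be >= 0")
        if self.n_invasive < 2:
            raise ValueError("need at least the two focal invasive species")
        if self.blocks_per_site < 2:
            raise ValueError("need at least the two focal-anchored blocks")
        n_species = self.n_native + self.n_invasive + self.n_introduced
        if self.blocks_per_site > n_species:
            raise ValueError("more blocks than species")
        if self.blocks_per_site > self.transects_per_site:
            raise ValueError("more blocks than transects per site")
        if self.n_sites > len(_SITE_CODES):
            raise ValueError(f"at most {len(_SITE_CODES)} sites supported")


@dataclass
class SyntheticGroundTruth:
    """Planted structure underlying one generated study."""

    config: SyntheticConfig
    species_block: dict[str, int]  # global block membership of each species
    transect_block: dict[str, dict[str, int]]  # site -> transect -> block
    block_anchor: dict[int, str]  # block -> anchoring species code
    site_dominance: dict[str, float]  # site -> focal dominance weight w
    occupancy: dict[str, pd.DataFrame]  # site -> realised presence matrix

    @property
    def focal_blocks(self) -> tuple[int, int]:
        return 0, 1

    def planted_partners(self, which: int) -> set[str]:
        """Non-focal species planted in focal block ``which`` (0 or 1)."""
        focal = self.config.focal_codes[which]
        return {
            s
            for s, b in self.species_block.items()
            if b == which and s != focal
        }


def _species_codes(prefix: str, n: int, taken: set[str]) -> list[str]:
    """Deterministic unique 3-letter codes: prefix + AA, AB, ..."""
    out = []
    for a, b in itertools.product(string.ascii_uppercase, repeat=2):
        if len(out) == n:
            break
        code = f"{prefix}{a}{b}"
        if code not in taken:
            out.append(code)
            taken.add(code)
    return out


def _make_metadata(config: SyntheticConfig) -> SpeciesMetadata:
    f1, f2 = config.focal_codes
    taken = {f1, f2}
    records = [
        SpeciesRecord(f1, "Lantana camara (synthetic survey)", "invasive"),
        SpeciesRecord(f2, "Prosopis juliflora (synthetic survey)", "invasive"),
    ]
    for code in _species_codes("V", config.n_invasive - 2, taken):
        records.append(
            SpeciesRecord(code, f"Invasiva synthetica {code.lower()}", "invasive")
        )
    for code in _species_codes("I", config.n_introduced, taken):
        records.append(
            SpeciesRecord(code, f"Introducta synthetica {code.lower()}", "introduced")
        )
    for code in _species_codes("N", config.n_native, taken):
        records.append(
            SpeciesRecord(code, f"Nativa synthetica {code.lower()}", "native")
        )
    return SpeciesMetadata(records)


def _shifted_negbin(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """1 + NegBin draw with the given mean and size (dispersion) parameter."""
    extra_mean = max(mean - 1.0, 1e-9)
    p = dispersion / (dispersion + extra_mean)
    return 1 + int(rng.negative_binomial(dispersion, p))


def generate_study(
    config: SyntheticConfig,
) -> tuple[SurveyTable, SpeciesMetadata, SyntheticGroundTruth]:
    """Generate one synthetic multi-site survey (fully seed-reproducible)."""
    meta = _make_metadata(config)
    f1, f2 = config.focal_codes
    gamma = config.exclusion_strength
    n_blocks = config.blocks_per_site

    # global stream: species-block assignment and site dominance weights
    g_rng = np.random.default_rng([config.seed, 999_983])
    non_focal = sorted(c for c in meta if c not in (f1, f2))
    shuffled = list(non_focal)
    g_rng.shuffle(shuffled)
    species_block = {f1: 0, f2: 1}
    for i, code in enumerate(shuffled):
        species_block[code] = i % n_blocks

    # anchors: focals anchor blocks 0 and 1; the lowest-coded native member
    # anchors each remaining block
    block_anchor = {0: f1, 1: f2}
    for b in range(2, n_blocks):
        members = sorted(
            s
            for s, blk in species_block.items()
            if blk == b and meta.status_of(s) == "native"
        )
        block_anchor[b] = members[0] if members else sorted(
            s for s, blk in species_block.items() if blk == b
        )[0]

    # sites alternate between the dominance endpoints: a deterministic
    # mosaic of LC-dominated and PJ-dominated fragments whose tilt depends
    # only on the site index, so adding sites never perturbs existing ones
    lo, hi = config.focal_dominance_range
    sites = _SITE_CODES[: config.n_sites]
    site_dominance = {
        s: float(hi if i % 2 == 0 else lo) for i, s in enumerate(sites)
    }
    species_order = sorted(meta)

    records: list[SurveyRecord] = []
    transect_block: dict[str, dict[str, int]] = {}
    occupancy: dict[str, pd.DataFrame] = {}
    for si, site in enumerate(sites):
        rng = np.random.default_rng([config.seed, si])
        w = site_dominance[site]
        transects = [f"T{i + 1:02d}" for i in range(config.transects_per_site)]
        # round-robin over a shuffled order guarantees every block >= 1 transect
        order = rng.permutation(config.transects_per_site)
        t_block = {transects[t]: int(i % n_blocks) for i, t in enumerate(order)}
        transect_block[site] = t_block

        occ = pd.DataFrame(False, index=transects, columns=species_order)
        for t in transects:
            bt = t_block[t]
            for s in species_order:
                bs = species_block[s]
                if bs == bt:
                    # the block's anchor (focal invader or native hub) defines
                    # the block: it occupies every own-block transect, which is
                    # what makes it the planted hub of the community
                    p = 1.0 if block_anchor[bs] == s else config.p_in
                else:
                    conflict = (bs == 0 and bt == 1) or (bs == 1 and bt == 0)
                    p = config.p_out * (1 - gamma * conflict)
                if rng.random() >= p:
                    continue
                occ.loc[t, s] = True
                if s == f1:
                    mean = config.mean_abundance * (1 + config.dominance_boost * w)
                elif s == f2:
                    mean = config.mean_abundance * (
                        1 + config.dominance_boost * (1 - w)
                    )
                else:
                    mean = config.mean_abundance
                count = _shifted_negbin(rng, mean, config.abundance_dispersion)
                records.append(SurveyRecord(site, t, s, count))
        occupancy[site] = occ

    truth = SyntheticGroundTruth(
        config=config,
        species_block=species_block,
        transect_block=transect_block,
        block_anchor=block_anchor,
        site_dominance=site_dominance,
        occupancy=occupancy,
    )
    return SurveyTable(records), meta, truth


def recovery_metrics(
    truth: SyntheticGroundTruth,
    cliques: list[Clique],
    correlation: CorrelationResult,
    focal_graph: FocalAssociationGraph,
) -> dict:
    """Score pipeline output against the planted structure.

    Returns a dict with

    * ``exclusion_per_site`` / ``exclusion_global`` — the focals landed in
      different cliques (at every site);
    * ``partner_precision`` / ``partner_recall`` — recovered exclusive-module
      partners vs the planted focal-block species, pooled over both focals;
    * ``correlation_r`` / ``correlation_p`` / ``significant_negative`` — the
      abundance anti-correlation between the two focals.
    """
    f1, f2 = truth.config.focal_codes
    if (focal_graph.focal1, focal_graph.focal2) != (f1, f2):
        raise ValueError("focal graph focals do not match the generated study")
    known = set(truth.species_block)
    stray = set(focal_graph.partners) - known
    if stray:
        raise ValueError(f"partners outside the generated species universe: {sorted(stray)}")

    per_site, global_ok = site_exclusion_check(cliques, (f1, f2))

    planted1 = truth.planted_partners(0)
    planted2 = truth.planted_partners(1)
    recovered1 = set(focal_graph.exclusive1)
    recovered2 = set(focal_graph.exclusive2)
    tp = len(recovered1 & planted1) + len(recovered2 & planted2)
    n_recovered = len(recovered1) + len(recovered2)
    n_planted = len(planted1) + len(planted2)
    precision = tp / n_recovered if n_recovered else (1.0 if n_planted == 0 else 0.0)
    recall = tp / n_planted if n_planted else 1.0

    return {
        "exclusion_per_site": per_site,
        "exclusion_global": global_ok,
        "partner_precision": precision,
        "partner_recall": recall,
        "correlation_r": correlation.r,
        "correlation_p": correlation.p_value,
        "significant_negative": correlation.r < 0 and correlation.significant,
    }
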