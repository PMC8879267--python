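"""Packaged reference datasets.

``ridge_cliques`` / ``ridge_species``
    The published community table of a six-fragment urban woodland survey
    from the South Delhi Ridge (25 species cliques across sites SV, TUQ,
    HK, JCF, MEH and JNU), transcribed to species codes.  The two dominant
    invaders, *Lantana camara* (LC) and *Prosopis juliflora* (PJ), never
    share a clique in this table — the exclusion pattern the analysis
    machinery is built to detect.  The underlying field data is not
    deposited, so only this derived table is shipped.

``toy_survey`` / ``toy_species``
    A small synthetic two-site, six-transect, eight-species survey with an
    obvious planted structure (one LC block and one PJ block per site),
    used as a worked example and as a hand-checkable pipeline fixture.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .io import SpeciesMetadata, SurveyTable, read_species_metadata, read_survey
from .partition import Clique

__all__ = [
    "ridge_species",
    "ridge_cliques",
    "toy_species",
    "toy_survey",
    "toy_survey_path",
    "cliques_from_frame",
]


def _data_path(name: str) -> Path:
    return Path(resources.files("vegnet") / "data" / name)


def ridge_species() -> SpeciesMetadata:
    """Species metadata for the published community table."""
    return read_species_metadata(_data_path("ridge_species.csv"))


def cliques_from_frame(df: pd.DataFrame) -> list[Clique]:
    """Build :class:`Clique` objects from a cliques table.

    Expects columns ``site, clique_rank, species_code`` and optionally
    ``is_hub``.
    """
    cliques = []
    for (site, rank), group in df.groupby(["site", "clique_rank"], sort=True):
        members = sorted(group["species_code"])
        hubs = (
            sorted(group.loc[group["is_hub"].astype(bool), "species_code"])
            if "is_hub" in group
            else []
        )
        cliques.append(
            Clique(site_id=str(site), rank=int(rank), members=members, hubs=hubs)
        )
    return cliques


def ridge_cliques() -> list[Clique]:
    """The 25 published species cliques of the six-site woodland survey."""
    return cliques_from_frame(pd.read_csv(_data_path("ridge_cliques.csv")))


def toy_species() -> SpeciesMetadata:
    return read_species_metadata(_data_path("toy_species.csv"))


def toy_survey() -> SurveyTable:
    return read_survey(_data_path("toy_survey.csv"), toy_species())


def toy_survey_path() -> tuple[Path, Path]:
    """Paths of the packaged toy survey and species CSVs."""
    return _data_path("toy_survey.csv"), _data_path("toy_species.csv")
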