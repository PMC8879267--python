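"""Domain types and readers/writers for vegetation survey data.

The root input of the pipeline is a long-format survey table: one row per
(site, transect, species) observation with a non-negative individual count,
optionally carrying girth-at-breast-height and canopy-cover measurements.
Species identities are resolved against a separate metadata table assigning
each species a short code (2-4 uppercase letters), a scientific name, and an
invasion status: ``native``, ``invasive`` or ``introduced``.

Per-site transect x species abundance matrices are derived from the survey
table; presence/absence bipartite networks and all downstream statistics are
computed from those matrices.  Networks are exchanged as SIF (simple
interaction format) edge lists, one ``transect<TAB>occurs_in<TAB>species``
line per edge.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "STATUSES",
    "SIF_RELATION",
    "SpeciesRecord",
    "SpeciesMetadata",
    "SurveyRecord",
    "SurveyTable",
    "AbundanceMatrix",
    "ValidationError",
    "read_species_metadata",
    "write_species_metadata",
    "read_survey",
    "write_survey",
    "to_abundance_matrix",
    "transect_node_id",
    "write_sif",
    "read_sif",
]

#: Recognised invasion-status labels.
STATUSES = ("native", "invasive", "introduced")

#: Relation label used in SIF output.  The two-column edge lists this format
#: mirrors carry no relation, but standard SIF requires one.
SIF_RELATION = "occurs_in"

_CODE_RE = re.compile(r"^[A-Z]{2,4}$")


class ValidationError(ValueError):
    """Raised when survey or metadata input violates an invariant."""


@dataclass(frozen=True)
class SpeciesRecord:
    """One species: short code, scientific name, invasion status."""

    code: str
    name: str
    status: str

    def __post_init__(self) -> None:
        if not _CODE_RE.match(self.code):
            raise ValidationError(
                f"species code {self.code!r} must be 2-4 uppercase letters"
            )
        if self.status not in STATUSES:
            raise ValidationError(
                f"species {self.code}: status {self.status!r} not one of {STATUSES}"
            )
        # scientific names normalised to NFC so round-trips are byte-stable
        object.__setattr__(self, "name", unicodedata.normalize("NFC", self.name))


class SpeciesMetadata(Mapping[str, SpeciesRecord]):
    """Immutable code -> :class:`SpeciesRecord` mapping with status helpers."""

    def __init__(self, records: Iterable[SpeciesRecord]):
        self._records: dict[str, SpeciesRecord] = {}
        for rec in records:
            if rec.code in self._records:
                raise ValidationError(f"duplicate species code {rec.code!r}")
            self._records[rec.code] = rec

    def __getitem__(self, code: str) -> SpeciesRecord:
        return self._records[code]

    def __iter__(self):
        return iter(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def codes_with_status(self, status: str) -> list[str]:
        if status not in STATUSES:
            raise ValueError(f"unknown status {status!r}")
        return sorted(c for c, r in self._records.items() if r.status == status)

    def status_counts(self) -> dict[str, int]:
        return {s: len(self.codes_with_status(s)) for s in STATUSES}

    def status_of(self, code: str) -> str:
        return self._records[code].status


@dataclass(frozen=True)
class SurveyRecord:
    """One aggregated survey observation."""

    site: str
    transect: str
    species_code: str
    count: int
    gbh_cm: float | None = None
    canopy_cover: float | None = None


@dataclass
class SurveyTable:
    """Aggregated long-format survey table.

    Records are unique on (site, transect, species_code); duplicate input
    rows are summed on read (field sheets are often split across pages, so
    duplicates carry abundance, they are not errors).
    """

    records: list[SurveyRecord] = field(default_factory=list)

    @property
    def sites(self) -> list[str]:
        return sorted({r.site for r in self.records})

    def transects(self, site: str) -> list[str]:
        return sorted({r.transect for r in self.records if r.site == site})

    def species(self, site: str | None = None) -> list[str]:
        if site is None:
            return sorted({r.species_code for r in self.records})
        return sorted({r.species_code for r in self.records if r.site == site})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "site": r.site,
                    "transect": r.transect,
                    "species_code": r.species_code,
                    "count": r.count,
                    "gbh_cm": r.gbh_cm,
                    "canopy_cover": r.canopy_cover,
                }
                for r in self.records
            ],
            columns=[
                "site",
                "transect",
                "species_code",
                "count",
                "gbh_cm",
                "canopy_cover",
            ],
        )


@dataclass
class AbundanceMatrix:
    """Per-site transect x species count matrix.

    ``counts[t, s]`` is the number of individuals of species ``species[s]``
    recorded on transect ``transects[t]``.  Species with zero total at the
    site are excluded, so every column has a positive total.
    """

    site_id: str
    transects: list[str]
    species: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.transects), len(self.species)):
            raise ValidationError("counts shape does not match transect/species labels")
        if (self.counts < 0).any():
            raise ValidationError("abundance counts must be non-negative")

    @property
    def species_totals(self) -> np.ndarray:
        """Per-species totals N_i = sum over transects."""
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        """Grand total N = sum of all counts."""
        return int(self.counts.sum())

    @property
    def richness(self) -> int:
        return len(self.species)

    def presence(self) -> np.ndarray:
        """Boolean presence/absence view of the counts."""
        return self.counts > 0

    def species_vector(self) -> pd.Series:
        """Species totals as a code-indexed Series (for dissimilarities)."""
        return pd.Series(self.species_totals, index=self.species)


# ---------------------------------------------------------------------------
# species metadata CSV


def read_species_metadata(path: str | Path) -> SpeciesMetadata:
    """Read a ``code,scientific_name,status`` CSV into :class:`SpeciesMetadata`."""
    df = pd.read_csv(path, dtype=str)
    required = {"code", "scientific_name", "status"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"species metadata missing columns: {sorted(missing)}")
    return SpeciesMetadata(
        SpeciesRecord(row.code, row.scientific_name, row.status)
        for row in df.itertuples()
    )


def write_species_metadata(meta: SpeciesMetadata, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {"code": r.code, "scientific_name": r.name, "status": r.status}
            for r in (meta[c] for c in sorted(meta))
        ]
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# survey CSV


def read_survey(
    path: str | Path,
    meta: SpeciesMetadata | None = None,
    *,
    allow_unknown: bool = False,
) -> SurveyTable:
    """Read a survey CSV, aggregating duplicate (site, transect, species) rows.

    Parameters
    ----------
    path:
        CSV with columns ``site,transect,species_code,count`` and optional
        ``gbh_cm,canopy_cover``.
    meta:
        Species metadata used to validate codes.  Unknown codes raise a
        :class:`ValidationError` unless ``allow_unknown`` is set, in which
        case they are kept and reported via the error message path only.
    """
    df = pd.read_csv(path, dtype={"site": str, "transect": str, "species_code": str})
    required = {"site", "transect", "species_code", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"survey file missing columns: {sorted(missing)}")
    if df.empty:
        return SurveyTable([])

    counts = pd.to_numeric(df["count"])
    bad = counts < 0
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise ValidationError(f"negative count at line {row} of {path}")
    if (counts != counts.astype(int)).any():
        raise ValidationError("counts must be integers")
    df["count"] = counts.astype(int)

    if meta is not None:
        unknown = sorted(set(df["species_code"]) - set(meta))
        if unknown and not allow_unknown:
            raise ValidationError(f"unknown species codes: {unknown}")

    for col in ("gbh_cm", "canopy_cover"):
        if col not in df.columns:
            df[col] = np.nan

    grouped = df.groupby(["site", "transect", "species_code"], sort=True).agg(
        count=("count", "sum"),
        gbh_cm=("gbh_cm", "mean"),
        canopy_cover=("canopy_cover", "mean"),
    )
    records = [
        SurveyRecord(
            site=site,
            transect=transect,
            species_code=code,
            count=int(row["count"]),
            gbh_cm=None if pd.isna(row["gbh_cm"]) else float(row["gbh_cm"]),
            canopy_cover=(
                None if pd.isna(row["canopy_cover"]) else float(row["canopy_cover"])
            ),
        )
        for (site, transect, code), row in grouped.iterrows()
    ]
    return SurveyTable(records)


def write_survey(table: SurveyTable, path: str | Path) -> None:
    """Write an aggregated survey table back to CSV (lossless round-trip)."""
    df = table.to_frame().sort_values(["site", "transect", "species_code"])
    df.to_csv(path, index=False)


def to_abundance_matrix(table: SurveyTable, site: str) -> AbundanceMatrix:
    """Tabulate one site's records into an :class:`AbundanceMatrix`.

    Species never observed at the site are excluded from the columns.
    """
    if site not in table.sites:
        raise ValidationError(
            f"unknown site {site!r}; available sites: {table.sites}"
        )
    rows = [r for r in table.records if r.site == site]
    transects = sorted({r.transect for r in rows})
    species = sorted({r.species_code for r in rows})
    t_idx = {t: i for i, t in enumerate(transects)}
    s_idx = {s: j for j, s in enumerate(species)}
    counts = np.zeros((len(transects), len(species)), dtype=np.int64)
    for r in rows:
        counts[t_idx[r.transect], s_idx[r.species_code]] += r.count
    keep = counts.sum(axis=0) > 0
    species = [s for s, k in zip(species, keep) if k]
    counts = counts[:, keep]
    return AbundanceMatrix(site, transects, species, counts)


# ---------------------------------------------------------------------------
# SIF edge lists


def transect_node_id(site: str, transect: str) -> str:
    """Namespace a transect id by its site code (``HK`` + ``3`` -> ``HK3``).

    Transect labels that already start with the site code are kept as-is, so
    surveys labelled ``HK1..HK12`` are not double-prefixed.  Prefixing keeps
    transect node ids from colliding with species codes in the shared graph
    namespace.
    """
    return transect if transect.startswith(site) else f"{site}{transect}"


def write_sif(network: nx.Graph, path: str | Path) -> None:
    """Write a bipartite network as SIF, sorted by transect then species."""
    lines = []
    for u, v in network.edges():
        if network.nodes[u].get("partite") == "transect":
            t, s = u, v
        else:
            t, s = v, u
        lines.append((t, s))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for t, s in sorted(lines):
            fh.write(f"{t}\t{SIF_RELATION}\t{s}\n")


def read_sif(path: str | Path, site_id: str | None = None) -> nx.Graph:
    """Read a 3-column SIF file back into a bipartite graph.

    The first column is taken as the transect node, the third as the species
    node, matching :func:`write_sif`.
    """
    g = nx.Graph(site_id=site_id)
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValidationError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(parts)}"
                )
            t, _rel, s = parts
            g.add_node(t, partite="transect")
            g.add_node(s, partite="species")
            g.add_edge(t, s)
    return g
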