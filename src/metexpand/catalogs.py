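"""Compound catalogs, popularity annotation and candidate ranking.

A compound is *known* when it occurs in at least one catalog.  Catalogs
carry a class label — ``biological`` (metabolic databases), ``bioactive``
(bioactivity databases) or ``chemical`` (general chemistry databases) —
and when a compound occurs in several, it is counted once with precedence
biological > bioactive > chemical.

Candidate ranking follows the literature-popularity heuristic: popularity
is the sum of the citation and patent counts attached to a compound, and
only compounds with at least one annotation are kept as biosynthesis
targets.  Ties are broken by compound name (ascending); the candidate
tables never report ties in a documented order otherwise.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError

CATALOG_CLASSES = ("biological", "bioactive", "chemical")


@dataclass
class CompoundCatalog:
    """Membership table of one catalog class."""

    catalog_class: str
    members: dict[str, list[tuple[str, str]]] = field(default_factory=dict)  # key -> [(db, id)]

    def __post_init__(self) -> None:
        if self.catalog_class not in CATALOG_CLASSES:
            raise ValidationError(
                f"catalog class must be one of {CATALOG_CLASSES}, got {self.catalog_class!r}"
            )

    def __contains__(self, key: str) -> bool:
        return key in self.members

    def add(self, key: str, database: str, identifier: str) -> None:
        self.members.setdefault(key, []).append((database, identifier))

    # --- TSV round trip -----------------------------------------------------
    HEADER = ("canonical_key", "catalog_class", "database", "identifier")

    def to_tsv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf, delimiter="\t", lineterminator="\n")
        w.writerow(self.HEADER)
        for key in sorted(self.members):
            for db, ident in self.members[key]:
                w.writerow([key, self.catalog_class, db, ident])
        return buf.getvalue()


def catalogs_from_tsv(text: str) -> list[CompoundCatalog]:
    """Read one or more catalogs from a single TSV table."""
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    missing = set(CompoundCatalog.HEADER) - set(reader.fieldnames or ())
    if missing:
        raise ValidationError(f"catalog table missing columns: {sorted(missing)}")
    by_class: dict[str, CompoundCatalog] = {}
    for row in reader:
        cat = by_class.setdefault(
            row["catalog_class"], CompoundCatalog(row["catalog_class"])
        )
        cat.add(row["canonical_key"], row["database"], row["identifier"])
    return [by_class[c] for c in CATALOG_CLASSES if c in by_class]


def catalogs_to_tsv(catalogs: Iterable[CompoundCatalog]) -> str:
    parts = []
    for i, cat in enumerate(catalogs):
        text = cat.to_tsv()
        parts.append(text if i == 0 else text.split("\n", 1)[1])
    return "".join(parts)


def classify_compound(key: str, catalogs: Iterable[CompoundCatalog]) -> str | None:
    """Catalog class of *key* with precedence biological > bioactive >
    chemical; None when the compound occurs in no catalog."""
    found = {c.catalog_class for c in catalogs if key in c}
    for klass in CATALOG_CLASSES:
        if klass in found:
            return klass
    return None


# ---------------------------------------------------------------------------
# annotations


@dataclass(frozen=True)
class AnnotationRecord:
    compound_key: str
    citations: int
    patents: int

    def __post_init__(self) -> None:
        if self.citations < 0 or self.patents < 0:
            raise ValidationError("citation and patent counts must be >= 0")

    @property
    def popularity(self) -> int:
        return self.citations + self.patents


def popularity(citations: int, patents: int) -> int:
    """Popularity = citations + patents (both must be non-negative)."""
    if citations < 0 or patents < 0:
        raise ValidationError("citation and patent counts must be >= 0")
    return citations + patents


def annotations_from_tsv(text: str) -> dict[str, AnnotationRecord]:
    """Read an annotation table (canonical_key, name, citations, patents).

    A ``reported_total`` column, when present, is checked against the
    definitional sum; inconsistent rows are collected (not repaired) and
    returned via :func:`annotation_inconsistencies`.
    """
    out: dict[str, AnnotationRecord] = {}
    for row in csv.DictReader(io.StringIO(text), delimiter="\t"):
        rec = AnnotationRecord(
            compound_key=row["canonical_key"],
            citations=int(row["citations"]),
            patents=int(row["patents"]),
        )
        out[rec.compound_key] = rec
    return out


def annotation_inconsistencies(text: str) -> list[dict]:
    """Rows whose reported total disagrees with citations + patents."""
    bad = []
    for row in csv.DictReader(io.StringIO(text), delimiter="\t"):
        total = row.get("reported_total")
        if total in (None, ""):
            continue
        s = int(row["citations"]) + int(row["patents"])
        if int(total) != s:
            bad.append({**row, "computed_total": s})
    return bad


# ---------------------------------------------------------------------------
# candidate ranking (one-step candidate table semantics)

REPORT_COLUMNS = [
    "rank", "name", "popularity", "citations", "patents",
    "distance", "best_score", "predicted_ec",
]


def rank_candidates(
    network,
    annotations: Mapping[str, AnnotationRecord],
    exclude: Iterable[str] = (),
    names: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Rank the network's compounds by descending popularity.

    Seed metabolites (*exclude*) and compounds without a single annotation
    are dropped.  ``distance`` is the compound's generation (reaction steps
    from the seed pathway).  Ties are broken by name ascending.  The
    ``best_score``/``predicted_ec`` columns are filled by the enzyme-ranking
    stage (:func:`metexpand.enzymes.attach_enzyme_columns`) and are NA here.
    """
    excluded = set(exclude)
    names = names or {}
    rows = []
    for key, entry in network.compounds.items():
        if key in excluded or entry.generation == 0:
            continue
        rec = annotations.get(key)
        cites, pats = (rec.citations, rec.patents) if rec else (0, 0)
        pop = cites + pats
        if pop == 0:
            continue  # the >= 1 annotation filter
        rows.append({
            "key": key,
            "name": names.get(key) or entry.molecule.name or key,
            "popularity": pop,
            "citations": cites,
            "patents": pats,
            "distance": entry.generation,
            "best_score": pd.NA,
            "predicted_ec": pd.NA,
        })
    df = pd.DataFrame(
        rows,
        columns=["key", "name", "popularity", "citations", "patents",
                 "distance", "best_score", "predicted_ec"],
    )
    df = df.sort_values(
        ["popularity", "name"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df.insert(0, "rank", range(1, len(df) + 1))
    return df


def one_step_candidates(report: pd.DataFrame, network, seed_pathway=None) -> pd.DataFrame:
    """Rows of *report* whose compound is one reaction step from a seed
    intermediate (generation 1); ranks are renumbered."""
    keep = report[report["distance"] == 1].copy().reset_index(drop=True)
    keep["rank"] = range(1, len(keep) + 1)
    return keep


def report_to_tsv(df: pd.DataFrame, float_format: str = "%.2f") -> str:
    """Serialize a candidate report body (no config header) as TSV."""
    out = df.drop(columns=[c for c in ("key",) if c in df.columns])
    return out.to_csv(sep="\t", index=False, float_format=float_format)


def load_table(path: str | Path) -> str:
    return Path(path).read_text()
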