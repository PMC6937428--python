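"""Default semantic-theme vocabulary for literature-derived knowledge graphs.

The vocabulary follows the GNBR schema: relationships between drug, disease
and gene entities are labelled with short theme codes (e.g. ``"T"`` for
treatment, ``"U"`` for causal mutations) organised into four categories by
the entity types they connect.  There are 32 distinct codes; a few (``B``,
``E+``, ``E``, ``J``) appear in more than one category, so the full
(code, category) table has 36 rows.
"""

from __future__ import annotations

import csv
from pathlib import Path

from .kg import Theme

# (code, category, description) rows, grouped by category.
_DEFAULT_ROWS: list[tuple[str, str, str]] = [
    # drug - gene
    ("A+", "Dr-G", "agonism, activation"),
    ("A-", "Dr-G", "antagonism, blocking"),
    ("B", "Dr-G", "binding, ligand (esp. receptors)"),
    ("E+", "Dr-G", "increases expression/production"),
    ("E-", "Dr-G", "decreases expression/production"),
    ("E", "Dr-G", "affects expression/production (neutral)"),
    ("N", "Dr-G", "inhibits"),
    ("O", "Dr-G", "transport, channels"),
    ("K", "Dr-G", "metabolism, pharmacokinetics"),
    ("Z", "Dr-G", "enzyme activity"),
    # drug - disease
    ("T", "Dr-Dz", "treatment/therapy (incl. investigatory)"),
    ("C", "Dr-Dz", "inhibits cell growth (esp. cancers)"),
    ("Sa", "Dr-Dz", "side effect/adverse event"),
    ("Pr", "Dr-Dz", "prevents, suppresses"),
    ("Pa", "Dr-Dz", "alleviates, reduces"),
    ("J", "Dr-Dz", "role in disease pathogenesis"),
    ("Mp", "Dr-Dz", "biomarkers (of disease progression)"),
    # disease - gene
    ("U", "Dz-G", "causal mutations"),
    ("Ud", "Dz-G", "mutations affecting disease course"),
    ("D", "Dz-G", "drug targets"),
    ("J", "Dz-G", "role in pathogenesis"),
    ("Te", "Dz-G", "possible therapeutic effect"),
    ("Y", "Dz-G", "polymorphisms alter risk"),
    ("G", "Dz-G", "promotes progression"),
    ("Md", "Dz-G", "biomarkers (diagnostic)"),
    ("X", "Dz-G", "overexpression in disease"),
    ("L", "Dz-G", "improper regulation linked to disease"),
    # gene - gene
    ("B", "G-G", "binding, ligand (esp. receptors)"),
    ("W", "G-G", "enhances response"),
    ("V+", "G-G", "activates, stimulates"),
    ("E+", "G-G", "increases expression/production"),
    ("E", "G-G", "affects expression/production"),
    ("I", "G-G", "signaling pathway"),
    ("H", "G-G", "same protein or complex"),
    ("Rg", "G-G", "regulation"),
    ("Q", "G-G", "production by cell population"),
]


def default_vocabulary() -> list[Theme]:
    """The 32-code, four-category default theme vocabulary."""
    return [Theme(code=c, category=cat, description=d) for c, cat, d in _DEFAULT_ROWS]


def read_vocabulary(path: str | Path) -> list[Theme]:
    """Read a theme vocabulary from a TSV with columns code, category, description."""
    themes: list[Theme] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        for row in reader:
            themes.append(
                Theme(
                    code=row["code"],
                    category=row["category"],
                    description=row.get("description", "") or "",
                )
            )
    return themes


def write_vocabulary(themes: list[Theme], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["code", "category", "description"])
        for t in themes:
            writer.writerow([t.code, t.category, t.description])
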