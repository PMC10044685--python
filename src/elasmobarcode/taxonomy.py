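"""Taxonomic data model: rank chains (lineages) and name handling.

A :class:`Lineage` records the chain species -> genus -> subfamily -> family
-> order -> infraclass -> class for one cartilaginous-fish species.  Sharks
carry infraclass Selachii and batoids (rays, skates, guitarfishes) Batoidea;
chimaeras belong to class Holocephali and have no infraclass.  A missing
subfamily is treated as equal to the family, so that subfamily-level
comparisons degrade gracefully where no subfamilial classification exists.

Provisional names as used in barcoding reports are supported: ``cf.``
qualifiers ("Hemitrygon cf. parvonigra") and numbered candidate species
("Narcine cf. maculata sp. 1").  By default these are distinct working
hypotheses; :func:`normalize_name` can collapse them onto the nominal
binomial when a nominal-species count is wanted.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path


class LookupError_(KeyError):
    """Species name absent from the taxonomy table."""


SELACHII = "Selachii"
BATOIDEA = "Batoidea"
ELASMOBRANCHII = "Elasmobranchii"
HOLOCEPHALI = "Holocephali"


@dataclass(frozen=True)
class Lineage:
    """Rank chain for one species.

    ``subfamily`` defaults to the family; ``infraclass`` is empty exactly
    when ``class_`` is Holocephali.
    """

    species: str
    genus: str
    family: str
    order: str
    class_: str
    subfamily: str = ""
    infraclass: str = ""

    def __post_init__(self):
        if not self.subfamily:
            object.__setattr__(self, "subfamily", self.family)
        if self.class_ == ELASMOBRANCHII and not self.infraclass:
            raise ValueError(
                f"{self.species}: elasmobranchs require an infraclass")
        if self.class_ == HOLOCEPHALI and self.infraclass:
            raise ValueError(
                f"{self.species}: Holocephali carry no infraclass")

    @property
    def is_shark(self) -> bool:
        return self.infraclass == SELACHII

    @property
    def is_batoid(self) -> bool:
        return self.infraclass == BATOIDEA


_CF_RE = re.compile(r"\bcf\.?\s+")
_SP_N_RE = re.compile(r"\s+sp\.?\s*\d+\s*$")


def normalize_name(name: str, collapse: bool = False) -> str:
    """Canonicalize a species name.

    Always collapses whitespace and writes ``cf`` as ``cf.``.  With
    ``collapse=True`` the provisional markers are stripped, mapping e.g.
    "Narcine cf. maculata sp. 1" onto "Narcine maculata".
    """
    name = re.sub(r"\s+", " ", name.strip())
    name = re.sub(r"\bcf\b(?!\.)", "cf.", name)
    if collapse:
        name = _SP_N_RE.sub("", name)
        name = _CF_RE.sub("", name)
    return name


def is_provisional(name: str) -> bool:
    """True for indeterminate labels: 'cf.' qualifiers or 'sp.' epithets."""
    name = normalize_name(name)
    return bool(_CF_RE.search(name)) or bool(re.search(r"\bsp\.?(\s|$)", name))


class Taxonomy:
    """Species-name -> :class:`Lineage` table."""

    def __init__(self, lineages: dict[str, Lineage]):
        self._lineages = dict(lineages)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Taxonomy":
        lineages = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                lin = Lineage(
                    species=row["species"],
                    genus=row["genus"],
                    subfamily=row.get("subfamily", "") or "",
                    family=row["family"],
                    order=row["order"],
                    infraclass=row.get("infraclass", "") or "",
                    class_=row["class"],
                )
                lineages[lin.species] = lin
        return cls(lineages)

    @classmethod
    def packaged(cls) -> "Taxonomy":
        """The taxonomy shipped with the package (all report species)."""
        ref = resources.files("elasmobarcode.data") / "taxonomy.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)

    def __contains__(self, name: str) -> bool:
        try:
            self.lookup(name)
            return True
        except LookupError_:
            return False

    def __len__(self) -> int:
        return len(self._lineages)

    def species(self) -> list[str]:
        return sorted(self._lineages)

    def lookup(self, name: str, collapse: bool = True) -> Lineage:
        """Resolve ``name`` to its lineage.

        Provisional forms resolve to the nominal species' lineage when
        ``collapse`` is on (the default for lookup: a provisional form has
        no catalogue entry of its own).
        """
        key = normalize_name(name)
        if key in self._lineages:
            return self._lineages[key]
        if collapse:
            key = normalize_name(name, collapse=True)
            if key in self._lineages:
                return self._lineages[key]
        raise LookupError_(f"species not in taxonomy: {name!r}")
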