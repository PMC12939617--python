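"""Cataract case definition and drug-name standardisation.

Cases are defined at the MedDRA Preferred Term (PT) level.  The broad query
set is the six cataract PTs used for the primary analysis; the narrow set
(the single PT "Cataract", 10007739) drives the sensitivity analysis, so
every narrow case is by construction also a broad case.

Verbatim drug strings in spontaneous reports are noisy (brands, salts,
spelling variants).  :class:`DrugNameMap` performs a normalised lookup
against an editable TSV shipped with the package; salts/esters consolidate
to the base ingredient except where an explicit entry keeps an ester
distinct (e.g. prednisolone acetate, an ophthalmic product reported as its
own entity), and combination products are entities of their own, never
folded into their components.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

#: The six cataract Preferred Terms (MedDRA code -> PT name), broad query.
CATARACT_PTS_BROAD: dict[str, str] = {
    "10069649": "Atopic cataract",
    "10007739": "Cataract",
    "10007748": "Cataract cortical",
    "10007759": "Cataract nuclear",
    "10044135": "Toxic cataract",
    "10024214": "Lenticular opacities",
}

#: Narrow query: the single PT "Cataract".
CATARACT_PTS_NARROW: dict[str, str] = {"10007739": "Cataract"}


@dataclass(frozen=True)
class PtQuerySet:
    """A named set of MedDRA PT codes defining the event of interest."""

    name: str
    pt_codes: frozenset[str]
    pt_names: Mapping[str, str]

    @classmethod
    def broad(cls) -> "PtQuerySet":
        return cls("broad", frozenset(CATARACT_PTS_BROAD), dict(CATARACT_PTS_BROAD))

    @classmethod
    def narrow(cls) -> "PtQuerySet":
        return cls("narrow", frozenset(CATARACT_PTS_NARROW), dict(CATARACT_PTS_NARROW))

    @classmethod
    def from_mode(cls, mode: str) -> "PtQuerySet":
        if mode == "broad":
            return cls.broad()
        if mode == "narrow":
            return cls.narrow()
        raise ValueError(f"unknown PT query mode {mode!r} (expected broad|narrow)")

    @classmethod
    def from_json(cls, path: str | Path) -> "PtQuerySet":
        """Load a custom query set: {"name": ..., "pts": {code: name, ...}}."""
        data = json.loads(Path(path).read_text())
        pts = {str(k): str(v) for k, v in data["pts"].items()}
        return cls(str(data.get("name", "custom")), frozenset(pts), pts)


def is_cataract_case(report_pts: Iterable[str | int], query: PtQuerySet) -> bool:
    """True iff any of the report's PT codes is in the query set."""
    return any(str(pt).strip() in query.pt_codes for pt in report_pts)


_PUNCT = re.compile(r"[.,;:!?'\"()\[\]{}*#]+")
_WS = re.compile(r"\s+")
_SLASH_WS = re.compile(r"\s*/\s*")


def normalize_name(verbatim: str) -> str:
    """Canonical form for drug-name lookup.

    Lower-case, punctuation stripped (slashes kept — they delimit the
    components of combination products), backslashes folded to slashes,
    whitespace collapsed.
    """
    s = str(verbatim).strip().lower().replace("\\", "/")
    s = _PUNCT.sub(" ", s)
    s = _SLASH_WS.sub("/", s)
    s = _WS.sub(" ", s).strip()
    return s


@dataclass(frozen=True)
class StandardizedDrug:
    """Result of a drug-name lookup."""

    entity: str
    is_combination: bool = False
    drug_class: str = "other"
    mapped: bool = True


class DrugNameMap:
    """Verbatim drug string -> unique generic entity.

    Backed by a plain TSV (columns: verbatim, generic, is_combination,
    drug_class) so the harmonisation is data-driven and auditable.  Lookups
    are case-, whitespace- and punctuation-insensitive.  Unmapped names come
    back as their normalised verbatim flagged ``mapped=False`` (and are
    counted), so downstream screening still treats them as entities.
    Lookup is idempotent: every generic maps to itself.
    """

    def __init__(self, entries: Mapping[str, StandardizedDrug]):
        self._entries: dict[str, StandardizedDrug] = dict(entries)
        # every generic output must resolve to itself
        for sd in list(self._entries.values()):
            key = normalize_name(sd.entity)
            self._entries.setdefault(key, sd)
        self.unmapped_seen: dict[str, int] = {}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DrugNameMap":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        entries: dict[str, StandardizedDrug] = {}
        for row in df.itertuples(index=False):
            entries[normalize_name(row.verbatim)] = StandardizedDrug(
                entity=normalize_name(row.generic),
                is_combination=str(row.is_combination).strip().lower()
                in ("1", "true", "yes"),
                drug_class=str(row.drug_class).strip() or "other",
            )
        return cls(entries)

    @classmethod
    def packaged(cls) -> "DrugNameMap":
        """The map shipped with the package (24 signal drugs + variants)."""
        with resources.as_file(
            resources.files("faersig.data") / "drug_map.tsv"
        ) as p:
            return cls.from_tsv(p)

    def lookup(self, verbatim: str) -> StandardizedDrug:
        key = normalize_name(verbatim)
        if key in self._entries:
            return self._entries[key]
        self.unmapped_seen[key] = self.unmapped_seen.get(key, 0) + 1
        return StandardizedDrug(entity=key, mapped=False)

    def entity_class(self, entity: str) -> str:
        sd = self._entries.get(normalize_name(entity))
        return sd.drug_class if sd is not None else "other"

    def __len__(self) -> int:
        return len(self._entries)


def standardize_drug_name(verbatim: str, name_map: DrugNameMap) -> StandardizedDrug:
    """Functional wrapper around :meth:`DrugNameMap.lookup`."""
    return name_map.lookup(verbatim)
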