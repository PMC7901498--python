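"""Code vocabularies that define the opioid-use phenotype.

UK primary-care records carry two kinds of machine-readable codes: *clinical*
codes (Read in older extracts, SNOMED CT in newer ones) recording diagnoses
and observations, and *product* codes recording prescriptions.  A phenotype
codelist classifies each code as a definite indicator of illicit opioid use
(e.g. "heroin dependence"), a probable indicator (e.g. injecting-drug-use
codes that do not name opioids), an opioid-agonist-therapy (OAT) product, or
an excluded code retained only for audit.

This module represents such codelists, persists them as CSV, supports the
keyword search used to assemble candidate codes from a terminology
dictionary, and matches a patient's dated events against a codelist.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Keyword patterns used to search terminology dictionaries for candidate
#: opioid-use codes.  A trailing ``*`` is a prefix wildcard on a word stem.
DEFAULT_SEARCH_PATTERNS: tuple[str, ...] = (
    "methadone",
    "buprenorphine",
    "abus*",
    "addict",
    "dependen*",
    "drug user",
    "heroin",
    "inject",
    "misus*",
    "opiate",
    "opioid",
    "overdose",
)


class Terminology(str, Enum):
    READ = "READ"
    SNOMED = "SNOMED"
    PRODUCT = "PRODUCT"


class Category(str, Enum):
    CLINICAL_DEFINITE = "CLINICAL_DEFINITE"
    CLINICAL_PROBABLE = "CLINICAL_PROBABLE"
    OAT_PRODUCT = "OAT_PRODUCT"
    EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class CodeEntry:
    """One terminology code with its phenotype classification.

    ``category`` is ``None`` for freshly searched candidates that have not
    been curated yet.
    """

    code_id: str
    terminology: Terminology
    description: str = ""
    category: Category | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if not self.code_id:
            raise ValueError("code_id must be non-empty")


@dataclass
class Codelist:
    """A named, versioned collection of :class:`CodeEntry`.

    Lookup by ``(terminology, code_id)`` resolves to at most one entry;
    duplicates are rejected on construction.
    """

    entries: list[CodeEntry] = field(default_factory=list)
    name: str = "codelist"
    version: str = "0"

    def __post_init__(self) -> None:
        self._index: dict[tuple[Terminology, str], CodeEntry] = {}
        for e in self.entries:
            key = (e.terminology, e.code_id)
            if key in self._index:
                raise ValueError(
                    f"duplicate code ({e.terminology.value}, {e.code_id}) in codelist {self.name!r}"
                )
            self._index[key] = e

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def lookup(self, terminology: Terminology | str, code_id: str) -> CodeEntry | None:
        return self._index.get((Terminology(terminology), code_id))

    def matching_categories(self, include_probable: bool = False) -> set[Category]:
        cats = {Category.CLINICAL_DEFINITE, Category.OAT_PRODUCT}
        if include_probable:
            cats.add(Category.CLINICAL_PROBABLE)
        return cats


def _compile_pattern(pattern: str) -> re.Pattern[str]:
    """Compile one keyword pattern to a case-insensitive regex.

    A single ``*`` is allowed, only at the end, and means "stem followed by
    any word characters" (``misus*`` matches "misuse", "misused",
    "Misusing").  Multi-word patterns match as contiguous substrings.
    """
    if not pattern or not pattern.strip("*"):
        raise ValueError(f"malformed pattern: {pattern!r}")
    stem = pattern
    wildcard = False
    if pattern.endswith("*"):
        stem, wildcard = pattern[:-1], True
    if "*" in stem:
        raise ValueError(
            f"malformed pattern: {pattern!r} (wildcard '*' only allowed at the end)"
        )
    body = re.escape(stem)
    if wildcard:
        body += r"\w*"
    return re.compile(body, re.IGNORECASE)


def keyword_search(
    dictionary: pd.DataFrame | Iterable[tuple[str, str, str]],
    patterns: Sequence[str] = DEFAULT_SEARCH_PATTERNS,
) -> list[CodeEntry]:
    """Search a terminology dictionary for candidate phenotype codes.

    Parameters
    ----------
    dictionary
        Rows of ``(code_id, terminology, description)``, or a DataFrame with
        those columns.
    patterns
        Keyword patterns; a trailing ``*`` is a prefix wildcard on the stem.

    Returns
    -------
    list of CodeEntry
        Every dictionary row whose description matches at least one pattern,
        case-insensitively, with ``category=None`` (curation assigns it).
        Duplicate ``(terminology, code_id)`` rows are returned once.
    """
    if not patterns:
        raise ValueError("patterns must be non-empty")
    compiled = [_compile_pattern(p) for p in patterns]

    if isinstance(dictionary, pd.DataFrame):
        rows = dictionary[["code_id", "terminology", "description"]].itertuples(index=False)
    else:
        rows = iter(dictionary)

    out: list[CodeEntry] = []
    seen: set[tuple[str, str]] = set()
    for code_id, terminology, description in rows:
        desc = str(description)
        if any(rx.search(desc) for rx in compiled):
            key = (str(terminology), str(code_id))
            if key in seen:
                continue
            seen.add(key)
            out.append(
                CodeEntry(
                    code_id=str(code_id),
                    terminology=Terminology(terminology),
                    description=desc,
                    category=None,
                    source="keyword_search",
                )
            )
    return out


def match_patient_codes(
    events: pd.DataFrame,
    codelist: Codelist,
    include_probable: bool = False,
) -> list[tuple[pd.Timestamp, CodeEntry]]:
    """Match one patient's dated events against a codelist.

    ``events`` needs columns ``date``, ``code_id``, ``terminology``
    (clinical events and prescriptions can be concatenated; prescriptions use
    terminology ``PRODUCT``).  Matches definite clinical codes and OAT
    products; probable clinical codes only when ``include_probable`` is set;
    excluded codes never match.  Events with an unknown terminology are
    skipped with a logged warning count.

    Returns matches sorted ascending by date.
    """
    cats = codelist.matching_categories(include_probable)
    matches: list[tuple[pd.Timestamp, CodeEntry]] = []
    n_unknown_term = 0
    for row in events.itertuples(index=False):
        try:
            term = Terminology(row.terminology)
        except ValueError:
            n_unknown_term += 1
            continue
        entry = codelist.lookup(term, str(row.code_id))
        if entry is not None and entry.category in cats:
            matches.append((pd.Timestamp(row.date), entry))
    if n_unknown_term:
        logger.warning("skipped %d events with unknown terminology", n_unknown_term)
    matches.sort(key=lambda m: m[0])
    return matches


CODELIST_COLUMNS = ["code_id", "terminology", "description", "category", "source"]


def load_codelist(path: str | Path, name: str | None = None, version: str = "0") -> Codelist:
    """Load a codelist from a CSV with header
    ``code_id,terminology,description,category,source``.

    Unknown category or terminology tokens, and duplicate
    ``(terminology, code_id)`` pairs, are hard errors naming the row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CODELIST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    entries: list[CodeEntry] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            term = Terminology(row.terminology)
        except ValueError:
            raise ValueError(
                f"{path} row {i}: unknown terminology {row.terminology!r}"
            ) from None
        cat_token = row.category
        if cat_token == "":
            cat = None
        else:
            try:
                cat = Category(cat_token)
            except ValueError:
                raise ValueError(
                    f"{path} row {i}: unknown category {cat_token!r}"
                ) from None
        entries.append(
            CodeEntry(
                code_id=row.code_id,
                terminology=term,
                description=row.description,
                category=cat,
                source=row.source,
            )
        )
    return Codelist(entries=entries, name=name or path.stem, version=version)


def save_codelist(codelist: Codelist, path: str | Path) -> None:
    """Persist a codelist as CSV; ``load_codelist`` round-trips it exactly."""
    df = pd.DataFrame(
        [
            {
                "code_id": e.code_id,
                "terminology": e.terminology.value,
                "description": e.description,
                "category": e.category.value if e.category is not None else "",
                "source": e.source,
            }
            for e in codelist
        ],
        columns=CODELIST_COLUMNS,
    )
    df.to_csv(path, index=False)


def example_codelist() -> Codelist:
    """The small illustrative codelist bundled with the package.

    It demonstrates the format and feeds the synthetic-data generator; it is
    not the licence-held published codelist.
    """
    return load_codelist(
        Path(__file__).parent / "data" / "example_codelist.csv",
        name="example",
        version="1",
    )
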