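"""UMLS-style concept vocabulary store.

Parses MRCONSO/MRSTY-dialect release files (pipe-delimited RRF with fixed
column positions) into an in-memory :class:`ConceptStore` that supports
normalized exact-term lookup, source-code lookup and token-subset scans.
Column positions are configurable but default to the public RRF layout
(CUI first; source vocabulary, source code and term string at their
standard indices), so format-faithful fixtures parse without options.

Matching is case-insensitive throughout: headings in source vocabularies
vary in capitalization, and exact string matching would otherwise miss
them.  The normalization rule is fixed (case-fold, punctuation to spaces,
whitespace collapsed) and deliberately excludes stemming, which would
merge terms that the source vocabularies keep distinct.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

_PUNCT_RE = re.compile(r"[^\w\s]|_")
_WS_RE = re.compile(r"\s+")

#: Semantic types in the default resolution-priority order (highest first).
PRIORITY_SEMANTIC_TYPES: tuple[str, ...] = (
    "Disease or Syndrome",
    "Neoplastic Process",
    "Mental or Behavioral Dysfunction",
    "Congenital Abnormality",
    "Sign or Symptom",
    "Finding",
    "Laboratory Procedure",
    "Injury or Poisoning",
    "Individual Behavior",
    "Diagnostic Procedure",
)

#: Additional types accepted at load time but outside the priority list.
OTHER_SEMANTIC_TYPES: tuple[str, ...] = (
    "Pathologic Function",
    "Anatomical Abnormality",
    "Cell or Molecular Dysfunction",
    "Organism Function",
    "Pharmacologic Substance",
)

CONTROLLED_SEMANTIC_TYPES: tuple[str, ...] = (
    PRIORITY_SEMANTIC_TYPES + OTHER_SEMANTIC_TYPES
)

_CANONICAL_TYPE = {t.casefold(): t for t in CONTROLLED_SEMANTIC_TYPES}


class MalformedRowError(ValueError):
    """An RRF row with the wrong number of fields."""


def normalize_term(term: str) -> str:
    """Normalize free text for exact matching.

    Case-folds, replaces punctuation (and underscores) with spaces,
    collapses runs of whitespace and strips the ends.  Idempotent.
    """
    return _WS_RE.sub(" ", _PUNCT_RE.sub(" ", term.casefold())).strip()


def canonical_semantic_type(name: str) -> str:
    """Return the controlled spelling of a semantic-type name.

    Matching is case-insensitive; an unknown name raises ``ValueError``
    naming the offending string.
    """
    try:
        return _CANONICAL_TYPE[name.strip().casefold()]
    except KeyError:
        raise ValueError(f"unknown semantic type: {name!r}") from None


@dataclass(frozen=True)
class Synonym:
    """One term string for a concept, tagged with its source vocabulary."""

    term: str
    sab: str  # source vocabulary code, e.g. MSH, ICD10, SNOMEDCT_US
    code: str  # identifier of the term inside its source vocabulary


@dataclass
class Concept:
    cui: str
    preferred_name: str
    synonyms: set[Synonym] = field(default_factory=set)
    semantic_types: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class MrconsoLayout:
    """Column positions of an MRCONSO-dialect file (defaults: public RRF)."""

    cui: int = 0
    sab: int = 11
    code: int = 13
    term: int = 14
    n_fields: int = 18


@dataclass(frozen=True)
class MrstyLayout:
    cui: int = 0
    sty: int = 3
    n_fields: int = 6


@dataclass
class LoadReport:
    path: str
    rows_read: int = 0
    rows_kept: int = 0
    rows_skipped: int = 0
    case_insensitive: bool = True
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "path": self.path,
                "rows_read": self.rows_read,
                "rows_kept": self.rows_kept,
                "rows_skipped": self.rows_skipped,
                "case_insensitive": self.case_insensitive,
                "warnings": self.warnings,
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class SemanticTypeTable:
    """cui -> set of controlled semantic-type names."""

    rows: dict[str, set[str]] = field(default_factory=dict)

    def types_for(self, cui: str) -> set[str]:
        return self.rows.get(cui, set())


class ConceptStore:
    """Concepts indexed for normalized exact lookup.

    The term index is total over every loaded synonym: looking up the raw
    text of any loaded synonym returns at least the concept that owns it.
    """

    def __init__(self) -> None:
        self.concepts: dict[str, Concept] = {}
        self.load_report: LoadReport | None = None
        # normalized term -> {(cui, sab)}
        self._term_index: dict[str, set[tuple[str, str]]] = {}
        # (sab, code) -> {cui}
        self._code_index: dict[tuple[str, str], set[str]] = {}
        # lazily built: [(frozenset of tokens, cui)] for synonyms >= 2 tokens
        self._subset_entries: list[tuple[frozenset[str], str]] | None = None

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, cui: str) -> bool:
        return cui in self.concepts

    def __iter__(self) -> Iterator[Concept]:
        return iter(self.concepts.values())

    def add_synonym(self, cui: str, term: str, sab: str, code: str) -> None:
        if not cui:
            raise ValueError("empty CUI")
        if not term:
            raise ValueError(f"empty term text for CUI {cui}")
        concept = self.concepts.get(cui)
        if concept is None:
            concept = Concept(cui=cui, preferred_name=term)
            self.concepts[cui] = concept
        concept.synonyms.add(Synonym(term=term, sab=sab, code=code))
        norm = normalize_term(term)
        if norm:
            self._term_index.setdefault(norm, set()).add((cui, sab))
        if code:
            self._code_index.setdefault((sab, code), set()).add(cui)
        self._subset_entries = None

    def attach_semantic_types(self, table: SemanticTypeTable) -> None:
        for cui, types in table.rows.items():
            if cui in self.concepts:
                self.concepts[cui].semantic_types.update(types)

    def lookup(
        self, term: str, source_filter: Iterable[str] | None = None
    ) -> set[str]:
        """CUIs whose synonyms normalize to ``normalize_term(term)``."""
        hits = self._term_index.get(normalize_term(term), set())
        if source_filter is None:
            return {cui for cui, _sab in hits}
        allowed = set(source_filter)
        return {cui for cui, sab in hits if sab in allowed}

    def lookup_code(self, sab: str, code: str) -> set[str]:
        """CUIs attached to an exact source-vocabulary code."""
        return set(self._code_index.get((sab, code), set()))

    def token_subset_matches(self, tokens: set[str]) -> set[str]:
        """CUIs owning a >=2-token synonym whose tokens all occur in ``tokens``."""
        if self._subset_entries is None:
            entries = []
            for concept in self.concepts.values():
                for syn in concept.synonyms:
                    toks = frozenset(normalize_term(syn.term).split())
                    if len(toks) >= 2:
                        entries.append((toks, concept.cui))
            self._subset_entries = entries
        return {cui for toks, cui in self._subset_entries if toks <= tokens}


def lookup_exact(
    store: ConceptStore, term: str, source_filter: Iterable[str] | None = None
) -> set[str]:
    """Module-level alias for :meth:`ConceptStore.lookup`."""
    return store.lookup(term, source_filter)


def _split_rrf_line(line: str, n_fields: int, where: str) -> list[str]:
    fields = line.rstrip("\n").split("|")
    if fields and fields[-1] == "":  # trailing pipe tolerated
        fields = fields[:-1]
    if len(fields) != n_fields:
        raise MalformedRowError(
            f"{where}: expected {n_fields} fields, found {len(fields)}"
        )
    return fields


def read_mrconso(
    path: str | Path,
    source_filter: Iterable[str] | None = None,
    layout: MrconsoLayout = MrconsoLayout(),
) -> ConceptStore:
    """Load an MRCONSO-dialect file into a :class:`ConceptStore`.

    Rows whose source vocabulary is outside ``source_filter`` are skipped
    and counted in the load report; lines starting with ``#`` are treated
    as comments.  A malformed row (wrong field count) is a hard error
    carrying the line number.
    """
    path = Path(path)
    allowed = set(source_filter) if source_filter is not None else None
    store = ConceptStore()
    report = LoadReport(path=path.name)
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split_rrf_line(line, layout.n_fields, f"{path.name}:{lineno}")
            report.rows_read += 1
            sab = fields[layout.sab]
            if allowed is not None and sab not in allowed:
                report.rows_skipped += 1
                continue
            store.add_synonym(
                cui=fields[layout.cui],
                term=fields[layout.term],
                sab=sab,
                code=fields[layout.code],
            )
            report.rows_kept += 1
    if report.rows_read == 0:
        report.warnings.append("empty MRCONSO file: store has no concepts")
    store.load_report = report
    return store


def write_mrconso(
    store: ConceptStore,
    path: str | Path,
    layout: MrconsoLayout = MrconsoLayout(),
    header: str | None = None,
) -> None:
    """Write a store back to the MRCONSO dialect (deterministic row order)."""
    path = Path(path)
    rows = []
    for concept in store.concepts.values():
        for syn in concept.synonyms:
            fields = [""] * layout.n_fields
            fields[layout.cui] = concept.cui
            fields[layout.sab] = syn.sab
            fields[layout.code] = syn.code
            fields[layout.term] = syn.term
            rows.append("|".join(fields) + "|")
    rows.sort()
    with path.open("w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("\n".join(rows) + ("\n" if rows else ""))


def read_semantic_types(
    path: str | Path, layout: MrstyLayout = MrstyLayout()
) -> SemanticTypeTable:
    """Load an MRSTY-dialect file; unknown type names are a hard error."""
    path = Path(path)
    table = SemanticTypeTable()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split_rrf_line(line, layout.n_fields, f"{path.name}:{lineno}")
            cui = fields[layout.cui]
            sty = canonical_semantic_type(fields[layout.sty])
            table.rows.setdefault(cui, set()).add(sty)
    return table
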