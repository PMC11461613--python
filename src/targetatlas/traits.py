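"""Mapping of GWAS trait descriptions onto anchored disease concepts.

Reported traits reach a concept identifier through a cascade of routes,
tried in a fixed order; the first productive route wins and is recorded:

1. ``curation_overlay`` — a declarative manual-curation file that
   pre-empts every automatic route (an empty decision forces unmapped);
2. ``direct_string`` — exact normalized match of the trait text against
   the loaded vocabulary;
3. ``candidate_resolved`` — a deterministic candidate generator (exact
   plus token-subset matches) followed by the resolution policy:
   direct matches first, then the candidates carrying the
   highest-priority semantic type present;
4. ``crossmap_disgenet`` / ``crossmap_metathesaurus`` — lookup of the
   trait's mapped ontology terms in external cross-map tables;
5. ``pubmed_mesh_major`` — exact match of the publication's *major*
   MeSH annotations.

ICD-10 phenotype codes are matched by exact source code (stage
``icd10_code``), not by string.  Every attempted route leaves its
candidate set in the result's audit trail, so rejected candidates are
never lost.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .vocab import (
    ConceptStore,
    PRIORITY_SEMANTIC_TYPES,
    SemanticTypeTable,
    normalize_term,
)

CASCADE_STAGES: tuple[str, ...] = (
    "curation_overlay",
    "direct_string",
    "candidate_resolved",
    "crossmap_disgenet",
    "crossmap_metathesaurus",
    "pubmed_mesh_major",
    "icd10_code",
    "unmapped",
)

_ICD10_RE = re.compile(r"^[A-Z]\d{2}(\.\d+)?$")


@dataclass(frozen=True)
class MeshAnnotation:
    term: str
    is_major: bool = False


@dataclass(frozen=True)
class TraitRecord:
    """One study trait: free text plus its ontology and MeSH annotations."""

    reported_trait: str = ""
    mapped_ontology_terms: frozenset[str] = frozenset()
    pubmed_id: str | None = None
    study_mesh_terms: frozenset[MeshAnnotation] = frozenset()
    icd10_code: str | None = None

    def __post_init__(self) -> None:
        if not self.reported_trait and not self.icd10_code:
            raise ValueError("trait needs a reported trait or an ICD-10 code")

    @property
    def key(self) -> str:
        return self.reported_trait or self.icd10_code  # type: ignore[return-value]


@dataclass(frozen=True)
class ResolutionPolicy:
    """Ambiguity resolution: direct matches first, then type priority."""

    priority: tuple[str, ...] = PRIORITY_SEMANTIC_TYPES
    direct_match_first: bool = True

    def __post_init__(self) -> None:
        folded = [p.casefold() for p in self.priority]
        if len(set(folded)) != len(folded):
            raise ValueError("duplicate entries in semantic-type priority")


DEFAULT_POLICY = ResolutionPolicy()


@dataclass
class MappingResult:
    trait: TraitRecord
    cuis: frozenset[str]
    stage: str
    audit: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in CASCADE_STAGES:
            raise ValueError(f"unknown cascade stage: {self.stage!r}")
        if self.stage == "unmapped" and self.cuis:
            raise ValueError("unmapped result must carry no concepts")
        # an empty concept set is legal only when unmapped or forced by curation
        if not self.cuis and self.stage not in ("unmapped", "curation_overlay"):
            raise ValueError(f"stage {self.stage} produced no concepts")

    @property
    def is_unmapped(self) -> bool:
        return not self.cuis


@dataclass
class CrossMapTable:
    """Ontology-term identifier -> concept set, with a provenance label."""

    provenance: str
    rows: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [k for k, v in self.rows.items() if not v]
        if empty:
            raise ValueError(f"cross-map rows with empty target sets: {empty[:3]}")

    @classmethod
    def read_tsv(cls, path: str | Path, provenance: str) -> "CrossMapTable":
        rows: dict[str, set[str]] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            term_id, cui = line.split("\t")[:2]
            rows.setdefault(term_id, set()).add(cui)
        return cls(provenance=provenance,
                   rows={k: frozenset(v) for k, v in rows.items()})

    def lookup_terms(self, terms: Iterable[str]) -> set[str]:
        hits: set[str] = set()
        for term in terms:
            hits.update(self.rows.get(term, frozenset()))
        return hits


@dataclass
class CurationOverlay:
    """Manual decisions keyed by normalized trait text.

    A decision replaces every automatic route; an empty concept list
    forces the trait to count as unmapped.
    """

    decisions: dict[str, frozenset[str]] = field(default_factory=dict)

    @classmethod
    def empty(cls) -> "CurationOverlay":
        return cls()

    @classmethod
    def read(cls, path: str | Path) -> "CurationOverlay":
        text = Path(path).read_text(encoding="utf-8")
        doc = yaml.safe_load(text) or {}
        raw = doc.get("decisions", doc) or {}
        return cls(
            decisions={
                normalize_term(k): frozenset(v or []) for k, v in raw.items()
            }
        )

    def decision_for(self, trait_text: str) -> frozenset[str] | None:
        return self.decisions.get(normalize_term(trait_text))


def candidate_concepts(trait: str, store: ConceptStore) -> set[str]:
    """Deterministic candidate generator for a trait string.

    Returns exact normalized matches plus token-subset matches: concepts
    owning a synonym of at least two tokens, all of which occur among the
    trait's tokens.  The two-token floor keeps single common words from
    flooding the candidate set.
    """
    norm = normalize_term(trait)
    candidates = store.lookup(norm)
    candidates |= store.token_subset_matches(set(norm.split()))
    return candidates


def resolve_candidates(
    trait: str,
    candidates: set[str],
    store: ConceptStore,
    types: SemanticTypeTable,
    policy: ResolutionPolicy = DEFAULT_POLICY,
) -> set[str]:
    """Resolve an ambiguous candidate set.

    Direct (exact normalized) matches win outright.  Otherwise the
    priority list is scanned in order and all candidates carrying the
    first semantic type present are kept — ties inside a tier are
    preserved, not broken arbitrarily.  Candidates typed entirely outside
    the list are returned unchanged.
    """
    if not candidates:
        raise ValueError("resolve_candidates requires a nonempty candidate set")
    if policy.direct_match_first:
        direct = store.lookup(trait) & candidates
        if direct:
            return direct
    for sty in policy.priority:
        key = sty.casefold()
        tier = {
            cui
            for cui in candidates
            if key in {t.casefold() for t in types.types_for(cui)}
        }
        if tier:
            return tier
    return set(candidates)


def map_trait_cascade(
    trait: TraitRecord,
    store: ConceptStore,
    types: SemanticTypeTable,
    crossmaps: Sequence[CrossMapTable] = (),
    overlay: CurationOverlay | None = None,
    policy: ResolutionPolicy = DEFAULT_POLICY,
) -> MappingResult:
    """Run the full cascade for one trait; first productive stage wins."""
    audit: dict[str, object] = {}

    if overlay is not None and trait.reported_trait:
        decision = overlay.decision_for(trait.reported_trait)
        if decision is not None:
            audit["curation_overlay"] = sorted(decision)
            return MappingResult(trait, frozenset(decision), "curation_overlay", audit)

    if trait.reported_trait:
        direct = store.lookup(trait.reported_trait)
        audit["direct_string"] = sorted(direct)
        if direct:
            return MappingResult(trait, frozenset(direct), "direct_string", audit)

        raw = candidate_concepts(trait.reported_trait, store)
        audit["candidate_raw"] = sorted(raw)
        if raw:
            resolved = resolve_candidates(
                trait.reported_trait, raw, store, types, policy
            )
            audit["candidate_resolved"] = sorted(resolved)
            return MappingResult(
                trait, frozenset(resolved), "candidate_resolved", audit
            )

    for table in crossmaps:
        stage = f"crossmap_{table.provenance}"
        hits = table.lookup_terms(trait.mapped_ontology_terms)
        audit[stage] = sorted(hits)
        if hits:
            return MappingResult(trait, frozenset(hits), stage, audit)

    major = [m.term for m in trait.study_mesh_terms if m.is_major]
    hits: set[str] = set()
    for term in major:
        hits |= store.lookup(term, source_filter={"MSH"})
    audit["pubmed_mesh_major"] = sorted(hits)
    if hits:
        return MappingResult(trait, frozenset(hits), "pubmed_mesh_major", audit)

    return MappingResult(trait, frozenset(), "unmapped", audit)


def map_icd10_traits(
    codes: Sequence[str],
    store: ConceptStore,
    source_vocab: str = "ICD10",
) -> list[MappingResult]:
    """Map ICD-10 phenotype codes by exact source code (not by string).

    A malformed code yields a record-level unmapped result with the error
    in its audit; processing continues.  Duplicate codes each get their
    own (identical) result.
    """
    results = []
    for code in codes:
        trait = TraitRecord(icd10_code=code)
        if not _ICD10_RE.match(code):
            results.append(
                MappingResult(
                    trait, frozenset(), "unmapped",
                    {"error": f"malformed ICD-10 code: {code!r}"},
                )
            )
            continue
        cuis = store.lookup_code(source_vocab, code)
        if cuis:
            results.append(
                MappingResult(trait, frozenset(cuis), "icd10_code",
                              {"icd10_code": sorted(cuis)})
            )
        else:
            results.append(
                MappingResult(trait, frozenset(), "unmapped",
                              {"icd10_code": []})
            )
    return results


def collapse_to_disease_set(
    results: Sequence[MappingResult],
    chapters: Mapping[str, set[str]],
    excluded: set[str],
) -> tuple[set[str], dict[str, object]]:
    """Union all mapped concepts and drop chapter-excluded diseases.

    A disease is dropped only when its chapter set lies entirely inside
    the excluded chapters; a disease classified in both an excluded and a
    kept chapter is retained.  Concepts absent from the chapter map fall
    into an ``Unclassified`` chapter.  The rollup counts each disease
    once per chapter plus a separate unique count.
    """
    mapped: set[str] = set()
    for result in results:
        mapped |= result.cuis
    kept = {
        cui
        for cui in mapped
        if not set(chapters.get(cui, {"Unclassified"})) <= excluded
    }
    per_chapter: dict[str, int] = {}
    for cui in kept:
        for chapter in sorted(chapters.get(cui, {"Unclassified"})):
            per_chapter[chapter] = per_chapter.get(chapter, 0) + 1
    rollup = {
        "unique": len(kept),
        "excluded": len(mapped) - len(kept),
        "per_chapter": dict(sorted(per_chapter.items())),
    }
    return kept, rollup


@dataclass(frozen=True)
class GwasColumns:
    """Column names of a GWAS-catalog-style trait file."""

    reported_trait: str = "reported_trait"
    mapped_terms: str = "mapped_ontology_terms"
    pubmed_id: str = "pubmed_id"
    mesh_terms: str = "study_mesh_terms"


def read_gwas_traits(
    path: str | Path, columns: GwasColumns = GwasColumns()
) -> list[TraitRecord]:
    """Read a trait TSV.

    Mapped ontology terms are ``|``-separated; study MeSH terms are
    ``;``-separated with major terms prefixed by ``*``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        row_d = row._asdict()
        mapped = frozenset(
            t for t in row_d.get(columns.mapped_terms, "").split("|") if t
        )
        mesh = frozenset(
            MeshAnnotation(term=t.lstrip("*"), is_major=t.startswith("*"))
            for t in row_d.get(columns.mesh_terms, "").split(";")
            if t.strip()
        )
        records.append(
            TraitRecord(
                reported_trait=row_d[columns.reported_trait],
                mapped_ontology_terms=mapped,
                pubmed_id=row_d.get(columns.pubmed_id) or None,
                study_mesh_terms=mesh,
            )
        )
    return records


def read_chapter_map(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column TSV of concept -> chapter (repeated rows union)."""
    chapters: dict[str, set[str]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cui, chapter = line.split("\t")[:2]
        chapters.setdefault(cui, set()).add(chapter)
    return chapters


def mapping_results_to_frame(results: Sequence[MappingResult]) -> pd.DataFrame:
    rows = [
        {
            "trait": r.trait.key,
            "stage": r.stage,
            "cuis": "|".join(sorted(r.cuis)),
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=["trait", "stage", "cuis"])


def audit_to_json(results: Sequence[MappingResult]) -> str:
    return json.dumps(
        {r.trait.key: r.audit for r in results}, indent=2, sort_keys=True
    )
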