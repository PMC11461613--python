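"""Sample-space, intersection and opportunity arithmetic.

The coverage picture is built from nested target x disease grids:

* **A** — all protein-coding genes x all diseases in the reference
  disease ontology (the full denominator);
* **B** — druggable genes x all diseases;
* **C** — clinically investigated targets x clinically investigated
  indications;
* **D** — approved-drug targets x approved indications.

Each grid's size is the exact integer product of its bounds, and the
explored fraction is the share of unique (gene, concept) pairs actually
touched by drug development.  Percentages are rounded half-up at the
number of decimals each report uses, which reproduces printed
percentages exactly from integer numerators and denominators.
"""

from __future__ import annotations

import statistics
from collections import namedtuple
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

from .drugs import StagePartition, TargetIndicationPair


def sample_space(n_targets: int, n_diseases: int) -> int:
    """Exact integer size of a target x disease grid."""
    if n_targets < 0 or n_diseases < 0:
        raise ValueError("sample-space bounds must be non-negative")
    return int(n_targets) * int(n_diseases)


def percent_round(numerator: int, denominator: int, decimals: int = 1):
    """100 * n / d rounded half-up to 0 or 1 decimals.

    Returns an ``int`` for zero decimals and a ``float`` otherwise, so a
    report prints ``16`` rather than ``16.0`` where integers are used.
    """
    if denominator == 0:
        raise ValueError("zero denominator in percentage")
    if decimals not in (0, 1):
        raise ValueError("decimals must be 0 or 1")
    quantum = Decimal(1).scaleb(-decimals)
    value = (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        quantum, rounding=ROUND_HALF_UP
    )
    return int(value) if decimals == 0 else float(value)


@dataclass(frozen=True)
class SampleSpaceReport:
    label: str
    n_targets: int
    n_diseases: int
    size: int
    explored: int
    explored_pct: float

    def __post_init__(self) -> None:
        if self.size != self.n_targets * self.n_diseases:
            raise ValueError("size must be the exact product of the bounds")
        if self.explored > self.size:
            raise ValueError("explored pairs exceed the sample space")

    def to_dict(self) -> dict[str, object]:
        return {
            "label": self.label,
            "n_targets": self.n_targets,
            "n_diseases": self.n_diseases,
            "size": self.size,
            "explored": self.explored,
            "explored_pct": self.explored_pct,
        }


def make_sample_space_report(
    label: str, n_targets: int, n_diseases: int, explored: int, decimals: int = 1
) -> SampleSpaceReport:
    size = sample_space(n_targets, n_diseases)
    pct = percent_round(explored, size, decimals) if size else 0.0
    return SampleSpaceReport(
        label=label,
        n_targets=n_targets,
        n_diseases=n_diseases,
        size=size,
        explored=explored,
        explored_pct=pct,
    )


@dataclass
class MembershipMatrix:
    """Exclusive membership patterns over named sets (UpSet-style).

    ``counts`` maps a bit tuple (one flag per set, in ``set_names``
    order) to the number of elements with exactly that membership
    pattern; every element of the union is counted under exactly one
    pattern, so the counts always sum to the union size.
    """

    set_names: tuple[str, ...]
    counts: dict[tuple[int, ...], int]
    set_totals: dict[str, int] = field(default_factory=dict)
    pairwise: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def union_size(self) -> int:
        return sum(self.counts.values())


def membership_matrix(named_sets: Mapping[str, Iterable]) -> MembershipMatrix:
    """Count exclusive membership patterns over up to 16 named sets."""
    names = tuple(named_sets)
    if len(names) > 16:
        raise ValueError("membership matrix limited to 16 sets")
    sets = {name: set(named_sets[name]) for name in names}
    union: set = set().union(*sets.values()) if sets else set()
    counts: dict[tuple[int, ...], int] = {}
    for element in union:
        pattern = tuple(int(element in sets[name]) for name in names)
        counts[pattern] = counts.get(pattern, 0) + 1
    matrix = MembershipMatrix(
        set_names=names,
        counts=counts,
        set_totals={name: len(sets[name]) for name in names},
        pairwise={
            (a, b): len(sets[a] & sets[b])
            for i, a in enumerate(names)
            for b in names[i + 1:]
        },
    )
    if matrix.union_size != len(union):  # conservation, checked on every call
        raise AssertionError("membership counts do not sum to the union size")
    return matrix


OverlapPartition = namedtuple("OverlapPartition", "overlap gwas_only devel_only")


def gwas_overlap_partition(
    gwas_diseases: Iterable, devel_diseases: Iterable
) -> OverlapPartition:
    """Two-set partition of genetically studied vs developed diseases."""
    gwas, devel = set(gwas_diseases), set(devel_diseases)
    return OverlapPartition(
        overlap=len(gwas & devel),
        gwas_only=len(gwas - devel),
        devel_only=len(devel - gwas),
    )


QuartileStats = namedtuple("QuartileStats", "median q1 q3 n")


def _quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    """Median-of-halves quartiles, halves excluding the median point.

    For [1, 2, 4] this yields Q1=1, median=2, Q3=4 (the convention the
    printed summary statistics follow).  A single value is its own
    median and both quartiles.
    """
    xs = sorted(values)
    n = len(xs)
    if n == 0:
        raise ValueError("quartiles of an empty sequence")
    med = statistics.median(xs)
    if n == 1:
        return med, med, med
    lower = xs[: n // 2]
    upper = xs[n // 2 + (n % 2):]
    return med, statistics.median(lower), statistics.median(upper)


def targets_per_indication_stats(
    pairs: Iterable[TargetIndicationPair],
) -> QuartileStats:
    """Median and quartiles of distinct genes per disease.

    The caller restricts the pair set to the stage of interest (e.g.
    approved pairs only).  An empty pair set is a hard error.
    """
    genes_per_disease: dict[str, set[str]] = {}
    for pair in pairs:
        genes_per_disease.setdefault(pair.cui, set()).add(pair.gene)
    if not genes_per_disease:
        raise ValueError("no pairs to summarize")
    counts = [len(genes) for genes in genes_per_disease.values()]
    med, q1, q3 = _quartiles(counts)
    return QuartileStats(median=med, q1=q1, q3=q3, n=len(counts))


@dataclass(frozen=True)
class TargetIndicationCount:
    gene: str
    unique_diseases: int
    per_chapter: tuple[tuple[str, int], ...]  # disease counted once per chapter

    @property
    def chapter_sum(self) -> int:
        return sum(n for _c, n in self.per_chapter)


def indications_per_target_counts(
    pairs: Iterable[TargetIndicationPair],
    chapters: Mapping[str, set[str]],
    threshold: int = 25,
) -> list[TargetIndicationCount]:
    """Per-gene disease counts, chapter-wise and unique, above a threshold.

    A disease classified in several chapters is counted once per chapter,
    so the chapter-wise sum can exceed the unique-disease count.  Only
    genes with strictly more than ``threshold`` unique diseases are
    reported, sorted by descending unique count.
    """
    diseases_per_gene: dict[str, set[str]] = {}
    for pair in pairs:
        diseases_per_gene.setdefault(pair.gene, set()).add(pair.cui)
    out = []
    for gene, diseases in diseases_per_gene.items():
        if len(diseases) <= threshold:
            continue
        per_chapter: dict[str, int] = {}
        for cui in diseases:
            for chapter in chapters.get(cui, {"Unclassified"}):
                per_chapter[chapter] = per_chapter.get(chapter, 0) + 1
        out.append(
            TargetIndicationCount(
                gene=gene,
                unique_diseases=len(diseases),
                per_chapter=tuple(sorted(per_chapter.items())),
            )
        )
    out.sort(key=lambda t: (-t.unique_diseases, t.gene))
    return out


Opportunity = namedtuple("Opportunity", "gene cui gene_stage")

OPPORTUNITY_KINDS: tuple[str, ...] = (
    "indication_expansion",
    "repurposing",
    "de_novo",
)


@dataclass(frozen=True)
class OpportunityList:
    kind: str
    entries: frozenset[Opportunity]

    def __post_init__(self) -> None:
        if self.kind not in OPPORTUNITY_KINDS:
            raise ValueError(f"unknown opportunity kind: {self.kind!r}")


def opportunity_lists(
    partition: StagePartition,
    pairs: Iterable[TargetIndicationPair],
    gwas_diseases: Iterable[str],
) -> dict[str, OpportunityList]:
    """Three disjoint target-disease opportunity lists, prioritized by GWAS.

    * ``indication_expansion`` — approved-drug targets x genetically
      studied diseases not yet paired with them;
    * ``repurposing`` — targets with clinical or preclinical history but
      no approval, x genetically studied diseases not yet paired;
    * ``de_novo`` — druggable but never-investigated targets x
      genetically studied diseases.

    A gene that is both approved (for something) and in clinical
    development contributes to indication expansion only, keeping the
    gene strata — and hence the lists — pairwise disjoint.  Any existing
    (gene, disease) pairing at any stage excludes that couple from every
    list.
    """
    gwas = set(gwas_diseases)
    existing = {(p.gene, p.cui) for p in pairs}
    strata = {
        "indication_expansion": partition.approved,
        "repurposing": (partition.clinical | partition.preclinical)
        - partition.approved,
        "de_novo": partition.undrugged,
    }
    stage_of = {
        "indication_expansion": "approved",
        "repurposing": "clinical",
        "de_novo": "undrugged",
    }
    lists = {}
    for kind, genes in strata.items():
        entries = frozenset(
            Opportunity(gene=g, cui=d, gene_stage=stage_of[kind])
            for g in genes
            for d in gwas
            if (g, d) not in existing
        )
        lists[kind] = OpportunityList(kind=kind, entries=entries)
    return lists
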