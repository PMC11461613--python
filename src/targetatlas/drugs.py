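"""Drug, target and indication tables -> staged target-indication pairs.

Reads ChEMBL-style exports (compounds with a maximum clinical phase and
withdrawn / non-human-use flags, compound-target links, target-gene
links, MeSH-keyed indications), applies the exclusion rules, maps
indication headings onto anchored disease concepts, and emits the atom
of all downstream coverage counts: the (gene, concept, stage) pair.

Stage coding follows the max-phase convention: phase 4 is approved,
phases 1-3 clinical, phase 0 preclinical.  The convention is a config
table because phase encodings have changed across database releases.
The pair's stage is driven by the per-indication phase, not by the
compound's global maximum, matching the semantics of the drug-indication
table.  Multiple target identifiers per gene collapse to the gene for
counting purposes; both granularities survive in the input tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .vocab import ConceptStore

STAGES: tuple[str, ...] = ("approved", "clinical", "preclinical")

#: Default stage convention: max-phase code -> stage label.
DEFAULT_STAGE_CODES: Mapping[int, str] = {
    0: "preclinical",
    1: "clinical",
    2: "clinical",
    3: "clinical",
    4: "approved",
}


def classify_stage(
    max_phase: int, convention: Mapping[int, str] = DEFAULT_STAGE_CODES
) -> str:
    """Map a max-phase code to a development-stage label.

    Out-of-domain codes are a hard error: silently binning an unexpected
    phase would corrupt every downstream count.
    """
    try:
        return convention[int(max_phase)]
    except (KeyError, ValueError):
        raise ValueError(f"max phase code outside declared domain: {max_phase!r}")


@dataclass(frozen=True)
class TargetIndicationPair:
    """One (gene, disease concept, stage) atom; unique on those three."""

    gene: str
    cui: str
    stage: str
    in_druggable: bool = field(default=True, compare=False)


@dataclass(frozen=True)
class IndicationRecord:
    compound_id: str
    mesh_term: str
    cui: str | None  # None = the MeSH heading failed to resolve
    max_phase_for_indication: int

    @property
    def is_unmapped(self) -> bool:
        return self.cui is None


@dataclass
class ExclusionReport:
    """Which compounds were dropped and why, plus record-level errors."""

    withdrawn: list[str] = field(default_factory=list)
    non_human: list[str] = field(default_factory=list)
    record_errors: list[str] = field(default_factory=list)
    unmapped_mesh: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def excluded_compounds(self) -> set[str]:
        return set(self.withdrawn) | set(self.non_human)


@dataclass
class DrugTables:
    compounds: pd.DataFrame
    compound_targets: pd.DataFrame
    target_genes: pd.DataFrame
    indications: pd.DataFrame


def read_drug_tables(
    compounds: str | Path,
    compound_targets: str | Path,
    target_genes: str | Path,
    indications: str | Path,
) -> DrugTables:
    """Read the four CSV exports (``#`` lines are comments)."""
    read = lambda p, **kw: pd.read_csv(p, comment="#", dtype=str,
                                       keep_default_na=False, **kw)
    comp = read(compounds)
    for col in ("max_phase", "withdrawn", "for_human_use"):
        comp[col] = comp[col].astype(int)
    ind = read(indications)
    ind["max_phase_for_indication"] = ind["max_phase_for_indication"].astype(int)
    return DrugTables(
        compounds=comp,
        compound_targets=read(compound_targets),
        target_genes=read(target_genes),
        indications=ind,
    )


@dataclass
class TargetGeneMap:
    """target id -> {(uniprot, ensembl gene)}, plus the druggable gene set."""

    rows: dict[str, frozenset[tuple[str, str]]]
    druggable: frozenset[str]

    @classmethod
    def from_tables(
        cls, target_genes: pd.DataFrame, druggable: Iterable[str]
    ) -> "TargetGeneMap":
        rows: dict[str, set[tuple[str, str]]] = {}
        for row in target_genes.itertuples(index=False):
            rows.setdefault(row.target_id, set()).add(
                (row.uniprot, row.ensembl_gene_id)
            )
        return cls(
            rows={k: frozenset(v) for k, v in rows.items()},
            druggable=frozenset(druggable),
        )

    def genes_for(self, target_id: str) -> set[str]:
        return {gene for _up, gene in self.rows.get(target_id, frozenset())}


def read_gene_list(path: str | Path) -> frozenset[str]:
    return frozenset(
        line.strip()
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.startswith("#")
    )


def load_compound_indications(
    tables: DrugTables, store: ConceptStore
) -> tuple[list[IndicationRecord], ExclusionReport]:
    """Resolve indication rows to disease concepts after compound exclusion.

    Withdrawn and non-human compounds are dropped before any pairing; the
    report lists the dropped identifiers.  An indication row naming an
    unknown compound is a record-level error, not a hard stop.  MeSH
    headings that fail to resolve are flagged unmapped and excluded from
    coverage counts.
    """
    report = ExclusionReport()
    status: dict[str, str] = {}
    for row in tables.compounds.itertuples(index=False):
        if int(row.withdrawn):
            report.withdrawn.append(row.compound_id)
            status[row.compound_id] = "withdrawn"
        elif not int(row.for_human_use):
            report.non_human.append(row.compound_id)
            status[row.compound_id] = "non_human"
        else:
            status[row.compound_id] = "kept"

    records: list[IndicationRecord] = []
    for row in tables.indications.itertuples(index=False):
        state = status.get(row.compound_id)
        if state is None:
            report.record_errors.append(
                f"indication references unknown compound {row.compound_id!r}"
            )
            continue
        if state != "kept":
            continue
        cuis = store.lookup(row.mesh_term, source_filter={"MSH"})
        if not cuis:
            cui = None
            report.unmapped_mesh.append(row.mesh_term)
        elif len(cuis) == 1:
            cui = next(iter(cuis))
        else:
            cui = min(cuis)
            report.warnings.append(
                f"MeSH term {row.mesh_term!r} maps to {len(cuis)} concepts;"
                f" kept {cui}"
            )
        records.append(
            IndicationRecord(
                compound_id=row.compound_id,
                mesh_term=row.mesh_term,
                cui=cui,
                max_phase_for_indication=int(row.max_phase_for_indication),
            )
        )
    return records, report


def build_pairs(
    indications: Sequence[IndicationRecord],
    tables: DrugTables,
    genemap: TargetGeneMap,
    convention: Mapping[int, str] = DEFAULT_STAGE_CODES,
) -> set[TargetIndicationPair]:
    """Expand compound x targets x indications into de-duplicated pairs.

    Genes outside the druggable set are retained but flagged, so they can
    be excluded from genome-partition counts without losing provenance.
    """
    targets_of: dict[str, list[str]] = {}
    for row in tables.compound_targets.itertuples(index=False):
        targets_of.setdefault(row.compound_id, []).append(row.target_id)

    pairs: set[TargetIndicationPair] = set()
    for ind in indications:
        if ind.cui is None:
            continue
        stage = classify_stage(ind.max_phase_for_indication, convention)
        for target_id in targets_of.get(ind.compound_id, ()):
            for gene in genemap.genes_for(target_id):
                pairs.add(
                    TargetIndicationPair(
                        gene=gene,
                        cui=ind.cui,
                        stage=stage,
                        in_druggable=gene in genemap.druggable,
                    )
                )
    return pairs


@dataclass(frozen=True)
class StagePartition:
    """Druggable-genome partition by furthest development stage reached.

    The approved / clinical / preclinical sets may overlap (a gene can
    carry compounds at several stages); ``undrugged`` is the complement
    of their union within the druggable set.
    """

    approved: frozenset[str]
    clinical: frozenset[str]
    preclinical: frozenset[str]
    undrugged: frozenset[str]
    druggable: frozenset[str]

    @property
    def drugged(self) -> frozenset[str]:
        return self.approved | self.clinical | self.preclinical

    def __post_init__(self) -> None:
        if self.undrugged != self.druggable - self.drugged:
            raise ValueError("undrugged set is not the complement of drugged")

    def counts(self) -> dict[str, int]:
        return {
            "approved": len(self.approved),
            "clinical": len(self.clinical),
            "preclinical": len(self.preclinical),
            "drugged": len(self.drugged),
            "undrugged": len(self.undrugged),
            "druggable": len(self.druggable),
        }


def partition_genome(
    pairs: Iterable[TargetIndicationPair], druggable: Iterable[str]
) -> StagePartition:
    """Per-stage gene sets over the druggable genome, plus the complement."""
    druggable = frozenset(druggable)
    by_stage: dict[str, set[str]] = {stage: set() for stage in STAGES}
    for pair in pairs:
        if pair.gene in druggable:
            by_stage[pair.stage].add(pair.gene)
    drugged = by_stage["approved"] | by_stage["clinical"] | by_stage["preclinical"]
    return StagePartition(
        approved=frozenset(by_stage["approved"]),
        clinical=frozenset(by_stage["clinical"]),
        preclinical=frozenset(by_stage["preclinical"]),
        undrugged=druggable - drugged,
        druggable=druggable,
    )
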