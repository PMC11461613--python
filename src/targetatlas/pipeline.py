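"""End-to-end orchestration and report emission.

``run_pipeline`` executes vocabulary load -> trait mapping -> drug
pairing -> coverage analysis from a single config and writes a
deterministic report bundle: per-trait mapping TSV with cascade stage,
audit JSON, the pair table, the genome stage partition, sample-space and
intersection reports, the three opportunity lists, the printed-constant
arithmetic table and a manifest with input checksums and per-stage row
counts.  Identical config and inputs give byte-identical outputs; all
logging goes to stderr.

``emit_paper_arithmetic`` checks the reference survey's twelve printed
identities — the nested sample-space products, explored fractions,
complement counts and the chapter-exclusion difference — from its
printed constants alone, using the same ``sample_space`` /
``percent_round`` primitives the pipeline uses on live data.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import yaml

from . import __version__
from .coverage import (
    SampleSpaceReport,
    gwas_overlap_partition,
    indications_per_target_counts,
    make_sample_space_report,
    membership_matrix,
    opportunity_lists,
    percent_round,
    sample_space,
    targets_per_indication_stats,
)
from .drugs import (
    TargetGeneMap,
    build_pairs,
    load_compound_indications,
    partition_genome,
    read_drug_tables,
    read_gene_list,
)
from .traits import (
    CASCADE_STAGES,
    CrossMapTable,
    CurationOverlay,
    MappingResult,
    ResolutionPolicy,
    audit_to_json,
    collapse_to_disease_set,
    map_icd10_traits,
    map_trait_cascade,
    mapping_results_to_frame,
    read_chapter_map,
    read_gwas_traits,
)
from .vocab import read_mrconso, read_semantic_types

logger = logging.getLogger("targetatlas")

#: Printed reference constants of the survey this package reimplements.
PAPER_CONSTANTS: dict[str, int] = {
    "protein_coding_genes": 19813,
    "disease_ontology_terms": 11158,
    "druggable_genes": 4729,
    "approved_targets": 755,
    "clinical_targets": 1218,
    "preclinical_targets": 418,
    "drugged_targets": 1234,
    "approved_diseases": 612,
    "clinical_diseases": 1401,
    "preclinical_diseases": 210,
    "developed_diseases": 1549,
    "gwas_diseases": 1914,
    "gwas_devel_overlap": 703,
    "explored_clinical_pairs": 42199,
    "explored_approved_pairs": 5221,
    "curated_gwas_diseases": 983,
    "excluded_chapter_diseases": 30,
}

DEFAULT_EXCLUDED_CHAPTERS: tuple[str, ...] = (
    "Animal diseases",
    "Findings, not elsewhere classified",
    "Pregnancy, childbirth and the puerperium",
)


@dataclass(frozen=True)
class IdentityCheck:
    name: str
    computed: float
    expected: float

    @property
    def passed(self) -> bool:
        return self.computed == self.expected


def _identity_specs() -> Sequence[tuple[str, Callable[[Mapping[str, int]], float], float]]:
    return (
        ("space_A",
         lambda c: sample_space(c["protein_coding_genes"], c["disease_ontology_terms"]),
         221073454),
        ("space_B",
         lambda c: sample_space(c["druggable_genes"], c["disease_ontology_terms"]),
         52766182),
        ("space_C",
         lambda c: sample_space(c["clinical_targets"], c["clinical_diseases"]),
         1706418),
        ("space_D",
         lambda c: sample_space(c["approved_targets"], c["approved_diseases"]),
         462060),
        ("explored_pct_C",
         lambda c: percent_round(
             c["explored_clinical_pairs"],
             sample_space(c["clinical_targets"], c["clinical_diseases"]), 1),
         2.5),
        ("explored_pct_D",
         lambda c: percent_round(
             c["explored_approved_pairs"],
             sample_space(c["approved_targets"], c["approved_diseases"]), 0),
         1),
        ("space_C_pct_of_B",
         lambda c: percent_round(
             sample_space(c["clinical_targets"], c["clinical_diseases"]),
             sample_space(c["druggable_genes"], c["disease_ontology_terms"]), 1),
         3.2),
        ("space_C_pct_of_A",
         lambda c: percent_round(
             sample_space(c["clinical_targets"], c["clinical_diseases"]),
             sample_space(c["protein_coding_genes"], c["disease_ontology_terms"]), 1),
         0.8),
        ("undrugged_targets",
         lambda c: c["druggable_genes"] - c["drugged_targets"],
         3495),
        ("undrugged_pct",
         lambda c: percent_round(
             c["druggable_genes"] - c["drugged_targets"], c["druggable_genes"], 1),
         73.9),
        ("gwas_only_diseases",
         lambda c: c["gwas_diseases"] - c["gwas_devel_overlap"],
         1211),
        ("chapter_exclusion_kept",
         lambda c: c["curated_gwas_diseases"] - c["excluded_chapter_diseases"],
         953),
    )


def emit_paper_arithmetic(
    constants: Mapping[str, int] = PAPER_CONSTANTS,
) -> list[IdentityCheck]:
    """Recompute the twelve printed identities from printed constants."""
    if not constants:
        return []
    return [
        IdentityCheck(name=name, computed=fn(constants), expected=expected)
        for name, fn, expected in _identity_specs()
    ]


@dataclass
class RunConfig:
    """All inputs, constants and policy settings for one pipeline run."""

    mrconso: Path
    mrsty: Path
    compounds: Path
    compound_targets: Path
    target_genes: Path
    indications: Path
    gwas_traits: Path
    icd10_list: Path
    druggable_genes: Path
    chapter_map: Path
    crossmap_disgenet: Path
    crossmap_metathesaurus: Path
    out_dir: Path
    overlay: Path | None = None
    seed: int = 0
    gene_universe: int = 19813
    disease_universe: int = 11158
    excluded_chapters: tuple[str, ...] = DEFAULT_EXCLUDED_CHAPTERS
    indication_threshold: int = 25
    policy: ResolutionPolicy = field(default_factory=ResolutionPolicy)

    _PATH_FIELDS = (
        "mrconso", "mrsty", "compounds", "compound_targets", "target_genes",
        "indications", "gwas_traits", "icd10_list", "druggable_genes",
        "chapter_map", "crossmap_disgenet", "crossmap_metathesaurus",
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
        base = path.parent
        kwargs: dict = {}
        for name in cls._PATH_FIELDS:
            kwargs[name] = base / doc[name]
        if doc.get("overlay"):
            kwargs["overlay"] = base / doc["overlay"]
        kwargs["out_dir"] = base / doc.get("out_dir", "reports")
        for name in ("seed", "gene_universe", "disease_universe",
                     "indication_threshold"):
            if name in doc:
                kwargs[name] = int(doc[name])
        if "excluded_chapters" in doc:
            kwargs["excluded_chapters"] = tuple(doc["excluded_chapters"])
        return cls(**kwargs)

    def validate(self) -> None:
        if self.gene_universe <= 0 or self.disease_universe <= 0:
            raise ValueError("universe constants must be positive")
        missing = [
            str(getattr(self, name))
            for name in self._PATH_FIELDS
            if not Path(getattr(self, name)).exists()
        ]
        if self.overlay is not None and not Path(self.overlay).exists():
            missing.append(str(self.overlay))
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


@dataclass
class PipelineResult:
    """In-memory handle on everything a run computed and wrote."""

    config: RunConfig
    trait_results: list[MappingResult]
    icd10_results: list[MappingResult]
    gwas_diseases: set[str]
    pairs: set
    partition: object
    spaces: dict[str, SampleSpaceReport]
    manifest: dict

    @property
    def out_dir(self) -> Path:
        return Path(self.config.out_dir)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_membership_tsv(path: Path, matrix) -> None:
    lines = ["\t".join(list(matrix.set_names) + ["count"])]
    for pattern in sorted(matrix.counts, reverse=True):
        lines.append(
            "\t".join([str(b) for b in pattern] + [str(matrix.counts[pattern])])
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def run_pipeline(config: RunConfig, stages: str = "all") -> PipelineResult:
    """Execute the pipeline and write the report bundle.

    ``stages`` limits execution: ``"traits"`` stops after trait mapping,
    ``"drugs"`` after pairing, ``"all"`` runs the coverage analysis too.
    A hard module error aborts before any further output; record-level
    errors accumulate in the manifest.
    """
    if stages not in ("traits", "drugs", "all"):
        raise ValueError(f"unknown stage selection: {stages!r}")
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {},
        "counts": {},
        "record_errors": [],
    }
    for name in RunConfig._PATH_FIELDS:
        p = Path(getattr(config, name))
        manifest["inputs"][name] = {"file": p.name, "sha256": _sha256(p)}
    if config.overlay is not None:
        p = Path(config.overlay)
        manifest["inputs"]["overlay"] = {"file": p.name, "sha256": _sha256(p)}

    # --- vocabulary ---------------------------------------------------
    store = read_mrconso(config.mrconso)
    types = read_semantic_types(config.mrsty)
    store.attach_semantic_types(types)
    assert store.load_report is not None
    if (store.load_report.rows_kept + store.load_report.rows_skipped
            != store.load_report.rows_read):
        raise AssertionError("vocabulary load report does not conserve rows")
    manifest["counts"]["vocab"] = {
        "concepts": len(store),
        "rows_read": store.load_report.rows_read,
        "rows_kept": store.load_report.rows_kept,
        "rows_skipped": store.load_report.rows_skipped,
    }
    (out / "vocab_load_report.json").write_text(
        store.load_report.to_json() + "\n", encoding="utf-8"
    )
    logger.info("vocabulary: %d concepts (%.2fs)", len(store),
                time.perf_counter() - t0)

    # --- trait mapping ------------------------------------------------
    crossmaps = [
        CrossMapTable.read_tsv(config.crossmap_disgenet, "disgenet"),
        CrossMapTable.read_tsv(config.crossmap_metathesaurus, "metathesaurus"),
    ]
    overlay = (
        CurationOverlay.read(config.overlay)
        if config.overlay is not None
        else CurationOverlay.empty()
    )
    traits = read_gwas_traits(config.gwas_traits)
    trait_results = [
        map_trait_cascade(t, store, types, crossmaps, overlay, config.policy)
        for t in traits
    ]
    icd_codes = [
        line.strip()
        for line in Path(config.icd10_list).read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.startswith("#")
    ]
    icd_results = map_icd10_traits(icd_codes, store)
    for r in icd_results:
        if "error" in r.audit:
            manifest["record_errors"].append(str(r.audit["error"]))

    stage_buckets = {s: 0 for s in CASCADE_STAGES}
    for r in trait_results:
        stage_buckets[r.stage] += 1
    if sum(stage_buckets.values()) != len(trait_results):
        raise AssertionError("trait stage buckets do not sum to the trait count")
    manifest["counts"]["traits"] = {
        "read": len(traits),
        "mapped": sum(1 for r in trait_results if not r.is_unmapped),
        "unmapped": sum(1 for r in trait_results if r.is_unmapped),
        "by_stage": {k: v for k, v in sorted(stage_buckets.items()) if v},
    }
    manifest["counts"]["icd10"] = {
        "read": len(icd_codes),
        "mapped": sum(1 for r in icd_results if not r.is_unmapped),
        "unmapped": sum(1 for r in icd_results if r.is_unmapped),
    }

    chapters = read_chapter_map(config.chapter_map)
    gwas_diseases, rollup = collapse_to_disease_set(
        list(trait_results) + list(icd_results),
        chapters,
        set(config.excluded_chapters),
    )
    manifest["counts"]["gwas_diseases"] = rollup

    frame = mapping_results_to_frame(trait_results)
    frame.to_csv(out / "trait_mappings.tsv", sep="\t", index=False)
    mapping_results_to_frame(icd_results).to_csv(
        out / "icd10_mappings.tsv", sep="\t", index=False
    )
    (out / "mapping_audit.json").write_text(
        audit_to_json(list(trait_results) + list(icd_results)) + "\n",
        encoding="utf-8",
    )
    logger.info("traits: %d mapped of %d (%.2fs)",
                manifest["counts"]["traits"]["mapped"], len(traits),
                time.perf_counter() - t0)

    if stages == "traits":
        _finish_manifest(out, manifest)
        return PipelineResult(config, trait_results, icd_results,
                              gwas_diseases, set(), None, {}, manifest)

    # --- drug pairing -------------------------------------------------
    tables = read_drug_tables(
        config.compounds, config.compound_targets,
        config.target_genes, config.indications,
    )
    indications, excl = load_compound_indications(tables, store)
    manifest["record_errors"].extend(excl.record_errors)
    druggable = read_gene_list(config.druggable_genes)
    genemap = TargetGeneMap.from_tables(tables.target_genes, druggable)
    pairs = build_pairs(indications, tables, genemap)
    partition = partition_genome(pairs, druggable)

    n_compounds = len(tables.compounds)
    n_excluded = len(excl.excluded_compounds)
    if n_excluded + (n_compounds - n_excluded) != n_compounds:
        raise AssertionError("compound exclusion does not conserve rows")
    manifest["counts"]["compounds"] = {
        "read": n_compounds,
        "kept": n_compounds - n_excluded,
        "excluded": n_excluded,
        "withdrawn": sorted(excl.withdrawn),
        "non_human": sorted(excl.non_human),
    }
    manifest["counts"]["indications"] = {
        "resolved": sum(1 for i in indications if not i.is_unmapped),
        "unmapped_mesh": sorted(set(excl.unmapped_mesh)),
    }
    manifest["counts"]["pairs"] = len(pairs)
    manifest["counts"]["partition"] = partition.counts()

    pair_lines = ["gene\tcui\tstage\tin_druggable"]
    for p in sorted(pairs, key=lambda p: (p.gene, p.cui, p.stage)):
        pair_lines.append(f"{p.gene}\t{p.cui}\t{p.stage}\t{int(p.in_druggable)}")
    (out / "pairs.tsv").write_text("\n".join(pair_lines) + "\n", encoding="utf-8")
    (out / "stage_partition.json").write_text(
        json.dumps(
            {
                "approved": sorted(partition.approved),
                "clinical": sorted(partition.clinical),
                "preclinical": sorted(partition.preclinical),
                "undrugged": sorted(partition.undrugged),
            },
            indent=2, sort_keys=True,
        )
        + "\n",
        encoding="utf-8",
    )
    logger.info("pairs: %d over %d druggable genes (%.2fs)", len(pairs),
                len(druggable), time.perf_counter() - t0)

    if stages == "drugs":
        _finish_manifest(out, manifest)
        return PipelineResult(config, trait_results, icd_results,
                              gwas_diseases, pairs, partition, {}, manifest)

    # --- coverage analysis --------------------------------------------
    disease_by_stage = {
        stage: {p.cui for p in pairs if p.stage == stage}
        for stage in ("approved", "clinical", "preclinical")
    }
    devel_diseases = set().union(*disease_by_stage.values())
    druggable_pairs = {(p.gene, p.cui) for p in pairs if p.in_druggable}
    clinical_pairs = {
        (p.gene, p.cui) for p in pairs if p.in_druggable and p.stage == "clinical"
    }
    approved_pairs = {
        (p.gene, p.cui) for p in pairs if p.in_druggable and p.stage == "approved"
    }
    spaces = {
        "A": make_sample_space_report(
            "A", config.gene_universe, config.disease_universe,
            len({(p.gene, p.cui) for p in pairs})),
        "B": make_sample_space_report(
            "B", len(partition.druggable), config.disease_universe,
            len(druggable_pairs)),
        "C": make_sample_space_report(
            "C", len(partition.clinical), len(disease_by_stage["clinical"]),
            len(clinical_pairs)),
        "D": make_sample_space_report(
            "D", len(partition.approved), len(disease_by_stage["approved"]),
            len(approved_pairs)),
    }
    overlap = gwas_overlap_partition(gwas_diseases, devel_diseases)

    gene_matrix = membership_matrix(
        {
            "approved": partition.approved,
            "clinical": partition.clinical,
            "preclinical": partition.preclinical,
        }
    )
    disease_matrix = membership_matrix(
        {**disease_by_stage, "gwas": gwas_diseases}
    )
    _write_membership_tsv(out / "membership_genes.tsv", gene_matrix)
    _write_membership_tsv(out / "membership_diseases.tsv", disease_matrix)

    approved_only = {p for p in pairs if p.stage == "approved" and p.in_druggable}
    stats = (
        targets_per_indication_stats(approved_only) if approved_only else None
    )
    per_target = indications_per_target_counts(
        approved_only, chapters, config.indication_threshold
    )
    opps = opportunity_lists(partition, pairs, gwas_diseases)
    for kind, olist in sorted(opps.items()):
        lines = ["gene\tcui\tgene_stage"]
        for e in sorted(olist.entries):
            lines.append(f"{e.gene}\t{e.cui}\t{e.gene_stage}")
        (out / f"opportunities_{kind}.tsv").write_text(
            "\n".join(lines) + "\n", encoding="utf-8"
        )

    coverage_doc = {
        "sample_spaces": {k: v.to_dict() for k, v in spaces.items()},
        "gwas_overlap": {
            "overlap": overlap.overlap,
            "gwas_only": overlap.gwas_only,
            "devel_only": overlap.devel_only,
        },
        "targets_per_approved_indication": (
            {"median": stats.median, "q1": stats.q1, "q3": stats.q3, "n": stats.n}
            if stats else None
        ),
        "indications_per_target": [
            {
                "gene": t.gene,
                "unique_diseases": t.unique_diseases,
                "per_chapter": dict(t.per_chapter),
            }
            for t in per_target
        ],
        "opportunity_counts": {k: len(v.entries) for k, v in sorted(opps.items())},
    }
    (out / "coverage.json").write_text(
        json.dumps(coverage_doc, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )

    checks = emit_paper_arithmetic(PAPER_CONSTANTS)
    arith_lines = ["identity\tcomputed\texpected\tpassed"]
    for c in checks:
        arith_lines.append(f"{c.name}\t{c.computed}\t{c.expected}\t{c.passed}")
    (out / "arithmetic.tsv").write_text(
        "\n".join(arith_lines) + "\n", encoding="utf-8"
    )

    manifest["counts"]["coverage"] = {
        "gwas_diseases": len(gwas_diseases),
        "devel_diseases": len(devel_diseases),
        "overlap": overlap.overlap,
        "opportunities": coverage_doc["opportunity_counts"],
        "arithmetic_passed": sum(c.passed for c in checks),
        "arithmetic_total": len(checks),
    }
    _finish_manifest(out, manifest)
    logger.info("pipeline complete (%.2fs)", time.perf_counter() - t0)
    return PipelineResult(
        config, trait_results, icd_results, gwas_diseases, pairs, partition,
        spaces, manifest,
    )


def _finish_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
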