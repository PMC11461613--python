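"""Seeded miniature worlds with a planted ground-truth ledger.

The generator writes a complete, schema-faithful input bundle — an
MRCONSO/MRSTY-dialect vocabulary, ChEMBL-style compound / target /
indication CSVs, a GWAS-catalog-style trait TSV, an ICD-10 phenotype
list, a druggable gene list, a chapter map, cross-map tables and a
curation overlay — together with a :class:`TruthLedger` recording, for
every planted trait, gene and pair, what the pipeline should recover.

Concept names are drawn from a pronounceable synthetic lexicon of
globally unique words, never real disease names, so nothing downstream
can lean on real-world string knowledge, and token-subset matches are
unambiguous by construction.  Every trait is planted to resolve at one
intended cascade route: the trait text, ontology annotations and MeSH
annotations are arranged so that all earlier routes are unproductive.
Identical seed and config produce a byte-identical bundle.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__

_SYLLABLES = (
    "ba", "be", "bo", "da", "de", "do", "fa", "fe", "fi", "ga", "go",
    "ka", "ke", "ki", "la", "le", "lo", "ma", "me", "mi", "na", "ne",
    "no", "pa", "pe", "po", "ra", "re", "ro", "sa", "se", "so", "ta",
    "te", "to", "va", "ve", "vo", "za", "zo", "lu", "ry", "xi", "qu",
    "or", "un", "il", "en", "ar", "os",
)

#: Trait-text modifiers; reserved so they never collide with lexicon words.
_MODIFIERS = ("severe", "chronic", "acute", "juvenile", "recurrent", "familial")

#: Chapters whose exclusively-classified diseases are dropped downstream.
EXCLUDED_CHAPTERS = (
    "Animal diseases",
    "Findings, not elsewhere classified",
    "Pregnancy, childbirth and the puerperium",
)

_STAGE_PHASE = {"approved": 4, "preclinical": 0}  # clinical drawn 1-3

_TRAIT_ROUTE_WEIGHTS = {
    "direct_string": 0.35,
    "candidate_resolved": 0.30,
    "crossmap_disgenet": 0.10,
    "crossmap_metathesaurus": 0.10,
    "pubmed_mesh_major": 0.15,
}

_TYPE_WEIGHTS = (
    ("Disease or Syndrome", 0.55),
    ("Neoplastic Process", 0.12),
    ("Finding", 0.10),
    ("Sign or Symptom", 0.08),
    ("Mental or Behavioral Dysfunction", 0.06),
    ("Laboratory Procedure", 0.05),
    ("Congenital Abnormality", 0.04),
)


@dataclass(frozen=True)
class WorldConfig:
    """Knobs of the synthetic study conditions.

    Defaults match the desk-scale world the package is validated on:
    200 traits over 150 concepts, 40 compounds, with a 15% one-to-many
    trait ambiguity rate.
    """

    seed: int = 1
    n_concepts: int = 150
    n_traits: int = 200
    ambiguity_rate: float = 0.15
    n_genes: int = 300
    n_druggable: int = 120
    n_compounds: int = 40
    stage_mix: tuple[float, float, float] = (0.35, 0.45, 0.20)
    n_diseases: int = 40
    chapter_count: int = 8
    edge_cases: bool = True

    def validate(self) -> None:
        counts = (self.n_concepts, self.n_traits, self.n_genes,
                  self.n_druggable, self.n_compounds, self.n_diseases,
                  self.chapter_count)
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be non-negative")
        if abs(sum(self.stage_mix) - 1.0) > 1e-9:
            raise ValueError("stage_mix proportions must sum to 1")
        if any(p < 0 for p in self.stage_mix):
            raise ValueError("stage_mix proportions must be non-negative")
        if self.n_druggable > self.n_genes:
            raise ValueError("n_druggable cannot exceed n_genes")
        if not 0.0 <= self.ambiguity_rate <= 1.0:
            raise ValueError("ambiguity_rate must lie in [0, 1]")
        if self.n_diseases > self.n_concepts:
            raise ValueError("n_diseases cannot exceed n_concepts")


@dataclass
class TraitTruth:
    trait: str
    cuis: tuple[str, ...]
    stage: str
    candidates: tuple[str, ...] = ()


@dataclass
class TruthLedger:
    """What the pipeline should recover from a generated bundle."""

    trait_truth: dict[str, TraitTruth] = field(default_factory=dict)
    icd10_truth: dict[str, str | None] = field(default_factory=dict)
    gene_stage_truth: dict[str, str] = field(default_factory=dict)
    pair_truth: set[tuple[str, str, str]] = field(default_factory=set)
    disease_chapter_truth: dict[str, tuple[str, ...]] = field(default_factory=dict)
    concept_truth: dict[str, dict] = field(default_factory=dict)
    excluded_compounds: dict[str, str] = field(default_factory=dict)

    def stage_sets(self) -> dict[str, set[str]]:
        """Planted per-stage gene sets plus the undrugged complement."""
        sets: dict[str, set[str]] = {
            "approved": set(), "clinical": set(), "preclinical": set(),
            "undrugged": set(),
        }
        for gene, stage in self.gene_stage_truth.items():
            sets[stage].add(gene)
        for gene, cui, stage in self.pair_truth:
            sets[stage].add(gene)
        sets["undrugged"] -= (
            sets["approved"] | sets["clinical"] | sets["preclinical"]
        )
        return sets

    def to_json(self) -> str:
        doc = {
            "trait_truth": {
                k: asdict(v) for k, v in sorted(self.trait_truth.items())
            },
            "icd10_truth": dict(sorted(self.icd10_truth.items())),
            "gene_stage_truth": dict(sorted(self.gene_stage_truth.items())),
            "pair_truth": sorted(list(p) for p in self.pair_truth),
            "disease_chapter_truth": {
                k: list(v) for k, v in sorted(self.disease_chapter_truth.items())
            },
            "concept_truth": dict(sorted(self.concept_truth.items())),
            "excluded_compounds": dict(sorted(self.excluded_compounds.items())),
        }
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "TruthLedger":
        text = Path(path).read_text(encoding="utf-8")
        return cls.from_json(text)

    @classmethod
    def from_json(cls, text: str) -> "TruthLedger":
        body = "\n".join(
            line for line in text.splitlines() if not line.startswith("#")
        )
        doc = json.loads(body)
        return cls(
            trait_truth={
                k: TraitTruth(
                    trait=v["trait"], cuis=tuple(v["cuis"]), stage=v["stage"],
                    candidates=tuple(v.get("candidates", ())),
                )
                for k, v in doc["trait_truth"].items()
            },
            icd10_truth=doc["icd10_truth"],
            gene_stage_truth=doc["gene_stage_truth"],
            pair_truth={tuple(p) for p in doc["pair_truth"]},
            disease_chapter_truth={
                k: tuple(v) for k, v in doc["disease_chapter_truth"].items()
            },
            concept_truth=doc["concept_truth"],
            excluded_compounds=doc["excluded_compounds"],
        )


class _Lexicon:
    """Globally unique pronounceable words from a seeded RNG."""

    def __init__(self, rng: random.Random):
        self._rng = rng
        self._used: set[str] = set(_MODIFIERS)
        self._counter = 0

    def word(self) -> str:
        for _ in range(1000):
            w = "".join(
                self._rng.choice(_SYLLABLES)
                for _ in range(self._rng.randint(2, 3))
            )
            if w not in self._used:
                self._used.add(w)
                return w
        self._counter += 1  # pathological configs only
        w = f"lex{self._counter}"
        self._used.add(w)
        return w


@dataclass
class _ConceptSpec:
    cui: str
    name: str  # lowercase two-word preferred name
    types: list[str]
    mesh_code: str
    icd10_code: str | None = None
    alt_synonym: str | None = None

    @property
    def mesh_term(self) -> str:
        return self.name.title()


@dataclass
class World:
    """In-memory bundle; :meth:`write` serializes it deterministically."""

    config: WorldConfig
    concepts: list[_ConceptSpec] = field(default_factory=list)
    mrsty_rows: list[tuple[str, str]] = field(default_factory=list)
    compounds: list[dict] = field(default_factory=list)
    compound_targets: list[tuple[str, str]] = field(default_factory=list)
    target_genes: list[tuple[str, str, str]] = field(default_factory=list)
    indications: list[dict] = field(default_factory=list)
    traits: list[dict] = field(default_factory=list)
    icd10_codes: list[str] = field(default_factory=list)
    druggable: list[str] = field(default_factory=list)
    chapter_rows: list[tuple[str, str]] = field(default_factory=list)
    crossmap_disgenet: list[tuple[str, str]] = field(default_factory=list)
    crossmap_metathesaurus: list[tuple[str, str]] = field(default_factory=list)
    overlay: dict = field(default_factory=dict)
    ledger: TruthLedger = field(default_factory=TruthLedger)
    disease_cuis: list[str] = field(default_factory=list)

    # -- serialization ------------------------------------------------

    @property
    def _header(self) -> str:
        return f"# seed={self.config.seed} generator=targetatlas-synth/{__version__}\n"

    def _mrconso_lines(self) -> list[str]:
        lines = []
        for c in self.concepts:
            rows = [(c.cui, "MSH", c.mesh_code, c.mesh_term)]
            if c.alt_synonym:
                rows.append((c.cui, "SNOMEDCT_US", f"S-{c.mesh_code}", c.alt_synonym))
            if c.icd10_code:
                rows.append((c.cui, "ICD10", c.icd10_code, c.mesh_term))
            for cui, sab, code, term in rows:
                fields = [""] * 18
                fields[0], fields[11], fields[13], fields[14] = cui, sab, code, term
                lines.append("|".join(fields) + "|")
        return lines

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        def emit(name: str, body: str) -> None:
            path = outdir / name
            path.write_text(self._header + body, encoding="utf-8")
            paths[name] = path

        emit("MRCONSO.RRF", "\n".join(self._mrconso_lines()) + "\n")
        emit(
            "MRSTY.RRF",
            "\n".join(
                "|".join([cui, "", "", sty, "", ""]) + "|"
                for cui, sty in self.mrsty_rows
            )
            + "\n",
        )
        emit(
            "compounds.csv",
            "compound_id,max_phase,withdrawn,for_human_use\n"
            + "\n".join(
                f"{c['compound_id']},{c['max_phase']},{c['withdrawn']},{c['for_human_use']}"
                for c in self.compounds
            )
            + "\n",
        )
        emit(
            "compound_targets.csv",
            "compound_id,target_id\n"
            + "\n".join(f"{c},{t}" for c, t in self.compound_targets)
            + "\n",
        )
        emit(
            "target_genes.csv",
            "target_id,uniprot,ensembl_gene_id\n"
            + "\n".join(f"{t},{u},{g}" for t, u, g in self.target_genes)
            + "\n",
        )
        emit(
            "indications.csv",
            "compound_id,mesh_term,max_phase_for_indication\n"
            + "\n".join(
                f"{i['compound_id']},{i['mesh_term']},{i['max_phase_for_indication']}"
                for i in self.indications
            )
            + "\n",
        )
        emit(
            "gwas_traits.tsv",
            "reported_trait\tmapped_ontology_terms\tpubmed_id\tstudy_mesh_terms\n"
            + "\n".join(
                "\t".join(
                    (t["reported_trait"], t["mapped_ontology_terms"],
                     t["pubmed_id"], t["study_mesh_terms"])
                )
                for t in self.traits
            )
            + "\n",
        )
        emit("icd10_phenotypes.tsv", "\n".join(self.icd10_codes) + "\n")
        emit("druggable_genes.txt", "\n".join(self.druggable) + "\n")
        emit(
            "chapter_map.tsv",
            "\n".join(f"{cui}\t{ch}" for cui, ch in self.chapter_rows) + "\n",
        )
        emit(
            "crossmap_disgenet.tsv",
            "\n".join(f"{t}\t{c}" for t, c in self.crossmap_disgenet) + "\n",
        )
        emit(
            "crossmap_metathesaurus.tsv",
            "\n".join(f"{t}\t{c}" for t, c in self.crossmap_metathesaurus) + "\n",
        )
        emit(
            "overlay.yaml",
            yaml.safe_dump({"decisions": self.overlay}, sort_keys=True),
        )
        emit("truth_ledger.json", self.ledger.to_json() + "\n")

        run_config = {
            "mrconso": "MRCONSO.RRF",
            "mrsty": "MRSTY.RRF",
            "compounds": "compounds.csv",
            "compound_targets": "compound_targets.csv",
            "target_genes": "target_genes.csv",
            "indications": "indications.csv",
            "gwas_traits": "gwas_traits.tsv",
            "icd10_list": "icd10_phenotypes.tsv",
            "druggable_genes": "druggable_genes.txt",
            "chapter_map": "chapter_map.tsv",
            "crossmap_disgenet": "crossmap_disgenet.tsv",
            "crossmap_metathesaurus": "crossmap_metathesaurus.tsv",
            "overlay": "overlay.yaml",
            "out_dir": "reports",
            "seed": self.config.seed,
            "gene_universe": self.config.n_genes,
            "disease_universe": self.config.n_concepts,
            "excluded_chapters": list(EXCLUDED_CHAPTERS),
            "indication_threshold": 2,
        }
        emit("run_config.yaml", yaml.safe_dump(run_config, sort_keys=True))
        return paths


def build_world(config: WorldConfig) -> World:
    """Assemble the in-memory world (no edge cases, no files)."""
    config.validate()
    rng = random.Random(config.seed)
    lex = _Lexicon(rng)
    world = World(config=config)

    # --- concepts -----------------------------------------------------
    type_names = [t for t, _w in _TYPE_WEIGHTS]
    type_weights = [w for _t, w in _TYPE_WEIGHTS]
    icd_letters = "ABCDEFGHJK"
    icd_used: set[str] = set()
    for i in range(config.n_concepts):
        cui = f"C{i + 1:07d}"
        name = f"{lex.word()} {lex.word()}"
        if i == 0:
            types = ["Disease or Syndrome"]
        elif i in (1, 2, 3):
            types = ["Finding"]  # guaranteed lower-priority pool
        else:
            types = [rng.choices(type_names, weights=type_weights, k=1)[0]]
            if rng.random() < 0.10:
                extra = rng.choice(type_names)
                if extra not in types:
                    types.append(extra)
        spec = _ConceptSpec(
            cui=cui, name=name, types=types, mesh_code=f"D{i + 1:06d}"
        )
        if rng.random() < 0.40:
            spec.alt_synonym = lex.word().title()
        if rng.random() < 0.30:
            while True:
                code = f"{rng.choice(icd_letters)}{rng.randint(10, 99)}"
                if code not in icd_used:
                    icd_used.add(code)
                    break
            spec.icd10_code = code
        world.concepts.append(spec)
        for sty in types:
            world.mrsty_rows.append((cui, sty))
        world.ledger.concept_truth[cui] = {
            "name": spec.mesh_term,
            "types": sorted(types),
            "icd10_code": spec.icd10_code,
        }

    by_cui = {c.cui: c for c in world.concepts}
    ds_pool = [c for c in world.concepts if "Disease or Syndrome" in c.types]
    non_ds_pool = [c for c in world.concepts if "Disease or Syndrome" not in c.types]

    # --- chapters -----------------------------------------------------
    chapter_names = [
        f"Diseases of the {lex.word()} system" for _ in range(config.chapter_count)
    ]
    for idx, c in enumerate(world.concepts):
        if chapter_names:
            chosen = [rng.choice(chapter_names)]
            if rng.random() < 0.15:
                second = rng.choice(chapter_names)
                if second not in chosen:
                    chosen.append(second)
        else:
            chosen = []
        # a couple of concepts live exclusively in excluded chapters
        if idx in (4, 5):
            chosen = [EXCLUDED_CHAPTERS[idx - 4]]
        for ch in chosen:
            world.chapter_rows.append((c.cui, ch))
        world.ledger.disease_chapter_truth[c.cui] = tuple(sorted(chosen))

    # --- traits -------------------------------------------------------
    routes = list(_TRAIT_ROUTE_WEIGHTS)
    counts = _largest_remainder(
        [_TRAIT_ROUTE_WEIGHTS[r] for r in routes], config.n_traits
    )
    plan = [r for r, n in zip(routes, counts) for _ in range(n)]
    rng.shuffle(plan)

    direct_pool = world.concepts[:]
    rng.shuffle(direct_pool)
    used_texts: set[str] = set()
    crossmap_serial = 0
    for route in plan:
        if route == "direct_string":
            concept = direct_pool.pop() if direct_pool else rng.choice(world.concepts)
            text = concept.name  # lowercase; MRCONSO carries title case
            if text in used_texts:
                continue
            truth = TraitTruth(trait=text, cuis=(concept.cui,), stage=route)
            row = _trait_row(text)
        elif route == "candidate_resolved":
            modifier = rng.choice(_MODIFIERS)
            ambiguous = rng.random() < config.ambiguity_rate
            if ambiguous and ds_pool and non_ds_pool:
                a = rng.choice(ds_pool)
                b = rng.choice(non_ds_pool)
                text = f"{modifier} {a.name} {b.name}"
                truth = TraitTruth(
                    trait=text, cuis=(a.cui,), stage=route,
                    candidates=tuple(sorted((a.cui, b.cui))),
                )
            else:
                concept = rng.choice(world.concepts)
                text = f"{modifier} {concept.name} {lex.word()}"
                truth = TraitTruth(
                    trait=text, cuis=(concept.cui,), stage=route,
                    candidates=(concept.cui,),
                )
            row = _trait_row(text)
        elif route in ("crossmap_disgenet", "crossmap_metathesaurus"):
            concept = rng.choice(world.concepts)
            text = f"{lex.word()} {lex.word()}"
            crossmap_serial += 1
            if route == "crossmap_disgenet":
                term = f"EFO:{7000 + crossmap_serial}"
                world.crossmap_disgenet.append((term, concept.cui))
            else:
                term = f"MONDO:{8000 + crossmap_serial}"
                world.crossmap_metathesaurus.append((term, concept.cui))
            truth = TraitTruth(trait=text, cuis=(concept.cui,), stage=route)
            row = _trait_row(text, mapped_terms=term)
        else:  # pubmed_mesh_major
            concept = rng.choice(world.concepts)
            distractor = rng.choice(world.concepts)
            text = f"{lex.word()} {lex.word()}"
            mesh = f"*{concept.mesh_term}"
            if distractor.cui != concept.cui:
                mesh += f";{distractor.mesh_term}"
            truth = TraitTruth(trait=text, cuis=(concept.cui,), stage=route)
            row = _trait_row(
                text, pubmed_id=str(30000000 + crossmap_serial + len(world.traits)),
                mesh_terms=mesh,
            )
        if text in used_texts:
            continue
        used_texts.add(text)
        world.traits.append(row)
        world.ledger.trait_truth[text] = truth

    # --- ICD-10 phenotype list ---------------------------------------
    coded = [c for c in world.concepts if c.icd10_code]
    for c in coded[:15]:
        world.icd10_codes.append(c.icd10_code)  # type: ignore[arg-type]
        world.ledger.icd10_truth[c.icd10_code] = c.cui  # type: ignore[index]
    for code in ("Z98", "Z99"):  # absent from the vocabulary on purpose
        if code not in icd_used:
            world.icd10_codes.append(code)
            world.ledger.icd10_truth[code] = None

    # --- genes and druggable set -------------------------------------
    genes = [f"ENSG{i + 1:011d}" for i in range(config.n_genes)]
    world.druggable = sorted(rng.sample(genes, config.n_druggable))
    for gene in world.druggable:
        world.ledger.gene_stage_truth[gene] = "undrugged"

    # --- compounds, targets, indications -----------------------------
    disease_pool = ds_pool if len(ds_pool) >= config.n_diseases else world.concepts
    world.disease_cuis = [
        c.cui for c in rng.sample(disease_pool, config.n_diseases)
    ]
    stage_counts = _largest_remainder(list(config.stage_mix), config.n_compounds)
    stages = (
        ["approved"] * stage_counts[0]
        + ["clinical"] * stage_counts[1]
        + ["preclinical"] * stage_counts[2]
    )
    rng.shuffle(stages)
    free_genes = world.druggable[:]
    rng.shuffle(free_genes)
    serial = 0
    for i, stage in enumerate(stages):
        compound_id = f"CHEMBL{100000 + i}"
        phase = _STAGE_PHASE.get(stage, rng.randint(1, 3))
        world.compounds.append(
            {"compound_id": compound_id, "max_phase": phase,
             "withdrawn": 0, "for_human_use": 1}
        )
        n_targets = 2 if rng.random() < 0.20 and len(free_genes) >= 2 else 1
        genes_of: list[str] = []
        for _ in range(n_targets):
            if not free_genes:
                break
            serial += 1
            gene = free_genes.pop()
            target_id = f"CHEMBL{200000 + serial}"
            world.compound_targets.append((compound_id, target_id))
            world.target_genes.append((target_id, f"Q{10000 + serial}", gene))
            world.ledger.gene_stage_truth[gene] = stage
            genes_of.append(gene)
        n_ind = rng.randint(1, min(3, len(world.disease_cuis)))
        for cui in rng.sample(world.disease_cuis, n_ind):
            world.indications.append(
                {"compound_id": compound_id,
                 "mesh_term": by_cui[cui].mesh_term,
                 "max_phase_for_indication": phase}
            )
            for gene in genes_of:
                world.ledger.pair_truth.add((gene, cui, stage))
    return world


def _trait_row(
    text: str, mapped_terms: str = "", pubmed_id: str = "", mesh_terms: str = ""
) -> dict:
    return {
        "reported_trait": text,
        "mapped_ontology_terms": mapped_terms,
        "pubmed_id": pubmed_id,
        "study_mesh_terms": mesh_terms,
    }


def _largest_remainder(weights: list[float], total: int) -> list[int]:
    """Apportion ``total`` into integer counts proportional to weights."""
    raw = [w * total for w in weights]
    counts = [int(r) for r in raw]
    remainder = total - sum(counts)
    order = sorted(
        range(len(raw)), key=lambda i: (raw[i] - counts[i], -i), reverse=True
    )
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def plant_edge_cases(world: World) -> World:
    """Inject the documented boundary conditions into a built world.

    Adds a withdrawn compound and a non-human compound (both excluded
    from every downstream count), a disease indicated at two stages, a
    disease classified in two chapters, a trait matching two concepts of
    different semantic types, and a gene carrying two target identifiers.
    """
    rng = random.Random(world.config.seed + 104729)
    by_cui = {c.cui: c for c in world.concepts}
    ds_pool = [c for c in world.concepts if "Disease or Syndrome" in c.types]
    non_ds_pool = [c for c in world.concepts if "Disease or Syndrome" not in c.types]
    undrugged = sorted(
        g for g, s in world.ledger.gene_stage_truth.items() if s == "undrugged"
    )
    diseases = world.disease_cuis or [c.cui for c in world.concepts[:5]]
    serial = len(world.target_genes) + 1000

    # 1-2: excluded compounds, each with its own otherwise-undrugged gene
    for tag, flags in (("withdrawn", {"withdrawn": 1, "for_human_use": 1}),
                       ("non_human", {"withdrawn": 0, "for_human_use": 0})):
        compound_id = f"CHEMBL9{len(world.compounds):05d}"
        world.compounds.append(
            {"compound_id": compound_id, "max_phase": 4, **flags}
        )
        if undrugged:
            gene = undrugged.pop()
            serial += 1
            target_id = f"CHEMBL{300000 + serial}"
            world.compound_targets.append((compound_id, target_id))
            world.target_genes.append((target_id, f"Q{20000 + serial}", gene))
            # gene stays undrugged in the ledger: the compound never counts
        world.indications.append(
            {"compound_id": compound_id,
             "mesh_term": by_cui[rng.choice(diseases)].mesh_term,
             "max_phase_for_indication": 4}
        )
        world.ledger.excluded_compounds[compound_id] = tag

    # 3: one disease indicated at both approved and clinical stage
    approved_pairs = [p for p in world.ledger.pair_truth if p[2] == "approved"]
    if approved_pairs and undrugged:
        _g, cui, _s = sorted(approved_pairs)[0]
        gene = undrugged.pop()
        serial += 1
        compound_id = f"CHEMBL9{len(world.compounds):05d}"
        target_id = f"CHEMBL{300000 + serial}"
        world.compounds.append(
            {"compound_id": compound_id, "max_phase": 2,
             "withdrawn": 0, "for_human_use": 1}
        )
        world.compound_targets.append((compound_id, target_id))
        world.target_genes.append((target_id, f"Q{20000 + serial}", gene))
        world.indications.append(
            {"compound_id": compound_id, "mesh_term": by_cui[cui].mesh_term,
             "max_phase_for_indication": 2}
        )
        world.ledger.gene_stage_truth[gene] = "clinical"
        world.ledger.pair_truth.add((gene, cui, "clinical"))

    # 4: one indication disease classified in two chapters
    if diseases:
        cui = sorted(diseases)[0]
        existing = set(world.ledger.disease_chapter_truth.get(cui, ()))
        extra = "Diseases of the planted second system"
        if extra not in existing:
            world.chapter_rows.append((cui, extra))
            world.ledger.disease_chapter_truth[cui] = tuple(
                sorted(existing | {extra})
            )

    # 5: one trait matching two concepts of different semantic types
    if ds_pool and non_ds_pool:
        a, b = ds_pool[0], non_ds_pool[0]
        text = f"acute {a.name} {b.name}"
        if text not in world.ledger.trait_truth:
            world.traits.append(_trait_row(text))
            world.ledger.trait_truth[text] = TraitTruth(
                trait=text, cuis=(a.cui,), stage="candidate_resolved",
                candidates=tuple(sorted((a.cui, b.cui))),
            )

    # 6: one gene carrying a second target identifier
    if world.target_genes:
        target_id, _up, gene = world.target_genes[0]
        owners = [c for c, t in world.compound_targets if t == target_id]
        if owners:
            serial += 1
            second = f"CHEMBL{300000 + serial}"
            world.target_genes.append((second, f"Q{20000 + serial}", gene))
            world.compound_targets.append((owners[0], second))
    return world


def generate_world(
    config: WorldConfig, outdir: str | Path
) -> tuple[dict[str, Path], TruthLedger]:
    """Build, optionally edge-case, and write a bundle; return its ledger."""
    world = build_world(config)
    if config.edge_cases:
        world = plant_edge_cases(world)
    paths = world.write(outdir)
    return paths, world.ledger
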