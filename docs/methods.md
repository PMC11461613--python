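# Methods

## Scope and model

`targetatlas` measures the coverage, overlap and divergence of two
efforts that address human disease — genome-wide association studies and
drug development — by projecting both into a single disease space keyed
by UMLS-style concept identifiers (CUIs), and by counting pairs on
nested target × disease grids. The package implements the harmonization
machinery, the stage partition of the druggable genome and the coverage
arithmetic; it deliberately does not attempt to reproduce headline
counts that depend on licensed, release-pinned external databases
(UMLS Metathesaurus, ChEMBL, GWAS Catalog) and on human curation. Those
figures enter the package only as *printed constants* whose internal
arithmetic relationships are recomputed and checked (see "Printed
arithmetic" below).

## Vocabulary store

Concept and semantic-type tables are read in the pipe-delimited RRF
dialect with configurable column positions defaulting to the public
layout (CUI at index 0; source vocabulary, source code and term string
at 11, 13 and 14; 18 fields, trailing pipe tolerated). Licensed
releases cannot ship with the code, so fixtures must be format-faithful;
the reader also skips `#` comment lines because generated fixtures carry
a seed-stamped header.

Term matching is exact after a fixed normalization: case-fold,
punctuation (and underscores) to spaces, whitespace collapsed, ends
stripped. The rule is idempotent. No stemming is applied: stemming
would merge terms the source vocabularies keep distinct, creating false
concept merges that nothing downstream could detect. Case-insensitivity
is required because headings differ in capitalization across source
vocabularies; the load report records this choice.

Semantic-type names are validated against a controlled list (the ten
priority types plus a handful of common others) at load time; an
unknown name is a hard error naming the offending string, because a
typo in a type name would silently distort resolution priorities.

## Trait mapping cascade

Each trait record is resolved by the first productive of these routes,
in order; the route label is stored on the result and every attempted
route leaves its candidate set in an audit trail:

1. **Curation overlay** — a declarative YAML/JSON file mapping trait
   text to accepted CUIs; an empty decision forces the trait unmapped.
   The overlay is applied *before* the automatic routes so that a
   curated pipeline is idempotent: re-running automation can never
   override a human decision. The audit still records what automation
   would have said.
2. **Direct string match** against all loaded synonyms.
3. **Candidate generation + resolution.** The candidate generator is a
   deterministic stand-in for dictionary-tagger concept recognition,
   kept behind its own function so a heavier recognizer could be
   substituted: it returns exact matches plus token-subset matches
   (every token of a ≥2-token synonym occurs among the trait's tokens).
   The two-token floor prevents single common words from flooding the
   candidate set. Resolution keeps direct matches outright if any
   exist; otherwise it scans the semantic-type priority list
   (*Disease or Syndrome*, *Neoplastic Process*, *Mental or Behavioral
   Dysfunction*, *Congenital Abnormality*, *Sign or Symptom*,
   *Finding*, *Laboratory Procedure*, *Injury or Poisoning*,
   *Individual Behavior*, *Diagnostic Procedure*) and keeps **all**
   candidates of the first tier present — ties are preserved rather
   than broken arbitrarily, since multi-mapping is a real feature of
   trait vocabularies. Candidates typed entirely outside the list are
   returned unchanged. Type names compare case-insensitively
   ("behaviour"/"behavior" spellings coexist in the wild).
4. **Cross-map tables** (DisGeNET-style, then Metathesaurus-style):
   the trait's mapped ontology terms are looked up in two-column
   term → CUI tables with a provenance label each.
5. **Major MeSH annotations** of the trait's publication, matched as
   direct strings against the MeSH source vocabulary only. Non-major
   annotations are ignored: they describe the study, not the trait.

ICD-10 phenotype codes (biobank-style inputs) are matched by **exact
source code**, never by string; this route carries its own stage label
(`icd10_code`). A malformed code is a record-level error that does not
stop processing.

After mapping, the union of mapped CUIs is collapsed to a disease set:
a disease is dropped only when its chapter set lies entirely inside the
excluded chapters (animal diseases; findings, not elsewhere classified;
pregnancy, childbirth and the puerperium); a disease in both an
excluded and a kept chapter is retained. Unmapped concepts fall into an
`Unclassified` chapter. Roll-ups count each disease once per chapter
plus once in a separate unique count.

## Drug pairing

Compounds flagged withdrawn or not for human use are excluded before
any pairing; the exclusion report lists their identifiers, and the
survivors plus exclusions always partition the input. Targets map
through UniProt accessions to Ensembl gene identifiers; multiple target
identifiers per gene collapse to the gene for counting. Indication
headings resolve through the same concept store (MeSH vocabulary only);
unresolvable headings are flagged and excluded from coverage counts.

Stage coding is a configurable table defaulting to max-phase semantics:
4 → approved, 1–3 → clinical, 0 → preclinical. An out-of-domain code is
a hard error. The **per-indication** phase, not the compound's global
maximum, drives a pair's stage, matching the semantics of
drug-indication tables. The unit of all coverage counts is the
de-duplicated (gene, CUI, stage) triple; a (gene, CUI) couple may
legitimately appear at several stages. Genes outside the druggable set
are retained on pairs but flagged, and only druggable genes enter the
genome partition; `undrugged` is always the exact complement of the
drugged union within the druggable set (checked at construction).

## Coverage analysis

* Sample-space sizes are exact integer products; Python integers make
  overflow a non-issue at any realistic scale.
* Percentages are rounded **half-up** (`decimal`), 0 or 1 decimals per
  report. Half-up, not banker's rounding, is what reproduces every
  printed percentage from its printed numerator and denominator.
* The membership matrix counts exclusive membership patterns
  (UpSet-style) and asserts on every call that pattern counts sum to
  the union size.
* "Explored pairing" is keyed on (gene, CUI) ignoring stage, since
  unique target–indication pairings are counted across clinical
  development as a whole.
* Quartiles of genes-per-indication use median-of-halves with the
  median excluded from the halves (Moore–McCabe): for counts
  [1, 2, 4] this gives Q1 1, median 2, Q3 4, matching the printed
  summary convention. (The printed "first quartile: 1, second
  quartile: 4" is read as Q1/Q3.)
* Opportunity lists are pairwise disjoint by gene stratum: approved
  genes feed *indication expansion*; genes with clinical or preclinical
  history but no approval feed *repurposing*; druggable-but-undrugged
  genes feed *de novo*. A gene approved for anything contributes to
  indication expansion only. Any existing (gene, CUI) pairing at any
  stage excludes that couple from every list.

## Printed arithmetic

Twelve identities connect the published survey's printed constants:
the four sample-space products
(19,813 × 11,158 = 221,073,454; 4,729 × 11,158 = 52,766,182;
1,218 × 1,401 = 1,706,418; 755 × 612 = 462,060), the explored fractions
of C and D (42,199 / 1,706,418 → 2.5%; 5,221 / 462,060 → 1%), C as a
share of B (3.2%) and of A (0.8%), the undrugged complement
(4,729 − 1,234 = 3,495) and its share (73.9%), the GWAS-only disease
count (1,914 − 703 = 1,211) and the chapter-exclusion difference
(983 − 30 = 953). `emit_paper_arithmetic` recomputes all twelve through
the same `sample_space`/`percent_round` primitives the pipeline applies
to live data. Note that two gene totals circulate for the
protein-coding genome (19,995 and 19,813); 19,813 is used because only
it reproduces 221,073,454 exactly.

## Synthetic worlds

The generator emulates the *schemas* and the failure modes of the real
inputs, not their marginal distributions. Defaults define the study
conditions the package is validated under: 150 concepts, 200 traits,
300 genes of which 120 druggable, 40 compounds with stage mix
35/45/20% approved/clinical/preclinical, 40 indication diseases, 8
chapters, 15% trait ambiguity. Concept names are two-word strings from
a pronounceable synthetic lexicon of globally unique words — never real
disease names — so no test can lean on real-world string knowledge and
token-subset matches are unambiguous by construction.

Each trait is planted to resolve at one intended route by making all
earlier routes unproductive: direct-route traits are (case-varied)
synonym strings; candidate-route traits embed a concept name among
reserved modifier words and fresh lexicon words; cross-map-route traits
are fresh two-word strings whose ontology term appears in exactly one
cross-map table; MeSH-route traits carry one major annotation naming
the true concept plus a non-major distractor. Ambiguous traits embed
two concept names whose semantic types differ in priority rank, and the
ledger records both candidates and the planted winner. Planted edge
cases add a withdrawn and a non-human compound (each attached to an
otherwise-undrugged gene, so exclusion is observable), a disease
indicated at two stages, a disease in two chapters, a two-concept trait
and a gene with two target identifiers.

All randomness flows from one root `random.Random(seed)`; every file
carries a `# seed=… generator=…` header and identical seed + config
yields a byte-identical bundle. What passing tests on these worlds show
is that the *machinery* is correct — exact recovery of planted truth,
conservation of counts, oracle-equivalent statistics. What they cannot
show is robustness to real-data phenomena the generator does not
emulate: typographical variance beyond case, hierarchical term
granularity mismatches, concept drift across vocabulary releases, and
the long-tailed synonym distributions of real metathesauri.

## Determinism and reports

The pipeline validates every input path before writing anything, routes
all logging to stderr, and writes reports with sorted keys and sorted
rows and no timestamps, so identical config + inputs give byte-identical
bundles. The manifest records input SHA-256 checksums, per-stage row
counts (conserved: kept + skipped = read at every stage) and the package
version. Record-level errors (dangling compound references, malformed
ICD-10 codes) accumulate in the manifest and set CLI exit code 2; hard
errors abort with the failing stage.

## Known limitations

* The candidate generator is intentionally weaker than a full
  biomedical concept recognizer: no variant generation, no word-order
  scoring, no abbreviation expansion.
* Cross-map tables are static inputs; no live ontology services are
  queried.
* The analysis weights all diseases equally — no prevalence, mortality
  or tractability weighting.
* Assigning GWAS association signals to causal genes is out of scope;
  the atlas treats GWAS disease coverage as gene-agnostic.
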