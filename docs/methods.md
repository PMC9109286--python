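# Methods

This note records the model implemented by `icd11kit`, the design choices made
where the architecture leaves room, the numerical and tie-breaking rules that
make every operation deterministic, and what the synthetic data does and does
not establish.

## The Foundation graph and content model

The Foundation is a directed acyclic graph over concept records, single-rooted
at a *virtual root* so that reachability and exhaustiveness are well defined
(nothing in the architecture itself demands one root; we require it as a
modelling choice). Each record carries the content model: a permanent URI,
language-tagged concept title and fully specified name, synonyms, a brief
definition, optional clinical attributes (body system, manifestations,
etiology, genomic association, severity, temporality, functional impact), an
optional explicit sibling rank, and residual-suppression flags. Required
elements are the URI, the English title and fully specified name, the brief
definition, and — except for the root — at least one parent. Synonyms and the
classification kind are optional. Labels are keyed by BCP-47 tags; lookups
fall back to English, which is mandatory.

Child links are never stored: they are derived from `parent_uris`, so the two
directions cannot disagree. The two mutators preserve acyclicity by
construction — `add_entity` only attaches a new node below existing ones, and
`add_parent_link` rejects any link whose target is a descendant of (or equal
to) the child. `validate_foundation` nevertheless re-checks everything from
scratch (three-colour DFS for cycles, per-entity field validation,
reachability of the root), because foundations can also arrive from files.

Extension codes (anatomy, histology, severity values…) live in a dedicated
chapter of the *same* graph, flagged `classification_kind = extension_value`.

### Deterministic sibling order

Everything downstream — default primary-parent selection, linearization child
order, code assignment — uses one ordering convention: explicitly ranked
siblings first (ascending `sibling_rank`), then the rest by English title,
with the URI as the final tie-break. This single rule is what makes
linearization derivation and code assignment bytewise reproducible.

## Linearization

`derive_linearization` walks each configured chapter depth-first along
*primary-child* links. The primary parent of a concept is the configured
override when present (it must name an actual Foundation parent), else the
first parent in sibling order. Because every concept has exactly one primary
parent, each appears at most once — mutual exclusivity is structural, and
`verify_statistical_properties` re-checks it anyway.

**Shoreline.** By default a concept is above the shoreline when its primary
chain stays inside the configured chapters and its depth (chapter = 1) is at
most `max_depth` (default 4, matching the 7-character code capacity). An
explicit `include` set replaces the depth rule entirely; excluded
intermediate concepts then cause included descendants to attach to their
nearest included primary ancestor. Note that a concept whose primary parent
chain leaves the configured chapters is below the shoreline even at shallow
depth — its secondary parents do not rescue it, which mirrors the fact that a
tabulation renders a concept only where its linear parent is rendered.

**Residual categories.** Each branch gains an "Other specified ⟨title⟩" and a
"⟨title⟩, unspecified" child, minus the kinds suppressed on the source entity.
The rule for *where* residuals attach went through one refinement worth
recording. A node receives residuals iff

1. it has at least one rendered (non-residual) child, **or** it has at least
   one Foundation descendant below the shoreline — either way unlisted
   content exists beneath it; and
2. its depth is strictly less than `max_depth` — a residual child of a
   full-depth node would need an eight- or nine-character code, which the
   fixed-digit scheme cannot express.

"A leaf gets no residuals" therefore means *Foundation* leaf, not
linearization leaf: a chapter that renders none of its children still needs a
residual when Foundation-only content descends from it, otherwise that content
is uncodable and the classification is not exhaustive. The virtual root never
receives residuals — it is not a category, and the coding scheme reserves no
chapter-level residual slot. Insertion is idempotent: existing residual nodes
are kept, never doubled. Residual nodes carry no `source_uri`; they exist only
inside the linearization.

**Residual routing.** A below-shoreline concept is coded by first finding its
nearest rendered ancestor (breadth-first over all parent links, levels visited
in sibling order so ties resolve reproducibly), then climbing the
linearization from there to the first node offering a residual child —
preferring `other_specified` (the concept *is* specified, merely not listed)
and falling back to `unspecified` where the former is suppressed. If the climb
reaches the root without finding one, the concept is uncodable and
`verify_statistical_properties` reports the linearization as not exhaustive;
with unsuppressed chapters this cannot happen, but suppression flags let
authors create such gaps deliberately, and the engine reports rather than
hides them.

## Coding scheme

34-symbol alphabet (digits plus uppercase letters without O and I, which are
confusable with 0 and 1); 1 chapter symbol, then one 2-symbol pair per level,
3 levels — full-depth codes have 7 characters. Ordinary siblings take pairs in
base-34 order; the top two pairs `ZY`/`ZZ` are reserved for the residuals, so
ordinary capacity is 1154 per level and residual codes can never collide with
ordinary ones. The display form inserts a dot after the fourth character;
canonical codes are dotless and the decoder accepts both. Sibling overflow
(>1154 ordinary children) and depth overflow raise immediately rather than
truncating.

`encode_entity` is total over the chapter closure of an exhaustive
linearization and single-valued by construction (above-shoreline: own code;
below: the routed residual's code), which is the coding-level form of "one and
only one way of capturing a condition".

The search index is a plain inverted index over case-folded,
punctuation-stripped tokens of titles, fully specified names and synonyms in
all languages; completion ranks by number of matching tokens, then English
title, then URI. No fuzzy matching or stemming is attempted.

## Post-coordination

Expressions are canonicalized on composition (extensions sorted by
(axis, value), exact duplicates removed), so every downstream operation is a
function of the canonical form — normalization is confluent under extension
reordering by construction. Validation checks each extension independently
and reports *all* failures: unsanctioned axis, value outside the
descendant-or-equal closure of the stem's allowed value roots, and more than
one value on a single-valued axis (severity and stage default to
single-valued, anatomy and histology to multi-valued; the rules file can
override per axis). Equivalence matching is exact-set on the canonical pairs —
no partial or subsumption matching, since nothing defines which subsumption
would be meant. The text grammar `STEMCODE & axis=VALUECODE & …` is
repo-defined; parsing reports the character offset of the first malformed
clause, and residual codes are rejected when a text form is lifted back to
URIs because a residual names no single concept.

## Serialization

All writers emit UTF-8 with LF endings and are deterministic (sorted keys,
sorted entities, fixed child order), so round-trip tests compare bytes. The
foundation JSON dialect validates structurally on read (errors carry
JSON-pointer paths) and then graph-wide. ClaML export is the pragmatic
`Class`/`SuperClass`/`SubClass`/`Rubric(preferred, definition)` subset;
residuals export like ordinary classes with their generated labels. The SKOS
Turtle writer emits triples directly (typing, `prefLabel` per language,
`altLabel` per synonym, `broader`/`narrower` per link) so that output bytes
are a pure function of the graph; tests re-parse it with an independent RDF
library and check the triple arithmetic
`|entities| + |labels| + 2·|links|`.

## Synthetic data

The generator emulates the structural features the engine depends on:
depth-structured chapters (depth drawn uniformly from 2 to
`max_foundation_depth`, default 6, so a default depth-4 linearization has
below-shoreline content), multiple inheritance (each concept gains one extra,
strictly shallower parent with probability 0.3 — shallower-only extra parents
make acyclicity structural), pronounceable pseudo-word labels with synonyms so
search is meaningful, an extension chapter with anatomy/histology/severity
subtrees, residual suppression on 5 % of concepts, and sanctioning rules whose
equivalence rows pair an existing specialized child with (parent stem +
in-subtree extensions), so normalization has real targets. All draws are
integer draws from one seeded `random.Random`; identical seeds give identical
JSON bytes.

What it does **not** emulate: realistic disease-frequency or branching
distributions, clinical plausibility of labels, cross-axis dependencies, or
the scale of a real release (~10²–10³ concepts per run here, chosen so the
full suite runs in seconds). Passing tests therefore establish the
architectural invariants — acyclicity, exclusivity, exhaustiveness, prefix
coding, confluent normalization, byte-stable serialization — not fidelity to
any real terminology's content.

The worked fixture encodes the classic motif by hand: stomach cancer with two
parents, linearized once under neoplasms; anatomy sanctioned on gastric
cancer restricted to the stomach subtree; one equivalence row to a
pre-coordinated "gastric cancer of body of stomach".

## Known limitations

* No ontology layer: no OWL/description-logic axioms or reasoning, and no
  derivation of equivalence rows from formal definitions — the equivalence
  table is an input.
* No linearization diffing across Foundation versions, no authoring UI, no
  compatibility with any hosted API's payload schema.
* Search is exact-prefix only.
* `include`-set shorelines trust the author: codes still overflow loudly if
  the included set is deeper than the code capacity.
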