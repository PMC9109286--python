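"""Content model and the Foundation multi-parent acyclic concept graph.

The Foundation is the semantic network underpinning the classification: a
single-rooted acyclic graph in which a concept may have several parents
(stomach cancer sits both in the neoplasms hierarchy and in the digestive
disease chapter).  Every concept carries an information-model record — a
permanent URI, language-tagged titles, a fully specified name, synonyms,
definitions and optional clinical attributes.  Tabular classifications are
*derived* from this graph (see :mod:`icd11kit.linearize`); the graph itself is
never constrained to a tree and may descend to arbitrary depth.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence

__all__ = [
    "CLASSIFICATION_KINDS",
    "RESIDUAL_KINDS",
    "EntityRecord",
    "Violation",
    "SkosRelation",
    "Foundation",
    "FoundationReport",
    "FoundationError",
    "UnknownUriError",
    "DuplicateUriError",
    "UnresolvedParentError",
    "CycleError",
    "EntityInvalidError",
    "FoundationInvalidError",
    "validate_entity",
    "validate_foundation",
    "to_skos_relations",
]

#: Kinds a concept may declare in its classification properties.
CLASSIFICATION_KINDS = frozenset(
    {
        "disease",
        "syndrome",
        "symptom",
        "finding",
        "health_condition",
        "extension_value",
        "chapter",
    }
)

#: Residual-category kinds that an author may suppress on a concept.
RESIDUAL_KINDS = ("other_specified", "unspecified")


class FoundationError(Exception):
    """Base class for Foundation graph errors."""


class UnknownUriError(FoundationError, KeyError):
    """A URI does not resolve to any entity in the Foundation."""


class DuplicateUriError(FoundationError):
    """An entity with this URI is already present."""


class UnresolvedParentError(FoundationError):
    """A parent URI does not resolve to an existing entity."""


class CycleError(FoundationError):
    """The requested link would make a concept its own ancestor."""


class EntityInvalidError(FoundationError):
    """An entity record violates the content model."""

    def __init__(self, violations: Sequence["Violation"]):
        self.violations = list(violations)
        super().__init__("; ".join(str(v) for v in self.violations))


class FoundationInvalidError(FoundationError):
    """A Foundation-wide validation report contains violations."""

    def __init__(self, report: "FoundationReport"):
        self.report = report
        super().__init__(report.summary())


@dataclass(frozen=True)
class Violation:
    """One broken content-model rule, naming the field and the rule."""

    field: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: {self.rule} ({self.message})"


@dataclass(frozen=True)
class SkosRelation:
    """A broader/narrower assertion between two concepts."""

    subject_uri: str
    predicate: str  # "broader" | "narrower"
    object_uri: str


@dataclass
class EntityRecord:
    """Information-model record for one Foundation concept.

    ``uri`` is permanent: no operation on a Foundation ever rewrites it.
    ``concept_title`` / ``fully_specified_name`` map BCP-47 language tags to
    text; an ``"en"`` entry is mandatory for required fields.  ``parent_uris``
    is an ordered tuple — order is informative only, hierarchy order is
    governed by the deterministic sibling convention (:func:`sibling_key`).
    """

    uri: str
    concept_title: dict[str, str] = field(default_factory=dict)
    fully_specified_name: dict[str, str] = field(default_factory=dict)
    brief_definition: str = ""
    synonyms: dict[str, list[str]] = field(default_factory=dict)
    classification_kind: Optional[str] = None
    parent_uris: tuple[str, ...] = ()
    long_description: Optional[str] = None
    body_system: Optional[list[str]] = None
    manifestations: Optional[list[str]] = None
    etiology: Optional[list[str]] = None
    genomic_association: Optional[list[str]] = None
    severity: Optional[list[str]] = None
    temporality: Optional[list[str]] = None
    functional_impact: Optional[list[str]] = None
    sibling_rank: Optional[int] = None
    residual_suppression: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.parent_uris = tuple(dict.fromkeys(self.parent_uris))
        self.residual_suppression = frozenset(self.residual_suppression)

    def title(self, language: str = "en") -> str:
        """Concept title in ``language``, falling back to English."""
        return self.concept_title.get(language) or self.concept_title.get("en", "")

    def label_texts(self) -> Iterator[tuple[str, str, str]]:
        """Yield (field, language, text) for every label-bearing field."""
        for lang, text in sorted(self.concept_title.items()):
            yield "concept_title", lang, text
        for lang, text in sorted(self.fully_specified_name.items()):
            yield "fully_specified_name", lang, text
        for lang, texts in sorted(self.synonyms.items()):
            for text in texts:
                yield "synonyms", lang, text


def sibling_key(entity: EntityRecord) -> tuple:
    """Deterministic sibling order: explicit rank first, then English title,
    URI as the final tie-break.  Used for default primary-parent selection,
    linearization child order and code assignment."""
    if entity.sibling_rank is not None:
        return (0, entity.sibling_rank, entity.title(), entity.uri)
    return (1, 0, entity.title(), entity.uri)


def validate_entity(entity: EntityRecord, *, is_root: bool = False) -> list[Violation]:
    """Check one record against the content model; return violations.

    Required elements: the URI, English concept title, English fully
    specified name, a brief definition, and (except for the virtual root)
    at least one parent link.  Violations are returned, never raised.
    """
    out: list[Violation] = []
    if not entity.uri:
        out.append(Violation("uri", "required", "uri must be a non-empty string"))
    if not entity.concept_title.get("en"):
        out.append(Violation("concept_title", "required", "missing 'en' concept title"))
    if not entity.fully_specified_name.get("en"):
        out.append(
            Violation(
                "fully_specified_name", "required", "missing 'en' fully specified name"
            )
        )
    if not entity.brief_definition:
        out.append(Violation("brief_definition", "required", "missing brief definition"))
    if not is_root and not entity.parent_uris:
        out.append(
            Violation("parent_uris", "required", "non-root entity needs >=1 parent")
        )
    if entity.uri and entity.uri in entity.parent_uris:
        out.append(Violation("parent_uris", "self-parent", "uri listed as own parent"))
    if (
        entity.classification_kind is not None
        and entity.classification_kind not in CLASSIFICATION_KINDS
    ):
        out.append(
            Violation(
                "classification_kind",
                "enum",
                f"unknown kind {entity.classification_kind!r}",
            )
        )
    bad = entity.residual_suppression - set(RESIDUAL_KINDS)
    if bad:
        out.append(
            Violation(
                "residual_suppression", "enum", f"unknown kinds {sorted(bad)!r}"
            )
        )
    return out


@dataclass
class FoundationReport:
    """Foundation-wide validation result.

    ``cycles`` lists the URIs on each detected parent-link cycle;
    ``dangling_parents`` are (child, missing-parent) pairs; ``unreachable``
    entities cannot reach the root via parent links; ``entity_violations``
    maps URIs to their content-model violations.
    """

    cycles: list[list[str]] = field(default_factory=list)
    dangling_parents: list[tuple[str, str]] = field(default_factory=list)
    unreachable: list[str] = field(default_factory=list)
    entity_violations: dict[str, list[Violation]] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not (
            self.cycles
            or self.dangling_parents
            or self.unreachable
            or self.entity_violations
        )

    def summary(self) -> str:
        parts = []
        if self.cycles:
            parts.append(f"{len(self.cycles)} cycle(s)")
        if self.dangling_parents:
            parts.append(f"{len(self.dangling_parents)} dangling parent(s)")
        if self.unreachable:
            parts.append(f"{len(self.unreachable)} unreachable entit(ies)")
        if self.entity_violations:
            parts.append(f"{len(self.entity_violations)} invalid entit(ies)")
        return "valid foundation" if not parts else "; ".join(parts)


class Foundation:
    """Validated single-rooted acyclic multi-parent graph of entity records.

    Child links are derived from ``parent_uris`` (never stored), so the two
    directions cannot disagree.  Mutators (:meth:`add_entity`,
    :meth:`add_parent_link`) preserve acyclicity by construction and return
    ``self`` for chaining.
    """

    def __init__(self, root_uri: str, root_title: str = "Foundation root") -> None:
        root = EntityRecord(
            uri=root_uri,
            concept_title={"en": root_title},
            fully_specified_name={"en": root_title},
            brief_definition="Virtual root under which every concept is reachable.",
        )
        self.root_uri = root_uri
        self._entities: dict[str, EntityRecord] = {root_uri: root}
        self._children: dict[str, list[str]] = {root_uri: []}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_entities(
        cls, root_uri: str, entities: Iterable[EntityRecord]
    ) -> "Foundation":
        """Build from a full entity list (root included or not) and validate.

        Raises :class:`FoundationInvalidError` if the assembled graph breaks
        any Foundation invariant.
        """
        obj = cls.__new__(cls)
        obj.root_uri = root_uri
        obj._entities = {}
        for entity in entities:
            if entity.uri in obj._entities:
                raise DuplicateUriError(entity.uri)
            obj._entities[entity.uri] = entity
        if root_uri not in obj._entities:
            obj._entities[root_uri] = EntityRecord(
                uri=root_uri,
                concept_title={"en": "Foundation root"},
                fully_specified_name={"en": "Foundation root"},
                brief_definition="Virtual root.",
            )
        obj._rebuild_children()
        report = validate_foundation(obj)
        if not report.ok:
            raise FoundationInvalidError(report)
        return obj

    def _rebuild_children(self) -> None:
        self._children = {uri: [] for uri in self._entities}
        for uri, entity in self._entities.items():
            for parent in entity.parent_uris:
                if parent in self._children:
                    self._children[parent].append(uri)

    # -- lookup ------------------------------------------------------------

    def __contains__(self, uri: str) -> bool:
        return uri in self._entities

    def __len__(self) -> int:
        return len(self._entities)

    def __iter__(self) -> Iterator[str]:
        return iter(self._entities)

    @property
    def entities(self) -> Mapping[str, EntityRecord]:
        return self._entities

    def get(self, uri: str) -> EntityRecord:
        try:
            return self._entities[uri]
        except KeyError:
            raise UnknownUriError(uri) from None

    def parents(self, uri: str) -> tuple[str, ...]:
        return self.get(uri).parent_uris

    def sorted_parents(self, uri: str) -> list[str]:
        """Parents of ``uri`` in the deterministic sibling order."""
        return sorted(self.get(uri).parent_uris, key=lambda p: sibling_key(self.get(p)))

    def children(self, uri: str) -> list[str]:
        """Children of ``uri`` in the deterministic sibling order (derived)."""
        self.get(uri)
        kids = self._children.get(uri, [])
        return sorted(kids, key=lambda c: sibling_key(self.get(c)))

    def link_count(self) -> int:
        return sum(len(e.parent_uris) for e in self._entities.values())

    # -- mutation ----------------------------------------------------------

    def add_entity(self, entity: EntityRecord) -> "Foundation":
        """Insert a validated entity whose parents already exist."""
        violations = validate_entity(entity)
        if violations:
            raise EntityInvalidError(violations)
        if entity.uri in self._entities:
            raise DuplicateUriError(entity.uri)
        for parent in entity.parent_uris:
            if parent not in self._entities:
                raise UnresolvedParentError(
                    f"{entity.uri}: parent {parent!r} not in foundation"
                )
        self._entities[entity.uri] = entity
        self._children[entity.uri] = []
        for parent in entity.parent_uris:
            self._children[parent].append(entity.uri)
        return self

    def add_parent_link(self, child_uri: str, new_parent_uri: str) -> "Foundation":
        """Add one parent link, refusing any link that closes a directed cycle.

        The link is rejected when ``new_parent_uri`` equals ``child_uri`` or is
        already a descendant of it — either would make a concept its own
        ancestor.
        """
        child = self.get(child_uri)
        self.get(new_parent_uri)
        if new_parent_uri in child.parent_uris:
            raise DuplicateUriError(
                f"link {child_uri} -> {new_parent_uri} already present"
            )
        if new_parent_uri == child_uri or new_parent_uri in self.descendants(child_uri):
            raise CycleError(
                f"linking {child_uri} under {new_parent_uri} would create a cycle"
            )
        self._entities[child_uri] = replace(
            child, parent_uris=child.parent_uris + (new_parent_uri,)
        )
        self._children[new_parent_uri].append(child_uri)
        return self

    def update_entity(self, uri: str, **changes) -> "Foundation":
        """Revise label/definition fields of an entity; the URI is permanent
        and may not appear in ``changes``."""
        if "uri" in changes or "parent_uris" in changes:
            raise FoundationError("uri and parent links cannot be rewritten here")
        self._entities[uri] = replace(self.get(uri), **changes)
        return self

    # -- traversal ---------------------------------------------------------

    def ancestors(self, uri: str) -> set[str]:
        """Transitive closure over parent links, excluding ``uri`` itself."""
        self.get(uri)
        seen: set[str] = set()
        queue = deque(self.get(uri).parent_uris)
        while queue:
            cur = queue.popleft()
            if cur in seen or cur not in self._entities:
                continue
            seen.add(cur)
            queue.extend(self._entities[cur].parent_uris)
        return seen

    def descendants(self, uri: str) -> set[str]:
        """Transitive closure over child links, excluding ``uri`` itself."""
        self.get(uri)
        seen: set[str] = set()
        queue = deque(self._children.get(uri, ()))
        while queue:
            cur = queue.popleft()
            if cur in seen:
                continue
            seen.add(cur)
            queue.extend(self._children.get(cur, ()))
        return seen


def validate_foundation(foundation: Foundation) -> FoundationReport:
    """Full invariant check: acyclicity, resolvable parents, reachability of
    the root, and per-entity content-model conformance."""
    report = FoundationReport()
    entities = foundation.entities

    for uri, entity in entities.items():
        violations = validate_entity(entity, is_root=(uri == foundation.root_uri))
        if violations:
            report.entity_violations[uri] = violations
        for parent in entity.parent_uris:
            if parent not in entities:
                report.dangling_parents.append((uri, parent))

    # Iterative three-colour DFS over parent links: grey-hit = cycle.
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {uri: WHITE for uri in entities}
    for start in sorted(entities):
        if colour[start] != WHITE:
            continue
        stack: list[tuple[str, Iterator[str]]] = [
            (start, iter(entities[start].parent_uris))
        ]
        colour[start] = GREY
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if nxt not in entities:
                    continue
                if colour[nxt] == GREY:
                    cycle = [nxt]
                    for frame_uri, _ in reversed(stack):
                        cycle.append(frame_uri)
                        if frame_uri == nxt:
                            break
                    report.cycles.append(cycle)
                elif colour[nxt] == WHITE:
                    colour[nxt] = GREY
                    stack.append((nxt, iter(entities[nxt].parent_uris)))
                    advanced = True
                    break
            if not advanced:
                colour[node] = BLACK
                stack.pop()

    if not report.cycles:
        for uri in sorted(entities):
            if uri == foundation.root_uri:
                continue
            if foundation.root_uri not in foundation.ancestors(uri):
                report.unreachable.append(uri)
    return report


def to_skos_relations(foundation: Foundation) -> list[SkosRelation]:
    """Broader/narrower pairs for every parent link.

    Each child→parent link yields ``(child, broader, parent)`` and its inverse
    ``(parent, narrower, child)``, so the count is twice the link count and
    the exported set regenerates the parent-link set exactly.
    """
    out: list[SkosRelation] = []
    for uri in sorted(foundation.entities):
        for parent in foundation.entities[uri].parent_uris:
            out.append(SkosRelation(uri, "broader", parent))
            out.append(SkosRelation(parent, "narrower", uri))
    return out
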