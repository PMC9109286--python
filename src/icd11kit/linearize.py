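"""Derivation of strict single-parent linearizations from the Foundation.

A linearization "walks the Foundation in a line": for every concept in the
selected chapters one parent is deliberately chosen as the *primary* (linear)
parent, producing a strict hierarchy that is mutually exclusive, and — after
residual "Other specified" / "unspecified" categories are inserted —
exhaustive.  Concepts too deep (or not explicitly included) stay "below the
shoreline": they live only in the Foundation and are coded through residuals
or post-coordination.  Several linearizations with different primary-parent
choices can coexist over one Foundation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterator, Optional

from .foundation import Foundation, sibling_key

__all__ = [
    "LinearizationConfig",
    "LinNode",
    "Linearization",
    "ShorelineReport",
    "PropertyReport",
    "LinearizationError",
    "ConfigurationError",
    "MismatchError",
    "select_primary_parent",
    "derive_linearization",
    "insert_residuals",
    "shoreline_partition",
    "verify_statistical_properties",
    "residual_target_node",
]

RESIDUAL_NONE = "none"
RESIDUAL_OTHER = "other_specified"
RESIDUAL_UNSPEC = "unspecified"


class LinearizationError(Exception):
    pass


class ConfigurationError(LinearizationError):
    """The linearization configuration contradicts the Foundation."""


class MismatchError(LinearizationError):
    """Foundation and linearization do not belong together."""


@dataclass(frozen=True)
class LinearizationConfig:
    """Parameters of one linearization.

    ``max_depth`` counts levels below the virtual root (a chapter is depth 1);
    it bounds what fits the fixed-digit code space.  ``primary_parent_overrides``
    maps a concept to the Foundation parent to inherit from in *this*
    linearization; every override must name an actual parent.  When
    ``include_uris`` is given it replaces the depth rule as the above-shoreline
    membership test (chapters are always members).
    """

    name: str
    chapter_uris: tuple[str, ...]
    max_depth: int = 4
    primary_parent_overrides: dict[str, str] = field(default_factory=dict)
    include_uris: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chapter_uris", tuple(self.chapter_uris))
        if self.include_uris is not None:
            object.__setattr__(self, "include_uris", frozenset(self.include_uris))
        if self.max_depth < 1:
            raise ConfigurationError("max_depth must be >= 1")


@dataclass
class LinNode:
    """One node of a linearization tree.

    Residual nodes (``residual_kind`` != "none") have no ``source_uri``: they
    exist only inside the linearization and are never referenced by the
    Foundation.
    """

    node_id: str
    label: str
    source_uri: Optional[str] = None
    residual_kind: str = RESIDUAL_NONE
    parent_id: Optional[str] = None
    code: Optional[str] = None

    @property
    def is_residual(self) -> bool:
        return self.residual_kind != RESIDUAL_NONE


ROOT_NODE_ID = "root"


class Linearization:
    """A strict single-parent tree of :class:`LinNode` derived from a
    Foundation.  Child order is deterministic; every Foundation URI occurs at
    most once among non-residual nodes."""

    def __init__(self, config: LinearizationConfig, foundation_ref: str) -> None:
        self.config = config
        self.foundation_ref = foundation_ref
        self.nodes: dict[str, LinNode] = {}
        self.children: dict[str, list[str]] = {}
        self._by_source: dict[str, str] = {}

    # -- structure ---------------------------------------------------------

    def add_node(self, node: LinNode) -> LinNode:
        if node.node_id in self.nodes:
            raise LinearizationError(f"duplicate node id {node.node_id!r}")
        if node.parent_id is not None and node.parent_id not in self.nodes:
            raise LinearizationError(f"parent {node.parent_id!r} missing")
        self.nodes[node.node_id] = node
        self.children[node.node_id] = []
        if node.parent_id is not None:
            self.children[node.parent_id].append(node.node_id)
        if node.source_uri is not None:
            self._by_source.setdefault(node.source_uri, node.node_id)
        return node

    def remove_subtree(self, node_id: str) -> None:
        for child in list(self.children.get(node_id, ())):
            self.remove_subtree(child)
        node = self.nodes.pop(node_id)
        self.children.pop(node_id, None)
        if node.parent_id is not None and node.parent_id in self.children:
            self.children[node.parent_id].remove(node_id)
        if node.source_uri is not None and self._by_source.get(node.source_uri) == node_id:
            del self._by_source[node.source_uri]

    @property
    def root(self) -> LinNode:
        return self.nodes[ROOT_NODE_ID]

    def node_for_uri(self, uri: str) -> Optional[LinNode]:
        node_id = self._by_source.get(uri)
        return self.nodes[node_id] if node_id is not None else None

    def source_uris(self) -> set[str]:
        return {n.source_uri for n in self.nodes.values() if n.source_uri is not None}

    def depth(self, node_id: str) -> int:
        """Levels below the root node (root = 0, chapter = 1)."""
        d = 0
        node = self.nodes[node_id]
        while node.parent_id is not None:
            node = self.nodes[node.parent_id]
            d += 1
        return d

    def walk(self) -> Iterator[LinNode]:
        """Depth-first, children in stored (deterministic) order."""
        stack = [ROOT_NODE_ID]
        while stack:
            node_id = stack.pop()
            yield self.nodes[node_id]
            stack.extend(reversed(self.children[node_id]))

    def copy(self) -> "Linearization":
        return copy.deepcopy(self)


# -- primary-parent selection ---------------------------------------------


def select_primary_parent(
    foundation: Foundation, uri: str, config: LinearizationConfig
) -> str:
    """The single parent a concept inherits from in this linearization.

    An explicit override wins; otherwise the first parent under the
    deterministic sibling-order convention.  The result is always one of the
    concept's actual Foundation parents.
    """
    parents = foundation.get(uri).parent_uris
    if not parents:
        raise ConfigurationError(f"{uri!r} has no parents to select from")
    override = config.primary_parent_overrides.get(uri)
    if override is not None:
        if override not in parents:
            raise ConfigurationError(
                f"override for {uri!r} names {override!r}, not one of its parents"
            )
        return override
    return foundation.sorted_parents(uri)[0]


def chapter_closure(foundation: Foundation, config: LinearizationConfig) -> set[str]:
    """All URIs under the linearized chapters (chapters included)."""
    closure: set[str] = set()
    for chapter in config.chapter_uris:
        closure.add(chapter)
        closure |= foundation.descendants(chapter)
    return closure


def _validate_config(foundation: Foundation, config: LinearizationConfig) -> None:
    for chapter in config.chapter_uris:
        if chapter not in foundation:
            raise ConfigurationError(f"chapter {chapter!r} not in foundation")
    for child, parent in config.primary_parent_overrides.items():
        if child not in foundation:
            raise ConfigurationError(f"override child {child!r} not in foundation")
        if parent not in foundation.get(child).parent_uris:
            raise ConfigurationError(
                f"override for {child!r} names {parent!r}, not one of its parents"
            )


def derive_linearization(
    foundation: Foundation, config: LinearizationConfig
) -> Linearization:
    """Derive the strict single-parent tree for ``config``.

    Each above-shoreline concept appears exactly once, under its primary
    parent.  Above-shoreline membership is the depth rule (primary-parent
    chain from a chapter, depth <= ``max_depth``) unless ``include_uris``
    replaces it, in which case an included concept attaches under its nearest
    included ancestor along the primary chain.  Output is deterministic for
    fixed inputs.
    """
    _validate_config(foundation, config)
    closure = chapter_closure(foundation, config)
    chapters = set(config.chapter_uris)

    # Primary-child map restricted to the chapter closure.
    primary_children: dict[str, list[str]] = {uri: [] for uri in closure}
    for uri in closure:
        if uri in chapters:
            continue
        parent = select_primary_parent(foundation, uri, config)
        if parent in closure:
            primary_children[parent].append(uri)
    for uri in primary_children:
        primary_children[uri].sort(key=lambda c: sibling_key(foundation.get(c)))

    lin = Linearization(config, foundation_ref=foundation.root_uri)
    root_entity = foundation.get(foundation.root_uri)
    lin.add_node(
        LinNode(node_id=ROOT_NODE_ID, label=root_entity.title(), source_uri=foundation.root_uri)
    )

    include = config.include_uris

    def admit(uri: str, depth: int) -> bool:
        if uri in chapters:
            return True
        if include is not None:
            return uri in include
        return depth <= config.max_depth

    # Depth-first from each chapter; an excluded node's included descendants
    # attach to the nearest included ancestor (relevant with include_uris).
    for chapter in config.chapter_uris:
        entity = foundation.get(chapter)
        chapter_node = lin.add_node(
            LinNode(node_id=chapter, label=entity.title(), source_uri=chapter,
                    parent_id=ROOT_NODE_ID)
        )
        stack: list[tuple[str, int, str]] = [
            (child, 2, chapter_node.node_id)
            for child in reversed(primary_children[chapter])
        ]
        while stack:
            uri, depth, attach_id = stack.pop()
            if lin.node_for_uri(uri) is not None:
                continue  # already placed via an earlier chapter
            if admit(uri, depth):
                node = lin.add_node(
                    LinNode(
                        node_id=uri,
                        label=foundation.get(uri).title(),
                        source_uri=uri,
                        parent_id=attach_id,
                    )
                )
                attach_below = node.node_id
                descend = include is not None or depth < config.max_depth
            else:
                attach_below = attach_id
                descend = include is not None  # depth rule prunes whole branch
            if descend:
                for child in reversed(primary_children[uri]):
                    stack.append((child, depth + 1, attach_below))
    return lin


# -- residual categories ---------------------------------------------------


def _residual_id(parent_id: str, kind: str) -> str:
    return f"{parent_id}//{kind}"


def residual_label(parent_label: str, kind: str) -> str:
    if kind == RESIDUAL_OTHER:
        return f"Other specified {parent_label}"
    return f"{parent_label}, unspecified"


def insert_residuals(linearization: Linearization, foundation: Foundation) -> Linearization:
    """Add "Other specified" and "unspecified" children on every branch.

    A node gains the two residual children when it has at least one
    non-residual child in the tree, or when its source concept has
    Foundation descendants that are not rendered (below the shoreline) —
    either way unlisted content exists below it.  A node that is a leaf in
    the Foundation too gains none: it is already fully specific.  Nodes at
    the depth limit gain none either — a residual child there would not fit
    the fixed-digit code space; their unlisted content is absorbed by an
    ancestor's residual instead.  Kinds the source entity suppresses are
    never added.  The virtual root is skipped — it is not a classification
    category and has no code slot for residual siblings of chapters.
    Idempotent: residuals already present are kept, not doubled.
    """
    lin = linearization.copy()
    above = lin.source_uris()
    for node_id in list(lin.nodes):
        node = lin.nodes[node_id]
        if node.is_residual or node_id == ROOT_NODE_ID:
            continue
        if lin.depth(node_id) >= lin.config.max_depth:
            continue
        ordinary = [c for c in lin.children[node_id] if not lin.nodes[c].is_residual]
        unlisted_below = node.source_uri is not None and any(
            d not in above for d in foundation.descendants(node.source_uri)
        )
        if not ordinary and not unlisted_below:
            continue
        suppressed = (
            foundation.get(node.source_uri).residual_suppression
            if node.source_uri is not None and node.source_uri in foundation
            else frozenset()
        )
        for kind in (RESIDUAL_OTHER, RESIDUAL_UNSPEC):
            if kind in suppressed:
                continue
            rid = _residual_id(node_id, kind)
            if rid in lin.nodes:
                continue
            lin.add_node(
                LinNode(
                    node_id=rid,
                    label=residual_label(node.label, kind),
                    source_uri=None,
                    residual_kind=kind,
                    parent_id=node_id,
                )
            )
    return lin


def residual_child(linearization: Linearization, node_id: str, kind: str) -> Optional[LinNode]:
    rid = _residual_id(node_id, kind)
    return linearization.nodes.get(rid)


# -- shoreline -------------------------------------------------------------


@dataclass(frozen=True)
class ShorelineReport:
    """Partition of the chapter closure into concepts rendered in the
    linearization (*above* the shoreline) and Foundation-only ones (*below*)."""

    above: frozenset[str]
    below: frozenset[str]


def shoreline_partition(
    foundation: Foundation, linearization: Linearization
) -> ShorelineReport:
    """Split the chapter closure by presence as a non-residual node."""
    if linearization.foundation_ref != foundation.root_uri:
        raise MismatchError(
            "linearization was derived from a different foundation"
        )
    closure = chapter_closure(foundation, linearization.config)
    above = linearization.source_uris() - {foundation.root_uri}
    if not above <= closure:
        raise MismatchError("linearization contains URIs outside its chapter closure")
    return ShorelineReport(above=frozenset(above), below=frozenset(closure - above))


# -- residual routing (shared with coding) ---------------------------------


def nearest_above_shoreline_ancestor(
    foundation: Foundation, linearization: Linearization, uri: str
) -> Optional[LinNode]:
    """Closest Foundation ancestor of ``uri`` rendered in the linearization.

    Breadth-first over parent links, each level visited in the deterministic
    sibling order, so ties resolve reproducibly.
    """
    seen: set[str] = {uri}
    frontier = list(foundation.sorted_parents(uri))
    while frontier:
        for cand in frontier:
            node = linearization.node_for_uri(cand)
            if node is not None and cand != foundation.root_uri:
                return node
        nxt: list[tuple[tuple, str]] = []
        level_seen: set[str] = set()
        for cand in frontier:
            for parent in foundation.sorted_parents(cand):
                if parent not in seen and parent not in level_seen:
                    level_seen.add(parent)
                    nxt.append((sibling_key(foundation.get(parent)), parent))
        seen |= level_seen
        frontier = [u for _, u in sorted(nxt)]
    return None


def residual_target_node(
    foundation: Foundation, linearization: Linearization, uri: str
) -> Optional[LinNode]:
    """The residual node that codes a below-shoreline concept.

    Starting from the nearest above-shoreline ancestor, walk up the
    linearization until some node offers a residual child, preferring
    ``other_specified`` (the concept *is* specified, just not listed) and
    falling back to ``unspecified`` where the former is suppressed.  ``None``
    means the concept is uncodable — an exhaustiveness failure.
    """
    anchor = nearest_above_shoreline_ancestor(foundation, linearization, uri)
    node = anchor
    while node is not None:
        for kind in (RESIDUAL_OTHER, RESIDUAL_UNSPEC):
            hit = residual_child(linearization, node.node_id, kind)
            if hit is not None:
                return hit
        node = (
            linearization.nodes[node.parent_id]
            if node.parent_id is not None and node.parent_id != ROOT_NODE_ID
            else None
        )
    return None


# -- statistical-classification properties ---------------------------------


@dataclass(frozen=True)
class PropertyReport:
    """Whether a linearization behaves as a statistical classification:
    mutually exclusive (no concept twice) and exhaustive (every closure
    concept codable, directly or via a residual)."""

    mutually_exclusive: bool
    duplicate_uris: tuple[str, ...]
    exhaustive: bool
    uncovered_uris: tuple[str, ...]


def verify_statistical_properties(
    linearization: Linearization, foundation: Foundation
) -> PropertyReport:
    counts: dict[str, int] = {}
    for node in linearization.nodes.values():
        if node.source_uri is not None and node.node_id != ROOT_NODE_ID:
            counts[node.source_uri] = counts.get(node.source_uri, 0) + 1
    duplicates = tuple(sorted(u for u, c in counts.items() if c > 1))

    closure = chapter_closure(foundation, linearization.config)
    above = linearization.source_uris()
    uncovered = []
    for uri in sorted(closure):
        if uri in above:
            continue
        if residual_target_node(foundation, linearization, uri) is None:
            uncovered.append(uri)
    return PropertyReport(
        mutually_exclusive=not duplicates,
        duplicate_uris=duplicates,
        exhaustive=not uncovered,
        uncovered_uris=tuple(uncovered),
    )
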