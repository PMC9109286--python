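"""Fixed-digit hierarchical codes and the thesaurus search index.

A linearization is numbered with fixed-digit alphanumeric codes: one symbol
for the chapter and one two-symbol pair per level below it, so a node at full
depth (chapter + 3 levels) carries a seven-character code.  A child's code
extends its parent's code as a prefix; the pairs ``ZY``/``ZZ`` at the top of
the pair space are reserved for the two residual categories, leaving
34² − 2 = 1154 ordinary sibling slots per level.  Any concept of the chapter
closure — above or below the shoreline — maps to exactly one code.

The same module builds the word-completion index over titles, fully
specified names and synonyms; the functional index of the classification is
built from the Foundation, not from any single tabulation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .foundation import Foundation, UnknownUriError
from .linearize import (
    ROOT_NODE_ID,
    Linearization,
    RESIDUAL_OTHER,
    chapter_closure,
    residual_target_node,
)

__all__ = [
    "CodingScheme",
    "CodeAssignment",
    "CodingError",
    "SiblingOverflowError",
    "DepthOverflowError",
    "UnknownCodeError",
    "ExhaustivenessError",
    "assign_codes",
    "encode_entity",
    "decode_code",
    "SearchIndex",
    "SearchHit",
    "build_search_index",
    "suggest",
    "tokenize",
]


class CodingError(Exception):
    pass


class SiblingOverflowError(CodingError):
    """More ordinary siblings than the pair space can number."""


class DepthOverflowError(CodingError):
    """A node lies deeper than the fixed-digit code capacity."""


class UnknownCodeError(CodingError, KeyError):
    pass


class ExhaustivenessError(CodingError):
    """A concept of the closure has no code — no residual is available."""


# Uppercase alphabet without O and I (confusable with 0 and 1): 34 symbols.
_DEFAULT_ALPHABET = "0123456789ABCDEFGHJKLMNPQRSTUVWXYZ"


@dataclass(frozen=True)
class CodingScheme:
    """Geometry of the fixed-digit code space.

    Defaults give the seven-character scheme: 1 chapter symbol + 2 symbols per
    level × 3 levels.  The display dot after the fourth character is cosmetic;
    canonical codes are dotless.
    """

    alphabet: str = _DEFAULT_ALPHABET
    chapter_chars: int = 1
    chars_per_level: int = 2
    max_levels: int = 3
    other_specified_pair: str = "ZY"
    unspecified_pair: str = "ZZ"
    display_dot_after: int = 4

    @property
    def base(self) -> int:
        return len(self.alphabet)

    @property
    def full_code_length(self) -> int:
        return self.chapter_chars + self.chars_per_level * self.max_levels

    @property
    def ordinary_capacity(self) -> int:
        """Ordinary sibling slots per level (reserved residual pairs excluded)."""
        return self.base ** self.chars_per_level - 2

    def pair(self, index: int) -> str:
        if index >= self.ordinary_capacity:
            raise SiblingOverflowError(
                f"sibling index {index} exceeds capacity {self.ordinary_capacity}"
            )
        symbols = []
        for _ in range(self.chars_per_level):
            symbols.append(self.alphabet[index % self.base])
            index //= self.base
        return "".join(reversed(symbols))

    def display(self, code: str) -> str:
        if len(code) > self.display_dot_after:
            return code[: self.display_dot_after] + "." + code[self.display_dot_after:]
        return code


DEFAULT_SCHEME = CodingScheme()


@dataclass
class CodeAssignment:
    """Bijection between linearization nodes and code strings."""

    scheme: CodingScheme
    code_of: dict[str, str] = field(default_factory=dict)
    node_of: dict[str, str] = field(default_factory=dict)

    def code(self, node_id: str) -> str:
        return self.code_of[node_id]


def assign_codes(
    linearization: Linearization, scheme: CodingScheme = DEFAULT_SCHEME
) -> CodeAssignment:
    """Number the tree: chapters get single symbols in configuration order,
    each level below appends one pair per ordinary sibling index; residuals
    always take their reserved pairs.  Raises on sibling or depth overflow."""
    assignment = CodeAssignment(scheme=scheme)

    def put(node_id: str, code: str) -> None:
        assignment.code_of[node_id] = code
        assignment.node_of[code] = node_id

    chapters = linearization.children[ROOT_NODE_ID]
    if len(chapters) > scheme.base:
        raise SiblingOverflowError(
            f"{len(chapters)} chapters exceed the {scheme.base}-symbol alphabet"
        )

    def assign_children(node_id: str, prefix: str) -> None:
        ordinary_index = 0
        for child_id in linearization.children[node_id]:
            child = linearization.nodes[child_id]
            if child.is_residual:
                pair = (
                    scheme.other_specified_pair
                    if child.residual_kind == RESIDUAL_OTHER
                    else scheme.unspecified_pair
                )
            else:
                pair = scheme.pair(ordinary_index)
                ordinary_index += 1
            code = prefix + pair
            if len(code) > scheme.full_code_length:
                raise DepthOverflowError(
                    f"node {child_id!r} needs a {len(code)}-character code; "
                    f"capacity is {scheme.full_code_length}"
                )
            put(child_id, code)
            assign_children(child_id, code)

    for i, chapter_id in enumerate(chapters):
        if linearization.nodes[chapter_id].is_residual:
            raise CodingError("residual node at chapter level has no code slot")
        code = scheme.alphabet[i] * scheme.chapter_chars
        put(chapter_id, code)
        assign_children(chapter_id, code)
    return assignment


def encode_entity(
    foundation: Foundation,
    linearization: Linearization,
    assignment: CodeAssignment,
    uri: str,
) -> str:
    """The unique code of any concept in the linearized chapter closure.

    Above the shoreline the concept's own node code is returned; below it,
    the residual code of the nearest rendered ancestor (``other_specified``
    preferred, ``unspecified`` where that kind is suppressed).  Exactly one
    code exists per concept — the mutual-exclusivity guarantee at coding
    level.
    """
    foundation.get(uri)  # raises UnknownUriError
    node = linearization.node_for_uri(uri)
    if node is not None and node.node_id != ROOT_NODE_ID:
        return assignment.code_of[node.node_id]
    if uri not in chapter_closure(foundation, linearization.config):
        raise UnknownUriError(f"{uri!r} is outside the linearized chapters")
    target = residual_target_node(foundation, linearization, uri)
    if target is None:
        raise ExhaustivenessError(
            f"{uri!r} has no residual category available — linearization not exhaustive"
        )
    return assignment.code_of[target.node_id]


def decode_code(assignment: CodeAssignment, code: str) -> str:
    """Node id for a code, accepting the display form with a dot."""
    canonical = code.replace(".", "")
    try:
        return assignment.node_of[canonical]
    except KeyError:
        raise UnknownCodeError(code) from None


# -- thesaurus index -------------------------------------------------------

_TOKEN_RE = re.compile(r"[^0-9a-z]+")


def tokenize(text: str) -> list[str]:
    """Case-folded, punctuation-stripped, whitespace-split tokens."""
    return [t for t in _TOKEN_RE.split(text.casefold()) if t]


@dataclass
class SearchIndex:
    """Inverted token index over titles, fully specified names and synonyms.

    ``postings`` maps each token to the sorted URIs containing it;
    ``titles`` keeps the English title for deterministic ranking.
    """

    postings: dict[str, tuple[str, ...]] = field(default_factory=dict)
    titles: dict[str, str] = field(default_factory=dict)
    _sorted_tokens: tuple[str, ...] = ()

    def tokens_of(self, uri: str) -> set[str]:
        return {t for t, uris in self.postings.items() if uri in uris}


@dataclass(frozen=True)
class SearchHit:
    uri: str
    title: str
    matched_tokens: int


def build_search_index(foundation: Foundation) -> SearchIndex:
    """Index every label-bearing field of every entity (root excluded)."""
    buckets: dict[str, set[str]] = {}
    titles: dict[str, str] = {}
    for uri, entity in foundation.entities.items():
        if uri == foundation.root_uri:
            continue
        titles[uri] = entity.title()
        for _field, _lang, text in entity.label_texts():
            for token in tokenize(text):
                buckets.setdefault(token, set()).add(uri)
    index = SearchIndex(
        postings={t: tuple(sorted(uris)) for t, uris in sorted(buckets.items())},
        titles=titles,
    )
    index._sorted_tokens = tuple(sorted(index.postings))
    return index


def suggest(index: SearchIndex, prefix: str, k: int) -> list[SearchHit]:
    """Word-completion query: entities holding a token with this prefix,
    ranked by matching-token count, then English title, then URI."""
    if k < 1:
        raise ValueError("k must be >= 1")
    prefix = prefix.casefold().strip()
    if not prefix:
        return []
    matches: dict[str, int] = {}
    for token in index._sorted_tokens:
        if token.startswith(prefix):
            for uri in index.postings[token]:
                matches[uri] = matches.get(uri, 0) + 1
    ranked = sorted(
        matches.items(), key=lambda item: (-item[1], index.titles[item[0]], item[0])
    )
    return [SearchHit(uri, index.titles[uri], n) for uri, n in ranked[:k]]
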