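"""Post-coordination: clinical "sentences" built from a stem plus extension
codes, validated by sanctioning rules and normalized against the
pre-coordination equivalence table.

A stem (e.g. gastric cancer) may be refined along axes — anatomy, histology,
severity, stage, extent — whose values come from the extension-code chapter.
Sanctioning rules state which axes each stem accepts and restrict the value
set to related subtrees (gastric cancer takes anatomy only from the stomach
region, not from limb anatomy).  Where a post-coordinated combination already
exists as a pre-coordinated entity, normalization replaces it with that
entity's single code, keeping one — and only one — way of capturing a
condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .coding import CodeAssignment, decode_code, encode_entity
from .foundation import Foundation, UnknownUriError
from .linearize import Linearization

__all__ = [
    "AxisDef",
    "SanctioningRuleSet",
    "PostcoordinatedExpression",
    "CodedExpression",
    "ValidationOutcome",
    "ExpressionError",
    "InvalidExpressionError",
    "ExpressionSyntaxError",
    "compose_expression",
    "validate_expression",
    "normalize_expression",
    "serialize_coded",
    "parse_coded",
    "serialize_expression",
    "parse_expression",
]

AXIS_NOT_SANCTIONED = "axis_not_sanctioned"
VALUE_OUTSIDE_SUBTREE = "value_outside_subtree"
DUPLICATE = "duplicate"


class ExpressionError(Exception):
    pass


class InvalidExpressionError(ExpressionError):
    def __init__(self, outcome: "ValidationOutcome"):
        self.outcome = outcome
        super().__init__(
            "; ".join(f"{axis}: {reason}" for axis, reason in outcome.violations)
        )


class ExpressionSyntaxError(ExpressionError):
    """Malformed expression text; ``position`` is the 0-based offset."""

    def __init__(self, message: str, position: int):
        self.position = position
        super().__init__(f"{message} at position {position}")


@dataclass(frozen=True)
class AxisDef:
    """One post-coordination axis and its global value domain (the descendant
    closure of extension-chapter roots).  ``multi_valued`` says whether a
    stem may carry several values on this axis at once."""

    axis_name: str
    value_root_uris: frozenset[str]
    multi_valued: bool = True


@dataclass
class SanctioningRuleSet:
    """Which axes may extend which stems, with per-stem value subtrees, plus
    the pre/post-coordination equivalence table.

    ``stem_rules[stem][axis]`` is the set of allowed value-root URIs; an
    extension value must fall inside the descendant-or-equal closure of one
    of them.  ``equivalences`` maps the canonical (stem, extension-set) key
    to the pre-coordinated entity URI.
    """

    axes: dict[str, AxisDef] = field(default_factory=dict)
    stem_rules: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)
    equivalences: dict[tuple[str, tuple[tuple[str, str], ...]], str] = field(
        default_factory=dict
    )

    def add_equivalence(
        self,
        stem_uri: str,
        extensions: Iterable[tuple[str, str]],
        precoordinated_uri: str,
    ) -> None:
        key = (stem_uri, _canonical(extensions))
        existing = self.equivalences.get(key)
        if existing is not None and existing != precoordinated_uri:
            raise ExpressionError(
                f"conflicting equivalence rows for {key!r}: "
                f"{existing!r} vs {precoordinated_uri!r}"
            )
        self.equivalences[key] = precoordinated_uri


@dataclass(frozen=True)
class PostcoordinatedExpression:
    """A stem plus canonical (axis, value) extensions — sorted, de-duplicated."""

    stem_uri: str
    extensions: tuple[tuple[str, str], ...] = ()

    @property
    def key(self) -> tuple[str, tuple[tuple[str, str], ...]]:
        return (self.stem_uri, self.extensions)


@dataclass(frozen=True)
class CodedExpression:
    """The final coding result: a stem code and coded extensions (empty when
    an equivalence row discharged the expression into a pre-coordinated
    code)."""

    stem_code: str
    extensions: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class ValidationOutcome:
    valid: bool
    violations: tuple[tuple[str, str], ...] = ()


def _canonical(extensions: Iterable[tuple[str, str]]) -> tuple[tuple[str, str], ...]:
    return tuple(sorted(set((str(a), str(v)) for a, v in extensions)))


def compose_expression(
    stem_uri: str, extensions: Sequence[tuple[str, str]] = ()
) -> PostcoordinatedExpression:
    """Build the canonical expression; composition is order-insensitive and
    idempotent (exact duplicate pairs collapse)."""
    return PostcoordinatedExpression(stem_uri=stem_uri, extensions=_canonical(extensions))


def validate_expression(
    expr: PostcoordinatedExpression,
    rules: SanctioningRuleSet,
    foundation: Foundation,
) -> ValidationOutcome:
    """Check every extension against the sanctioning rules.

    An extension fails with ``axis_not_sanctioned`` when the stem does not
    accept the axis at all, ``value_outside_subtree`` when the value is not in
    the descendant-or-equal closure of any allowed value root, and
    ``duplicate`` when a single-valued axis carries more than one value.
    All failures are reported, not just the first.
    """
    foundation.get(expr.stem_uri)
    for _axis, value in expr.extensions:
        foundation.get(value)

    stem_axes = rules.stem_rules.get(expr.stem_uri, {})
    violations: list[tuple[str, str]] = []
    per_axis_count: dict[str, int] = {}
    for axis, _value in expr.extensions:
        per_axis_count[axis] = per_axis_count.get(axis, 0) + 1

    for axis, value in expr.extensions:
        if axis not in stem_axes:
            violations.append((axis, AXIS_NOT_SANCTIONED))
            continue
        allowed_roots = stem_axes[axis]
        if not any(
            value == root or root in foundation.ancestors(value)
            for root in allowed_roots
        ):
            violations.append((axis, VALUE_OUTSIDE_SUBTREE))
    for axis, count in sorted(per_axis_count.items()):
        axis_def = rules.axes.get(axis)
        if axis_def is not None and not axis_def.multi_valued and count > 1:
            violations.append((axis, DUPLICATE))
    violations.sort()
    return ValidationOutcome(valid=not violations, violations=tuple(violations))


def normalize_expression(
    expr: PostcoordinatedExpression,
    rules: SanctioningRuleSet,
    foundation: Foundation,
    linearization: Linearization,
    assignment: CodeAssignment,
) -> CodedExpression:
    """Produce the final coding result for a valid expression.

    If the canonical (stem, extensions) matches an equivalence-table row the
    expression is discharged into the pre-coordinated entity's single code;
    otherwise the stem code is kept and each extension value is coded.
    Confluent: the result depends only on the canonical form.
    """
    expr = compose_expression(expr.stem_uri, expr.extensions)
    outcome = validate_expression(expr, rules, foundation)
    if not outcome.valid:
        raise InvalidExpressionError(outcome)
    precoordinated = rules.equivalences.get(expr.key)
    if precoordinated is not None:
        return CodedExpression(
            stem_code=encode_entity(foundation, linearization, assignment, precoordinated)
        )
    stem_code = encode_entity(foundation, linearization, assignment, expr.stem_uri)
    coded_ext = tuple(
        (axis, encode_entity(foundation, linearization, assignment, value))
        for axis, value in expr.extensions
    )
    return CodedExpression(stem_code=stem_code, extensions=coded_ext)


# -- text form --------------------------------------------------------------

_SEPARATOR = " & "


def serialize_coded(coded: CodedExpression) -> str:
    """Canonical text form: ``STEMCODE & axis=VALUECODE & …``."""
    clauses = [coded.stem_code]
    clauses.extend(f"{axis}={code}" for axis, code in coded.extensions)
    return _SEPARATOR.join(clauses)


def parse_coded(text: str) -> CodedExpression:
    """Inverse of :func:`serialize_coded`; reports the offset of the first
    malformed clause."""
    position = 0
    clauses: list[tuple[int, str]] = []
    for raw in text.split("&"):
        clauses.append((position, raw))
        position += len(raw) + 1
    if not clauses or not clauses[0][1].strip():
        raise ExpressionSyntaxError("empty stem clause", clauses[0][0] if clauses else 0)
    stem = clauses[0][1].strip()
    if "=" in stem:
        raise ExpressionSyntaxError("stem clause must not contain '='", clauses[0][0])
    extensions: list[tuple[str, str]] = []
    for offset, raw in clauses[1:]:
        clause = raw.strip()
        if not clause:
            raise ExpressionSyntaxError("empty extension clause", offset)
        if "=" not in clause:
            raise ExpressionSyntaxError("extension clause needs axis=VALUE", offset)
        axis, _, value = clause.partition("=")
        axis, value = axis.strip(), value.strip()
        if not axis or not value:
            raise ExpressionSyntaxError("axis and value must be non-empty", offset)
        extensions.append((axis, value))
    return CodedExpression(stem_code=stem, extensions=tuple(sorted(set(extensions))))


def serialize_expression(
    expr: PostcoordinatedExpression,
    foundation: Foundation,
    linearization: Linearization,
    assignment: CodeAssignment,
) -> str:
    """Code the expression's URIs and render the canonical text form (no
    equivalence normalization is applied — see :func:`normalize_expression`)."""
    expr = compose_expression(expr.stem_uri, expr.extensions)
    coded = CodedExpression(
        stem_code=encode_entity(foundation, linearization, assignment, expr.stem_uri),
        extensions=tuple(
            (axis, encode_entity(foundation, linearization, assignment, value))
            for axis, value in expr.extensions
        ),
    )
    return serialize_coded(coded)


def parse_expression(
    text: str,
    linearization: Linearization,
    assignment: CodeAssignment,
) -> PostcoordinatedExpression:
    """Parse the text form back to a URI-level expression.  Codes must decode
    to nodes with a Foundation source (a residual code has no single source
    concept and cannot be inverted)."""
    coded = parse_coded(text)

    def uri_for(code: str, offset: int) -> str:
        node = linearization.nodes[decode_code(assignment, code)]
        if node.source_uri is None:
            raise ExpressionSyntaxError(
                f"code {code!r} is a residual category and names no single concept",
                offset,
            )
        return node.source_uri

    stem_uri = uri_for(coded.stem_code, 0)
    extensions = [(axis, uri_for(code, 0)) for axis, code in coded.extensions]
    return compose_expression(stem_uri, extensions)
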