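"""Readers and writers: foundation JSON, ClaML, SKOS Turtle, TSV, and the
configuration / sanctioning-rules files.

All writers are deterministic — the same in-memory objects always produce
byte-identical UTF-8 files with LF line endings — so round-trip tests can
compare bytes.  The foundation JSON dialect is this package's canonical
interchange format; ClaML export is the pragmatic Class / SuperClass /
SubClass / Rubric subset sufficient for classification interchange.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Optional, Union

from lxml import etree

from .coding import CodeAssignment
from .foundation import EntityRecord, Foundation
from .linearize import ROOT_NODE_ID, Linearization, LinearizationConfig
from .postcoord import AxisDef, SanctioningRuleSet

__all__ = [
    "FOUNDATION_FORMAT_VERSION",
    "SchemaError",
    "read_foundation_json",
    "write_foundation_json",
    "write_claml",
    "read_claml_tree",
    "write_skos_ttl",
    "write_tsv",
    "read_linearization_config",
    "write_linearization_config",
    "read_sanctioning_rules",
    "write_sanctioning_rules",
]

FOUNDATION_FORMAT_VERSION = 1

PathLike = Union[str, Path]


class SchemaError(ValueError):
    """A structural problem in an input file; ``pointer`` is the JSON-pointer
    path of the offending element."""

    def __init__(self, message: str, pointer: str):
        self.pointer = pointer
        super().__init__(f"{message} (at {pointer})")


# -- foundation JSON -------------------------------------------------------

_OPTIONAL_LIST_FIELDS = (
    "body_system",
    "manifestations",
    "etiology",
    "genomic_association",
    "severity",
    "temporality",
    "functional_impact",
)


def _entity_to_dict(entity: EntityRecord) -> dict[str, Any]:
    out: dict[str, Any] = {
        "uri": entity.uri,
        "concept_title": dict(sorted(entity.concept_title.items())),
        "fully_specified_name": dict(sorted(entity.fully_specified_name.items())),
        "brief_definition": entity.brief_definition,
        "parent_uris": list(entity.parent_uris),
    }
    if entity.synonyms:
        out["synonyms"] = {k: list(v) for k, v in sorted(entity.synonyms.items())}
    if entity.classification_kind is not None:
        out["classification_kind"] = entity.classification_kind
    if entity.long_description is not None:
        out["long_description"] = entity.long_description
    for name in _OPTIONAL_LIST_FIELDS:
        value = getattr(entity, name)
        if value is not None:
            out[name] = list(value)
    if entity.sibling_rank is not None:
        out["sibling_rank"] = entity.sibling_rank
    if entity.residual_suppression:
        out["residual_suppression"] = sorted(entity.residual_suppression)
    return out


def _require(obj: dict, key: str, typ, pointer: str):
    if key not in obj:
        raise SchemaError(f"missing required key {key!r}", pointer)
    value = obj[key]
    if not isinstance(value, typ):
        raise SchemaError(
            f"key {key!r} must be {typ.__name__}, got {type(value).__name__}",
            f"{pointer}/{key}",
        )
    return value


def _entity_from_dict(obj: Any, pointer: str) -> EntityRecord:
    if not isinstance(obj, dict):
        raise SchemaError("entity must be an object", pointer)
    uri = _require(obj, "uri", str, pointer)
    title = _require(obj, "concept_title", dict, pointer)
    fsn = _require(obj, "fully_specified_name", dict, pointer)
    parents = _require(obj, "parent_uris", list, pointer)
    return EntityRecord(
        uri=uri,
        concept_title={str(k): str(v) for k, v in title.items()},
        fully_specified_name={str(k): str(v) for k, v in fsn.items()},
        brief_definition=str(obj.get("brief_definition", "")),
        synonyms={
            str(k): [str(x) for x in v] for k, v in obj.get("synonyms", {}).items()
        },
        classification_kind=obj.get("classification_kind"),
        parent_uris=tuple(str(p) for p in parents),
        long_description=obj.get("long_description"),
        sibling_rank=obj.get("sibling_rank"),
        residual_suppression=frozenset(obj.get("residual_suppression", ())),
        **{
            name: (list(obj[name]) if name in obj else None)
            for name in _OPTIONAL_LIST_FIELDS
        },
    )


def write_foundation_json(foundation: Foundation, path: PathLike) -> None:
    """Write the canonical dialect: sorted keys, entities sorted by URI."""
    payload = {
        "format_version": FOUNDATION_FORMAT_VERSION,
        "root_uri": foundation.root_uri,
        "entities": [
            _entity_to_dict(foundation.entities[uri])
            for uri in sorted(foundation.entities)
        ],
    }
    text = json.dumps(payload, indent=2, sort_keys=True, ensure_ascii=False) + "\n"
    Path(path).write_text(text, encoding="utf-8", newline="\n")


def read_foundation_json(path: PathLike) -> Foundation:
    """Read and validate; schema problems carry JSON-pointer paths and
    Foundation-invariant problems raise with the full validation report."""
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}", "") from exc
    if not isinstance(payload, dict):
        raise SchemaError("top level must be an object", "")
    version = _require(payload, "format_version", int, "")
    if version != FOUNDATION_FORMAT_VERSION:
        raise SchemaError(f"unsupported format_version {version}", "/format_version")
    root_uri = _require(payload, "root_uri", str, "")
    entities_raw = _require(payload, "entities", list, "")
    entities = [
        _entity_from_dict(obj, f"/entities/{i}") for i, obj in enumerate(entities_raw)
    ]
    return Foundation.from_entities(root_uri, entities)


# -- ClaML ------------------------------------------------------------------


def write_claml(
    linearization: Linearization,
    assignment: CodeAssignment,
    foundation: Foundation,
    path: PathLike,
) -> None:
    """Export the coded tree as ClaML: one ``Class`` per coded node with
    ``SuperClass``/``SubClass`` links and ``preferred`` / ``definition``
    rubrics.  Residual categories export like ordinary classes, with their
    generated labels and no definition."""
    root = etree.Element("ClaML", version="2.0.0")
    title = etree.SubElement(
        root, "Title", name=linearization.config.name, version="1"
    )
    title.text = f"Linearization {linearization.config.name}"

    coded_nodes = [
        node
        for node in linearization.walk()
        if node.node_id != ROOT_NODE_ID
    ]
    for node in coded_nodes:
        if node.node_id not in assignment.code_of:
            raise ValueError(f"node {node.node_id!r} has no code")
    for node in coded_nodes:
        code = assignment.code_of[node.node_id]
        cls = etree.SubElement(root, "Class", code=code, kind="category")
        if node.parent_id is not None and node.parent_id != ROOT_NODE_ID:
            etree.SubElement(
                cls, "SuperClass", code=assignment.code_of[node.parent_id]
            )
        for child_id in linearization.children[node.node_id]:
            etree.SubElement(cls, "SubClass", code=assignment.code_of[child_id])
        rubric = etree.SubElement(cls, "Rubric", kind="preferred")
        label = etree.SubElement(rubric, "Label")
        label.set("{http://www.w3.org/XML/1998/namespace}lang", "en")
        label.text = node.label
        definition = (
            foundation.get(node.source_uri).brief_definition
            if node.source_uri is not None and node.source_uri in foundation
            else ""
        )
        if definition:
            rubric = etree.SubElement(cls, "Rubric", kind="definition")
            label = etree.SubElement(rubric, "Label")
            label.set("{http://www.w3.org/XML/1998/namespace}lang", "en")
            label.text = definition

    data = etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )
    Path(path).write_bytes(data)


def read_claml_tree(path: PathLike) -> dict[str, dict[str, Any]]:
    """Re-parse a ClaML export into ``code -> {label, parent_code, children}``
    for structural round-trip checks."""
    tree = etree.parse(str(path))
    out: dict[str, dict[str, Any]] = {}
    for cls in tree.getroot().iter("Class"):
        code = cls.get("code")
        superclass = cls.find("SuperClass")
        label = ""
        for rubric in cls.findall("Rubric"):
            if rubric.get("kind") == "preferred":
                label = rubric.findtext("Label") or ""
        out[code] = {
            "label": label,
            "parent_code": superclass.get("code") if superclass is not None else None,
            "children": tuple(sc.get("code") for sc in cls.findall("SubClass")),
        }
    return out


# -- SKOS Turtle ------------------------------------------------------------


def _ttl_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"').replace("\n", "\\n")


def _ttl_ref(uri: str) -> str:
    return f"<{uri}>"


def write_skos_ttl(foundation: Foundation, path: PathLike) -> None:
    """Write one ``skos:Concept`` per entity with ``prefLabel`` per language,
    ``altLabel`` per synonym, and ``broader``/``narrower`` triples mirroring
    the parent links.  The writer emits Turtle directly so output bytes are a
    pure function of the Foundation.
    """
    lines = [
        "@prefix skos: <http://www.w3.org/2004/02/skos/core#> .",
        "",
    ]
    for uri in sorted(foundation.entities):
        entity = foundation.entities[uri]
        preds: list[str] = ["a skos:Concept"]
        for lang, text in sorted(entity.concept_title.items()):
            preds.append(f'skos:prefLabel "{_ttl_escape(text)}"@{lang}')
        for lang, texts in sorted(entity.synonyms.items()):
            for text in texts:
                preds.append(f'skos:altLabel "{_ttl_escape(text)}"@{lang}')
        for parent in entity.parent_uris:
            preds.append(f"skos:broader {_ttl_ref(parent)}")
        for child in foundation.children(uri):
            preds.append(f"skos:narrower {_ttl_ref(child)}")
        lines.append(_ttl_ref(uri))
        for i, pred in enumerate(preds):
            sep = " ;" if i < len(preds) - 1 else " ."
            lines.append(f"    {pred}{sep}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8", newline="\n")


# -- TSV --------------------------------------------------------------------

_TSV_HEADER = ("code", "depth", "label", "source_uri", "residual_kind", "parent_code")


def write_tsv(
    linearization: Linearization, assignment: CodeAssignment, path: PathLike
) -> None:
    """Flat table of the coded tree, one row per coded node, in code order.
    Residual rows carry an empty ``source_uri``."""
    rows = []
    for node in linearization.walk():
        if node.node_id == ROOT_NODE_ID:
            continue
        code = assignment.code_of[node.node_id]
        parent_code = (
            assignment.code_of[node.parent_id]
            if node.parent_id is not None and node.parent_id != ROOT_NODE_ID
            else ""
        )
        rows.append(
            (
                code,
                str(linearization.depth(node.node_id)),
                node.label,
                node.source_uri or "",
                node.residual_kind,
                parent_code,
            )
        )
    rows.sort(key=lambda r: r[0])
    lines = ["\t".join(_TSV_HEADER)]
    lines.extend("\t".join(row) for row in rows)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


# -- linearization config ----------------------------------------------------


def write_linearization_config(config: LinearizationConfig, path: PathLike) -> None:
    import yaml

    payload = {
        "name": config.name,
        "max_depth": config.max_depth,
        "chapters": list(config.chapter_uris),
        "primary_parent_overrides": dict(sorted(config.primary_parent_overrides.items())),
    }
    if config.include_uris is not None:
        payload["include"] = sorted(config.include_uris)
    Path(path).write_text(
        yaml.safe_dump(payload, sort_keys=True, default_flow_style=False),
        encoding="utf-8",
        newline="\n",
    )


def read_linearization_config(path: PathLike) -> LinearizationConfig:
    import yaml

    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(payload, dict):
        raise SchemaError("config must be a mapping", "")
    if "name" not in payload or "chapters" not in payload:
        raise SchemaError("config needs 'name' and 'chapters'", "")
    return LinearizationConfig(
        name=str(payload["name"]),
        chapter_uris=tuple(payload["chapters"]),
        max_depth=int(payload.get("max_depth", 4)),
        primary_parent_overrides=dict(payload.get("primary_parent_overrides", {})),
        include_uris=(
            frozenset(payload["include"]) if payload.get("include") is not None else None
        ),
    )


# -- sanctioning rules -------------------------------------------------------


def write_sanctioning_rules(rules: SanctioningRuleSet, path: PathLike) -> None:
    import yaml

    payload = {
        "axes": [
            {
                "axis_name": axis.axis_name,
                "value_roots": sorted(axis.value_root_uris),
                "multi_valued": axis.multi_valued,
            }
            for _, axis in sorted(rules.axes.items())
        ],
        "stems": {
            stem: {axis: sorted(roots) for axis, roots in sorted(by_axis.items())}
            for stem, by_axis in sorted(rules.stem_rules.items())
        },
        "equivalences": [
            {
                "stem": stem,
                "extensions": [{"axis": a, "value": v} for a, v in extensions],
                "precoordinated": pre,
            }
            for (stem, extensions), pre in sorted(rules.equivalences.items())
        ],
    }
    Path(path).write_text(
        yaml.safe_dump(payload, sort_keys=True, default_flow_style=False),
        encoding="utf-8",
        newline="\n",
    )


def read_sanctioning_rules(path: PathLike) -> SanctioningRuleSet:
    import yaml

    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(payload, dict):
        raise SchemaError("rules file must be a mapping", "")
    axes = {
        a["axis_name"]: AxisDef(
            axis_name=a["axis_name"],
            value_root_uris=frozenset(a.get("value_roots", ())),
            multi_valued=bool(a.get("multi_valued", True)),
        )
        for a in payload.get("axes", ())
    }
    rules = SanctioningRuleSet(
        axes=axes,
        stem_rules={
            stem: {axis: frozenset(roots) for axis, roots in by_axis.items()}
            for stem, by_axis in payload.get("stems", {}).items()
        },
    )
    for row in payload.get("equivalences", ()):
        rules.add_equivalence(
            row["stem"],
            [(e["axis"], e["value"]) for e in row.get("extensions", ())],
            row["precoordinated"],
        )
    return rules
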