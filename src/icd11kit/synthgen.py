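"""Deterministic synthetic Foundations, sanctioning rules and the worked
gastric-cancer fixture.

Real classification content cannot ship with the package, so every test input
is generated here: depth-structured multi-parent concept graphs with
pronounceable pseudo-word labels and synonyms (so search is meaningful), an
extension-code chapter with anatomy / histology / severity subtrees, stem
sanctioning rules with subtree-restricted value sets, and equivalence rows
whose pre-coordinated side is a real specialized entity of the graph.  All
randomness flows from one integer seed through ``random.Random`` using
integer draws only, so the same seed yields byte-identical artifacts on any
platform.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .foundation import EntityRecord, Foundation, RESIDUAL_KINDS
from .linearize import LinearizationConfig
from .postcoord import AxisDef, SanctioningRuleSet

__all__ = [
    "SynthParams",
    "generate_foundation",
    "generate_sanctioning_rules",
    "default_config",
    "variant_config",
    "paper_fixture",
    "EXTENSION_CHAPTER_URI",
    "AXIS_SUBTREES",
]

EXTENSION_CHAPTER_URI = "urn:synth:ext"

#: axis name -> (subtree root uri, number of regions, values per region)
AXIS_SUBTREES = {
    "anatomy": ("urn:synth:ext:anatomy", 3, 4),
    "histology": ("urn:synth:ext:histology", 2, 4),
    "severity": ("urn:synth:ext:severity", 1, 4),
}

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"
_KINDS = ("disease", "syndrome", "symptom", "finding", "health_condition")


@dataclass(frozen=True)
class SynthParams:
    """Knobs of the generator.

    ``n_entities`` counts disease-side concepts (chapters and extension values
    excluded).  ``multiparent_probability`` is the chance that a concept gains
    one extra parent besides its primary one — extra parents always sit at a
    strictly shallower level, which keeps the graph acyclic by construction.
    ``max_foundation_depth`` is measured from the root (chapters are depth 1);
    set it above a linearization's ``max_depth`` to guarantee below-shoreline
    content.  ``suppression_probability`` is the chance a concept suppresses
    residual insertion for one or both kinds.
    """

    seed: int = 0
    n_entities: int = 200
    n_chapters: int = 5
    multiparent_probability: float = 0.3
    max_foundation_depth: int = 6
    extension_chapter: bool = True
    n_equivalences: int = 12
    suppression_probability: float = 0.05

    def __post_init__(self) -> None:
        if self.n_entities < 1 or self.n_chapters < 1:
            raise ValueError("counts must be positive")
        for p in (self.multiparent_probability, self.suppression_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.max_foundation_depth < 2:
            raise ValueError("max_foundation_depth must be >= 2")


def _bernoulli(rng: random.Random, p: float) -> bool:
    # integer draw only, for cross-platform reproducibility
    return rng.randrange(10**9) < int(round(p * 10**9))


def _word(rng: random.Random) -> str:
    n = 2 + rng.randrange(2)
    return "".join(
        _CONSONANTS[rng.randrange(len(_CONSONANTS))] + _VOWELS[rng.randrange(len(_VOWELS))]
        for _ in range(n)
    )


def _title(rng: random.Random) -> str:
    words = [_word(rng) for _ in range(1 + rng.randrange(2))]
    return " ".join(words).capitalize()


def _entity(
    rng: random.Random,
    uri: str,
    title: str,
    parents: tuple[str, ...],
    kind: str,
    *,
    synonyms: int = 0,
    rank: int | None = None,
    suppression: frozenset[str] = frozenset(),
) -> EntityRecord:
    syns = {"en": [f"{_title(rng)} ({title.lower()})" for _ in range(synonyms)]} if synonyms else {}
    return EntityRecord(
        uri=uri,
        concept_title={"en": title},
        fully_specified_name={"en": f"{title}, of the synthetic foundation"},
        brief_definition=f"Synthetic concept '{title}' generated for testing.",
        synonyms=syns,
        classification_kind=kind,
        parent_uris=parents,
        sibling_rank=rank,
        residual_suppression=suppression,
    )


def _add_extension_chapter(rng: random.Random, foundation: Foundation) -> None:
    foundation.add_entity(
        _entity(
            rng,
            EXTENSION_CHAPTER_URI,
            "Extension codes",
            (foundation.root_uri,),
            "chapter",
        )
    )
    for axis, (root_uri, n_regions, n_values) in AXIS_SUBTREES.items():
        foundation.add_entity(
            _entity(rng, root_uri, axis.capitalize(), (EXTENSION_CHAPTER_URI,), "extension_value")
        )
        for r in range(n_regions):
            region_uri = f"{root_uri}:r{r}"
            foundation.add_entity(
                _entity(rng, region_uri, f"{_title(rng)} region", (root_uri,), "extension_value")
            )
            for v in range(n_values):
                foundation.add_entity(
                    _entity(
                        rng,
                        f"{region_uri}:v{v}",
                        _title(rng),
                        (region_uri,),
                        "extension_value",
                    )
                )


def generate_foundation(params: SynthParams) -> Foundation:
    """Generate a valid Foundation: depth-structured chapters of multi-parent
    disease concepts, plus the extension chapter when flagged.

    Every concept gets one primary parent one level up; with
    ``multiparent_probability`` it gains a second parent at any strictly
    shallower level, so multiple inheritance is present but no directed cycle
    can form.  Fully reproducible per seed.
    """
    rng = random.Random(params.seed)
    foundation = Foundation("urn:synth:root", "Synthetic foundation root")

    by_depth: dict[int, list[str]] = {1: []}
    for c in range(params.n_chapters):
        uri = f"urn:synth:ch{c}"
        foundation.add_entity(
            _entity(rng, uri, f"Chapter {_title(rng)}", (foundation.root_uri,), "chapter", rank=c)
        )
        by_depth[1].append(uri)

    for i in range(params.n_entities):
        depth = 2 + rng.randrange(params.max_foundation_depth - 1)
        while not by_depth.get(depth - 1):
            depth -= 1
        parent_pool = by_depth[depth - 1]
        primary = parent_pool[rng.randrange(len(parent_pool))]
        parents = [primary]
        if _bernoulli(rng, params.multiparent_probability):
            shallow = [
                u
                for d in range(1, depth)
                for u in by_depth.get(d, ())
                if u != primary
            ]
            if shallow:
                parents.append(shallow[rng.randrange(len(shallow))])
        suppression: frozenset[str] = frozenset()
        if _bernoulli(rng, params.suppression_probability):
            pick = rng.randrange(3)
            suppression = frozenset(
                RESIDUAL_KINDS if pick == 2 else (RESIDUAL_KINDS[pick],)
            )
        rank = rng.randrange(1000) if _bernoulli(rng, 0.2) else None
        uri = f"urn:synth:e{i}"
        foundation.add_entity(
            _entity(
                rng,
                uri,
                _title(rng),
                tuple(parents),
                _KINDS[rng.randrange(len(_KINDS))],
                synonyms=rng.randrange(3),
                rank=rank,
                suppression=suppression,
            )
        )
        by_depth.setdefault(depth, []).append(uri)

    if params.extension_chapter:
        _add_extension_chapter(rng, foundation)
    return foundation


def default_config(
    foundation: Foundation, name: str = "mms", max_depth: int = 4
) -> LinearizationConfig:
    """Configuration covering every chapter (root child) with no overrides."""
    return LinearizationConfig(
        name=name,
        chapter_uris=tuple(foundation.children(foundation.root_uri)),
        max_depth=max_depth,
    )


def variant_config(
    foundation: Foundation,
    seed: int,
    name: str = "variant",
    max_depth: int = 4,
) -> LinearizationConfig:
    """A second linearization over the same Foundation: for every multi-parent
    concept, flip the primary parent away from the deterministic default with
    probability 1/2.  Used to exercise the multiple-simultaneous-linearization
    property."""
    rng = random.Random(seed)
    overrides: dict[str, str] = {}
    for uri in sorted(foundation.entities):
        parents = foundation.sorted_parents(uri)
        if len(parents) > 1 and rng.randrange(2):
            overrides[uri] = parents[1 + rng.randrange(len(parents) - 1)]
    return LinearizationConfig(
        name=name,
        chapter_uris=tuple(foundation.children(foundation.root_uri)),
        max_depth=max_depth,
        primary_parent_overrides=overrides,
    )


def generate_sanctioning_rules(
    foundation: Foundation, params: SynthParams
) -> SanctioningRuleSet:
    """Random sanctioning rules over the extension chapter.

    Each selected stem accepts a random non-empty subset of axes, with its
    value roots drawn inside the axis subtree ("limited to an area that makes
    sense").  Equivalence rows pair an existing specialized child entity with
    (parent stem + extensions) so normalization has real pre-coordinated
    targets; every row's post-coordinated side validates by construction.
    """
    if EXTENSION_CHAPTER_URI not in foundation:
        raise ValueError("foundation has no extension chapter")
    rng = random.Random(params.seed + 1)

    axes = {
        name: AxisDef(
            axis_name=name,
            value_root_uris=frozenset({root}),
            multi_valued=name not in ("severity", "stage"),
        )
        for name, (root, _, _) in AXIS_SUBTREES.items()
    }
    axis_names = sorted(axes)

    disease_uris = sorted(
        uri
        for uri, e in foundation.entities.items()
        if uri != foundation.root_uri
        and e.classification_kind not in ("chapter", "extension_value")
    )
    rules = SanctioningRuleSet(axes=axes)
    n_stems = min(len(disease_uris), max(10, len(disease_uris) // 3))
    stems = sorted(rng.sample(disease_uris, n_stems)) if disease_uris else []
    for stem in stems:
        chosen = [a for a in axis_names if _bernoulli(rng, 0.6)]
        if not chosen:
            chosen = [axis_names[rng.randrange(len(axis_names))]]
        per_axis: dict[str, frozenset[str]] = {}
        for axis in chosen:
            root, n_regions, _ = AXIS_SUBTREES[axis]
            if _bernoulli(rng, 0.5):
                per_axis[axis] = frozenset({root})
            else:
                per_axis[axis] = frozenset({f"{root}:r{rng.randrange(n_regions)}"})
        rules.stem_rules[stem] = per_axis

    # Equivalence rows: (stem + extensions) == an existing child of the stem.
    candidates = [
        (stem, child)
        for stem in stems
        for child in foundation.children(stem)
        if foundation.get(child).classification_kind != "extension_value"
    ]
    rng.shuffle(candidates)
    for stem, child in candidates:
        if len(rules.equivalences) >= params.n_equivalences:
            break
        extensions = []
        for axis, roots in sorted(rules.stem_rules[stem].items()):
            root = sorted(roots)[0]
            values = sorted({root} | foundation.descendants(root))
            extensions.append((axis, values[rng.randrange(len(values))]))
            if len(extensions) >= 2:
                break
        if not extensions:
            continue
        key = (stem, tuple(sorted(extensions)))
        if key in rules.equivalences:
            continue
        rules.add_equivalence(stem, extensions, child)
    return rules


# -- the worked multi-parent motif -----------------------------------------


def paper_fixture() -> tuple[Foundation, LinearizationConfig, SanctioningRuleSet]:
    """Small fixed foundation with the gastric-cancer motif.

    Stomach cancer is a child of both the neoplasms hierarchy and the
    digestive-disease chapter; an anatomy extension subtree carries a stomach
    region and an unrelated limb region; sanctioning restricts anatomy on
    gastric cancer to the stomach subtree; one equivalence row maps
    (gastric cancer + body-of-stomach anatomy) to the pre-coordinated
    "gastric cancer of body of stomach" entity.  The configuration linearizes
    stomach cancer once, under the neoplasms chapter.
    """
    f = Foundation("urn:fixture:root", "Fixture root")

    def add(uri, title, parents, kind, synonyms=(), suppression=frozenset()):
        f.add_entity(
            EntityRecord(
                uri=uri,
                concept_title={"en": title},
                fully_specified_name={"en": f"{title} (fully specified)"},
                brief_definition=f"{title}.",
                synonyms={"en": list(synonyms)} if synonyms else {},
                classification_kind=kind,
                parent_uris=tuple(parents),
                residual_suppression=frozenset(suppression),
            )
        )

    add("urn:fixture:neoplasms", "Neoplasms", [f.root_uri], "chapter")
    add("urn:fixture:digestive", "Diseases of the digestive system", [f.root_uri], "chapter")
    add("urn:fixture:extension", "Extension codes", [f.root_uri], "chapter")

    add(
        "urn:fixture:malignant-gi",
        "Malignant neoplasms of digestive organs",
        ["urn:fixture:neoplasms"],
        "disease",
    )
    add(
        "urn:fixture:stomach-disorders",
        "Disorders of the stomach",
        ["urn:fixture:digestive"],
        "disease",
    )
    add(
        "urn:fixture:stomach-cancer",
        "Gastric cancer",
        ["urn:fixture:malignant-gi", "urn:fixture:stomach-disorders"],
        "disease",
        synonyms=["Stomach cancer", "Malignant neoplasm of stomach"],
    )
    add(
        "urn:fixture:stomach-cancer-body",
        "Gastric cancer of body of stomach",
        ["urn:fixture:stomach-cancer"],
        "disease",
    )

    add("urn:fixture:anatomy", "Anatomy", ["urn:fixture:extension"], "extension_value")
    add("urn:fixture:stomach-region", "Stomach", ["urn:fixture:anatomy"], "extension_value")
    add("urn:fixture:stomach-body", "Body of stomach", ["urn:fixture:stomach-region"], "extension_value")
    add("urn:fixture:stomach-antrum", "Antrum of stomach", ["urn:fixture:stomach-region"], "extension_value")
    add("urn:fixture:limb", "Limb", ["urn:fixture:anatomy"], "extension_value")
    add("urn:fixture:forearm", "Forearm", ["urn:fixture:limb"], "extension_value")

    config = LinearizationConfig(
        name="mms",
        chapter_uris=(
            "urn:fixture:neoplasms",
            "urn:fixture:digestive",
            "urn:fixture:extension",
        ),
        max_depth=4,
        primary_parent_overrides={"urn:fixture:stomach-cancer": "urn:fixture:malignant-gi"},
    )

    rules = SanctioningRuleSet(
        axes={
            "anatomy": AxisDef(
                axis_name="anatomy",
                value_root_uris=frozenset({"urn:fixture:anatomy"}),
                multi_valued=True,
            )
        },
        stem_rules={
            "urn:fixture:stomach-cancer": {
                "anatomy": frozenset({"urn:fixture:stomach-region"})
            }
        },
    )
    rules.add_equivalence(
        "urn:fixture:stomach-cancer",
        [("anatomy", "urn:fixture:stomach-body")],
        "urn:fixture:stomach-cancer-body",
    )
    return f, config, rules
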