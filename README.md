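# icd11kit

A classification engine built on the architecture that modern revisions of the
International Classification of Diseases use: a **Foundation** — a single-rooted,
acyclic, *multi-parent* semantic network of medical concepts, each carrying a
content-model record (permanent URI, language-tagged titles, fully specified
name, synonyms, definitions) — from which strict single-parent
**linearizations** are derived for statistical tabulation. The library is for
people who build or study terminology infrastructure: it makes the whole
pipeline executable and testable — graph validation, primary-parent selection,
algorithmic **residual categories** ("Other specified …" / "…, unspecified"),
the **shoreline** partition between rendered and Foundation-only concepts,
fixed seven-digit hierarchical **codes**, a thesaurus index with word
completion, and **post-coordination** of stem codes with extension codes under
sanctioning rules and pre-coordination equivalence normalization.

## The model in brief

* The Foundation is a DAG `(V, E)` with a virtual root; a concept may have many
  parents (stomach cancer sits under both the neoplasms hierarchy and the
  digestive-disease chapter). Published hierarchy uses SKOS
  `broader`/`narrower` pairs, one inverse pair per parent link.
* A linearization chooses one *primary parent* per concept (explicit override,
  else a deterministic sibling-order default), yielding a tree over the
  concepts that fit a depth budget; everything deeper stays "below the
  shoreline" and is still codable through residual categories.
* Codes are fixed-digit: 1 chapter symbol + one 2-symbol pair per level over a
  34-symbol alphabet (0–9, A–Z without O/I), so full depth = 7 characters and
  each level offers 34² − 2 = 1154 ordinary slots — `ZY`/`ZZ` are reserved for
  the two residuals. A child's code extends its parent's as a prefix.
* A post-coordinated expression `stem + {(axis, value)…}` is valid when each
  axis is sanctioned for the stem and each value lies in the allowed value
  subtree; if an equivalent pre-coordinated entity exists, normalization
  replaces the expression by that entity's single code, keeping exactly one way
  to capture a condition.

No real WHO content ships here — a deterministic synthetic generator
(`icd11kit.synthgen`) produces Foundations, rules, and a small worked
gastric-cancer fixture.

## Worked example

```python
import icd11kit as k

foundation, config, rules = k.paper_fixture()
lin = k.insert_residuals(k.derive_linearization(foundation, config), foundation)
codes = k.assign_codes(lin)

print(k.encode_entity(foundation, lin, codes, "urn:fixture:stomach-cancer"))

expr = k.compose_expression(
    "urn:fixture:stomach-cancer", [("anatomy", "urn:fixture:stomach-body")]
)
print(k.serialize_expression(expr, foundation, lin, codes))
print(k.serialize_coded(k.normalize_expression(expr, rules, foundation, lin, codes)))
```

prints

```
00000
00000 & anatomy=2000101
0000000
```

`00000` is gastric cancer's own code (chapter `0` = Neoplasms, then two
2-symbol levels). The post-coordinated sentence "gastric cancer, anatomy =
body of stomach" serializes as a stem clause plus an `axis=VALUECODE` clause —
but because the rule set records an equivalent pre-coordinated entity
("Gastric cancer of body of stomach", code `0000000`), normalization
discharges the expression into that single code. An anatomy value from an
unrelated subtree (say the forearm, under limb anatomy) fails validation with
`value_outside_subtree`. The linearization places stomach cancer **once**,
under the neoplasms chapter, even though the Foundation gives it two parents;
branch by branch, residual children such as `00000ZY` ("Other specified
Gastric cancer") guarantee that every deeper Foundation concept still has a
code.

The same pipeline is scriptable from a shell:

```bash
icd11kit synth --seed 7 --entities 200 --out work/
icd11kit linearize work/foundation.json --config work/config.yaml --out work/lin/
icd11kit search work/foundation.json --prefix gast -k 5
icd11kit code-expression work/foundation.json --config work/config.yaml \
    --rules work/rules.yaml --expr "100 & anatomy=2000100"
```

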