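# Mechanism JSON format, version 1.0

One document per mechanism.  Top level:

```json
{
  "format_version": "1.0",
  "mechanism": {
    "mechanism_id": "alpha_amylase",
    "annotations": {
      "ec": ["3.2.1.1"],
      "cath": ["3.20.20.80"]
    },
    "steps": [ ... ]
  }
}
```

* `format_version` — string, `"1.0"`.
* `mechanism_id` — non-empty string, unique within a corpus; used as
  the node key in exports.
* `annotations` — optional free-form map, preserved verbatim.  The
  corpus tools read `ec` (list of EC number strings) and `cath` (list
  of CATH superfamily identifiers of catalytic domains).

Each step:

```json
{
  "step_index": 1,
  "atoms": [
    {"id": 1, "element": 8, "charge": -1},
    {"id": 2, "element": 6}
  ],
  "bonds": [
    {"atoms": [1, 2], "order": "single"}
  ],
  "arrows": [
    {
      "electrons": 2,
      "source": {"kind": "atom", "atoms": [1]},
      "sink":   {"kind": "incipient", "atoms": [1, 10]}
    }
  ]
}
```

* `step_index` — consecutive 1..n over the mechanism.
* `atoms` — `id` unique within the step, `element` atomic number
  (1–118), `charge` integer formal charge (omitted when 0).
  Hydrogens that take part in the chemistry are explicit.
* `bonds` — unordered atom pairs, at most one bond per pair, no
  self-bonds; `order` one of `single`, `double`, `triple`, `aromatic`
  (default `single`).  Aromatic is a first-class order; no
  kekulization is implied.
* `arrows` — at least one per step.  `electrons` is 1 or 2.  Endpoint
  `kind`:
  * `atom` — one atom id (lone pair or radical site; any atom as a
    sink);
  * `bond` — two atom ids of an existing bond;
  * `incipient` — two distinct atom ids **not** bonded in this step's
    state (sink only): the bond being formed.

  Source and sink must differ.

Writers must order atoms by `id`, bonds by their atom pair, and emit
keys sorted alphabetically, making output byte-stable; readers must
validate every invariant above and report all violations at once.
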