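{
  "format_version": "1.0",
  "mechanism": {
    "mechanism_id": "glycosylation_step",
    "steps": [
      {
        "arrows": [
          {
            "electrons": 2,
            "sink": {
              "atoms": [
                1,
                10
              ],
              "kind": "incipient"
            },
            "source": {
              "atoms": [
                1
              ],
              "kind": "atom"
            }
          },
          {
            "electrons": 2,
            "sink": {
              "atoms": [
                14,
                31
              ],
              "kind": "incipient"
            },
            "source": {
              "atoms": [
                10,
                14
              ],
              "kind": "bond"
            }
          },
          {
            "electrons": 2,
            "sink": {
              "atoms": [
                30
              ],
              "kind": "atom"
            },
            "source": {
              "atoms": [
                30,
                31
              ],
              "kind": "bond"
            }
          }
        ],
        "atoms": [
          {
            "charge": -1,
            "element": 8,
            "id": 1
          },
          {
            "element": 6,
            "id": 2
          },
          {
            "element": 8,
            "id": 3
          },
          {
            "element": 6,
            "id": 4
          },
          {
            "element": 1,
            "id": 5
          },
          {
            "element": 1,
            "id": 6
          },
          {
            "element": 6,
            "id": 10
          },
          {
            "element": 8,
            "id": 11
          },
          {
            "element": 6,
            "id": 12
          },
          {
            "element": 1,
            "id": 13
          },
          {
            "element": 8,
            "id": 14
          },
          {
            "element": 6,
            "id": 15
          },
          {
            "element": 6,
            "id": 16
          },
          {
            "element": 1,
            "id": 17
          },
          {
            "element": 8,
            "id": 18
          },
          {
            "element": 1,
            "id": 19
          },
          {
            "element": 6,
            "id": 20
          },
          {
            "element": 1,
            "id": 21
          },
          {
            "element": 6,
            "id": 22
          },
          {
            "element": 1,
            "id": 24
          },
          {
            "element": 1,
            "id": 25
          },
          {
            "element": 8,
            "id": 30
          },
          {
            "element": 1,
            "id": 31
          },
          {
            "element": 6,
            "id": 32
          },
          {
            "element": 8,
            "id": 33
          },
          {
            "element": 6,
            "id": 34
          },
          {
            "element": 1,
            "id": 35
          },
          {
            "element": 1,
            "id": 36
          }
        ],
        "bonds": [
          {
            "atoms": [
              1,
              2
            ],
            "order": "single"
          },
          {
            "atoms": [
              2,
              3
            ],
            "order": "double"
          },
          {
            "atoms": [
              2,
              4
            ],
            "order": "single"
          },
          {
            "atoms": [
              4,
              5
            ],
            "order": "single"
          },
          {
            "atoms": [
              4,
              6
            ],
            "order": "single"
          },
          {
            "atoms": [
              10,
              11
            ],
            "order": "single"
          },
          {
            "atoms": [
              10,
              12
            ],
            "order": "single"
          },
          {
            "atoms": [
              10,
              13
            ],
            "order": "single"
          },
          {
            "atoms": [
              10,
              14
            ],
            "order": "single"
          },
          {
            "atoms": [
              11,
              16
            ],
            "order": "single"
          },
          {
            "atoms": [
              12,
              17
            ],
            "order": "single"
          },
          {
            "atoms": [
              12,
              18
            ],
            "order": "single"
          },
          {
            "atoms": [
              12,
              20
            ],
            "order": "single"
          },
          {
            "atoms": [
              14,
              15
            ],
            "order": "single"
          },
          {
            "atoms": [
              15,
              21
            ],
            "order": "single"
          },
          {
            "atoms": [
              15,
              22
            ],
            "order": "single"
          },
          {
            "atoms": [
              16,
              24
            ],
            "order": "single"
          },
          {
            "atoms": [
              16,
              25
            ],
            "order": "single"
          },
          {
            "atoms": [
              18,
              19
            ],
            "order": "single"
          },
          {
            "atoms": [
              30,
              31
            ],
            "order": "single"
          },
          {
            "atoms": [
              30,
              32
            ],
            "order": "single"
          },
          {
            "atoms": [
              32,
              33
            ],
            "order": "double"
          },
          {
            "atoms": [
              32,
              34
            ],
            "order": "single"
          },
          {
            "atoms": [
              34,
              35
            ],
            "order": "single"
          },
          {
            "atoms": [
              34,
              36
            ],
            "order": "single"
          }
        ],
        "step_index": 1
      }
    ]
  }
}
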