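# Factor definitions for the packaged design fixtures.
#
# rsm: the four medium components varied in the 29-run Box-Behnken design
#      (coded -1/0/+1; center and halfwidth in g/L).
# pb:  the screening factors of the 12-run Plackett-Burman design, each at
#      two real levels (low/high -> coded -1/+1).  D1-D3 are dummy columns
#      carrying no real variable; their apparent effects estimate error.
rsm:
  columns_coded: true   # the fixture stores coded -1/0/+1 levels directly
  factors:
    - {name: kappa_carrageenan, unit: g/L, center: 2.0, halfwidth: 1.0, column: X1}
    - {name: NaCl, unit: g/L, center: 20.0, halfwidth: 5.0, column: X2}
    - {name: yeast_extract, unit: g/L, center: 1.0, halfwidth: 0.5, column: X3}
    - {name: FOS, unit: g/L, center: 1.0, halfwidth: 0.5, column: X4}
  responses:
    - {name: EA, unit: U/mL}
    - {name: BM, unit: OD600}
pb:
  factors:
    - {name: kappa_carrageenan, unit: g/L, low: 1.0, high: 2.5, column: A}
    - {name: FOS, unit: g/L, low: 0.5, high: 1.5, column: B}
    - {name: tryptone, unit: g/L, low: 0.5, high: 1.5, column: C}
    - {name: yeast_extract, unit: g/L, low: 1.0, high: 2.0, column: D}
    - {name: NaCl, unit: g/L, low: 10.0, high: 25.0, column: E}
    - {name: K2HPO4, unit: g/L, low: 0.1, high: 0.3, column: F}
    - {name: MgSO4, unit: g/L, low: 0.1, high: 0.3, column: G}
    - {name: CaCl2, unit: g/L, low: 0.1, high: 0.3, column: H}
  dummy_columns: [D1, D2, D3]
  responses:
    - {name: EA, unit: U/mL}
    - {name: BM, unit: OD600}
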