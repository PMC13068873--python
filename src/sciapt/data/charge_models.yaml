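# Packaged functional-charge models for phosphatidylserine (PS) and the five
# aptamer building blocks (ABBs).  Charges are in units of the elementary
# charge e.  The tokens "+delta" / "-delta" denote partial charges of
# magnitude `delta`, a single package-wide constant (default 0.2 e).
#
# Site order is the order along the 1D interaction axis before orientation;
# the lattice builder places the backbone phosphate (PO4-) nearest the
# interaction partner (override with orient_phosphate_inward: false).

delta: 0.2

lengths:
  a_Pu: 0.34      # purine axial size, nm (B-DNA axial rise)
  a_Py: 0.30      # pyrimidine axial size, nm
  ps_span: 0.90   # PS headgroup axial extent, nm

alphabet: [A, G, C, T, U]

molecules:
  PS:
    mol_class: lipid
    net_sign: negative
    sites:
      - {label: "PO4-", charge: -1.0}
      - {label: "NH3+", charge: 1.0}
      - {label: "CO2-", charge: -1.0}
  A:
    mol_class: purine
    net_sign: negative
    sites:
      - {label: "Hd+", charge: "+delta"}
      - {label: "Nd-", charge: "-delta"}
      - {label: "PO4-", charge: -1.0}
  G:
    mol_class: purine
    net_sign: negative
    sites:
      - {label: "Hd+", charge: "+delta"}
      - {label: "Hd+", charge: "+delta"}
      - {label: "Od-", charge: "-delta"}
      - {label: "PO4-", charge: -1.0}
  C:
    mol_class: pyrimidine
    net_sign: negative
    sites:
      - {label: "Hd+", charge: "+delta"}
      - {label: "Nd-", charge: "-delta"}
      - {label: "Od-", charge: "-delta"}
      - {label: "PO4-", charge: -1.0}
  T:
    mol_class: pyrimidine
    net_sign: negative
    sites:
      - {label: "Hd+", charge: "+delta"}
      - {label: "Od-", charge: "-delta"}
      - {label: "PO4-", charge: -1.0}
  U:
    mol_class: pyrimidine
    net_sign: negative
    sites:
      - {label: "Hd+", charge: "+delta"}
      - {label: "Od-", charge: "-delta"}
      - {label: "PO4-", charge: -1.0}
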