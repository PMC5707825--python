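{
  "_comment": "Van der Waals radii (Angstrom) per element, Tsai/Taylor/Chothia/Gerstein-style protein set. 'default' is used for elements not listed (metals, halides in ligands).",
  "C": 1.88,
  "N": 1.64,
  "O": 1.42,
  "S": 1.77,
  "P": 1.80,
  "SE": 1.90,
  "default": 1.80
}
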