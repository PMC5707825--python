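{
 "_comment": "Theoretical maximum side-chain SASA (A^2): side-chain SASA of X in an extended Gly-X-Gly tripeptide (phi -120, psi 130, all chi 180) built from ideal_geometry.json; Shrake-Rupley, probe 1.4 A, 960 points. Regenerate with scripts/make_geometry_table.py.",
 "A": 66.33,
 "C": 91.37,
 "D": 102.42,
 "E": 134.41,
 "F": 165.61,
 "H": 145.44,
 "I": 141.39,
 "K": 164.39,
 "L": 128.29,
 "M": 152.83,
 "N": 105.99,
 "P": 117.59,
 "Q": 139.61,
 "R": 205.65,
 "S": 75.93,
 "T": 105.96,
 "V": 115.76,
 "W": 204.15,
 "Y": 175.62
}
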