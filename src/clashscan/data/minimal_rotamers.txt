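# Minimal embedded side-chain rotamer library.
#
# Columns (whitespace-separated):
#   res_type  phi  psi  frequency  chi1 [chi2 chi3 chi4]
#
# res_type: three- or one-letter amino acid code.
# phi/psi:  backbone torsion of the row's bin centre in degrees, or "."
#           for a backbone-independent row.
# frequency: relative rotamer frequency within the residue type.
# chi*:     modal chi dihedrals in degrees; exactly as many values as the
#           residue type has chi angles (Ala/Gly rows carry none).
#
# This file ships canonical gauche-/trans/gauche+ chi modes with
# approximate literature-style frequencies so the package works offline.
# It is NOT a backbone-dependent statistical library; load a full
# Dunbrack-format file for production-grade frequency ordering.
ALA . . 1.0
GLY . . 1.0
SER . . 0.48 64
SER . . 0.29 -65
SER . . 0.23 180
CYS . . 0.50 -65
CYS . . 0.26 63
CYS . . 0.24 180
THR . . 0.49 60
THR . . 0.43 -60
THR . . 0.08 180
VAL . . 0.73 175
VAL . . 0.20 -64
VAL . . 0.07 64
ILE . . 0.60 -65 170
ILE . . 0.15 -65 -65
ILE . . 0.10 62 170
ILE . . 0.08 -177 170
ILE . . 0.04 -65 100
ILE . . 0.03 -177 66
LEU . . 0.59 -65 175
LEU . . 0.29 -177 65
LEU . . 0.05 -172 145
LEU . . 0.04 -85 65
LEU . . 0.02 65 175
PRO . . 0.55 28 -36
PRO . . 0.45 -26 36
ASP . . 0.51 -68 -15
ASP . . 0.23 -177 5
ASP . . 0.14 62 -10
ASP . . 0.07 -68 60
ASP . . 0.05 -177 65
ASN . . 0.30 -68 -25
ASN . . 0.22 -177 0
ASN . . 0.12 -68 120
ASN . . 0.12 62 -10
ASN . . 0.09 -177 60
ASN . . 0.08 -68 60
ASN . . 0.07 62 90
HIS . . 0.29 -65 -70
HIS . . 0.25 -65 165
HIS . . 0.20 -177 -165
HIS . . 0.13 -177 60
HIS . . 0.09 62 80
HIS . . 0.04 62 -75
PHE . . 0.44 -65 -85
PHE . . 0.33 -177 80
PHE . . 0.13 62 90
PHE . . 0.10 -65 -30
TYR . . 0.44 -65 -85
TYR . . 0.33 -177 80
TYR . . 0.13 62 90
TYR . . 0.10 -65 -30
TRP . . 0.32 -65 95
TRP . . 0.18 -177 -105
TRP . . 0.16 -177 105
TRP . . 0.15 -65 -5
TRP . . 0.11 62 -90
TRP . . 0.08 62 90
MET . . 0.20 -65 -65 -70
MET . . 0.18 -65 -65 100
MET . . 0.15 -65 180 75
MET . . 0.13 -65 180 180
MET . . 0.12 -177 180 75
MET . . 0.10 -177 180 180
MET . . 0.07 -177 65 75
MET . . 0.05 62 180 75
GLU . . 0.26 -65 180 -10
GLU . . 0.21 -177 180 0
GLU . . 0.15 -65 -65 -40
GLU . . 0.12 -177 65 10
GLU . . 0.10 -65 85 0
GLU . . 0.08 62 180 -10
GLU . . 0.08 -177 180 60
GLN . . 0.26 -65 180 -25
GLN . . 0.21 -177 180 0
GLN . . 0.15 -65 -65 -40
GLN . . 0.12 -177 65 10
GLN . . 0.10 -65 85 0
GLN . . 0.08 62 180 20
GLN . . 0.08 -65 180 100
LYS . . 0.25 -65 180 180 180
LYS . . 0.15 -177 180 180 180
LYS . . 0.10 -65 -68 180 180
LYS . . 0.09 -65 180 -68 180
LYS . . 0.08 -65 180 180 -65
LYS . . 0.08 -177 68 180 180
LYS . . 0.07 -177 180 68 180
LYS . . 0.06 62 180 180 180
LYS . . 0.06 -65 180 68 65
LYS . . 0.06 -65 -68 -68 180
ARG . . 0.19 -65 180 180 180
ARG . . 0.13 -65 180 180 85
ARG . . 0.12 -177 180 180 180
ARG . . 0.10 -65 180 65 85
ARG . . 0.09 -65 180 180 -85
ARG . . 0.08 -177 180 65 85
ARG . . 0.08 -65 -68 180 180
ARG . . 0.07 -177 180 180 85
ARG . . 0.07 62 180 180 180
ARG . . 0.07 -65 -68 -65 -85
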