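# clashscan

Fast steric-clash prediction for amino acid substitutions in protein
structures.

Many disease-causing missense variants are harmful simply because the new
side chain does not fit: it collides with surrounding atoms and forces a
local or global structural rearrangement. `clashscan` answers, for each
requested substitution in a PDB-format structure, whether **any common
side-chain rotamer** can be placed at the site without a steric clash.
It is aimed at structural bioinformaticians and variant analysts who need
a desk-scale, scriptable clash screen over many variants, and at protein
engineers screening candidate substitutions.

## Method

For every substitution the predictor first applies three fast assumptions:

1. **Glycine** fits at every position (no side chain to place).
2. At an **accessible** site — side-chain relative accessibility
   ≥ 0.5, where relative accessibility is the side-chain SASA divided by
   the residue type's theoretical maximum, and the original side chain has
   ≥ 3 heavy atoms — every substitution is assumed to fit.
3. A substitution to a **smaller** side chain (fewer heavy atoms) fits,
   except for short-but-branched targets (Val, Leu, Ile, Thr), which are
   still tested explicitly.

Everything else goes to rotamer testing. Candidate rotamers for the target
residue type are drawn from a backbone-dependent rotamer library at the
site's (φ, ψ) bin and tested in decreasing order of frequency. Each rotamer
is built onto the site's backbone by internal-coordinate placement from an
ideal-geometry table, and every side-chain atom after Cβ is tested against
every atom within the search cutoff of the site's Cα using the overlap

```
c = r_atom1 + r_atom2 − d_atoms − d_allowed
```

where `r` are van der Waals radii, `d_atoms` the pair distance and
`d_allowed` = 0.4 Å the tolerated overlap. Two special cases: a pair of
potential hydrogen-bond partners (both N or O) uses a fixed radius sum of
2.5 Å, and a pair of cysteine side-chain atoms (potential disulfide) is
judged by the Cα–Cα distance instead (clash iff < 4 Å). A positive `c`
discards the rotamer; the **first** fitting rotamer settles the verdict as
`fits`, and if no rotamer fits the substitution is predicted to `clash`
(and is likely harmful). Ligands and other non-water hetero atoms count as
clash partners; waters and hydrogens are removed on input.

The search cutoff is conservative by construction: the Cα→Nη reach of a
fully extended arginine plus the nitrogen van der Waals radius (1.64 Å),
the largest tabulated radius and `d_allowed` — no potentially overlapping
partner can be missed (audited in the test suite).

## Worked example

Score all 19 substitutions at a buried site. The fixture generator builds
a structure whose central alanine is enclosed by a carbon shell 2 Å from
its Cβ:

```python
from clashscan.fixtures import make_cage
from clashscan.structure_model import write_pdb
open("cage.pdb", "w").write(write_pdb(make_cage(2.0)))
open("variants.txt", "w").write("1\n")   # position only => all 19
```

```
$ clashscan cage.pdb --variants variants.txt | cut -f6,7,8 | column -t
to_aa  verdict  decision_path
C      clash    no_rotamer_fits
D      clash    no_rotamer_fits
E      clash    no_rotamer_fits
F      clash    no_rotamer_fits
G      fits     glycine_rule
H      clash    no_rotamer_fits
I      clash    no_rotamer_fits
K      clash    no_rotamer_fits
L      clash    no_rotamer_fits
M      clash    no_rotamer_fits
N      clash    no_rotamer_fits
P      clash    no_rotamer_fits
Q      clash    no_rotamer_fits
R      clash    no_rotamer_fits
S      clash    no_rotamer_fits
T      clash    no_rotamer_fits
V      clash    no_rotamer_fits
W      clash    no_rotamer_fits
Y      clash    no_rotamer_fits
```

Every substitution with a side chain reaching past Cβ collides with the
shell, so no rotamer fits; glycine is accepted unconditionally by the
fast path. The full report also lists the fitting rotamer's χ angles, the
number of clashing pairs, the worst overlap in Å and the clash partners
(`chain:resnum:atom`). On an open site every row comes back `fits`.

Variant lines accept `98` (all 19 substitutions), `A:98`, `L98R`,
`A:L98R`, and insertion codes (`123A`). By default the variant's stated
original residue must match the structure (`--no-check` disables this),
and `--pdb-id XXXX --fetch` downloads a structure instead of reading a
local file (network access is opt-in).

## Evaluating against labelled variants

`clashscan.evaluation` scores predictions against clash/fits labels with
clash as the positive class: accuracy, PPV, NPV, sensitivity, specificity
and the Matthews correlation coefficient, each left undefined (not
zero-filled) when its denominator vanishes. A TSV reader
(`read_label_table`) ingests externally prepared variant/label tables.

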