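# Methods

## Model and assumptions

`clashscan` treats a substitution as structurally tolerated iff at least
one common rotamer of the new side chain can be placed on the site's
fixed backbone without a positive hard-sphere overlap against the rest of
the structure. The backbone never moves and the environment's side
chains never repack; the only degrees of freedom are the candidate
rotamer's χ dihedrals, taken as discrete modal values from a library.
This makes the method fast and deterministic, at the cost of
over-predicting clashes wherever real proteins would relax — most
visibly for proline, whose accommodation is largely a backbone
rearrangement; proline predictions are therefore warning-flagged rather
than special-cased.

Severity is not graded: the output is a binary fits/clash verdict plus
the evidence (fitting rotamer, or the least-clashing rotamer's contact
list).

## Decision cascade

Rules are applied in the order glycine → accessible → smaller → rotamer
testing. Glycine is hoisted first because it is unconditional. The
accessible rule requires both side-chain relative accessibility ≥ 0.5
and an original side chain of ≥ 3 heavy atoms; "size" is
operationalized as side-chain heavy-atom count throughout (Gly 0, Ala 1,
…, Trp 10). The smaller rule is suppressed for β-branched targets —
Val and Leu per the method's motivating observation, extended to Ile and
Thr on the same branching rationale; the set is configurable
(`DecisionParams.branched_exceptions`).

Rotamer testing walks the candidate list in decreasing frequency and
returns at the first fitting rotamer; exhaustion means clash. For a
clash verdict the reported contacts are those of the best (fewest
clashes, tie → most frequent) rotamer, since "best fitting" is
otherwise undefined for a failed search.

## Overlap test and constants

The pair overlap is `c = r1 + r2 − d − d_allowed` with defaults:
`d_allowed` 0.4 Å; hydrogen-bond-capable pairs (both atoms N or O —
no donor/acceptor geometry check, a deliberately permissive
element-level criterion that can only relax the test) use a fixed radius
sum of 2.5 Å; cysteine side-chain pairs (CB/SG of distinct cysteines,
covering potential disulfides) are judged by Cα–Cα distance ≥ 4 Å.
Only atoms strictly after Cβ are tested, so Ala (and Gly) substitutions
can never clash — a property the test suite asserts globally.

Radii ship as a data file (`data/vdw_radii.json`): C 1.88, N 1.64,
O 1.42, S 1.77, P 1.80, Se 1.90, default 1.80 Å (a
Tsai–Taylor–Chothia–Gerstein-style protein set). Only the site's own
atoms are excluded from the environment; adjacent-residue backbone atoms
remain clash partners, which is the main residual source of
over-prediction near the backbone (and the mechanism behind the proline
pathology above).

The neighbor search (scipy cKDTree) uses a cutoff around the site's Cα
equal to the Cα→Nη distance of a fully extended ideal arginine
(≈ 7.45 Å, computed once from the geometry table with all χ = 180°)
plus the nitrogen radius 1.64 Å, the largest tabulated radius and
`d_allowed` (≈ 11.39 Å total). A construction audit in the tests
verifies over a χ-grid of every residue type that no buildable
side-chain atom can overlap anything beyond this cutoff.

## Geometry

Side chains are built by sequential internal-coordinate (NeRF)
placement. The per-residue tree (which atom is placed from which frame,
and which χ or fixed dihedral governs it) is authored in
`scripts/make_geometry_table.py`; the numeric bond lengths, angles and
branch offsets are measured from the wwPDB chemical component
dictionary's ideal residue coordinates and shipped as
`data/ideal_geometry.json`. Rebuilding each residue type at its
template's own χ angles reproduces the template heavy atoms to
< 0.5 Å RMSD (< 0.01 Å for unbranched chains; ring-closure
approximations dominate the rest). χ angles beyond the library's χ1–χ4
(ring orientations, sp2 terminal groups) are fixed at ideal values.
Cβ is placed at ideal tetrahedral geometry on the L-amino-acid side via
the signed improper dihedral C–N–Cα–Cβ; Gly sites get a constructed Cβ
so they can host any substitution.

Backbone torsions are standard signed dihedrals (IUPAC convention),
undefined at termini and across chain breaks (consecutive Cα–Cα
> 4.5 Å).

Accessibility is an internal Shrake–Rupley implementation (probe 1.4 Å,
960 deterministic golden-spiral points; quadrature error on an isolated
sphere < 2%, asserted in tests); a site's side-chain SASA sums its atoms
from Cβ onward, and the relative value divides by a theoretical maximum
table (`data/max_sidechain_asa.json`) computed as the side-chain SASA of
X in an extended Gly-X-Gly tripeptide with the same engine. The ratio is
not clamped at 1; only the ≥ 0.5 threshold consumes it, so modest
table differences rarely flip a decision. An external
accessibility program could be substituted for parity runs; it is a
diagnostic, not a dependency.

## Rotamer library

The loader accepts a Dunbrack-style text format (res, φ, ψ, frequency,
χ1..χ4) binned at 10° by default, with half-open bins on [−180, 180)
and a backbone-independent marginal aggregated over bins. Queries at
sites with undefined φ/ψ, or falling in unpopulated bins, use the
marginal, so every query is answerable. Only modal χ values are tested
(no ±σ sampling): the search exits at the first fit, so extra samples
mostly cost time.

The embedded minimal library (`data/minimal_rotamers.txt`) carries
canonical g−/t/g+ χ modes with approximate literature-style
frequencies, backbone-independent only. It exists so the package
installs, predicts and tests offline; it is not a statistical library,
and frequency *ordering* (not coverage) is its weak point. For
production-grade ordering load a full backbone-dependent file. A
frequency floor (`min_frequency`, default 0 = keep all) is exposed
because no principled cutoff for "common" rotamers is defined; widening
the list can only add fits, never clashes (tested property).

## Synthetic fixtures: what they do and do not show

The fixture generators produce structures with *known* ground truth:
ideal helices (torsion recovery), isolated extended residues (maximum
accessibility), spherical carbon cages around a site (guaranteed clash
below a wall gap, guaranteed fit beyond the cutoff, exercising the
hetero-atom path), and seeded random atom blobs (oracle equivalence of
the spatial-index engine against a brute-force all-pairs scan). They
are deterministic down to byte-identical PDB text.

They deliberately do not emulate real packing: no realistic density,
no hydrogen-bond networks, no experimental coordinate error, no
alternate conformations under strain. Passing the suite therefore
demonstrates that the machinery (geometry, search, rules, bookkeeping)
is correct and deterministic — not that the biological error rate on
real structures matches any particular figure; that depends on the
rotamer library supplied and on how far real proteins relax, which is
exactly what the published validation-set confusion matrices summarize.

## Numerical choices and degenerate inputs

- Torsions on collinear triples raise an explicit error; batch torsion
  computation treats such sites as undefined.
- Altloc selection: highest occupancy, ties prefer "A", then
  lexicographic. Model 1 only for ensembles. Occupancy-zero atoms are
  retained (no published filter to mirror). MSE maps to Met (Se → S);
  other nonstandard polymer residues become hetero clash partners.
- Residue identity is (chain, author seq number, insertion code),
  exactly as in the file; no renumbering. Variants failing the
  original-residue check error out by default (`--no-check` to relax),
  because variant/structure numbering drift is a common failure mode.
- Rotamer ties at equal frequency break by ascending χ1 for
  reproducibility; all outputs are deterministic, and the report writer
  is row-independent (streaming-safe).
- Problem sizes in the test and acceptance battery (20-residue helices,
  ~300-atom cages, 40-atom blobs × 100 seeds) were chosen as the
  smallest fixtures that exercise every code path and keep the whole
  suite comfortably desk-scale.

## Known limitations

- No backbone flexibility or environment repacking: clash predictions
  are an upper bound, worst for proline and for sites tightly coupled
  to neighboring side chains.
- The Cβ-exempt test means substitutions *to* Ala can never clash even
  in impossibly tight sites; this is inherent to the rule as defined.
- Hydrogen-bond detection by element pair alone can under-call clashes
  between N/O pairs that are not actually bonded.
- The embedded library's frequencies are approximate; verdicts are
  insensitive (any fitting rotamer suffices) but the identity of the
  reported "most common fitting rotamer" is not.
- mmCIF, assemblies/symmetry mates and hydrogen placement are out of
  scope.
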