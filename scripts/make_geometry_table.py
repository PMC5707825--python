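"""Regenerate the packaged geometry data files.

Stage 1 writes src/clashscan/data/ideal_geometry.json: for each residue
type, the side-chain atom tree beyond C-beta with bond length, bond
angle and dihedral specification (chi index + branch offset, or a fixed
value for ring/sp2 atoms).  Numeric values are measured from the ideal
residue coordinates bundled with biotite (wwPDB chemical component
dictionary); the tree topology and chi assignments are defined here.

Stage 2 writes max_sidechain_asa.json: the theoretical maximum
side-chain SASA per residue type, computed as the side-chain SASA of X
in an extended Gly-X-Gly tripeptide built from stage 1's geometry with
the package's own Shrake-Rupley engine (probe 1.4 A, 960 points).

Run from the repository root:  python scripts/make_geometry_table.py
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

DATA = ROOT / "src" / "clashscan" / "data"

# (atom, frame (a, b, c), governing dihedral)
# governing dihedral: ("chi", k) the atom defines chi_k;
#                     ("branch", k, ref) offset from ref's chi_k dihedral;
#                     ("fixed",) conformation-independent (rings, sp2 ends).
TOPOLOGY: dict[str, list[tuple]] = {
    "ARG": [
        ("CG", ("N", "CA", "CB"), ("chi", 1)),
        ("CD", ("CA", "CB", "CG"), ("chi", 2)),
        ("NE", ("CB", "CG", "CD"), ("chi", 3)),
        ("CZ", ("CG", "CD", "NE"), ("chi", 4)),
        ("NH1", ("CD", "NE", "CZ"), ("fixed",)),
        ("NH2", ("CD", "NE", "CZ"), ("fixed",)),
    ],
    "ASN": [
        ("CG", ("N", "CA", "CB"), ("chi", 1)),
        ("OD1", ("CA", "CB", "CG"), ("chi", 2)),
        ("ND2", ("CA", "CB", "CG"), ("branch", 2, "OD1")),
    ],
    "ASP": [
        ("CG", ("N", "CA", "CB"), ("chi", 1)),
        ("OD1", ("CA", "CB", "CG"), ("chi", 2)),
        ("OD2", ("CA", "CB", "CG"), ("branch", 2, "OD1")),
    ],
    "CYS": [("SG", ("N", "CA", "CB"), ("chi", 1))],
    "GLN": [
        ("CG", ("N", "CA", "CB"), ("chi", 1)),
        ("CD", ("CA", "CB", "CG"), ("chi", 2)),
        ("OE1", ("CB", "CG", "CD"), ("chi", 3)),
        ("NE2", ("CB", "CG", "CD"), ("branch", 3, "OE1")),
    ],
    "GLU": [
        ("CG", ("N", "CA", "CB"), ("chi", 1)),
        ("CD", ("CA", "CB", "CG"), ("chi", 2)),
        ("OE1", ("CB", "CG", "CD"), ("chi", 3)),
        ("OE2", ("CB", "CG", "CD"), ("branch", 3, "OE1")),
    ],
    "HIS": [
        ("CG", ("N", "CA", "CB"), ("chi", 1)),
        ("ND1", ("CA", "CB", "CG"), ("chi", 2)),
        ("CD2", ("CA", "CB", "CG"), ("branch", 2, "ND1")),
        ("CE1", ("CB", "CG", "ND1"), ("fixed",)),
        ("NE2", ("CB", "CG", "CD2"), ("fixed",)),
    ],
    "ILE": [
        ("CG1", ("N", "CA", "CB"), ("chi", 1)),
        ("CG2", ("N", "CA", "CB"), ("branch", 1, "CG1")),
        ("CD1", ("CA", "CB", "CG1"), ("chi", 2)),
    ],
    "LEU": [
        ("CG", ("N", "CA", "CB"), ("chi", 1)),
        ("CD1", ("CA", "CB", "CG"), ("chi", 2)),
        ("CD2", ("CA", "CB", "CG"), ("branch", 2, "CD1")),
    ],
    "LYS": [
        ("CG", ("N", "CA", "CB"), ("chi", 1)),
        ("CD", ("CA", "CB", "CG"), ("chi", 2)),
        ("CE", ("CB", "CG", "CD"), ("chi", 3)),
        ("NZ", ("CG", "CD", "CE"), ("chi", 4)),
    ],
    "MET": [
        ("CG", ("N", "CA", "CB"), ("chi", 1)),
        ("SD", ("CA", "CB", "CG"), ("chi", 2)),
        ("CE", ("CB", "CG", "SD"), ("chi", 3)),
    ],
    "PHE": [
        ("CG", ("N", "CA", "CB"), ("chi", 1)),
        ("CD1", ("CA", "CB", "CG"), ("chi", 2)),
        ("CD2", ("CA", "CB", "CG"), ("branch", 2, "CD1")),
        ("CE1", ("CB", "CG", "CD1"), ("fixed",)),
        ("CE2", ("CB", "CG", "CD2"), ("fixed",)),
        ("CZ", ("CG", "CD1", "CE1"), ("fixed",)),
    ],
    "PRO": [
        ("CG", ("N", "CA", "CB"), ("chi", 1)),
        ("CD", ("CA", "CB", "CG"), ("chi", 2)),
    ],
    "SER": [("OG", ("N", "CA", "CB"), ("chi", 1))],
    "THR": [
        ("OG1", ("N", "CA", "CB"), ("chi", 1)),
        ("CG2", ("N", "CA", "CB"), ("branch", 1, "OG1")),
    ],
    "TRP": [
        ("CG", ("N", "CA", "CB"), ("chi", 1)),
        ("CD1", ("CA", "CB", "CG"), ("chi", 2)),
        ("CD2", ("CA", "CB", "CG"), ("branch", 2, "CD1")),
        ("NE1", ("CB", "CG", "CD1"), ("fixed",)),
        ("CE2", ("CB", "CG", "CD2"), ("fixed",)),
        ("CE3", ("CB", "CG", "CD2"), ("fixed",)),
        ("CZ2", ("CG", "CD2", "CE2"), ("fixed",)),
        ("CZ3", ("CG", "CD2", "CE3"), ("fixed",)),
        ("CH2", ("CD2", "CE2", "CZ2"), ("fixed",)),
    ],
    "TYR": [
        ("CG", ("N", "CA", "CB"), ("chi", 1)),
        ("CD1", ("CA", "CB", "CG"), ("chi", 2)),
        ("CD2", ("CA", "CB", "CG"), ("branch", 2, "CD1")),
        ("CE1", ("CB", "CG", "CD1"), ("fixed",)),
        ("CE2", ("CB", "CG", "CD2"), ("fixed",)),
        ("CZ", ("CG", "CD1", "CE1"), ("fixed",)),
        ("OH", ("CD1", "CE1", "CZ"), ("fixed",)),
    ],
    "VAL": [
        ("CG1", ("N", "CA", "CB"), ("chi", 1)),
        ("CG2", ("N", "CA", "CB"), ("branch", 1, "CG1")),
    ],
}


def template_coords(res_name: str) -> dict[str, np.ndarray]:
    import biotite.structure.info as info

    arr = info.residue(res_name)
    arr = arr[arr.element != "H"]
    return {name: arr.coord[i] for i, name in enumerate(arr.atom_name)}


def measure(coords, a, b, c, d):
    from clashscan.geometry import dihedral

    ba = coords[c] - coords[b]
    dc = coords[d] - coords[c]
    length = float(np.linalg.norm(dc))
    cosang = float(
        np.dot(coords[b] - coords[c], dc)
        / (np.linalg.norm(coords[b] - coords[c]) * np.linalg.norm(dc))
    )
    angle = float(np.degrees(np.arccos(cosang)))
    dih = dihedral(coords[a], coords[b], coords[c], coords[d])
    return length, angle, dih


def wrap(angle: float) -> float:
    a = ((angle + 180.0) % 360.0) - 180.0
    return 180.0 if a == -180.0 else a


def stage1() -> dict:
    table: dict = {
        "_comment": (
            "Ideal side-chain internal coordinates beyond C-beta, measured "
            "from wwPDB CCD ideal residue coordinates (via biotite) on the "
            "tree topology defined in scripts/make_geometry_table.py. "
            "dihedral: {chi: k, offset: deg} means chi_k + offset; "
            "{fixed: deg} is conformation-independent."
        )
    }
    ala = template_coords("ALA")
    from clashscan.geometry import dihedral

    cb_len = float(np.linalg.norm(ala["CB"] - ala["CA"]))
    v1 = ala["N"] - ala["CA"]
    v2 = ala["CB"] - ala["CA"]
    cb_ang = float(
        np.degrees(np.arccos(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))))
    )
    cb_improper = dihedral(ala["C"], ala["N"], ala["CA"], ala["CB"])
    table["CB"] = {
        "length": round(cb_len, 4),
        "angle": round(cb_ang, 3),
        "improper": round(cb_improper, 3),
    }

    for res_name, entries in sorted(TOPOLOGY.items()):
        coords = template_coords(res_name)
        chi_dihedrals: dict[int, float] = {}
        rows = []
        for name, frame, gov in entries:
            a, b, c = frame
            length, angle, dih = measure(coords, a, b, c, name)
            if gov[0] == "chi":
                chi_dihedrals[gov[1]] = dih
                dspec = {"chi": gov[1], "offset": 0.0}
            elif gov[0] == "branch":
                offset = wrap(dih - chi_dihedrals[gov[1]])
                dspec = {"chi": gov[1], "offset": round(offset, 3)}
            else:
                dspec = {"fixed": round(dih, 3)}
            rows.append(
                {
                    "name": name,
                    "frame": list(frame),
                    "length": round(length, 4),
                    "angle": round(angle, 3),
                    "dihedral": dspec,
                }
            )
        table[res_name] = rows
    return table


def stage2() -> dict:
    from clashscan._aa import AA1_TO_AA3, CHI_COUNTS
    from clashscan.fixtures import build_peptide
    from clashscan.geometry import sasa

    out = {
        "_comment": (
            "Theoretical maximum side-chain SASA (A^2): side-chain SASA of X "
            "in an extended Gly-X-Gly tripeptide (phi -120, psi 130, all chi "
            "180) built from ideal_geometry.json; Shrake-Rupley, probe 1.4 A, "
            "960 points. Regenerate with scripts/make_geometry_table.py."
        )
    }
    for aa in sorted(AA1_TO_AA3):
        if aa == "G":
            continue
        chi = {1: tuple([180.0] * CHI_COUNTS[aa])} if CHI_COUNTS[aa] else None
        s = build_peptide(f"G{aa}G", -120.0, 130.0, chi=chi)
        out[aa] = round(float(sasa(s)[s.residues[1].key]), 2)
    return out


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    geometry = stage1()
    (DATA / "ideal_geometry.json").write_text(json.dumps(geometry, indent=1) + "\n")
    print(f"wrote {DATA / 'ideal_geometry.json'}")
    # stage 2 must see stage 1's file through a fresh cache
    from clashscan import geometry as gmod

    gmod.load_ideal_geometry.cache_clear()
    maxasa = stage2()
    (DATA / "max_sidechain_asa.json").write_text(json.dumps(maxasa, indent=1) + "\n")
    print(f"wrote {DATA / 'max_sidechain_asa.json'}")


if __name__ == "__main__":
    main()
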