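"""Torsions, solvent accessibility and ideal side-chain construction.

Side chains are built by sequential internal-coordinate (NeRF) placement
from a packaged ideal-geometry table: each atom is positioned from three
ancestors via a bond length, a bond angle and a dihedral that is either
one of the rotamer's chi angles (possibly with a fixed branch offset) or
a fixed value (ring atoms, sp2 terminal groups).

SASA is computed with an internal Shrake-Rupley implementation (probe
1.4 A, 960 quadrature points by default) over the package's van der
Waals radii; the side-chain accessibility of a residue sums its atoms
from C-beta onward.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from ._aa import AA1_TO_AA3, CHI_COUNTS, is_sidechain_atom
from .errors import (
    GeometryError,
    NoSideChainError,
    ResolutionError,
    UndefinedTorsionError,
)
from .structure_model import AtomRecord, ResidueSite, Structure, radius_for_element

__all__ = [
    "dihedral",
    "place_atom",
    "backbone_torsions",
    "sasa",
    "sidechain_sasa",
    "relative_accessibility",
    "build_cb",
    "build_side_chain",
    "load_ideal_geometry",
    "load_max_accessibility",
    "CHAIN_BREAK_CA_DISTANCE",
]

CHAIN_BREAK_CA_DISTANCE = 4.5  # A; consecutive CA further apart => chain break


# ---------------------------------------------------------------------------
# torsions


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, in (-180, 180].

    IUPAC convention: looking from p2 toward p3, a clockwise rotation of
    p4 relative to p1 is positive.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise UndefinedTorsionError("three consecutive points are collinear")
    b2n = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2n))
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def place_atom(a, b, c, length: float, angle: float, dih: float) -> np.ndarray:
    """NeRF placement: position d with |c-d| = length, angle(b,c,d) = angle
    and dihedral(a,b,c,d) = dih (degrees)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = math.radians(angle)
    phi = math.radians(dih)
    bc = c - b
    nbc = np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nbc < 1e-9 or nn < 1e-9:
        raise GeometryError("degenerate reference frame for atom placement")
    bc /= nbc
    n /= nn
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -length * math.cos(theta),
            length * math.sin(theta) * math.cos(phi),
            length * math.sin(theta) * math.sin(phi),
        ]
    )
    rot = np.column_stack([bc, m, n])
    return c + rot @ d2


def backbone_torsions(structure: Structure) -> dict[tuple[str, int, str], tuple[float | None, float | None]]:
    """Per-site (phi, psi) in degrees; None at termini and chain breaks.

    phi(i) = dihedral(C(i-1), N(i), CA(i), C(i));
    psi(i) = dihedral(N(i), CA(i), C(i), N(i+1)).
    A CA-CA gap above 4.5 A between consecutive residues is a chain break.
    Values are also stored on the ResidueSite objects.
    """
    out: dict[tuple[str, int, str], tuple[float | None, float | None]] = {}
    for chain_id in structure.chains():
        residues = structure.chain_residues(chain_id)
        linked = []  # linked[i] True if residues i-1, i are connected
        for i in range(len(residues)):
            if i == 0:
                linked.append(False)
                continue
            a, b = residues[i - 1].atom("CA"), residues[i].atom("CA")
            ok = (
                a is not None
                and b is not None
                and float(np.linalg.norm(a.coords - b.coords)) <= CHAIN_BREAK_CA_DISTANCE
            )
            linked.append(ok)
        for i, res in enumerate(residues):
            phi = psi = None
            try:
                if i > 0 and linked[i] and residues[i - 1].atom("C") is not None and res.has_backbone:
                    phi = dihedral(
                        residues[i - 1].coord("C"), res.coord("N"), res.coord("CA"), res.coord("C")
                    )
                if (
                    i + 1 < len(residues)
                    and linked[i + 1]
                    and residues[i + 1].atom("N") is not None
                    and res.has_backbone
                ):
                    psi = dihedral(
                        res.coord("N"), res.coord("CA"), res.coord("C"), residues[i + 1].coord("N")
                    )
            except UndefinedTorsionError:
                phi = psi = None
            res.phi, res.psi = phi, psi
            out[res.key] = (phi, psi)
    return out


# ---------------------------------------------------------------------------
# solvent accessibility


@lru_cache(maxsize=8)
def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral quadrature points on the unit sphere."""
    i = np.arange(n)
    phi = np.arccos(1.0 - 2.0 * (i + 0.5) / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def sasa_per_atom(atoms: list[AtomRecord], probe: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Shrake-Rupley SASA (A^2) for each atom against all others."""
    if n_points < 16:
        raise ResolutionError(f"n_points={n_points} is below the minimum of 16")
    if not atoms:
        return np.zeros(0)
    coords = np.array([a.coords for a in atoms])
    radii = np.array([a.vdw_radius for a in atoms]) + probe
    tree = cKDTree(coords)
    unit = _sphere_points(n_points)
    max_r = radii.max()
    areas = np.zeros(len(atoms))
    for i in range(len(atoms)):
        r = radii[i]
        pts = coords[i] + r * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], r + max_r) if j != i]
        if neighbors:
            nb_coords = coords[neighbors]
            nb_r = radii[neighbors]
            d2 = ((pts[:, None, :] - nb_coords[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nb_r**2)[None, :]).any(axis=1)
            exposed = int((~buried).sum())
        else:
            exposed = n_points
        areas[i] = 4.0 * math.pi * r * r * exposed / n_points
    return areas


def sasa(structure: Structure, probe: float = 1.4, n_points: int = 960) -> dict[tuple[str, int, str], float]:
    """Per-site side-chain absolute accessibility (A^2).

    All atoms (polymer and retained hetero atoms) occlude; a site's value
    sums its atoms beyond C-alpha.  Glycine gets 0.
    """
    atoms = structure.all_atoms()
    areas = sasa_per_atom(atoms, probe=probe, n_points=n_points)
    by_atom = {id(a): areas[i] for i, a in enumerate(atoms)}
    out: dict[tuple[str, int, str], float] = {}
    for res in structure.residues:
        if res.res_type == "G":
            out[res.key] = 0.0
            continue
        out[res.key] = float(
            sum(by_atom[id(a)] for a in res.atoms if is_sidechain_atom(a.name))
        )
    return out


def sidechain_sasa(structure: Structure, site: ResidueSite, **kw) -> float:
    return sasa(structure, **kw)[site.key]


@lru_cache(maxsize=1)
def load_max_accessibility() -> dict[str, float]:
    """Residue type (one-letter) -> maximum side-chain SASA (A^2).

    Theoretical maxima: side-chain SASA of X in an extended Gly-X-Gly
    tripeptide built from the package's ideal geometry (see
    scripts/make_geometry_table.py).
    """
    text = resources.files("clashscan.data").joinpath("max_sidechain_asa.json").read_text()
    raw = json.loads(text)
    return {k: float(v) for k, v in raw.items() if not k.startswith("_")}


def relative_accessibility(
    site_abs_acc: float, res_type: str, table: dict[str, float] | None = None
) -> float:
    """Side-chain SASA divided by the residue type's maximum.

    May slightly exceed 1 for unusually exposed conformations; the value
    is only compared against the 0.5 accessibility threshold, so no
    clamping is applied.
    """
    if res_type == "G":
        raise NoSideChainError("glycine has no side chain to measure")
    table = load_max_accessibility() if table is None else table
    return float(site_abs_acc) / float(table[res_type])


# ---------------------------------------------------------------------------
# side-chain construction


@lru_cache(maxsize=1)
def load_ideal_geometry() -> dict:
    """Packaged ideal side-chain geometry table.

    Schema: {"CB": {length, angle, improper}, "<AA3>": [entry, ...]} with
    entry = {name, frame: [a, b, c], length, angle,
             dihedral: {"chi": k, "offset": deg} | {"fixed": deg}}.
    The frame names reference backbone atoms or previously placed
    side-chain atoms; the placed dihedral is a-b-c-new.
    """
    text = resources.files("clashscan.data").joinpath("ideal_geometry.json").read_text()
    return json.loads(text)


def build_cb(N, CA, C) -> np.ndarray:
    """Ideal C-beta from the backbone triad, on the L-amino-acid side."""
    geo = load_ideal_geometry()["CB"]
    return place_atom(C, N, CA, geo["length"], geo["angle"], geo["improper"])


def build_side_chain(
    site: ResidueSite,
    to_aa: str,
    chi: tuple[float, ...],
    table: dict | None = None,
) -> list[AtomRecord]:
    """Construct the substituting side chain in the site's backbone frame.

    Returns AtomRecords starting with C-beta, in placement order.  The
    chi tuple's arity must match the target residue type.
    """
    if to_aa == "G":
        raise NoSideChainError("glycine has no side chain to build")
    table = load_ideal_geometry() if table is None else table
    n_chi = CHI_COUNTS[to_aa]
    if len(chi) != n_chi:
        raise GeometryError(
            f"{AA1_TO_AA3[to_aa]} needs {n_chi} chi angles, got {len(chi)}"
        )
    coords: dict[str, np.ndarray] = {
        "N": site.coord("N"),
        "CA": site.coord("CA"),
        "C": site.coord("C"),
    }
    coords["CB"] = build_cb(coords["N"], coords["CA"], coords["C"])
    placed = ["CB"]
    for entry in table.get(AA1_TO_AA3[to_aa], []):
        a, b, c = (coords[x] for x in entry["frame"])
        dspec = entry["dihedral"]
        if "fixed" in dspec:
            dih = dspec["fixed"]
        else:
            dih = chi[dspec["chi"] - 1] + dspec.get("offset", 0.0)
        coords[entry["name"]] = place_atom(a, b, c, entry["length"], entry["angle"], dih)
        placed.append(entry["name"])
    out: list[AtomRecord] = []
    for i, name in enumerate(placed):
        element = name[0]
        out.append(
            AtomRecord(
                serial=-(i + 1),
                name=name,
                element=element,
                coords=coords[name],
                is_hetero=False,
                vdw_radius=radius_for_element(element),
                chain_id=site.chain_id,
                res_name=AA1_TO_AA3[to_aa],
                res_seq=site.seq_number,
                icode=site.insertion_code,
            )
        )
    return out
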