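"""Neighbor search and the atom-pair van der Waals overlap test.

The overlap between two heavy atoms is

    c = r_atom1 + r_atom2 - d_atoms - d_allowed

with a positive c recorded as a clash.  Two special cases modify the
test: a hydrogen-bond-capable pair (both atoms N or O) replaces the
radius sum by a fixed 2.5 A, and a pair of cysteine side-chain atoms
(potential disulfide) replaces the atom-pair test by the requirement
that the two C-alpha atoms are at least 4 A apart.

The search neighborhood around a substitution site is every atom within
a cutoff of its C-alpha, where the cutoff is the C-alpha-to-N-eta reach
of a fully extended ideal arginine plus the nitrogen van der Waals
radius (1.64 A), plus the largest tabulated radius and d_allowed so that
no potentially overlapping partner can be missed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

from .errors import ClashscanError
from .structure_model import AtomRecord, ResidueSite, Structure, load_radii_table

__all__ = [
    "ClashParams",
    "ClashResult",
    "extended_arginine_reach",
    "neighborhood",
    "pair_overlap",
    "rotamer_fits",
]

_HBOND_ELEMENTS = frozenset({"N", "O"})
_CYS_SIDECHAIN = frozenset({"CB", "SG"})


@lru_cache(maxsize=1)
def extended_arginine_reach() -> float:
    """CA -> N-eta distance (A) of a fully extended ideal arginine.

    Built once from the ideal-geometry table with all chi = 180 on a
    reference backbone; the larger of the two N-eta distances is used.
    """
    from .geometry import build_side_chain, place_atom
    from .structure_model import ResidueSite as _Site

    # reference backbone triad with ideal internal geometry
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.458, 0.0, 0.0])
    c = place_atom(np.array([0.0, 1.0, 0.0]), n, ca, 1.525, 111.2, 120.0)
    site = _Site(chain_id="A", seq_number=1, insertion_code="", res_type="A")
    site.atoms = [
        AtomRecord(1, "N", "N", n, chain_id="A", res_name="ALA", res_seq=1),
        AtomRecord(2, "CA", "C", ca, chain_id="A", res_name="ALA", res_seq=1),
        AtomRecord(3, "C", "C", c, chain_id="A", res_name="ALA", res_seq=1),
    ]
    atoms = build_side_chain(site, "R", (180.0, 180.0, 180.0, 180.0))
    reach = max(
        float(np.linalg.norm(a.coords - ca)) for a in atoms if a.name in ("NH1", "NH2")
    )
    return reach


@dataclass
class ClashParams:
    """Constants of the overlap test and the derived search cutoff."""

    d_allowed: float = 0.4
    hbond_radius_sum: float = 2.5
    cys_ca_min: float = 4.0
    nitrogen_vdw: float = 1.64
    radii_table: dict[str, float] = field(default_factory=load_radii_table)

    def __post_init__(self) -> None:
        if self.d_allowed < 0:
            raise ValueError("d_allowed must be nonnegative")
        if any(r <= 0 for r in self.radii_table.values()):
            raise ValueError("all van der Waals radii must be positive")

    @property
    def search_cutoff(self) -> float:
        """Superset-safe neighbor radius around the site's C-alpha."""
        max_radius = max(self.radii_table.values())
        return (
            extended_arginine_reach()
            + self.nitrogen_vdw
            + max_radius
            + self.d_allowed
        )


@dataclass
class ClashResult:
    """A positive-overlap (or rule-triggering) atom pair."""

    overlap_c: float
    atom1: AtomRecord  # rotamer atom
    atom2: AtomRecord  # environment atom
    rule: str  # "normal" | "hbond" | "cysteine"

    @property
    def is_clash(self) -> bool:
        return self.overlap_c > 0


def neighborhood(structure: Structure, site: ResidueSite, params: ClashParams) -> list[AtomRecord]:
    """All atoms within the search cutoff of the site's C-alpha.

    The site's own atoms are excluded (its side chain is conceptually
    replaced and its backbone anchors the rotamer); everything else,
    including adjacent-residue backbone atoms and retained hetero/ligand
    atoms, is a potential clash partner.
    """
    ca = site.coord("CA")
    atoms = [a for a in structure.all_atoms() if a.residue_key != site.key]
    if not atoms:
        return []
    coords = np.array([a.coords for a in atoms])
    tree = cKDTree(coords)
    idx = tree.query_ball_point(ca, params.search_cutoff)
    return [atoms[i] for i in sorted(idx)]


def _is_cys_pair(atom1: AtomRecord, atom2: AtomRecord) -> bool:
    return (
        atom1.res_name == "CYS"
        and atom2.res_name == "CYS"
        and atom1.name in _CYS_SIDECHAIN
        and atom2.name in _CYS_SIDECHAIN
        and atom1.residue_key != atom2.residue_key
    )


def pair_overlap(
    atom1: AtomRecord,
    atom2: AtomRecord,
    params: ClashParams,
    cys_context: tuple[np.ndarray, np.ndarray] | None = None,
) -> ClashResult:
    """Overlap test for one atom pair; symmetric in its arguments.

    ``cys_context`` carries the two C-alpha coordinates and enables the
    disulfide rule when both atoms are cysteine side-chain atoms (CB/SG
    of distinct cysteines): the pair clashes iff the C-alpha distance is
    below 4 A.  A pair with both elements in {N, O} is treated as
    hydrogen-bond capable and uses the fixed 2.5 A radius sum.
    """
    for a in (atom1, atom2):
        if a.element.upper() in ("H", "D"):
            raise ClashscanError("hydrogen atoms must not reach the overlap test")
    if cys_context is not None and _is_cys_pair(atom1, atom2):
        ca1, ca2 = cys_context
        d_ca = float(np.linalg.norm(np.asarray(ca1) - np.asarray(ca2)))
        return ClashResult(params.cys_ca_min - d_ca, atom1, atom2, "cysteine")
    d = float(np.linalg.norm(atom1.coords - atom2.coords))
    if atom1.element.upper() in _HBOND_ELEMENTS and atom2.element.upper() in _HBOND_ELEMENTS:
        return ClashResult(params.hbond_radius_sum - d - params.d_allowed, atom1, atom2, "hbond")
    c = atom1.vdw_radius + atom2.vdw_radius - d - params.d_allowed
    return ClashResult(c, atom1, atom2, "normal")


def _env_ca_map(structure: Structure) -> dict[tuple[str, int, str], np.ndarray]:
    out = {}
    for res in structure.residues:
        a = res.atom("CA")
        if a is not None:
            out[res.key] = a.coords
    return out


def rotamer_fits(
    structure: Structure,
    site: ResidueSite,
    sidechain_atoms: list[AtomRecord],
    neighborhood_atoms: list[AtomRecord],
    params: ClashParams,
    collect_all: bool = False,
) -> tuple[bool, list[ClashResult]]:
    """Test a built side chain against the neighborhood.

    Only atoms strictly after C-beta are tested (C-beta itself never is,
    which is why alanine substitutions cannot clash).  Returns
    ``(fits, clashes)``; with ``collect_all=False`` the enumeration
    stops at the first positive overlap.
    """
    tested = [a for a in sidechain_atoms if a.name != "CB"]
    site_ca = site.coord("CA")
    ca_map = _env_ca_map(structure)
    clashes: list[ClashResult] = []
    for a1 in tested:
        for a2 in neighborhood_atoms:
            ctx = None
            if a1.res_name == "CYS" and a2.res_name == "CYS":
                ca2 = ca_map.get(a2.residue_key)
                if ca2 is not None:
                    ctx = (site_ca, ca2)
            result = pair_overlap(a1, a2, params, cys_context=ctx)
            if result.is_clash:
                clashes.append(result)
                if not collect_all:
                    return False, clashes
    return len(clashes) == 0, clashes
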