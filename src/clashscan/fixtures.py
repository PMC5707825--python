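"""Synthetic PDB-format structures with known geometric ground truth.

These generators make every other module testable offline: ideal
polyalanine helices at chosen backbone torsions, isolated extended
residues, enclosed "cage" sites whose walls guarantee (or preclude)
clashes, and seeded random atom blobs for oracle-equivalence sweeps.
All generation is deterministic: the same spec yields byte-identical
PDB text.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from ._aa import AA1_TO_AA3
from .clash_engine import ClashParams, ClashResult, pair_overlap
from .geometry import build_cb, build_side_chain, place_atom
from .structure_model import AtomRecord, ResidueSite, Structure, radius_for_element

__all__ = [
    "FixtureSpec",
    "build_peptide",
    "make_helix",
    "make_extended_residue",
    "make_cage",
    "make_random_blob",
    "brute_force_clash",
]

# ideal backbone internal coordinates (Engh-Huber-style)
_N_CA, _CA_C, _C_N, _C_O = 1.458, 1.525, 1.329, 1.231
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA, _ANG_CA_C_O = 111.2, 116.2, 121.7, 120.8
_OMEGA = 180.0


@dataclass(frozen=True)
class FixtureSpec:
    """Serializable description of a synthetic structure."""

    kind: str  # helix | extended_residue | cage | random_blob
    n_residues: int = 1
    seed: int = 0
    phi: float = -57.0
    psi: float = -47.0
    site_gap: float = 2.0
    site_aa: str = "A"
    n_atoms: int = 60
    radius: float = 8.0

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    def build(self) -> Structure:
        if self.kind == "helix":
            return make_helix(self.n_residues, self.phi, self.psi)
        if self.kind == "extended_residue":
            return make_extended_residue(self.site_aa)
        if self.kind == "cage":
            return make_cage(self.site_gap, site_aa=self.site_aa)
        if self.kind == "random_blob":
            return make_random_blob(self.n_atoms, self.seed, radius=self.radius)
        raise ValueError(f"unknown fixture kind {self.kind!r}")


def _mk_atom(serial, name, element, coords, chain, res_name, res_seq, hetero=False):
    return AtomRecord(
        serial=serial,
        name=name,
        element=element,
        coords=np.asarray(coords, dtype=float),
        is_hetero=hetero,
        vdw_radius=radius_for_element(element),
        chain_id=chain,
        res_name=res_name,
        res_seq=res_seq,
    )


def build_peptide(
    sequence: str,
    phi: float | list[float],
    psi: float | list[float],
    chain_id: str = "A",
    with_cb: bool = True,
    chi: dict[int, tuple[float, ...]] | None = None,
) -> Structure:
    """Build an ideal-geometry peptide at the requested backbone torsions.

    phi[i] shapes residue i (phi of the first residue is immaterial);
    psi[i] links residue i to i+1.  ``chi`` optionally maps 0-based
    residue indices to chi tuples for full side-chain construction;
    otherwise residues carry backbone + C-beta (Gly: backbone only).
    """
    n = len(sequence)
    phis = [phi] * n if np.isscalar(phi) else list(phi)
    psis = [psi] * n if np.isscalar(psi) else list(psi)
    bb: list[dict[str, np.ndarray]] = []
    for i in range(n):
        if i == 0:
            N = np.array([0.0, 0.0, 0.0])
            CA = np.array([_N_CA, 0.0, 0.0])
            C = place_atom(np.array([0.0, 1.0, 0.0]), N, CA, _CA_C, _ANG_N_CA_C, 57.0)
        else:
            prev = bb[i - 1]
            N = place_atom(prev["N"], prev["CA"], prev["C"], _C_N, _ANG_CA_C_N, psis[i - 1])
            CA = place_atom(prev["CA"], prev["C"], N, _N_CA, _ANG_C_N_CA, _OMEGA)
            C = place_atom(prev["C"], N, CA, _CA_C, _ANG_N_CA_C, phis[i])
            prev["O"] = place_atom(prev["N"], prev["CA"], prev["C"], _C_O, _ANG_CA_C_O, psis[i - 1] - 180.0)
        bb.append({"N": N, "CA": CA, "C": C})
    last = bb[-1]
    last["O"] = place_atom(last["N"], last["CA"], last["C"], _C_O, _ANG_CA_C_O, psis[-1] - 180.0)

    structure = Structure(source_id=f"peptide-{sequence}")
    serial = 0
    for i, aa in enumerate(sequence):
        res_name = AA1_TO_AA3[aa]
        site = ResidueSite(chain_id=chain_id, seq_number=i + 1, insertion_code="", res_type=aa)
        for name in ("N", "CA", "C", "O"):
            serial += 1
            element = name[0]
            site.atoms.append(_mk_atom(serial, name, element, bb[i][name], chain_id, res_name, i + 1))
        if aa != "G" and with_cb:
            if chi is not None and i in chi:
                sc = build_side_chain(site, aa, chi[i])
            else:
                cb = build_cb(bb[i]["N"], bb[i]["CA"], bb[i]["C"])
                sc = [_mk_atom(0, "CB", "C", cb, chain_id, res_name, i + 1)]
            for a in sc:
                serial += 1
                a.serial = serial
                site.atoms.append(a)
        structure.residues.append(site)
    return structure


def make_helix(n: int = 20, phi: float = -57.0, psi: float = -47.0) -> Structure:
    """Ideal polyalanine helix; backbone_torsions recovers (phi, psi)."""
    if n < 3:
        raise ValueError("a helix fixture needs at least 3 residues")
    s = build_peptide("A" * n, phi, psi)
    s.source_id = f"helix-{n}"
    return s


def make_extended_residue(aa: str = "R") -> Structure:
    """One isolated residue with its side chain fully extended (chi=180)."""
    from ._aa import CHI_COUNTS

    chi = {0: tuple([180.0] * CHI_COUNTS[aa])} if CHI_COUNTS[aa] > 0 else None
    s = build_peptide(aa, -120.0, 130.0, chi=chi)
    s.source_id = f"extended-{aa}"
    return s


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    phi = np.arccos(1.0 - 2.0 * (i + 0.5) / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def make_cage(site_gap: float, site_aa: str = "A", n_wall: int = 300) -> Structure:
    """A single residue enclosed by a spherical shell of carbon
    pseudo-atoms (HETATM) of radius ``site_gap`` centred on its C-beta.

    For small gaps every substitution with two or more side-chain atoms
    must clash with the wall; for gaps beyond the search cutoff all 19
    substitutions fit.  The hetero-atom clash path is exercised by
    construction.
    """
    if site_gap <= 0:
        raise ValueError("site_gap must be positive")
    s = build_peptide(site_aa, -120.0, 130.0)
    s.source_id = f"cage-{site_gap:g}"
    res = s.residues[0]
    cb = res.atom("CB")
    center = cb.coords if cb is not None else build_cb(
        res.coord("N"), res.coord("CA"), res.coord("C")
    )
    serial = max(a.serial for a in res.atoms)
    for point in _fibonacci_sphere(n_wall):
        serial += 1
        s.hetero_atoms.append(
            _mk_atom(serial, "C", "C", center + site_gap * point, "X", "CAG", serial, hetero=True)
        )
    return s


def make_random_blob(n_atoms: int = 60, seed: int = 0, radius: float = 8.0) -> Structure:
    """A central residue surrounded by seeded random hetero atoms.

    Positions are uniform in a shell (2 A .. ``radius``) around the
    C-alpha; elements are drawn from C/N/O/S so every overlap rule can
    fire.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    s = build_peptide("A", -120.0, 130.0)
    s.source_id = f"blob-{seed}"
    ca = s.residues[0].coord("CA")
    elements = rng.choice(["C", "N", "O", "S"], size=n_atoms, p=[0.55, 0.2, 0.2, 0.05])
    serial = max(a.serial for a in s.residues[0].atoms)
    count = 0
    while count < n_atoms:
        v = rng.uniform(-radius, radius, size=3)
        r = float(np.linalg.norm(v))
        if r > radius or r < 2.0:
            continue
        serial += 1
        s.hetero_atoms.append(
            _mk_atom(serial, "C1", str(elements[count]), ca + v, "X", "BLB", serial, hetero=True)
        )
        count += 1
    return s


def brute_force_clash(
    structure: Structure,
    sidechain_atoms: list[AtomRecord],
    params: ClashParams,
) -> list[ClashResult]:
    """All-pairs clash oracle with no spatial index.

    Tests every side-chain atom after C-beta against every atom of the
    structure outside the substituted residue, with the same pair rules
    as the clash engine.
    """
    if not sidechain_atoms:
        return []
    site_key = sidechain_atoms[0].residue_key
    ca_map = {}
    site_ca = None
    for res in structure.residues:
        a = res.atom("CA")
        if a is not None:
            ca_map[res.key] = a.coords
            if res.key == site_key:
                site_ca = a.coords
    clashes: list[ClashResult] = []
    for a1 in sidechain_atoms:
        if a1.name == "CB":
            continue
        for a2 in structure.all_atoms():
            if a2.residue_key == site_key:
                continue
            ctx = None
            if a1.res_name == "CYS" and a2.res_name == "CYS" and site_ca is not None:
                ca2 = ca_map.get(a2.residue_key)
                if ca2 is not None:
                    ctx = (site_ca, ca2)
            result = pair_overlap(a1, a2, params, cys_context=ctx)
            if result.is_clash:
                clashes.append(result)
    return clashes
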