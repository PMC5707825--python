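"""Torsions, SASA, C-beta construction and side-chain building."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from clashscan._aa import AA1_TO_AA3, CHI_COUNTS
from clashscan.errors import NoSideChainError, ResolutionError, UndefinedTorsionError
from clashscan.fixtures import build_peptide, make_cage, make_extended_residue, make_helix
from clashscan.geometry import (
    backbone_torsions,
    build_cb,
    build_side_chain,
    dihedral,
    load_ideal_geometry,
    load_max_accessibility,
    relative_accessibility,
    sasa,
    sasa_per_atom,
)
from clashscan.structure_model import AtomRecord, ResidueSite


def quaternion_dihedral(p1, p2, p3, p4):
    """Independent torsion oracle: rotate the central bond onto z and read
    the polar angle difference of the flanking bonds."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b2 = p3 - p2
    rot, _ = Rotation.align_vectors([[0.0, 0.0, 1.0]], [b2])
    u = rot.apply(p1 - p2)
    v = rot.apply(p4 - p3)
    a1 = math.atan2(u[1], u[0])
    a2 = math.atan2(v[1], v[0])
    ang = math.degrees(a2 - a1)
    ang = ((ang + 180.0) % 360.0) - 180.0
    return 180.0 if ang == -180.0 else ang


class TestDihedral:
    def test_planar_cis_is_zero(self):
        assert dihedral((1, 1, 0), (0, 1, 0), (0, -1, 0), (1, -1, 0)) == pytest.approx(0.0)

    def test_planar_trans_is_180(self):
        assert abs(dihedral((1, 1, 0), (0, 1, 0), (0, -1, 0), (-1, -1, 0))) == pytest.approx(180.0)

    def test_matches_quaternion_oracle_on_reference_points(self):
        pts = ((1, 0, 0), (0, 0, 0), (0, 1, 0), (1, 1, 1))
        assert dihedral(*pts) == pytest.approx(-45.0)
        assert dihedral(*pts) == pytest.approx(quaternion_dihedral(*pts))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_quaternion_oracle_randomized(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(4, 3)) * 3.0
        try:
            ours = dihedral(*pts)
        except UndefinedTorsionError:
            return
        assert ours == pytest.approx(quaternion_dihedral(*pts), abs=1e-6)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_reversal_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.normal(size=(4, 3)) * 3.0
        try:
            fwd = dihedral(p[0], p[1], p[2], p[3])
        except UndefinedTorsionError:
            return
        assert fwd == pytest.approx(dihedral(p[3], p[2], p[1], p[0]), abs=1e-9)

    def test_collinear_raises(self):
        with pytest.raises(UndefinedTorsionError):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


class TestBackboneTorsions:
    def test_helix_recovers_built_angles(self):
        s = make_helix(20, -57.0, -47.0)
        torsions = backbone_torsions(s)
        for i, res in enumerate(s.residues):
            phi, psi = torsions[res.key]
            if 0 < i:
                assert phi == pytest.approx(-57.0, abs=0.5)
            if i < len(s.residues) - 1:
                assert psi == pytest.approx(-47.0, abs=0.5)

    def test_undefined_at_termini(self):
        s = make_helix(5)
        torsions = backbone_torsions(s)
        assert torsions[s.residues[0].key][0] is None
        assert torsions[s.residues[-1].key][1] is None

    def test_no_torsion_across_chain_break(self):
        s = make_helix(6)
        # translate the last three residues far away: a chain break
        for res in s.residues[3:]:
            for a in res.atoms:
                a.coords = a.coords + np.array([50.0, 0.0, 0.0])
        torsions = backbone_torsions(s)
        assert torsions[s.residues[3].key][0] is None
        assert torsions[s.residues[2].key][1] is None


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        a = AtomRecord(1, "C1", "C", np.zeros(3), vdw_radius=1.88)
        area = sasa_per_atom([a], probe=1.4, n_points=960)[0]
        exact = 4.0 * math.pi * (1.88 + 1.4) ** 2
        assert area == pytest.approx(exact, rel=0.02)

    def test_far_separated_atoms_are_additive(self):
        a = AtomRecord(1, "C1", "C", np.zeros(3), vdw_radius=1.88)
        b = AtomRecord(2, "O1", "O", np.array([50.0, 0.0, 0.0]), vdw_radius=1.42)
        areas = sasa_per_atom([a, b])
        singles = [sasa_per_atom([x])[0] for x in (a, b)]
        assert areas == pytest.approx(singles)

    def test_enclosed_cage_centre_is_buried(self):
        s = make_cage(2.0)
        cb = s.residues[0].atom("CB")
        atoms = s.all_atoms()
        areas = sasa_per_atom(atoms)
        idx = next(i for i, a in enumerate(atoms) if a is cb)
        assert areas[idx] == 0.0

    def test_quadrature_converges(self):
        s = make_helix(8)
        atoms = s.all_atoms()
        a1 = sasa_per_atom(atoms, n_points=960)
        a2 = sasa_per_atom(atoms, n_points=1920)
        # per-atom change under refinement, relative to the atom's full sphere
        full = np.array([4 * math.pi * (a.vdw_radius + 1.4) ** 2 for a in atoms])
        assert np.max(np.abs(a1 - a2) / full) < 0.01

    def test_too_few_points_rejected(self):
        a = AtomRecord(1, "C1", "C", np.zeros(3), vdw_radius=1.88)
        with pytest.raises(ResolutionError):
            sasa_per_atom([a], n_points=8)

    def test_matches_biopython_shrake_rupley(self):
        """Dual-route check: the internal Shrake-Rupley engine agrees with
        Biopython's implementation on per-site side-chain SASA."""
        import collections
        import io

        from Bio.PDB import PDBParser
        from Bio.PDB.SASA import ShrakeRupley

        from clashscan._aa import BACKBONE_ATOMS
        from clashscan.structure_model import load_radii_table, write_pdb

        s = make_helix(12)
        ours = sasa(s)
        bio = PDBParser(QUIET=True).get_structure("h", io.StringIO(write_pdb(s)))
        radii = {k: v for k, v in load_radii_table().items() if k != "default"}
        ShrakeRupley(probe_radius=1.4, n_points=960, radii_dict=radii).compute(bio, level="A")
        theirs = collections.defaultdict(float)
        for atom in bio.get_atoms():
            if atom.get_name() not in BACKBONE_ATOMS:
                res = atom.get_parent()
                key = (res.get_parent().id, res.id[1], res.id[2].strip())
                theirs[key] += atom.sasa
        for key, value in ours.items():
            assert value == pytest.approx(theirs[key], abs=1.5)

    def test_glycine_site_reports_zero(self):
        s = build_peptide("AGA", -57.0, -47.0)
        per_site = sasa(s)
        assert per_site[s.residues[1].key] == 0.0


class TestRelativeAccessibility:
    def test_ratio_arithmetic(self):
        assert relative_accessibility(60.0, "K", {"K": 120.0}) == pytest.approx(0.5)
        assert relative_accessibility(0.0, "K", {"K": 120.0}) == 0.0

    def test_glycine_refused(self):
        with pytest.raises(NoSideChainError):
            relative_accessibility(10.0, "G")

    def test_extended_arginine_in_isolation_is_fully_exposed(self):
        s = make_extended_residue("R")
        abs_acc = sasa(s)[s.residues[0].key]
        assert relative_accessibility(abs_acc, "R") >= 0.95

    def test_max_table_covers_all_sidechain_types(self):
        table = load_max_accessibility()
        assert set(table) == set(AA1_TO_AA3) - {"G"}
        assert all(v > 0 for v in table.values())


class TestBuildCb:
    def test_bond_length_is_ideal(self):
        n, ca, c = np.array([0.0, 0, 0]), np.array([1.458, 0, 0]), np.array([2.0, 1.4, 0])
        cb = build_cb(n, ca, c)
        ideal = load_ideal_geometry()["CB"]["length"]
        assert np.linalg.norm(cb - ca) == pytest.approx(ideal, abs=1e-6)

    def test_matches_helix_fixture_cb(self, helix):
        res = helix.residues[10]
        built = build_cb(res.coord("N"), res.coord("CA"), res.coord("C"))
        assert np.linalg.norm(built - res.coord("CB")) < 0.25

    def test_l_chirality_of_construction(self):
        """build_cb always picks the L-amino-acid side: the signed
        improper dihedral C-N-CA-CB matches the table, and reflecting CB
        through the backbone plane flips its sign (the D side)."""
        n, ca, c = np.array([0.0, 0, 0]), np.array([1.458, 0, 0]), np.array([2.0, 1.4, 0])
        cb = build_cb(n, ca, c)
        ideal = load_ideal_geometry()["CB"]["improper"]
        assert dihedral(c, n, ca, cb) == pytest.approx(ideal, abs=1e-6)
        normal = np.cross(ca - n, c - ca)
        normal /= np.linalg.norm(normal)
        cb_reflected = cb - 2.0 * np.dot(cb - ca, normal) * normal
        assert dihedral(c, n, ca, cb_reflected) == pytest.approx(-ideal, abs=1e-6)


def _bare_site(res_type="A"):
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.458, 0.0, 0.0])
    c = np.array([2.009, 1.42, 0.0])
    site = ResidueSite("A", 1, "", res_type)
    for i, (nm, el, xyz) in enumerate([("N", "N", n), ("CA", "C", ca), ("C", "C", c)]):
        site.atoms.append(AtomRecord(i + 1, nm, el, xyz, chain_id="A", res_name="ALA", res_seq=1))
    return site


class TestBuildSideChain:
    def test_alanine_is_single_cbeta(self):
        atoms = build_side_chain(_bare_site(), "A", ())
        assert [a.name for a in atoms] == ["CB"]

    def test_wrong_chi_arity_rejected(self):
        from clashscan.errors import GeometryError

        with pytest.raises(GeometryError):
            build_side_chain(_bare_site(), "S", (60.0, 60.0))

    @pytest.mark.parametrize("aa", sorted(set(AA1_TO_AA3) - {"G", "A"}))
    def test_requested_chi_angles_are_realized(self, aa):
        """Building at given chi and re-measuring the dihedrals recovers them."""
        table = load_ideal_geometry()
        chi = tuple([-66.0, 170.0, 55.0, -179.0][: CHI_COUNTS[aa]])
        atoms = build_side_chain(_bare_site(), aa, chi)
        coords = {a.name: a.coords for a in atoms}
        site = _bare_site()
        coords.update({n: site.coord(n) for n in ("N", "CA", "C")})
        k = 0
        for entry in table[AA1_TO_AA3[aa]]:
            d = entry["dihedral"]
            if "chi" in d and d["offset"] == 0.0:
                k += 1
                a, b, c = (coords[x] for x in entry["frame"])
                measured = dihedral(a, b, c, coords[entry["name"]])
                assert measured == pytest.approx(chi[k - 1], abs=1e-6)
        assert k == CHI_COUNTS[aa]

    @pytest.mark.parametrize("aa", sorted(set(AA1_TO_AA3) - {"G", "A"}))
    def test_bond_lengths_match_table(self, aa):
        table = load_ideal_geometry()
        chi = tuple([180.0] * CHI_COUNTS[aa])
        atoms = build_side_chain(_bare_site(), aa, chi)
        coords = {a.name: a.coords for a in atoms}
        site = _bare_site()
        coords.update({n: site.coord(n) for n in ("N", "CA", "C")})
        for entry in table[AA1_TO_AA3[aa]]:
            parent = coords[entry["frame"][2]]
            length = np.linalg.norm(coords[entry["name"]] - parent)
            assert length == pytest.approx(entry["length"], abs=1e-6)

    def test_sidechain_atom_counts(self):
        from clashscan._aa import SIDECHAIN_SIZE

        for aa in sorted(set(AA1_TO_AA3) - {"G"}):
            atoms = build_side_chain(_bare_site(), aa, tuple([180.0] * CHI_COUNTS[aa]))
            assert len(atoms) == SIDECHAIN_SIZE[aa]

    def test_extended_arginine_reach_consistent_with_cutoff_constant(self):
        from clashscan.clash_engine import extended_arginine_reach

        site = _bare_site()
        atoms = build_side_chain(site, "R", (180.0,) * 4)
        ca = site.coord("CA")
        reach = max(
            np.linalg.norm(a.coords - ca) for a in atoms if a.name in ("NH1", "NH2")
        )
        assert reach == pytest.approx(extended_arginine_reach(), abs=1e-9)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_rigid_motion_invariance(seed):
    """Rotating+translating the backbone leaves torsions and built-side-chain
    internal distances unchanged."""
    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng)
    shift = rng.normal(size=3) * 10

    s1 = make_helix(6)
    s2 = make_helix(6)
    for res in s2.residues:
        for a in res.atoms:
            a.coords = rot.apply(a.coords) + shift
    t1 = backbone_torsions(s1)
    t2 = backbone_torsions(s2)
    for key in t1:
        for v1, v2 in zip(t1[key], t2[key]):
            if v1 is None:
                assert v2 is None
            else:
                assert v2 == pytest.approx(v1, abs=1e-6)

    chi = (-60.0, 180.0)
    a1 = build_side_chain(s1.residues[2], "L", chi)
    a2 = build_side_chain(s2.residues[2], "L", chi)
    d1 = [np.linalg.norm(x.coords - y.coords) for x in a1 for y in a1]
    d2 = [np.linalg.norm(x.coords - y.coords) for x in a2 for y in a2]
    assert np.allclose(d1, d2, atol=1e-6)
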