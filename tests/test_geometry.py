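"""Dihedrals, bond metrics, chi/phi/psi recovery, and chirality."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from atomdiff.fixtures import (
    InternalCoordinateSpec,
    build_fixture,
    helix_spec,
    mixed_rotamer_spec,
    strand_spec,
)
from atomdiff.geometry import (
    bond_angles,
    bond_length_rmse,
    bond_lengths,
    chi_angles,
    chirality_check,
    default_ideal_table,
    dihedral,
    evaluate,
    phi_psi,
)
from atomdiff.internal import N_CHI, REFERENCE_CHIS, SYMMETRIC_CHI, place_atom
from atomdiff.residues import AA1_TO_AA3, ATOM37_INDEX


def _rigid(s, seed=0):
    rng = np.random.default_rng(seed)
    out = s.copy()
    R = Rotation.random(rng=rng).as_matrix()
    out.coords37 = s.coords37 @ R.T + rng.normal(size=3) * 5
    return out


# --------------------------------------------------------------- dihedral


def test_dihedral_cis_trans():
    a, b, c = [0.0, 1.0, 0.0], [0.0, 0.0, 0.0], [1.0, 0.0, 0.0]
    assert dihedral(a, b, c, [1.0, 1.0, 0.0]) == pytest.approx(0.0, abs=1e-12)
    assert dihedral(a, b, c, [1.0, -1.0, 0.0]) == pytest.approx(180.0, abs=1e-12)


def test_dihedral_collinear_rejected():
    with pytest.raises(ValueError):
        dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])


@given(
    st.floats(-179.9, 179.9),
    st.floats(30.0, 150.0),
    st.floats(0.8, 2.0),
)
def test_place_atom_dihedral_roundtrip(torsion, angle, length):
    """place_atom and dihedral are exact inverses."""
    a, b, c = np.array([1.0, 1.0, 0.0]), np.zeros(3), np.array([1.5, 0.0, 0.0])
    p = place_atom(a, b, c, length, angle, torsion)
    assert np.linalg.norm(p - c) == pytest.approx(length, abs=1e-9)
    assert dihedral(a, b, c, p) == pytest.approx(torsion, abs=1e-6)
    from atomdiff.geometry import bond_angle

    assert bond_angle(b, c, p) == pytest.approx(angle, abs=1e-6)


def test_place_atom_continuity():
    a, b, c = np.array([1.0, 1.0, 0.0]), np.zeros(3), np.array([1.5, 0.0, 0.0])
    eps = 1e-6
    base = place_atom(a, b, c, 1.5, 109.5, 60.0)
    for d_args in ((eps, 0, 0), (0, eps, 0), (0, 0, eps)):
        moved = place_atom(a, b, c, 1.5 + d_args[0], 109.5 + d_args[1],
                           60.0 + d_args[2])
        assert np.linalg.norm(moved - base) < 1e-4


def test_place_atom_collinear_refs_rejected():
    with pytest.raises(ValueError):
        place_atom([0, 0, 0], [1, 0, 0], [2, 0, 0], 1.5, 109.5, 60.0)


# ------------------------------------------------------------- bond RMSE


def test_ideal_fixture_rmse_zero(helix50):
    assert bond_length_rmse(helix50) == pytest.approx(0.0, abs=1e-12)


def test_single_bond_perturbation_closed_form(helix50):
    """Stretching one of N bonds by delta gives RMSE delta / sqrt(N)."""
    s = helix50.copy()
    n_bonds = len(bond_lengths(s))
    delta = 0.25
    # stretch the final C=O bond along its own axis (shared with no other bond)
    i, c_idx, o_idx = 49, ATOM37_INDEX["C"], ATOM37_INDEX["O"]
    axis = s.coords37[i, o_idx] - s.coords37[i, c_idx]
    s.coords37[i, o_idx] += delta * axis / np.linalg.norm(axis)
    assert bond_length_rmse(s) == pytest.approx(delta / np.sqrt(n_bonds), abs=1e-9)


def test_rmse_invariant_under_rigid_motion(mixed_target):
    assert bond_length_rmse(_rigid(mixed_target)) == pytest.approx(
        bond_length_rmse(mixed_target), abs=1e-9
    )


def test_no_bonds_rejected():
    from atomdiff.residues import CollapsedStructure

    s = CollapsedStructure("A", np.zeros((1, 37, 3)), np.zeros((1, 37), bool))
    with pytest.raises(ValueError):
        bond_length_rmse(s)


def test_bond_angles_ideal_on_fixture(helix50):
    for _, observed, ideal in bond_angles(helix50):
        assert observed == pytest.approx(ideal, abs=1e-6)


def test_ideal_table_lengths_plausible():
    table = default_ideal_table()
    for (_aa, _pair), length in table.bond_length.items():
        assert 1.0 <= length <= 2.1


# ------------------------------------------------------------- chi angles


def test_ala_gly_have_no_chis():
    s = build_fixture(helix_spec(sequence="AGA"))
    for i in range(3):
        assert chi_angles(s, i) == []


def test_ser_chi1_roundtrip():
    spec = InternalCoordinateSpec("SSS", [-57.0] * 3, [-47.0] * 3,
                                  chis=[(60.0,)] * 3)
    s = build_fixture(spec)
    for i in range(3):
        assert chi_angles(s, i) == [pytest.approx(60.0, abs=1e-6)]


def test_all_residue_chis_roundtrip():
    """Every rotatable chi of every residue type is recovered exactly."""
    for aa3, n_chi in N_CHI.items():
        if n_chi == 0 or aa3 == "PRO":
            continue
        aa1 = [k for k, v in AA1_TO_AA3.items() if v == aa3][0]
        chis = tuple(40.0 + 15.0 * k for k in range(n_chi))
        spec = InternalCoordinateSpec(aa1 * 3, [-57.0] * 3, [-47.0] * 3,
                                      chis=[chis] * 3)
        s = build_fixture(spec)
        measured = chi_angles(s, 1)
        for k, (want, got) in enumerate(zip(chis, measured), start=1):
            expect = (want + 90.0) % 180.0 - 90.0 if (aa3, k) in SYMMETRIC_CHI \
                else (want + 180.0) % 360.0 - 180.0
            assert got == pytest.approx(expect, abs=1e-6), (aa3, k)


def test_symmetric_chi_half_range():
    """ASP chi2 is 180-degree periodic: 150 reports as -30."""
    spec = InternalCoordinateSpec("DDD", [-57.0] * 3, [-47.0] * 3,
                                  chis=[(-70.0, 150.0)] * 3)
    s = build_fixture(spec)
    chis = chi_angles(s, 1)
    assert chis[1] == pytest.approx(-30.0, abs=1e-6)
    assert -90.0 <= chis[1] < 90.0


def test_chi_missing_atoms_reported_absent(mixed_target):
    s = mixed_target.copy()
    i = next(k for k, c in enumerate(s.sequence) if AA1_TO_AA3[c] not in ("ALA", "GLY"))
    quad_last = __import__("atomdiff.internal", fromlist=["CHI_ATOMS"]).CHI_ATOMS[
        AA1_TO_AA3[s.sequence[i]]
    ][0][-1]
    s.atom_mask[i, ATOM37_INDEX[quad_last]] = False
    assert chi_angles(s, i)[0] is None


# ---------------------------------------------------------------- phi/psi


def test_helix_phi_psi_recovered(helix50):
    for i, (phi, psi) in enumerate(phi_psi(helix50)):
        if 0 < i:
            assert phi == pytest.approx(-57.0, abs=1e-6)
        if i < 49:
            assert psi == pytest.approx(-47.0, abs=1e-6)


def test_strand_phi_psi_recovered():
    s = build_fixture(strand_spec(10))
    phi, psi = phi_psi(s)[5]
    assert phi == pytest.approx(-139.0, abs=1e-6)
    assert psi == pytest.approx(135.0, abs=1e-6)


def test_termini_absent(helix50):
    pp = phi_psi(helix50)
    assert pp[0][0] is None and pp[-1][1] is None


def test_phi_psi_invariant_under_rigid_motion(helix50):
    a = phi_psi(helix50)
    b = phi_psi(_rigid(helix50, seed=5))
    for (pa, sa), (pb, sb) in zip(a[1:-1], b[1:-1]):
        assert pa == pytest.approx(pb, abs=1e-8)
        assert sa == pytest.approx(sb, abs=1e-8)


def test_chain_break_yields_absent_values(helix50):
    s = helix50.copy()
    s.coords37[25:] += 100.0          # break the chain between 24 and 25
    pp = phi_psi(s)
    assert pp[25][0] is None and pp[24][1] is None
    assert pp[26][0] is not None


# -------------------------------------------------------------- chirality


def test_fixture_chirality_all_L(mixed_target):
    for i, c in enumerate(mixed_target.sequence):
        expected = "undetermined" if c == "G" else "L"
        assert chirality_check(mixed_target, i) == expected


def test_mirror_image_is_D(mixed_target):
    mirror = mixed_target.copy()
    mirror.coords37 = mirror.coords37.copy()
    mirror.coords37[..., 0] *= -1
    for i, c in enumerate(mirror.sequence):
        if c != "G":
            assert chirality_check(mirror, i) == "D"


def test_glycine_undetermined():
    s = build_fixture(helix_spec(sequence="AGA"))
    assert chirality_check(s, 1) == "undetermined"


# ------------------------------------------------------------------ report


def test_full_report(mixed_target):
    rep = evaluate(mixed_target)
    assert rep.bond_length_rmse == pytest.approx(0.0, abs=1e-12)
    assert rep.summary()["n_D_residues"] == 0
    df = rep.to_frame()
    assert {"bond", "observed_A", "ideal_A", "deviation_A"} <= set(df.columns)
    assert len(df) == len(rep.bonds)
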