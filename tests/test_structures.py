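import math

import numpy as np
import pytest

from conftest import brute_force_contacts, quaternion_superpose_rmsd
from gammasec.errors import (
    ChainError,
    ConfigurationError,
    EmptyModelError,
    RegionError,
    SelectionError,
    StructureFormatError,
)
from gammasec.fixtures import HelixSpec, ToyComplexSpec, helix_pair, m1_complex, m2_complex, make_toy_complex
from gammasec.structures import (
    Atom,
    RegionSpec,
    StructureModel,
    catalytic_distances,
    classify_conformation,
    contact_map,
    per_residue_displacement,
    read_structure,
    superpose,
    write_pdb,
)


def rotation_z(deg):
    a = math.radians(deg)
    return np.array([[math.cos(a), -math.sin(a), 0], [math.sin(a), math.cos(a), 0], [0, 0, 1.0]])


@pytest.fixture
def pair_model():
    return helix_pair(separation=12.0, n_residues=18)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------


def test_read_fixture_pdb(tmp_path, pair_model):
    path = tmp_path / "pair.pdb"
    write_pdb(pair_model, path)
    model = read_structure(path)
    assert len(model) == 36
    assert model.chains == ("A", "B")


def test_waters_only_file_is_empty_model(tmp_path):
    path = tmp_path / "waters.pdb"
    path.write_text(
        "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\n"
        "HETATM    2  O   HOH A   2       3.000   0.000   0.000  1.00  0.00           O\n"
        "END\n"
    )
    with pytest.raises(EmptyModelError):
        read_structure(path)


def test_unparseable_file_is_format_error(tmp_path):
    path = tmp_path / "junk.cif"
    path.write_text("this is not a structure\n")
    with pytest.raises((StructureFormatError, EmptyModelError)):
        read_structure(path, format="mmcif")


def test_round_trip_precision(tmp_path):
    spec = ToyComplexSpec(
        helices=(HelixSpec(n_residues=10, chain="A", origin=(0.1234, -5.6789, 2.5)),)
    )
    model = make_toy_complex(spec)
    path = tmp_path / "rt.pdb"
    write_pdb(model, path)
    back = read_structure(path)
    assert len(back) == len(model)
    for a, b in zip(model.atoms, back.atoms):
        assert a.pos == pytest.approx(b.pos, abs=1e-3)  # PDB coordinate precision
        assert (a.chain, a.resnum, a.name, a.element) == (b.chain, b.resnum, b.name, b.element)


def test_hydrogens_and_altlocs_filtered(tmp_path):
    path = tmp_path / "alt.pdb"
    path.write_text(
        "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.50  0.00           C\n"
        "ATOM      2  CA BALA A   1       9.000   9.000   9.000  0.50  0.00           C\n"
        "ATOM      3  H   ALA A   1       1.000   0.000   0.000  1.00  0.00           H\n"
        "END\n"
    )
    model = read_structure(path)
    assert len(model) == 1
    assert model.atoms[0].pos == pytest.approx((0.0, 0.0, 0.0))


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------


def anchor_model(n=25, start=381, jitter_seed=None):
    spec = ToyComplexSpec(
        helices=(HelixSpec(n_residues=n, chain="P", start=start),),
        jitter_sigma=0.3 if jitter_seed is not None else 0.0,
        seed=jitter_seed or 0,
    )
    return make_toy_complex(spec)


def test_superpose_self_is_identity():
    model = anchor_model()
    res = superpose(model, model, [(381, 405)], chain="P")
    assert res.rmsd == pytest.approx(0.0, abs=1e-9)
    assert res.rotation == pytest.approx(np.eye(3), abs=1e-9)
    assert res.translation == pytest.approx(np.zeros(3), abs=1e-9)
    assert abs(np.linalg.det(res.rotation) - 1.0) < 1e-9


def test_superpose_recovers_constructed_transform():
    ref = anchor_model(jitter_seed=7)  # jittered so the cloud is full-rank
    R = rotation_z(90.0)
    t = np.array([5.0, 0.0, 0.0])
    mov = ref.transformed(R, t)
    res = superpose(ref, mov, [(381, 405)], chain="P")
    assert res.rmsd < 1e-6
    # recovered transform is the inverse of the applied one
    assert res.rotation == pytest.approx(R.T, abs=1e-6)
    assert res.translation == pytest.approx(-R.T @ t, abs=1e-6)
    assert res.n_atoms == 25


def test_superpose_matches_quaternion_oracle():
    rng = np.random.default_rng(42)
    for _ in range(10):
        ref_xyz = rng.normal(size=(10, 3)) * 5.0
        mov_xyz = ref_xyz + rng.normal(size=(10, 3))
        ref = StructureModel(
            "r", [Atom("P", i + 1, "", "ALA", "CA", "C", tuple(p)) for i, p in enumerate(ref_xyz)]
        )
        mov = StructureModel(
            "m", [Atom("P", i + 1, "", "ALA", "CA", "C", tuple(p)) for i, p in enumerate(mov_xyz)]
        )
        res = superpose(ref, mov, [(1, 10)], chain="P")
        assert res.rmsd == pytest.approx(quaternion_superpose_rmsd(mov_xyz, ref_xyz), abs=1e-9)


def test_rmsd_invariant_under_rigid_pretransform():
    rng = np.random.default_rng(3)
    ref = anchor_model(jitter_seed=1)
    mov = anchor_model(jitter_seed=2)
    base = superpose(ref, mov, [(381, 405)], chain="P").rmsd
    pre = mov.transformed(rotation_z(37.0), np.array([1.0, -2.0, 3.0]))
    assert superpose(ref, pre, [(381, 405)], chain="P").rmsd == pytest.approx(base, abs=1e-9)


def test_too_few_common_atoms_is_selection_error():
    model = anchor_model()
    with pytest.raises(SelectionError):
        superpose(model, model, [(381, 382)], chain="P")


def test_collinear_selection_sets_rank_warning():
    xyz = [(0.0, 0.0, float(i)) for i in range(5)]
    atoms = [Atom("P", i + 1, "", "ALA", "CA", "C", p) for i, p in enumerate(xyz)]
    line = StructureModel("line", atoms)
    res = superpose(line, line, [(1, 5)], chain="P")
    assert res.rank_warning


def test_per_residue_displacement_identical_models():
    model = anchor_model()
    res = superpose(model, model, [(381, 405)], chain="P")
    disp = per_residue_displacement(model, model, res, (381, 405), chain="P")
    assert len(disp.entries) == 25
    assert all(d == pytest.approx(0.0, abs=1e-9) for _, d in disp.entries)


def test_probe_translation_after_anchor_alignment():
    """Anchor helix fixed, probe helix shifted 7 Å: displacement = 7 everywhere."""
    anchor = HelixSpec(n_residues=20, chain="P", start=381)
    probe_ref = HelixSpec(n_residues=15, chain="P", start=244, origin=(15.0, 0.0, 0.0))
    probe_mov = HelixSpec(n_residues=15, chain="P", start=244, origin=(22.0, 0.0, 0.0))
    ref = make_toy_complex(ToyComplexSpec(helices=(anchor, probe_ref)))
    mov = make_toy_complex(ToyComplexSpec(helices=(anchor, probe_mov)))
    res = superpose(ref, mov, [(381, 400)], chain="P")
    assert res.rmsd < 1e-9
    disp = per_residue_displacement(ref, mov, res, (244, 258), chain="P")
    assert len(disp.entries) == 15
    for _, d in disp.entries:
        assert d == pytest.approx(7.0, abs=1e-6)


def test_displacement_lists_unresolved_probe_residues():
    anchor = HelixSpec(n_residues=20, chain="P", start=381)
    probe_full = HelixSpec(n_residues=15, chain="P", start=244, origin=(15.0, 0.0, 0.0))
    probe_short = HelixSpec(n_residues=10, chain="P", start=244, origin=(15.0, 0.0, 0.0))
    ref = make_toy_complex(ToyComplexSpec(helices=(anchor, probe_full)))
    mov = make_toy_complex(ToyComplexSpec(helices=(anchor, probe_short)))
    res = superpose(ref, mov, [(381, 400)], chain="P")
    disp = per_residue_displacement(ref, mov, res, (244, 258), chain="P")
    assert len(disp.entries) == 10
    assert disp.absent == tuple(range(254, 259))


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------


def test_far_apart_helices_have_no_contacts():
    model = helix_pair(separation=50.0)
    assert len(contact_map(model, "A", "B", 4.5)) == 0


def test_twelve_angstrom_axes_exceed_cutoff(pair_model):
    # min possible Cα–Cα distance is 12 − 2·2.3 = 7.4 Å > 4.5 Å cutoff
    assert len(contact_map(pair_model, "A", "B", 4.5)) == 0


@pytest.mark.parametrize("separation,cutoff", [(7.0, 4.5), (7.0, 6.0), (9.0, 5.5)])
def test_contact_map_equals_brute_force(separation, cutoff):
    model = helix_pair(separation=separation)
    cm = contact_map(model, "A", "B", cutoff)
    oracle = brute_force_contacts(model, "A", "B", cutoff)
    assert cm.pair_set() == set(oracle)
    for a, b, d in cm.pairs:
        assert d == pytest.approx(oracle[(a, b)], abs=1e-9)
    assert len(cm) > 0  # the geometry does produce contacts


def test_contact_map_symmetric_in_chain_order():
    model = helix_pair(separation=7.0)
    ab = contact_map(model, "A", "B", 4.5)
    ba = contact_map(model, "B", "A", 4.5)
    assert {(b, a) for a, b in ab.pair_set()} == ba.pair_set()


def test_shrinking_cutoff_never_adds_pairs():
    model = helix_pair(separation=7.0)
    wide = contact_map(model, "A", "B", 6.0).pair_set()
    narrow = contact_map(model, "A", "B", 4.0).pair_set()
    assert narrow <= wide


def test_contact_map_missing_chain():
    model = helix_pair(separation=7.0)
    with pytest.raises(ChainError):
        contact_map(model, "A", "Z", 4.5)


# ---------------------------------------------------------------------------
# conformation calls
# ---------------------------------------------------------------------------


def test_classify_shipped_fixtures():
    regions = RegionSpec()
    for builder, expected in ((m1_complex, "M1"), (m2_complex, "M2")):
        model = builder()
        cm = contact_map(model, regions.app_chain, regions.ps1_chain, 4.5)
        call = classify_conformation(cm, regions)
        assert call.call == expected
        assert call.m1_score + call.m2_score <= 1.0
        assert (call.m1_score if expected == "M1" else call.m2_score) == 1.0


def test_classify_ambiguous_when_margin_exceeds_gap():
    regions = RegionSpec()
    cm = contact_map(m1_complex(), regions.app_chain, regions.ps1_chain, 4.5)
    call = classify_conformation(cm, regions, margin=1.0)
    assert call.call == "ambiguous"


def test_classify_no_contacts_is_ambiguous():
    regions = RegionSpec()
    model = helix_pair(separation=50.0)
    cm = contact_map(model, "A", "B", 4.5)
    call = classify_conformation(cm, RegionSpec(ps1_chain="B", app_chain="A"))
    assert call.call == "ambiguous"
    assert call.n_contacts == 0


def test_classify_rejects_overlapping_regions():
    regions = RegionSpec(d1=(251, 380), d2=(364, 400))
    cm = contact_map(m1_complex(), "A", "P", 4.5)
    with pytest.raises(ConfigurationError):
        classify_conformation(cm, regions)


# ---------------------------------------------------------------------------
# catalytic distances
# ---------------------------------------------------------------------------


def pseudo_active_site(asp_atoms):
    """One VIAT Cα at the origin region and two pseudo-aspartates."""
    atoms = [Atom("A", 713, "", "ALA", "CA", "C", (0.0, 0.0, 0.0))]
    atoms += asp_atoms
    return StructureModel("site", atoms)


def test_catalytic_distances_by_construction():
    asp = [
        Atom("P", 257, "", "ASP", "CA", "C", (10.0, 0.0, 0.0)),
        Atom("P", 257, "", "ASP", "OD1", "O", (6.0, 0.0, 0.0)),
        Atom("P", 385, "", "ASP", "CA", "C", (0.0, 9.0, 0.0)),
        Atom("P", 385, "", "ASP", "OD1", "O", (0.0, 5.0, 0.0)),
    ]
    model = pseudo_active_site(asp)
    res = catalytic_distances(model, RegionSpec())
    assert res.d_viat_asp1 == pytest.approx(6.0)
    assert res.d_viat_asp2 == pytest.approx(5.0)
    assert not res.asp1_ca_fallback and not res.asp2_ca_fallback


def test_catalytic_distances_ca_fallback_flagged():
    asp = [
        Atom("P", 257, "", "ASP", "CA", "C", (6.0, 0.0, 0.0)),
        Atom("P", 385, "", "ASP", "CA", "C", (0.0, 5.0, 0.0)),
        Atom("P", 385, "", "ASP", "OD2", "O", (0.0, 4.0, 0.0)),
    ]
    res = catalytic_distances(pseudo_active_site(asp), RegionSpec())
    assert res.asp1_ca_fallback and not res.asp2_ca_fallback
    assert res.d_viat_asp1 == pytest.approx(6.0)
    assert res.d_viat_asp2 == pytest.approx(4.0)


def test_catalytic_distances_brute_force_oracle():
    model = m1_complex()
    # toy PS1 helix covers 255-272, so use an aspartate position inside it
    regions = RegionSpec(catalytic_asp=(257, 260), viat=(711, 714))
    res = catalytic_distances(model, regions)
    viat = [a.pos for a in model.atoms if a.chain == "A" and 711 <= a.resnum <= 714]
    for got, asp_pos in ((res.d_viat_asp1, 257), (res.d_viat_asp2, 260)):
        asp = [a.pos for a in model.atoms if a.chain == "P" and a.resnum == asp_pos]
        expected = min(math.dist(v, p) for v in viat for p in asp)
        assert got == pytest.approx(expected, abs=1e-12)


def test_catalytic_distances_unresolvable_regions():
    model = m1_complex()
    with pytest.raises(RegionError):
        catalytic_distances(model, RegionSpec(catalytic_asp=(300, 385)))
    with pytest.raises(RegionError):
        catalytic_distances(model, RegionSpec(viat=(900, 903), catalytic_asp=(257, 260)))


# ---------------------------------------------------------------------------
# region config
# ---------------------------------------------------------------------------


def test_region_spec_from_file(tmp_path):
    cfg = tmp_path / "regions.cfg"
    cfg.write_text(
        "# toy config\n"
        "d1 = B:251-286\n"
        "d2 = B:364-400\n"
        "app_tm = C:700-723\n"
        "viat = C:711-714\n"
        "app_offset = 671\n"
    )
    regions = RegionSpec.from_file(cfg)
    assert regions.ps1_chain == "B" and regions.app_chain == "C"
    assert regions.d1 == (251, 286)
    assert regions.app_position(711) == 40  # Aβ numbering
    bad = tmp_path / "bad.cfg"
    bad.write_text("nope = 1\n")
    with pytest.raises(ConfigurationError):
        RegionSpec.from_file(bad)


def test_region_spec_invariants():
    with pytest.raises(ConfigurationError):
        RegionSpec(viat=(711, 715))  # not 4 residues
    with pytest.raises(ConfigurationError):
        RegionSpec(d1=(286, 251))
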