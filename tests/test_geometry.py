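"""B-factor statistics, backbone torsions and Ramachandran classification."""

import math

import gemmi
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from chainview import fixtures as fx
from chainview.geometry import (
    ConformationClass,
    RamaTable,
    backbone_torsions,
    bfactor_summary,
    dihedral_angle,
    load_default_rama_tables,
    rama_classify,
    rama_probability,
    rama_category,
)
from chainview.model_io import AtomRecord, Residue, structure_to_model


def residue_with_b(values):
    atoms = [
        AtomRecord(f"C{i}", "C", 6, np.array([float(i), 0, 0]), b, 1.0)
        for i, b in enumerate(values)
    ]
    return Residue(1, "", "ALA", atoms)


class TestBFactorSummary:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([10, 10, 10], (10, 10, 10, 0)),
            ([10, 20], (10, 20, 15, 5)),  # population SD
            ([42], (42, 42, 42, 0)),
        ],
    )
    def test_hand_cases(self, values, expected):
        stats = bfactor_summary(residue_with_b(values))
        assert (stats.minimum, stats.maximum, stats.mean, stats.sd) == pytest.approx(
            expected
        )

    def test_matches_brute_force_on_random_residues(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            values = rng.uniform(2, 120, size=rng.integers(1, 12)).tolist()
            stats = bfactor_summary(residue_with_b(values))
            assert stats.minimum == pytest.approx(min(values))
            assert stats.maximum == pytest.approx(max(values))
            assert stats.mean == pytest.approx(sum(values) / len(values))
            mean = sum(values) / len(values)
            var = sum((v - mean) ** 2 for v in values) / len(values)
            assert stats.sd == pytest.approx(math.sqrt(var))
            assert stats.minimum <= stats.mean <= stats.maximum

    def test_hydrogens_excluded_by_default(self):
        atoms = [
            AtomRecord("CA", "C", 6, np.zeros(3), 10.0, 1.0),
            AtomRecord("H", "H", 1, np.ones(3), 99.0, 1.0),
        ]
        res = Residue(1, "", "ALA", atoms)
        assert bfactor_summary(res).mean == pytest.approx(10.0)
        assert bfactor_summary(res, include_hydrogens=True).mean == pytest.approx(
            54.5
        )

    def test_no_atoms_returns_absent(self):
        res = Residue(1, "", "ALA", [AtomRecord("H", "H", 1, np.zeros(3), 1, 1)])
        assert bfactor_summary(res) is None


class TestBackboneTorsions:
    def test_helix_fixture_recovers_input_angles(self, helix_model):
        chain = helix_model.chains[0]
        for i in range(1, len(chain.residues) - 1):
            phi, psi = backbone_torsions(chain, i)
            assert phi == pytest.approx(-57.0, abs=1e-3)
            assert psi == pytest.approx(-47.0, abs=1e-3)

    def test_chain_termini_have_absent_angles(self, helix_model):
        chain = helix_model.chains[0]
        phi0, psi0 = backbone_torsions(chain, 0)
        assert phi0 is None and psi0 is not None
        phin, psin = backbone_torsions(chain, len(chain.residues) - 1)
        assert phin is not None and psin is None

    def test_collinear_atoms_give_absent_torsion(self):
        p = [np.array([float(i), 0.0, 0.0]) for i in range(4)]
        assert dihedral_angle(*p) is None

    def test_agrees_with_gemmi_dihedral(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 3
            ours = dihedral_angle(*pts)
            if ours is None:
                continue
            ref = math.degrees(
                gemmi.calculate_dihedral(*(gemmi.Position(*p) for p in pts))
            )
            if ref >= 180.0:
                ref -= 360.0
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_rigid_motion_invariance(self, helix_spec):
        base = structure_to_model(fx.synthetic_model(helix_spec))
        rotated = structure_to_model(fx.synthetic_model(helix_spec))
        rot = Rotation.from_euler("xyz", [31.0, -68.0, 114.0], degrees=True)
        shift = np.array([5.0, -3.0, 12.0])
        for chain in rotated.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    new = rot.apply(atom.position) + shift
                    object.__setattr__(atom, "position", new)
        for i in range(len(base.chains[0].residues)):
            a = backbone_torsions(base.chains[0], i)
            b = backbone_torsions(rotated.chains[0], i)
            for x, y in zip(a, b):
                if x is None:
                    assert y is None
                else:
                    assert x == pytest.approx(y, abs=1e-6)

    def test_chain_break_suppresses_angles(self, helix_spec):
        model = structure_to_model(fx.synthetic_model(helix_spec))
        chain = model.chains[0]
        # translate the tail of the chain away to open a break before idx 4
        for res in chain.residues[4:]:
            for atom in res.atoms:
                object.__setattr__(atom, "position", atom.position + 50.0)
        phi4, _ = backbone_torsions(chain, 4)
        _, psi3 = backbone_torsions(chain, 3)
        assert phi4 is None
        assert psi3 is None


class TestRamaProbability:
    def test_uniform_table_returns_constant(self):
        table = RamaTable("general", np.full((8, 8), 0.5), -180, -180, 45, 45)
        for phi, psi in [(-57, -47), (0, 0), (179, -180)]:
            assert rama_probability(phi, psi, table) == pytest.approx(0.5)

    def test_grid_node_identity(self):
        rng = np.random.default_rng(1)
        grid = rng.random((12, 12))
        table = RamaTable("general", grid, -180, -180, 30, 30)
        assert rama_probability(-180 + 30 * 3, -180 + 30 * 7, table) == pytest.approx(
            grid[3, 7]
        )

    def test_midpoint_bilinear_value(self):
        grid = np.zeros((4, 4))
        # cell corners (0,0),(1,0) -> 0 ; (0,1),(1,1) -> 1
        grid[0, 1] = grid[1, 1] = 1.0
        table = RamaTable("general", grid, -180, -180, 90, 90)
        # midpoint of the 4 nodes: average of {0,0,1,1} = 0.5
        assert rama_probability(-135, -135, table) == pytest.approx(0.5)

    def test_periodic_wrap(self):
        rng = np.random.default_rng(2)
        grid = rng.random((24, 24))
        table = RamaTable("general", grid, -180, -180, 15, 15)
        assert rama_probability(-180, 0, table) == pytest.approx(
            rama_probability(180, 0, table)
        )


class TestRamaClassify:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.02, ConformationClass.FAVORED),  # boundary inclusive
            (0.5, ConformationClass.FAVORED),
            (0.01, ConformationClass.ALLOWED),
            (0.002, ConformationClass.ALLOWED),
            (0.0, ConformationClass.OUTLIER),
            (0.001, ConformationClass.OUTLIER),
        ],
    )
    def test_default_thresholds(self, p, expected):
        assert rama_classify(p) is expected

    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    def test_partition_exactly_one_class(self, p):
        cls = rama_classify(p)
        assert cls in (
            ConformationClass.FAVORED,
            ConformationClass.ALLOWED,
            ConformationClass.OUTLIER,
        )

    @given(
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
    )
    def test_monotone_in_probability(self, p1, p2):
        order = {
            ConformationClass.OUTLIER: 0,
            ConformationClass.ALLOWED: 1,
            ConformationClass.FAVORED: 2,
        }
        lo, hi = sorted([p1, p2])
        assert order[rama_classify(lo)] <= order[rama_classify(hi)]


class TestRamaCategory:
    def test_categories(self):
        gly = Residue(1, "", "GLY", [AtomRecord("CA", "C", 6, np.zeros(3), 1, 1)])
        pro = Residue(2, "", "PRO", [AtomRecord("CA", "C", 6, np.zeros(3), 1, 1)])
        val = Residue(3, "", "VAL", [AtomRecord("CA", "C", 6, np.zeros(3), 1, 1)])
        ala = Residue(4, "", "ALA", [AtomRecord("CA", "C", 6, np.zeros(3), 1, 1)])
        assert rama_category(gly, None) == "GLY"
        assert rama_category(pro, None) == "PRO"
        assert rama_category(ala, pro) == "pre-PRO"
        assert rama_category(val, None) == "ILE_VAL"
        assert rama_category(ala, val) == "general"

    def test_default_tables_cover_all_categories(self):
        tables = load_default_rama_tables()
        assert {"general", "GLY", "PRO", "pre-PRO", "ILE_VAL"} <= set(tables)
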