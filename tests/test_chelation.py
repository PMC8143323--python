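"""Chelate construction, job-spec emission, and binding-energy bookkeeping."""

import json
import math
from importlib import resources

import numpy as np
import pytest

from fqchelate import chelation
from fqchelate.chelation import (
    HARTREE_TO_KCAL,
    METALS,
    Species,
    TorsionRule,
    binding_energy,
    build_chelate_geometry,
    donor_bond_lengths,
    emit_qm_jobspec,
    enumerate_conformer_starts,
    hartree_to_kcal,
    kcal_to_hartree,
    ledger_binding_energies,
    make_binding_reaction,
    metal_hexahydrate,
    parse_qm_jobspec,
    protonated_fq_cation,
    read_xyz,
    water_species,
    write_xyz,
)
from fqchelate.errors import (
    AdapterError,
    DomainError,
    GeometryError,
    LedgerError,
    StoichiometryError,
    SubstructureError,
)

CIPRO = "C1CC1N2C=C(C(=O)C3=CC(=C(C=C32)N4CCNCC4)F)C(=O)O"


def ledger_path():
    return str(
        resources.files("fqchelate.data").joinpath("fig2_energies_synthetic.json")
    )


def simple_species(label, role, charge, formula, e=0.0, g=0.0):
    return Species(
        label=label, role=role, charge=charge, formula=formula,
        e_pcm_sp=e, g_thermal_corr=g,
    )


@pytest.fixture(scope="module")
def cipro_cation():
    return protonated_fq_cation(CIPRO, label="cipro_cation")


class TestUnitConversion:
    def test_constant(self):
        assert hartree_to_kcal(1.0) == 627.5095

    def test_round_trip_identity(self):
        for value in (-16.1, 0.9, 123.456):
            assert kcal_to_hartree(hartree_to_kcal(value)) == pytest.approx(
                value, rel=1e-12
            )

    def test_centihartree(self):
        assert hartree_to_kcal(-0.01) == pytest.approx(-6.275095, rel=1e-12)


class TestCationConstruction:
    def test_charge_and_donors(self, cipro_cation):
        assert cipro_cation.charge == 1
        assert cipro_cation.role == "fq_cation"
        i_cbx, i_keto = cipro_cation.donor_indices
        elems = [atom[0] for atom in cipro_cation.geometry]
        assert elems[i_cbx] == "O" and elems[i_keto] == "O"
        # composition gains one proton over the neutral C17H18FN3O3 drug
        comp = cipro_cation.composition()
        assert (comp["C"], comp["H"], comp["N"], comp["O"], comp["F"]) == (17, 19, 3, 3, 1)

    def test_pocket_oxygens_are_close(self, cipro_cation):
        coords = cipro_cation.coords()
        i, j = cipro_cation.donor_indices
        assert 2.0 < np.linalg.norm(coords[i] - coords[j]) < 3.6

    def test_structure_without_pocket_rejected(self):
        with pytest.raises(SubstructureError):
            protonated_fq_cation("CCN")  # amine, but no carboxyl/keto pocket


class TestChelateGeometry:
    @pytest.mark.parametrize("metal, expected_charge", [("Al", 4), ("Mg", 3), ("Ca", 3)])
    def test_complex_charge(self, cipro_cation, metal, expected_charge):
        cplx = build_chelate_geometry(cipro_cation, metal)
        assert cplx.charge == expected_charge

    def test_six_coordinate_metal_with_four_waters(self, cipro_cation):
        cplx = build_chelate_geometry(cipro_cation, "Mg")
        # FQ atoms + metal + 4 waters of 3 atoms
        assert len(cplx.geometry) == len(cipro_cation.geometry) + 1 + 12
        coords = cplx.coords()
        m_idx = next(i for i, a in enumerate(cplx.geometry) if a[0] == "Mg")
        oxygens = [
            i for i, a in enumerate(cplx.geometry)
            if a[0] == "O" and np.linalg.norm(coords[i] - coords[m_idx]) < 2.6
        ]
        assert len(oxygens) == 6  # 2 donors + 4 waters

    def test_hexahydrate_minus_complex_displaces_two_waters(self, cipro_cation):
        hexa = metal_hexahydrate("Ca")
        cplx = build_chelate_geometry(cipro_cation, "Ca")
        n_water_o = sum(1 for a in hexa.geometry if a[0] == "O")
        complex_water_o = (
            sum(1 for a in cplx.geometry if a[0] == "O")
            - sum(1 for a in cipro_cation.geometry if a[0] == "O")
        )
        assert n_water_o - complex_water_o == 2

    def test_donor_distances_match_metal_radius(self, cipro_cation):
        for metal, (_q, d) in METALS.items():
            cplx = build_chelate_geometry(cipro_cation, metal)
            d1, d2 = donor_bond_lengths(cplx)
            assert d1 == pytest.approx(d, abs=1e-6)
            assert d2 == pytest.approx(d, abs=1e-6)

    def test_unknown_metal_rejected(self, cipro_cation):
        with pytest.raises(DomainError):
            build_chelate_geometry(cipro_cation, "Fe")


class TestDonorBondLengths:
    def test_coordinate_geometry(self):
        cplx = Species(
            label="toy", role="chelate_complex", charge=4,
            geometry=[("O", 1.9, 0.0, 0.0), ("O", 0.0, 1.8, 0.0), ("Al", 0.0, 0.0, 0.0)],
            donor_indices=(0, 1),
        )
        assert donor_bond_lengths(cplx) == (pytest.approx(1.9), pytest.approx(1.8))

    def test_symmetric_donors_have_equal_lengths(self):
        cplx = Species(
            label="toy", role="chelate_complex", charge=4,
            geometry=[("O", 1.0, 1.0, 0.0), ("O", -1.0, 1.0, 0.0), ("Mg", 0.0, 0.0, 0.0)],
            donor_indices=(0, 1),
        )
        d1, d2 = donor_bond_lengths(cplx)
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_two_metals_rejected(self):
        cplx = Species(
            label="toy", role="chelate_complex", charge=4,
            geometry=[("Al", 0, 0, 0), ("Al", 3, 0, 0), ("O", 1.9, 0, 0)],
        )
        with pytest.raises(SubstructureError):
            donor_bond_lengths(cplx)


class TestConformerStarts:
    @staticmethod
    def chain_species():
        # butane-like 4-atom chain with one rotatable torsion
        return Species(
            label="chain", role="fq_cation", charge=1,
            geometry=[
                ("C", 0.0, 0.0, 0.0),
                ("C", 1.5, 0.0, 0.0),
                ("C", 2.25, 1.3, 0.0),
                ("C", 3.75, 1.3, 0.0),
            ],
        )

    def test_grid_bound_and_dedup(self):
        species = self.chain_species()
        rule = TorsionRule((0, 1, 2, 3), (0.0, 120.0, 240.0), frozenset({3}))
        starts = enumerate_conformer_starts(species, [rule])
        assert 1 <= len(starts) <= 3
        # duplicated grid angle collapses to a single start
        dup = TorsionRule((0, 1, 2, 3), (60.0, 60.0), frozenset({3}))
        assert len(enumerate_conformer_starts(species, [dup])) == 1

    def test_adapter_sorts_ascending(self):
        species = self.chain_species()
        rule = TorsionRule((0, 1, 2, 3), (0.0, 120.0, 240.0), frozenset({3}))

        def score(geometry):  # arbitrary deterministic score
            return -geometry[3][1]

        starts = enumerate_conformer_starts(species, [rule], adapter=score)
        scores = [score(s.geometry) for s in starts]
        assert scores == sorted(scores)

    def test_adapter_failure_serializes_geometry(self):
        species = self.chain_species()
        rule = TorsionRule((0, 1, 2, 3), (0.0,), frozenset({3}))

        def broken(geometry):
            raise RuntimeError("engine crashed")

        with pytest.raises(AdapterError, match="C 0.0"):
            enumerate_conformer_starts(species, [rule], adapter=broken)


class TestJobSpecs:
    def test_frequencies_stage_carries_310K(self):
        spec = parse_qm_jobspec(emit_qm_jobspec(water_species(), "frequencies"))
        assert spec.temperature == 310.0
        assert spec.basis == "6-31G(d)"

    def test_single_point_stage_uses_diffuse_basis_and_pcm(self):
        spec = parse_qm_jobspec(emit_qm_jobspec(water_species(), "single_point"))
        assert spec.basis == "6-31+G(d,p)"
        assert spec.solvent_model == "pcm_water"

    def test_emit_parse_emit_is_byte_identical(self):
        text = emit_qm_jobspec(metal_hexahydrate("Al"), "optimize")
        again = chelation.serialize_qm_jobspec(parse_qm_jobspec(text))
        assert again == text

    def test_missing_geometry_rejected(self):
        bare = Species(label="ghost", role="water", charge=0, formula="H2O")
        with pytest.raises(DomainError):
            emit_qm_jobspec(bare, "optimize")


class TestBindingEnergy:
    @staticmethod
    def toy_reaction(e_complex=0.0, g_complex=0.0, **kwargs):
        fq = simple_species("fq", "fq_cation", 1, "C17H19FN3O3",
                            kwargs.get("e_fq", 0.0), kwargs.get("g_fq", 0.0))
        hexa = simple_species("hex", "metal_hexahydrate", 3, "AlH12O6",
                              kwargs.get("e_hex", 0.0), kwargs.get("g_hex", 0.0))
        water = simple_species("w", "water", 0, "H2O",
                               kwargs.get("e_w", 0.0), kwargs.get("g_w", 0.0))
        cplx = simple_species("cplx", "chelate_complex", 4, "C17H27AlFN3O7",
                              e_complex, g_complex)
        return cplx, fq, hexa, water

    def test_null_reaction_is_zero(self):
        assert binding_energy(*self.toy_reaction()) == 0.0

    def test_conversion_applied(self):
        cplx, fq, hexa, water = self.toy_reaction(e_complex=-0.01)
        assert binding_energy(cplx, fq, hexa, water) == pytest.approx(-6.275095)

    def test_hand_summed_fixture(self):
        # independent spreadsheet-style hand sum:
        # (-1558.6035 + 2*(-76.33)) - (-1010.50 - 700.80) = 0.0365 Eh
        cplx, fq, hexa, water = self.toy_reaction(
            e_complex=-1558.6035, e_fq=-1010.50, e_hex=-700.80, e_w=-76.33
        )
        assert binding_energy(cplx, fq, hexa, water) == pytest.approx(
            0.0365 * HARTREE_TO_KCAL, rel=1e-9
        )

    def test_gibbs_adds_thermal_corrections(self):
        cplx, fq, hexa, water = self.toy_reaction(
            e_complex=0.0, g_complex=0.01, g_fq=0.002, g_hex=0.003, g_w=0.001
        )
        expected = (0.01 + 2 * 0.001 - 0.002 - 0.003) * HARTREE_TO_KCAL
        assert binding_energy(cplx, fq, hexa, water, "gibbs") == pytest.approx(expected)

    def test_unbalanced_atoms_rejected(self):
        cplx, fq, hexa, water = self.toy_reaction()
        bad_fq = simple_species("fq", "fq_cation", 1, "C16H19FN3O3")  # lost a carbon
        with pytest.raises(StoichiometryError, match="C"):
            binding_energy(cplx, bad_fq, hexa, water)

    def test_unbalanced_charge_rejected(self):
        cplx, fq, hexa, water = self.toy_reaction()
        bad_cplx = simple_species("cplx", "chelate_complex", 3, "C17H27AlFN3O7")
        with pytest.raises(StoichiometryError, match="charge"):
            binding_energy(bad_cplx, fq, hexa, water)

    def test_missing_energy_component_rejected(self):
        cplx, fq, hexa, water = self.toy_reaction()
        fq.g_thermal_corr = None
        with pytest.raises(LedgerError, match="g_thermal_corr"):
            binding_energy(cplx, fq, hexa, water, "gibbs")

    def test_hess_additivity_over_composed_steps(self):
        # step1: A -> B, step2: B -> C share the intermediate B; the total
        # equals the sum of the steps exactly
        def g(label, e):
            return simple_species(label, "water", 0, "H2O", e, 0.0)

        a, b, c = g("a", -76.40), g("b", -76.35), g("c", -76.30)
        step1 = hartree_to_kcal(b.e_pcm_sp - a.e_pcm_sp)
        step2 = hartree_to_kcal(c.e_pcm_sp - b.e_pcm_sp)
        total = hartree_to_kcal(c.e_pcm_sp - a.e_pcm_sp)
        assert total == pytest.approx(step1 + step2, abs=1e-12)


class TestLedger:
    def test_reference_gibbs_ordering_reproduced(self):
        rows = {r["label"]: r for r in ledger_binding_energies(ledger_path())}
        dg = {m: rows[f"ciprofloxacin+{m}"]["delta_g_bind_kcal"] for m in ("Al", "Mg", "Ca")}
        assert dg["Al"] == pytest.approx(-16.1, abs=1e-6)
        assert dg["Mg"] == pytest.approx(-5.3, abs=1e-6)
        assert dg["Ca"] == pytest.approx(0.9, abs=1e-6)
        assert dg["Al"] < dg["Mg"] < dg["Ca"]

    def test_corrupted_ledger_rejected(self, tmp_path):
        payload = json.loads(open(ledger_path()).read())
        for entry in payload["species"]:
            if entry["role"] == "fq_cation":
                entry["formula"] = "C17H18FN3O3"  # drop the extra proton
        bad = tmp_path / "bad.json"
        bad.write_text(json.dumps(payload))
        with pytest.raises(StoichiometryError):
            ledger_binding_energies(bad)

    def test_reaction_object_checks_balance(self):
        cplx, fq, hexa, water = TestBindingEnergy.toy_reaction()
        rxn = make_binding_reaction(cplx, fq, hexa, water)
        assert rxn.delta_e_bind == 0.0 and rxn.delta_g_bind == 0.0


class TestXYZ:
    def test_round_trip(self, tmp_path, cipro_cation):
        path = tmp_path / "cipro.xyz"
        write_xyz(cipro_cation, path)
        back = read_xyz(path, role="fq_cation", charge=1)
        assert len(back.geometry) == len(cipro_cation.geometry)
        np.testing.assert_allclose(back.coords(), cipro_cation.coords(), atol=1e-6)
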