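"""Model container, I/O round-trips and bound-editing semantics."""

import json

import numpy as np
import pytest

from redoxplane import (
    ModelParseError,
    apply_deletions,
    fba,
    load_model,
    set_uptake,
)
from redoxplane.model_core import MetabolicModel, objective_connectivity_report


class TestRoundTrips:
    def test_json_roundtrip_is_exact(self, sc, tmp_path):
        path = tmp_path / "sc.json"
        sc.write_json(path)
        back = load_model(path, format="bigg_json")
        assert back.model_id == sc.model_id
        assert [m.id for m in back.metabolites] == [m.id for m in sc.metabolites]
        assert [r.id for r in back.reactions] == [r.id for r in sc.reactions]
        assert np.array_equal(back.lower_bounds, sc.lower_bounds)
        assert np.array_equal(back.upper_bounds, sc.upper_bounds)
        assert np.array_equal(back.objective_coeffs, sc.objective_coeffs)
        assert (back.S != sc.S).nnz == 0

    @pytest.mark.parametrize("toy", ["sc", "ss"])
    def test_sbml_roundtrip_preserves_network_and_optimum(
        self, toy, sc, ss, tmp_path
    ):
        model = {"sc": sc, "ss": ss}[toy]
        path = tmp_path / f"{toy}.xml"
        model.write_sbml(path)
        back = load_model(path, format="sbml")
        assert back.n_reactions == model.n_reactions
        assert back.n_metabolites == model.n_metabolites
        assert np.allclose(back.lower_bounds, model.lower_bounds)
        assert np.allclose(back.upper_bounds, model.upper_bounds)
        assert back.objective_id == model.objective_id
        assert abs(fba(back).objective - fba(model).objective) < 1e-9

    def test_loading_same_file_twice_is_deterministic(self, sc, tmp_path):
        path = tmp_path / "sc.json"
        sc.write_json(path)
        a, b = load_model(path), load_model(path)
        assert [r.id for r in a.reactions] == [r.id for r in b.reactions]
        assert np.array_equal(a.lower_bounds, b.lower_bounds)
        assert (a.S != b.S).nnz == 0


class TestLoadErrors:
    def test_zero_reaction_model_is_a_parse_error(self, tmp_path):
        path = tmp_path / "empty.json"
        path.write_text(json.dumps({"id": "m", "metabolites": [], "reactions": []}))
        with pytest.raises(ModelParseError, match="zero reactions"):
            load_model(path)

    def test_garbage_file_is_a_parse_error(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(ModelParseError):
            load_model(path)

    def test_unknown_format_suffix(self, tmp_path):
        path = tmp_path / "model.dat"
        path.write_text("")
        with pytest.raises(ModelParseError, match="guess"):
            load_model(path)

    def test_model_without_objective_loads_with_warning_and_refuses_fba(
        self, sc, tmp_path
    ):
        d = sc.to_dict()
        for r in d["reactions"]:
            r["objective_coefficient"] = 0.0
        path = tmp_path / "noobj.json"
        path.write_text(json.dumps(d))
        with pytest.warns(UserWarning, match="no objective"):
            model = load_model(path)
        assert model.no_objective_warning
        with pytest.raises(ValueError, match="no objective"):
            fba(model)


class TestInvariants:
    def test_bound_ordering_enforced(self, sc):
        bad = sc.copy()
        bad.lower_bounds[0] = 5.0
        bad.upper_bounds[0] = -5.0
        with pytest.raises(ValueError, match="lower bound exceeds"):
            bad.validate()

    def test_duplicate_reaction_ids_rejected(self, sc):
        with pytest.raises(ValueError, match="already present"):
            sc.add_reaction("BIOMASS", {"atp_c": -1}, 0, 1)

    def test_every_reaction_column_nonempty(self, sc):
        assert (sc.S.getnnz(axis=0) > 0).all()

    def test_exchanges_are_single_metabolite_columns(self, sc):
        # the maintenance drain is a single-metabolite column, hence a
        # boundary reaction by the structural definition (as in COBRA)
        assert set(sc.exchange_ids) == {
            "EX_glc", "EX_o2", "EX_eth", "EX_glyc", "EX_co2", "ATPM"
        }

    def test_objective_metabolites_reachable_from_exchanges(self, sc, ss):
        assert objective_connectivity_report(sc) == []
        assert objective_connectivity_report(ss) == []


class TestSetUptake:
    def test_uptake_becomes_negative_lower_bound(self, ss):
        m = set_uptake(ss, "EX_glc", 4.45)
        assert m.lower_bounds[m.reaction_index("EX_glc")] == -4.45

    def test_zero_uptake_closes_exchange(self, sc):
        m = set_uptake(sc, "EX_o2", 0)
        j = m.reaction_index("EX_o2")
        assert m.lower_bounds[j] == 0

    def test_unbounded_maps_to_default_bound(self, sc):
        m = set_uptake(sc, "EX_o2", "unbounded")
        assert m.lower_bounds[m.reaction_index("EX_o2")] == -1000

    def test_original_model_is_never_mutated(self, sc):
        before = sc.lower_bounds.copy()
        set_uptake(sc, "EX_o2", 3.3)
        assert np.array_equal(sc.lower_bounds, before)

    def test_non_exchange_and_negative_uptake_rejected(self, sc):
        with pytest.raises(ValueError, match="not an exchange"):
            set_uptake(sc, "FERM", 1.0)
        with pytest.raises(ValueError, match="non-negative"):
            set_uptake(sc, "EX_o2", -1.0)


class TestApplyDeletions:
    def test_deletion_pins_bounds_to_zero(self, ss):
        m = apply_deletions(ss, {"NDH1", "AOX"})
        for rid in ("NDH1", "AOX"):
            j = m.reaction_index(rid)
            assert m.lower_bounds[j] == m.upper_bounds[j] == 0

    def test_empty_set_is_identity(self, sc):
        m = apply_deletions(sc, set())
        assert np.array_equal(m.lower_bounds, sc.lower_bounds)
        assert np.array_equal(m.upper_bounds, sc.upper_bounds)

    def test_unknown_ids_listed_in_error(self, sc):
        with pytest.raises(KeyError, match="NOPE"):
            apply_deletions(sc, {"FERM", "NOPE"})

    def test_deleting_biomass_gives_zero_growth(self, sc):
        m = apply_deletions(sc, {"BIOMASS"})
        assert fba(m, check_degeneracy=False).objective == pytest.approx(0.0, abs=1e-9)

    def test_input_not_mutated(self, sc):
        before = sc.upper_bounds.copy()
        apply_deletions(sc, {"FERM"})
        assert np.array_equal(sc.upper_bounds, before)
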