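"""Model-document validation, serialisation round-trips and SBML export."""

import numpy as np
import pytest

import hepaflux.fixtures as fx
from hepaflux.document import (
    DocumentError,
    MetaboliteSpec,
    ModelDocument,
    ReactionSpec,
    document_from_dict,
    document_to_dict,
    load_model,
    validate_model,
    write_model,
)
from hepaflux.ratelaws import RateLaw


class TestValidation:
    def test_reference_counts(self, reference_doc):
        rep = validate_model(reference_doc, reference=True)
        assert rep.ok and rep.reference_ok
        assert rep.counts["species"] == 34
        assert rep.counts["reactions"] == 47
        assert rep.counts["dynamic_reactions"] == 27
        assert rep.counts["static_reactions"] == 20
        assert rep.counts["x_d"] == 13
        assert rep.counts["x_s"] == 21
        assert rep.counts["zonation_overrides"] == 13

    def test_reference_parameters_have_provenance(self, reference_doc):
        prov = reference_doc.metadata["provenance"]
        for r in reference_doc.reactions:
            if r.rate_law is None:
                continue
            for p in r.rate_law.parameters:
                assert f"{r.id}.{p}" in prov

    def test_empty_document_fails_with_both_messages(self):
        rep = validate_model(ModelDocument([], []))
        assert not rep.ok
        assert "no species" in rep.errors
        assert "no reactions" in rep.errors

    def test_dynamic_reaction_without_rate_law_rejected(self):
        with pytest.raises(DocumentError, match="lacks a rate law"):
            ReactionSpec("r1", {"a": -1.0}, "dynamic")

    def test_boundary_species_in_stoichiometry_rejected(self):
        doc = ModelDocument(
            [MetaboliteSpec("b", boundary=True), MetaboliteSpec("a", initial=1.0)],
            [ReactionSpec("r", {"b": -1, "a": 1}, "static")],
        )
        rep = validate_model(doc)
        assert any("boundary species" in e for e in rep.errors)

    def test_wrong_zonation_count_flagged_against_reference(self, reference_doc):
        doc = reference_doc.copy()
        # remove one zonation difference: set pericentral equal to periportal
        key = ("v_GK", "Vmax")
        doc.zones["pericentral"][key] = doc.zones["periportal"][key]
        rep = validate_model(doc, reference=True)
        assert rep.ok
        assert any("zonation count mismatch" in e for e in rep.reference_errors)


class TestRoundTrip:
    def test_reference_document_round_trip(self, reference_doc, tmp_path):
        path = tmp_path / "model.yaml"
        write_model(reference_doc, path)
        loaded = load_model(path)
        assert document_to_dict(loaded) == document_to_dict(reference_doc)

    @pytest.mark.parametrize("seed", range(5))
    def test_generated_toy_documents_round_trip(self, seed, tmp_path):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        toy = fx.make_linear_chain(n, seed=seed)
        path = tmp_path / "toy.yaml"
        write_model(toy.document, path)
        assert document_to_dict(load_model(path)) == document_to_dict(toy.document)

    def test_unknown_fields_rejected(self):
        data = document_to_dict(fx.make_branch_mfa().document)
        data["species"][0]["flavour"] = "strange"
        with pytest.raises(DocumentError, match="unknown field"):
            document_from_dict(data)

    def test_missing_rate_law_rejected_on_load(self):
        data = document_to_dict(fx.make_linear_chain(3).document)
        del data["reactions"][0]["rate_law"]
        with pytest.raises(DocumentError, match="lacks a rate law"):
            document_from_dict(data)

    def test_unparseable_file_rejected(self, tmp_path):
        path = tmp_path / "broken.yaml"
        path.write_text("species: [unclosed\n")
        with pytest.raises(DocumentError):
            load_model(path)


class TestIntermediateZone:
    def test_midpoint_interpolation(self, reference_doc):
        pp = reference_doc.zone_profile("periportal")
        pc = reference_doc.zone_profile("pericentral")
        mid = reference_doc.zone_profile("intermediate")
        for key in set(pp.overrides) | set(pc.overrides):
            lo = pp.overrides[key]
            hi = pc.overrides[key]
            assert mid.overrides[key] == pytest.approx(0.5 * (lo + hi))

    def test_unknown_zone_rejected(self, reference_doc):
        with pytest.raises(DocumentError):
            reference_doc.zone_profile("zone-x")


class TestPresetsScaling:
    def test_scale_vmax_touches_base_and_overrides(self, reference_doc):
        doc = reference_doc.copy()
        before = doc.reaction("v_PEPCK").rate_law.parameters["Vmax"]
        before_pp = doc.zones["periportal"][("v_PEPCK", "Vmax")]
        doc.scale_vmax("v_PEPCK", 1.5)
        assert doc.reaction("v_PEPCK").rate_law.parameters["Vmax"] == pytest.approx(1.5 * before)
        assert doc.zones["periportal"][("v_PEPCK", "Vmax")] == pytest.approx(1.5 * before_pp)
        # the original document is untouched
        assert reference_doc.zones["periportal"][("v_PEPCK", "Vmax")] == before_pp


class TestSbmlExport:
    def test_reference_export_structure(self, reference_doc, tmp_path):
        from hepaflux.sbml import export_sbml
        from lxml import etree

        path = tmp_path / "model.xml"
        export_sbml(reference_doc, path)
        tree = etree.parse(str(path))
        ns = {"s": "http://www.sbml.org/sbml/level3/version2/core"}
        reactions = tree.findall(".//s:reaction", ns)
        assert len(reactions) == 47
        species = tree.findall(".//s:species", ns)
        assert len(species) == 37  # 34 balanced + 3 boundary
        kinetic = tree.findall(".//s:kineticLaw", ns)
        assert len(kinetic) == 27  # dynamic reactions only

    def test_export_reimported_by_sbml_library(self, reference_doc, tmp_path):
        libsbml = pytest.importorskip("libsbml")
        from hepaflux.sbml import export_sbml

        path = tmp_path / "model.xml"
        export_sbml(reference_doc, path)
        sdoc = libsbml.readSBMLFromFile(str(path))
        assert sdoc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) == 0
        model = sdoc.getModel()
        assert model.getNumReactions() == 47
        assert model.getNumSpecies() == 37

    def test_no_zone_annotation_without_overrides(self, tmp_path):
        from hepaflux.sbml import export_sbml
        toy = fx.make_linear_chain(3)
        path = tmp_path / "toy.xml"
        export_sbml(toy.document, path)
        assert b"zonation" not in path.read_bytes()
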