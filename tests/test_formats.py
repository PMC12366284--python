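"""JSON canonical format, MRV subset reader and graph export."""

import json

import networkx as nx
import pandas as pd
import pytest

from mechsim import (
    GeneratorConfig,
    MechanismParseError,
    MechanismValidationError,
    Mechanism,
    MrvParseError,
    ONE_AWAY,
    export_similarity_graph,
    extract_arrow_env,
    make_fig1_step,
    parse_mechanism_json,
    parse_mrv_step,
    random_mechanism,
    write_mechanism_json,
)
from mechsim.generate import BUNDLED_FIXTURES, load_bundled, make_glycosidase_pair

PRINTED = "[#6]-[#8&-:23].[#8]-[#6:22](-[#8])(-[#1])-[#6]"


class TestJson:
    def test_round_trip_is_identity_on_canonical_form(self, pair, small_corpus):
        for mech in (*pair, *small_corpus[:3]):
            text = write_mechanism_json(mech)
            again = write_mechanism_json(parse_mechanism_json(text))
            assert text == again

    def test_write_is_byte_stable(self, pair):
        a, _ = pair
        assert write_mechanism_json(a) == write_mechanism_json(a)

    def test_annotations_preserved_verbatim(self, pair):
        a, _ = pair
        back = parse_mechanism_json(write_mechanism_json(a))
        assert dict(back.annotations) == dict(a.annotations)

    def test_glycosidase_fixture_file_shape(self):
        mech = load_bundled("alpha_amylase")
        assert len(mech.steps) == 2
        assert all(len(s.arrows) == 3 for s in mech.steps)

    def test_malformed_json_reports_position(self):
        with pytest.raises(MechanismParseError, match=r"line \d+ column \d+"):
            parse_mechanism_json('{"format_version": "1.0",,}')

    def test_missing_keys_is_parse_error(self):
        with pytest.raises(MechanismParseError):
            parse_mechanism_json('{"format_version": "1.0"}')

    def test_empty_steps_is_validation_error(self):
        doc = {"format_version": "1.0", "mechanism": {"mechanism_id": "x", "steps": []}}
        with pytest.raises(MechanismValidationError, match="at least one step"):
            parse_mechanism_json(json.dumps(doc))

    def test_invalid_mechanism_rejected_on_write(self):
        with pytest.raises(MechanismValidationError):
            write_mechanism_json(Mechanism("x", ()))

    @pytest.mark.parametrize("name", BUNDLED_FIXTURES)
    def test_bundled_files_byte_match_constructors(self, name):
        from importlib.resources import files

        constructors = {
            "alpha_amylase": lambda: make_glycosidase_pair()[0],
            "xyloglucan_transferase": lambda: make_glycosidase_pair()[1],
            "glycosylation_step": lambda: Mechanism(
                "glycosylation_step", (make_fig1_step(),)
            ),
        }
        on_disk = files("mechsim.data").joinpath(f"{name}.json").read_text()
        assert on_disk == write_mechanism_json(constructors[name]())


MINIMAL_MRV = """<cml><MDocument><MChemicalStruct><molecule>
  <atomArray>
    <atom id="a1" elementType="O" formalCharge="-1"/>
    <atom id="a2" elementType="C"/>
    <atom id="a3" elementType="O"/>
  </atomArray>
  <bondArray>
    <bond id="b1" atomRefs2="a1 a2" order="1"/>
    <bond id="b2" atomRefs2="a2 a3" order="2"/>
  </bondArray>
</molecule></MChemicalStruct>
<MEFlow electronCount="2">
  <atomSetPoint atomRefs="a1"/>
  <atomSetPoint atomRefs="a1 a3"/>
</MEFlow>
</MDocument></cml>"""


class TestMrv:
    def test_minimal_document(self):
        step = parse_mrv_step(MINIMAL_MRV)
        assert len(step.state.atoms) == 3
        assert len(step.state.bonds) == 2
        assert len(step.arrows) == 1
        arrow = step.arrows[0]
        assert arrow.electrons == 2
        assert arrow.source.atoms == (1,)
        assert arrow.sink.kind.value == "incipient"

    def test_attribute_array_syntax(self):
        xml = """<cml><molecule>
          <atomArray atomID="a1 a2" elementType="O H" formalCharge="-1 0"/>
          <bondArray><bond atomRefs2="a1 a2" order="1"/></bondArray>
          <MEFlow><atomSetPoint atomRefs="a1 a2"/><atomSetPoint atomRefs="a1"/></MEFlow>
        </molecule></cml>"""
        step = parse_mrv_step(xml)
        assert [a.element for a in step.state.atoms] == [8, 1]
        assert step.arrows[0].source.kind.value == "bond"

    def test_no_arrows_is_validation_error(self):
        xml = MINIMAL_MRV.replace(
            '<MEFlow electronCount="2">\n  <atomSetPoint atomRefs="a1"/>\n  <atomSetPoint atomRefs="a1 a3"/>\n</MEFlow>',
            "",
        )
        with pytest.raises(MechanismValidationError, match="at least one arrow"):
            parse_mrv_step(xml)

    def test_unsupported_bond_order_named(self):
        with pytest.raises(MrvParseError, match="'4'"):
            parse_mrv_step(MINIMAL_MRV.replace('order="2"', 'order="4"'))

    def test_undeclared_atom_reference(self):
        with pytest.raises(MrvParseError, match="a9"):
            parse_mrv_step(MINIMAL_MRV.replace('atomRefs="a1"/>', 'atomRefs="a9"/>'))

    def test_fig1_reencoding_reproduces_printed_smarts(self):
        """An MRV encoding of the nucleophilic-attack arrow (carboxylate
        plus the anomeric-carbon shell) yields the published SMARTS."""
        xml = """<cml><molecule>
          <atomArray>
            <atom id="a1" elementType="O" formalCharge="-1"/>
            <atom id="a2" elementType="C"/>
            <atom id="a3" elementType="C"/>
            <atom id="a4" elementType="O"/>
            <atom id="a5" elementType="C"/>
            <atom id="a6" elementType="H"/>
            <atom id="a7" elementType="O"/>
          </atomArray>
          <bondArray>
            <bond atomRefs2="a1 a2" order="1"/>
            <bond atomRefs2="a3 a4" order="1"/>
            <bond atomRefs2="a3 a5" order="1"/>
            <bond atomRefs2="a3 a6" order="1"/>
            <bond atomRefs2="a3 a7" order="1"/>
          </bondArray>
          <MEFlow>
            <atomSetPoint atomRefs="a1"/>
            <atomSetPoint atomRefs="a1 a3"/>
          </MEFlow>
        </molecule></cml>"""
        step = parse_mrv_step(xml)
        env = extract_arrow_env(step, step.arrows[0], ONE_AWAY)
        assert env.smarts == PRINTED


def _score_frame(rows):
    return pd.DataFrame(rows, columns=["mech_a", "mech_b", "score"])


class TestGraphExport:
    SCORES = _score_frame(
        [("A", "B", 0.6), ("A", "C", 0.4), ("B", "C", 0.9)]
    )

    def test_cutoff_half_gives_two_edges(self, tmp_path):
        g = export_similarity_graph(
            self.SCORES, 0.5, graphml_path=tmp_path / "g.graphml"
        )
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == 2
        loaded = nx.read_graphml(tmp_path / "g.graphml")
        assert loaded.number_of_edges() == 2

    def test_cutoff_zero_is_complete(self):
        g = export_similarity_graph(self.SCORES, 0.0)
        assert g.number_of_edges() == 3

    def test_cutoff_one_isolates_everything(self):
        g = export_similarity_graph(self.SCORES, 1.0)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 3

    def test_edge_count_monotone_in_cutoff(self):
        counts = [
            export_similarity_graph(self.SCORES, c).number_of_edges()
            for c in (0.0, 0.3, 0.5, 0.7, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_conflicting_duplicate_rejected(self):
        bad = _score_frame([("A", "B", 0.6), ("B", "A", 0.7)])
        with pytest.raises(ValueError, match="asymmetric"):
            export_similarity_graph(bad, 0.5)

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValueError):
            export_similarity_graph(_score_frame([("A", "B", 1.2)]), 0.5)

    def test_annotations_on_nodes(self, tmp_path):
        ann = {"A": {"ec": ["1.1.1.1"], "cath": ["3.20.20.80"]}}
        g = export_similarity_graph(self.SCORES, 0.5, annotations=ann)
        assert g.nodes["A"]["ec"] == "1.1.1.1"
        assert g.nodes["B"]["ec"] == ""

    def test_edge_tsv_written(self, tmp_path):
        export_similarity_graph(self.SCORES, 0.5, tsv_path=tmp_path / "e.tsv")
        df = pd.read_csv(tmp_path / "e.tsv", sep="\t")
        assert list(df.columns) == ["mech_a", "mech_b", "score", "definition", "method"]
        assert len(df) == 2
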