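"""Parsing, writing, detection and cross-validation of the file family."""

import json

import numpy as np
import pytest
from hypothesis import given, strategies as st
from lxml import etree

from pointworlds import (Dataset, FormatError, InformationFile,
                         InformationLayer, convert, detect_format,
                         read_dataset, read_information, validate_pair,
                         write_dataset, write_information)
from pointworlds.formats import CSV_DEFAULT_NAME, DIALECTS

from conftest import make_random_dataset, make_random_information

# -- strategies -------------------------------------------------------------

_name = st.text(
    alphabet=st.characters(categories=("L", "Nd"), include_characters=" _-"),
    min_size=0, max_size=12)
_coord = st.floats(allow_nan=False, allow_infinity=False,
                   min_value=-1e12, max_value=1e12)
_points = st.lists(st.tuples(_coord, _coord, _coord), min_size=1, max_size=20)


@st.composite
def datasets(draw):
    return Dataset(name=draw(_name), chain=draw(st.booleans()),
                   points=np.array(draw(_points), dtype=float))


@st.composite
def information_files(draw, surjective=True):
    n = draw(st.integers(1, 15))
    n_layers = draw(st.integers(1, 3))
    layers = []
    for _ in range(n_layers):
        k = draw(st.integers(1, min(5, n)))
        base = list(range(k)) + draw(
            st.lists(st.integers(0, k - 1), min_size=n - k, max_size=n - k))
        perm = draw(st.permutations(base)) if surjective else base
        labels = draw(st.one_of(
            st.none(),
            st.lists(_name, min_size=k, max_size=k)))
        layers.append(InformationLayer(
            num_classes=k, values=np.array(perm, dtype=int),
            name=draw(st.one_of(st.none(), _name)), labels=labels))
    return InformationFile(layers=layers)


# -- detection --------------------------------------------------------------

@pytest.mark.parametrize("text,expected", [
    ('{"dataset": {"points": [[0, 0, 1.5]]}}', ("json", "dataset")),
    ('{"information": [{"numClass": 1, "values": [0]}]}',
     ("json", "information")),
    ("<dataset><points><point><x>1</x><y>2</y><z>3</z></point></points>"
     "</dataset>", ("xml", "dataset")),
    ("<information><set><numClass>1</numClass><values><value>0</value>"
     "</values></set></information>", ("xml", "information")),
    ("0.5,1.5,2.5\n", ("csv", "dataset")),
    ("0,1\n1,0\n", ("csv", "information")),
    ("0\n1\n0\n", ("csv", "information")),
])
def test_detect_format_by_root_token(text, expected):
    assert detect_format(text) == expected


@pytest.mark.parametrize("text,code", [
    ("", "UNRECOGNISED_FORMAT"),
    ("   \n ", "UNRECOGNISED_FORMAT"),
    ('{"other": 1}', "UNRECOGNISED_FORMAT"),
    ("<thing/>", "UNRECOGNISED_FORMAT"),
    ("a,b,c\n", "UNRECOGNISED_FORMAT"),
    ("1,2,3\n4,5,6\n", "AMBIGUOUS_CSV_FAMILY"),
])
def test_detect_format_rejects_rather_than_guessing(text, code):
    with pytest.raises(FormatError) as exc:
        detect_format(text)
    assert exc.value.code == code


def test_ambiguous_integer_csv_resolved_by_explicit_family():
    text = "1,2,3\n4,5,6\n"
    assert detect_format(text, family="dataset") == ("csv", "dataset")
    assert detect_format(text, family="information") == ("csv", "information")


# -- dataset reading --------------------------------------------------------

def test_minimal_three_point_dataset_parses(worked_pair):
    ds, _ = worked_pair
    text, _ = write_dataset(ds, "json")
    parsed = read_dataset(text, "json")
    assert parsed.n_points == 3
    assert parsed.chain is False
    assert parsed.name == "minimal example"
    assert np.array_equal(parsed.points, ds.points)


def test_chain_flag_defaults_to_false_when_absent():
    parsed = read_dataset('{"dataset": {"points": [[1, 2, 3]]}}', "json")
    assert parsed.chain is False
    parsed = read_dataset(
        "<dataset><points><point><x>1</x><y>2</y><z>3</z></point>"
        "</points></dataset>", "xml")
    assert parsed.chain is False


def test_single_point_chain_is_legal():
    parsed = read_dataset(
        '{"dataset": {"chain": true, "points": [[0, 0, 0]]}}', "json")
    assert parsed.chain is True and parsed.n_points == 1


def test_csv_dataset_gets_default_name_and_no_chain():
    parsed = read_dataset(" 0.5 , 1.5 ,2.5\r\n3.5,4.5,5.5\n\n", "csv")
    assert parsed.name == CSV_DEFAULT_NAME
    assert parsed.chain is False
    assert parsed.points.tolist() == [[0.5, 1.5, 2.5], [3.5, 4.5, 5.5]]


def test_duplicate_points_are_legal():
    parsed = read_dataset("1,1,1.5\n1,1,1.5\n", "csv")
    assert parsed.n_points == 2


@pytest.mark.parametrize("dialect,text,code", [
    ("json", '{"dataset": {"points": [[1, 2]]}}', "BAD_ARITY"),
    ("json", '{"dataset": {"points": [[1, 2, "x"]]}}', "BAD_COORDINATE"),
    ("json", '{"dataset": {"points": [[1, 2, NaN]]}}', "BAD_COORDINATE"),
    ("json", '{"dataset": {"points": [[1, 2, true]]}}', "BAD_COORDINATE"),
    ("json", '{"dataset": {"points": []}}', "EMPTY_DATASET"),
    ("json", '{"dataset": {"chain": "yes", "points": [[1, 2, 3]]}}',
     "BAD_BOOLEAN"),
    ("json", '{"points": [[1, 2, 3]]}', "MISSING_ROOT"),
    ("json", '{"dataset": ', "SYNTAX_ERROR"),
    ("xml", "<dataset><points><point><x>1</x><y>2</y></point></points>"
     "</dataset>", "BAD_ARITY"),
    ("xml", "<dataset><points><point><x>1</x><y>2</y><z>z</z></point>"
     "</points></dataset>", "BAD_COORDINATE"),
    ("xml", "<dataset><chain>maybe</chain><points><point><x>1</x><y>2</y>"
     "<z>3</z></point></points></dataset>", "BAD_BOOLEAN"),
    ("xml", "<info/>", "MISSING_ROOT"),
    ("xml", "<dataset><points>", "SYNTAX_ERROR"),
    ("csv", "1,2,3,4\n", "BAD_ARITY"),
    ("csv", "1,2\n", "BAD_ARITY"),
    ("csv", "1,2,inf\n", "BAD_COORDINATE"),
])
def test_dataset_parse_defects_carry_their_code(dialect, text, code):
    with pytest.raises(FormatError) as exc:
        read_dataset(text, dialect)
    assert exc.value.code == code


def test_xml_boolean_is_case_insensitive():
    for token, expected in [("TRUE", True), ("True", True), ("false", False),
                            ("FALSE", False)]:
        text = (f"<dataset><chain>{token}</chain><points><point><x>1</x>"
                f"<y>2</y><z>3</z></point></points></dataset>")
        assert read_dataset(text, "xml").chain is expected


# -- information reading ----------------------------------------------------

def test_worked_example_information_file(worked_pair):
    _, info = worked_pair
    text, _ = write_information(info, "json")
    parsed = read_information(text, "json")
    assert len(parsed.layers) == 2
    assert parsed.n_points == 3
    a, b = parsed.layers
    assert a.num_classes == 2 and a.values.tolist() == [0, 0, 1]
    assert b.num_classes == 3 and b.values.tolist() == [0, 1, 2]


def test_single_class_csv_column():
    parsed = read_information("0\n0\n0\n", "csv")
    assert len(parsed.layers) == 1
    layer = parsed.layers[0]
    assert layer.num_classes == 1 and layer.values.tolist() == [0, 0, 0]
    assert layer.name is None and layer.labels is None


def test_one_based_values_are_shifted_with_warning():
    text = '{"information": [{"numClass": 2, "values": [1, 1, 2]}]}'
    parsed = read_information(text, "json")
    assert parsed.layers[0].values.tolist() == [0, 0, 1]
    assert [w.code for w in parsed.warnings] == ["ONE_BASED_NORMALISED"]


def test_csv_arbitrary_ids_rank_mapped_with_warning():
    parsed = read_information("5\n5\n7\n", "csv")
    assert parsed.layers[0].values.tolist() == [0, 0, 1]
    assert parsed.layers[0].num_classes == 2
    assert [w.code for w in parsed.warnings] == ["REMAPPED_VALUES"]


def test_repair_mode_raises_num_classes_instead_of_erroring():
    text = '{"information": [{"numClass": 2, "values": [0, 1, 5]}]}'
    with pytest.raises(FormatError) as exc:
        read_information(text, "json")
    assert exc.value.code == "VALUE_OUT_OF_RANGE"
    parsed = read_information(text, "json", repair=True)
    assert parsed.layers[0].num_classes == 6
    assert [w.code for w in parsed.warnings] == ["REPAIRED_NUM_CLASS"]


@pytest.mark.parametrize("dialect,text,code", [
    ("json", '{"information": []}', "EMPTY_INFORMATION"),
    ("json", '{"information": [{"numClass": 1, "values": [0, 0]},'
     ' {"numClass": 1, "values": [0]}]}', "RAGGED_LAYERS"),
    ("json", '{"information": [{"numClass": 2, "labels": ["a"],'
     ' "values": [0, 1]}]}', "LABEL_COUNT_MISMATCH"),
    ("json", '{"information": [{"numClass": 2, "values": [0.5]}]}',
     "VALUE_OUT_OF_RANGE"),
    ("json", '{"layers": []}', "MISSING_ROOT"),
    ("xml", "<information/>", "EMPTY_INFORMATION"),
    ("xml", "<information><set><values><value>0</value></values></set>"
     "</information>", "VALUE_OUT_OF_RANGE"),
    ("csv", "0,1\n0\n", "RAGGED_LAYERS"),
    ("csv", "0.5\n", "VALUE_OUT_OF_RANGE"),
])
def test_information_parse_defects_carry_their_code(dialect, text, code):
    with pytest.raises(FormatError) as exc:
        read_information(text, dialect)
    assert exc.value.code == code


# -- round trips ------------------------------------------------------------

@pytest.mark.parametrize("dialect", ["json", "xml"])
@given(ds=datasets())
def test_dataset_round_trip_is_identity_in_lossless_dialects(dialect, ds):
    text, warnings = write_dataset(ds, dialect)
    assert warnings == []
    again = read_dataset(text, dialect)
    assert again == ds
    # canonical writer output is byte-stable
    assert write_dataset(again, dialect)[0] == text


@given(datasets())
def test_dataset_csv_round_trip_preserves_coordinates_exactly(ds):
    text, warnings = write_dataset(ds, "csv")
    again = read_dataset(text, "csv")
    assert np.array_equal(again.points, ds.points)
    lossy = {w.locus for w in warnings if w.code == "LOSSY_CSV"}
    expected = set()
    if ds.name not in ("", CSV_DEFAULT_NAME):
        expected.add("name")
    if ds.chain:
        expected.add("chain")
    assert lossy == expected


@pytest.mark.parametrize("dialect", ["json", "xml"])
@given(info=information_files())
def test_information_round_trip_is_identity_in_lossless_dialects(dialect, info):
    text, warnings = write_information(info, dialect)
    assert warnings == []
    again = read_information(text, dialect)
    assert again == info
    assert write_information(again, dialect)[0] == text


@given(information_files(surjective=True))
def test_information_csv_round_trip_preserves_canonical_values(info):
    text, warnings = write_information(info, "csv")
    again = read_information(text, "csv")
    assert again.warnings == []  # canonical values re-read without remap
    for orig, back in zip(info.layers, again.layers):
        assert back.values.tolist() == orig.values.tolist()
        assert back.num_classes == orig.num_classes
        assert back.name is None and back.labels is None
    named = [l for l in info.layers if l.name or l.labels]
    assert (len([w for w in warnings if w.code == "LOSSY_CSV"]) > 0) \
        == bool(named)


def test_dialect_loop_json_xml_csv_restores_canonical_dataset():
    rng = np.random.default_rng(42)
    for _ in range(25):
        ds = make_random_dataset(rng)
        ds.chain = False
        ds.name = CSV_DEFAULT_NAME
        text = write_dataset(ds, "json")[0]
        for dialect in ("xml", "csv", "json"):
            text = convert(text, dialect, family="dataset")[0]
        assert read_dataset(text, "json") == ds


def test_convert_to_csv_on_named_dataset_warns():
    ds = Dataset(name="my dataset", points=np.array([[0.5, 1.5, 2.5]]))
    text = write_dataset(ds, "json")[0]
    _, warnings = convert(text, "csv")
    assert any(w.code == "LOSSY_CSV" for w in warnings)


def test_convert_xml_to_json_matches_direct_json(worked_pair):
    ds, _ = worked_pair
    xml_text = write_dataset(ds, "xml")[0]
    json_text, warnings = convert(xml_text, "json")
    assert warnings == []
    assert json_text == write_dataset(ds, "json")[0]


def test_canonical_xml_output_validates_against_shipped_dtds(worked_pair):
    from importlib import resources

    ds, info = worked_pair
    schemas = resources.files("pointworlds") / "schemas"
    for text, dtd_name in [
            (write_dataset(ds, "xml")[0], "dataset.xml.dtd"),
            (write_information(info, "xml")[0], "information.xml.dtd")]:
        dtd = etree.DTD((schemas / dtd_name).open("r"))
        assert dtd.validate(etree.fromstring(text.encode())), dtd.error_log


def test_canonical_json_output_matches_shipped_schema_shape(worked_pair):
    # structural check without a JSON-Schema engine: required keys and types
    ds, info = worked_pair
    doc = json.loads(write_dataset(ds, "json")[0])
    assert set(doc) == {"dataset"}
    assert set(doc["dataset"]) == {"name", "chain", "points"}
    idoc = json.loads(write_information(info, "json")[0])
    assert set(idoc) == {"information"}
    for entry in idoc["information"]:
        assert {"numClass", "values"} <= set(entry)


# -- pair validation --------------------------------------------------------

def test_worked_example_pair_validates_cleanly(worked_pair):
    ds, info = worked_pair
    assert validate_pair(ds, info) == []


def test_length_mismatch_is_an_error_with_layer_locus(worked_pair):
    ds, _ = worked_pair
    bad = InformationFile(layers=[InformationLayer(
        num_classes=2, values=np.array([0, 1, 0, 1]))])
    issues = validate_pair(ds, bad)
    assert [(i.severity, i.code, i.locus) for i in issues] == \
        [("error", "LENGTH_MISMATCH", "layer[0]")]


def test_declared_but_empty_class_is_a_warning(worked_pair):
    ds, _ = worked_pair
    info = InformationFile(layers=[InformationLayer(
        num_classes=3, values=np.array([0, 0, 2]))])
    issues = validate_pair(ds, info)
    assert [(i.severity, i.code) for i in issues] == \
        [("warning", "EMPTY_CLASS")]


def test_every_corrupted_layer_yields_exactly_one_length_mismatch():
    rng = np.random.default_rng(7)
    for _ in range(30):
        n = int(rng.integers(2, 20))
        ds = make_random_dataset(rng, n=n)
        info = make_random_information(rng, n=n)
        corrupt = sorted(rng.choice(
            len(info.layers), size=int(rng.integers(0, len(info.layers) + 1)),
            replace=False))
        layers = []
        for i, layer in enumerate(info.layers):
            if i in corrupt:
                delta = int(rng.choice([-1, 1])) if n > 1 else 1
                values = np.resize(layer.values, n + delta) % layer.num_classes
                layers.append(InformationLayer(
                    num_classes=layer.num_classes, values=values))
            else:
                layers.append(layer)
        # bypass the equal-length container invariant to test validate_pair
        mixed = InformationFile.__new__(InformationFile)
        mixed.layers = layers
        mixed.source_dialect = None
        mixed.warnings = []
        errors = [i for i in validate_pair(ds, mixed)
                  if i.code == "LENGTH_MISMATCH"]
        assert sorted(i.locus for i in errors) == \
            [f"layer[{i}]" for i in corrupt]
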