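"""Read, write, validate and inter-convert the two-file point-cloud model.

Two file families are supported, each in three dialects (JSON, XML, CSV):

* **dataset** files hold one named, ordered set of N 3D points with an
  optional ``chain`` flag (``true`` = consecutive points are joined by a
  solid line, as for a protein backbone; default ``false`` = independent
  particles, as for a cell population).
* **information** files hold one or more *information layers*: per-point
  class assignments (e.g. cluster membership) over the same N points, each
  with a declared class count (``numClass``) and optional class labels.

The CSV dialect is deliberately minimal: a dataset CSV is ``x,y,z`` per
line and an information CSV is one column per layer; CSV can express
neither names, labels nor the chain flag, and every such loss is reported
as an explicit ``LOSSY_CSV`` warning, never silently.

Issue-code catalogue (closed; every :class:`ValidationIssue` uses one)::

    errors   UNRECOGNISED_FORMAT  no dialect/family rule matches the text
             AMBIGUOUS_CSV_FAMILY 3-column all-integer CSV needs a family hint
             SYNTAX_ERROR         document does not parse in its dialect
             MISSING_ROOT         parsed, but root token is not dataset/information
             BAD_COORDINATE       coordinate not a finite real number
             BAD_ARITY            a point without exactly three coordinates
             BAD_BOOLEAN          chain flag not a boolean
             EMPTY_DATASET        dataset with zero points
             EMPTY_INFORMATION    information file with zero layers
             RAGGED_LAYERS        layers (or CSV rows) of unequal length
             VALUE_OUT_OF_RANGE   class value not mappable into [0, numClass)
             LABEL_COUNT_MISMATCH labels length differs from numClass
             LENGTH_MISMATCH      layer length differs from dataset point count
             BAD_COLUMN           table column selector does not resolve
             NO_CA_ATOMS          PDB text has no usable C-alpha atoms
             CHAIN_NOT_FOUND      requested PDB chain id is absent
    warnings LOSSY_CSV            a field CSV cannot express was dropped
             ONE_BASED_NORMALISED values used 1..numClass and were shifted down
             REMAPPED_VALUES      CSV column ids were rank-mapped to 0..k-1
             REPAIRED_NUM_CLASS   repair mode raised numClass to max value + 1
             EMPTY_CLASS          a declared class has no points

Canonical in-memory form uses 0-based integer class values.  Files whose
values occupy 1..numClass with no 0 are accepted as 1-based and shifted
down with a ``ONE_BASED_NORMALISED`` warning; any other out-of-range value
is an error unless ``repair=True``, which raises ``num_classes`` instead.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from lxml import etree

__all__ = [
    "Dataset",
    "InformationLayer",
    "InformationFile",
    "ValidationIssue",
    "FormatError",
    "ISSUE_CODES",
    "DIALECTS",
    "CSV_DEFAULT_NAME",
    "detect_format",
    "read_dataset",
    "read_information",
    "write_dataset",
    "write_information",
    "validate_pair",
    "convert",
]

DIALECTS = ("json", "xml", "csv")

#: Name assigned to datasets parsed from CSV, which cannot carry a name.
CSV_DEFAULT_NAME = "unnamed"

ISSUE_CODES = frozenset({
    "UNRECOGNISED_FORMAT", "AMBIGUOUS_CSV_FAMILY", "SYNTAX_ERROR",
    "MISSING_ROOT", "BAD_COORDINATE", "BAD_ARITY", "BAD_BOOLEAN",
    "EMPTY_DATASET", "EMPTY_INFORMATION", "RAGGED_LAYERS",
    "VALUE_OUT_OF_RANGE", "LABEL_COUNT_MISMATCH", "LENGTH_MISMATCH",
    "BAD_COLUMN", "NO_CA_ATOMS", "CHAIN_NOT_FOUND",
    "LOSSY_CSV", "ONE_BASED_NORMALISED", "REMAPPED_VALUES",
    "REPAIRED_NUM_CLASS", "EMPTY_CLASS",
})


@dataclass
class ValidationIssue:
    """Machine-readable diagnostic from parsing or cross-validation."""

    severity: str  # "error" | "warning"
    code: str
    message: str
    locus: str = ""

    def __post_init__(self) -> None:
        if self.code not in ISSUE_CODES:
            raise ValueError(f"unknown issue code {self.code!r}")
        if self.severity not in ("error", "warning"):
            raise ValueError(f"bad severity {self.severity!r}")

    def __str__(self) -> str:  # one-line report form used by the CLI
        loc = f" [{self.locus}]" if self.locus else ""
        return f"{self.severity}:{self.code}{loc} {self.message}"


class FormatError(ValueError):
    """Raised when a document cannot be parsed or violates an invariant."""

    def __init__(self, issue: ValidationIssue):
        super().__init__(str(issue))
        self.issue = issue
        self.code = issue.code


def _err(code: str, message: str, locus: str = "") -> FormatError:
    return FormatError(ValidationIssue("error", code, message, locus))


@dataclass(eq=False)
class Dataset:
    """A named, ordered set of N 3D points.

    ``points`` is an (N, 3) float array; row order is file order and is
    semantically meaningful (layers index points by position).
    """

    name: str
    points: np.ndarray
    chain: bool = False
    source_dialect: Optional[str] = None
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if pts.shape[0] < 1:
            raise ValueError("dataset needs at least one point")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points must be finite")
        self.points = pts

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return (self.name == other.name and self.chain == other.chain
                and np.array_equal(self.points, other.points))


@dataclass(eq=False)
class InformationLayer:
    """One per-point class assignment (canonical 0-based values)."""

    num_classes: int
    values: np.ndarray
    name: Optional[str] = None
    labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=int)
        if vals.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.num_classes < 1:
            raise ValueError("num_classes must be positive")
        if vals.size and (vals.min() < 0 or vals.max() >= self.num_classes):
            raise ValueError("values outside [0, num_classes)")
        if self.labels is not None and len(self.labels) != self.num_classes:
            raise ValueError("labels length must equal num_classes")
        self.values = vals

    def __len__(self) -> int:
        return int(self.values.size)

    def class_sizes(self) -> np.ndarray:
        return np.bincount(self.values, minlength=self.num_classes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InformationLayer):
            return NotImplemented
        return (self.num_classes == other.num_classes
                and self.name == other.name and self.labels == other.labels
                and np.array_equal(self.values, other.values))


@dataclass(eq=False)
class InformationFile:
    """An ordered sequence of one or more equal-length layers."""

    layers: list[InformationLayer]
    source_dialect: Optional[str] = None
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("an information file needs at least one layer")
        lengths = {len(l) for l in self.layers}
        if len(lengths) != 1:
            raise ValueError("layers must all have the same length")

    @property
    def n_points(self) -> int:
        return len(self.layers[0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InformationFile):
            return NotImplemented
        return self.layers == other.layers


# ---------------------------------------------------------------------------
# detection

def _csv_rows(raw_text: str) -> list[list[str]]:
    text = raw_text.replace("\r\n", "\n").replace("\r", "\n")
    lines = text.split("\n")
    while lines and lines[-1].strip() == "":
        lines.pop()
    return [[f.strip() for f in line.split(",")] for line in lines]


def _is_float(tok: str) -> bool:
    try:
        v = float(tok)
    except ValueError:
        return False
    return math.isfinite(v)


def _is_int(tok: str) -> bool:
    try:
        int(tok)
    except ValueError:
        return False
    return True


def detect_format(raw_text: str, family: Optional[str] = None) -> tuple[str, str]:
    """Identify ``(dialect, family)`` of a document.

    JSON and XML are recognised by their root token (``dataset`` /
    ``information``).  CSV is recognised structurally: three numeric
    columns with at least one non-integer field is a dataset, all-integer
    columns are an information file, and a three-column all-integer CSV is
    genuinely ambiguous — pass ``family`` to resolve it; detection never
    guesses silently.
    """
    if family is not None and family not in ("dataset", "information"):
        raise ValueError(f"bad family hint {family!r}")
    stripped = raw_text.strip()
    if not stripped:
        raise _err("UNRECOGNISED_FORMAT", "empty document")
    if stripped.startswith("{"):
        try:
            obj = json.loads(stripped)
        except json.JSONDecodeError:
            # unparseable, but the root token may still classify it; the
            # reader will then report a precise SYNTAX_ERROR
            m = re.match(r'\{\s*"(dataset|information)"', stripped)
            if m:
                return ("json", m.group(1))
            raise _err("UNRECOGNISED_FORMAT",
                       "JSON-like text without a dataset/information root")
        if isinstance(obj, dict) and "dataset" in obj:
            return ("json", "dataset")
        if isinstance(obj, dict) and "information" in obj:
            return ("json", "information")
        raise _err("UNRECOGNISED_FORMAT",
                   "JSON root has neither 'dataset' nor 'information'")
    if stripped.startswith("<"):
        try:
            root_tag = etree.fromstring(stripped.encode("utf-8")).tag
        except etree.XMLSyntaxError:
            m = re.match(r"<(dataset|information)[\s>]", stripped)
            if m:
                return ("xml", m.group(1))
            raise _err("UNRECOGNISED_FORMAT",
                       "XML-like text without a dataset/information root")
        if root_tag in ("dataset", "information"):
            return ("xml", root_tag)
        raise _err("UNRECOGNISED_FORMAT",
                   f"XML root <{root_tag}> is neither <dataset> nor "
                   "<information>")
    # CSV: no structural root
    rows = _csv_rows(stripped)
    if not rows:
        raise _err("UNRECOGNISED_FORMAT", "empty document")
    if family is not None:
        return ("csv", family)
    widths = {len(r) for r in rows}
    all_numeric = all(_is_float(f) for r in rows for f in r)
    if not all_numeric:
        raise _err("UNRECOGNISED_FORMAT", "CSV contains non-numeric fields")
    all_int = all(_is_int(f) for r in rows for f in r)
    if widths == {3}:
        if all_int:
            raise _err("AMBIGUOUS_CSV_FAMILY",
                       "3-column all-integer CSV could be either family; "
                       "pass an explicit family")
        return ("csv", "dataset")
    if all_int:
        return ("csv", "information")
    raise _err("UNRECOGNISED_FORMAT",
               "CSV is neither 3 numeric columns nor all-integer columns")


# ---------------------------------------------------------------------------
# dataset reading

_JSON_CONST = object()


def _json_loads(text: str, locus: str = ""):
    def reject(tok):
        raise _err("BAD_COORDINATE", f"non-finite constant {tok!r}", locus)
    try:
        return json.loads(text, parse_constant=reject)
    except FormatError:
        raise
    except json.JSONDecodeError as e:
        raise _err("SYNTAX_ERROR", f"invalid JSON: {e}", locus) from e


def _coerce_coord(value, locus: str) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise _err("BAD_COORDINATE", f"coordinate {value!r} is not a number", locus)
    v = float(value)
    if not math.isfinite(v):
        raise _err("BAD_COORDINATE", f"coordinate {value!r} is not finite", locus)
    return v


def _points_from_lists(raw_points, locus_prefix: str = "points") -> np.ndarray:
    if not isinstance(raw_points, list) or not raw_points:
        raise _err("EMPTY_DATASET", "dataset contains no points", locus_prefix)
    out = np.empty((len(raw_points), 3), dtype=float)
    for i, p in enumerate(raw_points):
        locus = f"{locus_prefix}[{i}]"
        if not isinstance(p, (list, tuple)):
            raise _err("BAD_ARITY", f"point is not a coordinate triple", locus)
        if len(p) != 3:
            raise _err("BAD_ARITY",
                       f"point has {len(p)} coordinates, expected 3", locus)
        out[i] = [_coerce_coord(c, locus) for c in p]
    return out


def _parse_bool(value, locus: str) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, str) and value.strip().lower() in ("true", "false"):
        return value.strip().lower() == "true"
    raise _err("BAD_BOOLEAN", f"chain flag {value!r} is not a boolean", locus)


def _read_dataset_json(raw_text: str) -> Dataset:
    obj = _json_loads(raw_text)
    if not isinstance(obj, dict) or "dataset" not in obj:
        raise _err("MISSING_ROOT", "no root object 'dataset'")
    body = obj["dataset"]
    if not isinstance(body, dict):
        raise _err("MISSING_ROOT", "'dataset' is not an object")
    name = body.get("name", "")
    if not isinstance(name, str):
        raise _err("SYNTAX_ERROR", "'name' must be a string", "dataset.name")
    chain = False
    if "chain" in body:
        if not isinstance(body["chain"], bool):
            raise _err("BAD_BOOLEAN",
                       f"chain flag {body['chain']!r} is not a boolean",
                       "dataset.chain")
        chain = body["chain"]
    points = _points_from_lists(body.get("points", []))
    return Dataset(name=name, points=points, chain=chain, source_dialect="json")


def _xml_root(raw_text: str, expected: str) -> etree._Element:
    try:
        root = etree.fromstring(raw_text.encode("utf-8"))
    except etree.XMLSyntaxError as e:
        raise _err("SYNTAX_ERROR", f"invalid XML: {e}") from e
    if root.tag != expected:
        raise _err("MISSING_ROOT",
                   f"root element is <{root.tag}>, expected <{expected}>")
    return root


def _read_dataset_xml(raw_text: str) -> Dataset:
    root = _xml_root(raw_text, "dataset")
    name_el = root.find("name")
    name = (name_el.text or "") if name_el is not None else ""
    chain = False
    chain_el = root.find("chain")
    if chain_el is not None:
        chain = _parse_bool(chain_el.text or "", "dataset/chain")
    points_el = root.find("points")
    raw_points = [] if points_el is None else points_el.findall("point")
    if not raw_points:
        raise _err("EMPTY_DATASET", "dataset contains no points", "points")
    out = np.empty((len(raw_points), 3), dtype=float)
    for i, pt in enumerate(raw_points):
        locus = f"points/point[{i}]"
        children = [c for c in pt if isinstance(c.tag, str)]
        tags = [c.tag for c in children]
        if sorted(tags) != ["x", "y", "z"]:
            raise _err("BAD_ARITY",
                       f"point has coordinates {tags}, expected x, y, z", locus)
        coords = {c.tag: c.text for c in children}
        for j, axis in enumerate(("x", "y", "z")):
            txt = (coords[axis] or "").strip()
            if not _is_float(txt):
                raise _err("BAD_COORDINATE",
                           f"coordinate {axis}={txt!r} is not a finite number",
                           locus)
            out[i, j] = float(txt)
    return Dataset(name=name, points=out, chain=chain, source_dialect="xml")


def _read_dataset_csv(raw_text: str) -> Dataset:
    rows = _csv_rows(raw_text)
    if not rows:
        raise _err("EMPTY_DATASET", "dataset contains no points")
    out = np.empty((len(rows), 3), dtype=float)
    for i, row in enumerate(rows):
        locus = f"line {i + 1}"
        if len(row) != 3:
            raise _err("BAD_ARITY",
                       f"line has {len(row)} fields, expected 3", locus)
        for j, tok in enumerate(row):
            if not _is_float(tok):
                raise _err("BAD_COORDINATE",
                           f"field {tok!r} is not a finite number", locus)
            out[i, j] = float(tok)
    return Dataset(name=CSV_DEFAULT_NAME, points=out, chain=False,
                   source_dialect="csv")


def read_dataset(raw_text: str, dialect: str) -> Dataset:
    """Parse a dataset document of the stated dialect.

    The chain flag defaults to false when absent; CSV datasets receive the
    documented default name (:data:`CSV_DEFAULT_NAME`) and ``chain=False``
    because CSV cannot express either field.
    """
    if dialect == "json":
        return _read_dataset_json(raw_text)
    if dialect == "xml":
        return _read_dataset_xml(raw_text)
    if dialect == "csv":
        return _read_dataset_csv(raw_text)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# information reading

def _canonicalise_values(raw: Sequence[int], num_classes: int, locus: str,
                         warnings: list, repair: bool) -> tuple[np.ndarray, int]:
    vals = np.asarray(raw, dtype=int)
    if vals.size == 0:
        raise _err("VALUE_OUT_OF_RANGE", "layer has no values", locus)
    lo, hi = int(vals.min()), int(vals.max())
    if lo >= 0 and hi < num_classes:
        return vals, num_classes
    if lo >= 1 and hi <= num_classes:
        warnings.append(ValidationIssue(
            "warning", "ONE_BASED_NORMALISED",
            "values use 1-based classes; shifted to canonical 0-based", locus))
        return vals - 1, num_classes
    if repair and lo >= 0:
        warnings.append(ValidationIssue(
            "warning", "REPAIRED_NUM_CLASS",
            f"numClass raised from {num_classes} to {hi + 1} to cover values",
            locus))
        return vals, hi + 1
    raise _err("VALUE_OUT_OF_RANGE",
               f"values span [{lo}, {hi}], not mappable into "
               f"[0, {num_classes})", locus)


def _layer_from_parts(name, num_classes, labels, raw_values, locus: str,
                      warnings: list, repair: bool) -> InformationLayer:
    if not isinstance(num_classes, int) or isinstance(num_classes, bool) \
            or num_classes < 1:
        raise _err("VALUE_OUT_OF_RANGE",
                   f"numClass {num_classes!r} is not a positive integer", locus)
    for v in raw_values:
        if isinstance(v, bool) or not isinstance(v, (int, np.integer)):
            raise _err("VALUE_OUT_OF_RANGE",
                       f"class value {v!r} is not an integer", locus)
    if labels is not None and len(labels) != num_classes:
        raise _err("LABEL_COUNT_MISMATCH",
                   f"{len(labels)} labels for numClass={num_classes}", locus)
    vals, num_classes = _canonicalise_values(raw_values, num_classes, locus,
                                             warnings, repair)
    if labels is not None and len(labels) < num_classes:
        # only reachable in repair mode, where numClass may grow
        labels = list(labels) + [""] * (num_classes - len(labels))
    return InformationLayer(num_classes=num_classes, values=vals,
                            name=name, labels=labels)


def _read_information_json(raw_text: str, repair: bool) -> InformationFile:
    obj = _json_loads(raw_text)
    if not isinstance(obj, dict) or "information" not in obj:
        raise _err("MISSING_ROOT", "no root element 'information'")
    sets = obj["information"]
    if not isinstance(sets, list):
        raise _err("MISSING_ROOT", "'information' is not a list")
    if not sets:
        raise _err("EMPTY_INFORMATION", "information file defines no layers")
    warnings: list = []
    layers = []
    for i, entry in enumerate(sets):
        locus = f"information[{i}]"
        if not isinstance(entry, dict):
            raise _err("SYNTAX_ERROR", "layer entry is not an object", locus)
        name = entry.get("name")
        if name is not None and not isinstance(name, str):
            raise _err("SYNTAX_ERROR", "'name' must be a string", locus)
        labels = entry.get("labels")
        if labels is not None and (not isinstance(labels, list) or
                                   any(not isinstance(l, str) for l in labels)):
            raise _err("SYNTAX_ERROR", "'labels' must be a list of strings",
                       locus)
        values = entry.get("values")
        if not isinstance(values, list):
            raise _err("SYNTAX_ERROR", "'values' must be a list", locus)
        layers.append(_layer_from_parts(name, entry.get("numClass"), labels,
                                        values, locus, warnings, repair))
    _check_equal_lengths(layers)
    return InformationFile(layers=layers, source_dialect="json",
                           warnings=warnings)


def _read_information_xml(raw_text: str, repair: bool) -> InformationFile:
    root = _xml_root(raw_text, "information")
    sets = root.findall("set")
    if not sets:
        raise _err("EMPTY_INFORMATION", "information file defines no layers")
    warnings: list = []
    layers = []
    for i, el in enumerate(sets):
        locus = f"information/set[{i}]"
        name_el = el.find("name")
        name = (name_el.text or "") if name_el is not None else None
        nc_el = el.find("numClass")
        if nc_el is None or not _is_int((nc_el.text or "").strip()):
            raise _err("VALUE_OUT_OF_RANGE",
                       "numClass missing or not an integer", locus)
        num_classes = int(nc_el.text.strip())
        labels_el = el.find("labels")
        labels = None
        if labels_el is not None:
            labels = [(l.text or "") for l in labels_el.findall("label")]
        values_el = el.find("values")
        raw_values = [] if values_el is None else values_el.findall("value")
        vals = []
        for v in raw_values:
            txt = (v.text or "").strip()
            if not _is_int(txt):
                raise _err("VALUE_OUT_OF_RANGE",
                           f"class value {txt!r} is not an integer", locus)
            vals.append(int(txt))
        layers.append(_layer_from_parts(name, num_classes, labels, vals,
                                        locus, warnings, repair))
    _check_equal_lengths(layers)
    return InformationFile(layers=layers, source_dialect="xml",
                           warnings=warnings)


def _read_information_csv(raw_text: str, repair: bool) -> InformationFile:
    rows = _csv_rows(raw_text)
    if not rows:
        raise _err("EMPTY_INFORMATION", "information file defines no layers")
    width = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != width:
            raise _err("RAGGED_LAYERS",
                       f"line {i + 1} has {len(row)} fields, expected {width}")
        for tok in row:
            if not _is_int(tok):
                raise _err("VALUE_OUT_OF_RANGE",
                           f"class value {tok!r} is not an integer",
                           f"line {i + 1}")
    warnings: list = []
    layers = []
    for c in range(width):
        column = [int(r[c]) for r in rows]
        locus = f"column {c + 1}"
        # CSV declares no numClass: infer it as the count of distinct ids,
        # and rank-map arbitrary ids onto the canonical 0-based range
        distinct = sorted(set(column))
        k = len(distinct)
        if distinct == list(range(1, k + 1)):
            warnings.append(ValidationIssue(
                "warning", "ONE_BASED_NORMALISED",
                "values use 1-based classes; shifted to canonical 0-based",
                locus))
        elif distinct != list(range(k)):
            warnings.append(ValidationIssue(
                "warning", "REMAPPED_VALUES",
                f"class ids {distinct} rank-mapped onto 0..{k - 1}", locus))
        mapping = {v: i for i, v in enumerate(distinct)}
        values = np.array([mapping[v] for v in column], dtype=int)
        layers.append(InformationLayer(num_classes=k, values=values))
    return InformationFile(layers=layers, source_dialect="csv",
                           warnings=warnings)


def _check_equal_lengths(layers: list[InformationLayer]) -> None:
    lengths = {len(l) for l in layers}
    if len(lengths) > 1:
        raise _err("RAGGED_LAYERS",
                   f"layers have unequal lengths {sorted(lengths)}")


def read_information(raw_text: str, dialect: str,
                     repair: bool = False) -> InformationFile:
    """Parse an information-layer document of the stated dialect.

    One layer per list element (JSON/XML) or per column (CSV).  CSV layers
    get ``num_classes`` inferred as the count of distinct values in the
    column and carry no name or labels.  ``repair=True`` opts into raising
    ``num_classes`` to cover out-of-range values instead of erroring.
    """
    if dialect == "json":
        return _read_information_json(raw_text, repair)
    if dialect == "xml":
        return _read_information_xml(raw_text, repair)
    if dialect == "csv":
        return _read_information_csv(raw_text, repair)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# writing

def _fmt(v: float) -> str:
    # shortest round-trip decimal form, byte-stable across runs
    return repr(float(v))


def _write_dataset_json(ds: Dataset) -> str:
    body = {
        "name": ds.name,
        "chain": ds.chain,
        "points": [[float(x), float(y), float(z)] for x, y, z in ds.points],
    }
    return json.dumps({"dataset": body}, indent=2) + "\n"


def _write_dataset_xml(ds: Dataset) -> str:
    root = etree.Element("dataset")
    etree.SubElement(root, "name").text = ds.name
    etree.SubElement(root, "chain").text = "true" if ds.chain else "false"
    points = etree.SubElement(root, "points")
    for x, y, z in ds.points:
        pt = etree.SubElement(points, "point")
        etree.SubElement(pt, "x").text = _fmt(x)
        etree.SubElement(pt, "y").text = _fmt(y)
        etree.SubElement(pt, "z").text = _fmt(z)
    return etree.tostring(root, pretty_print=True, encoding="unicode")


def _write_dataset_csv(ds: Dataset) -> tuple[str, list]:
    warnings = []
    if ds.name not in ("", CSV_DEFAULT_NAME):
        warnings.append(ValidationIssue(
            "warning", "LOSSY_CSV",
            f"dataset name {ds.name!r} cannot be expressed in CSV", "name"))
    if ds.chain:
        warnings.append(ValidationIssue(
            "warning", "LOSSY_CSV",
            "chain flag cannot be expressed in CSV; points will load as "
            "particles", "chain"))
    lines = [",".join(_fmt(c) for c in row) for row in ds.points]
    return "\n".join(lines) + "\n", warnings


def write_dataset(ds: Dataset, dialect: str) -> tuple[str, list]:
    """Serialise a dataset; returns ``(text, warnings)``.

    The emitted text re-parses to an equal dataset, except that CSV drops
    the name and chain flag — each such loss yields a ``LOSSY_CSV``
    warning.
    """
    if dialect == "json":
        return _write_dataset_json(ds), []
    if dialect == "xml":
        return _write_dataset_xml(ds), []
    if dialect == "csv":
        return _write_dataset_csv(ds)
    raise ValueError(f"unknown dialect {dialect!r}")


def _write_information_json(info: InformationFile) -> str:
    sets = []
    for layer in info.layers:
        entry: dict = {}
        if layer.name is not None:
            entry["name"] = layer.name
        entry["numClass"] = int(layer.num_classes)
        if layer.labels is not None:
            entry["labels"] = list(layer.labels)
        entry["values"] = [int(v) for v in layer.values]
        sets.append(entry)
    return json.dumps({"information": sets}, indent=2) + "\n"


def _write_information_xml(info: InformationFile) -> str:
    root = etree.Element("information")
    for layer in info.layers:
        el = etree.SubElement(root, "set")
        if layer.name is not None:
            etree.SubElement(el, "name").text = layer.name
        etree.SubElement(el, "numClass").text = str(int(layer.num_classes))
        if layer.labels is not None:
            labels = etree.SubElement(el, "labels")
            for label in layer.labels:
                etree.SubElement(labels, "label").text = label
        values = etree.SubElement(el, "values")
        for v in layer.values:
            etree.SubElement(values, "value").text = str(int(v))
    return etree.tostring(root, pretty_print=True, encoding="unicode")


def _write_information_csv(info: InformationFile) -> tuple[str, list]:
    warnings = []
    for i, layer in enumerate(info.layers):
        locus = f"layer[{i}]"
        if layer.name:
            warnings.append(ValidationIssue(
                "warning", "LOSSY_CSV",
                f"layer name {layer.name!r} cannot be expressed in CSV", locus))
        if layer.labels:
            warnings.append(ValidationIssue(
                "warning", "LOSSY_CSV",
                "class labels cannot be expressed in CSV", locus))
        if layer.num_classes > len(set(int(v) for v in layer.values)):
            warnings.append(ValidationIssue(
                "warning", "LOSSY_CSV",
                f"numClass={layer.num_classes} exceeds the distinct values; "
                "CSV re-read will infer a smaller class count", locus))
    n = info.n_points
    lines = [",".join(str(int(layer.values[i])) for layer in info.layers)
             for i in range(n)]
    return "\n".join(lines) + "\n", warnings


def write_information(info: InformationFile, dialect: str) -> tuple[str, list]:
    """Serialise an information file; returns ``(text, warnings)``.

    CSV emits one column per layer and warns about every dropped name,
    label list, or declared-but-empty class.
    """
    if dialect == "json":
        return _write_information_json(info), []
    if dialect == "xml":
        return _write_information_xml(info), []
    if dialect == "csv":
        return _write_information_csv(info)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# cross-validation and conversion

def validate_pair(ds: Dataset, info: InformationFile) -> list:
    """Cross-check a dataset against an information file.

    Returns a (possibly empty) list of issues: a ``LENGTH_MISMATCH`` error
    per layer whose values length differs from the dataset's point count,
    and an ``EMPTY_CLASS`` warning per declared class with no points.
    """
    issues: list = []
    n = ds.n_points
    for i, layer in enumerate(info.layers):
        locus = f"layer[{i}]"
        if len(layer) != n:
            issues.append(ValidationIssue(
                "error", "LENGTH_MISMATCH",
                f"layer has {len(layer)} values for {n} points", locus))
            continue
        sizes = layer.class_sizes()
        for c in np.flatnonzero(sizes == 0):
            issues.append(ValidationIssue(
                "warning", "EMPTY_CLASS",
                f"class {int(c)} is declared but assigned to no point",
                locus))
    return issues


def convert(raw_text: str, out_dialect: str, family: Optional[str] = None,
            repair: bool = False) -> tuple[str, list]:
    """Re-serialise a document into another dialect.

    Detects dialect and family, parses, and writes; returns
    ``(text, warnings)`` where warnings combine normalisation notes from
    reading and lossiness notes from writing.
    """
    if out_dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {out_dialect!r}")
    dialect, fam = detect_format(raw_text, family=family)
    if fam == "dataset":
        ds = read_dataset(raw_text, dialect)
        text, warnings = write_dataset(ds, out_dialect)
        return text, list(ds.warnings) + warnings
    info = read_information(raw_text, dialect, repair=repair)
    text, warnings = write_information(info, out_dialect)
    return text, list(info.warnings) + warnings
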