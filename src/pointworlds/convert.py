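"""Importers: coordinate tables, categorical label vectors, PDB structures.

These bring common upstream outputs into the two-file model: a PCA score
table becomes a dataset, a clustering's label vector becomes an
information layer, and a protein structure's C-alpha trace becomes a
chained dataset suitable for backbone display.
"""

from __future__ import annotations

import io
import math
import warnings as _pywarnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .formats import Dataset, FormatError, InformationLayer, ValidationIssue

__all__ = ["ColumnSpec", "table_to_dataset", "labels_to_layer",
           "pdb_to_chain_dataset"]

Selector = Union[int, str]


@dataclass
class ColumnSpec:
    """Which table columns hold the x, y, z coordinates.

    Selectors are 0-based column indices or header names; they must be
    distinct and resolve to existing columns.
    """

    x_col: Selector
    y_col: Selector
    z_col: Selector
    label_cols: tuple = ()

    def __post_init__(self) -> None:
        sel = (self.x_col, self.y_col, self.z_col, *self.label_cols)
        if len(set(sel)) != len(sel):
            raise ValueError("column selectors must be distinct")

    @property
    def coord_cols(self) -> tuple[Selector, Selector, Selector]:
        return (self.x_col, self.y_col, self.z_col)


def _err(code: str, message: str, locus: str = "") -> FormatError:
    return FormatError(ValidationIssue("error", code, message, locus))


def _resolve(selector: Selector, header: Optional[list[str]],
             n_cols: int) -> int:
    if isinstance(selector, str):
        if header is None or selector not in header:
            raise _err("BAD_COLUMN", f"no column named {selector!r}")
        return header.index(selector)
    idx = int(selector)
    if not 0 <= idx < n_cols:
        raise _err("BAD_COLUMN",
                   f"column index {idx} outside 0..{n_cols - 1}")
    return idx


def table_to_dataset(table: str, spec: ColumnSpec, name: str,
                     delimiter: str = ",") -> Dataset:
    """Build a dataset from a delimited text table.

    A header row is recognised when a selector is a header name or when
    the first row is non-numeric in a selected coordinate column; it is
    then excluded from the points.  Row order is preserved; the result is
    a particle dataset (``chain=False``).
    """
    df = pd.read_csv(io.StringIO(table), sep=delimiter, header=None,
                     dtype=str, skipinitialspace=True,
                     skip_blank_lines=True, engine="python")
    if df.empty:
        raise _err("BAD_COORDINATE", "table has no rows")
    rows = df.fillna("").astype(str).values.tolist()
    rows = [[c.strip() for c in r] for r in rows]
    n_cols = len(rows[0])

    uses_names = any(isinstance(s, str) for s in
                     (*spec.coord_cols, *spec.label_cols))
    header: Optional[list[str]] = None
    body = rows
    if uses_names:
        header = rows[0]
        body = rows[1:]
    else:
        idxs = [_resolve(s, None, n_cols) for s in spec.coord_cols]
        first = rows[0]
        if any(not _is_number(first[i]) for i in idxs):
            header = first  # numeric selectors over a headered table
            body = rows[1:]
    if not body:
        raise _err("BAD_COORDINATE", "table has no data rows")

    idxs = [_resolve(s, header, n_cols) for s in spec.coord_cols]
    out = np.empty((len(body), 3), dtype=float)
    offset = 2 if header is not None else 1
    for r, row in enumerate(body):
        for j, i in enumerate(idxs):
            cell = row[i] if i < len(row) else ""
            if not _is_number(cell):
                raise _err("BAD_COORDINATE",
                           f"cell {cell!r} is not a finite number",
                           f"row {r + offset}, column {i}")
            out[r, j] = float(cell)
    return Dataset(name=name, points=out, chain=False)


def _is_number(tok: str) -> bool:
    try:
        v = float(tok)
    except (TypeError, ValueError):
        return False
    return math.isfinite(v)


def labels_to_layer(labels: Sequence, name: Optional[str] = None) -> InformationLayer:
    """Turn a categorical label vector into an information layer.

    Class indices follow first-appearance order (class 0 is the first
    distinct label seen), the layer's class labels are the original
    category names, and ``num_classes`` is the number of distinct labels.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("labels must be non-empty")
    order: dict = {}
    for label in labels:
        if label not in order:
            order[label] = len(order)
    values = np.array([order[l] for l in labels], dtype=int)
    return InformationLayer(num_classes=len(order), values=values,
                            name=name, labels=[str(l) for l in order])


def pdb_to_chain_dataset(pdb_text: str,
                         chain_id: Optional[str] = None) -> Dataset:
    """Extract a C-alpha backbone trace from PDB-format text.

    Takes the CA atom of every standard-residue position of the selected
    chain (or the first chain containing CA atoms), in residue order,
    from the first model only; for alternate locations the first altloc
    identifier wins.  The result is a chained dataset, one point per
    residue.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    with _pywarnings.catch_warnings():
        _pywarnings.simplefilter("ignore")
        try:
            structure = parser.get_structure("imported", io.StringIO(pdb_text))
        except Exception as e:
            raise _err("NO_CA_ATOMS", f"PDB text could not be parsed: {e}") \
                from e
    models = list(structure)
    if not models:
        raise _err("NO_CA_ATOMS", "no model in PDB text")
    model = models[0]
    chains = {c.id: c for c in model}
    if chain_id is not None:
        if chain_id not in chains:
            raise FormatError(ValidationIssue(
                "error", "CHAIN_NOT_FOUND",
                f"no chain {chain_id!r}; present: {sorted(chains)}"))
        candidates = [chains[chain_id]]
    else:
        candidates = list(model)
    coords: list[tuple[float, float, float]] = []
    used_chain = None
    for chain in candidates:
        chain_coords = []
        for residue in chain:
            ca = _first_altloc_ca(residue)
            if ca is not None:
                chain_coords.append(tuple(float(v) for v in ca))
        if chain_coords:
            coords = chain_coords
            used_chain = chain.id
            break
    if not coords:
        raise _err("NO_CA_ATOMS", "no CA atoms in the selected chain(s)")
    # ATOM records store 3 decimal places; round away float32 noise
    points = np.round(np.asarray(coords, dtype=float), 3)
    return Dataset(name=f"chain {used_chain} CA trace",
                   points=points, chain=True)


def _first_altloc_ca(residue):
    if not residue.has_id("CA"):
        return None
    atom = residue["CA"]
    if atom.is_disordered():
        altloc = sorted(atom.disordered_get_id_list())[0]
        atom = atom.disordered_get(altloc)
    return atom.get_coord()
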