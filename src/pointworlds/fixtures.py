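"""Deterministic example and synthetic data generators.

Two generators make every other module testable without downloads:

* :func:`worked_example` builds the canonical minimal pair — a three-point
  dataset plus an information file with two layers (one clustering that
  groups the first two points and isolates the third; one that gives each
  point its own class).
* :func:`simulate_clusters` emulates a clustered 3D cell map, such as a
  spatial map of pseudo-cells in an annelid brain where groups of cells
  share a gene-expression profile: an isotropic Gaussian mixture of ``k``
  clusters with known (true-label) class assignments.

:func:`emit_fixture_suite` writes both, in all three dialects, plus a
corpus of deliberately corrupted files (one planted defect each) with a
manifest, for exercising parsers and validators end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from . import formats
from .formats import Dataset, InformationFile, InformationLayer

__all__ = ["ClusterSimSpec", "worked_example", "simulate_clusters",
           "emit_fixture_suite", "CORRUPTED_CORPUS"]


def worked_example() -> tuple[Dataset, InformationFile]:
    """The minimal 3-point dataset and its 2-layer information file.

    Coordinates are the unit-simplex corners — injective, so tests can
    verify that point order survives serialisation.  Layer A declares two
    classes with values ``[0, 0, 1]``; layer B puts each point in its own
    class (``num_classes`` equals the point count).
    """
    ds = Dataset(
        name="minimal example",
        points=np.array([[1.0, 0.0, 0.0],
                         [0.0, 1.0, 0.0],
                         [0.0, 0.0, 1.0]]),
        chain=False,
    )
    layer_a = InformationLayer(
        num_classes=2, values=np.array([0, 0, 1]),
        name="pairing clustering", labels=["class one", "class two"])
    layer_b = InformationLayer(
        num_classes=3, values=np.array([0, 1, 2]),
        name="singleton clustering")
    return ds, InformationFile(layers=[layer_a, layer_b])


@dataclass
class ClusterSimSpec:
    """Parameters of the Gaussian-mixture cell-map simulation.

    k             number of clusters (>= 1)
    n_per_cluster points per cluster (>= 1)
    centers       (k, 3) cluster centres, or None to draw them uniformly
                  in the unit cube
    sigma         isotropic noise standard deviation (>= 0), in the same
                  dimensionless units as the coordinates
    seed          RNG seed; output is bit-reproducible given the seed
    """

    k: int = 3
    n_per_cluster: int = 50
    centers: Optional[np.ndarray] = None
    sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1 or self.n_per_cluster < 1 or self.sigma < 0:
            raise ValueError("need k >= 1, n_per_cluster >= 1, sigma >= 0")
        if self.centers is not None:
            c = np.asarray(self.centers, dtype=float)
            if c.shape != (self.k, 3):
                raise ValueError(f"centers must have shape ({self.k}, 3)")
            self.centers = c


def simulate_clusters(spec: ClusterSimSpec) -> tuple[Dataset, InformationLayer]:
    """Sample a clustered point cloud with its true-label layer.

    Point i of cluster c is ``centers[c] + Normal(0, sigma^2 I_3)``;
    the returned layer assigns each point its generating cluster index,
    so N = k * n_per_cluster and the layer always validates against the
    dataset.
    """
    rng = np.random.default_rng(spec.seed)
    centers = spec.centers
    if centers is None:
        centers = rng.uniform(0.0, 1.0, size=(spec.k, 3))
    points = np.repeat(centers, spec.n_per_cluster, axis=0)
    points = points + rng.normal(0.0, spec.sigma, size=points.shape)
    values = np.repeat(np.arange(spec.k), spec.n_per_cluster)
    ds = Dataset(name=f"simulated cell map (k={spec.k})", points=points)
    layer = InformationLayer(num_classes=spec.k, values=values,
                             name="true clusters",
                             labels=[f"cluster {c}" for c in range(spec.k)])
    return ds, layer


# ---------------------------------------------------------------------------
# corrupted corpus: (filename, family, dialect, expected issue code, text)

CORRUPTED_CORPUS: list[tuple[str, str, str, str, str]] = [
    ("bad_syntax.dataset.json", "dataset", "json", "SYNTAX_ERROR",
     '{"dataset": {"name": "broken", "points": [[0, 0, 0]'),
    ("missing_root.dataset.json", "dataset", "json", "MISSING_ROOT",
     '{"data": {"points": [[0, 0, 0]]}}\n'),
    ("bad_coordinate.dataset.json", "dataset", "json", "BAD_COORDINATE",
     '{"dataset": {"name": "x", "points": [[0, 0, "oops"]]}}\n'),
    ("bad_arity.dataset.json", "dataset", "json", "BAD_ARITY",
     '{"dataset": {"name": "x", "points": [[0, 0], [1, 1, 1]]}}\n'),
    ("bad_boolean.dataset.json", "dataset", "json", "BAD_BOOLEAN",
     '{"dataset": {"name": "x", "chain": "maybe",'
     ' "points": [[0, 0, 0]]}}\n'),
    ("empty.dataset.json", "dataset", "json", "EMPTY_DATASET",
     '{"dataset": {"name": "x", "points": []}}\n'),
    ("bad_arity.dataset.csv", "dataset", "csv", "BAD_ARITY",
     "0.5,1.5,2.5\n3.5,4.5\n"),
    ("bad_coordinate.dataset.csv", "dataset", "csv", "BAD_COORDINATE",
     "0.5,1.5,2.5\n3.5,4.5,oops\n"),
    ("bad_boolean.dataset.xml", "dataset", "xml", "BAD_BOOLEAN",
     "<dataset><name>x</name><chain>maybe</chain><points>"
     "<point><x>0</x><y>0</y><z>0</z></point></points></dataset>\n"),
    ("bad_arity.dataset.xml", "dataset", "xml", "BAD_ARITY",
     "<dataset><name>x</name><points>"
     "<point><x>0</x><y>0</y></point></points></dataset>\n"),
    ("missing_root.information.xml", "information", "xml", "MISSING_ROOT",
     "<layers><set><numClass>1</numClass><values><value>0</value>"
     "</values></set></layers>\n"),
    ("empty.information.json", "information", "json", "EMPTY_INFORMATION",
     '{"information": []}\n'),
    ("ragged.information.json", "information", "json", "RAGGED_LAYERS",
     '{"information": [{"numClass": 1, "values": [0, 0]},'
     ' {"numClass": 1, "values": [0]}]}\n'),
    ("out_of_range.information.json", "information", "json",
     "VALUE_OUT_OF_RANGE",
     '{"information": [{"numClass": 2, "values": [0, 1, 5]}]}\n'),
    ("label_mismatch.information.json", "information", "json",
     "LABEL_COUNT_MISMATCH",
     '{"information": [{"numClass": 2, "labels": ["only one"],'
     ' "values": [0, 1]}]}\n'),
    ("ragged.information.csv", "information", "csv", "RAGGED_LAYERS",
     "0,1\n0\n"),
]


def _corrupted_reader(family: str, dialect: str):
    if family == "dataset":
        return lambda text: formats.read_dataset(text, dialect)
    return lambda text: formats.read_information(text, dialect)


def emit_fixture_suite(directory: Union[str, Path],
                       sim_spec: Optional[ClusterSimSpec] = None) -> dict:
    """Write the full fixture suite and return its manifest.

    Emits the worked example and a cluster simulation, each as a
    dataset/information pair in all three dialects, plus the corrupted
    corpus.  The manifest (also written as ``manifest.tsv``) maps each
    file to its family, dialect and expected issue code ("OK" for clean
    files).  Output is byte-identical across runs for a fixed spec.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if sim_spec is None:
        sim_spec = ClusterSimSpec()
    manifest: dict[str, dict] = {}

    def emit(stem: str, family: str, dialect: str, text: str,
             expect: str = "OK") -> None:
        path = directory / stem
        path.write_text(text)
        manifest[stem] = {"family": family, "dialect": dialect,
                          "expect": expect}

    ds, info = worked_example()
    sim_ds, sim_layer = simulate_clusters(sim_spec)
    sim_info = InformationFile(layers=[sim_layer])
    for dialect in formats.DIALECTS:
        emit(f"worked_example.dataset.{dialect}", "dataset", dialect,
             formats.write_dataset(ds, dialect)[0])
        emit(f"worked_example.information.{dialect}", "information", dialect,
             formats.write_information(info, dialect)[0])
        emit(f"cluster_sim.dataset.{dialect}", "dataset", dialect,
             formats.write_dataset(sim_ds, dialect)[0])
        emit(f"cluster_sim.information.{dialect}", "information", dialect,
             formats.write_information(sim_info, dialect)[0])
    for stem, family, dialect, expect, text in CORRUPTED_CORPUS:
        emit(stem, family, dialect, text, expect)

    lines = ["file\tfamily\tdialect\texpect"]
    lines += [f"{stem}\t{m['family']}\t{m['dialect']}\t{m['expect']}"
              for stem, m in sorted(manifest.items())]
    (directory / "manifest.tsv").write_text("\n".join(lines) + "\n")
    return manifest
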