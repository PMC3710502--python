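# pointworlds

A toolkit for sharing and viewing 3D biological point clouds with
categorical annotation layers. It targets the common situation where a
structure has been described as a set of 3D-referenced points — cell
positions from confocal microscopy, pseudo-cells in a spatial
gene-expression map, PCA scores, a protein backbone — and a downstream
analysis (typically clustering) has assigned each point to a class that
needs to be seen in its spatial context.

The data model is two plain-text files:

* a **dataset** file: one named, ordered list of N points
  (x<sub>i</sub>, y<sub>i</sub>, z<sub>i</sub>), with an optional `chain`
  flag (`true` draws a solid line from point i to point i+1, for
  sequential data such as C-alpha traces; the default `false` renders
  independent particles);
* an **information layer** file: one or more class-assignment vectors
  c<sub>i</sub> ∈ {0, …, numClass−1} over the same N points, in the same
  order, each with a declared class count and optional class labels.

Both families exist in three dialects — JSON, XML and CSV — that carry
the same information, except that CSV cannot express names, labels or
the chain flag (every such loss is reported explicitly). Datasets and
layers are composed into a *scene* of up to four *worlds* (side-by-side
sub-views), with per-class visibility and colour control, global axis
scaling, opacity/size settings and optional centering of the cloud
around the origin. Scenes render to:

* a **single self-contained interactive HTML document** (drag to rotate,
  scroll to zoom; no network access needed), or
* a **static PNG** for figures.

Rendering always draws a faint "shadow" batch of all raw points beneath
the coloured classes, so hidden or unclassified points keep their
spatial context visible.

## Worked example

```python
import pointworlds as pw

# the canonical minimal pair: 3 points, 2 information layers
ds, info = pw.worked_example()
print(ds.n_points, len(info.layers), pw.validate_pair(ds, info))
# 3 2 []

# layer A groups the first two points; layer B isolates every point
print([l.num_classes for l in info.layers])   # [2, 3]
print(info.layers[0].values.tolist())         # [0, 0, 1]

# serialise: CSV is lossy and says so
text, warnings = pw.write_dataset(ds, "csv")
print(text, str(warnings[0]), sep="")
# 1.0,0.0,0.0
# 0.0,1.0,0.0
# 0.0,0.0,1.0
# warning:LOSSY_CSV [name] dataset name 'minimal example' cannot be expressed in CSV

# scene -> interactive document
scene = pw.Scene()
world = scene.add_world()
world.add_dataset(ds)
world.attach_layer(ds, info.layers[0], info)
html = pw.render_document(scene)
print([(p.kind, p.n, p.tag[2]) for p in pw.extract_primitives(html)])
# [('particles', 3, 'raw'), ('particles', 2, 'class:0'), ('particles', 1, 'class:1')]
```

The extracted primitives show the rendering contract: one 3-point shadow
batch of the raw data plus one particle batch per visible class (2
points in class 0, 1 point in class 1 — together conserving N = 3).

The same operations are scriptable from the shell:

```sh
pointworlds synth fixtures/ --k 3 --n 50 --sigma 0.05 --seed 7
pointworlds validate fixtures/cluster_sim.dataset.json \
                     fixtures/cluster_sim.information.json   # exit 0
pointworlds convert fixtures/cluster_sim.dataset.json ds.xml --to xml
pointworlds render scene.json --out scene.html
pointworlds stats fixtures/cluster_sim.dataset.json \
                  fixtures/cluster_sim.information.json
```

`synth` also emits a corpus of deliberately broken files with a manifest
of their planted defect codes, useful for testing pipelines that consume
these formats. Exit codes: 0 success, 1 validation errors, 2 usage/IO
error.

## File format schemas

Formal schemas for the canonical writer output ship in
`src/pointworlds/schemas/`: JSON Schemas and XML DTDs for both file
families, the CSV grammar, and the scene-configuration schema used by
`pointworlds render`.
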