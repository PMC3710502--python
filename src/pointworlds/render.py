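"""Compile worlds into drawable primitives and serialise them.

A :class:`Primitive` is a renderer-agnostic drawable: a particle batch or
a polyline with a single colour, opacity and size, tagged with its
provenance (world id, dataset name, class index or ``raw``).  Two
back-ends consume primitives:

* :func:`render_document` writes a single self-contained interactive HTML
  file (no network access needed to view it).  The geometry is embedded
  in a machine-extractable *data island* (format documented below) that a
  small hand-written canvas renderer reads in the browser; tests read the
  same island with :func:`extract_primitives`.
* :func:`render_static` rasterises the scene to a PNG via matplotlib for
  publication figures.

For every bound dataset the compiled primitives are: (a) one low-opacity
"shadow" particle batch of *all* raw points, so hidden or unclassified
points remain faintly visible; (b) one particle batch per *visible* class
in that class's display colour; and (c), for chain datasets, one polyline
through all points in file order (N-1 segments).

Data island format, version 1 (``text/x-pointworlds-geometry``): a header
line ``#pointworlds-geometry 1``; then per primitive one metadata line ::

    >world=<id>;kind=<particles|polyline>;dataset=<pct-encoded name>;\
tag=<raw|chain|class:<i>>;colour=<r>,<g>,<b>;opacity=<o>;size=<s>;n=<N>

followed by N lines ``x,y,z``.  Field order is fixed; names are
percent-encoded so delimiters cannot collide.
"""

from __future__ import annotations

import io
import urllib.parse
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .scene import MAX_WORLDS, Scene, SceneError, Settings, World, apply_settings

__all__ = [
    "Primitive",
    "build_primitives",
    "render_document",
    "render_static",
    "extract_primitives",
    "GEOMETRY_VERSION",
    "SHADOW_COLOUR",
    "CHAIN_COLOUR",
    "CHAIN_OPACITY",
]

GEOMETRY_VERSION = 1

SHADOW_COLOUR = (0.55, 0.55, 0.55)
CHAIN_COLOUR = (0.35, 0.35, 0.35)
CHAIN_OPACITY = 0.8


@dataclass(eq=False)
class Primitive:
    kind: str  # "particles" | "polyline"
    positions: np.ndarray  # (N, 3)
    colour: tuple[float, float, float]
    opacity: float
    size: float
    tag: tuple  # (world_id, dataset_name, class_tag)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        minimum = 2 if self.kind == "polyline" else 1
        if pos.shape[0] < minimum:
            raise ValueError(f"{self.kind} needs >= {minimum} positions")
        if self.kind not in ("particles", "polyline"):
            raise ValueError(f"unknown primitive kind {self.kind!r}")
        if not 0.0 < self.opacity <= 1.0:
            raise ValueError("opacity must be in (0, 1]")
        self.positions = pos
        self.colour = tuple(float(c) for c in self.colour)

    @property
    def n(self) -> int:
        return int(self.positions.shape[0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Primitive):
            return NotImplemented
        return (self.kind == other.kind and self.tag == other.tag
                and self.colour == other.colour
                and self.opacity == other.opacity and self.size == other.size
                and np.array_equal(self.positions, other.positions))


def build_primitives(world: World, settings: Settings) -> list[Primitive]:
    """Compile one world's bindings into an ordered primitive sequence."""
    prims: list[Primitive] = []
    for binding in world.bindings:
        ds = binding.dataset
        pts = apply_settings(ds.points, settings)
        prims.append(Primitive(
            kind="particles", positions=pts, colour=SHADOW_COLOUR,
            opacity=settings.raw_opacity, size=settings.raw_size,
            tag=(world.id, ds.name, "raw")))
        if ds.chain and ds.n_points >= 2:
            prims.append(Primitive(
                kind="polyline", positions=pts, colour=CHAIN_COLOUR,
                opacity=CHAIN_OPACITY, size=settings.raw_size,
                tag=(world.id, ds.name, "chain")))
        if binding.layer is not None:
            values = binding.layer.values
            for c, state in enumerate(binding.class_display):
                if not state.visible:
                    continue
                mask = values == c
                if not mask.any():
                    continue  # declared-but-empty class draws nothing
                prims.append(Primitive(
                    kind="particles", positions=pts[mask],
                    colour=state.colour, opacity=settings.layer_opacity,
                    size=settings.layer_size,
                    tag=(world.id, ds.name, f"class:{c}")))
    return prims


def chain_segment_count(n_points: int) -> int:
    """Number of solid-line segments a chain of ``n_points`` draws."""
    return max(0, n_points - 1)


# ---------------------------------------------------------------------------
# data island serialisation

def _fmt(v: float) -> str:
    return repr(float(v))


def _island_lines(prims: Sequence[Primitive]) -> list[str]:
    lines = [f"#pointworlds-geometry {GEOMETRY_VERSION}"]
    for p in prims:
        world_id, ds_name, class_tag = p.tag
        meta = (f">world={world_id}"
                f";kind={p.kind}"
                f";dataset={urllib.parse.quote(str(ds_name), safe='')}"
                f";tag={urllib.parse.quote(str(class_tag), safe=':')}"
                f";colour={_fmt(p.colour[0])},{_fmt(p.colour[1])},{_fmt(p.colour[2])}"
                f";opacity={_fmt(p.opacity)}"
                f";size={_fmt(p.size)}"
                f";n={p.n}")
        lines.append(meta)
        lines.extend(",".join(_fmt(c) for c in row) for row in p.positions)
    return lines


def extract_primitives(document: str) -> list[Primitive]:
    """Recover the exact primitive set from a rendered document's island."""
    start = document.index('id="pw-geometry"')
    body_start = document.index(">", start) + 1
    body_end = document.index("</script>", body_start)
    lines = document[body_start:body_end].strip("\n").split("\n")
    if not lines or not lines[0].startswith("#pointworlds-geometry"):
        raise ValueError("no geometry island header")
    version = int(lines[0].split()[1])
    if version != GEOMETRY_VERSION:
        raise ValueError(f"unsupported geometry version {version}")
    prims: list[Primitive] = []
    i = 1
    while i < len(lines):
        line = lines[i]
        if not line.startswith(">"):
            raise ValueError(f"expected primitive header at line {i}")
        fields = dict(part.split("=", 1) for part in line[1:].split(";"))
        n = int(fields["n"])
        coords = np.array([[float(t) for t in lines[i + 1 + j].split(",")]
                           for j in range(n)])
        colour = tuple(float(t) for t in fields["colour"].split(","))
        prims.append(Primitive(
            kind=fields["kind"], positions=coords, colour=colour,
            opacity=float(fields["opacity"]), size=float(fields["size"]),
            tag=(int(fields["world"]),
                 urllib.parse.unquote(fields["dataset"]),
                 urllib.parse.unquote(fields["tag"]))))
        i += 1 + n
    return prims


# ---------------------------------------------------------------------------
# HTML document

_VIEWER_JS = r"""
(function () {
  "use strict";
  var island = document.getElementById("pw-geometry").textContent;
  var lines = island.replace(/^\s+|\s+$/g, "").split("\n");
  var prims = [];
  for (var i = 1; i < lines.length;) {
    var meta = {};
    lines[i].slice(1).split(";").forEach(function (kv) {
      var j = kv.indexOf("=");
      meta[kv.slice(0, j)] = kv.slice(j + 1);
    });
    var n = parseInt(meta.n, 10);
    var pts = new Float64Array(3 * n);
    for (var k = 0; k < n; k++) {
      var t = lines[i + 1 + k].split(",");
      pts[3 * k] = +t[0]; pts[3 * k + 1] = +t[1]; pts[3 * k + 2] = +t[2];
    }
    var col = meta.colour.split(",").map(Number);
    prims.push({world: parseInt(meta.world, 10), kind: meta.kind,
                points: pts, n: n, colour: col,
                opacity: +meta.opacity, size: +meta.size});
    i += 1 + n;
  }
  var center = [0, 0, 0], radius = 1;
  (function () {
    var lo = [Infinity, Infinity, Infinity], hi = [-Infinity, -Infinity, -Infinity];
    prims.forEach(function (p) {
      for (var k = 0; k < p.n; k++)
        for (var a = 0; a < 3; a++) {
          var v = p.points[3 * k + a];
          if (v < lo[a]) lo[a] = v;
          if (v > hi[a]) hi[a] = v;
        }
    });
    for (var a = 0; a < 3; a++) center[a] = (lo[a] + hi[a]) / 2;
    radius = Math.max(hi[0] - lo[0], hi[1] - lo[1], hi[2] - lo[2], 1e-9) / 2;
  })();
  document.querySelectorAll("canvas.pw-world").forEach(function (canvas) {
    var world = parseInt(canvas.dataset.world, 10);
    var mine = prims.filter(function (p) { return p.world === world; });
    var rx = 0.4, ry = 0.6, dragging = false, lastX = 0, lastY = 0, zoom = 1;
    function draw() {
      var ctx = canvas.getContext("2d");
      var w = canvas.width, h = canvas.height;
      ctx.clearRect(0, 0, w, h);
      var s = 0.45 * Math.min(w, h) / radius * zoom;
      var ca = Math.cos(ry), sa = Math.sin(ry);
      var cb = Math.cos(rx), sb = Math.sin(rx);
      function project(x, y, z, out) {
        x -= center[0]; y -= center[1]; z -= center[2];
        var x1 = ca * x + sa * z, z1 = -sa * x + ca * z;
        var y1 = cb * y - sb * z1;
        out[0] = w / 2 + s * x1;
        out[1] = h / 2 - s * y1;
      }
      var q = [0, 0];
      mine.forEach(function (p) {
        ctx.globalAlpha = p.opacity;
        var css = "rgb(" + Math.round(255 * p.colour[0]) + "," +
                  Math.round(255 * p.colour[1]) + "," +
                  Math.round(255 * p.colour[2]) + ")";
        if (p.kind === "polyline") {
          ctx.strokeStyle = css;
          ctx.lineWidth = Math.max(1, p.size);
          ctx.beginPath();
          for (var k = 0; k < p.n; k++) {
            project(p.points[3 * k], p.points[3 * k + 1], p.points[3 * k + 2], q);
            if (k === 0) ctx.moveTo(q[0], q[1]); else ctx.lineTo(q[0], q[1]);
          }
          ctx.stroke();
        } else {
          ctx.fillStyle = css;
          var r = Math.max(1.5, 2 * p.size);
          for (var k2 = 0; k2 < p.n; k2++) {
            project(p.points[3 * k2], p.points[3 * k2 + 1], p.points[3 * k2 + 2], q);
            ctx.fillRect(q[0] - r / 2, q[1] - r / 2, r, r);
          }
        }
      });
      ctx.globalAlpha = 1;
    }
    canvas.addEventListener("mousedown", function (e) {
      dragging = true; lastX = e.clientX; lastY = e.clientY;
    });
    window.addEventListener("mouseup", function () { dragging = false; });
    window.addEventListener("mousemove", function (e) {
      if (!dragging) return;
      ry += (e.clientX - lastX) * 0.01;
      rx += (e.clientY - lastY) * 0.01;
      lastX = e.clientX; lastY = e.clientY;
      draw();
    });
    canvas.addEventListener("wheel", function (e) {
      e.preventDefault();
      zoom *= e.deltaY < 0 ? 1.1 : 1 / 1.1;
      draw();
    });
    draw();
  });
})();
"""

_PAGE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>pointworlds scene</title>
<style>
body {{ margin: 0; background: #111; color: #ddd;
       font-family: sans-serif; }}
#pw-grid {{ display: grid; grid-template-columns: {columns};
            gap: 2px; width: 100vw; height: 100vh; }}
.pw-cell {{ position: relative; background: #1b1b1b; }}
.pw-cell span {{ position: absolute; top: 4px; left: 6px;
                 font-size: 12px; opacity: 0.7; }}
canvas.pw-world {{ width: 100%; height: 100%; display: block; }}
</style>
</head>
<body>
<div id="pw-grid">
{cells}
</div>
<script type="text/x-pointworlds-geometry" id="pw-geometry">
{island}
</script>
<script>
window.addEventListener("load", function () {{
  document.querySelectorAll("canvas.pw-world").forEach(function (c) {{
    c.width = c.clientWidth; c.height = c.clientHeight;
  }});
{viewer}
}});
</script>
</body>
</html>
"""


def _grid_columns(n_worlds: int) -> str:
    # 1 world -> full window, 2 -> side-by-side split, 3-4 -> 2x2 grid
    return "1fr" if n_worlds == 1 else "1fr 1fr"


def render_document(scene: Scene) -> str:
    """Render the scene to one self-contained interactive HTML document.

    The page needs no network access: styles, the viewer script and the
    geometry island are all inline.  One sub-view (canvas) is emitted per
    world.
    """
    bound_worlds = [w for w in scene.worlds if w.bindings]
    if not bound_worlds:
        raise SceneError("EMPTY_SCENE",
                         "scene has no world with a bound dataset")
    prims: list[Primitive] = []
    for world in scene.worlds:
        prims.extend(build_primitives(world, scene.settings))
    cells = "\n".join(
        f'<div class="pw-cell"><span>world {w.id}</span>'
        f'<canvas class="pw-world" data-world="{w.id}"></canvas></div>'
        for w in scene.worlds)
    return _PAGE.format(columns=_grid_columns(len(scene.worlds)),
                        cells=cells,
                        island="\n".join(_island_lines(prims)),
                        viewer=_VIEWER_JS)


# ---------------------------------------------------------------------------
# static raster export

def render_static(scene: Scene, view: tuple[float, float] = (-60.0, 30.0),
                  size: tuple[int, int] = (640, 480)) -> bytes:
    """Rasterise the scene to PNG bytes (matplotlib Agg backend).

    ``view`` is (azimuth, elevation) in degrees, applied to every world's
    sub-view; ``size`` is the output (width, height) in pixels.  The
    output is deterministic for a given scene, view and size.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    bound_worlds = [w for w in scene.worlds if w.bindings]
    if not bound_worlds:
        raise SceneError("EMPTY_SCENE",
                         "scene has no world with a bound dataset")
    azim, elev = view
    width, height = size
    dpi = 100.0
    n = len(scene.worlds)
    ncols = 1 if n == 1 else 2
    nrows = 1 if n <= 2 else 2
    fig = plt.figure(figsize=(width / dpi, height / dpi), dpi=dpi)
    try:
        for idx, world in enumerate(scene.worlds):
            ax = fig.add_subplot(nrows, ncols, idx + 1, projection="3d")
            ax.view_init(elev=elev, azim=azim)
            ax.set_title(f"world {world.id}", fontsize=8)
            for p in build_primitives(world, scene.settings):
                if p.kind == "polyline":
                    ax.plot(p.positions[:, 0], p.positions[:, 1],
                            p.positions[:, 2], color=p.colour,
                            alpha=p.opacity, linewidth=p.size)
                else:
                    ax.scatter(p.positions[:, 0], p.positions[:, 1],
                               p.positions[:, 2], color=[p.colour],
                               alpha=p.opacity, s=(3 * p.size) ** 2,
                               depthshade=False)
        buf = io.BytesIO()
        fig.savefig(buf, format="png", dpi=dpi,
                    metadata={"Software": "pointworlds"})
        return buf.getvalue()
    finally:
        plt.close(fig)
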