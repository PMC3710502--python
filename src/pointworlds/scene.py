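"""Visualisation state: worlds, bindings, class display control, settings.

A :class:`Scene` holds up to four *worlds* (independent visualisation
sub-windows shown side by side for comparison).  Each world binds one or
more datasets; each binding may select one active information layer, which
expands into per-class display states (visible flag + RGB colour).
Settings are global across all worlds and datasets: per-axis scale
factors, opacities and sizes for raw versus layer-coloured points, and an
optional centering of the data around the origin.
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .formats import (Dataset, InformationFile, InformationLayer,
                      ValidationIssue, validate_pair)

__all__ = [
    "MAX_WORLDS",
    "DisplayState",
    "Settings",
    "Binding",
    "World",
    "Scene",
    "SceneError",
    "default_palette",
    "apply_settings",
]

MAX_WORLDS = 4


class SceneError(ValueError):
    """Scene-state violation; carries a machine code (e.g. WORLD_LIMIT)."""

    def __init__(self, code: str, message: str):
        super().__init__(f"{code}: {message}")
        self.code = code


@dataclass
class DisplayState:
    """Visibility and colour of one class of one bound layer."""

    visible: bool = True
    colour: tuple[float, float, float] = (0.5, 0.5, 0.5)

    def __post_init__(self) -> None:
        c = tuple(float(x) for x in self.colour)
        if len(c) != 3 or any(not (0.0 <= x <= 1.0) for x in c):
            raise ValueError(f"colour {self.colour!r} outside [0,1]^3")
        self.colour = c


@dataclass
class Settings:
    """Global display settings, applied to all worlds and datasets.

    axis_scale   multiplicative factor per axis (x, y, z), dimensionless
    raw_opacity  opacity of the raw-data "shadow" points, in (0, 1]
    layer_opacity opacity of layer-coloured points, in (0, 1]
    raw_size / layer_size  marker sizes in display units, > 0
    center       subtract the per-axis bounding-box midpoint first, so the
                 cloud sits symmetrically around 0
    """

    axis_scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    raw_opacity: float = 0.15
    layer_opacity: float = 0.9
    raw_size: float = 1.0
    layer_size: float = 1.0
    center: bool = False

    def __post_init__(self) -> None:
        scale = tuple(float(s) for s in self.axis_scale)
        if len(scale) != 3 or any(not (s > 0 and np.isfinite(s)) for s in scale):
            raise ValueError("axis_scale components must be positive finite")
        self.axis_scale = scale
        for attr in ("raw_opacity", "layer_opacity"):
            v = float(getattr(self, attr))
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{attr} must be in (0, 1]")
            setattr(self, attr, v)
        for attr in ("raw_size", "layer_size"):
            v = float(getattr(self, attr))
            if not (v > 0 and np.isfinite(v)):
                raise ValueError(f"{attr} must be positive")
            setattr(self, attr, v)


def default_palette(k: int) -> list[tuple[float, float, float]]:
    """``k`` maximally hue-separated colours for class display.

    Hues are evenly spaced around the colour wheel at fixed saturation
    0.65 and value 0.9 (HSV), so k=2 gives complementary colours 180
    degrees apart and k=1 is a fixed warm red.  Deterministic; pairwise
    distinct for k up to 64 and beyond.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return [colorsys.hsv_to_rgb(i / k, 0.65, 0.9) for i in range(k)]


def apply_settings(points: np.ndarray, settings: Settings) -> np.ndarray:
    """Transform coordinates per the global settings.

    With ``center=True`` the per-axis bounding-box midpoint is subtracted
    (so each axis' min and max are symmetric about 0), then each axis is
    multiplied by its scale factor.  Identity when centering is off and
    all scales are 1.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] == 0:
        raise ValueError("points must be a non-empty (N, 3) array")
    out = pts.copy()
    if settings.center:
        mid = (out.min(axis=0) + out.max(axis=0)) / 2.0
        out -= mid
    out *= np.asarray(settings.axis_scale, dtype=float)
    return out


@dataclass
class Binding:
    """One dataset bound into a world, with an optional active layer."""

    dataset: Dataset
    layer: Optional[InformationLayer] = None
    class_display: list[DisplayState] = field(default_factory=list)


class World:
    """One visualisation sub-window (id 1..4)."""

    def __init__(self, world_id: int):
        if not 1 <= world_id <= MAX_WORLDS:
            raise SceneError("WORLD_LIMIT",
                             f"world id {world_id} outside 1..{MAX_WORLDS}")
        self.id = world_id
        self.bindings: list[Binding] = []
        # customised display states survive detach/re-attach of a layer
        self._display_cache: dict[tuple[str, object], list[DisplayState]] = {}

    def add_dataset(self, dataset: Dataset) -> Binding:
        binding = Binding(dataset=dataset)
        self.bindings.append(binding)
        return binding

    def attach_layer(self, dataset: Dataset, layer: InformationLayer,
                     info: Optional[InformationFile] = None) -> list[DisplayState]:
        """Select ``layer`` as the active layer for ``dataset``.

        The pair must cross-validate cleanly (lengths match).  Returns one
        display state per class — all visible, coloured from the default
        palette — except that states previously customised for the same
        (dataset, layer) pair are preserved.
        """
        errors = [i for i in validate_pair(dataset, InformationFile([layer]))
                  if i.severity == "error"]
        if errors:
            raise SceneError("INVALID_PAIR",
                             "; ".join(str(i) for i in errors))
        binding = self._binding_for(dataset)
        key = (dataset.name, layer.name if layer.name is not None
               else int(layer.num_classes))
        cached = self._display_cache.get(key)
        if cached is not None and len(cached) == layer.num_classes:
            states = cached
        else:
            states = [DisplayState(visible=True, colour=c)
                      for c in default_palette(layer.num_classes)]
            self._display_cache[key] = states
        binding.layer = layer
        binding.class_display = states
        return states

    def _binding_for(self, dataset: Dataset) -> Binding:
        for b in self.bindings:
            if b.dataset is dataset:
                return b
        return self.add_dataset(dataset)


class Scene:
    """Up to four worlds plus the global settings."""

    def __init__(self, settings: Optional[Settings] = None):
        self.worlds: list[World] = []
        self.settings = settings if settings is not None else Settings()

    def add_world(self) -> World:
        """Create the next world; at most four may exist."""
        if len(self.worlds) >= MAX_WORLDS:
            raise SceneError("WORLD_LIMIT",
                             f"a scene holds at most {MAX_WORLDS} worlds")
        used = {w.id for w in self.worlds}
        next_id = min(i for i in range(1, MAX_WORLDS + 1) if i not in used)
        world = World(next_id)
        self.worlds.append(world)
        return world

    def remove_world(self, world_id: int) -> None:
        before = len(self.worlds)
        self.worlds = [w for w in self.worlds if w.id != world_id]
        if len(self.worlds) == before:
            raise SceneError("WORLD_LIMIT", f"no world with id {world_id}")

    def world(self, world_id: int) -> World:
        for w in self.worlds:
            if w.id == world_id:
                return w
        raise SceneError("WORLD_LIMIT", f"no world with id {world_id}")


# ---------------------------------------------------------------------------
# scene configuration document (human-editable JSON; schema shipped in
# pointworlds/schemas/scene-config.schema.json)

def scene_config_to_text(config: dict) -> str:
    return json.dumps(config, indent=2) + "\n"


def build_scene(config: dict, loader) -> Scene:
    """Construct a Scene from a parsed configuration document.

    ``loader(path) -> str`` resolves file references to raw text (the CLI
    passes a filesystem reader; tests may pass a dict lookup).  Structure::

        {"settings": {...optional Settings fields...},
         "worlds": [{"datasets": [{"path": ..., "family_hint": ...,
                                   "layers": {"path": ..., "index": 0},
                                   "hidden_classes": [..],
                                   "colours": {"0": [r,g,b], ...}}]}]}
    """
    from . import formats

    raw_settings = dict(config.get("settings", {}))
    if "axis_scale" in raw_settings:
        raw_settings["axis_scale"] = tuple(raw_settings["axis_scale"])
    settings = Settings(**raw_settings)
    scene = Scene(settings=settings)
    worlds_cfg = config.get("worlds", [])
    if len(worlds_cfg) > MAX_WORLDS:
        raise SceneError("WORLD_LIMIT",
                         f"configuration declares {len(worlds_cfg)} worlds; "
                         f"at most {MAX_WORLDS} are allowed")
    for wcfg in worlds_cfg:
        world = scene.add_world()
        for dcfg in wcfg.get("datasets", []):
            text = loader(dcfg["path"])
            dialect, fam = formats.detect_format(
                text, family=dcfg.get("family_hint"))
            if fam != "dataset":
                raise SceneError("INVALID_PAIR",
                                 f"{dcfg['path']} is not a dataset file")
            ds = formats.read_dataset(text, dialect)
            if "name" in dcfg:
                ds.name = dcfg["name"]
            world.add_dataset(ds)
            lcfg = dcfg.get("layer")
            if lcfg is not None:
                ltext = loader(lcfg["path"])
                ldialect, lfam = formats.detect_format(
                    ltext, family=lcfg.get("family_hint", "information"))
                info = formats.read_information(ltext, ldialect)
                layer = info.layers[int(lcfg.get("index", 0))]
                states = world.attach_layer(ds, layer, info)
                for c in dcfg.get("hidden_classes", []):
                    states[int(c)].visible = False
                for c, rgb in dcfg.get("colours", {}).items():
                    states[int(c)].colour = tuple(float(v) for v in rgb)
    return scene
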