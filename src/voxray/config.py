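"""Render-job configuration: YAML/JSON loading and validation.

A config document looks like::

    camera:
      position: [0.5, 0.5, 3.0]
      target: [0.5, 0.5, 0.5]
      up: [0, 1, 0]
      vfov: 30
      width: 128
      height: 128
    volumes:
      - file: head.nii
        transfer_function: tf.json
        volume_shader: blinn_phong        # registry name, default "default"
        params: {k_ambient: 0.3}
    init_shader: carving                  # optional
    init_params: {sphere_radius: 0.2}
    step: 0.01                            # optional
    ert_threshold: 0.99                   # optional
    background: [0, 0, 0, 1]
    time: 0.0
    interaction_point: [0.5, 0.5, 0.5]
    depth_image: depth.npy                # optional
    output: out.png
    frames: {count: 10, t_start: 0.0, t_end: 1.2566}   # animate only

Validation runs before any compute and reports every offending key.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .effects import REGISTRY, make_effect
from .io import read_depth_image, read_volume
from .rays import Camera, RenderSettings, Scene, VolumeNode
from .volume import TransferFunction

__all__ = ["ConfigError", "RenderJob", "load_job"]


class ConfigError(ValueError):
    """A render configuration failed validation."""


@dataclass
class RenderJob:
    """A validated, fully-loaded rendering task."""

    scene: Scene
    camera: Camera
    settings: RenderSettings
    output: str
    depth_image: np.ndarray | None = None
    frames: dict | None = None
    errors: list[str] = field(default_factory=list)


def _load_doc(path: Path) -> dict:
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        doc = yaml.safe_load(text)
    elif path.suffix == ".json":
        doc = json.loads(text)
    else:
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as e:
            raise ConfigError(f"{path}: cannot parse config: {e}") from e
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config root must be a mapping")
    return doc


def load_job(path, *, output: str | None = None) -> RenderJob:
    """Load and validate a render config; raises :class:`ConfigError`
    listing every problem found."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"{path}: no such file")
    doc = _load_doc(path)
    base = path.parent
    errors: list[str] = []

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    camera = None
    cam_doc = doc.get("camera")
    if not isinstance(cam_doc, dict):
        errors.append("camera: missing or not a mapping")
    else:
        try:
            camera = Camera(**cam_doc)
        except (TypeError, ValueError) as e:
            errors.append(f"camera: {e}")

    nodes: list[VolumeNode] = []
    vols_doc = doc.get("volumes")
    if not isinstance(vols_doc, list) or not vols_doc:
        errors.append("volumes: need a non-empty list")
        vols_doc = []
    for i, v in enumerate(vols_doc):
        key = f"volumes[{i}]"
        if not isinstance(v, dict) or "file" not in v:
            errors.append(f"{key}: needs a mapping with a 'file' entry")
            continue
        try:
            volume = read_volume(resolve(v["file"]))
        except Exception as e:  # noqa: BLE001 - collected for the report
            errors.append(f"{key}.file: {e}")
            continue
        tf_path = v.get("transfer_function")
        if tf_path is None:
            tf = TransferFunction.grayscale_ramp()
        else:
            try:
                tf = TransferFunction.from_json_file(resolve(tf_path))
            except Exception as e:  # noqa: BLE001
                errors.append(f"{key}.transfer_function: {e}")
                continue
        shader = v.get("volume_shader", "default")
        if shader not in REGISTRY:
            errors.append(f"{key}.volume_shader: unknown effect '{shader}'")
            continue
        try:
            effect = make_effect(shader, v.get("params"))
        except ValueError as e:
            errors.append(f"{key}.params: {e}")
            continue
        nodes.append(VolumeNode(volume=volume, tf=tf, effect=effect,
                                name=str(v.get("name", f"volume{i}"))))

    init_effect = None
    init_name = doc.get("init_shader")
    if init_name is not None:
        try:
            init_effect = make_effect(init_name, doc.get("init_params"))
        except ValueError as e:
            errors.append(f"init_shader: {e}")

    stop_effect = None
    stop_name = doc.get("stop_condition")
    if stop_name is not None:
        try:
            stop_effect = make_effect(stop_name, doc.get("stop_params"))
        except ValueError as e:
            errors.append(f"stop_condition: {e}")

    settings = None
    try:
        settings = RenderSettings(
            step=doc.get("step"),
            ert_threshold=doc.get("ert_threshold"),
            background=doc.get("background", (0, 0, 0, 1)),
            time=float(doc.get("time", 0.0)),
            interaction_point=doc.get("interaction_point", (0.5, 0.5, 0.5)),
        )
    except (TypeError, ValueError) as e:
        errors.append(f"settings: {e}")

    depth = None
    if doc.get("depth_image"):
        try:
            depth = read_depth_image(resolve(doc["depth_image"]))
            if camera is not None and depth.shape != (camera.height, camera.width):
                errors.append(
                    f"depth_image: shape {depth.shape} does not match the "
                    f"camera's ({camera.height}, {camera.width})"
                )
        except Exception as e:  # noqa: BLE001
            errors.append(f"depth_image: {e}")

    frames = doc.get("frames")
    if frames is not None:
        if not isinstance(frames, dict) or "count" not in frames \
                or int(frames.get("count", 0)) < 1:
            errors.append("frames: needs a mapping with a positive 'count'")
            frames = None

    scene = None
    if nodes and not errors:
        try:
            scene = Scene(nodes=nodes, init=init_effect, stop=stop_effect)
        except ValueError as e:
            errors.append(f"volumes: {e}")

    if errors:
        raise ConfigError(
            f"{path}: invalid render configuration:\n  - "
            + "\n  - ".join(errors)
        )
    assert scene is not None and camera is not None and settings is not None
    return RenderJob(scene=scene, camera=camera, settings=settings,
                     output=output or str(doc.get("output", "render.png")),
                     depth_image=depth, frames=frames)
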