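"""Readers and writers shared by all components.

Formats: PNG for images and masks (masks stored 0/255, held 0/1 in memory),
JSON for clicks, manifests and reports, YAML for run configuration, a
compressed npz archive for guidance maps, and a single-file npz checkpoint
with the network configuration embedded alongside the weights.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .network import InteractiveSegModel, NetworkConfig, build_model
from .synthetic import InstanceSample

__all__ = [
    "load_sample",
    "save_sample",
    "load_manifest_samples",
    "save_guidance_maps",
    "load_guidance_maps",
    "save_checkpoint",
    "load_checkpoint",
    "load_run_config",
    "write_resolved_config",
]


def load_sample(image_path: str | Path, mask_path: str | Path) -> InstanceSample:
    """Decode an image/mask pair; masks are thresholded at 128 to binary."""
    try:
        image = np.asarray(Image.open(image_path).convert("RGB"))
    except Exception as exc:
        raise IOError(f"unreadable image {image_path}: {exc}") from exc
    try:
        mask_raw = np.asarray(Image.open(mask_path).convert("L"))
    except Exception as exc:
        raise IOError(f"unreadable mask {mask_path}: {exc}") from exc
    if image.shape[:2] != mask_raw.shape:
        raise ValueError(
            f"image {image.shape[:2]} and mask {mask_raw.shape} have different sizes "
            f"({image_path} vs {mask_path})"
        )
    mask = (mask_raw >= 128).astype(np.uint8)
    return InstanceSample(image=image, mask=mask, meta={"image_path": str(image_path)})


def save_sample(sample: InstanceSample, image_path: str | Path, mask_path: str | Path) -> None:
    Image.fromarray(sample.image).save(image_path)
    Image.fromarray((sample.mask * 255).astype(np.uint8)).save(mask_path)


def load_manifest_samples(
    data_dir: str | Path, split: str | None = None
) -> list[InstanceSample]:
    """Load all samples listed in a dataset manifest (optionally one split)."""
    data_dir = Path(data_dir)
    with open(data_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    out = []
    for entry in manifest["samples"]:
        if split is not None and entry["split"] != split:
            continue
        s = load_sample(data_dir / entry["image"], data_dir / entry["mask"])
        s.meta.update(entry.get("meta", {}))
        s.meta["id"] = entry["id"]
        out.append(s)
    return out


def save_guidance_maps(d_pos: np.ndarray, d_neg: np.ndarray, path: str | Path) -> None:
    np.savez_compressed(path, d_pos=d_pos, d_neg=d_neg)


def load_guidance_maps(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    with np.load(path) as data:
        return data["d_pos"], data["d_neg"]


def save_checkpoint(model: InteractiveSegModel, path: str | Path, extra: dict | None = None) -> None:
    """Single-file checkpoint: weights, buffers and the embedded config."""
    payload = {
        "network_config": dataclasses.asdict(model.config),
        "extra": extra or {},
    }
    state = {f"state::{k}": v for k, v in model.state_dict().items()}
    np.savez_compressed(path, __meta__=np.frombuffer(json.dumps(payload).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | Path) -> tuple[InteractiveSegModel, dict]:
    """Rebuild the model described by a checkpoint and restore its weights."""
    with np.load(path) as data:
        payload = json.loads(bytes(data["__meta__"]).decode())
        state = {
            k[len("state::") :]: data[k] for k in data.files if k.startswith("state::")
        }
    cfg_dict = payload["network_config"]
    for key in ("skip_channels_raw", "skip_channels_reduced", "aspp_dilations"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = NetworkConfig(**cfg_dict)
    model = build_model(config, seed=0)
    model.load_state_dict(state)
    return model, payload.get("extra", {})


def load_run_config(path: str | Path) -> dict:
    """Parse a YAML run configuration; errors carry the offending line."""
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        loc = f" (line {mark.line + 1})" if mark is not None else ""
        raise ValueError(f"invalid YAML in {path}{loc}: {exc}") from exc
    return cfg or {}


def write_resolved_config(config: dict, out_dir: str | Path, name: str = "resolved_config.yaml") -> None:
    """Write the fully resolved configuration next to a run's outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / name, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
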