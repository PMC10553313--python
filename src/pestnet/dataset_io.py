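"""Disk round-trip for synthetic datasets and run artifacts.

Images are written as PNG; the dataset manifest is a CSV with columns
path,label,split,box_cx,box_cy,box_half (box columns empty when no truth
box is present); generator parameters are echoed to a YAML sidecar so a
run can be regenerated exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .attention import AttentionBox
from .synthetic import LabeledImage, SceneSpec

__all__ = ["save_dataset", "load_dataset", "save_checkpoint", "load_checkpoint"]

MANIFEST_COLUMNS = ["path", "label", "split", "box_cx", "box_cy", "box_half"]


def save_dataset(samples: list[LabeledImage], outdir: str | Path,
                 spec: SceneSpec | None = None) -> Path:
    """Write PNGs + manifest.csv (+ scene.yaml sidecar); returns outdir."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, im in enumerate(samples):
        rel = f"images/{i:06d}_c{im.label}.png"
        arr = np.clip(np.round(im.pixels * 255), 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(outdir / rel)
        b = im.truth_box
        rows.append({"path": rel, "label": im.label, "split": im.split_tag,
                     "box_cx": "" if b is None else b.tx,
                     "box_cy": "" if b is None else b.ty,
                     "box_half": "" if b is None else b.tl})
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(
        outdir / "manifest.csv", index=False)
    if spec is not None:
        with open(outdir / "scene.yaml", "w") as fh:
            yaml.safe_dump(dataclasses.asdict(spec), fh)
    return outdir


def load_dataset(outdir: str | Path) -> list[LabeledImage]:
    """Read a dataset written by :func:`save_dataset` (pixel values are
    quantized to 8 bits by the PNG round trip)."""
    outdir = Path(outdir)
    df = pd.read_csv(outdir / "manifest.csv", keep_default_na=False)
    samples = []
    for i, row in df.iterrows():
        arr = np.asarray(Image.open(outdir / row["path"]), dtype=np.float32) / 255.0
        box = None
        if row["box_cx"] != "":
            box = AttentionBox(float(row["box_cx"]), float(row["box_cy"]),
                               float(row["box_half"]))
        samples.append(LabeledImage(pixels=arr, label=int(row["label"]),
                                    truth_box=box, split_tag=row["split"],
                                    uid=int(i)))
    return samples


CHECKPOINT_FORMAT = 1


def save_checkpoint(path: str | Path, state: dict[str, np.ndarray],
                    config: dict) -> None:
    """Versioned checkpoint: npz weights next to a JSON config echo."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **state)
    meta = {"format_version": CHECKPOINT_FORMAT, "config": config}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as z:
        state = {k: z[k] for k in z.files}
    meta = json.loads(path.with_suffix(".json").read_text())
    if meta.get("format_version") != CHECKPOINT_FORMAT:
        raise ValueError(f"unsupported checkpoint format: {meta.get('format_version')}")
    return state, meta["config"]
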