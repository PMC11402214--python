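"""Reading and writing of the pipeline's on-disk artifacts.

Images travel as TIFF: multi-channel fields as one 8-bit page per channel
with the channel order recorded in the image description, probability maps
as single 8-bit pages, label images as 16-bit pages, masks as 8-bit 0/255.
Tabular and structured outputs are CSV (cell tables, grid-search rankings)
and JSON (ground truth, annotations, summaries, manifests).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imops import to_8bit
from .synthgen import CHANNELS, AnnotationFixture, SynthTruth


def write_multichannel_tiff(path, image: dict, channels=CHANNELS) -> None:
    """Write one 8-bit page per channel; order recorded in the description."""
    stack = np.stack([to_8bit(image[ch]) for ch in channels])
    tifffile.imwrite(path, stack, photometric="minisblack",
                     description=json.dumps({"channels": list(channels)}))


def read_multichannel_tiff(path, channel_order=CHANNELS) -> dict:
    """Read a multi-channel field back to float planes on [0, 1].

    Channel names come from the description metadata when present, else
    from ``channel_order``.
    """
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        desc = tf.pages[0].description
    names = list(channel_order)
    if desc:
        try:
            meta = json.loads(desc)
            names = list(meta.get("channels", names))
        except (json.JSONDecodeError, AttributeError):
            pass
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] != len(names):
        raise ValueError(f"{path}: {stack.shape[0]} pages but {len(names)} channel names")
    return {name: stack[i].astype(np.float64) / 255.0 for i, name in enumerate(names)}


def write_plane_tiff(path, plane: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(plane))


def write_probability_map(path, prob_map: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(prob_map, dtype=np.uint8))


def read_probability_map(path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: probability map must be 8-bit")
    return arr


def write_labels(path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for 16-bit storage")
    tifffile.imwrite(path, labels.astype(np.uint16))


def read_labels(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def write_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path) > 0


def write_truth(path_json, path_labels, truth: SynthTruth) -> None:
    """Ground truth as JSON (centroids, types, levels, group) + label TIFF."""
    payload = {
        "group": truth.group,
        "donor_id": truth.donor_id,
        "nucleus_centroids": truth.nucleus_centroids.tolist(),
        "nucleus_radii": truth.nucleus_radii.tolist(),
        "cell_types": {str(k): v for k, v in truth.cell_types.items()},
        "true_cell_levels": {str(k): v for k, v in truth.true_cell_levels.items()},
    }
    Path(path_json).write_text(json.dumps(payload, indent=1, sort_keys=True))
    write_labels(path_labels, truth.cell_labels)


def write_annotation(path_json, path_mask, fixture: AnnotationFixture) -> None:
    Path(path_json).write_text(
        json.dumps({"manual_centroids": fixture.manual_centroids.tolist()}, indent=1)
    )
    write_mask(path_mask, fixture.manual_islet_mask)


def read_annotation(path_json, path_mask) -> AnnotationFixture:
    payload = json.loads(Path(path_json).read_text())
    return AnnotationFixture(
        manual_islet_mask=read_mask(path_mask),
        manual_centroids=np.asarray(payload["manual_centroids"], dtype=float).reshape(-1, 2),
    )


def write_cell_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_cell_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
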