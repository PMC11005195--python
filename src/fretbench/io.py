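"""Readers and writers: OME-TIFF lambda stacks, ROI files, configs, CSV.

Lambda stacks travel as OME-TIFF with the band edges, excitation line and
stage tag serialized as JSON in the OME image description. Third-party
OME-TIFFs lacking that annotation load via a JSON sidecar
(``<path>.bands.json`` with keys ``band_edges`` and optionally
``excitation_nm``).
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .spectral import LambdaStack


class FormatError(ValueError):
    """Raised when a file cannot be parsed into the expected structure."""


_META_KEY = "fretbench"


def write_lambda_stack(stack: LambdaStack, path: str | Path) -> Path:
    """Write a lambda stack as OME-TIFF with band metadata embedded."""
    path = Path(path)
    desc = json.dumps(
        {
            _META_KEY: {
                "band_edges": [float(e) for e in stack.band_edges],
                "excitation_nm": float(stack.excitation_nm),
                "meta": stack.meta,
            }
        }
    )
    # axes: (z, y, x, band) -> store band as channel axis
    data = np.moveaxis(stack.data, -1, 0).astype(np.float32)
    tifffile.imwrite(
        path, data, ome=True, metadata={"axes": "CZYX", "Description": desc}
    )
    return path


def read_lambda_stack(path: str | Path) -> LambdaStack:
    """Read a lambda stack written by :func:`write_lambda_stack` or a
    third-party OME-TIFF accompanied by a band-metadata sidecar."""
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            ome = tf.ome_metadata or ""
    except Exception as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    meta = _extract_band_metadata(ome)
    if meta is None:
        sidecar = path.with_suffix(path.suffix + ".bands.json")
        if not sidecar.exists():
            candidates = [path.with_name(path.name + ".bands.json")]
            sidecar = next((c for c in candidates if c.exists()), sidecar)
        if not sidecar.exists():
            raise FormatError(
                f"{path} carries no band metadata; provide a sidecar "
                f"{path.name}.bands.json with keys 'band_edges' (nm, length "
                "n_bands+1) and optionally 'excitation_nm'"
            )
        meta = json.loads(sidecar.read_text())
    edges = np.asarray(meta["band_edges"], dtype=float)
    if data.ndim == 3:  # (C, Y, X) -> single z-plane
        data = data[:, None]
    if data.ndim != 4:
        raise FormatError(f"{path}: expected 3-D or 4-D image data, got {data.ndim}-D")
    if data.shape[0] != edges.size - 1:
        raise FormatError(
            f"{path}: {data.shape[0]} channels but {edges.size - 1} bands in metadata"
        )
    return LambdaStack(
        data=np.moveaxis(data, 0, -1).astype(float),
        band_edges=edges,
        excitation_nm=float(meta.get("excitation_nm", 458.0)),
        meta=dict(meta.get("meta", {})),
    )


def _extract_band_metadata(ome_xml: str) -> dict | None:
    # the JSON blob survives XML-escaped inside <Description>
    m = re.search(r"<Description>(.*?)</Description>", ome_xml, re.DOTALL)
    if not m:
        return None
    text = (
        m.group(1)
        .replace("&quot;", '"')
        .replace("&amp;", "&")
        .replace("&lt;", "<")
        .replace("&gt;", ">")
    )
    try:
        payload = json.loads(text)
    except json.JSONDecodeError:
        return None
    return payload.get(_META_KEY)


def write_frame_pair(
    donor: np.ndarray, acceptor: np.ndarray, path: str | Path, meta: dict | None = None
) -> Path:
    """Write a 2-channel (donor, acceptor) frame pair as OME-TIFF."""
    path = Path(path)
    data = np.stack([donor, acceptor]).astype(np.float32)
    desc = json.dumps({_META_KEY: {"channels": ["donor", "acceptor"], "meta": meta or {}}})
    tifffile.imwrite(path, data, ome=True, metadata={"axes": "CYX", "Description": desc})
    return path


def read_rois_json(path: str | Path, shape: tuple[int, int]):
    """Load polygon ROIs from JSON: a list of {label, vertices: [[y, x], ...]}."""
    from .fretindex import ROI

    payload = json.loads(Path(path).read_text())
    if not isinstance(payload, list):
        raise FormatError("ROI JSON must be a list of {label, vertices} objects")
    return [ROI.from_polygon(item["label"], item["vertices"], shape) for item in payload]


def read_mask(path: str | Path) -> np.ndarray:
    """Binary mask from TIFF/PNG: nonzero pixels are foreground."""
    from imageio.v3 import imread

    arr = np.asarray(imread(Path(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def load_config(path: str | Path) -> dict:
    """YAML (or JSON; JSON is a YAML subset) config file to a dict."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise FormatError(f"config {path} must be a mapping")
    return data


def save_config(config: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config, sort_keys=True))
    return path


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
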