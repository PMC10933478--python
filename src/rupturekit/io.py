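"""File formats: OME-TIFF stacks, tidy CSV tables, GMT gene sets, manifests.

Tables are tidy (one row per cell / gap / condition) and carry a schema tag in
a leading comment line so readers can detect version drift. Every pipeline
stage writes a JSON run manifest recording the package version, a hash of the
effective configuration, the seed, and row counts, which makes any output
traceable to config + seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "write_stack",
    "read_stack",
    "get_channel",
    "write_table",
    "read_table",
    "read_plate_map",
    "read_gmt",
    "config_hash",
    "make_manifest",
    "write_manifest",
    "read_manifest",
]

TABLE_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# images

def write_stack(path, array: np.ndarray, channel_names: list[str],
                spacing=None) -> None:
    """Write a multi-channel stack as OME-TIFF.

    ``array`` is (C, Y, X) or (C, Z, Y, X); ``spacing`` is the physical voxel
    size, (dy, dx) or (dz, dy, dx) in µm, stored in the OME metadata.
    """
    array = np.asarray(array)
    if array.ndim not in (3, 4):
        raise ValueError("expected a (C, Y, X) or (C, Z, Y, X) array")
    if array.shape[0] != len(channel_names):
        raise ValueError("number of channel names must match axis 0")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    axes = "CYX" if array.ndim == 3 else "CZYX"
    meta = {"axes": axes, "Channel": {"Name": list(channel_names)}}
    if spacing is not None:
        sp = [float(s) for s in np.atleast_1d(spacing)]
        meta["PhysicalSizeX"], meta["PhysicalSizeY"] = sp[-1], sp[-2]
        if len(sp) == 3:
            meta["PhysicalSizeZ"] = sp[0]
        for k in ("X", "Y", "Z"):
            if f"PhysicalSize{k}" in meta:
                meta[f"PhysicalSize{k}Unit"] = "µm"
    tifffile.imwrite(path, array, ome=True, metadata=meta,
                     photometric="minisblack")


def read_stack(path) -> tuple[np.ndarray, list[str]]:
    """Read an OME-TIFF stack; returns (array, channel names)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        array = tif.asarray()
        names: list[str] = []
        if tif.ome_metadata:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tif.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            names = [c.get("Name") or "" for c in
                     root.findall(".//ome:Channel", ns)]
    return array, names


def get_channel(path, name: str) -> np.ndarray:
    """One named channel of a stack; errors name the file and the channel."""
    array, names = read_stack(path)
    if name not in names:
        raise KeyError(
            f"channel {name!r} not found in {path} (available: {names})")
    return array[names.index(name)]


# ---------------------------------------------------------------------------
# tables

def write_table(df: pd.DataFrame, path, schema: str) -> None:
    """Write a tidy CSV with a schema tag comment in the first line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# rupturekit table schema={schema} v{TABLE_SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)


def read_table(path, schema: str | None = None) -> pd.DataFrame:
    """Read a tidy CSV written by :func:`write_table`; checks the schema tag."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    with open(path) as fh:
        first = fh.readline()
        if schema is not None and f"schema={schema} " not in first:
            raise ValueError(
                f"{path}: expected schema {schema!r}, header was {first.strip()!r}")
        return pd.read_csv(fh)


def read_plate_map(path, image_root=None) -> pd.DataFrame:
    """Plate map CSV: well_id, condition, replicate, image (relative path).

    When ``image_root`` is given, every referenced image must exist; a missing
    file raises with its full path.
    """
    pm = pd.read_csv(path, comment="#")
    required = {"well_id", "condition", "replicate"}
    missing = required - set(pm.columns)
    if missing:
        raise ValueError(f"plate map {path}: missing columns {sorted(missing)}")
    if image_root is not None and "image" in pm.columns:
        root = Path(image_root)
        for rel in pm["image"]:
            full = root / rel
            if not full.exists():
                raise FileNotFoundError(f"plate map references absent image: {full}")
    return pm


# ---------------------------------------------------------------------------
# gene sets

def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """Parse a GMT file into {term: (description, genes)}.

    Duplicate terms are resolved last-wins, with a warning naming the term.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT lines need term, description, >=1 gene")
            term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if term in sets:
                warnings.warn(f"GMT term {term!r} duplicated; keeping the later "
                              f"definition (line {lineno})", stacklevel=2)
            sets[term] = (desc, genes)
    return sets


# ---------------------------------------------------------------------------
# manifests

def config_hash(config: dict) -> str:
    """SHA-256 of the canonical JSON encoding of a configuration dict."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def make_manifest(stage: str, config: dict, seed: int,
                  counts: dict[str, int]) -> dict:
    """Run manifest: version, config hash, seed, and output row counts."""
    from . import __version__

    return {
        "schema_version": TABLE_SCHEMA_VERSION,
        "stage": stage,
        "version": __version__,
        "config_hash": config_hash(config),
        "seed": int(seed),
        "counts": {k: int(v) for k, v in counts.items()},
    }


def write_manifest(path, manifest: dict) -> None:
    """Write a manifest with a creation timestamp added."""
    out = dict(manifest)
    out["created"] = datetime.now(timezone.utc).isoformat()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(out, indent=2, sort_keys=True) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
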