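"""File formats and run configuration.

Formats used across the pipeline:

* images: TIFF, 16-bit (single frame or stack);
* localization tables: CSV with headers ``"x [nm]"``, ``"y [nm]"``,
  ``"uncertainty [nm]"`` (tolerant header matching, e.g. ``x[nm]``);
* chains: CSV with columns ``chain_id, vertex_index, x_um, y_um``;
* tracks: CSV with columns ``t_s, x_um, y_um, track_id`` — for pure
  transverse tracks ``x_um`` holds the (zero) longitudinal and ``y_um``
  the signed transverse coordinate;
* fits and reports: JSON.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .chains import FiberChain
from .dynamics import TransverseTrack

__all__ = [
    "PipelineConfig",
    "read_localizations",
    "write_localizations",
    "read_image_stack",
    "write_image",
    "read_chains",
    "write_chains",
    "read_transverse_tracks",
    "write_transverse_tracks",
    "write_json",
]

#: sentinel used when a localization table has no uncertainty column
UNCERTAINTY_SENTINEL = np.nan


@dataclass
class PipelineConfig:
    """Run configuration; unknown keys in config files are rejected."""

    pixel_size_um: float = 0.1
    psf_sigma_nm: float = 20.0
    temperature_K: float = 298.0
    viscosity_Pa_s: float = 1.0e-3
    alpha_stretch: float = 0.0
    beta_bend: float = 20.0
    image_weight: float = 2.0
    segment_length_um: float = 0.1
    regime_break_s: float = 2.0
    short_cutoff_s: float = 5.0
    seed: int = 0
    input_path: str = ""
    output_dir: str = "."

    def __post_init__(self) -> None:
        for name in (
            "pixel_size_um",
            "psf_sigma_nm",
            "temperature_K",
            "viscosity_Pa_s",
            "segment_length_um",
            "regime_break_s",
            "short_cutoff_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(path.read_text()) or {}
        elif path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(path.read_text())
        else:
            raise ValueError(f"unsupported config format: {path.suffix}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# localization tables

_LOC_PATTERNS = {
    "x [nm]": re.compile(r"^x\s*\[?nm\]?$"),
    "y [nm]": re.compile(r"^y\s*\[?nm\]?$"),
    "uncertainty [nm]": re.compile(r"^(uncertainty|uncertainty_xy)\s*\[?nm\]?$"),
}


def read_localizations(path: str | Path) -> pd.DataFrame:
    """Read a localization CSV into canonical nm columns.

    Headers are matched tolerantly (``x [nm]``, ``x[nm]``, ...); a missing
    uncertainty column is filled with NaN and flagged via
    ``df.attrs["uncertainty_missing"]``.  Missing coordinate columns and
    non-numeric cells raise with the offending name or row index.
    """
    df = pd.read_csv(path)
    rename: dict[str, str] = {}
    for col in df.columns:
        for canon, pat in _LOC_PATTERNS.items():
            if pat.match(col.strip().lower()):
                rename[col] = canon
    df = df.rename(columns=rename)
    missing = [c for c in ("x [nm]", "y [nm]") if c not in df.columns]
    if missing:
        raise ValueError(f"localization file {path} is missing columns: {missing}")
    out = pd.DataFrame()
    for c in ("x [nm]", "y [nm]"):
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.index[vals.isna() & df[c].notna()]
        if len(bad):
            raise ValueError(f"non-numeric value in column {c!r} at row {int(bad[0])}")
        if vals.isna().any():
            raise ValueError(
                f"empty cell in column {c!r} at row {int(vals.index[vals.isna()][0])}"
            )
        out[c] = vals
    if "uncertainty [nm]" in df.columns:
        out["uncertainty [nm]"] = pd.to_numeric(df["uncertainty [nm]"], errors="coerce")
        out.attrs["uncertainty_missing"] = False
    else:
        out["uncertainty [nm]"] = UNCERTAINTY_SENTINEL
        out.attrs["uncertainty_missing"] = True
    return out


def write_localizations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# images


def read_image_stack(
    path: str | Path, pixel_size_um: float | None = None
) -> tuple[np.ndarray, dict]:
    """Read a TIFF into an (n_frames, h, w) array, dtype preserved.

    Returns ``(stack, meta)``; ``meta["pixel_size_um"]`` comes from the
    argument when given (overriding any file metadata, with a notice in
    ``meta["notes"]``).
    """
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    elif data.ndim != 3:
        raise ValueError(f"expected a 2D image or 3D stack, got shape {data.shape}")
    meta: dict = {"shape": data.shape, "dtype": str(data.dtype), "notes": []}
    file_px = None
    try:
        with tifffile.TiffFile(str(path)) as tf:
            res = tf.pages[0].tags.get("XResolution")
            if res is not None and res.value[0] > 0:
                file_px = res.value[1] / res.value[0]
    except Exception:
        pass
    if pixel_size_um is not None:
        if file_px is not None and not np.isclose(file_px, pixel_size_um):
            meta["notes"].append(
                f"pixel size {pixel_size_um} um/px from config overrides "
                f"file metadata ({file_px} um/px)"
            )
        meta["pixel_size_um"] = pixel_size_um
    else:
        meta["pixel_size_um"] = file_px
    return data, meta


def write_image(image: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), np.asarray(image))


# ---------------------------------------------------------------------------
# chains and tracks


def write_chains(chains: list[FiberChain], path: str | Path) -> None:
    rows = []
    for i, ch in enumerate(chains):
        cid = ch.chain_id or f"chain-{i}"
        for j, (x, y) in enumerate(ch.vertices[:, :2]):
            rows.append((cid, j, x, y))
    pd.DataFrame(rows, columns=["chain_id", "vertex_index", "x_um", "y_um"]).to_csv(
        path, index=False
    )


def read_chains(path: str | Path, segment_length_um: float | None = None) -> list[FiberChain]:
    df = pd.read_csv(path)
    need = {"chain_id", "vertex_index", "x_um", "y_um"}
    if not need.issubset(df.columns):
        raise ValueError(f"chain file missing columns: {sorted(need - set(df.columns))}")
    chains = []
    for cid, grp in df.groupby("chain_id", sort=False):
        grp = grp.sort_values("vertex_index")
        verts = grp[["x_um", "y_um"]].to_numpy(dtype=float)
        seg = segment_length_um
        if seg is None:
            seg = float(np.median(np.linalg.norm(np.diff(verts, axis=0), axis=1)))
        chains.append(FiberChain(vertices=verts, segment_length=seg, chain_id=str(cid)))
    return chains


def write_transverse_tracks(tracks: list[TransverseTrack], path: str | Path) -> None:
    rows = []
    for i, tr in enumerate(tracks):
        tid = tr.track_id or f"track-{i}"
        for t, h in zip(tr.times, tr.displacement):
            rows.append((t, 0.0, h, tid))
    pd.DataFrame(rows, columns=["t_s", "x_um", "y_um", "track_id"]).to_csv(
        path, index=False
    )


def read_transverse_tracks(path: str | Path) -> list[TransverseTrack]:
    df = pd.read_csv(path)
    need = {"t_s", "x_um", "y_um", "track_id"}
    if not need.issubset(df.columns):
        raise ValueError(f"track file missing columns: {sorted(need - set(df.columns))}")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=False):
        grp = grp.sort_values("t_s")
        tracks.append(
            TransverseTrack(
                times=grp["t_s"].to_numpy(dtype=float),
                displacement=grp["y_um"].to_numpy(dtype=float),
                track_id=str(tid),
            )
        )
    return tracks


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
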