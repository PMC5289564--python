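"""Readers and writers for the blob feature table and scene artifacts.

The blob table is an RFC-4180 CSV with a '.' decimal separator and the
canonical header ``Blob_ID, Area, ..., Solidity, Class`` (the 20 numeric
descriptors between id and class; reading is order-insensitive).  Scene
artifacts are a PNG image plus a JSON ground-truth sidecar and a PNG
instance-label raster.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .balance import NEGATIVE_CLASS, POSITIVE_CLASS, TABLE_COLUMNS, TrainingTable
from .morphfeatures import FEATURE_COLUMNS

log = logging.getLogger(__name__)

_CLASS_ALIASES = {"tuna": POSITIVE_CLASS, "no-tuna": NEGATIVE_CLASS,
                  "no tuna": NEGATIVE_CLASS, "no_tuna": NEGATIVE_CLASS}


def read_blob_table(path, validate: bool = True,
                    strict: bool = False) -> TrainingTable:
    """Read an S1-schema blob table.

    The header is matched by name (order-insensitive, case-sensitive);
    a missing column or a non-numeric cell raises a ValueError naming it.
    With ``validate=True`` rows violating the descriptor consistency
    invariants are reported with 1-based data row numbers — as a warning
    by default, or a ValueError with ``strict=True``.  (SMOTE-balanced
    tables legitimately contain interpolated rows whose derived columns
    are no longer exactly consistent, so reading them must not fail.)
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column {missing[0]}")
    for col in FEATURE_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise ValueError(
                f"non-numeric value {df[col][bad].iloc[0]!r} in column "
                f"{col}, row {row}")
        df[col] = coerced
    df["Class"] = df["Class"].map(lambda c: _CLASS_ALIASES.get(str(c), c))
    unknown = ~df["Class"].isin([POSITIVE_CLASS, NEGATIVE_CLASS])
    if unknown.any():
        row = int(np.flatnonzero(unknown)[0]) + 1
        raise ValueError(
            f"unknown class {df['Class'][unknown].iloc[0]!r} in row {row}")
    if validate:
        problems = _invariant_violations(df)
        if problems:
            msg = "blob table invariant violations: " + \
                "; ".join(problems[:10])
            if strict:
                raise ValueError(msg)
            import warnings

            warnings.warn(msg)
    return TrainingTable(df)


def _invariant_violations(df: pd.DataFrame) -> list[str]:
    eps = 1e-6
    checks = [
        ("Area >= 1", df["Area"] >= 1),
        ("Major >= Minor", df["Major"] >= df["Minor"] - eps),
        ("AR = Major/Minor",
         (df["AR"] - df["Major"] / df["Minor"]).abs() <= 1e-3 * df["AR"] + eps),
        ("Roundness = 1/AR",
         (df["Roundness"] - 1.0 / df["AR"]).abs() <= 1e-3 + eps),
        ("MinFeret <= Feret", df["MinFeret"] <= df["Feret"] + eps),
        ("Width*Height >= Area",
         df["Width"] * df["Height"] >= df["Area"] - eps),
        ("Solidity <= 1", df["Solidity"] <= 1.0 + 1e-9),
        ("Solidity > 0", df["Solidity"] > 0),
    ]
    out = []
    for name, ok in checks:
        bad = np.flatnonzero(~ok.to_numpy())
        if len(bad):
            out.append(f"{name} violated at row(s) {[int(b) + 1 for b in bad[:5]]}")
    return out


def write_blob_table(table: TrainingTable, path) -> None:
    """Write the table as canonical-header CSV (header-only when empty)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.df[TABLE_COLUMNS].to_csv(path, index=False, lineterminator="\r\n")


# ---------------------------------------------------------------------------
# images and ground truth


def write_image(image: np.ndarray, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(image).save(path)


def read_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_ground_truth(gt, stem: Path) -> None:
    """Write ``<stem>.labels.png`` (uint16 instance raster) and
    ``<stem>.gt.json`` (per-blob truth)."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(gt.labels.astype(np.uint16)).save(
        stem.with_suffix(".labels.png"))
    payload = {
        "image_label": gt.image_label,
        "seed": gt.seed,
        "blobs": [
            {
                "blob_id": bid, "class": cls,
                "target_area": spec.target_area,
                "aspect_ratio": spec.aspect_ratio,
                "orientation_deg": spec.orientation_deg,
                "center": list(spec.center),
                "fill_color": list(spec.fill_color),
                "pixel_count": gt.pixel_count(i),
            }
            for i, (bid, cls, spec) in enumerate(gt.blobs)
        ],
    }
    stem.with_suffix(".gt.json").write_text(json.dumps(payload, indent=1))


def read_ground_truth_labels(stem: Path) -> np.ndarray:
    return np.asarray(Image.open(Path(stem).with_suffix(".labels.png")),
                      dtype=np.int32)


# ---------------------------------------------------------------------------
# layout config (key-value file, one sonar model per section)


def read_layout_config(path) -> dict:
    """Parse a key-value layout config.

    Format: ``key = value`` lines; keys ``center_x, center_y, radius,
    menu_x0, menu_y0, menu_x1, menu_y1`` and optionally
    ``overlay_palette`` as comma-separated hex colours.
    """
    from .preprocess import SonarLayout

    kv = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"bad layout line: {line!r}")
        k, v = (s.strip() for s in line.split("=", 1))
        kv[k] = v
    try:
        layout = SonarLayout(
            echogram_center=(int(kv["center_x"]), int(kv["center_y"])),
            echogram_radius=int(kv["radius"]),
            menu_panel_box=(int(kv["menu_x0"]), int(kv["menu_y0"]),
                            int(kv["menu_x1"]), int(kv["menu_y1"])),
        )
    except KeyError as e:  # pragma: no cover - config authoring error
        raise ValueError(f"layout config missing key {e}") from None
    palette = []
    if "overlay_palette" in kv:
        for tok in kv["overlay_palette"].split(","):
            tok = tok.strip().lstrip("#")
            palette.append(tuple(int(tok[i:i + 2], 16) for i in (0, 2, 4)))
    return {"layout": layout, "overlay_palette": palette}


def write_manifest(path, command: str, params: dict, seed=None) -> None:
    """Per-run JSON manifest: inputs, parameters, seed, software version."""
    from . import __version__

    payload = {"command": command, "params": params, "seed": seed,
               "version": __version__}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=1, default=str))
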