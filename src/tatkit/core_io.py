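"""Shared domain types, table/image I/O and study configuration.

All tables are comma-separated UTF-8 CSV with a mandatory header row and
dot decimals.  Times are stored in days post injection throughout the
package; activities are held in Bq internally and converted at I/O
boundaries.  Images are processed as floating-point gray values; the bit
depth is retained only so that inversion (``max_gray - pixel``) is
well defined.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image as PILImage
import tifffile


class SchemaError(ValueError):
    """A table does not match its declared schema."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _default_nuclide_path() -> Path:
    return Path(str(importlib.resources.files("tatkit") / "data" / "nuclides.yaml"))


@dataclass
class StudyConfig:
    """Thresholds and constants shared across pipeline stages.

    Parameters
    ----------
    seed:
        Master seed; every source of randomness in a pipeline run flows
        from it.
    block_size:
        Side length, in pixels, of the square tiles used for the
        block-parametric spatial correlation.
    sixfold_threshold:
        Relative tumor volume (vs. the day-1 volume) defining the
        growth-delay endpoint; 6.0 means "time to six-fold volume".
    r2_min:
        Minimum R^2 for a growth fit to be included in the analysis.
    hep_volume:
        Humane-endpoint tumor volume in cm^3; crossing it is the
        survival event.
    alpha:
        Significance level for all hypothesis tests.
    nuclide_table_path:
        YAML file with half-lives, decay-chain topology and absorbed
        energies.  Defaults to the table shipped with the package.
    density:
        Tissue density in g/mL used to convert %IA/mL to %IA/g and in
        the absorbed-dose calculation.
    """

    seed: int = 0
    block_size: int = 20
    sixfold_threshold: float = 6.0
    r2_min: float = 0.5
    hep_volume: float = 2.0
    alpha: float = 0.05
    nuclide_table_path: Path = field(default_factory=_default_nuclide_path)
    density: float = 1.0

    def __post_init__(self) -> None:
        if self.block_size < 2:
            raise ValueError("block_size must be >= 2")
        if self.sixfold_threshold <= 1:
            raise ValueError("sixfold_threshold must be > 1")
        if not 0 < self.r2_min < 1:
            raise ValueError("r2_min must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.hep_volume <= 0:
            raise ValueError("hep_volume must be positive")
        self.nuclide_table_path = Path(self.nuclide_table_path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

#: Column -> (dtype, non_negative) per schema.  Count and mass columns must
#: be non-negative; unconstrained numeric columns use ``False``.
TABLE_SCHEMAS: Mapping[str, Mapping[str, tuple[str, bool]]] = {
    "lindmo": {
        "cell_conc": ("float", True),
        "bound_cpm": ("float", True),
        "total_cpm": ("float", True),
        "background_cpm": ("float", True),
    },
    "competition": {
        "conc_nM": ("float", True),
        "bound_cpm": ("float", True),
    },
    "fractions": {
        "condition": ("str", False),
        "membrane_cpm": ("float", True),
        "internalized_cpm": ("float", True),
    },
    "biodist": {
        "animal": ("str", False),
        "group": ("str", False),
        "organ": ("str", False),
        "mass_g": ("float", True),
        "cpm": ("float", True),
        "dt_days": ("float", False),
    },
    "tac": {
        "voi": ("str", False),
        "day": ("float", True),
        "pct_ia_per_ml": ("float", True),
    },
    "growth": {
        "mouse": ("str", False),
        "group": ("str", False),
        "day": ("float", True),
        "volume_mm3": ("float", True),
    },
    "survival": {
        "mouse": ("str", False),
        "group": ("str", False),
        "time_days": ("float", True),
        "event": ("int", False),
    },
    "cd45_snapshots": {
        "mouse": ("str", False),
        "group": ("str", False),
        "snapshot": ("str", False),
        "positive_fraction_pct": ("float", True),
    },
}


@dataclass
class AssayTable:
    """A typed, unit-checked tabular input with provenance."""

    data: pd.DataFrame
    schema: str
    provenance: str = "<memory>"

    def __len__(self) -> int:
        return len(self.data)


def _validate_frame(df: pd.DataFrame, schema: str, provenance: str) -> pd.DataFrame:
    if schema not in TABLE_SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}")
    spec = TABLE_SCHEMAS[schema]
    missing = [c for c in spec if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{provenance}: schema {schema!r} is missing column(s) {missing}"
        )
    out = df.copy()
    for col, (dtype, non_negative) in spec.items():
        if dtype in ("float", "int"):
            try:
                out[col] = pd.to_numeric(out[col], errors="raise")
            except (ValueError, TypeError) as exc:
                bad = pd.to_numeric(df[col], errors="coerce")
                row = int(bad.index[bad.isna()][0]) if bad.isna().any() else -1
                raise SchemaError(
                    f"{provenance}: column {col!r} row {row}: "
                    f"unparseable number"
                ) from exc
            if dtype == "int":
                out[col] = out[col].astype(int)
            if non_negative and (out[col] < 0).any():
                row = int(out.index[out[col] < 0][0])
                raise SchemaError(
                    f"{provenance}: column {col!r} row {row}: negative value "
                    "not allowed"
                )
        else:
            out[col] = out[col].astype(str)
    return out[list(spec)]


def make_table(df: pd.DataFrame, schema: str, provenance: str = "<memory>") -> AssayTable:
    """Validate an in-memory DataFrame against a named schema."""
    return AssayTable(_validate_frame(df, schema, provenance), schema, provenance)


def read_table(path: str | Path, schema: str) -> AssayTable:
    """Read and validate a CSV table against a named schema."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    return AssayTable(_validate_frame(df, schema, str(path)), schema, str(path))


def write_table(table: AssayTable, path: str | Path) -> None:
    """Write an :class:`AssayTable` back to CSV (round-trips with read_table)."""
    table.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

@dataclass
class GrayImage:
    """A single-channel image held as floating-point gray values."""

    pixels: np.ndarray
    bit_depth: int = 16
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("GrayImage requires a 2-D pixel grid")
        if np.any(self.pixels < 0):
            raise ValueError("gray values must be non-negative")

    @property
    def max_gray(self) -> float:
        return float(2 ** self.bit_depth - 1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def inverted(self) -> "GrayImage":
        """Photographic inversion: ``max_gray - pixel``."""
        return GrayImage(self.max_gray - self.pixels, self.bit_depth,
                         self.pixel_size_um)


def read_image(path: str | Path, to_gray: bool = False) -> GrayImage:
    """Read a single-channel TIFF or PNG as a :class:`GrayImage`.

    Multi-channel images are rejected unless ``to_gray`` is set, in which
    case channels are averaged.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
        sample_depth = 16 if arr.dtype.kind == "f" else arr.dtype.itemsize * 8
    else:
        with PILImage.open(path) as img:
            arr = np.asarray(img)
        sample_depth = 16 if arr.dtype == np.uint16 else 8
    if arr.ndim == 3:
        if not to_gray:
            raise ValueError(
                f"{path}: multi-channel image; pass to_gray=True to average"
            )
        arr = arr.mean(axis=2)
    return GrayImage(arr.astype(float), bit_depth=sample_depth)


def write_image(image: GrayImage, path: str | Path) -> None:
    """Write a :class:`GrayImage` to TIFF (float32) or PNG (integer)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), image.pixels.astype(np.float32))
    else:
        depth = np.uint16 if image.bit_depth > 8 else np.uint8
        arr = np.clip(np.rint(image.pixels), 0, image.max_gray).astype(depth)
        PILImage.fromarray(arr).save(path)


__all__ = [
    "AssayTable",
    "GrayImage",
    "SchemaError",
    "StudyConfig",
    "TABLE_SCHEMAS",
    "make_table",
    "read_image",
    "read_table",
    "write_image",
    "write_table",
]
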