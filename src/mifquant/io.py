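"""Readers and writers for the pipeline's on-disk formats.

Images travel as multi-page TIFF (one page per channel, order recorded in a
YAML sidecar) or as one single-channel TIFF per marker; label masks as
unsigned-integer TIFF or PNG; cell tables as CSV with booleans encoded
0/1; configuration as YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .image import DEFAULT_CHANNELS, ImageValidationError, MultiplexImage, validate_label_mask


def read_multiplex(
    paths: str | Path | Sequence[str | Path],
    channel_names: Sequence[str] | None = None,
    *,
    round_id: int = 1,
) -> MultiplexImage:
    """Load a multiplexed stack from one multi-page TIFF or per-channel files.

    ``channel_names`` gives the channel order; for a single multi-page file
    it may be omitted when a ``<stem>.channels.yaml`` sidecar (written by
    :func:`write_multiplex`) is present.
    """
    if isinstance(paths, (str, Path)):
        path = Path(paths)
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ImageValidationError(f"{path}: expected 2D pages, got ndim={data.ndim}")
        if channel_names is None:
            sidecar = path.with_suffix(".channels.yaml")
            if not sidecar.exists():
                raise ImageValidationError(
                    f"{path}: no channel names given and no sidecar {sidecar.name}"
                )
            meta = yaml.safe_load(sidecar.read_text())
            channel_names = meta["channels"]
            round_id = meta.get("round_id", round_id)
        if len(channel_names) != data.shape[0]:
            raise ImageValidationError(
                f"{path}: {data.shape[0]} pages but {len(channel_names)} channel names"
            )
        channels = {name: data[i] for i, name in enumerate(channel_names)}
    else:
        files = [Path(p) for p in paths]
        if channel_names is None or len(channel_names) != len(files):
            raise ImageValidationError(
                f"need one channel name per file: {len(files)} files, "
                f"{0 if channel_names is None else len(channel_names)} names"
            )
        channels = {}
        for name, file in zip(channel_names, files):
            page = tifffile.imread(file)
            if page.ndim != 2:
                raise ImageValidationError(f"{file}: expected a single 2D channel")
            channels[name] = page
    return MultiplexImage(channels, round_id=round_id)


def write_multiplex(image: MultiplexImage, path: str | Path, *, sidecar: bool = True) -> Path:
    """Write a stack as float32 multi-page TIFF plus a channel-order sidecar."""
    path = Path(path)
    stack = np.stack([image[name] for name in image.names]).astype(np.float32)
    tifffile.imwrite(path, stack)
    if sidecar:
        meta = {"channels": list(image.names), "round_id": image.round_id}
        path.with_suffix(".channels.yaml").write_text(yaml.safe_dump(meta))
    return path


def read_labels(path: str | Path) -> np.ndarray:
    """Read an instance label mask (TIFF or PNG); rejects non-integer rasters."""
    path = Path(path)
    if path.suffix.lower() in (".png",):
        import imageio.v3 as iio

        arr = iio.imread(path)
    else:
        arr = tifffile.imread(path)
    return validate_label_mask(arr)


def write_labels(mask: np.ndarray, path: str | Path) -> Path:
    """Write a label mask as unsigned 32-bit TIFF (>65k instances headroom)."""
    mask = validate_label_mask(mask)
    path = Path(path)
    tifffile.imwrite(path, mask.astype(np.uint32))
    return path


def export_cell_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a per-cell table as CSV; boolean columns are encoded 0/1."""
    path = Path(path)
    out = table.copy()
    for col in out.columns:
        if out[col].dtype == bool:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False)
    return path


def read_cell_table(path: str | Path, bool_columns: Sequence[str] = ()) -> pd.DataFrame:
    """Read a cell table written by :func:`export_cell_table`."""
    table = pd.read_csv(path)
    for col in bool_columns:
        if col in table.columns:
            table[col] = table[col].astype(bool)
    return table


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end synthetic pipeline run."""

    n_cells: int = 1600
    field_shape: tuple[int, int] = (1024, 1024)
    mixture: str = "disease_free"  # disease_free | metastatic
    seed: int = 0
    two_rounds: bool = True
    round_shift: tuple[float, float] = (4.0, -3.0)
    round_rotation_deg: float = 1.5
    iou_thresholds: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7)
    match_policy: str = "one_to_one"
    ring_width: int = 3
    pixel_fraction: float = 0.2
    n_exemplars: int = 10
    segmentation: str = "baseline"  # baseline | truth | import
    external_mask: str | None = None
    channels: tuple[str, ...] = DEFAULT_CHANNELS

    def validate(self) -> None:
        arr = np.asarray(self.iou_thresholds, dtype=float)
        if (arr <= 0).any() or (arr > 1).any() or (np.diff(arr) <= 0).any():
            raise ValueError("iou_thresholds must be strictly increasing within (0, 1]")
        if self.mixture not in ("disease_free", "metastatic"):
            raise ValueError(f"unknown mixture preset {self.mixture!r}")
        if self.segmentation not in ("baseline", "truth", "import"):
            raise ValueError(f"unknown segmentation mode {self.segmentation!r}")
        if not 0.0 <= self.pixel_fraction <= 1.0:
            raise ValueError("pixel_fraction must be in [0, 1]")
        if self.n_cells < 0 or min(self.field_shape) <= 0:
            raise ValueError("n_cells must be >= 0 and field_shape positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("field_shape", "round_shift", "iou_thresholds", "channels"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path | None = None) -> str:
        data = asdict(self)
        for key in ("field_shape", "round_shift", "iou_thresholds", "channels"):
            data[key] = list(data[key])
        text = yaml.safe_dump(data, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text
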