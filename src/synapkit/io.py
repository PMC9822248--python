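"""Reading and writing the package's on-disk formats.

Images travel as multi-page TIFF (one page per channel) with a JSON sidecar
recording the pixel size and channel order; nested measurement tables and
per-cell summaries are delimited text handled by :mod:`synapkit.nested`;
traces are delimited text with a JSON header handled by
:mod:`synapkit.trace`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

DEFAULT_CHANNELS = ("vesicle", "psd", "test_protein")


def write_image(path, image: np.ndarray, pixel_size: float,
                channels: tuple[str, ...] | None = None) -> None:
    """Write a (C, H, W) or (H, W) image as TIFF with a JSON sidecar."""
    path = Path(path)
    image = np.asarray(image, dtype=np.float32)
    tifffile.imwrite(path, image)
    n_ch = 1 if image.ndim == 2 else image.shape[0]
    meta = {
        "pixel_size_nm": pixel_size,
        "channels": list(channels or DEFAULT_CHANNELS[:n_ch]),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_image(path) -> tuple[np.ndarray, dict]:
    """Read a TIFF written by :func:`write_image` plus its sidecar metadata."""
    path = Path(path)
    image = tifffile.imread(path).astype(float)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return image, meta
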