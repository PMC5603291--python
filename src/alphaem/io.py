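"""Plain-text and image export helpers.

Images go out two ways: CSV matrices carry the exact values; PNGs are
for display only, linearly windowed from each image's own minimum to its
maximum (8-bit gray).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .phantom import Phantom


def save_image_csv(path: str | Path, image: np.ndarray) -> None:
    np.savetxt(path, np.asarray(image, dtype=float), delimiter=",")


def load_image_csv(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",")


def save_image_png(path: str | Path, image: np.ndarray) -> None:
    """Min-max linear gray-scale PNG (each image windowed individually)."""
    img = np.asarray(image, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    scaled = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
    Image.fromarray((scaled * 255.0).round().astype(np.uint8), mode="L").save(path)


def save_sinogram_csv(path: str | Path, sino: np.ndarray,
                      scale: float | None = None, seed: int | None = None,
                      realization_index: int | None = None) -> None:
    """Sinogram CSV with a comment header recording its provenance."""
    header = []
    if scale is not None:
        header.append(f"scale={scale:g}")
    if seed is not None:
        header.append(f"seed={seed}")
    if realization_index is not None:
        header.append(f"realization_index={realization_index}")
    np.savetxt(path, np.asarray(sino, dtype=float), delimiter=",",
               header=" ".join(header))


def load_sinogram_csv(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",")


def save_phantom(path: str | Path, phantom: Phantom) -> None:
    Path(path).write_text(yaml.safe_dump(phantom.to_dict(), sort_keys=False))


def load_phantom(path: str | Path) -> Phantom:
    return Phantom.from_dict(yaml.safe_load(Path(path).read_text()))
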