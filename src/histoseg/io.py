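"""Image/mask readers and writers, model and run-config serialization.

Conventions (shared by every command and mask file):

* row-major rasters, origin top-left, 0-based indices;
* four-class label masks are indexed PNG/TIFF with background=0, tumour=1,
  stroma=2, lymphoid/necrosis=3;
* merged three-class masks use background=0, tumour=1, non_tumour=2;
* training masks use 0=unlabelled, then 1..4 in the canonical class order
  (tumour, stroma, lymphoid/necrosis, background);
* binary nuclei masks are 8-bit PNG with 0/255.

Internally labellings always use the canonical class order of
:mod:`histoseg.texture` (tumour=0, stroma=1, lymphoid/necrosis=2,
background=3); these helpers translate to and from the file palette.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .mrf import MERGED_CLASSES
from .stains import StainAmounts
from .texture import DEFAULT_CLASSES

# internal class index -> palette index in 4-class mask files
_TO_PALETTE_4 = np.array([1, 2, 3, 0], dtype=np.uint8)
_FROM_PALETTE_4 = np.array([3, 0, 1, 2], dtype=np.int64)
# merged internal (tumour=0, non_tumour=1, background=2) -> palette
_TO_PALETTE_3 = np.array([1, 2, 0], dtype=np.uint8)
_FROM_PALETTE_3 = np.array([2, 0, 1], dtype=np.int64)

#: Display colours for indexed mask files, by palette index.
MASK_COLOURS_4 = {0: (0, 0, 0), 1: (200, 30, 30), 2: (40, 160, 40), 3: (70, 70, 220)}
MASK_COLOURS_3 = {0: (0, 0, 0), 1: (200, 30, 30), 2: (120, 120, 120)}


def read_image(path: str | Path, on_16bit: str = "error") -> np.ndarray:
    """Read an 8-bit RGB image (PNG/TIFF) as an H x W x 3 uint8 array.

    16-bit input is rejected by default; ``on_16bit="rescale"`` divides it
    down to 8 bits instead.  An alpha channel, if present, is dropped with a
    warning; grayscale input raises.
    """
    img = Image.open(path)
    if img.mode in ("I", "I;16", "I;16B", "I;16L"):
        if on_16bit == "rescale":
            arr = np.asarray(img, dtype=np.float64)
            arr = np.clip(np.rint(arr / 257.0), 0, 255).astype(np.uint8)
            return np.repeat(arr[..., None], 3, axis=2)
        raise ValueError(
            f"{path}: 16-bit input; pass on_16bit='rescale' to convert, or "
            "supply 8-bit RGB"
        )
    if img.mode == "RGBA":
        warnings.warn(f"{path}: dropping alpha channel", stacklevel=2)
        img = img.convert("RGB")
    if img.mode == "P":
        img = img.convert("RGB")
    if img.mode != "RGB":
        raise ValueError(
            f"{path}: mode {img.mode!r} unsupported; supply an 8-bit RGB image"
        )
    return np.asarray(img, dtype=np.uint8)


def _write_indexed(values: np.ndarray, colours: dict[int, tuple], path: Path) -> None:
    img = Image.fromarray(values.astype(np.uint8), mode="P")
    palette = [0] * 768
    for idx, (r, g, b) in colours.items():
        palette[3 * idx : 3 * idx + 3] = [r, g, b]
    img.putpalette(palette)
    img.save(path)


def _read_indexed(path: Path, allowed: set[int]) -> np.ndarray:
    img = Image.open(path)
    if img.mode == "P":
        values = np.asarray(img, dtype=np.int64)
    elif img.mode == "L":
        values = np.asarray(img, dtype=np.int64)
    else:
        raise ValueError(f"{path}: expected an indexed/grayscale mask, got {img.mode!r}")
    found = set(np.unique(values).tolist())
    if not found <= allowed:
        raise ValueError(
            f"{path}: mask contains values {sorted(found - allowed)} outside the "
            f"palette {sorted(allowed)}"
        )
    return values


def write_mask(labels: np.ndarray, path: str | Path, kind: str = "4class") -> None:
    """Write an internal labelling as an indexed mask file.

    ``kind``: ``"4class"`` (tumour/stroma/lymphoid-necrosis/background),
    ``"3class"`` (merged), ``"train"`` (0=unlabelled then 1..4), or
    ``"binary"`` (boolean -> 0/255 grayscale PNG).
    """
    labels = np.asarray(labels)
    path = Path(path)
    if kind == "4class":
        _write_indexed(_TO_PALETTE_4[labels], MASK_COLOURS_4, path)
    elif kind == "3class":
        _write_indexed(_TO_PALETTE_3[labels], MASK_COLOURS_3, path)
    elif kind == "train":
        colours = {0: (0, 0, 0)}
        colours.update({i + 1: MASK_COLOURS_4[_TO_PALETTE_4[i]] for i in range(4)})
        _write_indexed(labels, colours, path)
    elif kind == "binary":
        Image.fromarray(np.where(labels, 255, 0).astype(np.uint8), mode="L").save(path)
    elif kind == "layers":
        # 8-layer map: greys ascending with layer index
        colours = {i: (32 * i + 16,) * 3 for i in range(8)}
        _write_indexed(labels, colours, path)
    else:
        raise ValueError(f"unknown mask kind {kind!r}")


def read_mask(path: str | Path, kind: str = "4class") -> np.ndarray:
    """Read an indexed mask file back into an internal labelling."""
    path = Path(path)
    if kind == "4class":
        return _FROM_PALETTE_4[_read_indexed(path, {0, 1, 2, 3})]
    if kind == "3class":
        return _FROM_PALETTE_3[_read_indexed(path, {0, 1, 2})]
    if kind == "train":
        return _read_indexed(path, {0, 1, 2, 3, 4})
    if kind == "layers":
        return _read_indexed(path, set(range(8)))
    if kind == "binary":
        return _read_indexed(path, {0, 255}) > 0
    raise ValueError(f"unknown mask kind {kind!r}")


def write_rgb(img: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(img, dtype=np.uint8), mode="RGB").save(path)


def write_stain_maps(
    amounts: StainAmounts, outdir: str | Path, previews: bool = True
) -> list[Path]:
    """Write per-stain amount maps as 32-bit float TIFF, one file per stain.

    Optional 8-bit preview PNGs are min–max scaled, with the scaling recorded
    in a JSON sidecar so the preview is interpretable.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, name in enumerate(amounts.stain_names):
        channel = amounts.amounts[..., i].astype(np.float32)
        tif = outdir / f"{name}.tif"
        tifffile.imwrite(tif, channel)
        written.append(tif)
        if previews:
            lo, hi = float(channel.min()), float(channel.max())
            scale = 255.0 / (hi - lo) if hi > lo else 0.0
            preview = ((channel - lo) * scale).astype(np.uint8)
            Image.fromarray(preview, mode="L").save(outdir / f"{name}_preview.png")
            (outdir / f"{name}_preview.json").write_text(
                json.dumps(
                    {
                        "stain": name,
                        "residual": amounts.is_residual[i],
                        "min": lo,
                        "max": hi,
                    },
                    indent=2,
                )
            )
    return written


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run, emitted alongside outputs."""

    stain_system: str = "h&e"
    class_names: tuple[str, ...] = DEFAULT_CLASSES
    beta: float = 0.9
    neighborhood: int = 8
    relaxer: str = "metropolis"
    seed: int = 0
    include_background: bool = False
    extra: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["class_names"] = list(self.class_names)
        payload["merged_classes"] = list(MERGED_CLASSES)
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        payload.pop("merged_classes", None)
        payload["class_names"] = tuple(payload.get("class_names", DEFAULT_CLASSES))
        return cls(**payload)
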