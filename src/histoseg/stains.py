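"""Stain separation by optical-density colour deconvolution.

Transmitted-light microscopy obeys the Lambert–Beer law: the intensity
detected in channel C is ``I_C = I0_C * 10**(-A * eps_C)`` where ``A`` is the
amount of stain along the light path and ``eps_C`` its absorption factor in
that channel.  Converting to optical density ``OD_C = -log10(I_C / I0_C)``
makes the signal *linear* in stain amount, so a mixture of stains is a linear
combination of per-stain unit OD vectors and can be inverted pixel by pixel:
colour deconvolution (Ruifrok & Johnston 2001).

The stain colour system is a k x 3 matrix whose rows are the unit-norm OD
vectors of the individual stains.  Two-stain systems (H&E, H-DAB) are padded
with the cross product of the two rows so the 3 x 3 system is invertible; the
third, residual channel is kept and flagged rather than discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: Intensity-level guard so OD stays finite at pixel value 0.
OD_EPSILON = 1.0

#: Default incident (white-point) intensity per channel for 8-bit images.
DEFAULT_I0 = 255.0

# Ruifrok–Johnston stain OD vectors (rows: R, G, B optical densities).
# Normalized to unit length by normalize_stain_matrix.
RUIFROK_HE = np.array(
    [
        [0.65, 0.70, 0.29],  # haematoxylin
        [0.07, 0.99, 0.11],  # eosin
    ]
)
RUIFROK_H_DAB = np.array(
    [
        [0.650, 0.704, 0.286],  # haematoxylin
        [0.268, 0.570, 0.776],  # DAB
    ]
)
RUIFROK_HED = np.array(
    [
        [0.65, 0.70, 0.29],  # haematoxylin
        [0.07, 0.99, 0.11],  # eosin
        [0.27, 0.57, 0.78],  # DAB
    ]
)

#: Condition number above which a stain matrix is rejected as singular.
MAX_CONDITION = 1e6


@dataclass(frozen=True)
class StainMatrix:
    """Unit-row OD matrix describing a stain colour system.

    ``rows`` is always 3 x 3 (two-stain systems carry a synthesized residual
    row); ``n_stains`` tells how many rows are real stains.
    """

    rows: np.ndarray
    stain_names: tuple[str, ...]
    n_stains: int

    @property
    def has_residual(self) -> bool:
        return self.n_stains < 3

    def inverse(self) -> np.ndarray:
        """The colour-deconvolution matrix D = M^-1."""
        return np.linalg.inv(self.rows)


@dataclass(frozen=True)
class StainAmounts:
    """Per-pixel stain amounts (H x W x 3) recovered by deconvolution.

    The last channel is a residual (flagged via ``is_residual``) when the
    system had only two real stains.
    """

    amounts: np.ndarray
    stain_names: tuple[str, ...]
    is_residual: tuple[bool, ...]

    def channel(self, name: str) -> np.ndarray:
        return self.amounts[..., self.stain_names.index(name)]


def stain_preset(name: str) -> StainMatrix:
    """Return a built-in normalized stain matrix: ``"h&e"``, ``"h-dab"`` or ``"hed"``."""
    presets = {
        "h&e": (RUIFROK_HE, ("haematoxylin", "eosin")),
        "h-dab": (RUIFROK_H_DAB, ("haematoxylin", "dab")),
        "hed": (RUIFROK_HED, ("haematoxylin", "eosin", "dab")),
    }
    key = name.lower()
    if key not in presets:
        raise KeyError(f"unknown stain preset {name!r}; choose from {sorted(presets)}")
    raw, names = presets[key]
    return normalize_stain_matrix(raw, names)


def normalize_stain_matrix(
    raw: np.ndarray, stain_names: tuple[str, ...] | None = None
) -> StainMatrix:
    """Normalize raw OD vectors to unit length and pad to an invertible 3 x 3 system.

    Each row of ``raw`` (k x 3, k in {2, 3}) is one stain's OD vector and is
    divided by its Euclidean norm.  For k = 2 a residual row is synthesized as
    the unit cross product of the two stain rows.

    Raises
    ------
    ValueError
        If a row is all zeros or k is not 2 or 3.
    numpy.linalg.LinAlgError
        If the rows are (near-)collinear; the message reports the condition
        number of the padded matrix.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != 3 or raw.shape[0] not in (2, 3):
        raise ValueError(f"expected a k x 3 matrix with k in {{2, 3}}, got shape {raw.shape}")
    norms = np.linalg.norm(raw, axis=1)
    if np.any(norms == 0):
        raise ValueError("stain matrix contains an all-zero row")
    unit = raw / norms[:, None]
    k = unit.shape[0]
    if stain_names is None:
        stain_names = tuple(f"stain_{i}" for i in range(k))
    if len(stain_names) != k:
        raise ValueError("stain_names length must match the number of rows")
    if k == 2:
        residual = np.cross(unit[0], unit[1])
        res_norm = np.linalg.norm(residual)
        if res_norm < 1e-12:
            raise np.linalg.LinAlgError(
                "stain vectors are collinear; cannot synthesize a residual row"
            )
        unit = np.vstack([unit, residual / res_norm])
        stain_names = (*stain_names, "residual")
    cond = np.linalg.cond(unit)
    if not np.isfinite(cond) or cond > MAX_CONDITION:
        raise np.linalg.LinAlgError(
            f"stain matrix is singular or near-singular (condition number {cond:.3g})"
        )
    return StainMatrix(rows=unit, stain_names=tuple(stain_names), n_stains=k)


def rgb_to_od(img: np.ndarray, i0: float = DEFAULT_I0) -> np.ndarray:
    """Convert detected intensities to optical density, channelwise.

    ``od = -log10(max(pixel, OD_EPSILON) / i0)``; a pixel at the incident
    intensity ``i0`` maps to OD 0, and the one-level epsilon guard keeps the
    OD of a fully absorbing pixel finite.

    Pixels above ``i0`` (possible with a miscalibrated white point) are
    clamped with a warning.
    """
    if i0 <= 0:
        raise ValueError(f"incident intensity i0 must be positive, got {i0}")
    pixels = np.asarray(img, dtype=float)
    if np.any(pixels > i0):
        warnings.warn(
            f"{int(np.sum(pixels > i0))} pixel value(s) exceed i0={i0}; clamping",
            stacklevel=2,
        )
        pixels = np.minimum(pixels, i0)
    return -np.log10(np.maximum(pixels, OD_EPSILON) / i0)


def color_deconvolve(od: np.ndarray, matrix: StainMatrix) -> StainAmounts:
    """Recover per-stain amounts from an OD image.

    With row-vector OD ``od = c @ M`` for amounts ``c``, the amounts are
    ``c = od @ M^-1`` (D = M^-1 is the colour-deconvolution matrix).  All
    three output channels are returned; for a two-stain system the third is
    the residual projection and is flagged, not dropped.
    """
    od = np.asarray(od, dtype=float)
    if od.shape[-1] != 3:
        raise ValueError(f"OD image must have 3 channels, got shape {od.shape}")
    amounts = od @ matrix.inverse()
    is_residual = tuple(name == "residual" for name in matrix.stain_names)
    return StainAmounts(
        amounts=amounts, stain_names=matrix.stain_names, is_residual=is_residual
    )


def compose_rgb(
    amounts: np.ndarray, matrix: StainMatrix, i0: float = DEFAULT_I0
) -> np.ndarray:
    """Forward Lambert–Beer synthesis: stain amounts -> 8-bit RGB image.

    ``pixel_C = round(i0 * 10**(-sum_j amounts_j * M[j, C]))`` clipped to
    ``[0, i0]``.  ``amounts`` may carry ``matrix.n_stains`` channels (real
    stains only) or all 3 (including the residual).
    """
    if i0 <= 0:
        raise ValueError(f"incident intensity i0 must be positive, got {i0}")
    amounts = np.asarray(amounts, dtype=float)
    if np.any(amounts < 0):
        raise ValueError("stain amounts must be non-negative")
    k = amounts.shape[-1]
    if k not in (matrix.n_stains, 3):
        raise ValueError(
            f"amounts have {k} channels; expected {matrix.n_stains} or 3"
        )
    od = amounts @ matrix.rows[:k]
    pixels = np.clip(np.rint(i0 * 10.0 ** (-od)), 0, i0)
    return pixels.astype(np.uint8)
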