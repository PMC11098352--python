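"""Colour representation and receptor-noise-limited (RNL) discrimination.

Colours live in CIELAB (D65, 2-degree observer); rendering goes through
sRGB. Receptor quantum catches are obtained from linear RGB by a
configurable linear map, so any di-/tri-/tetrachromatic observer can be
plugged in via :class:`VisualSystem`. Chromatic distances use the RNL
model (log catch contrasts weighted by receptor Weber fractions);
achromatic distance is a Weber-scaled log luminance ratio.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.color import lab2rgb, rgb2lab

__all__ = [
    "CATCH_FLOOR",
    "ColourLab",
    "ColourSpaceBox",
    "FULL_BOX",
    "ReceptorCatch",
    "VisualSystem",
    "lab_to_srgb",
    "srgb_to_lab",
    "srgb_to_linear",
    "linear_to_srgb",
    "srgb_to_catches",
    "linear_to_catches",
    "linear_luminance",
    "rnl_chromatic",
    "rnl_achromatic",
    "narrow_space_from_background",
]

#: Floor applied to quantum catches and luminances before taking logs.
CATCH_FLOOR = 1e-4


@dataclass(frozen=True)
class ColourLab:
    """A CIELAB colour. ``L`` is clamped to [0, 100] on construction."""

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.L, self.a, self.b)):
            raise ValueError("ColourLab components must be finite")
        object.__setattr__(self, "L", float(min(max(self.L, 0.0), 100.0)))
        object.__setattr__(self, "a", float(self.a))
        object.__setattr__(self, "b", float(self.b))

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b], dtype=float)


@dataclass(frozen=True)
class ColourSpaceBox:
    """Axis-aligned box of admissible CIELAB colours."""

    L_range: tuple[float, float] = (0.0, 100.0)
    a_range: tuple[float, float] = (-50.0, 50.0)
    b_range: tuple[float, float] = (-10.0, 70.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.L_range, self.a_range, self.b_range):
            if not (math.isfinite(lo) and math.isfinite(hi) and lo <= hi):
                raise ValueError("each range must be a finite interval lo <= hi")

    @property
    def ranges(self) -> np.ndarray:
        """3x2 array of (lo, hi) per channel (L, a, b)."""
        return np.array([self.L_range, self.a_range, self.b_range], dtype=float)

    def contains(self, lab, tol: float = 0.0) -> bool:
        lab = np.asarray(lab, dtype=float)
        r = self.ranges
        return bool(np.all(lab >= r[:, 0] - tol) and np.all(lab <= r[:, 1] + tol))

    def lerp(self, t) -> np.ndarray:
        """Affine map of unit-interval coordinates onto the box (0 -> lo, 1 -> hi)."""
        t = np.asarray(t, dtype=float)
        r = self.ranges
        return r[:, 0] + t * (r[:, 1] - r[:, 0])

    def intersect(self, other: "ColourSpaceBox") -> "ColourSpaceBox":
        a, b = self.ranges, other.ranges
        lo = np.maximum(a[:, 0], b[:, 0])
        hi = np.minimum(a[:, 1], b[:, 1])
        hi = np.maximum(hi, lo)  # collapse to a point rather than go empty
        return ColourSpaceBox(tuple(map(float, (lo[0], hi[0]))),
                              tuple(map(float, (lo[1], hi[1]))),
                              tuple(map(float, (lo[2], hi[2]))))

    def to_dict(self) -> dict:
        return {"L": list(self.L_range), "a": list(self.a_range), "b": list(self.b_range)}

    @classmethod
    def from_dict(cls, d: dict) -> "ColourSpaceBox":
        return cls(tuple(d["L"]), tuple(d["a"]), tuple(d["b"]))


#: Default colour box: L in [0, 100], a in [-50, 50], b in [-10, 70].
FULL_BOX = ColourSpaceBox()


@dataclass(frozen=True)
class ReceptorCatch:
    """Quantum catches of one stimulus, floored so log contrasts exist."""

    q: np.ndarray

    def __post_init__(self) -> None:
        q = np.maximum(np.asarray(self.q, dtype=float), CATCH_FLOOR)
        object.__setattr__(self, "q", q)

    def __len__(self) -> int:
        return self.q.shape[0]


@dataclass(frozen=True)
class VisualSystem:
    """Linear receptor model: catches = receptor_matrix @ linear_rgb.

    ``weber`` holds the chromatic Weber fractions e_i (one per receptor),
    ``weber_lum`` the achromatic Weber fraction, and ``lum_weights`` maps
    linear RGB to the scalar luminance channel.
    """

    receptor_matrix: np.ndarray = field(
        default_factory=lambda: np.eye(3))
    weber: np.ndarray = field(
        default_factory=lambda: np.full(3, 0.05))
    weber_lum: float = 0.05
    lum_weights: np.ndarray = field(
        default_factory=lambda: np.full(3, 1.0 / 3.0))

    def __post_init__(self) -> None:
        m = np.asarray(self.receptor_matrix, dtype=float)
        w = np.asarray(self.weber, dtype=float)
        lw = np.asarray(self.lum_weights, dtype=float)
        if m.ndim != 2 or m.shape[1] != 3:
            raise ValueError("receptor_matrix must be n x 3")
        if m.shape[0] < 2:
            raise ValueError("need at least 2 receptors")
        if np.any(m < 0) or np.any(m.sum(axis=1) <= 0):
            raise ValueError("receptor_matrix rows must be non-negative with a positive entry")
        if w.shape != (m.shape[0],) or np.any(w <= 0):
            raise ValueError("weber must be positive, one value per receptor")
        if self.weber_lum <= 0:
            raise ValueError("weber_lum must be positive")
        if lw.shape != (3,) or np.any(lw < 0) or lw.sum() <= 0:
            raise ValueError("lum_weights must be a non-negative 3-vector with positive sum")
        object.__setattr__(self, "receptor_matrix", m)
        object.__setattr__(self, "weber", w)
        object.__setattr__(self, "weber_lum", float(self.weber_lum))
        object.__setattr__(self, "lum_weights", lw)

    @property
    def n_receptors(self) -> int:
        return self.receptor_matrix.shape[0]

    def to_json(self, path) -> None:
        d = {
            "receptor_matrix": self.receptor_matrix.tolist(),
            "weber": self.weber.tolist(),
            "weber_lum": self.weber_lum,
            "lum_weights": self.lum_weights.tolist(),
        }
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "VisualSystem":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["receptor_matrix"], float),
                   np.asarray(d["weber"], float),
                   float(d["weber_lum"]),
                   np.asarray(d["lum_weights"], float))


# ---------------------------------------------------------------------------
# sRGB <-> CIELAB plumbing

def srgb_to_linear(rgb01: np.ndarray) -> np.ndarray:
    """Invert the sRGB transfer function. Input and output in [0, 1]."""
    rgb01 = np.asarray(rgb01, dtype=float)
    lo = rgb01 / 12.92
    hi = ((rgb01 + 0.055) / 1.055) ** 2.4
    return np.where(rgb01 <= 0.04045, lo, hi)


def linear_to_srgb(lin: np.ndarray) -> np.ndarray:
    lin = np.clip(np.asarray(lin, dtype=float), 0.0, 1.0)
    lo = lin * 12.92
    hi = 1.055 * lin ** (1 / 2.4) - 0.055
    return np.where(lin <= 0.0031308, lo, hi)


def lab_to_srgb(lab) -> np.ndarray:
    """CIELAB -> 8-bit sRGB, per-channel clipped (never fails on gamut).

    Accepts a :class:`ColourLab`, a 3-vector, or an (..., 3) array;
    returns uint8 of the same leading shape.
    """
    if isinstance(lab, ColourLab):
        lab = lab.as_array()
    lab = np.asarray(lab, dtype=float)
    with warnings.catch_warnings():
        # out-of-gamut colours are clipped by design
        warnings.filterwarnings("ignore", message=".*color space.*clipped.*")
        rgb01 = lab2rgb(lab)  # D65 / 2deg; clipped to [0, 1] by skimage
    return np.round(rgb01 * 255.0).astype(np.uint8)


def srgb_to_lab(rgb) -> np.ndarray:
    """8-bit sRGB -> CIELAB (D65, 2-degree observer)."""
    rgb = np.asarray(rgb, dtype=float) / 255.0
    return rgb2lab(rgb)


def linear_to_catches(lin_rgb, vs: VisualSystem) -> ReceptorCatch:
    """Receptor catches from a linear-RGB triple (or mean triple)."""
    lin_rgb = np.asarray(lin_rgb, dtype=float)
    return ReceptorCatch(vs.receptor_matrix @ lin_rgb)


def srgb_to_catches(rgb, vs: VisualSystem) -> ReceptorCatch:
    """8-bit sRGB triple -> receptor catches (linearise, map, floor)."""
    rgb = np.asarray(rgb, dtype=float)
    if np.any(rgb < 0) or np.any(rgb > 255):
        raise ValueError("sRGB values must lie in [0, 255]")
    return linear_to_catches(srgb_to_linear(rgb / 255.0), vs)


def linear_luminance(lin_rgb, vs: VisualSystem) -> float:
    """Scalar luminance of a linear-RGB triple, floored."""
    return float(max(np.dot(vs.lum_weights, np.asarray(lin_rgb, float)), CATCH_FLOOR))


# ---------------------------------------------------------------------------
# RNL distances

def rnl_chromatic(A: ReceptorCatch, B: ReceptorCatch, vs: VisualSystem) -> float:
    """Chromatic RNL distance (just-noticeable-difference units).

    Uses the closed dichromat/trichromat forms and the general
    n-receptor expression

        dS^2 = sum_{i<j} w_ij (df_i - df_j)^2 / sum_i v_i

    with w_ij = prod_{k != i,j} e_k^2 and v_i = prod_{k != i} e_k^2,
    where df_i = ln(qA_i / qB_i).
    """
    if len(A) != len(B) or len(A) != vs.n_receptors:
        raise ValueError("catch dimensionality does not match the visual system")
    df = np.log(A.q / B.q)
    e = vs.weber
    n = e.shape[0]
    if n == 2:
        num = (df[0] - df[1]) ** 2
        den = e[0] ** 2 + e[1] ** 2
    elif n == 3:
        num = (e[0] ** 2 * (df[1] - df[2]) ** 2
               + e[1] ** 2 * (df[0] - df[2]) ** 2
               + e[2] ** 2 * (df[0] - df[1]) ** 2)
        den = ((e[0] * e[1]) ** 2 + (e[0] * e[2]) ** 2 + (e[1] * e[2]) ** 2)
    else:
        e2 = e ** 2
        prod_all = float(np.prod(e2))
        v = prod_all / e2                      # prod_{k != i} e_k^2
        num = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                w_ij = prod_all / (e2[i] * e2[j])
                num += w_ij * (df[i] - df[j]) ** 2
        den = float(v.sum())
    return float(np.sqrt(max(num / den, 0.0)))


def rnl_achromatic(lumA: float, lumB: float, vs: VisualSystem) -> float:
    """Achromatic RNL distance: |ln(lumA/lumB)| / weber_lum (JND units)."""
    la = max(float(lumA), CATCH_FLOOR)
    lb = max(float(lumB), CATCH_FLOOR)
    return abs(math.log(la / lb)) / vs.weber_lum


# ---------------------------------------------------------------------------

def narrow_space_from_background(bg: np.ndarray, k: float = 2.0,
                                 full_box: ColourSpaceBox = FULL_BOX) -> ColourSpaceBox:
    """Colour box spanning mean +/- k standard deviations of the background.

    Computed per CIELAB channel over all pixels of ``bg`` (8-bit sRGB,
    H x W x 3) and intersected with ``full_box``.
    """
    bg = np.asarray(bg)
    if bg.size == 0:
        raise ValueError("background image is empty")
    if k <= 0:
        raise ValueError("k must be positive")
    lab = srgb_to_lab(bg).reshape(-1, 3)
    mu = lab.mean(axis=0)
    sd = lab.std(axis=0)
    lo, hi = mu - k * sd, mu + k * sd
    box = ColourSpaceBox((lo[0], hi[0]), (lo[1], hi[1]), (lo[2], hi[2]))
    return box.intersect(full_box)
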