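"""Camouflage-efficacy metrics for rendered targets against backgrounds.

Four metric families are provided:

* chromatic / achromatic RNL distance between mean colours,
* a frequency-weighted colour distance (each target colour scored
  against the most similar background colour),
* a granularity pattern distance (L1 between octave band-energy
  spectra), and
* Gabor-based edge disruption: the share of "false" (outline-crossing)
  edge energy around the target boundary, in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.vq import kmeans2
from scipy.ndimage import convolve, gaussian_filter, uniform_filter1d
from skimage.filters import gabor_kernel
from skimage.measure import find_contours

from .colour_vision import (
    CATCH_FLOOR,
    VisualSystem,
    lab_to_srgb,
    linear_to_catches,
    rnl_achromatic,
    rnl_chromatic,
    srgb_to_lab,
    srgb_to_linear,
)
from .genome_pattern import TargetImage

__all__ = [
    "DEFAULT_SCALES",
    "GranularitySpectrum",
    "MetricsResult",
    "mean_colour_difference",
    "weighted_colour_difference",
    "background_colour_clusters",
    "granularity_spectrum",
    "pattern_difference",
    "gabrat_disruption",
    "compute_metrics",
]

#: Octave-spaced granularity band centres (px).
DEFAULT_SCALES = (2, 4, 8, 16, 32, 64)


@dataclass(frozen=True)
class GranularitySpectrum:
    scales: tuple[float, ...]
    energy: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energy, dtype=float)
        if e.shape[0] != len(self.scales):
            raise ValueError("energy and scales must have the same length")
        if np.any(e < 0):
            raise ValueError("band energies must be non-negative")
        object.__setattr__(self, "energy", e)
        object.__setattr__(self, "scales", tuple(float(s) for s in self.scales))


@dataclass(frozen=True)
class MetricsResult:
    target_id: str
    background_id: str
    delta_s_mean: float = np.nan
    delta_l_mean: float = np.nan
    delta_s_weighted: float = np.nan
    pattern_difference: float = np.nan
    gabrat: float = np.nan

    def as_dict(self) -> dict:
        return {
            "target_id": self.target_id,
            "background_id": self.background_id,
            "delta_s_mean": self.delta_s_mean,
            "delta_l_mean": self.delta_l_mean,
            "delta_s_weighted": self.delta_s_weighted,
            "pattern_difference": self.pattern_difference,
            "gabrat": self.gabrat,
        }


# ---------------------------------------------------------------------------
# mean-colour distances

def _mean_linear(rgb: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    lin = srgb_to_linear(np.asarray(rgb, float) / 255.0)
    if mask is not None:
        lin = lin[mask]
    return lin.reshape(-1, 3).mean(axis=0)


def mean_colour_difference(target: TargetImage, bg: np.ndarray,
                           vs: VisualSystem) -> tuple[float, float]:
    """(dS, dL) between the masked target mean and background mean colour."""
    if not target.alpha_mask.any():
        raise ValueError("target mask is empty")
    mt = _mean_linear(target.rgb, target.alpha_mask)
    mb = _mean_linear(bg)
    ds = rnl_chromatic(linear_to_catches(mt, vs), linear_to_catches(mb, vs), vs)
    dl = rnl_achromatic(float(vs.lum_weights @ mt), float(vs.lum_weights @ mb), vs)
    return ds, dl


# ---------------------------------------------------------------------------
# frequency-weighted colour distance

def _colour_clusters(pixels_lab: np.ndarray, k: int,
                     seed: int) -> tuple[np.ndarray, np.ndarray]:
    """(centroids_lab, frequencies). Uses the exact unique colours when
    there are at most ``k`` of them, otherwise seeded k-means."""
    uniq, counts = np.unique(np.round(pixels_lab, 6), axis=0, return_counts=True)
    if uniq.shape[0] <= k:
        return uniq, counts / counts.sum()
    centroids, labels = kmeans2(pixels_lab, k, minit="++",
                                seed=np.random.default_rng(seed))
    counts = np.bincount(labels, minlength=k).astype(float)
    keep = counts > 0
    return centroids[keep], counts[keep] / counts.sum()


def background_colour_clusters(bg: np.ndarray, k: int = 8, seed: int = 0,
                               max_pixels: int = 60000) -> np.ndarray:
    """Representative background colours (CIELAB centroids, seeded k-means)."""
    if k < 1:
        raise ValueError("need at least one background cluster")
    lab = srgb_to_lab(bg).reshape(-1, 3)
    if lab.shape[0] > max_pixels:
        idx = np.random.default_rng(seed).choice(lab.shape[0], max_pixels, replace=False)
        lab = lab[idx]
    centroids, _ = _colour_clusters(lab, k, seed)
    return centroids


def _lab_to_catches(lab_rows: np.ndarray, vs: VisualSystem) -> np.ndarray:
    rgb = lab_to_srgb(lab_rows)
    return np.maximum(srgb_to_linear(rgb.astype(float) / 255.0) @ vs.receptor_matrix.T,
                      CATCH_FLOOR)


def weighted_colour_difference(target: TargetImage, bg: np.ndarray,
                               vs: VisualSystem, n_bg_clusters: int = 8,
                               n_target_clusters: int = 4, seed: int = 0,
                               bg_clusters: np.ndarray | None = None) -> float:
    """Frequency-weighted mean of each target colour's RNL distance to the
    most similar background colour.

    ``bg_clusters`` may be precomputed with
    :func:`background_colour_clusters` to amortise the background k-means
    across many targets.
    """
    if n_bg_clusters < 1:
        raise ValueError("need at least one background cluster")
    if not target.alpha_mask.any():
        raise ValueError("target mask is empty")
    if bg_clusters is None:
        bg_clusters = background_colour_clusters(bg, n_bg_clusters, seed)
    t_lab = srgb_to_lab(target.rgb)[target.alpha_mask].reshape(-1, 3)
    centroids, freqs = _colour_clusters(t_lab, n_target_clusters, seed)
    qt = _lab_to_catches(centroids, vs)
    qb = _lab_to_catches(np.asarray(bg_clusters, float), vs)
    from .colour_vision import ReceptorCatch
    total = 0.0
    for ct, p in zip(qt, freqs):
        dmin = min(rnl_chromatic(ReceptorCatch(ct), ReceptorCatch(cb), vs)
                   for cb in qb)
        total += p * dmin
    return float(total)


# ---------------------------------------------------------------------------
# granularity analysis

def _luminance_image(rgb: np.ndarray) -> np.ndarray:
    return srgb_to_linear(np.asarray(rgb, float) / 255.0).mean(axis=2)


def granularity_spectrum(img: np.ndarray, mask: np.ndarray | None = None,
                         scales=DEFAULT_SCALES) -> GranularitySpectrum:
    """Octave band-pass energy spectrum of the luminance channel.

    Each band keeps spatial wavelengths within a factor of sqrt(2) of the
    band centre; band energy is the standard deviation of the filtered
    image over the masked region (whole image if ``mask`` is None).
    """
    img = np.asarray(img)
    lum = _luminance_image(img) if img.ndim == 3 else np.asarray(img, float)
    h, w = lum.shape
    if max(scales) > min(h, w):
        raise ValueError("largest scale exceeds the image size")
    F = np.fft.fft2(lum)
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    r = np.hypot(fx, fy)
    energies = []
    for s in scales:
        f0 = 1.0 / s
        band = (r >= f0 / np.sqrt(2.0)) & (r < f0 * np.sqrt(2.0))
        filt = np.fft.ifft2(F * band).real
        vals = filt[mask] if mask is not None else filt
        energies.append(float(vals.std()))
    return GranularitySpectrum(tuple(scales), np.array(energies))


def pattern_difference(t: GranularitySpectrum, b: GranularitySpectrum) -> float:
    """L1 distance between two granularity spectra on identical scales."""
    if t.scales != b.scales:
        raise ValueError("spectra were computed at different scales")
    return float(np.abs(t.energy - b.energy).sum())


# ---------------------------------------------------------------------------
# GabRat edge disruption

def composite_on_background(target: TargetImage, bg: np.ndarray,
                            position: tuple[int, int] | None = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Paste the target onto the background; returns (composite, full mask).

    ``position`` is the (row, col) of the target's top-left corner;
    defaults to centred. The target must fit inside the background.
    """
    bg = np.asarray(bg)
    h, w = target.rgb.shape[:2]
    H, W = bg.shape[:2]
    if h > H or w > W:
        raise ValueError("target larger than background")
    if position is None:
        position = ((H - h) // 2, (W - w) // 2)
    r0, c0 = position
    r0 = int(np.clip(r0, 0, H - h))
    c0 = int(np.clip(c0, 0, W - w))
    comp = bg.copy()
    region = comp[r0:r0 + h, c0:c0 + w]
    region[target.alpha_mask] = target.rgb[target.alpha_mask]
    full_mask = np.zeros((H, W), dtype=bool)
    full_mask[r0:r0 + h, c0:c0 + w] = target.alpha_mask
    return comp, full_mask


def _even_gabor(freq: float, theta: float, sigma: float) -> np.ndarray:
    """Even-symmetric Gabor kernel corrected to zero DC (so uniform
    regions produce exactly no response)."""
    # envelope elongated along the stripes (sigma_y) for sharper
    # orientation tuning than an isotropic envelope would give
    k = np.real(gabor_kernel(freq, theta=theta, sigma_x=sigma,
                             sigma_y=2.0 * sigma))
    env = np.real(gabor_kernel(0.0, theta=theta, sigma_x=sigma,
                               sigma_y=2.0 * sigma))
    return k - (k.sum() / env.sum()) * env


def gabrat_disruption(target: TargetImage, bg: np.ndarray, sigma: float = 3.0,
                      n_orient: int = 6,
                      position: tuple[int, int] | None = None) -> float:
    """Edge-disruption ratio in [0, 1] around the target outline.

    The target is composited onto the background; even-symmetric Gabor
    energies over ``n_orient`` orientations are evaluated on the
    luminance channel at each outline pixel. With g_par the energy at
    the orientation parallel to the local outline tangent and g_false
    the maximum over all other orientations, the result is the mean of
    g_false / (g_par + g_false) over responding outline pixels (0 when
    no pixel responds).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    comp, mask = composite_on_background(target, bg, position)

    # crop to the mask neighbourhood for speed
    rows = np.where(mask.any(axis=1))[0]
    cols = np.where(mask.any(axis=0))[0]
    if rows.size == 0:
        raise ValueError("degenerate mask: no outline")
    pad = int(np.ceil(4 * sigma)) + 2
    r0, r1 = max(rows[0] - pad, 0), min(rows[-1] + pad + 1, mask.shape[0])
    c0, c1 = max(cols[0] - pad, 0), min(cols[-1] + pad + 1, mask.shape[1])
    lum = _luminance_image(comp[r0:r1, c0:c1])
    sub_mask = mask[r0:r1, c0:c1]

    contours = find_contours(sub_mask.astype(float), 0.5)
    if not contours:
        raise ValueError("degenerate mask: no outline")
    contour = max(contours, key=len)
    smooth = uniform_filter1d(contour, size=7, axis=0, mode="wrap")
    tang = np.gradient(smooth, axis=0)
    # tangent angle in array coords (row = y), folded to [0, pi)
    phi = np.arctan2(tang[:, 0], tang[:, 1]) % np.pi

    freq = 1.0 / (2.0 * sigma)
    thetas = np.arange(n_orient) * np.pi / n_orient
    # rectified responses are pooled over ~sigma so the sampled energy does
    # not depend on the sub-pixel position of the outline relative to the
    # even filter's zero-crossing at a step edge
    responses = np.stack([
        gaussian_filter(
            np.abs(convolve(lum, _even_gabor(freq, th, sigma), mode="reflect")),
            sigma)
        for th in thetas])

    rr = np.clip(np.round(smooth[:, 0]).astype(int), 0, lum.shape[0] - 1)
    cc = np.clip(np.round(smooth[:, 1]).astype(int), 0, lum.shape[1] - 1)
    energies = responses[:, rr, cc]  # (n_orient, n_points)

    # a gabor with theta aligned to the edge NORMAL responds to that edge,
    # so the "parallel" filter for tangent angle phi sits at theta = phi + pi/2;
    # energies at the two bracketing orientations are interpolated, and the
    # false energy is the max over orientations >= one angular step away
    step = np.pi / n_orient
    theta_par = (phi + np.pi / 2.0) % np.pi
    lo_idx = np.floor(theta_par / step).astype(int) % n_orient
    hi_idx = (lo_idx + 1) % n_orient
    frac = (theta_par / step) - np.floor(theta_par / step)
    pts = np.arange(energies.shape[1])
    g_par = (1.0 - frac) * energies[lo_idx, pts] + frac * energies[hi_idx, pts]
    ang_dist = np.abs(((thetas[:, None] - theta_par[None, :]
                        + np.pi / 2.0) % np.pi) - np.pi / 2.0)
    masked = np.where(ang_dist >= step - 1e-9, energies, -np.inf)
    g_false = masked.max(axis=0)
    tot = g_par + g_false
    ok = tot > 1e-8  # below this is numerical noise from the DC correction
    if not ok.any():
        return 0.0
    return float(np.mean(g_false[ok] / tot[ok]))


# ---------------------------------------------------------------------------
# batch convenience

ALL_METRICS = ("delta_s_mean", "delta_l_mean", "delta_s_weighted",
               "pattern_difference", "gabrat")


def compute_metrics(target: TargetImage, bg: np.ndarray, vs: VisualSystem,
                    which=ALL_METRICS, seed: int = 0,
                    bg_clusters: np.ndarray | None = None,
                    bg_spectrum: GranularitySpectrum | None = None,
                    background_id: str = "background",
                    gabrat_sigma: float = 3.0, n_orient: int = 6,
                    position: tuple[int, int] | None = None) -> MetricsResult:
    """Evaluate the requested metrics for one target against one background."""
    vals: dict[str, float] = {}
    if "delta_s_mean" in which or "delta_l_mean" in which:
        ds, dl = mean_colour_difference(target, bg, vs)
        vals["delta_s_mean"], vals["delta_l_mean"] = ds, dl
    if "delta_s_weighted" in which:
        vals["delta_s_weighted"] = weighted_colour_difference(
            target, bg, vs, seed=seed, bg_clusters=bg_clusters)
    if "pattern_difference" in which:
        if bg_spectrum is None:
            bg_spectrum = granularity_spectrum(bg)
        t_spec = granularity_spectrum(target.rgb, target.alpha_mask,
                                      scales=bg_spectrum.scales)
        vals["pattern_difference"] = pattern_difference(t_spec, bg_spectrum)
    if "gabrat" in which:
        vals["gabrat"] = gabrat_disruption(target, bg, sigma=gabrat_sigma,
                                           n_orient=n_orient, position=position)
    return MetricsResult(target_id=target.genome_id, background_id=background_id,
                         **vals)
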