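"""Pattern genomes, genotype->phenotype decoding, and oval-target rendering.

A genome is a fixed-length vector of 20 genes in [0, 1]:

====  =======================================================
idx   meaning
====  =======================================================
0-11  4 palette colours x (L, a, b), affine-mapped onto the
      run's colour box
12-13 pattern scale (mean of the two genes, log-mapped to
      [4, 64] px)
14-16 colour coverage logits (softmax over 4 colours, with a
      fixed fourth logit)
17    pattern orientation, [0, pi)
18    pattern elongation, [1, 4]
19    edge softness (Gaussian blur sigma, [0, 2] px)
====  =======================================================

Rendering is a pure function of (genome, size): the noise field is
seeded from a hash of the gene vector, so repeated renders are
bit-identical.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from .colour_vision import ColourLab, ColourSpaceBox, lab_to_srgb

__all__ = [
    "GENOME_LENGTH",
    "N_COLOURS",
    "SCALE_RANGE",
    "Genome",
    "PhenotypeParams",
    "TargetImage",
    "random_genome",
    "decode_genome",
    "render_target",
    "mutate",
    "crossover",
    "genomes_to_frame",
    "genomes_from_frame",
]

N_COLOURS = 4
GENOME_LENGTH = 3 * N_COLOURS + 2 + (N_COLOURS - 1) + 2 + 1  # = 20
SCALE_RANGE = (4.0, 64.0)  # px, log-mapped
_PROP_LOGIT_FIXED = 0.5    # fixed fourth coverage logit
_PROP_BETA = 3.0           # softmax sharpness for coverage genes


@dataclass(frozen=True)
class Genome:
    genes: np.ndarray
    id: str
    parent_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        g = np.asarray(self.genes, dtype=float)
        if g.ndim != 1:
            raise ValueError("genes must be a 1-D vector")
        if np.any(g < 0) or np.any(g > 1) or not np.all(np.isfinite(g)):
            raise ValueError("every gene must lie in [0, 1]")
        if len(self.parent_ids) > 2:
            raise ValueError("a genome has at most two parents")
        object.__setattr__(self, "genes", g)
        object.__setattr__(self, "parent_ids", tuple(self.parent_ids))


@dataclass(frozen=True)
class PhenotypeParams:
    palette: tuple[ColourLab, ...]
    pattern_scale: float
    pattern_proportions: tuple[float, ...]
    orientation: float
    elongation: float
    edge_softness: float


@dataclass(frozen=True)
class TargetImage:
    """Rendered oval target: 8-bit RGB plus a boolean ellipse mask."""

    rgb: np.ndarray
    alpha_mask: np.ndarray
    genome_id: str

    def to_rgba(self) -> np.ndarray:
        a = (self.alpha_mask * 255).astype(np.uint8)
        return np.dstack([self.rgb, a])

    def to_png_bytes(self) -> bytes:
        buf = io.BytesIO()
        Image.fromarray(self.to_rgba(), mode="RGBA").save(buf, format="PNG")
        return buf.getvalue()

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            fh.write(self.to_png_bytes())


def random_genome(rng: np.random.Generator, space: ColourSpaceBox,
                  genome_id: str = "g0_000") -> Genome:
    """I.i.d. Uniform(0, 1) genes; decoding maps colours into ``space``."""
    return Genome(rng.uniform(0.0, 1.0, GENOME_LENGTH), genome_id)


def decode_genome(g: Genome, space: ColourSpaceBox) -> PhenotypeParams:
    genes = g.genes
    if genes.shape[0] != GENOME_LENGTH:
        raise ValueError(f"expected {GENOME_LENGTH} genes, got {genes.shape[0]}")
    palette = tuple(
        ColourLab(*space.lerp(genes[3 * i:3 * i + 3]))
        for i in range(N_COLOURS)
    )
    scale_t = genes[12:14].mean()
    lo, hi = np.log(SCALE_RANGE)
    pattern_scale = float(np.exp(lo + scale_t * (hi - lo)))
    logits = np.concatenate([genes[14:17], [_PROP_LOGIT_FIXED]]) * _PROP_BETA
    w = np.exp(logits - logits.max())
    proportions = tuple((w / w.sum()).tolist())
    orientation = float(genes[17] * np.pi)
    elongation = float(1.0 + genes[18] * 3.0)
    edge_softness = float(genes[19] * 2.0)
    return PhenotypeParams(palette, pattern_scale, proportions,
                           orientation, elongation, edge_softness)


# ---------------------------------------------------------------------------
# rendering

def _ellipse_mask(w: int, h: int, aspect: float = 18.0 / 14.0) -> np.ndarray:
    """Centred ellipse with semi-axis ratio ``aspect`` (width:height)."""
    semi_a = min(w / 2.0, (h / 2.0) * aspect) * 0.98
    semi_b = semi_a / aspect
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    return ((xx - cx) / semi_a) ** 2 + ((yy - cy) / semi_b) ** 2 <= 1.0


def _genome_seed(genes: np.ndarray) -> int:
    digest = hashlib.blake2b(np.ascontiguousarray(genes, dtype=np.float64).tobytes(),
                             digest_size=8).digest()
    return int.from_bytes(digest, "little")


def _noise_field(genes: np.ndarray, size: tuple[int, int],
                 scale: float, orientation: float, elongation: float) -> np.ndarray:
    """Band-limited anisotropic noise field, deterministic per genome."""
    w, h = size
    rng = np.random.default_rng(_genome_seed(genes))
    noise = rng.standard_normal((h, w))
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    c, s = np.cos(orientation), np.sin(orientation)
    u = fx * c + fy * s
    v = -fx * s + fy * c
    # Gaussian low-pass with correlation length ~ scale, stretched along u
    transfer = np.exp(-0.5 * ((u * scale * elongation) ** 2 + (v * scale / elongation) ** 2)
                      * (2.0 * np.pi ** 2) / 4.0)
    out = np.fft.ifft2(np.fft.fft2(noise) * transfer).real
    sd = out.std()
    return out / sd if sd > 0 else out


def render_target(p: PhenotypeParams, size_px: tuple[int, int] = (128, 96),
                  genome: Genome | None = None) -> TargetImage:
    """Render a phenotype as an oval target image.

    Colour patches are assigned by thresholding the noise field at the
    quantiles given by the coverage proportions, painted in CIELAB and
    optionally blurred (so blended boundary colours stay inside the
    colour box), then converted to sRGB.
    """
    w, h = size_px
    if w < 16 or h < 16:
        raise ValueError("target size must be at least 16 x 16 px")
    genes = genome.genes if genome is not None else np.concatenate([
        np.array([c.L for c in p.palette]),  # any deterministic fallback seed
        np.array([c.a for c in p.palette]),
    ])
    fld = _noise_field(np.asarray(genes, float), (w, h),
                       p.pattern_scale, p.orientation, p.elongation)
    cum = np.cumsum(p.pattern_proportions)[:-1]
    thresholds = np.quantile(fld, cum)
    index = np.searchsorted(thresholds, fld, side="right")
    palette_lab = np.array([c.as_array() for c in p.palette])
    lab_img = palette_lab[index]
    if p.edge_softness > 1e-3:
        for ch in range(3):
            lab_img[..., ch] = gaussian_filter(lab_img[..., ch], p.edge_softness,
                                               mode="nearest")
    rgb = lab_to_srgb(lab_img)
    mask = _ellipse_mask(w, h)
    rgb = np.where(mask[..., None], rgb, 0).astype(np.uint8)
    gid = genome.id if genome is not None else "anonymous"
    return TargetImage(rgb, mask, gid)


def render_genome(g: Genome, space: ColourSpaceBox,
                  size_px: tuple[int, int] = (128, 96)) -> TargetImage:
    """Decode and render in one step (the noise field is seeded from ``g``)."""
    return render_target(decode_genome(g, space), size_px, genome=g)


# ---------------------------------------------------------------------------
# GA operators

def mutate(g: Genome, rate: float, magnitude: float,
           rng: np.random.Generator, child_id: str | None = None) -> Genome:
    """Perturb each gene with probability ``rate`` by N(0, magnitude),
    reflecting back into [0, 1]."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    hit = rng.random(g.genes.shape[0]) < rate
    delta = rng.normal(0.0, magnitude, g.genes.shape[0])
    genes = g.genes + np.where(hit, delta, 0.0)
    # reflect into [0, 1] (handles overshoot of any size)
    genes = np.abs(genes) % 2.0
    genes = np.where(genes > 1.0, 2.0 - genes, genes)
    return Genome(genes, child_id or g.id, g.parent_ids)


def crossover(a: Genome, b: Genome, rng: np.random.Generator,
              child_id: str = "child") -> Genome:
    """Uniform crossover: each gene comes from either parent with p = 1/2."""
    if a.genes.shape[0] != b.genes.shape[0]:
        raise ValueError("parent genomes must have equal length")
    from_a = rng.random(a.genes.shape[0]) < 0.5
    genes = np.where(from_a, a.genes, b.genes)
    return Genome(genes, child_id, (a.id, b.id))


# ---------------------------------------------------------------------------
# serialisation

def genomes_to_frame(genomes: list[Genome], generation: int) -> pd.DataFrame:
    rows = []
    for g in genomes:
        row = {"id": g.id, "generation": generation,
               "parent_ids": ";".join(g.parent_ids)}
        for k, v in enumerate(g.genes):
            row[f"g{k:02d}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


#: float format that round-trips float64 exactly through CSV
GENE_FLOAT_FORMAT = "%.17g"


def read_genome_csv(path_or_buf) -> pd.DataFrame:
    """Read a genome table with exact float round-tripping (pandas' fast
    parser can be off by one ulp)."""
    return pd.read_csv(path_or_buf, float_precision="round_trip")


def genomes_from_frame(df: pd.DataFrame) -> list[Genome]:
    gene_cols = sorted(c for c in df.columns if c.startswith("g") and c[1:].isdigit())
    out = []
    for _, row in df.iterrows():
        raw = row.get("parent_ids", "")
        raw = "" if pd.isna(raw) else str(raw)
        parents = tuple(p for p in raw.split(";") if p)
        out.append(Genome(row[gene_cols].to_numpy(dtype=float), str(row["id"]), parents))
    return out
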