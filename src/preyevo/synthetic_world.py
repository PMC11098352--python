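"""Procedural backgrounds, a simulated observer, and the closed evolution loop.

This module lets every stage of the pipeline run at desk scale with no
field data: backgrounds are band-limited noise textures (optionally with
"wavy furrow" luminance ridges), and the observer attacks prey in an
order drawn from a softmax over a weighted combination of camouflage
metrics, truncated like a field trial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .camo_metrics import (
    GranularitySpectrum,
    background_colour_clusters,
    compute_metrics,
    granularity_spectrum,
)
from .colour_vision import (
    VisualSystem,
    lab_to_srgb,
    narrow_space_from_background,
)
from .evolution_engine import (
    GenerationRecord,
    RunConfig,
    advance_generation,
    initial_population,
    ranks_from_attacks,
    save_generation,
)
from .genome_pattern import render_genome

__all__ = [
    "BackgroundSpec",
    "ObserverModel",
    "generate_background",
    "attack_order_from_detectability",
    "simulate_attack_order",
    "run_closed_loop",
    "trend_report",
]


@dataclass(frozen=True)
class BackgroundSpec:
    size: tuple[int, int] = (512, 512)          # (width, height) px
    mean_lab: tuple[float, float, float] = (55.0, 5.0, 25.0)
    texture_scale: float = 16.0                  # correlation length, px
    texture_contrast: float = 8.0                # L-channel noise sd
    chroma_contrast: float = 4.0                 # a/b-channel noise sd
    furrow_amplitude: float = 0.0                # L-units; 0 = smooth
    furrow_wavelength: float = 128.0             # px
    seed: int = 0

    def __post_init__(self) -> None:
        if self.furrow_amplitude < 0:
            raise ValueError("furrow amplitude must be non-negative")
        if self.furrow_wavelength <= 0:
            raise ValueError("furrow wavelength must be positive")

    def to_dict(self) -> dict:
        return {"size": list(self.size), "mean_lab": list(self.mean_lab),
                "texture_scale": self.texture_scale,
                "texture_contrast": self.texture_contrast,
                "chroma_contrast": self.chroma_contrast,
                "furrow_amplitude": self.furrow_amplitude,
                "furrow_wavelength": self.furrow_wavelength, "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "BackgroundSpec":
        d = dict(d)
        d["size"] = tuple(d["size"])
        d["mean_lab"] = tuple(d["mean_lab"])
        return cls(**d)


@dataclass(frozen=True)
class ObserverModel:
    """Detectability = weights . (dS, dL, 1 - GabRat, pattern difference);
    attacks are drawn sequentially with probability proportional to
    exp(detectability / tau), without replacement."""

    weights: tuple[float, float, float, float] = (1.0, 1.0, 0.0, 0.0)
    tau: float = 0.5
    max_attacks: int | None = 3

    def __post_init__(self) -> None:
        if not any(w > 0 for w in self.weights):
            raise ValueError("observer needs at least one positive weight")
        if not np.isfinite(self.tau) or self.tau < 0:
            raise ValueError("tau must be finite and non-negative")

    def required_metrics(self) -> tuple[str, ...]:
        names = ("delta_s_mean", "delta_l_mean", "gabrat", "pattern_difference")
        req = [n for n, w in zip(names, self.weights) if w != 0]
        if "delta_s_mean" not in req and self.weights[1] != 0:
            req.append("delta_s_mean")  # dS/dL computed together anyway
        return tuple(req)

    def detectability(self, m) -> float:
        w = self.weights
        parts = (m.delta_s_mean, m.delta_l_mean,
                 1.0 - m.gabrat if w[2] else 0.0,
                 m.pattern_difference if w[3] else 0.0)
        return float(sum(wi * p for wi, p in zip(w, parts) if wi != 0))

    def to_dict(self) -> dict:
        return {"weights": list(self.weights), "tau": self.tau,
                "max_attacks": self.max_attacks}


# ---------------------------------------------------------------------------
# background generation

def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  scale: float) -> np.ndarray:
    """Unit-variance noise with correlation length ~ ``scale`` px."""
    noise = rng.standard_normal(shape)
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    transfer = np.exp(-0.5 * ((fx * scale) ** 2 + (fy * scale) ** 2)
                      * (2.0 * np.pi ** 2) / 4.0)
    out = np.fft.ifft2(np.fft.fft2(noise) * transfer).real
    sd = out.std()
    return out / sd if sd > 0 else out


def generate_background(spec: BackgroundSpec) -> np.ndarray:
    """Render a background texture as an 8-bit sRGB image (H x W x 3).

    Deterministic per spec/seed. A non-zero furrow amplitude adds
    low-frequency sinusoidal luminance ridges whose phase meanders with
    smooth noise ("wavy" furrows).
    """
    w, h = spec.size
    rng = np.random.default_rng(spec.seed)
    L = spec.mean_lab[0] + spec.texture_contrast * _smooth_noise(rng, (h, w),
                                                                 spec.texture_scale)
    a = spec.mean_lab[1] + spec.chroma_contrast * _smooth_noise(rng, (h, w),
                                                                spec.texture_scale)
    b = spec.mean_lab[2] + spec.chroma_contrast * _smooth_noise(rng, (h, w),
                                                                spec.texture_scale)
    if spec.furrow_amplitude > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        theta = rng.uniform(0, np.pi)
        meander = _smooth_noise(rng, (h, w), spec.furrow_wavelength)
        phase = (xx * np.cos(theta) + yy * np.sin(theta)
                 + 0.25 * spec.furrow_wavelength * meander)
        L = L + spec.furrow_amplitude * np.sin(2 * np.pi * phase
                                               / spec.furrow_wavelength)
    lab = np.dstack([np.clip(L, 0.0, 100.0), a, b])
    return lab_to_srgb(lab)


# ---------------------------------------------------------------------------
# simulated observer

def attack_order_from_detectability(d: np.ndarray, tau: float,
                                    max_attacks: int | None,
                                    rng: np.random.Generator) -> list[int]:
    """Sequential softmax sampling without replacement over detectability.

    tau -> 0 reduces to deterministic descending-detectability order;
    large tau approaches a uniform random order.
    """
    d = np.asarray(d, dtype=float)
    remaining = list(range(d.shape[0]))
    order: list[int] = []
    n_draw = len(remaining) if max_attacks is None else min(max_attacks,
                                                            len(remaining))
    for _ in range(n_draw):
        dv = d[remaining]
        if tau <= 1e-12:
            pick = int(np.argmax(dv))
        else:
            z = (dv - dv.max()) / tau
            p = np.exp(z)
            p /= p.sum()
            pick = int(rng.choice(len(remaining), p=p))
        order.append(remaining.pop(pick))
    return order


def simulate_attack_order(targets, positions, bg: np.ndarray,
                          obs: ObserverModel, vs: VisualSystem,
                          rng: np.random.Generator, seed: int = 0,
                          bg_clusters=None, bg_spectrum=None) -> list[int]:
    """Attack order (indices into ``targets``) for one group of prey.

    Detectability of each target is the observer-weighted combination of
    its camouflage metrics against ``bg``; ``positions`` (optional list
    of (row, col) top-left corners) only matter for edge-disruption
    compositing.
    """
    if len(targets) == 0:
        raise ValueError("need at least one target")
    which = obs.required_metrics()
    d = []
    for i, t in enumerate(targets):
        pos = None if positions is None else positions[i]
        m = compute_metrics(t, bg, vs, which=which, seed=seed,
                            bg_clusters=bg_clusters, bg_spectrum=bg_spectrum,
                            position=pos)
        d.append(obs.detectability(m))
    return attack_order_from_detectability(np.array(d), obs.tau,
                                           obs.max_attacks, rng)


# ---------------------------------------------------------------------------
# closed loop

DEFAULT_LOOP_METRICS = ("delta_s_mean", "delta_l_mean", "delta_s_weighted")


def run_closed_loop(cfg: RunConfig, bg_spec: BackgroundSpec,
                    obs: ObserverModel, vs: VisualSystem, out_dir,
                    colour_space: str = "full",
                    metrics: tuple[str, ...] = DEFAULT_LOOP_METRICS,
                    narrow_k: float = 2.0,
                    write_images: bool = False) -> dict:
    """Run a complete evolution experiment against a synthetic background.

    Generations 0 .. final_generation - 1 are scored by the simulated
    observer; one extra unscored generation is produced at the end (so
    ``final_generation + 1`` populations are written in total). All
    randomness flows through one generator seeded from ``cfg.seed``, so
    re-running with the same inputs reproduces every output byte.

    Writes ``gen_NNN/`` directories (genomes.csv, ranks.csv,
    record.json, optionally ``targets/``), a run-level ``metrics.csv``,
    and ``summary.json``; returns the summary dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bg = generate_background(bg_spec)
    if colour_space == "narrow":
        cfg = replace(cfg, colour_box=narrow_space_from_background(bg, narrow_k))
    elif colour_space != "full":
        raise ValueError("colour_space must be 'full' or 'narrow'")

    metric_set = tuple(dict.fromkeys(metrics + obs.required_metrics()))
    bg_clusters = (background_colour_clusters(bg, seed=cfg.seed)
                   if "delta_s_weighted" in metric_set else None)
    bg_spectrum = (granularity_spectrum(bg)
                   if "pattern_difference" in metric_set else None)

    rng = np.random.default_rng(cfg.seed)
    rec = GenerationRecord(initial_population(cfg, rng), seed=cfg.seed,
                           mode=cfg.selection_mode)
    prev: GenerationRecord | None = None
    rows: list[dict] = []

    def score_generation(record: GenerationRecord, scored: bool):
        pop = record.population
        targets = [render_genome(g, cfg.colour_box, cfg.target_size)
                   for g in pop.genomes]
        results = []
        for t in targets:
            m = compute_metrics(t, bg, vs, which=metric_set, seed=cfg.seed,
                                bg_clusters=bg_clusters, bg_spectrum=bg_spectrum)
            results.append(m)
            row = {"generation": pop.generation, **m.as_dict()}
            rows.append(row)
        if write_images:
            tdir = out_dir / f"gen_{pop.generation:03d}" / "targets"
            tdir.mkdir(parents=True, exist_ok=True)
            for t in targets:
                t.save(tdir / f"{t.genome_id}.png")
        if not scored:
            return None
        attacks = []
        ids = pop.ids()
        for grp in range(cfg.n_groups):
            sl = slice(grp * cfg.group_size, (grp + 1) * cfg.group_size)
            d = np.array([obs.detectability(m) for m in results[sl]])
            order = attack_order_from_detectability(
                d, obs.tau, obs.max_attacks, rng)
            for ai, local in enumerate(order, start=1):
                attacks.append((ids[sl][local], ai))
        return ranks_from_attacks(attacks, pop, cfg, rng)

    for gen in range(cfg.final_generation):
        rec.rank_table = score_generation(rec, scored=True)
        nxt = advance_generation(rec, prev, cfg, rng)
        save_generation(out_dir, rec)
        prev, rec = rec, nxt

    score_generation(rec, scored=False)  # extra, unscored final generation
    save_generation(out_dir, rec)

    metrics_df = pd.DataFrame(rows)
    col_order = ["generation", "target_id", "background_id",
                 "delta_s_mean", "delta_l_mean", "delta_s_weighted",
                 "pattern_difference", "gabrat"]
    metrics_df = metrics_df[[c for c in col_order if c in metrics_df.columns]]
    metrics_df.to_csv(out_dir / "metrics.csv", index=False)

    per_gen = metrics_df.drop(columns=["target_id", "background_id"]) \
        .groupby("generation").mean()
    summary = {
        "config": cfg.to_dict(),
        "background": bg_spec.to_dict(),
        "observer": obs.to_dict(),
        "colour_space": colour_space,
        "n_generations_written": cfg.final_generation + 1,
        "generation_means": {m: per_gen[m].tolist() for m in per_gen.columns},
    }
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


# ---------------------------------------------------------------------------
# trend analysis

def trend_report(metrics_by_generation: pd.DataFrame,
                 metric_cols: list[str] | None = None,
                 population_col: str | None = None,
                 n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """OLS slope of generation-mean metrics vs generation, with a
    bootstrap confidence interval.

    Resamples generation points with replacement ``n_boot`` times; the
    direction flag is the slope's sign when the 95% CI excludes zero,
    else 0. Requires at least three generations.
    """
    df = metrics_by_generation
    if "generation" not in df.columns:
        raise ValueError("need a 'generation' column")
    if metric_cols is None:
        skip = {"generation", "target_id", "background_id"}
        if population_col:
            skip.add(population_col)
        metric_cols = [c for c in df.columns if c not in skip
                       and pd.api.types.is_numeric_dtype(df[c])]
    group_keys = [population_col] if population_col else []
    rng = np.random.default_rng(seed)
    out_rows = []
    for keys, sub in (df.groupby(population_col) if population_col
                      else [(None, df)]):
        per_gen = sub.groupby("generation")[metric_cols].mean().sort_index()
        g = per_gen.index.to_numpy(dtype=float)
        if g.shape[0] < 3:
            raise ValueError("trend report needs at least three generations")
        for m in metric_cols:
            y = per_gen[m].to_numpy(dtype=float)
            slope = float(np.polyfit(g, y, 1)[0])
            boots = np.empty(n_boot)
            for i in range(n_boot):
                while True:
                    idx = rng.integers(0, g.shape[0], g.shape[0])
                    if np.unique(g[idx]).shape[0] >= 2:
                        break
                boots[i] = np.polyfit(g[idx], y[idx], 1)[0]
            lo, hi = np.percentile(boots, [2.5, 97.5])
            direction = 0
            if lo > 0:
                direction = 1
            elif hi < 0:
                direction = -1
            row = {"metric": m, "slope": slope, "ci_lo": float(lo),
                   "ci_hi": float(hi), "direction": direction}
            if population_col:
                row[population_col] = keys
            out_rows.append(row)
    return pd.DataFrame(out_rows)
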