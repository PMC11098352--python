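"""Arena assignment, manifests, print sheets, and attack-record parsing.

Prey are laid out in square trays; within a tray the four slots are
labelled by string colour in a fixed left-to-right order (red, green,
blue, yellow) so that field observations can address prey by colour.
Positions are rejection-sampled to keep a minimum pairwise distance,
standing in for the pseudo-randomised anti-clustering layout.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .evolution_engine import Population, RunConfig
from .genome_pattern import TargetImage

__all__ = [
    "SLOT_COLOURS",
    "ArenaSlot",
    "ArenaAssignment",
    "AttackRecord",
    "assign_arenas",
    "export_manifest",
    "parse_manifest",
    "parse_attack_csv",
    "export_print_sheet",
]

#: Fixed slot-colour order, leftmost to rightmost.
SLOT_COLOURS = ("red", "green", "blue", "yellow")

MANIFEST_HEADER = ["generation", "day", "tray", "slot", "colour",
                   "x_mm", "y_mm", "prey_id", "image"]


@dataclass(frozen=True)
class ArenaSlot:
    prey_id: str
    generation: int
    day: int
    tray: int
    slot: int          # 1..group_size, left to right
    colour: str
    x_mm: float
    y_mm: float


@dataclass(frozen=True)
class ArenaAssignment:
    slots: tuple[ArenaSlot, ...]
    tray_size_mm: float = 530.0

    def __len__(self) -> int:
        return len(self.slots)

    def by_tray(self) -> dict[tuple[int, int], list[ArenaSlot]]:
        out: dict[tuple[int, int], list[ArenaSlot]] = {}
        for s in self.slots:
            out.setdefault((s.day, s.tray), []).append(s)
        return out

    def prey_at(self, tray: int, slot: int, day: int | None = None) -> str:
        """Prey id at a tray slot; ``day`` disambiguates when the same tray
        is reused across days."""
        for s in self.slots:
            if s.tray == tray and s.slot == slot and \
                    (day is None or s.day == day):
                return s.prey_id
        raise KeyError(f"no prey at tray {tray}, slot {slot}, day {day}")

    def group_index(self, prey_id: str, cfg: RunConfig) -> int:
        """Tray-days enumerate the groups: group = (day-1)*n_trays + tray-1."""
        n_trays = {s.tray for s in self.slots}
        for s in self.slots:
            if s.prey_id == prey_id:
                return (s.day - 1) * len(n_trays) + (s.tray - 1)
        raise KeyError(prey_id)


@dataclass(frozen=True)
class AttackRecord:
    prey_id: str
    attack_index: int
    tray: int = 0
    generation: int = 0
    run_id: str = ""
    source: str = "manual"

    def __post_init__(self) -> None:
        if self.attack_index < 1:
            raise ValueError("attack_index must be >= 1")


# ---------------------------------------------------------------------------

def _sample_positions(n: int, tray_mm: float, d_min: float,
                      rng: np.random.Generator, max_retries: int = 1000
                      ) -> np.ndarray:
    margin = 20.0
    lo, hi = margin, tray_mm - margin
    for _ in range(max_retries):
        pts = rng.uniform(lo, hi, size=(n, 2))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        if d.min() >= d_min:
            return pts
    raise RuntimeError(f"could not place {n} prey with d_min={d_min} mm in a "
                       f"{tray_mm} mm tray after {max_retries} retries")


def assign_arenas(pop: Population, cfg: RunConfig, rng: np.random.Generator,
                  tray_size_mm: float = 530.0, d_min_mm: float = 100.0,
                  n_trays: int = 3) -> ArenaAssignment:
    """Assign the population to tray-days with anti-clustered positions.

    Groups are consecutive blocks of ``group_size`` prey; they are
    scheduled across ``n_trays`` trays per day (default three trays over
    two days for six groups). Within a tray, slots and colour labels run
    left to right in the fixed colour order.
    """
    if cfg.population_size % cfg.group_size != 0:
        raise ValueError("population size must be divisible by group size")
    if cfg.group_size > len(SLOT_COLOURS):
        raise ValueError("more slots per tray than colour labels")
    ids = pop.ids()
    slots: list[ArenaSlot] = []
    for grp in range(cfg.n_groups):
        members = ids[grp * cfg.group_size:(grp + 1) * cfg.group_size]
        day = grp // n_trays + 1
        tray = grp % n_trays + 1
        pts = _sample_positions(len(members), tray_size_mm, d_min_mm, rng)
        x_order = np.argsort(pts[:, 0])
        for slot_idx, member_idx in enumerate(x_order):
            slots.append(ArenaSlot(
                prey_id=members[member_idx],
                generation=pop.generation,
                day=day, tray=tray,
                slot=slot_idx + 1,
                colour=SLOT_COLOURS[slot_idx],
                x_mm=float(pts[member_idx, 0]),
                y_mm=float(pts[member_idx, 1]),
            ))
    return ArenaAssignment(tuple(slots), tray_size_mm)


def export_manifest(asg: ArenaAssignment, path) -> None:
    """Write the assignment as CSV (UTF-8, LF, fixed header)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(MANIFEST_HEADER)
        for s in sorted(asg.slots, key=lambda s: (s.day, s.tray, s.slot)):
            w.writerow([s.generation, s.day, s.tray, s.slot, s.colour,
                        repr(s.x_mm), repr(s.y_mm), s.prey_id,
                        f"{s.prey_id}.png"])


def parse_manifest(path) -> ArenaAssignment:
    slots = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != MANIFEST_HEADER:
            raise ValueError(f"unexpected manifest header: {reader.fieldnames}")
        for row in reader:
            slots.append(ArenaSlot(
                prey_id=row["prey_id"],
                generation=int(row["generation"]),
                day=int(row["day"]), tray=int(row["tray"]),
                slot=int(row["slot"]), colour=row["colour"],
                x_mm=float(row["x_mm"]), y_mm=float(row["y_mm"]),
            ))
    return ArenaAssignment(tuple(slots))


# ---------------------------------------------------------------------------

def _parse_tray(token: str, row_no: int) -> int:
    t = token.strip().lower()
    if t.startswith("tray"):
        t = t[4:]
    if not t.isdigit():
        raise ValueError(f"row {row_no}: cannot parse tray {token!r}")
    return int(t)


def parse_attack_csv(path, cfg: RunConfig,
                     assignment: ArenaAssignment | None = None
                     ) -> list[AttackRecord]:
    """Parse attack records from CSV with columns tray, prey, attack_index.

    The ``prey`` column accepts a prey id, a slot number, or a slot-colour
    name (resolved through ``assignment``; an optional ``day`` column
    disambiguates trays reused across days). Raises descriptive errors
    naming the offending row for duplicate or non-monotone attack indices
    within a tray.
    """
    records: list[AttackRecord] = []
    seen_idx: dict[tuple, list[int]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"tray", "prey", "attack_index"}
        if not required.issubset(set(reader.fieldnames or [])):
            raise ValueError(f"attack CSV must have columns {sorted(required)}")
        for row_no, row in enumerate(reader, start=2):
            tray = _parse_tray(row["tray"], row_no)
            day = int(row["day"]) if row.get("day") else None
            token = row["prey"].strip()
            idx = int(row["attack_index"])
            if token.lower() in SLOT_COLOURS:
                if assignment is None:
                    raise ValueError(f"row {row_no}: colour addressing needs an "
                                     f"arena assignment")
                slot = SLOT_COLOURS.index(token.lower()) + 1
                prey_id = assignment.prey_at(tray, slot, day)
            elif token.isdigit():
                if assignment is None:
                    raise ValueError(f"row {row_no}: slot addressing needs an "
                                     f"arena assignment")
                slot = int(token)
                if not 1 <= slot <= cfg.group_size:
                    raise ValueError(f"row {row_no}: slot {slot} out of range")
                prey_id = assignment.prey_at(tray, slot, day)
            else:
                prey_id = token
            idx_list = seen_idx.setdefault((day, tray), [])
            if idx in idx_list:
                raise ValueError(f"row {row_no}: duplicate attack_index {idx} "
                                 f"in tray {tray}")
            if idx_list and idx < max(idx_list):
                raise ValueError(f"row {row_no}: attack_index {idx} in tray "
                                 f"{tray} is not increasing")
            idx_list.append(idx)
            records.append(AttackRecord(prey_id=prey_id, attack_index=idx,
                                        tray=tray))
    return records


# ---------------------------------------------------------------------------

def export_print_sheet(targets: list[TargetImage], path,
                       grid: tuple[int, int] = (4, 6), dpi: float = 300.0,
                       cell_mm: tuple[float, float] = (18.0, 14.0),
                       caption_px: int = 12) -> None:
    """Deterministic labelled print sheet: a grid of targets at a stated
    physical scale (default 18 x 14 mm cells)."""
    cols, rows = grid
    if cols * rows < len(targets):
        raise ValueError(f"grid {grid} too small for {len(targets)} targets")
    px_per_mm = dpi / 25.4
    cw = int(round(cell_mm[0] * px_per_mm))
    ch = int(round(cell_mm[1] * px_per_mm))
    pad = 8
    W = cols * (cw + pad) + pad
    H = rows * (ch + caption_px + pad) + pad
    page = Image.new("RGB", (W, H), (255, 255, 255))
    draw = ImageDraw.Draw(page)
    for k, t in enumerate(targets):
        r, c = divmod(k, cols)
        x0 = pad + c * (cw + pad)
        y0 = pad + r * (ch + caption_px + pad)
        tile = Image.fromarray(t.to_rgba(), "RGBA").resize((cw, ch), Image.NEAREST)
        page.paste(tile, (x0, y0), tile)
        draw.text((x0, y0 + ch), t.genome_id, fill=(0, 0, 0))
    page.save(path, format="PNG", dpi=(dpi, dpi))
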