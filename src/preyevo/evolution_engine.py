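"""The genetic algorithm: ranks from attack order, survivor selection with
the rescue rule, breeding, a random-drift control mode, and generation
bookkeeping.

Selection follows the tray protocol: prey are ranked 1..group_size by
attack order within each group (1 = first attacked; unattacked prey get
the remaining top ranks in seeded-random order). The last two attacked
per group (ranks 3 and 4 for groups of four) survive and reproduce. The
rescue rule additionally keeps any prey ranked 1 or 2 now that held the
highest possible rank in the previous generation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .colour_vision import ColourSpaceBox, FULL_BOX
from .genome_pattern import (
    GENE_FLOAT_FORMAT,
    Genome,
    crossover,
    genomes_from_frame,
    genomes_to_frame,
    mutate,
    random_genome,
    read_genome_csv,
)

__all__ = [
    "RunConfig",
    "RankEntry",
    "RankTable",
    "Population",
    "GenerationRecord",
    "ranks_from_attacks",
    "select_survivors",
    "breed_next_generation",
    "random_control_selection",
    "advance_generation",
    "save_generation",
    "load_generation",
    "count_evolved_prey",
    "simulate_run_structure",
]


@dataclass(frozen=True)
class RunConfig:
    """Run-level configuration. ``final_generation`` is the index of the
    extra, unscored population produced after the last scored trial
    (scored generations are 0 .. final_generation - 1)."""

    population_size: int = 24
    group_size: int = 4
    n_groups: int = 6
    final_generation: int = 11
    colour_box: ColourSpaceBox = FULL_BOX
    mutation_rate: float = 0.2
    # 0.05 keeps the selection response going across ~16 generations instead
    # of hitting mutation-selection balance after a handful
    mutation_magnitude: float = 0.05
    selection_mode: str = "ranked"  # "ranked" | "random-control"
    seed: int = 0
    min_attacked_per_group: int = 3
    target_size: tuple[int, int] = (128, 96)
    panmictic: bool = True

    def __post_init__(self) -> None:
        if self.population_size != self.group_size * self.n_groups:
            raise ValueError("population_size must equal group_size * n_groups")
        if self.selection_mode not in ("ranked", "random-control"):
            raise ValueError("selection_mode must be 'ranked' or 'random-control'")
        if not 1 <= self.min_attacked_per_group <= self.group_size:
            raise ValueError("min_attacked_per_group out of range")

    def to_dict(self) -> dict:
        return {
            "population_size": self.population_size,
            "group_size": self.group_size,
            "n_groups": self.n_groups,
            "final_generation": self.final_generation,
            "colour_box": self.colour_box.to_dict(),
            "mutation_rate": self.mutation_rate,
            "mutation_magnitude": self.mutation_magnitude,
            "selection_mode": self.selection_mode,
            "seed": self.seed,
            "min_attacked_per_group": self.min_attacked_per_group,
            "target_size": list(self.target_size),
            "panmictic": self.panmictic,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "colour_box" in d:
            d["colour_box"] = ColourSpaceBox.from_dict(d["colour_box"])
        if "target_size" in d:
            d["target_size"] = tuple(d["target_size"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class RankEntry:
    prey_id: str
    group: int
    slot: int
    attack_index: int | None  # 1..group_size, None if never attacked
    fitness_rank: int         # 1 = first attacked ... group_size = last/unattacked


class RankTable:
    """Per-prey fitness ranks; ranks form a permutation within each group."""

    def __init__(self, entries: list[RankEntry], group_size: int):
        self.entries = {e.prey_id: e for e in entries}
        self.group_size = group_size
        if len(self.entries) != len(entries):
            raise ValueError("duplicate prey id in rank table")
        by_group: dict[int, list[int]] = {}
        for e in entries:
            by_group.setdefault(e.group, []).append(e.fitness_rank)
        for grp, ranks in by_group.items():
            if sorted(ranks) != list(range(1, group_size + 1)):
                raise ValueError(f"group {grp}: ranks are not a permutation of "
                                 f"1..{group_size}")

    def __getitem__(self, prey_id: str) -> RankEntry:
        return self.entries[prey_id]

    def __contains__(self, prey_id: str) -> bool:
        return prey_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def ids(self) -> set[str]:
        return set(self.entries)

    def groups(self) -> dict[int, list[RankEntry]]:
        out: dict[int, list[RankEntry]] = {}
        for e in self.entries.values():
            out.setdefault(e.group, []).append(e)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [{"prey_id": e.prey_id, "group": e.group, "slot": e.slot,
                 "attack_index": -1 if e.attack_index is None else e.attack_index,
                 "fitness_rank": e.fitness_rank}
                for e in sorted(self.entries.values(),
                                key=lambda e: (e.group, e.slot))]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, group_size: int) -> "RankTable":
        entries = [RankEntry(str(r.prey_id), int(r.group), int(r.slot),
                             None if int(r.attack_index) < 0 else int(r.attack_index),
                             int(r.fitness_rank))
                   for r in df.itertuples()]
        return cls(entries, group_size)


@dataclass(frozen=True)
class Population:
    generation: int
    genomes: tuple[Genome, ...]
    provenance: dict = field(default_factory=dict)  # prey_id -> flag

    def __post_init__(self) -> None:
        if self.generation < 0:
            raise ValueError("generation index must be non-negative")
        object.__setattr__(self, "genomes", tuple(self.genomes))

    def __len__(self) -> int:
        return len(self.genomes)

    def ids(self) -> list[str]:
        return [g.id for g in self.genomes]

    def group_of(self, index: int, group_size: int) -> int:
        return index // group_size


@dataclass
class GenerationRecord:
    population: Population
    rank_table: RankTable | None = None
    survivor_ids: set[str] = field(default_factory=set)
    rescue_ids: set[str] = field(default_factory=set)
    seed: int | None = None
    mode: str = "ranked"


# ---------------------------------------------------------------------------

def initial_population(cfg: RunConfig, rng: np.random.Generator,
                       generation: int = 0) -> Population:
    genomes = [random_genome(rng, cfg.colour_box, f"g{generation}_{i:03d}")
               for i in range(cfg.population_size)]
    prov = {g.id: "founder" for g in genomes}
    return Population(generation, tuple(genomes), prov)


def ranks_from_attacks(attacks, pop: Population, cfg: RunConfig,
                       rng: np.random.Generator) -> RankTable:
    """Build a rank table from attack records.

    ``attacks`` is a sequence of objects with ``prey_id`` and
    ``attack_index`` attributes (e.g. :class:`preyevo.field_io.AttackRecord`
    after prey-id resolution) or (prey_id, attack_index) pairs. Prey never
    attacked share the remaining top ranks in seeded-random order.
    """
    ids = pop.ids()
    id_to_idx = {pid: i for i, pid in enumerate(ids)}
    seen: dict[str, int] = {}
    for a in attacks:
        pid, ai = (a.prey_id, a.attack_index) if hasattr(a, "prey_id") else a
        if pid not in id_to_idx:
            raise ValueError(f"unknown prey id in attack record: {pid!r}")
        if pid in seen:
            raise ValueError(f"duplicate attack recorded for prey {pid!r}")
        seen[pid] = int(ai)

    entries = []
    for grp in range(cfg.n_groups):
        members = ids[grp * cfg.group_size:(grp + 1) * cfg.group_size]
        attacked = sorted((pid for pid in members if pid in seen),
                          key=lambda pid: seen[pid])
        order = [seen[pid] for pid in attacked]
        if order != sorted(order) or len(set(order)) != len(order):
            raise ValueError(f"group {grp}: attack indices must be strictly "
                             f"increasing and unique")
        unattacked = [pid for pid in members if pid not in seen]
        perm = rng.permutation(len(unattacked))
        ranked = attacked + [unattacked[i] for i in perm]
        for rank, pid in enumerate(ranked, start=1):
            slot = members.index(pid) + 1
            entries.append(RankEntry(pid, grp, slot, seen.get(pid), rank))
    return RankTable(entries, cfg.group_size)


def select_survivors(current: RankTable, previous: RankTable | None,
                     cfg: RunConfig) -> tuple[set[str], set[str]]:
    """Survivors = {last two attacked per group} plus rescues.

    A prey is rescued when its current rank is 1 or 2 but its rank in the
    previous generation was the highest possible (= group_size). Rescue
    matches prey by id; ids absent from the previous table simply have no
    previous rank, so they cannot be rescued.
    """
    survivors: set[str] = set()
    rescues: set[str] = set()
    for grp, entries in current.groups().items():
        for e in entries:
            if e.fitness_rank > cfg.group_size - 2:
                survivors.add(e.prey_id)
            elif (previous is not None and e.fitness_rank in (1, 2)
                  and e.prey_id in previous
                  and previous[e.prey_id].fitness_rank == cfg.group_size):
                survivors.add(e.prey_id)
                rescues.add(e.prey_id)
    return survivors, rescues


def random_control_selection(pop: Population, cfg: RunConfig,
                             rng: np.random.Generator) -> set[str]:
    """Drift control: 2 survivors per group chosen uniformly, ignoring ranks."""
    ids = pop.ids()
    survivors: set[str] = set()
    n_keep = 2
    for grp in range(cfg.n_groups):
        members = ids[grp * cfg.group_size:(grp + 1) * cfg.group_size]
        pick = rng.choice(len(members), size=n_keep, replace=False)
        survivors.update(members[i] for i in pick)
    return survivors


def breed_next_generation(survivors: list[Genome], cfg: RunConfig,
                          rng: np.random.Generator,
                          generation: int) -> Population:
    """Produce a full population of offspring from the survivor pool.

    Each child: two distinct parents drawn uniformly from the pool,
    uniform crossover, then mutation. Lineage is recorded in parent_ids.
    """
    if len(survivors) < 2:
        raise ValueError("breeding needs at least two survivors")
    children = []
    for i in range(cfg.population_size):
        pa, pb = rng.choice(len(survivors), size=2, replace=False)
        cid = f"g{generation}_{i:03d}"
        child = crossover(survivors[pa], survivors[pb], rng, cid)
        child = mutate(child, cfg.mutation_rate, cfg.mutation_magnitude, rng, cid)
        children.append(child)
    prov = {c.id: "offspring" for c in children}
    return Population(generation, tuple(children), prov)


def advance_generation(record_N: GenerationRecord,
                       record_prev: GenerationRecord | None,
                       cfg: RunConfig,
                       rng: np.random.Generator) -> GenerationRecord:
    """Select survivors from record_N (with rescue against record_prev) and
    breed the next generation. Fills in record_N's survivor/rescue sets."""
    if record_N.rank_table is None:
        raise ValueError("cannot advance: generation has no rank table")
    if cfg.selection_mode == "random-control":
        survivors = random_control_selection(record_N.population, cfg, rng)
        rescues: set[str] = set()
    else:
        prev_table = record_prev.rank_table if record_prev is not None else None
        survivors, rescues = select_survivors(record_N.rank_table, prev_table, cfg)
    record_N.survivor_ids = survivors
    record_N.rescue_ids = rescues
    pool = [g for g in record_N.population.genomes if g.id in survivors]
    next_pop = breed_next_generation(pool, cfg, rng,
                                     record_N.population.generation + 1)
    return GenerationRecord(next_pop, mode=cfg.selection_mode)


# ---------------------------------------------------------------------------
# persistence

def save_generation(run_dir, record: GenerationRecord) -> Path:
    gen = record.population.generation
    gdir = Path(run_dir) / f"gen_{gen:03d}"
    gdir.mkdir(parents=True, exist_ok=True)
    df = genomes_to_frame(list(record.population.genomes), gen)
    df["provenance"] = [record.population.provenance.get(i, "")
                        for i in df["id"]]
    df.to_csv(gdir / "genomes.csv", index=False, float_format=GENE_FLOAT_FORMAT)
    if record.rank_table is not None:
        record.rank_table.to_frame().to_csv(gdir / "ranks.csv", index=False)
    meta = {
        "generation": gen,
        "mode": record.mode,
        "seed": record.seed,
        "survivor_ids": sorted(record.survivor_ids),
        "rescue_ids": sorted(record.rescue_ids),
    }
    (gdir / "record.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return gdir


def load_generation(run_dir, generation: int, cfg: RunConfig) -> GenerationRecord:
    gdir = Path(run_dir) / f"gen_{generation:03d}"
    df = read_genome_csv(gdir / "genomes.csv")
    genomes = genomes_from_frame(df)
    prov = dict(zip(df["id"].astype(str), df.get("provenance", "")))
    pop = Population(generation, tuple(genomes), prov)
    table = None
    ranks_path = gdir / "ranks.csv"
    if ranks_path.exists():
        table = RankTable.from_frame(pd.read_csv(ranks_path), cfg.group_size)
    meta = json.loads((gdir / "record.json").read_text())
    rec = GenerationRecord(pop, table, set(meta["survivor_ids"]),
                           set(meta["rescue_ids"]), meta.get("seed"),
                           meta.get("mode", "ranked"))
    return rec


# ---------------------------------------------------------------------------
# bookkeeping

def simulate_run_structure(cfg: RunConfig, n_populations: int,
                           seed: int) -> list[list[Population]]:
    """Exercise the generation bookkeeping for one experimental run without
    rendering or metrics: attack order within each group is drawn at
    random, ranks and survivors follow the standard rules, and the extra
    unscored final generation is produced at the end.

    Returns one list of populations (indices 0..final_generation) per
    population line.
    """
    lines = []
    for p in range(n_populations):
        rng = np.random.default_rng((seed, p))
        pops = []
        prev_rec: GenerationRecord | None = None
        rec = GenerationRecord(initial_population(cfg, rng), mode=cfg.selection_mode)
        for gen in range(cfg.final_generation):
            pops.append(rec.population)
            order = rng.permutation(cfg.population_size)
            attacks = []
            for grp in range(cfg.n_groups):
                members = [i for i in order
                           if i // cfg.group_size == grp][:cfg.min_attacked_per_group]
                for ai, idx in enumerate(members, start=1):
                    attacks.append((rec.population.ids()[idx], ai))
            rec.rank_table = ranks_from_attacks(attacks, rec.population, cfg, rng)
            nxt = advance_generation(rec, prev_rec, cfg, rng)
            prev_rec, rec = rec, nxt
        pops.append(rec.population)  # unscored final generation
        lines.append(pops)
    return lines


def count_evolved_prey(lines: list[list[Population]]) -> int:
    """Count prey items in evolved generations (generation >= 1)."""
    return sum(len(pop) for line in lines for pop in line if pop.generation >= 1)
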