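"""Structured-coalescent simulator for neutral windowed-Fst nulls.

Simulates genealogies backwards in time for samples from multiple demes
connected by migration, population-size epochs and split (merge, looking
backwards) events, then drops infinite-sites mutations on branches. A
"window" of L bp is modelled as B independent non-recombining blocks whose
variants are concatenated — a cheap stand-in for intra-window recombination
that preserves its variance-reducing effect on window-mean Fst.

Conventions: time in generations, increasing into the past; population
sizes are diploid N (within-deme pairwise coalescence rate 1/(2N), so k
lineages coalesce at rate k(k-1)/(4N)); migration rates are backwards in
time, m[i->j] = probability per generation that a lineage currently in i
traces its ancestry to j.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genotypes import GenotypeCounts, SiteRecord

__all__ = [
    "SizeEpoch",
    "Population",
    "Split",
    "MigrationEpoch",
    "DemographicModel",
    "SimulatedWindow",
    "load_demography",
    "default_dog_wolf_model",
    "simulate_window",
    "haplotypes_to_genotypes",
    "null_distribution",
    "empirical_exceedance",
    "ExceedanceReport",
]


@dataclass(frozen=True)
class SizeEpoch:
    time: float  # epoch applies from this time (pastwards)
    size: float  # diploid N


@dataclass(frozen=True)
class Population:
    name: str
    epochs: tuple[SizeEpoch, ...]

    def size_at(self, t: float) -> float:
        size = self.epochs[0].size
        for ep in self.epochs:
            if ep.time <= t:
                size = ep.size
            else:
                break
        return size


@dataclass(frozen=True)
class Split:
    """At ``time`` (backwards), lineages in ``derived`` join ``ancestral``."""

    time: float
    derived: str
    ancestral: str


@dataclass(frozen=True)
class MigrationEpoch:
    time: float
    rates: dict[tuple[str, str], float]  # (from, to), backwards in time


@dataclass(frozen=True)
class DemographicModel:
    populations: tuple[Population, ...]
    splits: tuple[Split, ...] = ()
    migration: tuple[MigrationEpoch, ...] = ()
    mutation_rate: float = 1e-8  # per bp per generation
    window_length: int = 500_000
    blocks: int = 50

    def __post_init__(self) -> None:
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")
        times = [s.time for s in self.splits]
        if sorted(times) != times or len(set(times)) != len(times):
            raise ValueError("split times must be strictly increasing")
        for s in self.splits:
            if s.derived not in names or s.ancestral not in names:
                raise ValueError(f"split references unknown population: {s}")
        for ep in self.migration:
            for (src, dst), m in ep.rates.items():
                if m < 0:
                    raise ValueError("migration rates must be >= 0")
                if src not in names or dst not in names:
                    raise ValueError(f"migration references unknown deme {src}>{dst}")
        for p in self.populations:
            ts = [e.time for e in p.epochs]
            if ts != sorted(ts) or ts[0] != 0:
                raise ValueError(
                    f"population {p.name}: epochs must start at 0 and be ordered"
                )
            if any(e.size <= 0 for e in p.epochs):
                raise ValueError(f"population {p.name}: sizes must be positive")

    def population(self, name: str) -> Population:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    def migration_at(self, t: float) -> dict[tuple[str, str], float]:
        rates: dict[tuple[str, str], float] = {}
        for ep in self.migration:
            if ep.time <= t:
                rates = ep.rates
        return rates

    def breakpoints(self) -> list[float]:
        ts: set[float] = set()
        for p in self.populations:
            ts.update(e.time for e in p.epochs)
        ts.update(s.time for s in self.splits)
        ts.update(e.time for e in self.migration)
        ts.discard(0.0)
        return sorted(ts)


def load_demography(path: str | Path) -> DemographicModel:
    """Read a demographic model from a YAML config (documented schema:
    populations with size epochs, splits, migration epochs written as
    '"from>to": rate', mutation_rate, window_length, blocks)."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    pops = tuple(
        Population(
            name=p["name"],
            epochs=tuple(
                SizeEpoch(float(e["time"]), float(e["size"])) for e in p["epochs"]
            ),
        )
        for p in raw["populations"]
    )
    splits = tuple(
        Split(float(s["time"]), s["derived"], s["ancestral"])
        for s in raw.get("splits", [])
    )
    migration = []
    for ep in raw.get("migration", []):
        rates = {}
        for key, m in ep.get("rates", {}).items():
            src, dst = key.split(">")
            rates[(src, dst)] = float(m)
        migration.append(MigrationEpoch(float(ep["time"]), rates))
    return DemographicModel(
        populations=pops,
        splits=splits,
        migration=tuple(migration),
        mutation_rate=float(raw.get("mutation_rate", 1e-8)),
        window_length=int(raw.get("window_length", 500_000)),
        blocks=int(raw.get("blocks", 50)),
    )


def default_dog_wolf_model(**overrides) -> DemographicModel:
    """Illustrative two-deme model: a domesticate that passed through a
    strong bottleneck (N in the low thousands) splitting from its wild
    progenitor a few thousand generations ago, with weak symmetric
    migration. Parameter values are placeholders for exploration, not a
    fitted demography."""
    kwargs = dict(
        populations=(
            # domesticate: large recent census, sustained bottleneck in the
            # low thousands back to the split
            Population(
                "dog", (SizeEpoch(0, 25000.0), SizeEpoch(500.0, 2500.0))
            ),
            Population(
                "wolf", (SizeEpoch(0, 20000.0), SizeEpoch(4500.0, 25000.0))
            ),
        ),
        splits=(Split(4500.0, "dog", "wolf"),),
        migration=(
            MigrationEpoch(0.0, {("dog", "wolf"): 1e-4, ("wolf", "dog"): 1e-4}),
        ),
        mutation_rate=1e-8,
        window_length=500_000,
        blocks=50,
    )
    kwargs.update(overrides)
    return DemographicModel(**kwargs)


@dataclass
class SimulatedWindow:
    """Concatenated haplotypes for one simulated window."""

    haplotypes: np.ndarray  # (n_haplotypes, n_sites) of 0/1
    positions: np.ndarray  # 1-based bp, strictly increasing
    sample_populations: tuple[str, ...]  # per haplotype
    window_length: int

    @property
    def n_sites(self) -> int:
        return int(self.haplotypes.shape[1])


def _simulate_genealogy(
    model: DemographicModel,
    lineage_demes: Sequence[str],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One genealogy for leaves in the given demes.

    Returns (parent, time) arrays over 2n-1 nodes; leaves are nodes
    0..n-1, the root has parent -1.
    """
    n = len(lineage_demes)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    node_time = np.zeros(2 * n - 1, dtype=float)
    next_node = n

    active: dict[str, list[int]] = {}
    for i, d in enumerate(lineage_demes):
        active.setdefault(d, []).append(i)

    pending_bp = model.breakpoints()
    t = 0.0
    n_active = n
    while n_active > 1:
        # apply any split exactly at the current time
        for s in model.splits:
            if s.time == t and s.derived in active:
                active.setdefault(s.ancestral, []).extend(active.pop(s.derived))

        demes = {d: lin for d, lin in active.items() if lin}
        coal_rates = {
            d: len(lin) * (len(lin) - 1) / (4.0 * model.population(d).size_at(t))
            for d, lin in demes.items()
        }
        mig = model.migration_at(t)
        inactive = {s.derived for s in model.splits if s.time <= t}
        mig_rates = {
            (src, dst): len(demes[src]) * m
            for (src, dst), m in mig.items()
            if m > 0 and src in demes and dst not in inactive
        }
        total = sum(coal_rates.values()) + sum(mig_rates.values())
        next_bp = next((b for b in pending_bp if b > t), math.inf)
        if total <= 0.0:
            if math.isinf(next_bp):
                raise ValueError(
                    "lineages stranded in isolated demes with no future events; "
                    "demographic model is misspecified"
                )
            t = next_bp
            continue
        wait = rng.exponential(1.0 / total)
        if t + wait >= next_bp:
            t = next_bp
            continue
        t += wait
        u = rng.uniform(0.0, total)
        acc = 0.0
        event = None
        for d, r in coal_rates.items():
            acc += r
            if u < acc:
                event = ("coal", d)
                break
        if event is None:
            for pair, r in mig_rates.items():
                acc += r
                if u < acc:
                    event = ("mig", pair)
                    break
        if event is None:  # numerical edge
            event = ("coal", max(coal_rates, key=coal_rates.get))
        if event[0] == "coal":
            lin = active[event[1]]
            i, j = rng.choice(len(lin), size=2, replace=False)
            a, b = lin[int(i)], lin[int(j)]
            node = next_node
            next_node += 1
            parent[a] = node
            parent[b] = node
            node_time[node] = t
            lin.remove(a)
            lin.remove(b)
            lin.append(node)
            n_active -= 1
        else:
            src, dst = event[1]
            lin = active[src]
            idx = int(rng.integers(len(lin)))
            moved = lin.pop(idx)
            active.setdefault(dst, []).append(moved)
    return parent, node_time


def _leaf_sets(parent: np.ndarray, n_leaves: int) -> list[np.ndarray]:
    """Boolean leaf membership below each node."""
    n_nodes = parent.shape[0]
    below = [np.zeros(n_leaves, dtype=bool) for _ in range(n_nodes)]
    for i in range(n_leaves):
        below[i][i] = True
    # internal nodes are created in increasing time order, so a simple
    # pass in node order accumulates children before parents
    for node in range(n_nodes):
        p = parent[node]
        if p >= 0:
            below[p] |= below[node]
    return below


def simulate_window(
    model: DemographicModel,
    samples: Mapping[str, int],
    seed: int | np.random.Generator,
) -> SimulatedWindow:
    """Simulate one window of B independent blocks and concatenate.

    ``samples`` maps extant population name -> haplotype count. Mutations
    fall as a Poisson process at rate mu * block_length on each branch
    (infinite sites: every variant is a new biallelic position).
    Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for pop, k in samples.items():
        if k < 1:
            raise ValueError(f"need >= 1 haplotype in population {pop!r}")
        model.population(pop)  # existence check
    lineage_demes = [p for p, k in samples.items() for _ in range(k)]
    n = len(lineage_demes)
    block_len = model.window_length / model.blocks

    cols: list[np.ndarray] = []
    positions: list[int] = []
    used: set[int] = set()
    for b in range(model.blocks):
        parent, node_time = _simulate_genealogy(model, lineage_demes, rng)
        below = _leaf_sets(parent, n)
        lo = int(b * block_len)  # block spans [lo+1, lo+block_len]
        for node in range(parent.shape[0]):
            p = parent[node]
            if p < 0:
                continue
            branch = node_time[p] - node_time[node]
            n_mut = rng.poisson(model.mutation_rate * block_len * branch)
            for _ in range(n_mut):
                while True:
                    pos = lo + 1 + int(rng.integers(int(block_len)))
                    if pos not in used:
                        used.add(pos)
                        break
                positions.append(pos)
                cols.append(below[node].astype(np.uint8))
    if positions:
        order = np.argsort(positions)
        haps = np.stack([cols[i] for i in order], axis=1)
        pos_arr = np.asarray(positions, dtype=np.int64)[order]
    else:
        haps = np.zeros((n, 0), dtype=np.uint8)
        pos_arr = np.zeros(0, dtype=np.int64)
    return SimulatedWindow(
        haplotypes=haps,
        positions=pos_arr,
        sample_populations=tuple(lineage_demes),
        window_length=model.window_length,
    )


def haplotypes_to_genotypes(
    window: SimulatedWindow,
    chrom: str = "sim",
    pairing: str = "consecutive",
) -> list[SiteRecord]:
    """Pair haplotypes into diploids and emit per-site genotype counts.

    Each population's haplotypes are paired consecutively (the only
    pairing scheme implemented); an odd haplotype count is fatal.
    """
    if pairing != "consecutive":
        raise ValueError(f"unknown pairing scheme {pairing!r}")
    pops = list(dict.fromkeys(window.sample_populations))
    idx_by_pop = {
        p: [i for i, q in enumerate(window.sample_populations) if q == p]
        for p in pops
    }
    for p, idx in idx_by_pop.items():
        if len(idx) % 2:
            raise ValueError(f"odd haplotype count ({len(idx)}) in {p!r}")
    records: list[SiteRecord] = []
    for j in range(window.n_sites):
        col = window.haplotypes[:, j]
        counts = {}
        for p, idx in idx_by_pop.items():
            g = col[idx].reshape(-1, 2).sum(axis=1)
            counts[p] = GenotypeCounts(
                hom_ref=int((g == 0).sum()),
                het=int((g == 1).sum()),
                hom_alt=int((g == 2).sum()),
                missing=0,
            )
        records.append(
            SiteRecord(
                chrom=chrom,
                pos=int(window.positions[j]),
                ref="A",
                alt="C",
                counts=counts,
            )
        )
    return records


def null_distribution(
    model: DemographicModel,
    samples: Mapping[str, int],
    n_reps: int,
    seed: int,
) -> np.ndarray:
    """Neutral null of window-mean Fst: one realized mean per replicate.

    Each replicate simulates a window, pools haplotypes into diploids and
    runs the same per-site Weir & Cockerham path as empirical data; the
    unweighted mean over defined sites is recorded (NaN for windows with
    no usable site). Reproducible given the seed.
    """
    from .fst import compute_site_fst

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ss = np.random.SeedSequence(seed)
    means = np.full(n_reps, np.nan)
    for i, child in enumerate(ss.spawn(n_reps)):
        rng = np.random.default_rng(child)
        window = simulate_window(model, samples, rng)
        records = haplotypes_to_genotypes(window)
        fsts = [s.fst for s in compute_site_fst(records) if not math.isnan(s.fst)]
        if fsts:
            means[i] = float(np.mean(fsts))
    return means


@dataclass(frozen=True)
class ExceedanceReport:
    per_window: list[tuple[str, int, int, float, float]]  # chrom,start,end,mean,p
    max_null: float
    min_outlier_mean: float | None

    @property
    def gap(self) -> float | None:
        """min outlier window mean minus max simulated null mean; positive
        when no simulation reaches the weakest outlier window."""
        if self.min_outlier_mean is None:
            return None
        return self.min_outlier_mean - self.max_null


def empirical_exceedance(windows, null: Sequence[float]) -> ExceedanceReport:
    """Per-window empirical p against a simulated null of window means.

    p = (#{null >= observed} + 1) / (n + 1), so a window above every null
    value gets the floor 1/(n+1), never zero.
    """
    null_arr = np.asarray([v for v in null if not math.isnan(v)], dtype=float)
    if null_arr.size == 0:
        raise ValueError("null distribution is empty")
    per_window = []
    outlier_means = []
    for w in windows:
        if w.mean_fst is None:
            continue
        p = (float((null_arr >= w.mean_fst).sum()) + 1.0) / (null_arr.size + 1.0)
        per_window.append((w.chrom, w.start, w.end, w.mean_fst, p))
        if w.outlier:
            outlier_means.append(w.mean_fst)
    return ExceedanceReport(
        per_window=per_window,
        max_null=float(null_arr.max()),
        min_outlier_mean=min(outlier_means) if outlier_means else None,
    )
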