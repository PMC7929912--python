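"""Forward Wright-Fisher simulator for demographic archetypes.

Generates diploid genotype data with known ground truth under three
archetypes: *natural* beds (constant-size populations with partial selfing),
*cultivated* stock (pool-mixed breeding drawing gametes from several
contributing populations, suppressing selfing), and *introduced* populations
(founder bottlenecks with optional serial re-introduction pulses).  Optional
hard selective sweeps (single-locus additive viability selection from a new
mutation, with restart on loss) can be placed in a focal population.

Model: discrete generations, finite diploid census, Poisson crossovers along
each chromosome, infinite-sites mutation on a finite coordinate grid with
collision re-draw.  The ancestral population is initialised at mutation-drift
equilibrium by drawing standing variants from the neutral site-frequency
spectrum (counts proportional to 1/i), then evolved forward; all subsequent
dynamics are purely forward in time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from kelpscan.variant_io import GenotypeMatrix, PopulationMap

_BASES = np.array(list("ACGT"))

#: generations between fixed/lost column sweeps of the site table
_CLEANUP_EVERY = 25


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SweepLocus:
    chrom_index: int      # 0-based chromosome index
    position: int         # 1-based bp
    s: float              # additive selection coefficient (fitness 1, 1+s, 1+2s)


@dataclass(frozen=True)
class SweepResult:
    chrom: str
    position: int
    s: float
    final_freq: float
    completed: bool
    restarts: int


@dataclass
class SimulationConfig:
    """Scenario parameters; identical config + seed gives bit-identical output."""

    sample_sizes: dict[str, int]
    categories: dict[str, str]          # population -> natural|cultivated|introduced
    n_chromosomes: int = 1
    chrom_length_bp: int = 100_000
    ancestral_N: int = 500
    generations: int = 100              # per demographic phase
    mu: float = 1e-6                    # per site per generation
    rho: float = 1e-7                   # per bp per generation (crossovers)
    selfing_rate: float = 0.0
    founder_size: int = 4
    founder_growth_N: int = 50          # census after the founding generation
    n_reintroduction_pulses: int = 0
    pulse_fraction: float = 0.25
    pool_mixing: bool = True
    sweep_loci: tuple[SweepLocus, ...] = ()
    sweep_population: str | None = None
    sweep_min_freq: float = 0.9
    sweep_extra_generations: int = 50   # post-fixation recovery time
    sweep_max_restarts: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        loci = []
        for locus in self.sweep_loci:
            if not isinstance(locus, SweepLocus):
                locus = SweepLocus(int(locus[0]), int(locus[1]), float(locus[2]))
            loci.append(locus)
        self.sweep_loci = tuple(loci)

    def validate(self) -> None:
        for name, rate in (("mu", self.mu), ("rho", self.rho),
                           ("selfing_rate", self.selfing_rate),
                           ("pulse_fraction", self.pulse_fraction),
                           ("sweep_min_freq", self.sweep_min_freq)):
            if not (0.0 <= rate <= 1.0):
                raise ConfigurationError(f"{name}={rate} outside [0, 1]")
        if self.n_chromosomes < 1 or self.chrom_length_bp < 2:
            raise ConfigurationError("need >= 1 chromosome of >= 2 bp")
        if self.ancestral_N < 2 or self.generations < 1:
            raise ConfigurationError("ancestral_N >= 2 and generations >= 1 required")
        if not (1 <= self.founder_size <= self.ancestral_N):
            raise ConfigurationError("founder_size must lie in [1, ancestral_N]")
        if self.founder_growth_N < self.founder_size:
            raise ConfigurationError("founder_growth_N must be >= founder_size")
        if not self.sample_sizes:
            raise ConfigurationError("at least one population required")
        cats = set()
        for pop, n in self.sample_sizes.items():
            cat = self.categories.get(pop)
            if cat not in ("natural", "cultivated", "introduced"):
                raise ConfigurationError(f"population {pop!r} has invalid category {cat!r}")
            cats.add(cat)
            census = self.founder_growth_N if cat == "introduced" else self.ancestral_N
            if not (1 <= n <= census):
                raise ConfigurationError(
                    f"sample size {n} for {pop!r} exceeds its census {census}")
        if cats - {"natural"} and "natural" not in cats:
            raise ConfigurationError(
                "cultivated/introduced populations require a natural source population")
        for locus in self.sweep_loci:
            if not (0 <= locus.chrom_index < self.n_chromosomes):
                raise ConfigurationError(f"sweep chromosome index {locus.chrom_index} out of range")
            if not (1 <= locus.position <= self.chrom_length_bp):
                raise ConfigurationError(f"sweep position {locus.position} outside chromosome")
            if locus.s < 0:
                raise ConfigurationError("selection coefficient must be >= 0")
        if self.sweep_loci and self.sweep_population not in self.sample_sizes:
            raise ConfigurationError("sweep_population must name a simulated population")

    @property
    def theta(self) -> float:
        """Expected neutral per-bp diversity 4*N*mu of the ancestral population."""
        return 4.0 * self.ancestral_N * self.mu

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length_bp for i in range(self.n_chromosomes)}

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load from a flat YAML mapping (sweep loci as [chrom_index, pos, s])."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sweep_loci" in raw:
            raw["sweep_loci"] = tuple(
                SweepLocus(int(c), int(p), float(s)) for c, p, s in raw["sweep_loci"])
        return cls(**raw)


@dataclass
class SimulationTruth:
    """Ground truth of one simulation run."""

    theta: float
    sweeps: list[SweepResult] = field(default_factory=list)
    census: dict[str, list[int]] = field(default_factory=dict)


def write_truth(truth: SimulationTruth, path: str | Path) -> None:
    """TSV of sweep outcomes with theta in a comment header; round-trips."""
    with open(path, "w") as fh:
        fh.write(f"#theta={truth.theta!r}\n")
        fh.write("chrom\tpos\ts\tfinal_freq\tcompleted\trestarts\n")
        for sw in truth.sweeps:
            fh.write(f"{sw.chrom}\t{sw.position}\t{sw.s!r}\t{sw.final_freq!r}"
                     f"\t{int(sw.completed)}\t{sw.restarts}\n")


def read_truth(path: str | Path) -> SimulationTruth:
    theta = np.nan
    sweeps: list[SweepResult] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#theta="):
                theta = float(line.split("=", 1)[1])
                continue
            if not line or line.startswith("chrom\t"):
                continue
            chrom, pos, s, freq, completed, restarts = line.split("\t")
            sweeps.append(SweepResult(chrom, int(pos), float(s), float(freq),
                                      bool(int(completed)), int(restarts)))
    return SimulationTruth(theta=theta, sweeps=sweeps)


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

class _Engine:
    """Shared-site-table forward simulator over several populations.

    Every population's haplotype matrices are kept aligned to one global,
    per-chromosome site list so that migration and cross-population sampling
    stay consistent; frozen populations are zero-padded lazily.
    """

    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.L = cfg.chrom_length_bp
        self.n_chrom = cfg.n_chromosomes
        self.positions: list[list[int]] = [[] for _ in range(self.n_chrom)]
        self.pos_set: list[set[int]] = [set() for _ in range(self.n_chrom)]
        self._pos_cache: list[np.ndarray | None] = [None] * self.n_chrom
        self.pops: dict[str, list[np.ndarray]] = {}
        self.census: dict[str, list[int]] = {}
        self.protected: list[set[int]] = [set() for _ in range(self.n_chrom)]

    # -- site table -------------------------------------------------------
    def _pos_arr(self, c: int) -> np.ndarray:
        if self._pos_cache[c] is None:
            self._pos_cache[c] = np.array(self.positions[c], dtype=np.int64)
        return self._pos_cache[c]

    def _register_position(self, c: int, pos: int) -> int:
        self.positions[c].append(pos)
        self.pos_set[c].add(pos)
        self._pos_cache[c] = None
        return len(self.positions[c]) - 1

    def _draw_positions(self, c: int, n: int) -> list[int]:
        out = []
        for _ in range(n):
            pos = int(self.rng.integers(1, self.L + 1))
            while pos in self.pos_set[c]:
                pos = int(self.rng.integers(1, self.L + 1))
            out.append(pos)
            self.pos_set[c].add(pos)
        for pos in out:
            self.positions[c].append(pos)
        self._pos_cache[c] = None
        return out

    def _pad(self, pop: str) -> None:
        mats = self.pops[pop]
        for c in range(self.n_chrom):
            width = len(self.positions[c])
            if mats[c].shape[1] < width:
                extra = np.zeros((mats[c].shape[0], width - mats[c].shape[1]),
                                 dtype=np.uint8)
                mats[c] = np.hstack([mats[c], extra])
        self.pops[pop] = mats

    def cleanup(self) -> None:
        """Drop columns lost or fixed across all live populations."""
        for pop in self.pops:
            self._pad(pop)
        for c in range(self.n_chrom):
            width = len(self.positions[c])
            if width == 0:
                continue
            altsum = np.zeros(width, dtype=np.int64)
            total = 0
            for mats in self.pops.values():
                altsum += mats[c].sum(axis=0, dtype=np.int64)
                total += mats[c].shape[0]
            keep = (altsum > 0) & (altsum < total)
            if self.protected[c]:
                prot = np.isin(self._pos_arr(c), list(self.protected[c]))
                keep |= prot
            if keep.all():
                continue
            kept_pos = [p for p, k in zip(self.positions[c], keep) if k]
            self.positions[c] = kept_pos
            self.pos_set[c] = set(kept_pos)
            self._pos_cache[c] = None
            for pop, mats in self.pops.items():
                mats[c] = np.ascontiguousarray(mats[c][:, keep])

    # -- population bookkeeping ------------------------------------------
    def pop_size(self, pop: str) -> int:
        return self.pops[pop][0].shape[0] // 2

    def drop(self, pop: str) -> None:
        del self.pops[pop]

    def _record(self, pop: str) -> None:
        self.census.setdefault(pop, []).append(self.pop_size(pop))

    # -- initialisation ---------------------------------------------------
    def init_ancestral(self, pop: str) -> None:
        """Warm start at mutation-drift equilibrium via the neutral SFS."""
        cfg = self.cfg
        n_hap = 2 * cfg.ancestral_N
        theta_chrom = 4.0 * cfg.ancestral_N * cfg.mu * self.L
        mats = []
        for c in range(self.n_chrom):
            freqs = np.arange(1, n_hap)
            counts = self.rng.poisson(theta_chrom / freqs)
            derived = np.repeat(freqs, counts)
            self.rng.shuffle(derived)
            n_sites = int(derived.size)
            n_sites = min(n_sites, self.L)  # coordinate grid capacity
            derived = derived[:n_sites]
            pos = self.rng.choice(self.L, size=n_sites, replace=False) + 1
            for p in pos:
                self.positions[c].append(int(p))
                self.pos_set[c].add(int(p))
            self._pos_cache[c] = None
            hap = np.zeros((n_hap, n_sites), dtype=np.uint8)
            for col, k in enumerate(derived):
                carriers = self.rng.permutation(n_hap)[:k]
                hap[carriers, col] = 1
            mats.append(hap)
        self.pops[pop] = mats
        self._record(pop)

    # -- gamete formation -------------------------------------------------
    def _gametes(self, hap: np.ndarray, par: np.ndarray, c: int) -> np.ndarray:
        rng = self.rng
        n_g = par.size
        h = rng.integers(0, 2, n_g)
        rows = hap[2 * par + h]
        k = rng.poisson(self.cfg.rho * self.L, n_g)
        positions = self._pos_arr(c)[:hap.shape[1]]
        for g in np.flatnonzero(k):
            bps = np.sort(rng.integers(1, self.L, size=k[g]))
            side = (np.searchsorted(bps, positions, side="right") + h[g]) % 2
            rows[g] = np.where(side == 0, hap[2 * par[g]], hap[2 * par[g] + 1])
        return rows

    def _mutate(self, pop: str, n_offspring: int) -> None:
        rng = self.rng
        mats = self.pops[pop]
        for c in range(self.n_chrom):
            n_mut = rng.poisson(2 * n_offspring * self.cfg.mu * self.L)
            if n_mut == 0:
                continue
            self._draw_positions(c, n_mut)
            block = np.zeros((2 * n_offspring, n_mut), dtype=np.uint8)
            block[rng.integers(0, 2 * n_offspring, n_mut), np.arange(n_mut)] = 1
            mats[c] = np.hstack([mats[c], block])

    # -- generation steps -------------------------------------------------
    def wf_generation(self, pop: str, n_next: int, selfing: float,
                      fitness: np.ndarray | None = None,
                      target: str | None = None) -> None:
        """One Wright-Fisher generation (optionally into a new population)."""
        rng = self.rng
        self._pad(pop)
        mats = self.pops[pop]
        n_par = self.pop_size(pop)
        p = None
        if fitness is not None:
            w = np.asarray(fitness, dtype=float)
            p = w / w.sum()
        mothers = rng.choice(n_par, n_next, p=p)
        selfed = rng.random(n_next) < selfing
        fathers = np.where(selfed, mothers, rng.choice(n_par, n_next, p=p))
        par = np.empty(2 * n_next, dtype=np.intp)
        par[0::2] = mothers
        par[1::2] = fathers
        dest = target or pop
        self.pops[dest] = [self._gametes(mats[c], par, c)
                           for c in range(self.n_chrom)]
        self._mutate(dest, n_next)
        self._record(dest)

    def pooled_generation(self, pop: str, sources: Sequence[str],
                          n_next: int) -> None:
        """Offspring from a random union of gametes across source pools."""
        rng = self.rng
        for s in sources:
            self._pad(s)
        src_choice = rng.integers(0, len(sources), 2 * n_next)
        chrom_rows: list[np.ndarray] = [
            np.zeros((2 * n_next, len(self.positions[c])), dtype=np.uint8)
            for c in range(self.n_chrom)
        ]
        for k, s in enumerate(sources):
            idx = np.flatnonzero(src_choice == k)
            if idx.size == 0:
                continue
            par = rng.integers(0, self.pop_size(s), idx.size)
            mats = self.pops[s]
            for c in range(self.n_chrom):
                chrom_rows[c][idx] = self._gametes(mats[c], par, c)
        self.pops[pop] = chrom_rows
        self._mutate(pop, n_next)
        self._record(pop)

    def found_from(self, pop: str, source: str, individuals: np.ndarray) -> None:
        """Create a population from copies of chosen source individuals."""
        self._pad(source)
        mats = self.pops[source]
        rows = np.empty(2 * individuals.size, dtype=np.intp)
        rows[0::2] = 2 * individuals
        rows[1::2] = 2 * individuals + 1
        self.pops[pop] = [np.ascontiguousarray(mats[c][rows])
                          for c in range(self.n_chrom)]
        self._record(pop)

    def migrant_pulse(self, pop: str, source: str, fraction: float) -> None:
        rng = self.rng
        self._pad(pop)
        self._pad(source)
        n = self.pop_size(pop)
        k = max(1, int(round(fraction * n)))
        targets = rng.choice(n, size=min(k, n), replace=False)
        donors = rng.integers(0, self.pop_size(source), targets.size)
        for c in range(self.n_chrom):
            dst = self.pops[pop][c]
            src = self.pops[source][c]
            dst[2 * targets] = src[2 * donors]
            dst[2 * targets + 1] = src[2 * donors + 1]

    # -- sweep support ----------------------------------------------------
    def inject_allele(self, pop: str, locus: SweepLocus) -> int:
        """Place a single copy of the sweep allele; returns its position."""
        c = locus.chrom_index
        pos = locus.position
        while pos in self.pos_set[c]:
            pos = pos % self.L + 1
        self._register_position(c, pos)
        self.protected[c].add(pos)
        self._pad(pop)
        mats = self.pops[pop]
        hap = int(self.rng.integers(0, mats[c].shape[0]))
        mats[c][hap, -1] = 1
        return pos

    def allele_freq(self, pop: str, chrom_index: int, pos: int) -> float:
        self._pad(pop)
        col = np.flatnonzero(self._pos_arr(chrom_index) == pos)
        if col.size == 0:
            return 0.0
        hap = self.pops[pop][chrom_index]
        return float(hap[:, col[0]].sum()) / hap.shape[0]

    def genotype_counts(self, pop: str, chrom_index: int, pos: int) -> np.ndarray:
        """Per-individual count of sweep alleles (0/1/2)."""
        self._pad(pop)
        col = np.flatnonzero(self._pos_arr(chrom_index) == pos)
        n = self.pop_size(pop)
        if col.size == 0:
            return np.zeros(n, dtype=np.int64)
        hap = self.pops[pop][chrom_index][:, col[0]].astype(np.int64)
        return hap[0::2] + hap[1::2]


# ---------------------------------------------------------------------------
# Scenario orchestration
# ---------------------------------------------------------------------------

def _evolve_neutral(engine: _Engine, pop: str, gens: int, n: int,
                    selfing: float, pulses: list[int] | None = None,
                    source: str | None = None) -> None:
    cfg = engine.cfg
    for g in range(gens):
        engine.wf_generation(pop, n, selfing)
        if pulses and g in pulses and source is not None:
            engine.migrant_pulse(pop, source, cfg.pulse_fraction)
        if (g + 1) % _CLEANUP_EVERY == 0:
            engine.cleanup()


def _evolve_with_sweep(engine: _Engine, pop: str, locus: SweepLocus,
                       gens: int, n: int, selfing: float) -> SweepResult:
    """Run the population's phase under selection until the sweep completes.

    The sweep allele starts as a single new copy; loss triggers immediate
    re-injection, and a phase that ends without reaching ``sweep_min_freq``
    is re-run from a snapshot.  Raises after the restart budget is spent.
    """
    cfg = engine.cfg
    c = locus.chrom_index
    snapshot = [m.copy() for m in engine.pops[pop]]
    restarts = 0
    max_attempts = 50
    for _ in range(max_attempts):
        engine.pops[pop] = [m.copy() for m in snapshot]
        pos = engine.inject_allele(pop, locus)
        completed = False
        for _ in range(gens):
            counts = engine.genotype_counts(pop, c, pos)
            fitness = 1.0 + locus.s * counts
            engine.wf_generation(pop, n, selfing, fitness=fitness)
            freq = engine.allele_freq(pop, c, pos)
            if freq == 0.0:
                restarts += 1
                if restarts > cfg.sweep_max_restarts:
                    raise RuntimeError("sweep restart budget exhausted")
                engine.protected[c].discard(pos)
                pos = engine.inject_allele(pop, locus)
            elif freq >= cfg.sweep_min_freq:
                completed = True
                break
        if not completed:
            engine.protected[c].discard(pos)
        if completed:
            for g in range(cfg.sweep_extra_generations):
                counts = engine.genotype_counts(pop, c, pos)
                engine.wf_generation(pop, n, selfing,
                                     fitness=1.0 + locus.s * counts)
                if (g + 1) % _CLEANUP_EVERY == 0:
                    engine.cleanup()
            final = engine.allele_freq(pop, c, pos)
            return SweepResult(f"chr{locus.chrom_index + 1}", pos, locus.s,
                               final, True, restarts)
        restarts += 1
        if restarts > cfg.sweep_max_restarts:
            break
    raise RuntimeError(f"sweep in {pop!r} failed to complete within the retry budget")


def simulate_populations(config: SimulationConfig,
                         ) -> tuple[GenotypeMatrix, PopulationMap, SimulationTruth]:
    """Run the configured scenario and sample genotypes with ground truth.

    Phases: ancestral burn-in -> independent natural populations -> derived
    cultivated (gamete pooling) and introduced (founder bottleneck, optional
    re-introduction pulses) populations, each lasting ``config.generations``
    generations.  Sweeps run in ``config.sweep_population`` during its phase.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    engine = _Engine(cfg, rng)
    truth = SimulationTruth(theta=cfg.theta)

    anc = "__ancestral__"
    engine.init_ancestral(anc)
    _evolve_neutral(engine, anc, cfg.generations, cfg.ancestral_N, cfg.selfing_rate)

    naturals = [p for p in cfg.sample_sizes if cfg.categories[p] == "natural"]
    cultivated = [p for p in cfg.sample_sizes if cfg.categories[p] == "cultivated"]
    introduced = [p for p in cfg.sample_sizes if cfg.categories[p] == "introduced"]

    for pop in naturals:
        engine.wf_generation(anc, cfg.ancestral_N, cfg.selfing_rate, target=pop)
    engine.drop(anc)
    engine.cleanup()

    def run_phase(pop: str, gens: int, n: int, selfing: float,
                  pulses: list[int] | None = None, source: str | None = None) -> None:
        locus = cfg.sweep_loci[0] if (cfg.sweep_loci and cfg.sweep_population == pop) else None
        if locus is not None:
            truth.sweeps.append(
                _evolve_with_sweep(engine, pop, locus, gens, n, selfing))
            for extra in cfg.sweep_loci[1:]:
                truth.sweeps.append(
                    _evolve_with_sweep(engine, pop, extra, gens, n, selfing))
        else:
            _evolve_neutral(engine, pop, gens, n, selfing, pulses, source)
        engine.cleanup()

    for pop in naturals:
        run_phase(pop, cfg.generations, cfg.ancestral_N, cfg.selfing_rate)

    for pop in cultivated:
        if cfg.pool_mixing and cfg.sweep_loci and cfg.sweep_population == pop:
            raise ConfigurationError(
                "sweeps in pool-mixed populations are not supported; "
                "disable pool_mixing or choose another focal population")
        engine.pooled_generation(pop, naturals, cfg.ancestral_N)
        if cfg.pool_mixing:
            for g in range(cfg.generations):
                engine.pooled_generation(pop, naturals + [pop], cfg.ancestral_N)
                if (g + 1) % _CLEANUP_EVERY == 0:
                    engine.cleanup()
            engine.cleanup()
        else:
            run_phase(pop, cfg.generations, cfg.ancestral_N, 0.0)

    for pop in introduced:
        source = naturals[0]
        founders = rng.choice(cfg.ancestral_N, size=cfg.founder_size, replace=False)
        engine.found_from(pop, source, founders)
        pulses = None
        if cfg.n_reintroduction_pulses > 0:
            step = cfg.generations / (cfg.n_reintroduction_pulses + 1)
            pulses = [int(round((k + 1) * step)) for k in range(cfg.n_reintroduction_pulses)]
        run_phase(pop, cfg.generations, cfg.founder_growth_N, cfg.selfing_rate,
                  pulses=pulses, source=source)

    matrix, popmap = _sample(engine, cfg, rng)
    truth.census = engine.census
    return matrix, popmap, truth


def _sample(engine: _Engine, cfg: SimulationConfig, rng: np.random.Generator,
            ) -> tuple[GenotypeMatrix, PopulationMap]:
    sample_ids: list[str] = []
    entries: dict[str, tuple[str, str]] = {}
    geno_chrom: list[np.ndarray] = []
    for pop in cfg.sample_sizes:
        engine._pad(pop)
    for pop, k in cfg.sample_sizes.items():
        chosen = np.sort(rng.choice(engine.pop_size(pop), size=k, replace=False))
        for i, ind in enumerate(chosen):
            sample_ids.append(f"{pop}_{i:02d}")
            entries[f"{pop}_{i:02d}"] = (pop, cfg.categories[pop])
        rows = []
        for c in range(cfg.n_chromosomes):
            hap = engine.pops[pop][c]
            g = hap[2 * chosen] + hap[2 * chosen + 1]
            rows.append(g.astype(np.int8))
        geno_chrom.append(rows)

    chroms_out: list[np.ndarray] = []
    pos_out: list[np.ndarray] = []
    geno_out: list[np.ndarray] = []
    n_total = len(sample_ids)
    for c in range(cfg.n_chromosomes):
        g = np.vstack([per_pop[c] for per_pop in geno_chrom])
        pos = engine._pos_arr(c)
        order = np.argsort(pos, kind="stable")
        g = g[:, order]
        pos = pos[order]
        altsum = g.sum(axis=0, dtype=np.int64)
        keep = (altsum > 0) & (altsum < 2 * n_total)
        chroms_out.append(np.full(int(keep.sum()), f"chr{c + 1}", dtype=object))
        pos_out.append(pos[keep])
        geno_out.append(g[:, keep])

    n_sites = sum(p.size for p in pos_out)
    ref = _BASES[rng.integers(0, 4, n_sites)]
    alt = np.empty(n_sites, dtype=object)
    for j in range(n_sites):
        choices = [b for b in "ACGT" if b != ref[j]]
        alt[j] = choices[int(rng.integers(0, 3))]
    matrix = GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=np.concatenate(chroms_out) if chroms_out else np.empty(0, dtype=object),
        pos=np.concatenate(pos_out) if pos_out else np.empty(0, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=alt,
        genotypes=(np.hstack(geno_out) if geno_out
                   else np.empty((n_total, 0), dtype=np.int8)),
        contig_lengths=cfg.contig_lengths,
    )
    return matrix, PopulationMap(entries)


def synthetic_genes(contig_lengths: dict[str, int], gene_length: int = 2_000,
                    spacing: int = 5_000):
    """Uniformly spaced synthetic gene models as a BED-style data frame."""
    import pandas as pd

    rows = []
    k = 0
    for chrom, length in contig_lengths.items():
        start = spacing // 2
        while start + gene_length <= length:
            k += 1
            rows.append((chrom, start, start + gene_length, f"gene_{k:05d}"))
            start += spacing
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
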