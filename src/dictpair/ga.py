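"""Gray-coded genetic algorithm over the four PDPL hyperparameters.

A chromosome is 36 bits: four 9-bit Gray-coded substrings decoded by a
FieldD schema (arithmetic scaling between per-variable bounds, with
optional exclusion of either bound).  The generational loop is
fitness-proportionate stochastic universal sampling, single-point
crossover, bit-flip mutation and elitist reinsertion; fitness is the mean
leave-one-subject-out accuracy of the decoded parameter vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .evaluation import FeatureDataset, run_loso
from .pdpl import PDPLParams

log = logging.getLogger(__name__)

#: Decoded gamma of exactly 0 (allowed by the schema's inclusive lower bound)
#: is floored here so the analysis update stays well-posed.
GAMMA_FLOOR = 1e-12


@dataclass(frozen=True)
class FieldD:
    """Decoding schema: how each chromosome substring maps to a variable.

    ``code`` selects gray or plain binary; ``scale`` must be arithmetic;
    ``lbin``/``ubin`` flag whether each bound is part of the representation
    range (an excluded bound shifts the quantization grid one step inward).
    """

    names: tuple[str, ...] = ("m", "tau", "lam", "gam")
    len: tuple[int, ...] = (9, 9, 9, 9)
    lb: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0)
    ub: tuple[float, ...] = (310.0, 0.1, 0.01, 0.001)
    code: tuple[str, ...] = ("gray",) * 4
    scale: tuple[str, ...] = ("arithmetic",) * 4
    lbin: tuple[int, ...] = (0, 0, 1, 1)
    ubin: tuple[int, ...] = (1, 1, 1, 1)

    def __post_init__(self) -> None:
        n = len(self.names)
        for attr in ("len", "lb", "ub", "code", "scale", "lbin", "ubin"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"FieldD field {attr!r} has wrong length")
        for i in range(n):
            if self.len[i] <= 0:
                raise ValueError("substring lengths must be positive")
            if not self.lb[i] < self.ub[i]:
                raise ValueError(f"variable {self.names[i]!r}: need lb < ub")
            if self.scale[i] != "arithmetic":
                raise NotImplementedError("only arithmetic scaling is supported")

    @property
    def total_len(self) -> int:
        return sum(self.len)


def default_fieldd(m_ub: int = 310) -> FieldD:
    """The standard four-variable schema; ``m_ub`` is 310 or 70 depending on
    the dataset's sample budget."""
    return replace(FieldD(), ub=(float(m_ub), 0.1, 0.01, 0.001))


@dataclass
class GAConfig:
    max_gen: int = 50
    pop_size: int = 20
    ggap: float = 0.9
    p_mut: float = 0.7
    p_cross: float = 0.7
    mutation_mode: str = "individual"  # per-bit prob = p_mut / chrom length
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.ggap <= 1:
            raise ValueError("ggap must be in (0, 1]")
        if not 0 <= self.p_mut <= 1:
            raise ValueError("p_mut must be in [0, 1]")
        if self.mutation_mode not in ("individual", "per_bit"):
            raise ValueError("mutation_mode must be 'individual' or 'per_bit'")


@dataclass
class GATrace:
    """Per-generation log of the search (the data behind fitness curves)."""

    best_fitness: list[float] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    best_params: list[PDPLParams] = field(default_factory=list)

    def to_rows(self) -> list[dict]:
        return [
            {
                "generation": g + 1,
                "best_fitness": bf,
                "mean_fitness": mf,
                "m": p.m,
                "tau": p.tau,
                "lam": p.lam,
                "gam": p.gam,
            }
            for g, (bf, mf, p) in enumerate(
                zip(self.best_fitness, self.mean_fitness, self.best_params)
            )
        ]


def gray_to_binary(bits: np.ndarray) -> np.ndarray:
    """Decode a Gray-coded bit vector: b1 = g1, b_j = b_{j-1} XOR g_j."""
    bits = np.asarray(bits, dtype=int)
    if bits.size == 0:
        raise ValueError("empty bit vector")
    return np.bitwise_xor.accumulate(bits)


def binary_to_gray(bits: np.ndarray) -> np.ndarray:
    bits = np.asarray(bits, dtype=int)
    if bits.size == 0:
        raise ValueError("empty bit vector")
    return np.concatenate([bits[:1], bits[1:] ^ bits[:-1]])


def _scale(v: int, nbits: int, lb: float, ub: float, lbin: int, ubin: int) -> float:
    """Arithmetic scaling of integer v in [0, 2^nbits - 1] onto the
    representation range; an excluded bound drops its grid point."""
    num = 2**nbits
    span = ub - lb
    if lbin and ubin:
        return lb + v * span / (num - 1)
    if not lbin and ubin:
        return lb + (v + 1) * span / num
    if lbin and not ubin:
        return lb + v * span / num
    return lb + (v + 1) * span / (num + 1)


def decode_substrings(bits: np.ndarray, fd: FieldD) -> dict[str, float]:
    bits = np.asarray(bits, dtype=int)
    if bits.size != fd.total_len:
        raise ValueError(f"chromosome length {bits.size} != schema length {fd.total_len}")
    out: dict[str, float] = {}
    pos = 0
    for i, name in enumerate(fd.names):
        sub = bits[pos : pos + fd.len[i]]
        pos += fd.len[i]
        if fd.code[i] == "gray":
            sub = gray_to_binary(sub)
        v = int(sub @ (1 << np.arange(fd.len[i] - 1, -1, -1)))
        out[name] = _scale(v, fd.len[i], fd.lb[i], fd.ub[i], fd.lbin[i], fd.ubin[i])
    return out


def decode_chromosome(bits: np.ndarray, fd: FieldD, seed: int = 0) -> PDPLParams:
    """Decode a chromosome into PDPL hyperparameters.

    ``m`` is rounded half-up and floored at 1; a decoded gamma of 0 is
    floored at GAMMA_FLOOR.
    """
    vals = decode_substrings(bits, fd)
    return PDPLParams(
        m=max(1, int(np.floor(vals["m"] + 0.5))),
        tau=vals["tau"],
        lam=vals["lam"],
        gam=max(vals["gam"], GAMMA_FLOOR),
        seed=seed,
    )


def evaluate_fitness(params: PDPLParams, dataset: FeatureDataset) -> float:
    """Mean LOSO accuracy of ``params`` on ``dataset``; a failing fold scores
    0 so the GA never crashes mid-search."""
    return run_loso(dataset, params, on_fold_error="zero").mean


def sus_select(fitnesses: np.ndarray, n_select: int, rng: np.random.Generator) -> np.ndarray:
    """Stochastic universal sampling: one random offset, ``n_select`` equally
    spaced pointers.  Each individual's selection count is the floor or the
    ceiling of its expectation n_select * f_i / sum(f)."""
    f = np.asarray(fitnesses, dtype=float)
    if n_select < 1:
        raise ValueError("n_select must be >= 1")
    if (f < 0).any():
        raise ValueError("fitness values must be nonnegative")
    total = f.sum()
    if total == 0:
        f = np.ones_like(f)
        total = f.sum()
    step = total / n_select
    start = rng.uniform(0, step)
    pointers = start + step * np.arange(n_select)
    cum = np.cumsum(f)
    return np.searchsorted(cum, pointers, side="right")


def crossover(
    parents: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Single-point crossover applied to consecutive pairs with probability
    ``rate``; parents count must be even."""
    parents = np.asarray(parents, dtype=int)
    n, L = parents.shape
    if n % 2:
        raise ValueError("crossover needs an even number of parents")
    out = parents.copy()
    for i in range(0, n, 2):
        if rng.uniform() < rate:
            cut = int(rng.integers(1, L))
            out[i, cut:], out[i + 1, cut:] = (
                parents[i + 1, cut:].copy(),
                parents[i, cut:].copy(),
            )
    return out


def mutate(
    chrom: np.ndarray,
    p_mut: float,
    rng: np.random.Generator,
    mode: str = "individual",
) -> np.ndarray:
    """Bit-flip mutation.  ``individual`` mode spreads ``p_mut`` across the
    loci (per-bit probability p_mut / L); ``per_bit`` applies it per bit."""
    chrom = np.asarray(chrom, dtype=int)
    L = chrom.shape[-1]
    p_bit = p_mut / L if mode == "individual" else p_mut
    flips = rng.uniform(size=chrom.shape) < p_bit
    return chrom ^ flips.astype(int)


def reinsert(
    parents: np.ndarray,
    parent_fit: np.ndarray,
    offspring: np.ndarray,
    offspring_fit: np.ndarray,
    pop_size: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Elitist replacement: pool parents and offspring, keep the fittest
    ``pop_size`` (ties resolved by insertion order, parents first)."""
    if pop_size is None:
        pop_size = len(parents)
    pool = np.vstack([parents, offspring])
    fit = np.concatenate([parent_fit, offspring_fit])
    order = np.argsort(-fit, kind="stable")[:pop_size]
    return pool[order], fit[order]


def run_ga(
    dataset: FeatureDataset | None,
    cfg: GAConfig,
    fd: FieldD,
    fitness_fn: Callable[[PDPLParams], float] | None = None,
    train_seed: int = 0,
) -> tuple[PDPLParams, GATrace]:
    """Generational GA search; returns the best-ever decoded parameters and
    the full per-generation trace.

    ``fitness_fn`` overrides the default LOSO fitness (used for surrogate
    tests); fitness values are cached by chromosome bits, so identical bit
    strings are never evaluated twice per run.
    """
    if fitness_fn is None:
        if dataset is None:
            raise ValueError("either a dataset or a fitness_fn is required")
        fitness_fn = lambda p: evaluate_fitness(p, dataset)  # noqa: E731

    rng = np.random.default_rng(cfg.rng_seed)
    L = fd.total_len
    cache: dict[bytes, float] = {}

    def fitness_of(pop: np.ndarray) -> np.ndarray:
        out = np.empty(len(pop))
        for i, bits in enumerate(pop):
            key = np.packbits(bits).tobytes()
            if key not in cache:
                cache[key] = float(
                    fitness_fn(decode_chromosome(bits, fd, seed=train_seed))
                )
            out[i] = cache[key]
        return out

    pop = rng.integers(0, 2, size=(cfg.pop_size, L))
    fits = fitness_of(pop)
    best_bits = pop[int(np.argmax(fits))].copy()
    best_fit = float(fits.max())

    trace = GATrace()
    n_par = int(round(cfg.ggap * cfg.pop_size))
    for gen in range(cfg.max_gen):
        idx = sus_select(fits, n_par, rng)
        rng.shuffle(idx)
        parents = pop[idx]
        # an odd parent passes through crossover unchanged
        if n_par % 2:
            offspring = np.vstack(
                [crossover(parents[:-1], cfg.p_cross, rng), parents[-1:]]
            )
        else:
            offspring = crossover(parents, cfg.p_cross, rng)
        offspring = mutate(offspring, cfg.p_mut, rng, mode=cfg.mutation_mode)
        off_fits = fitness_of(offspring)
        pop, fits = reinsert(pop, fits, offspring, off_fits, cfg.pop_size)
        if fits[0] > best_fit:
            best_fit = float(fits[0])
            best_bits = pop[0].copy()
        trace.best_fitness.append(best_fit)
        trace.mean_fitness.append(float(fits.mean()))
        trace.best_params.append(decode_chromosome(best_bits, fd, seed=train_seed))
        log.debug(
            "generation %d: best=%.4f mean=%.4f cache=%d",
            gen + 1, best_fit, fits.mean(), len(cache),
        )

    return decode_chromosome(best_bits, fd, seed=train_seed), trace
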