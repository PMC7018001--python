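"""QUBO samplers: seeded simulated annealing, exhaustive enumeration, and a
pluggable sampler contract.

The simulated annealer is a classical single-spin-flip Metropolis sampler:
each read starts from a uniform random bitstring and performs sequential
sweeps (variable order 0..N-1, fixed for reproducibility) under a geometric
inverse-temperature ramp.  Local fields are cached and updated incrementally
on accepted flips, so a sweep costs O(N) attempts plus O(degree) per
accepted flip.  No spin-reversal transforms are applied.

The default temperature range is derived from the problem coefficients:
the hot end accepts the worst single flip with probability 1/2
(``beta_hot = ln 2 / max_u (|h_u| + sum_v |J_uv|)``) and the cold end
freezes a typical coupling (``beta_cold = ln 100 / median |J|`` over
nonzero couplings).  Tying the cold end to the *typical* rather than the
smallest coupling matters for modularity problems, whose coefficient
spectrum spans orders of magnitude: annealing far below the scale where
moves still occur wastes sweeps in a frozen state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Protocol, runtime_checkable

import numpy as np
from numba import njit

from .qubo import QUBOProblem, energy

__all__ = [
    "AnnealSchedule",
    "SampleSet",
    "SamplerContractError",
    "simulated_anneal",
    "exhaustive_solve",
    "SimulatedAnnealingSampler",
    "ExhaustiveSampler",
    "check_sampler_output",
]

#: hard cap for exhaustive enumeration (2^22 ~ 4M states)
EXHAUSTIVE_CAP = 22


class SamplerContractError(RuntimeError):
    """A sampler returned output inconsistent with the problem it was given."""


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric inverse-temperature program for the Metropolis annealer."""

    sweeps: int = 1000
    beta_range: tuple[float, float] | None = None  # None = auto from problem

    def __post_init__(self) -> None:
        if self.sweeps < 1:
            raise ValueError("sweeps must be >= 1")
        if self.beta_range is not None:
            lo, hi = self.beta_range
            if not (0 < lo < hi):
                raise ValueError("beta_range must satisfy 0 < beta_start < beta_end")

    def resolve(self, problem: QUBOProblem) -> np.ndarray:
        """The per-sweep inverse temperatures for a concrete problem."""
        if self.beta_range is not None:
            lo, hi = self.beta_range
        else:
            lo, hi = _auto_beta_range(problem)
        if self.sweeps == 1:
            return np.array([hi])
        r = np.arange(self.sweeps) / (self.sweeps - 1)
        return lo * (hi / lo) ** r


def _auto_beta_range(problem: QUBOProblem) -> tuple[float, float]:
    ptr, idx, val = problem.neighbor_lists()
    max_field = np.abs(problem.linear).copy()
    np.add.at(max_field, np.repeat(np.arange(problem.num_vars), np.diff(ptr)),
              np.abs(val))
    hot_scale = max_field.max() if max_field.size else 1.0
    # freeze the smallest scale that still matters: the typical coupling,
    # or the weakest linear bias if that is smaller (a penalty-dominated
    # problem must still pin every nearly-free bit at the cold end)
    scales = []
    nzq = np.abs(problem.vals[problem.vals != 0.0])
    if nzq.size:
        scales.append(float(np.median(nzq)))
    nzl = np.abs(problem.linear[problem.linear != 0.0])
    if nzl.size:
        scales.append(float(nzl.min()))
    cold_scale = min(scales) if scales else 1.0
    hot_scale = max(hot_scale, 1e-12)
    cold_scale = max(cold_scale, 1e-12)
    lo = np.log(2.0) / hot_scale
    hi = np.log(100.0) / cold_scale
    if hi <= lo:
        hi = 2.0 * lo
    return float(lo), float(hi)


@dataclass(frozen=True)
class SampleSet:
    """Samples from one solver call, aggregated and sorted by energy.

    ``bits`` is a ``num_distinct x N`` uint8 array; ``energies`` and
    ``counts`` are aligned with its rows, energies ascending.
    """

    bits: np.ndarray = field(repr=False)
    energies: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)
    metadata: dict[str, Any] = field(default_factory=dict, compare=False)

    @classmethod
    def from_reads(cls, bits: np.ndarray, energies: np.ndarray,
                   metadata: dict[str, Any] | None = None) -> "SampleSet":
        """Aggregate raw per-read bitstrings into a sorted sample set."""
        bits = np.ascontiguousarray(bits, dtype=np.uint8)
        uniq, inv = np.unique(bits, axis=0, return_inverse=True)
        counts = np.bincount(inv, minlength=uniq.shape[0])
        e = np.zeros(uniq.shape[0])
        e[inv] = energies  # any representative; identical bits -> same energy
        order = np.argsort(e, kind="stable")
        return cls(uniq[order], e[order], counts[order], metadata or {})

    @property
    def num_reads(self) -> int:
        return int(self.counts.sum())

    def best(self) -> tuple[np.ndarray, float]:
        """Lowest-energy bitstring and its energy."""
        return self.bits[0], float(self.energies[0])

    def __len__(self) -> int:
        return self.bits.shape[0]

    def __iter__(self):
        return iter(zip(self.bits, self.energies, self.counts))


@njit(cache=True)
def _metropolis_reads(linear, ptr, idx, val, betas, seeds, out_bits):  # pragma: no cover
    N = linear.shape[0]
    for r in range(seeds.shape[0]):
        np.random.seed(seeds[r])
        b = np.empty(N, np.int8)
        for u in range(N):
            b[u] = 1 if np.random.random() < 0.5 else 0
        # cached local fields: f[v] = h[v] + sum_u J_vu b[u]
        f = linear.copy()
        for u in range(N):
            if b[u] == 1:
                for p in range(ptr[u], ptr[u + 1]):
                    f[idx[p]] += val[p]
        for t in range(betas.shape[0]):
            beta = betas[t]
            for u in range(N):
                dE = (1 - 2 * b[u]) * f[u]
                if dE <= 0.0 or np.random.random() < np.exp(-beta * dE):
                    s = 1 - 2 * b[u]
                    b[u] += s
                    for p in range(ptr[u], ptr[u + 1]):
                        f[idx[p]] += val[p] * s
        out_bits[r] = b


def _read_energies(problem: QUBOProblem, bits: np.ndarray) -> np.ndarray:
    b = bits.astype(float)
    e = b @ problem.linear
    if problem.vals.size:
        e += (b[:, problem.rows] * b[:, problem.cols]) @ problem.vals
    return e + problem.offset


def simulated_anneal(
    problem: QUBOProblem,
    num_reads: int = 1000,
    schedule: AnnealSchedule | None = None,
    seed: int | None = None,
) -> SampleSet:
    """Run ``num_reads`` independent Metropolis anneals of a QUBO.

    Deterministic for a fixed ``(problem, num_reads, schedule, seed)``: the
    per-read generator seeds are spawned from ``seed`` and the sweep order
    is fixed.
    """
    if num_reads < 1:
        raise ValueError("num_reads must be >= 1")
    schedule = schedule or AnnealSchedule()
    betas = schedule.resolve(problem)
    seeds = np.random.SeedSequence(seed).generate_state(num_reads, dtype=np.uint32)
    ptr, idx, val = problem.neighbor_lists()
    bits = np.zeros((num_reads, problem.num_vars), dtype=np.int8)
    _metropolis_reads(problem.linear, ptr, idx, val, betas, seeds, bits)
    bits = bits.astype(np.uint8)
    return SampleSet.from_reads(
        bits,
        _read_energies(problem, bits),
        metadata={
            "sampler": "simulated_annealing",
            "num_reads": num_reads,
            "sweeps": schedule.sweeps,
            "beta_range": (float(betas[0]), float(betas[-1])),
            "seed": seed,
        },
    )


def exhaustive_solve(problem: QUBOProblem, ties_atol: float = 1e-9) -> SampleSet:
    """Enumerate all ``2^N`` assignments and return the full ground-state set.

    Refuses problems with more than 22 variables.  Ties within
    ``ties_atol`` of the minimum are all reported.
    """
    N = problem.num_vars
    if N > EXHAUSTIVE_CAP:
        raise ValueError(
            f"exhaustive enumeration capped at {EXHAUSTIVE_CAP} variables, got {N}"
        )
    shifts = np.arange(N, dtype=np.uint32)
    best_e = np.inf
    ground: list[np.ndarray] = []
    chunk = 1 << 16
    for start in range(0, 1 << N, chunk):
        codes = np.arange(start, min(start + chunk, 1 << N), dtype=np.uint32)
        bits = ((codes[:, None] >> shifts) & 1).astype(np.uint8)
        e = _read_energies(problem, bits)
        lo = e.min()
        if lo < best_e - ties_atol:
            best_e = lo
            ground = []
        keep = e <= best_e + ties_atol
        if keep.any():
            ground.append(bits[keep])
    gb = np.vstack(ground)
    ge = _read_energies(problem, gb)
    keep = ge <= ge.min() + ties_atol
    gb, ge = gb[keep], ge[keep]
    return SampleSet.from_reads(
        gb, ge, metadata={"sampler": "exhaustive", "num_enumerated": 1 << N}
    )


# -- pluggable sampler contract ----------------------------------------------


@runtime_checkable
class Sampler(Protocol):
    """Anything that maps a :class:`QUBOProblem` to a :class:`SampleSet`.

    External backends (e.g. a quantum annealer adapter) plug into the
    pipeline by honoring this contract.
    """

    def __call__(self, problem: QUBOProblem) -> SampleSet: ...


def check_sampler_output(problem: QUBOProblem, samples: SampleSet,
                         energy_atol: float = 1e-9) -> SampleSet:
    """Validate a sampler's output against the problem it was given.

    Raises :class:`SamplerContractError` on wrong bitstring length or
    energies inconsistent with the QUBO coefficients.
    """
    if samples.bits.ndim != 2 or samples.bits.shape[1] != problem.num_vars:
        raise SamplerContractError(
            f"sampler returned bitstrings of length "
            f"{samples.bits.shape[-1] if samples.bits.size else 0}, "
            f"expected {problem.num_vars}"
        )
    expect = _read_energies(problem, samples.bits)
    if samples.energies.size and np.abs(expect - samples.energies).max() > energy_atol:
        raise SamplerContractError("sampler energies disagree with QUBO coefficients")
    return samples


@dataclass(frozen=True)
class SimulatedAnnealingSampler:
    """Configured simulated-annealing backend satisfying :class:`Sampler`."""

    num_reads: int = 1000
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    seed: int | None = None

    def __call__(self, problem: QUBOProblem) -> SampleSet:
        return simulated_anneal(problem, self.num_reads, self.schedule, self.seed)


@dataclass(frozen=True)
class ExhaustiveSampler:
    """Exact backend for tiny problems, satisfying :class:`Sampler`."""

    def __call__(self, problem: QUBOProblem) -> SampleSet:
        return exhaustive_solve(problem)
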