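"""Binary-encoded genetic algorithm for membrane-parameter identification.

The five unknowns (K_l, K_b, K_a, K_v, VR) are encoded as a 640-bit string,
128 bits per parameter, decoded linearly between per-parameter bounds.
Each generation starts from a population of 60 parents; consecutive parents
are paired and, with probability 0.8, recombined by single-point crossover;
the resulting children receive a per-bit mutation (a bit flips when a
uniform draw exceeds the 0.6 threshold, i.e. an effective flip rate of
0.4).  Parents plus (mutated) children form 120 candidates, all evaluated
against the per-device experimental entry times through the error

    Error = sum_n |1 - ET_sim_n / ET_exp_n|

(one term per device; a forward run that exceeds twice the experimental
entry time is stopped and contributes |1 - 2| = 1).  The best 20 candidates
seed the next generation's population (elitism: the best error never
increases); the remaining seats are refilled with fresh random strings.
The loop stops when the best error is unchanged for 20 successive
generations.

All randomness flows through a single seeded generator, so identification
is reproducible bit-for-bit; evaluations within a generation are
independent of order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .membrane import PARAM_BOUNDS, PARAM_NAMES, CellModelParams

BITS_PER_PARAM = 128
N_PARAMS = 5
TOTAL_BITS = BITS_PER_PARAM * N_PARAMS


class GAError(ValueError):
    pass


@dataclass
class GAConfig:
    population_size: int = 60
    crossover_prob: float = 0.8
    mutation_prob: float = 0.6   # per-bit trigger threshold (flip if draw > p)
    elite_count: int = 20
    stall_generations: int = 20
    early_stop_factor: float = 2.0
    max_generations: int = 200
    bounds: np.ndarray = field(
        default_factory=lambda: PARAM_BOUNDS.copy())  # (5, 2)
    seed: int = 0

    def __post_init__(self) -> None:
        self.bounds = np.asarray(self.bounds, dtype=float)
        if self.bounds.shape != (N_PARAMS, 2):
            raise GAError("bounds must have shape (5, 2)")
        if self.elite_count > self.population_size:
            raise GAError("elite_count cannot exceed population_size")


@dataclass
class ExperimentalTargets:
    """Per-device experimental entry times for one cell diameter.

    ``devices`` are device identifiers (passed to the forward model),
    ``diameter_um`` the cell size under identification, ``entry_times_ms``
    the measured entry times (three devices in the standard protocol).
    """

    devices: tuple
    diameter_um: float
    entry_times_ms: tuple

    def __post_init__(self) -> None:
        if len(self.devices) != len(self.entry_times_ms):
            raise GAError("one entry time per device required")
        if any(t <= 0 for t in self.entry_times_ms):
            raise GAError("experimental entry times must be positive")


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

_DENOM = float(2**BITS_PER_PARAM - 1)


def decode(bits: np.ndarray, bounds: np.ndarray | None = None,
           ) -> CellModelParams:
    """Map a 640-bit string to parameter values.

    Each 128-bit block is read as an unsigned integer and mapped linearly:
    lower + int/(2^128 - 1) * (upper - lower).  The all-zero and all-one
    strings hit the bounds exactly.
    """
    bits = np.asarray(bits)
    if bits.shape != (TOTAL_BITS,):
        raise GAError(f"expected {TOTAL_BITS} bits, got shape {bits.shape}")
    bounds = PARAM_BOUNDS if bounds is None else np.asarray(bounds, float)
    vals = []
    for p in range(N_PARAMS):
        block = bits[p * BITS_PER_PARAM:(p + 1) * BITS_PER_PARAM]
        as_int = int("".join("1" if b else "0" for b in block), 2)
        lo, hi = bounds[p]
        if as_int == 0:
            vals.append(lo)          # exact at the bounds
        elif as_int == 2**BITS_PER_PARAM - 1:
            vals.append(hi)
        else:
            vals.append(lo + (as_int / _DENOM) * (hi - lo))
    return CellModelParams(*vals)


def encode(params: CellModelParams, bounds: np.ndarray | None = None,
           ) -> np.ndarray:
    """Quantize parameter values to the nearest representable bit string."""
    bounds = PARAM_BOUNDS if bounds is None else np.asarray(bounds, float)
    bits = np.zeros(TOTAL_BITS, dtype=np.uint8)
    for p, v in enumerate(params.as_array()):
        lo, hi = bounds[p]
        frac = 0.0 if hi == lo else (v - lo) / (hi - lo)
        as_int = int(round(frac * _DENOM))
        block = format(as_int, f"0{BITS_PER_PARAM}b")
        bits[p * BITS_PER_PARAM:(p + 1) * BITS_PER_PARAM] = [
            int(c) for c in block]
    return bits


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------

def evaluate(params: CellModelParams, targets: ExperimentalTargets,
             forward, early_stop_factor: float = 2.0) -> float:
    """Entry-time error of one parameter set over the target devices.

    ``forward(params, device, diameter_um, time_cap_ms)`` returns the
    simulated entry time in ms, or None when the run hit the cap without
    completing; a capped or failed device contributes |1 - cap/exp| = 1.
    """
    err = 0.0
    for dev, et_exp in zip(targets.devices, targets.entry_times_ms):
        cap = early_stop_factor * et_exp
        try:
            et_sim = forward(params, dev, targets.diameter_um, cap)
        except Exception:
            et_sim = None
        if et_sim is None or not math.isfinite(et_sim):
            et_sim = cap
        err += abs(1.0 - et_sim / et_exp)
    return err


# ---------------------------------------------------------------------------
# Evolution
# ---------------------------------------------------------------------------

def next_generation(parents: np.ndarray, config: GAConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Candidates of one generation: parents plus crossed-over/mutated children.

    Consecutive parents are paired; with probability ``crossover_prob`` a
    pair is recombined by single-point crossover over the full bit string,
    otherwise the children copy the parents; every child bit then flips
    when a uniform draw exceeds ``mutation_prob``.
    """
    n, width = parents.shape
    children = parents.copy()
    for pair in range(n // 2):
        i, j = 2 * pair, 2 * pair + 1
        if rng.random() < config.crossover_prob:
            point = int(rng.integers(1, width))
            children[i, point:] = parents[j, point:]
            children[j, point:] = parents[i, point:]
    flip = rng.random(children.shape) > config.mutation_prob
    children = np.where(flip, 1 - children, children)
    return np.vstack([parents, children])


@dataclass
class IdentificationResult:
    params: CellModelParams
    error: float
    history: pd.DataFrame     # generation, K_b, K_v, K_a, K_l, VR, Error
    generations: int
    seed: int
    stalled: bool             # stopped by the stall rule (vs budget)
    evaluations: int


def identify(targets, forward,
             config: GAConfig | None = None) -> IdentificationResult:
    """Run the GA until the best error stalls; return the best parameters.

    ``targets`` is one :class:`ExperimentalTargets` (the standard protocol:
    three devices at one cell diameter) or a sequence of them (e.g. several
    diameters), whose errors are summed.  The per-generation best parameter
    set and error are logged in the convergence-table format (generation,
    K_b, K_v, K_a, K_l, VR, Error).  Evaluations are memoized on the bit
    string, so elites carried between generations are not re-simulated.
    """
    config = config or GAConfig()
    target_list = ([targets] if isinstance(targets, ExperimentalTargets)
                   else list(targets))
    rng = np.random.default_rng(config.seed)
    pop = rng.integers(0, 2, size=(config.population_size, TOTAL_BITS),
                       dtype=np.uint8)
    cache: dict[bytes, float] = {}
    n_evals = 0

    def fitness(bits: np.ndarray) -> float:
        nonlocal n_evals
        key = bits.tobytes()
        if key not in cache:
            params = decode(bits, config.bounds)
            cache[key] = sum(
                evaluate(params, t, forward, config.early_stop_factor)
                for t in target_list)
            n_evals += 1
        return cache[key]

    best_bits = None
    best_err = math.inf
    stall = 0
    rows = []
    gen = 0
    stalled = False
    while gen < config.max_generations:
        gen += 1
        candidates = next_generation(pop, config, rng)
        errs = np.array([fitness(b) for b in candidates])
        order = np.argsort(errs, kind="stable")
        gen_best = errs[order[0]]
        if gen_best < best_err:
            best_err = gen_best
            best_bits = candidates[order[0]].copy()
            stall = 0
        else:
            stall += 1
        p = decode(candidates[order[0]], config.bounds)
        rows.append({"generation": gen, "K_b": p.K_b, "K_v": p.K_v,
                     "K_a": p.K_a, "K_l": p.K_l, "VR": p.VR,
                     "Error": gen_best})
        if stall >= config.stall_generations:
            stalled = True
            break
        elites = candidates[order[:config.elite_count]]
        fresh = rng.integers(
            0, 2, size=(config.population_size - config.elite_count,
                        TOTAL_BITS), dtype=np.uint8)
        pop = np.vstack([elites, fresh])

    return IdentificationResult(
        params=decode(best_bits, config.bounds),
        error=best_err,
        history=pd.DataFrame(rows),
        generations=gen,
        seed=config.seed,
        stalled=stalled,
        evaluations=n_evals,
    )
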