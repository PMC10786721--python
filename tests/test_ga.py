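import numpy as np
import pytest

from cellsqueeze.ga import (GAConfig, GAError, ExperimentalTargets, decode,
                            encode, evaluate, identify, next_generation,
                            TOTAL_BITS)
from cellsqueeze.membrane import PARAM_BOUNDS, CellModelParams
from cellsqueeze.synthetic import surrogate_forward, surrogate_targets


def test_decode_hits_bounds_exactly():
    zeros = np.zeros(TOTAL_BITS, dtype=np.uint8)
    ones = np.ones(TOTAL_BITS, dtype=np.uint8)
    lo = decode(zeros).as_array()
    hi = decode(ones).as_array()
    assert np.array_equal(lo, PARAM_BOUNDS[:, 0])
    assert np.array_equal(hi, PARAM_BOUNDS[:, 1])


def test_decode_midpoint_block():
    bits = np.zeros(TOTAL_BITS, dtype=np.uint8)
    bits[0] = 1  # leading bit of the first block: value 2^127
    p = decode(bits)
    assert p.K_l == pytest.approx(0.5e6, rel=1e-12)


def test_decode_wrong_length_rejected():
    with pytest.raises(GAError, match="640"):
        decode(np.zeros(100, dtype=np.uint8))


def test_decode_monotone_per_parameter(rng):
    bounds = PARAM_BOUNDS
    prev = -1.0
    for msb in range(0, 17, 4):
        bits = np.zeros(TOTAL_BITS, dtype=np.uint8)
        bits[msb:] = 0
        bits[:msb] = 1  # growing integer
        v = decode(bits, bounds).K_l
        assert v >= prev
        prev = v


def test_encode_decode_round_trip():
    p = CellModelParams(K_l=23203.0, K_b=45526.0, K_a=19816.0,
                        K_v=93182.0, VR=19.9)
    q = decode(encode(p)).as_array()
    assert np.allclose(q, p.as_array(), rtol=1e-12)


def test_error_function_cases():
    targets = ExperimentalTargets(
        devices=("device1", "device2", "device3"), diameter_um=18.0,
        entry_times_ms=(15.1, 10.6, 6.4))
    p = CellModelParams(1e4, 1e4, 1e4, 1e4, 5.0)

    sim = {"device1": 15.1, "device2": 10.6, "device3": 6.4}
    assert evaluate(p, targets, lambda pp, d, dd, cap: sim[d]) == 0.0
    # twice the experimental time everywhere
    assert evaluate(p, targets,
                    lambda pp, d, dd, cap: 2 * sim[d]) == pytest.approx(3.0)
    # two exact devices, one capped run (contributes |1 - 2| = 1)
    mixed = {"device1": 15.1, "device2": 10.6, "device3": None}
    assert evaluate(p, targets,
                    lambda pp, d, dd, cap: mixed[d]) == pytest.approx(1.0)
    # a forward-model failure also contributes 1
    def broken(pp, d, dd, cap):
        if d == "device3":
            raise RuntimeError("diverged")
        return sim[d]
    assert evaluate(p, targets, broken) == pytest.approx(1.0)


def test_targets_validation():
    with pytest.raises(GAError):
        ExperimentalTargets(devices=("a", "b"), diameter_um=16.0,
                            entry_times_ms=(1.0,))
    with pytest.raises(GAError):
        ExperimentalTargets(devices=("a",), diameter_um=16.0,
                            entry_times_ms=(-1.0,))


def test_generation_candidate_counts(rng):
    config = GAConfig(seed=3)
    parents = rng.integers(0, 2, size=(60, TOTAL_BITS), dtype=np.uint8)
    candidates = next_generation(parents, config, np.random.default_rng(3))
    assert candidates.shape == (120, TOTAL_BITS)  # 120 sets per generation
    assert np.array_equal(candidates[:60], parents)


def test_no_crossover_no_mutation_children_copy_parents(rng):
    config = GAConfig(crossover_prob=0.0, mutation_prob=1.0)  # flips never
    parents = rng.integers(0, 2, size=(10, TOTAL_BITS), dtype=np.uint8)
    candidates = next_generation(parents, config, np.random.default_rng(0))
    assert np.array_equal(candidates[10:], parents)


def test_mutation_rate_matches_threshold(rng):
    config = GAConfig(crossover_prob=0.0, mutation_prob=0.6)
    parents = np.zeros((60, TOTAL_BITS), dtype=np.uint8)
    candidates = next_generation(parents, config, np.random.default_rng(5))
    flip_rate = candidates[60:].mean()
    assert flip_rate == pytest.approx(0.4, abs=0.01)


def _quadratic_forward(p_star):
    def forward(params, device, diameter, cap):
        z = params.as_array() / PARAM_BOUNDS[:, 1]
        zs = p_star.as_array() / PARAM_BOUNDS[:, 1]
        base = {"device1": 3.0, "device2": 2.0, "device3": 1.0}[device]
        return base * (1.0 + ((z - zs) ** 2).sum())
    return forward


def test_identify_monotone_best_error_and_determinism():
    p_star = CellModelParams(4e5, 2e5, 6e5, 1e5, 20.0)
    forward = _quadratic_forward(p_star)
    targets = ExperimentalTargets(
        devices=("device1", "device2", "device3"), diameter_um=16.0,
        entry_times_ms=(3.0, 2.0, 1.0))
    cfg = GAConfig(seed=11, max_generations=12, stall_generations=50)
    res1 = identify(targets, forward, cfg)
    errs = res1.history["Error"].to_numpy()
    assert np.all(np.diff(errs) <= 1e-15)  # elitism: non-increasing
    res2 = identify(targets, forward, GAConfig(seed=11, max_generations=12,
                                               stall_generations=50))
    assert res2.history.equals(res1.history)  # bit-for-bit reproducible
    assert res2.params.as_array().tolist() == res1.params.as_array().tolist()


def test_identify_stall_rule_stops():
    targets = ExperimentalTargets(devices=("device1",), diameter_um=16.0,
                                  entry_times_ms=(1.0,))
    cfg = GAConfig(seed=0, stall_generations=5, max_generations=100)
    res = identify(targets, lambda *a: 1.0, cfg)  # constant fitness
    assert res.stalled
    # best error set at generation 1, unchanged for stall_generations after
    assert res.generations == 1 + cfg.stall_generations


def test_identify_history_has_convergence_log_columns():
    targets = surrogate_targets(CellModelParams(2e4, 4e4, 2e4, 9e4, 19.9))
    cfg = GAConfig(seed=2, max_generations=3, stall_generations=50)
    res = identify(targets, surrogate_forward, cfg)
    assert list(res.history.columns) == [
        "generation", "K_b", "K_v", "K_a", "K_l", "VR", "Error"]
    assert res.history["generation"].tolist() == [1, 2, 3]
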