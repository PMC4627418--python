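"""Degree-preserving network randomization and the NEST permutation test.

The null model is stub rewiring of the *unweighted* network: every edge is
cut into two stubs attached to its endpoints, and stubs are re-paired
uniformly at random, rejecting pairings that would create a self-loop or a
duplicate edge. Because rejection can leave the process stuck with only
illegal pairings, an attempt that stalls restarts from scratch; an attempt
is accepted once at least ``min_reconnect_fraction`` (default 98%) of the
original edges are placed and no further legal pairing exists, discarding
the few leftover stubs. Every placed edge carries weight 1 — the
randomization deliberately forgets confidence weights, while the observed
scores keep them.

The permutation test recomputes NEST scores on ``n_random`` rewired
networks and summarizes, per gene:

    Z = (real score − mean of random scores) / sd of random scores

with the empirical p taken from the tail in the direction of Z — the
fraction of random scores ≥ the real score when Z ≥ 0, ≤ when Z < 0. A
zero count is reported as p = 1/n_random and flagged as an upper bound.
"Spread of the random scores" is the sample standard deviation (divisor
n − 1), not sd/sqrt(n): a standard error would shrink with n_random and
make Z grow without bound as more random networks are drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Mapping
from typing import Optional

import numpy as np
import pandas as pd

from .errors import RewiringError, ValidationError
from .network import WeightedGeneNetwork
from .scoring import ValueVector, _as_series, nest_scores


@dataclass(frozen=True)
class RandomizationConfig:
    """Knobs of the randomization null.

    ``n_random`` random networks (the reference analysis used 1000);
    ``min_reconnect_fraction`` is the fraction of original edges a rewiring
    attempt must place to be accepted (0.98); ``max_restarts`` bounds how
    many stalled attempts are retried before giving up. Replicate ``i``
    uses seed ``seed + i``, so results are independent of execution order.
    """

    n_random: int = 1000
    seed: int = 0
    min_reconnect_fraction: float = 0.98
    max_restarts: int = 100

    def __post_init__(self):
        if self.n_random < 1:
            raise ValidationError("n_random must be >= 1")
        if not (0 < self.min_reconnect_fraction <= 1):
            raise ValidationError("min_reconnect_fraction must be in (0, 1]")
        if self.max_restarts < 1:
            raise ValidationError("max_restarts must be >= 1")


def _find_legal_pair(stubs: list[int], edges: set[tuple[int, int]]) -> Optional[tuple[int, int]]:
    """Exhaustively look for any legal pairing among the remaining stubs."""
    for i in range(len(stubs)):
        for j in range(i + 1, len(stubs)):
            a, b = stubs[i], stubs[j]
            if a != b and (min(a, b), max(a, b)) not in edges:
                return i, j
    return None


def _swap_pop(stubs: list[int], i: int) -> int:
    """O(1) removal: overwrite position i with the last element, pop the tail."""
    last = stubs.pop()
    if i < len(stubs):
        value = stubs[i]
        stubs[i] = last
        return value
    return last


def _rewire_attempt(stub_pool: np.ndarray, rng: np.random.Generator) -> set[tuple[int, int]]:
    """One stub-pairing pass; returns the placed edges.

    Stops only when fewer than two stubs remain or no legal pairing exists
    among them (verified exhaustively once random retries exceed the stall
    cap of 10 × remaining stub pairs without progress).
    """
    stubs = list(stub_pool)
    edges: set[tuple[int, int]] = set()
    failures = 0
    while len(stubs) >= 2:
        if failures > 10 * (len(stubs) // 2):
            # stalled: fall back to exhaustive search so the attempt ends
            # only when genuinely no legal pairing remains
            pair = _find_legal_pair(stubs, edges)
            if pair is None:
                break
            i, j = pair
            b = _swap_pop(stubs, j)
            a = _swap_pop(stubs, i)
            edges.add((min(a, b), max(a, b)))
            failures = 0
            continue
        i = int(rng.integers(len(stubs)))
        a = _swap_pop(stubs, i)
        j = int(rng.integers(len(stubs)))
        b = _swap_pop(stubs, j)
        if a == b or (min(a, b), max(a, b)) in edges:
            stubs.append(a)
            stubs.append(b)
            failures += 1
        else:
            edges.add((min(a, b), max(a, b)))
            failures = 0
    return edges


def stub_rewire(
    net: WeightedGeneNetwork,
    seed: int,
    cfg: Optional[RandomizationConfig] = None,
) -> WeightedGeneNetwork:
    """Degree-preserving randomization of ``net``; all output weights are 1.

    The node set is unchanged; the degree sequence is preserved up to the
    at most ``1 − min_reconnect_fraction`` of edges whose stubs could not
    be legally paired and were discarded.
    """
    cfg = cfg or RandomizationConfig()
    if net.n_edges < 2:
        raise ValidationError("stub rewiring needs a network with >= 2 edges")
    nodes = net.nodes
    index = {g: i for i, g in enumerate(nodes)}
    stub_pool = np.empty(2 * net.n_edges, dtype=np.int64)
    k = 0
    for a, b, _ in net.edges():
        stub_pool[k] = index[a]
        stub_pool[k + 1] = index[b]
        k += 2
    rng = np.random.default_rng(seed)
    m = net.n_edges
    best_fraction = 0.0
    for _ in range(cfg.max_restarts):
        shuffled = stub_pool.copy()
        rng.shuffle(shuffled)
        edges = _rewire_attempt(shuffled, rng)
        fraction = len(edges) / m
        best_fraction = max(best_fraction, fraction)
        if fraction >= cfg.min_reconnect_fraction - 1e-12:
            return WeightedGeneNetwork.from_edges(
                ((nodes[a], nodes[b], 1.0) for a, b in edges), nodes=nodes
            )
    raise RewiringError(
        f"failed to reconnect {cfg.min_reconnect_fraction:.0%} of {m} edges in "
        f"{cfg.max_restarts} restarts (best attempt: {best_fraction:.1%})"
    )


@dataclass
class PermutationResult:
    """Per-gene summary of the randomized-network null.

    ``table`` columns: ``nest_score`` (on the real weighted network),
    ``null_mean``, ``null_sd`` (sample sd over random networks), ``z``
    (NaN when the null is degenerate, null_sd = 0), ``p`` in (0, 1],
    ``p_is_upper_bound`` (True when the tail count was zero), and the raw
    tail counts ``n_ge`` / ``n_le`` (random scores ≥ / ≤ the real score,
    useful for fixed-direction calibration checks).
    """

    table: pd.DataFrame
    n_random: int
    config: RandomizationConfig = field(default_factory=RandomizationConfig)


def summarize_null(real: pd.Series, null_scores: np.ndarray, n_random: int) -> pd.DataFrame:
    """Turn a (genes × n_random) matrix of random scores into the Z/p table.

    Separated from the rewiring loop so the tail and Z conventions are
    directly testable on hand-constructed null draws.
    """
    if n_random < 2:
        raise ValidationError("n_random must be >= 2 for a null standard deviation")
    real_arr = real.to_numpy(dtype=float)[:, None]
    null_mean = null_scores.mean(axis=1)
    null_sd = null_scores.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(null_sd > 0, (real_arr[:, 0] - null_mean) / null_sd, np.nan)
    n_ge = (null_scores >= real_arr).sum(axis=1)
    n_le = (null_scores <= real_arr).sum(axis=1)
    upper = np.isnan(z) | (z >= 0)
    count = np.where(upper, n_ge, n_le)
    p_is_upper_bound = count == 0
    p = np.maximum(count, 1) / n_random
    return pd.DataFrame(
        {
            "nest_score": real_arr[:, 0],
            "null_mean": null_mean,
            "null_sd": null_sd,
            "z": z,
            "p": p,
            "p_is_upper_bound": p_is_upper_bound,
            "n_ge": n_ge,
            "n_le": n_le,
        },
        index=real.index,
    )


def permutation_test(
    net: WeightedGeneNetwork,
    values: ValueVector,
    cfg: Optional[RandomizationConfig] = None,
) -> PermutationResult:
    """NEST permutation test against the degree-preserving rewired null.

    Real scores use the network's true confidence weights; each of the
    ``n_random`` rewired networks is unweighted (weight-1 edges), following
    the randomization of the unweighted interaction network. Replicate
    ``i`` is rewired with seed ``cfg.seed + i``, making the whole result a
    pure function of the configuration.
    """
    cfg = cfg or RandomizationConfig()
    if cfg.n_random < 2:
        raise ValidationError("permutation test needs n_random >= 2")
    v = _as_series(values)
    real = nest_scores(net, v).scored()  # network nodes only
    order = list(real.index)
    null = np.empty((len(order), cfg.n_random), dtype=float)
    for i in range(cfg.n_random):
        rewired = stub_rewire(net, seed=cfg.seed + i, cfg=cfg)
        null[:, i] = nest_scores(rewired, v).scores.reindex(order).to_numpy()
    table = summarize_null(real, null, cfg.n_random)
    return PermutationResult(table=table, n_random=cfg.n_random, config=cfg)
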