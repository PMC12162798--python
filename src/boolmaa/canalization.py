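"""Sensitivity and effective connectivity of Boolean functions.

Sensitivity is the mean number of single-input flips that change the output,
averaged over all input states.  Effective connectivity measures how many
input values are actually needed to settle the output: for each input state
the covering prime implicants (of the ON-set if the output is 1, of the
OFF-set otherwise) tell how many inputs are redundant there, and the
in-degree minus the mean redundancy is the effective connectivity.  A value
well below the in-degree means the function is strongly canalizing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import logic

__all__ = [
    "sensitivity",
    "effective_connectivity",
    "EnsembleCanalization",
    "ensemble_canalization",
]


def _as_table(f) -> np.ndarray:
    """Accept an expression string, a (inputs, table) pair, or a table."""
    if isinstance(f, str):
        inputs, table = logic.table_from_expression(f)
        return np.asarray(table, dtype=np.uint8)
    if isinstance(f, tuple) and len(f) == 2 and not isinstance(f[0], (int, np.integer)):
        return np.asarray(f[1], dtype=np.uint8)
    table = np.asarray(f, dtype=np.uint8).ravel()
    if len(table) & (len(table) - 1):
        raise ValueError("truth-table length must be a power of two")
    return table


def sensitivity(f) -> float:
    """Average number of inputs whose flip changes the output.

    ``(1/2**k) * sum_x |{i : f(x) != f(x ^ e_i)}|``; equals k times the
    probability that a random single-input flip of a random state changes
    the output.
    """
    table = _as_table(f)
    k = int(np.log2(len(table))) if len(table) > 1 else 0
    if k == 0:
        return 0.0
    cube = table.reshape((2,) * k)
    total = 0
    for axis in range(k):
        lo = np.take(cube, 0, axis=axis)
        hi = np.take(cube, 1, axis=axis)
        total += 2 * int(np.count_nonzero(lo != hi))
    return total / len(table)


def effective_connectivity(f) -> float:
    """In-degree minus the mean input redundancy over all input states.

    For state x, the redundancy k_r(x) is the mean number of wildcards among
    the prime implicants (of x's own output class) covering x; the implicants
    covering a state are averaged unweighted.  Ranges from 0 (constant
    function) to k (no two adjacent states share an output class pattern).
    """
    table = _as_table(f)
    k = int(np.log2(len(table))) if len(table) > 1 else 0
    if k == 0:
        return 0.0
    primes = {0: logic.prime_implicants(table, value=0),
              1: logic.prime_implicants(table, value=1)}
    total_kr = 0.0
    for x in range(len(table)):
        cover = logic.covering_implicants(primes[int(table[x])], x)
        wildcards = [k - bin(mask).count("1") for mask, _ in cover]
        total_kr += sum(wildcards) / len(wildcards)
    return k - total_kr / len(table)


@dataclass(frozen=True)
class EnsembleCanalization:
    """Mean canalization measures of a random-function ensemble."""

    mean_sensitivity: float
    mean_effective_connectivity: float
    se_sensitivity: float | None = None
    se_effective_connectivity: float | None = None


def _all_tables(k: int) -> np.ndarray:
    """All 2**(2**k) truth tables on k inputs, one per row."""
    width = 1 << k
    ids = np.arange(1 << width, dtype=np.int64)
    return ((ids[:, None] >> np.arange(width)[None, :]) & 1).astype(np.uint8)


def ensemble_canalization(k: int, p: float, mode: str = "exact",
                          n: int | None = None, seed: int | None = None,
                          essential_only: bool = False) -> EnsembleCanalization:
    """Canalization measures of k-input functions with i.i.d. Bernoulli(p)
    truth-table entries.

    ``exact`` enumerates all 2**(2**k) tables (k <= 4) and weights each by
    ``p**ones * (1-p)**zeros``; ``sample`` draws ``n`` tables and reports
    Monte-Carlo means with standard errors.  ``essential_only`` conditions
    the ensemble on every input being essential.
    """
    if mode == "exact":
        if k > 4:
            raise ValueError("exact enumeration is limited to k <= 4")
        tables = _all_tables(k)
        ones = tables.sum(axis=1)
        logw = ones * np.log(p) + ((1 << k) - ones) * np.log1p(-p)
        weights = np.exp(logw)
        if essential_only:
            keep = np.array([len(logic.essential_inputs(t)) == k for t in tables])
            tables, weights = tables[keep], weights[keep]
            weights = weights / weights.sum()
        sens = np.array([sensitivity(t) for t in tables])
        ec = np.array([effective_connectivity(t) for t in tables])
        return EnsembleCanalization(float(weights @ sens), float(weights @ ec))
    if mode == "sample":
        if n is None:
            raise ValueError("sample mode requires n")
        rng = np.random.default_rng(seed)
        sens_list, ec_list = [], []
        while len(sens_list) < n:
            table = (rng.random(1 << k) < p).astype(np.uint8)
            if essential_only and len(logic.essential_inputs(table)) != k:
                continue
            sens_list.append(sensitivity(table))
            ec_list.append(effective_connectivity(table))
        sens = np.array(sens_list)
        ec = np.array(ec_list)
        return EnsembleCanalization(
            float(sens.mean()), float(ec.mean()),
            float(sens.std(ddof=1) / np.sqrt(n)) if n > 1 else None,
            float(ec.std(ddof=1) / np.sqrt(n)) if n > 1 else None,
        )
    raise ValueError(f"unknown mode {mode!r}")
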