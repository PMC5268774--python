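"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive results by exhaustive enumeration
or naive scanning, so that the package's dynamic programs and seeded
index-based scans are checked against a second, independent route.
"""

from __future__ import annotations

import math
import random

import pytest

from mircatch.folding import (
    HELIX_INIT_CENTS,
    MIN_HAIRPIN,
    R_KCAL,
    can_pair,
    stack_energy_cents,
)

# the three published capture-oligo sequences used as worked examples
MSLN_OLIGOS = {
    "MSLN_1": "AGAGGCTGGAAATGTTAGGTGGGTT",
    "MSLN_2": "AGGGTGTCTAGGGTGTCTTTGT",
    "MSLN_3": "TATTCGGACCCGTTCATGTTCTGGA",
}

DNA_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


# ---------------------------------------------------------------------------
# folding oracle: exhaustive enumeration of nested structures
# ---------------------------------------------------------------------------


def enumerate_structures(seq: str) -> list[frozenset[tuple[int, int]]]:
    """All nested structures (0-based pair sets) with hairpin >= 3."""
    n = len(seq)
    memo: dict[tuple[int, int], list[frozenset]] = {}

    def rec(i: int, j: int) -> list[frozenset]:
        if (i, j) in memo:
            return memo[(i, j)]
        if j - i + 1 <= 0:
            return [frozenset()]
        out = list(rec(i, j - 1))
        for k in range(i, j - MIN_HAIRPIN):
            if "N" not in (seq[k], seq[j]) and can_pair(seq[k], seq[j]):
                for left in rec(i, k - 1):
                    for inner in rec(k + 1, j - 1):
                        out.append(left | inner | {(k, j)})
        memo[(i, j)] = out
        return out

    return rec(0, n - 1)


def structure_energy_cents(seq: str, pairs) -> int:
    """Independent energy formula: stack sum + init per maximal helix."""
    ps = set(pairs)
    total = 0
    n_stacks = 0
    for (i, j) in ps:
        if (i + 1, j - 1) in ps:
            n_stacks += 1
            total += stack_energy_cents(seq[i], seq[j], seq[i + 1], seq[j - 1])
    return total + HELIX_INIT_CENTS * (len(ps) - n_stacks)


def dotbracket(n: int, pairs) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return "".join(db)


def boltzmann_ensemble(seq: str, temperature_c: float = 37.0):
    """(structures, weights, Z) by exhaustive enumeration."""
    beta = 1.0 / (R_KCAL * (temperature_c + 273.15))
    structs = enumerate_structures(seq)
    weights = [
        math.exp(-beta * structure_energy_cents(seq, s) / 100.0) for s in structs
    ]
    return structs, weights, sum(weights)


# ---------------------------------------------------------------------------
# self-dimer oracle: exhaustive offsets, runs and run subsets
# ---------------------------------------------------------------------------


def naive_self_dimer_dg(
    oligo: str,
    stack_dg37,
    min_run: int = 2,
    loop_penalty: float = 2.0,
) -> float | None:
    """Best self-dimer dG by brute force over offsets and helix subsets.

    ``stack_dg37(dinuc)`` gives the DNA:DNA stack free energy.
    """
    n = len(oligo)
    best = None
    for offset in range(2 * n - 1):
        runs: list[list[int]] = []
        cur: list[int] = []
        for i in range(max(0, offset - n + 1), min(n, offset + 1)):
            j = offset - i
            if DNA_COMP[oligo[i]] == oligo[j]:
                cur.append(i)
            else:
                if len(cur) >= min_run:
                    runs.append(cur)
                cur = []
        if len(cur) >= min_run:
            runs.append(cur)
        if not runs:
            continue
        scores = [
            sum(stack_dg37(oligo[i : i + 2]) for i in r[:-1]) for r in runs
        ]
        # all non-empty subsets of helices, each extra helix costs one loop
        m = len(scores)
        for mask in range(1, 2 ** m):
            chosen = [scores[b] for b in range(m) if mask >> b & 1]
            total = sum(chosen) + (len(chosen) - 1) * loop_penalty
            if best is None or total < best:
                best = total
    return best if best is not None and best < 0 else None


@pytest.fixture
def rng():
    return random.Random(20170126)
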