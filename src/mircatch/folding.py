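"""RNA secondary structure and accessibility under a simplified energy model.

The model is deliberately small so that every quantity can be verified by
exhaustive enumeration on short sequences:

* nested Watson-Crick and G:U pairs, no pseudoknots;
* hairpin loops of at least 3 unpaired bases;
* the energy of a structure is the sum of stacking terms for directly
  adjacent pairs (i, j), (i+1, j-1), read from a shipped table, plus a
  flat helix-initiation cost per maximal stacked helix (the standard
  nucleation penalty; without it, zero-cost isolated pairs proliferate
  entropically and every base looks paired in the ensemble).  Unpaired
  bases are free.

Since a structure's helix count equals its pair count minus its stack
count, the initiation cost is implemented exactly as a per-pair cost of
``HELIX_INIT`` with every stack bonus shifted by the same amount.

This is not a Turner-rule folder and makes no attempt to reproduce mFold
energies; its job is to locate single-stranded (accessible) regions of a
target mRNA for capture-oligo placement and to price the opening of a
miRNA binding site (dG_open).

All energies are handled internally in integer hundredths of kcal/mol so
that minimum-energy comparisons and tie-breaking are exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from .seqio import Interval, SequenceError, as_rna

__all__ = [
    "SecondaryStructure",
    "AccessibilityProfile",
    "SSRegion",
    "FoldingResourceError",
    "mfe_fold",
    "pair_probabilities",
    "windowed_accessibility",
    "single_stranded_regions",
    "ensemble_free_energy",
    "delta_g_open",
]

MIN_HAIRPIN = 3  # unpaired bases enclosed by any pair
R_KCAL = 0.0019872  # kcal/(mol*K)
HELIX_INIT_CENTS = 300  # +3.00 kcal/mol per maximal helix (nucleation cost)

_VALID_PAIRS = frozenset({"AU", "UA", "CG", "GC", "GU", "UG"})


class FoldingResourceError(RuntimeError):
    """Sequence exceeds the configured folding length limit."""


@lru_cache(maxsize=None)
def _stack_table() -> dict[tuple[str, str], int]:
    """Stack energies in centi-kcal/mol keyed by (outer pair, inner pair)."""
    text = resources.files("mircatch.data").joinpath("rna_fold_stacks.tsv").read_text()
    table: dict[tuple[str, str], int] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("pair5\t"):
            continue
        p5, p3, g = line.split("\t")
        table[(p5, p3)] = round(float(g) * 100)
    return table


def can_pair(a: str, b: str) -> bool:
    return a + b in _VALID_PAIRS


def stack_energy_cents(outer_5: str, outer_3: str, inner_5: str, inner_3: str) -> int:
    """Stacking energy of inner pair on outer pair, centi-kcal/mol."""
    return _stack_table()[(outer_5 + outer_3, inner_5 + inner_3)]


def _validate_rna(seq: str) -> str:
    rna = as_rna(seq)
    bad = set(rna) - set("ACGUN")
    if bad:
        raise SequenceError(f"invalid RNA character(s) {sorted(bad)}")
    if not rna:
        raise SequenceError("empty RNA sequence")
    return rna


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested secondary structure with its model energy (kcal/mol)."""

    dot_bracket: str
    pairs: tuple[tuple[int, int], ...]  # 1-based (i, j), i < j
    energy: float

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= len(self.dot_bracket)):
                raise ValueError(f"pair ({i},{j}) outside structure")
            if j - i - 1 < MIN_HAIRPIN:
                raise ValueError(f"pair ({i},{j}) closes a hairpin < {MIN_HAIRPIN}")
            if i in seen or j in seen:
                raise ValueError("base in more than one pair")
            seen.update((i, j))


@dataclass(frozen=True)
class AccessibilityProfile:
    """Per-base unpaired probabilities for an RNA sequence."""

    unpaired_prob: np.ndarray
    temperature_c: float
    model_id: str

    def __post_init__(self) -> None:
        p = np.asarray(self.unpaired_prob, dtype=float)
        if p.ndim != 1:
            raise ValueError("unpaired_prob must be one-dimensional")
        if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
            raise ValueError("unpaired probabilities outside [0, 1]")
        object.__setattr__(self, "unpaired_prob", np.clip(p, 0.0, 1.0))

    def __len__(self) -> int:
        return len(self.unpaired_prob)


@dataclass(frozen=True)
class SSRegion:
    """A contiguous single-stranded (accessible) region."""

    interval: Interval
    mean_unpaired_prob: float
    source: str  # "MFE" | "probability"


# ---------------------------------------------------------------------------
# minimum free energy folding
# ---------------------------------------------------------------------------

_INF = (10**9, 10**9)


def _mfe_tables(seq: str):
    """DP tables of (energy_cents, n_pairs), minimised lexicographically.

    ``E[i][j]`` is the optimum over all nested structures of seq[i..j];
    ``Eb[i][j]`` the optimum given that (i, j) is a pair.  Ties in energy
    prefer fewer pairs.
    """
    n = len(seq)
    E = [[(0, 0)] * n for _ in range(n)]
    Eb = [[_INF] * n for _ in range(n)]

    def e(i: int, j: int) -> tuple[int, int]:
        return (0, 0) if i > j else E[i][j]

    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            # --- Eb(i, j): (i, j) paired ---
            if (
                "N" not in (seq[i], seq[j])
                and can_pair(seq[i], seq[j])
                and j - i - 1 >= MIN_HAIRPIN
            ):
                best = e(i + 1, j - 1)
                inner = Eb[i + 1][j - 1]
                if inner != _INF:
                    s = (
                        stack_energy_cents(seq[i], seq[j], seq[i + 1], seq[j - 1])
                        - HELIX_INIT_CENTS
                    )
                    cand = (inner[0] + s, inner[1])
                    if cand < best:
                        best = cand
                Eb[i][j] = (best[0] + HELIX_INIT_CENTS, best[1] + 1)
            # --- E(i, j) ---
            best = E[i][j - 1] if j - 1 >= i else (0, 0)
            for k in range(i, j - MIN_HAIRPIN):
                kb = Eb[k][j]
                if kb == _INF:
                    continue
                left = e(i, k - 1)
                cand = (left[0] + kb[0], left[1] + kb[1])
                if cand < best:
                    best = cand
            E[i][j] = best
    return E, Eb


def mfe_fold(rna_seq: str) -> SecondaryStructure:
    """Minimum-energy nested structure under the stacking-only model.

    Deterministic: ties in energy prefer fewer pairs, then the
    lexicographically smallest dot-bracket string ('(' < ')' < '.').
    """
    seq = _validate_rna(rna_seq)
    n = len(seq)
    if n < MIN_HAIRPIN + 2:
        return SecondaryStructure("." * n, (), 0.0)
    E, Eb = _mfe_tables(seq)

    def e(i, j):
        return (0, 0) if i > j else E[i][j]

    trace_e_memo: dict[tuple[int, int], str] = {}
    trace_b_memo: dict[tuple[int, int], str] = {}

    def trace_e(i: int, j: int) -> str:
        if i > j:
            return ""
        key = (i, j)
        if key in trace_e_memo:
            return trace_e_memo[key]
        target = E[i][j]
        cands = []
        if (E[i][j - 1] if j - 1 >= i else (0, 0)) == target:
            cands.append(trace_e(i, j - 1) + ".")
        for k in range(i, j - MIN_HAIRPIN):
            kb = Eb[k][j]
            if kb == _INF:
                continue
            left = e(i, k - 1)
            if (left[0] + kb[0], left[1] + kb[1]) == target:
                cands.append(trace_e(i, k - 1) + trace_b(k, j))
        out = min(cands)
        trace_e_memo[key] = out
        return out

    def trace_b(i: int, j: int) -> str:
        key = (i, j)
        if key in trace_b_memo:
            return trace_b_memo[key]
        target = (Eb[i][j][0] - HELIX_INIT_CENTS, Eb[i][j][1] - 1)
        cands = []
        if e(i + 1, j - 1) == target:
            cands.append(trace_e(i + 1, j - 1))
        inner = Eb[i + 1][j - 1]
        if inner != _INF:
            s = (
                stack_energy_cents(seq[i], seq[j], seq[i + 1], seq[j - 1])
                - HELIX_INIT_CENTS
            )
            if (inner[0] + s, inner[1]) == target:
                cands.append(trace_b(i + 1, j - 1))
        out = "(" + min(cands) + ")"
        trace_b_memo[key] = out
        return out

    db = trace_e(0, n - 1)
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for idx, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            pairs.append((stack.pop(), idx))
    return SecondaryStructure(db, tuple(sorted(pairs)), E[0][n - 1][0] / 100.0)


# ---------------------------------------------------------------------------
# partition function (McCaskill-style) and accessibility
# ---------------------------------------------------------------------------


def _pf_inside(seq: str, beta: float, blocked: frozenset[int]):
    """Scaled inside partition function.

    Returns (Z, Zb, c) where Z[i, j] and Zb[i, j] are the partition
    functions over seq[i..j] divided by c**(j-i+1); ``blocked`` positions
    may not pair.  The per-base rescaling constant c is derived from the
    MFE so that values stay within float range for windows of a few
    hundred nucleotides.
    """
    n = len(seq)

    def pairable(i: int, j: int) -> bool:
        return (
            i not in blocked
            and j not in blocked
            and "N" not in (seq[i], seq[j])
            and can_pair(seq[i], seq[j])
            and j - i - 1 >= MIN_HAIRPIN
        )

    # numeric MFE with the same blocking, for the rescaling constant
    mfe_cents = 0
    if n >= MIN_HAIRPIN + 2:
        Ec = [[0] * n for _ in range(n)]
        Ebc = [[None] * n for _ in range(n)]
        for span in range(2, n + 1):
            for i in range(0, n - span + 1):
                j = i + span - 1
                if pairable(i, j):
                    best = Ec[i + 1][j - 1] if i + 1 <= j - 1 else 0
                    if Ebc[i + 1][j - 1] is not None:
                        s = (
                            stack_energy_cents(seq[i], seq[j], seq[i + 1], seq[j - 1])
                            - HELIX_INIT_CENTS
                        )
                        best = min(best, Ebc[i + 1][j - 1] + s)
                    Ebc[i][j] = best + HELIX_INIT_CENTS
                best = Ec[i][j - 1] if j - 1 >= i else 0
                for k in range(i, j - MIN_HAIRPIN):
                    if Ebc[k][j] is None:
                        continue
                    left = Ec[i][k - 1] if k - 1 >= i else 0
                    best = min(best, left + Ebc[k][j])
                Ec[i][j] = best
        mfe_cents = Ec[0][n - 1]
    c = math.exp(-beta * (mfe_cents / 100.0) / max(n, 1))

    w_pair = math.exp(-beta * HELIX_INIT_CENTS / 100.0)
    Z = np.zeros((n, n))
    Zb = np.zeros((n, n))
    for i in range(n):
        Z[i, i] = 1.0 / c
    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            if pairable(i, j):
                inner_z = Z[i + 1, j - 1] if i + 1 <= j - 1 else 1.0
                acc = inner_z
                if i + 1 <= j - 1 and Zb[i + 1, j - 1] > 0:
                    s = (
                        stack_energy_cents(seq[i], seq[j], seq[i + 1], seq[j - 1])
                        - HELIX_INIT_CENTS
                    )
                    sigma = math.exp(-beta * s / 100.0)
                    acc += (sigma - 1.0) * Zb[i + 1, j - 1]
                Zb[i, j] = w_pair * acc / (c * c)
            total = Z[i, j - 1] / c
            for k in range(i, j - MIN_HAIRPIN):
                if Zb[k, j] > 0:
                    left = Z[i, k - 1] if k - 1 >= i else 1.0
                    total += left * Zb[k, j]
            Z[i, j] = total
    return Z, Zb, c


def ensemble_free_energy(
    rna_seq: str,
    temperature_c: float = 37.0,
    force_unpaired: Interval | None = None,
) -> float:
    """Free energy -RT ln Z of the structure ensemble, in kcal/mol.

    ``force_unpaired`` constrains the given 1-based interval to stay
    unpaired in every structure of the ensemble.
    """
    seq = _validate_rna(rna_seq)
    blocked: frozenset[int] = frozenset()
    if force_unpaired is not None:
        if force_unpaired.end > len(seq):
            raise ValueError(f"interval {force_unpaired} outside sequence")
        blocked = frozenset(range(force_unpaired.start - 1, force_unpaired.end))
    beta = 1.0 / (R_KCAL * (temperature_c + 273.15))
    Z, _, c = _pf_inside(seq, beta, blocked)
    n = len(seq)
    log_z = math.log(Z[0, n - 1]) + n * math.log(c)
    return -log_z / beta


def delta_g_open(
    rna_seq: str, interval: Interval, temperature_c: float = 37.0
) -> float:
    """Free-energy cost (>= 0) of keeping *interval* unpaired.

    dG_open = G(ensemble with interval forced single-stranded) minus
    G(unconstrained ensemble); the accessibility cost term of
    accessibility-aware miRNA target scoring.
    """
    g_open = ensemble_free_energy(rna_seq, temperature_c, force_unpaired=interval)
    g_free = ensemble_free_energy(rna_seq, temperature_c)
    return max(g_open - g_free, 0.0)


def pair_probabilities(
    rna_seq: str, temperature_c: float = 37.0, max_len: int = 1500
) -> AccessibilityProfile:
    """Per-base unpaired probabilities from the partition function.

    Uses McCaskill-style inside/outside recursions over the same energy
    model as :func:`mfe_fold`; unpaired_prob(i) = 1 - sum_j P(i pairs j).
    Raises :class:`FoldingResourceError` beyond ``max_len`` (cubic cost);
    use :func:`windowed_accessibility` for long transcripts.
    """
    seq = _validate_rna(rna_seq)
    n = len(seq)
    if n > max_len:
        raise FoldingResourceError(
            f"sequence of {n} nt exceeds the folding limit of {max_len}; "
            "use windowed_accessibility for long transcripts"
        )
    beta = 1.0 / (R_KCAL * (temperature_c + 273.15))
    if n < MIN_HAIRPIN + 2:
        return AccessibilityProfile(np.ones(n), temperature_c, "stacking-pf")
    Z, Zb, c = _pf_inside(seq, beta, frozenset())

    # outside pass, processed by decreasing span
    Oz = np.zeros((n, n))
    Ob = np.zeros((n, n))
    Oz[0, n - 1] = 1.0
    for span in range(n, 1, -1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            oz = Oz[i, j]
            if oz != 0.0:
                if j - 1 >= i:
                    Oz[i, j - 1] += oz / c
                for k in range(i, j - MIN_HAIRPIN):
                    if Zb[k, j] > 0:
                        Ob[k, j] += oz * (Z[i, k - 1] if k - 1 >= i else 1.0)
                        if k - 1 >= i:
                            Oz[i, k - 1] += oz * Zb[k, j]
            ob = Ob[i, j]
            if ob != 0.0 and Zb[i, j] > 0:
                w_pair = math.exp(-beta * HELIX_INIT_CENTS / 100.0)
                Oz[i + 1, j - 1] += ob * w_pair / (c * c)
                if i + 1 <= j - 1 and Zb[i + 1, j - 1] > 0:
                    s = (
                        stack_energy_cents(seq[i], seq[j], seq[i + 1], seq[j - 1])
                        - HELIX_INIT_CENTS
                    )
                    sigma = math.exp(-beta * s / 100.0)
                    Ob[i + 1, j - 1] += ob * w_pair * (sigma - 1.0) / (c * c)

    z_total = Z[0, n - 1]
    P = Zb * Ob / z_total
    paired = P.sum(axis=1) + P.sum(axis=0)
    return AccessibilityProfile(1.0 - paired, temperature_c, "stacking-pf")


def pair_probability_matrix(
    rna_seq: str, temperature_c: float = 37.0
) -> np.ndarray:
    """Full base-pair probability matrix P[i, j] (0-based, i < j)."""
    seq = _validate_rna(rna_seq)
    n = len(seq)
    beta = 1.0 / (R_KCAL * (temperature_c + 273.15))
    if n < MIN_HAIRPIN + 2:
        return np.zeros((n, n))
    Z, Zb, c = _pf_inside(seq, beta, frozenset())
    Oz = np.zeros((n, n))
    Ob = np.zeros((n, n))
    Oz[0, n - 1] = 1.0
    for span in range(n, 1, -1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            oz = Oz[i, j]
            if oz != 0.0:
                if j - 1 >= i:
                    Oz[i, j - 1] += oz / c
                for k in range(i, j - MIN_HAIRPIN):
                    if Zb[k, j] > 0:
                        Ob[k, j] += oz * (Z[i, k - 1] if k - 1 >= i else 1.0)
                        if k - 1 >= i:
                            Oz[i, k - 1] += oz * Zb[k, j]
            ob = Ob[i, j]
            if ob != 0.0 and Zb[i, j] > 0:
                w_pair = math.exp(-beta * HELIX_INIT_CENTS / 100.0)
                Oz[i + 1, j - 1] += ob * w_pair / (c * c)
                if i + 1 <= j - 1 and Zb[i + 1, j - 1] > 0:
                    s = (
                        stack_energy_cents(seq[i], seq[j], seq[i + 1], seq[j - 1])
                        - HELIX_INIT_CENTS
                    )
                    sigma = math.exp(-beta * s / 100.0)
                    Ob[i + 1, j - 1] += ob * w_pair * (sigma - 1.0) / (c * c)
    return Zb * Ob / Z[0, n - 1]


def windowed_accessibility(
    rna_seq: str,
    window: int = 300,
    step: int = 150,
    temperature_c: float = 37.0,
) -> AccessibilityProfile:
    """Accessibility of a long RNA from overlapping folding windows.

    Each window of ``window`` nt (advanced by ``step``) is folded
    independently; per-base unpaired probabilities are averaged over all
    windows covering the base.  Local structure dominates accessibility,
    so this is the standard trade-off of accessibility-based target
    predictors rather than a whole-molecule fold.
    """
    seq = _validate_rna(rna_seq)
    n = len(seq)
    if window < MIN_HAIRPIN + 2 or step < 1:
        raise ValueError("window too small or step < 1")
    if n <= window:
        profile = pair_probabilities(seq, temperature_c, max_len=max(n, window))
        return AccessibilityProfile(
            profile.unpaired_prob, temperature_c, f"stacking-pf-w{window}"
        )
    acc = np.zeros(n)
    cover = np.zeros(n)
    start = 0
    while True:
        end = min(start + window, n)
        sub = pair_probabilities(seq[start:end], temperature_c, max_len=window)
        acc[start:end] += sub.unpaired_prob
        cover[start:end] += 1
        if end == n:
            break
        start += step
        if start + window > n:
            start = n - window
    return AccessibilityProfile(acc / cover, temperature_c, f"stacking-pf-w{window}")


def single_stranded_regions(
    structure_or_profile: SecondaryStructure | AccessibilityProfile,
    min_len: int = 20,
    prob_threshold: float = 0.5,
) -> list[SSRegion]:
    """Maximal single-stranded regions of length >= ``min_len``.

    From a :class:`SecondaryStructure`, runs of unpaired bases in the MFE
    structure; from an :class:`AccessibilityProfile`, runs of bases with
    unpaired probability >= ``prob_threshold``.  Sorted by position.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if isinstance(structure_or_profile, SecondaryStructure):
        free = [ch == "." for ch in structure_or_profile.dot_bracket]
        probs = [1.0 if f else 0.0 for f in free]
        source = "MFE"
    else:
        probs = list(structure_or_profile.unpaired_prob)
        free = [p >= prob_threshold for p in probs]
        source = "probability"
    regions: list[SSRegion] = []
    i = 0
    n = len(free)
    while i < n:
        if free[i]:
            j = i
            while j + 1 < n and free[j + 1]:
                j += 1
            if j - i + 1 >= min_len:
                mean_p = float(np.mean(probs[i : j + 1]))
                regions.append(SSRegion(Interval(i + 1, j + 1), mean_p, source))
            i = j + 1
        else:
            i += 1
    return regions
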