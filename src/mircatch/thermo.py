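"""Nearest-neighbor duplex thermodynamics for capture-oligo screening.

Implements two-state nearest-neighbor (NN) predictions of duplex formation
enthalpy/entropy, free energy at 37 degC and salt/concentration-corrected
melting temperature, plus the self-dimer screen used to reject oligos that
would rather hybridise with themselves than with the target mRNA.

Three duplex classes are supported:

``dna:dna``
    SantaLucia 1998 unified parameters; used for oligo self-dimers.
``dna:rna``
    Sugimoto 1995 hybrid parameters (keyed on the RNA strand); the
    physically appropriate class for a DNA capture oligo bound to its
    mRNA target, and the class whose two-state Tm is quoted in design
    reports.
``rna:rna``
    Xia 1998 parameters.  Design reports quote the annealing free energy
    of the probe::target duplex from this set (the convention of the
    commercial calculator that established the screening thresholds this
    package reproduces).

The melting temperature uses the entropic sodium correction
``dS' = dS + 0.368 * N_stacks * ln[Na+]`` and, by default, the
excess-strand concentration term ``R * ln(C_T)``; the symmetric
``R * ln(C_T/4)`` convention is available via :class:`Conditions`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from .seqio import SequenceError, as_dna, as_rna, reverse_complement

__all__ = [
    "Conditions",
    "DuplexThermo",
    "DimerResult",
    "NNParameterSet",
    "load_parameter_set",
    "duplex_thermo",
    "self_dimer",
    "dimer_ratio",
]

R_GAS = 1.987  # cal/(mol*K)
T37_K = 310.15

DUPLEX_CLASSES = ("dna:dna", "dna:rna", "rna:rna")

_DNA_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class Conditions:
    """Solution conditions for Tm evaluation.

    ``conc_convention`` selects the concentration term of the two-state Tm:
    ``excess`` uses R*ln(C_T) (one strand in excess, the calculator default
    this package mirrors), ``quarter`` uses R*ln(C_T/4) (equimolar
    non-self-complementary strands).
    """

    sodium_molar: float = 0.5
    strand_conc_molar: float = 2.5e-7
    temperature_c: float = 37.0
    conc_convention: str = "excess"

    def __post_init__(self) -> None:
        if self.sodium_molar <= 0:
            raise ValueError("sodium_molar must be > 0")
        if self.strand_conc_molar <= 0:
            raise ValueError("strand_conc_molar must be > 0")
        if self.conc_convention not in ("excess", "quarter"):
            raise ValueError(f"unknown conc_convention {self.conc_convention!r}")

    @property
    def conc_term(self) -> float:
        ct = self.strand_conc_molar
        if self.conc_convention == "quarter":
            ct /= 4.0
        return R_GAS * math.log(ct)


@dataclass(frozen=True)
class NNParameterSet:
    """A nearest-neighbor stack table with initiation/terminal terms.

    ``stacks`` maps a 5'->3' dinucleotide of the keyed strand to
    (dH kcal/mol, dS cal/(mol*K)).  ``keyed_on`` records which strand of
    the duplex the dinucleotides refer to (the probe itself, the probe
    read as RNA, or the complementary RNA target strand).
    """

    duplex_class: str
    stacks: dict[str, tuple[float, float]]
    initiation: tuple[float, float]
    per_end_init: dict[str, tuple[float, float]] | None = None
    terminal_au_penalty: tuple[float, float] | None = None
    keyed_on: str = "probe"

    def __post_init__(self) -> None:
        if len(self.stacks) != 16:
            raise ValueError(
                f"{self.duplex_class}: expected 16 stacks, got {len(self.stacks)}"
            )
        for k, (h, s) in self.stacks.items():
            if not (math.isfinite(h) and math.isfinite(s)):
                raise ValueError(f"non-finite parameters for stack {k}")


def _read_param_tsv(name: str) -> dict[str, tuple[float, float]]:
    text = resources.files("mircatch.data").joinpath(name).read_text()
    values: dict[str, tuple[float, float]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("stack\t"):
            continue
        key, h, s = line.split("\t")
        values[key] = (float(h), float(s))
    return values


@lru_cache(maxsize=None)
def load_parameter_set(duplex_class: str) -> NNParameterSet:
    """Load the shipped NN table for a duplex class."""
    if duplex_class == "dna:dna":
        raw = _read_param_tsv("nn_dna_dna_santalucia1998.tsv")
        gc = raw.pop("init_per_end_GC")
        at = raw.pop("init_per_end_AT")
        return NNParameterSet(
            duplex_class,
            raw,
            initiation=(0.0, 0.0),
            per_end_init={"G": gc, "C": gc, "A": at, "T": at},
            keyed_on="probe",
        )
    if duplex_class == "dna:rna":
        raw = _read_param_tsv("nn_dna_rna_sugimoto1995.tsv")
        init = raw.pop("init")
        return NNParameterSet(
            duplex_class, raw, initiation=init, keyed_on="target_rna"
        )
    if duplex_class == "rna:rna":
        raw = _read_param_tsv("nn_rna_rna_xia1998.tsv")
        init = raw.pop("init")
        term = raw.pop("terminal_AU")
        return NNParameterSet(
            duplex_class,
            raw,
            initiation=init,
            terminal_au_penalty=term,
            keyed_on="probe_as_rna",
        )
    raise ValueError(f"unknown duplex class {duplex_class!r}; use one of {DUPLEX_CLASSES}")


@dataclass(frozen=True)
class DuplexThermo:
    """NN thermodynamics of a probe bound to its exact complement."""

    dH: float  # kcal/mol
    dS: float  # cal/(mol*K)
    dG37: float  # kcal/mol
    tm_c: float
    duplex_class: str
    conditions: Conditions
    n_stacks: int


@dataclass(frozen=True)
class DimerResult:
    """Best self-dimer found by the ungapped offset scan.

    ``best_dG`` is ``None`` when no run of >= 2 complementary pairs exists.
    ``pairs`` lists the paired positions (i, j), 1-based on the two copies.
    """

    best_dG: float | None
    offset: int | None
    pairs: tuple[tuple[int, int], ...]
    n_helices: int = 0


def _nn_sums(seq: str, params: NNParameterSet) -> tuple[float, float]:
    dH, dS = params.initiation
    for i in range(len(seq) - 1):
        try:
            h, s = params.stacks[seq[i : i + 2]]
        except KeyError:
            raise SequenceError(f"no NN parameters for stack {seq[i:i+2]!r}") from None
        dH += h
        dS += s
    if params.per_end_init is not None:
        for end in (seq[0], seq[-1]):
            h, s = params.per_end_init[end]
            dH += h
            dS += s
    if params.terminal_au_penalty is not None:
        h, s = params.terminal_au_penalty
        for end in (seq[0], seq[-1]):
            if end in ("A", "U", "T"):
                dH += h
                dS += s
    return dH, dS


def duplex_thermo(
    probe_dna: str,
    duplex_class: str = "dna:rna",
    conditions: Conditions | None = None,
) -> DuplexThermo:
    """NN thermodynamics of *probe_dna* hybridised to its exact complement.

    The probe is a DNA oligo given 5'->3'; the target is assumed to be the
    exact complement in the stated duplex class.  Returns dH/dS summed over
    stacks plus initiation, dG at 37 degC, and the salt- and
    concentration-corrected two-state Tm.
    """
    conditions = conditions or Conditions()
    probe = as_dna(probe_dna)
    if len(probe) < 2:
        raise SequenceError("probe must be at least 2 nt")
    if set(probe) - set("ACGT"):
        raise SequenceError(f"probe contains non-ACGT characters: {probe}")
    params = load_parameter_set(duplex_class)
    if params.keyed_on == "probe":
        keyed_seq = probe
    elif params.keyed_on == "probe_as_rna":
        keyed_seq = as_rna(probe)
    else:  # the RNA strand of a DNA:RNA hybrid is the probe's complement
        keyed_seq = as_rna(reverse_complement(probe, "DNA"))
    dH, dS = _nn_sums(keyed_seq, params)
    dG37 = dH - T37_K * dS / 1000.0
    n_stacks = len(probe) - 1
    dS_salt = dS + 0.368 * n_stacks * math.log(conditions.sodium_molar)
    tm_c = dH * 1000.0 / (dS_salt + conditions.conc_term) - 273.15
    return DuplexThermo(dH, dS, dG37, tm_c, duplex_class, conditions, n_stacks)


def _stack_dg37(dinuc: str, params: NNParameterSet) -> float:
    h, s = params.stacks[dinuc]
    return h - T37_K * s / 1000.0


def self_dimer(
    oligo_dna: str,
    conditions: Conditions | None = None,
    min_run: int = 2,
    loop_penalty: float = 2.0,
) -> DimerResult:
    """Ungapped self-dimer scan of a DNA oligo.

    Two copies of the oligo are aligned antiparallel at every offset; each
    maximal run of >= ``min_run`` consecutive Watson-Crick pairs is scored
    as a helix by its DNA:DNA stack free energies.  Within one offset an
    optimal subset of helices is retained, charging a flat
    ``loop_penalty`` kcal/mol for each interior loop between consecutive
    retained helices.  The minimum total dG over all offsets is reported;
    ``best_dG`` is ``None`` when no helix exists anywhere.
    """
    oligo = as_dna(oligo_dna)
    if len(oligo) < 4:
        raise SequenceError("self_dimer requires an oligo of >= 4 nt")
    if set(oligo) - set("ACGT"):
        raise SequenceError(f"oligo contains non-ACGT characters: {oligo}")
    params = load_parameter_set("dna:dna")
    n = len(oligo)
    best: tuple[float, int, tuple[tuple[int, int], ...], int] | None = None
    for offset in range(2 * n - 1):
        # column i of the alignment pairs position i of copy A with
        # position offset - i of copy B (both 0-based)
        helices: list[list[int]] = []
        run: list[int] = []
        lo = max(0, offset - n + 1)
        hi = min(n, offset + 1)
        for i in range(lo, hi):
            j = offset - i
            if _DNA_COMP[oligo[i]] == oligo[j]:
                run.append(i)
            else:
                if len(run) >= min_run:
                    helices.append(run)
                run = []
        if len(run) >= min_run:
            helices.append(run)
        if not helices:
            continue
        scores = sorted(
            (
                sum(_stack_dg37(oligo[i : i + 2], params) for i in h[:-1]),
                h[0],
            )
            for h in helices
        )
        # keep the k most stable helices; each extra helix costs one loop
        total = 0.0
        best_k_total = None
        best_k = 0
        for k, (score, _) in enumerate(scores, start=1):
            total += score
            cand = total + (k - 1) * loop_penalty
            if best_k_total is None or cand < best_k_total:
                best_k_total = cand
                best_k = k
        kept_starts = {start for _, start in scores[:best_k]}
        pairs = tuple(
            (i + 1, offset - i + 1)
            for h in helices
            if h[0] in kept_starts
            for i in h
        )
        if best_k_total < 0 and (best is None or best_k_total < best[0]):
            best = (best_k_total, offset, pairs, best_k)
    if best is None:
        return DimerResult(None, None, ())
    return DimerResult(best[0], best[1], best[2], best[3])


def dimer_ratio(dimer: DimerResult, hybrid: DuplexThermo) -> float:
    """Self-dimer dG as a percentage of the probe::target hybridisation dG.

    Both free energies are negative, so the result is a positive percent.
    A dimer of ``None`` (no stable self-structure) gives 0%.
    """
    if hybrid.dG37 >= 0:
        raise ValueError("hybridisation dG must be negative to form a ratio")
    if dimer.best_dG is None:
        return 0.0
    return 100.0 * dimer.best_dG / hybrid.dG37
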