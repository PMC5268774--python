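"""Synthetic inputs with known ground truth for every pipeline stage.

Every generator is deterministic given its seed and returns both the
artefact and a :class:`FixtureTruth` record of what was planted, so tests
can check recovery end to end without any external data:

* :func:`synth_transcript` - an mRNA-like sequence with planted hairpins
  (forced structure) and planted low-complementarity stretches (forced
  single-stranded regions);
* :func:`synth_counts` - a miRNA x library count matrix with
  negative-binomial noise, library-specific size multipliers and planted
  capture enrichment/depletion;
* :func:`synth_mirna_reference` - a mature miRNA reference FASTA;
* :func:`synth_reads` - adapter-tagged small-RNA reads drawn from a
  mature reference at specified abundances.

The count generator's default shape emulates a capture-vs-scrambled
experiment: a few hundred mature miRNAs, three libraries per arm, and a
minority of miRNAs redistributed between the arms (enriched in the
capture arm, with a matching depleted set, as relative abundances must
sum to one).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .capture_diff import CountMatrix
from .seqio import Interval, Transcript, as_dna, reverse_complement

__all__ = [
    "FixtureTruth",
    "synth_transcript",
    "synth_counts",
    "synth_mirna_reference",
    "synth_reads",
]


@dataclass
class FixtureTruth:
    """Ground truth of a synthetic fixture; JSON round-trippable."""

    seed: int
    planted_ss_regions: list[tuple[int, int]] = field(default_factory=list)
    planted_hairpins: list[dict] = field(default_factory=list)
    planted_enriched_mirnas: list[tuple[str, float]] = field(default_factory=list)
    true_abundances: dict[str, float] = field(default_factory=dict)
    size_multipliers: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "FixtureTruth":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        data = json.loads(text)
        data["planted_ss_regions"] = [tuple(x) for x in data["planted_ss_regions"]]
        data["planted_enriched_mirnas"] = [
            (str(a), float(b)) for a, b in data["planted_enriched_mirnas"]
        ]
        return cls(**data)


def synth_transcript(
    seed: int,
    length: int,
    hairpin_specs: tuple[tuple[int, int, int], ...] = (),
    ss_specs: tuple[tuple[int, int], ...] = (),
) -> tuple[Transcript, FixtureTruth]:
    """Random RNA with planted hairpins and single-stranded stretches.

    ``hairpin_specs`` are ``(start_1based, stem_len, loop_len)``: a perfect
    inverted repeat occupying ``2*stem_len + loop_len`` bases from
    ``start``, with a GC-rich stem so the fold is strongly favoured.
    ``ss_specs`` are ``(start_1based, length)``: stretches drawn from
    {A, C} only.  When any ss stretch is planted, the background is
    sampled without adjacent G/U bases: every stacked helix involving the
    stretch would need a GG/GU/UG/UU dinucleotide somewhere as a partner,
    so the stretch stays accessible by construction (isolated pairs are
    already suppressed by the folding model's helix-initiation cost).
    Planted hairpin stems remain the only strong helices.
    """
    rng = np.random.default_rng(seed)
    occupied: list[Interval] = []

    def claim(start: int, span: int, what: str) -> Interval:
        iv = Interval(start, start + span - 1)
        if iv.end > length:
            raise ValueError(f"{what} at {iv} exceeds transcript length {length}")
        for other in occupied:
            if iv.overlaps(other):
                raise ValueError(f"overlapping feature specs at {iv} and {other}")
        occupied.append(iv)
        return iv

    if ss_specs:
        seq = []
        for _ in range(length):
            options = "AC" if seq and seq[-1] in "GU" else "ACGU"
            seq.append(str(rng.choice(list(options))))
    else:
        seq = list(rng.choice(list("ACGU"), size=length))
    truth = FixtureTruth(seed=seed)
    for start, stem_len, loop_len in hairpin_specs:
        iv = claim(start, 2 * stem_len + loop_len, "hairpin")
        stem = "".join(rng.choice(list("GC"), size=stem_len))
        loop = "".join(rng.choice(list("AU"), size=loop_len))
        hp = stem + loop + reverse_complement(stem, "RNA")
        seq[iv.start - 1 : iv.end] = list(hp)
        truth.planted_hairpins.append(
            {
                "stem5": [iv.start, iv.start + stem_len - 1],
                "stem3": [iv.end - stem_len + 1, iv.end],
                "loop_len": loop_len,
            }
        )
    for start, span in ss_specs:
        iv = claim(start, span, "ss region")
        seq[iv.start - 1 : iv.end] = list(rng.choice(list("AC"), size=span))
        truth.planted_ss_regions.append((iv.start, iv.end))
    transcript = Transcript(f"synth-tx-{seed}", "".join(seq), alphabet="RNA")
    return transcript, truth


def synth_counts(
    seed: int,
    n_mirnas: int = 325,
    n_per_group: int = 3,
    base_mean_distribution: tuple[float, float] = (80.0, 1.0),
    dispersion: float = 0.05,
    enriched_spec: tuple[tuple[int, float, float], ...] = (),
    size_multiplier_sigma: float = 0.15,
) -> tuple[CountMatrix, FixtureTruth]:
    """Negative-binomial capture/scrambled count matrix with planted truth.

    ``base_mean_distribution`` is (median, log-sigma) of the lognormal
    scrambled-arm means.  ``enriched_spec`` entries are
    ``(mirna_index, log2fc, base_mean)``: the capture-arm mean of that
    miRNA is multiplied by ``2**log2fc`` and its scrambled-arm mean pinned
    to ``base_mean`` (NaN keeps the drawn mean).  Negative log2fc plants
    relative depletion, the compositional counterpart of enrichment.
    Library-specific size multipliers (lognormal, ``sigma``) emulate
    sequencing-depth differences.  Variance model: mean + dispersion*mean^2.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    ids = [f"syn-mir-{i + 1:04d}" for i in range(n_mirnas)]
    median, sigma = base_mean_distribution
    mu_scr = rng.lognormal(mean=np.log(median), sigma=sigma, size=n_mirnas)
    fold = np.ones(n_mirnas)
    truth = FixtureTruth(seed=seed)
    for idx, log2fc, base_mean in enriched_spec:
        if not 0 <= idx < n_mirnas:
            raise ValueError(f"enriched index {idx} out of range")
        if base_mean == base_mean:  # not NaN
            mu_scr[idx] = base_mean
        fold[idx] = 2.0 ** log2fc
        truth.planted_enriched_mirnas.append((ids[idx], float(log2fc)))
    mu_cap = mu_scr * fold
    libs = [f"msln_{r + 1}" for r in range(n_per_group)] + [
        f"scr_{r + 1}" for r in range(n_per_group)
    ]
    groups = pd.Series(
        ["capture"] * n_per_group + ["scrambled"] * n_per_group, index=libs
    )
    mult = rng.lognormal(mean=0.0, sigma=size_multiplier_sigma, size=len(libs))
    cols = {}
    for lib, m, mu in zip(
        libs, mult, [mu_cap] * n_per_group + [mu_scr] * n_per_group
    ):
        lam = rng.gamma(shape=1.0 / dispersion, scale=(mu * m) * dispersion)
        cols[lib] = rng.poisson(lam)
    counts = pd.DataFrame(cols, index=ids)
    truth.true_abundances = {i: float(v) for i, v in zip(ids, mu_scr)}
    truth.size_multipliers = {lib: float(m) for lib, m in zip(libs, mult)}
    return CountMatrix(counts, groups), truth


def synth_mirna_reference(
    seed: int, n_mirnas: int, length_range: tuple[int, int] = (20, 23)
) -> list[Transcript]:
    """Random mature miRNA reference sequences with miRBase-style ids.

    Sequences are drawn without 5'-end collisions (distinct 16-nt
    prefixes) so that read assignment is unambiguous by construction.
    """
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    out: list[Transcript] = []
    prefixes: set[str] = set()
    while len(out) < n_mirnas:
        n = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list("ACGU"), size=n))
        if seq[:16] in prefixes:
            continue
        prefixes.add(seq[:16])
        out.append(
            Transcript(f"syn-mir-{len(out) + 1:04d}", seq, alphabet="RNA")
        )
    return out


def synth_reads(
    seed: int,
    counts_column: pd.Series,
    mature: list[Transcript],
    adapter: str,
    error_rate: float = 0.0,
    length_jitter: int = 0,
) -> tuple[list[tuple[str, str, str]], FixtureTruth]:
    """Small-RNA reads for one library: mature sequence + 3' adapter.

    ``counts_column`` maps miRNA id to the number of reads to emit.  Each
    read is the mature sequence (optionally +-``length_jitter`` nt at the
    3' end, trimmed or padded with adapter bases) followed by the adapter,
    with independent per-base substitution errors at ``error_rate``.
    Constant quality strings.  Deterministic per seed.
    """
    adapter = as_dna(adapter)
    if len(adapter) < 8:
        raise ValueError("adapter must be at least 8 nt")
    if (counts_column < 0).any():
        raise ValueError("abundances must be non-negative")
    rng = np.random.default_rng(seed)
    by_id = {m.id: as_dna(m.sequence) for m in mature}
    unknown = set(counts_column.index) - set(by_id)
    if unknown:
        raise ValueError(f"abundances for unknown miRNAs: {sorted(unknown)}")
    reads: list[tuple[str, str, str]] = []
    truth = FixtureTruth(seed=seed)
    truth.true_abundances = {
        str(k): float(v) for k, v in counts_column.items() if v > 0
    }
    alphabet = np.array(list("ACGT"))
    serial = 0
    for mirna_id in counts_column.index:
        n_reads = int(counts_column[mirna_id])
        insert_full = by_id[mirna_id]
        for _ in range(n_reads):
            insert = insert_full
            if length_jitter:
                delta = int(rng.integers(-length_jitter, length_jitter + 1))
                insert = insert[: len(insert) + delta] if delta < 0 else insert
            read = insert + adapter
            if error_rate > 0:
                arr = np.array(list(read))
                hits = rng.random(len(arr)) < error_rate
                for pos in np.nonzero(hits)[0]:
                    options = [b for b in alphabet if b != arr[pos]]
                    arr[pos] = options[int(rng.integers(0, 3))]
                read = "".join(arr)
            serial += 1
            reads.append((f"read_{serial}_{mirna_id}", read, "I" * len(read)))
    return reads, truth
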