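"""Quantification of captured miRNAs from small-RNA sequencing.

The pipeline mirrors the analysis stages of an affinity-capture (capture
vs scrambled-control) small-RNA experiment:

1. 3' adapter trimming of raw reads;
2. counting reads against a mature miRNA reference by direct, 5'-anchored
   sequence matching (at most one mismatch, length within +-2 nt);
3. median-of-ratios library normalisation;
4. a negative-binomial Wald test of enrichment in capture vs scrambled
   libraries with Benjamini-Hochberg correction;
5. candidate selection (adjusted p below alpha AND normalised mean count
   above a floor AND positive fold change);
6. 2^-ddCt relative quantification for the qPCR enrichment checks.

The testing procedure is count-model inspired rather than a re-implementation
of any particular differential-expression package: dispersions are
method-of-moments estimates shrunk toward a fitted mean-dispersion trend,
and the Wald statistic is referred to a standard normal (the standard
error is model-based rather than a per-feature sample variance, so the
normal reference stays calibrated at small replicate numbers; verified by
the null simulations in the test suite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from Bio import SeqIO

from .seqio import Transcript, as_dna

__all__ = [
    "CountMatrix",
    "TrimStats",
    "CountStats",
    "read_fastq",
    "write_fastq",
    "trim_adapter",
    "count_mature_mirnas",
    "size_factors",
    "differential_capture",
    "select_candidates",
    "ddct_enrichment",
]

GROUP_LABELS = ("capture", "scrambled")


class FastqError(ValueError):
    """Malformed FASTQ input."""


@dataclass
class CountMatrix:
    """miRNA x library raw counts with per-library group labels."""

    counts: pd.DataFrame  # index: miRNA ids, columns: library ids
    groups: pd.Series  # library id -> "capture" | "scrambled"

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(int)
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative integers")
        self.groups = pd.Series(self.groups)
        missing = set(self.counts.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"libraries without group labels: {sorted(missing)}")
        bad = set(self.groups.unique()) - set(GROUP_LABELS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        self.groups = self.groups.loc[self.counts.columns]

    def libraries(self, group: str) -> list[str]:
        return [lib for lib, g in self.groups.items() if g == group]


@dataclass
class TrimStats:
    total: int = 0
    trimmed: int = 0
    untrimmed: int = 0
    discarded_short: int = 0


@dataclass
class CountStats:
    total: int = 0
    assigned: int = 0
    unassigned: int = 0
    multimapped: int = 0


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """Read FASTQ records as (id, sequence, quality) tuples."""
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            records.append((rec.id, str(rec.seq).upper(), qual))
    except ValueError as exc:
        raise FastqError(f"{path}: malformed FASTQ near record {len(records) + 1}: {exc}")
    return records


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def _find_adapter(seq: str, adapter: str, min_overlap: int, max_mismatches: int) -> int:
    """Leftmost start of a 3' adapter occurrence, or -1.

    A match is a prefix of the adapter of length >= ``min_overlap``
    (truncated at the read end) with at most ``max_mismatches``.
    """
    n = len(seq)
    for start in range(0, n - min_overlap + 1):
        length = min(len(adapter), n - start)
        mism = 0
        ok = True
        for k in range(length):
            if seq[start + k] != adapter[k]:
                mism += 1
                if mism > max_mismatches:
                    ok = False
                    break
        if ok:
            return start
    return -1


def trim_adapter(
    records: Iterable[tuple[str, str, str]],
    adapter: str,
    min_overlap: int = 8,
    max_mismatches: int = 1,
    min_len: int = 16,
) -> tuple[list[tuple[str, str, str]], TrimStats]:
    """Remove 3' adapter sequence from reads.

    The adapter is located by its leftmost prefix match (minimum
    ``min_overlap`` nt, at most ``max_mismatches``); the read is truncated
    at the match start.  Reads shorter than ``min_len`` after trimming are
    discarded.
    """
    adapter = as_dna(adapter)
    if len(adapter) < 8:
        raise ValueError("adapter must be at least 8 nt")
    out = []
    stats_ = TrimStats()
    for rid, seq, qual in records:
        stats_.total += 1
        seq = as_dna(seq)
        cut = _find_adapter(seq, adapter, min_overlap, max_mismatches)
        if cut == -1:
            stats_.untrimmed += 1
            trimmed_seq, trimmed_qual = seq, qual
        else:
            stats_.trimmed += 1
            trimmed_seq, trimmed_qual = seq[:cut], qual[:cut]
        if len(trimmed_seq) < min_len:
            stats_.discarded_short += 1
            continue
        out.append((rid, trimmed_seq, trimmed_qual))
    return out, stats_


def _read_matches(read: str, mature: str, max_mismatches: int, max_len_diff: int):
    """(mismatches, |length difference|) if the read matches, else None."""
    len_diff = abs(len(read) - len(mature))
    if len_diff > max_len_diff:
        return None
    overlap = min(len(read), len(mature))
    mism = sum(1 for a, b in zip(read[:overlap], mature[:overlap]) if a != b)
    if mism > max_mismatches:
        return None
    return (mism, len_diff)


def count_mature_mirnas(
    reads: Iterable[tuple[str, str, str]] | Iterable[str],
    mature: Sequence[Transcript],
    max_mismatches: int = 1,
    max_len_diff: int = 2,
) -> tuple[pd.Series, CountStats]:
    """Count trimmed reads against mature miRNA sequences.

    A read is assigned to a mature miRNA when, anchored at the 5' end, it
    matches the mature sequence with at most ``max_mismatches`` and a
    length difference of at most ``max_len_diff``.  Reads matching two or
    more distinct miRNAs equally well are discarded and counted as
    multimapped.
    """
    ids = [m.id for m in mature]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate miRNA ids in mature reference: {dupes}")
    mature_dna = [(m.id, as_dna(m.sequence)) for m in mature]
    # pigeonhole seeding on the first 16 nt: a read with <= 1 mismatch
    # matches one of the two 8-mer halves of the mature prefix exactly
    index: dict[str, set[int]] = {}
    for idx, (_, seq) in enumerate(mature_dna):
        for half in (seq[0:8], seq[8:16]):
            if len(half) == 8:
                index.setdefault(half, set()).add(idx)
    counts = pd.Series(0, index=ids, dtype=int)
    stats_ = CountStats()
    for item in reads:
        seq = as_dna(item[1] if isinstance(item, tuple) else item)
        stats_.total += 1
        if max_mismatches <= 1 and len(seq) >= 16:
            candidates = index.get(seq[0:8], set()) | index.get(seq[8:16], set())
        else:
            candidates = set(range(len(mature_dna)))
        best = None
        best_ids: list[str] = []
        for idx in candidates:
            mid, mseq = mature_dna[idx]
            score = _read_matches(seq, mseq, max_mismatches, max_len_diff)
            if score is None:
                continue
            if best is None or score < best:
                best = score
                best_ids = [mid]
            elif score == best:
                best_ids.append(mid)
        if best is None:
            stats_.unassigned += 1
        elif len(best_ids) > 1:
            stats_.multimapped += 1
        else:
            counts[best_ids[0]] += 1
            stats_.assigned += 1
    return counts, stats_


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    factor_j = median over features (with all-positive counts) of
    count_ij / geometric_mean_i.
    """
    if counts.shape[1] < 2:
        raise ValueError("size factors need at least 2 libraries")
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError(
            "no feature has positive counts in every library; consider a "
            "pseudo-reference (e.g. add a pseudocount) before normalising"
        )
    log_geo = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_geo, axis=0)
    return np.exp(ratios.median(axis=0))


def _fit_dispersion_trend(mu: np.ndarray, alpha_mom: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu across all features with mu > 0.

    Negative moment estimates are kept in the fit (conditioning on
    positive estimates would bias the trend upward); coefficients are
    clipped at zero, falling back to the median moment estimate (or a
    small floor) when the fit is degenerate.
    """
    mask = mu > 0
    floor = 1e-8
    if mask.sum() >= 3:
        x = np.column_stack([np.ones(mask.sum()), 1.0 / mu[mask]])
        coef, *_ = np.linalg.lstsq(x, alpha_mom[mask], rcond=None)
        a0, a1 = np.clip(coef, 0.0, None)
        if a0 == 0.0 and a1 == 0.0:
            a0 = max(float(np.median(alpha_mom[mask])), floor)
    elif mask.any():
        a0, a1 = max(float(np.median(alpha_mom[mask])), floor), 0.0
    else:
        a0, a1 = floor, 0.0
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.where(mu > 0, mu, np.inf)
    return np.maximum(trend, floor)


def differential_capture(
    matrix: CountMatrix,
    alpha: float = 0.1,
    min_reads: float = 20.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-miRNA differential capture test (capture vs scrambled).

    Counts are normalised by median-of-ratios size factors.  For each
    miRNA with any nonzero count: base_mean is the mean normalised count,
    log2fc = log2((mean_capture + pc) / (mean_scrambled + pc)), and a
    Wald-type statistic log2fc / SE(log2fc) is referred to a standard
    normal, where the standard error comes from
    the delta method under a negative-binomial variance
    mu + alpha_i * mu^2 with trend-shrunk moment dispersions.
    Benjamini-Hochberg adjustment runs across tested miRNAs; all-zero
    miRNAs are reported with NA p-values.

    ``selected`` = (p_adj < alpha) & (base_mean > min_reads) & (log2fc > 0).
    """
    cap_libs = matrix.libraries("capture")
    scr_libs = matrix.libraries("scrambled")
    if not cap_libs or not scr_libs:
        raise ValueError("both capture and scrambled libraries are required")
    sf = size_factors(matrix.counts)
    norm = matrix.counts / sf
    cap = norm[cap_libs]
    scr = norm[scr_libs]
    n1, n2 = len(cap_libs), len(scr_libs)

    base_mean = norm.mean(axis=1)
    mu1 = cap.mean(axis=1)
    mu2 = scr.mean(axis=1)
    log2fc = np.log2((mu1 + pseudocount) / (mu2 + pseudocount))

    # pooled method-of-moments dispersion, then shrink toward the trend
    var_within = (cap.var(axis=1, ddof=1) * (n1 - 1) + scr.var(axis=1, ddof=1) * (n2 - 1)) / (
        n1 + n2 - 2
    )
    mu_pool = (mu1 * n1 + mu2 * n2) / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = (var_within - mu_pool) / mu_pool**2
    alpha_mom = alpha_mom.replace([np.inf, -np.inf], np.nan).fillna(0.0).to_numpy()
    trend = _fit_dispersion_trend(mu_pool.to_numpy(), alpha_mom)
    # geometric-mean shrink toward the trend; rows with a non-positive
    # moment estimate (no evidence of extra-Poisson noise) take the trend
    disp = np.where(
        alpha_mom > 0,
        np.exp(0.5 * (np.log(np.maximum(alpha_mom, 1e-12)) + np.log(trend))),
        trend,
    )

    var1 = (mu1 + disp * mu1**2) / n1
    var2 = (mu2 + disp * mu2**2) / n2
    ln2sq = math.log(2.0) ** 2
    se = np.sqrt(
        var1 / ((mu1 + pseudocount) ** 2 * ln2sq)
        + var2 / ((mu2 + pseudocount) ** 2 * ln2sq)
    )

    tested = base_mean > 0
    stat = log2fc[tested] / se[tested]
    pvals = 2.0 * stats.norm.sf(np.abs(stat))

    p_value = pd.Series(np.nan, index=norm.index)
    p_value[tested] = pvals
    p_adj = pd.Series(np.nan, index=norm.index)
    if tested.any():
        p_adj[tested] = multipletests(pvals, method="fdr_bh")[1]

    selected = (p_adj < alpha) & (base_mean > min_reads) & (log2fc > 0)
    result = pd.DataFrame(
        {
            "mirna": norm.index,
            "base_mean": base_mean.round(4),
            "log2fc": log2fc.round(4),
            "p_value": p_value,
            "p_adj": p_adj,
            "selected": selected.fillna(False),
        }
    ).reset_index(drop=True)
    return result


def select_candidates(
    results: pd.DataFrame, alpha: float = 0.1, min_reads: float = 20.0
) -> pd.DataFrame:
    """Shortlist of enriched miRNAs: p_adj < alpha and base_mean > min_reads.

    Both inequalities are strict; sorted by adjusted p then by descending
    |log2fc|.
    """
    if results.empty:
        return results.copy()
    keep = (
        (results["p_adj"] < alpha)
        & (results["base_mean"] > min_reads)
        & (results["log2fc"] > 0)
    )
    shortlist = results[keep.fillna(False)].copy()
    shortlist["abs_lfc"] = shortlist["log2fc"].abs()
    shortlist = shortlist.sort_values(
        ["p_adj", "abs_lfc"], ascending=[True, False]
    ).drop(columns="abs_lfc")
    return shortlist.reset_index(drop=True)


def ddct_enrichment(table: pd.DataFrame) -> tuple[pd.DataFrame, float, float]:
    """2^-ddCt fold enrichment of the target gene, capture vs scrambled.

    ``table`` must contain columns replicate, condition (capture or
    scrambled), gene (target or reference) and ct; each replicate needs
    all four Ct values in (0, 45).  Per replicate:

    ddCt = (Ct_target - Ct_reference)_capture
         - (Ct_target - Ct_reference)_scrambled,  fold = 2^-ddCt.

    Returns (per-replicate table, mean fold, SEM over replicates).
    """
    required = {"replicate", "condition", "gene", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if ((table["ct"] <= 0) | (table["ct"] >= 45)).any():
        raise ValueError("Ct values must lie in (0, 45)")
    rows = []
    for rep, sub in table.groupby("replicate", sort=True):
        cells = {}
        for _, row in sub.iterrows():
            cells[(row["condition"], row["gene"])] = float(row["ct"])
        expected = [
            ("capture", "target"), ("capture", "reference"),
            ("scrambled", "target"), ("scrambled", "reference"),
        ]
        absent = [k for k in expected if k not in cells]
        if absent:
            raise ValueError(f"replicate {rep!r} missing Ct values: {absent}")
        ddct = (cells[("capture", "target")] - cells[("capture", "reference")]) - (
            cells[("scrambled", "target")] - cells[("scrambled", "reference")]
        )
        rows.append({"replicate": rep, "ddct": ddct, "fold": 2.0 ** (-ddct)})
    per_rep = pd.DataFrame(rows)
    folds = per_rep["fold"].to_numpy()
    mean = float(folds.mean())
    sem = float(folds.std(ddof=1) / math.sqrt(len(folds))) if len(folds) > 1 else 0.0
    return per_rep, mean, sem
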