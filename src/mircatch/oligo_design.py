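"""Antisense capture-oligo design against accessible regions of a target mRNA.

Candidates are antisense DNA windows over single-stranded regions of the
target's predicted secondary structure.  Each candidate is annotated with:

* the two-state Tm of the probe::mRNA hybrid (DNA:RNA parameters) and the
  annealing free energy of the duplex (RNA:RNA parameters) - the pair of
  conventions under which the published screening thresholds (>70 degC,
  self-dimer < 15% of hybridisation dG) were established;
* a self-dimer screen (DNA:DNA);
* mean accessibility (unpaired probability) over the target interval;
* off-target complementarity against a transcript set.

Candidates failing any hard rule are excluded from the ranked report; long
but imperfect off-target matches (e.g. 14-15 nt) only penalise rank, since
a single internal mismatch is typically enough to abrogate capture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from . import folding, thermo
from .seqio import Interval, Transcript, as_dna, extract_region, reverse_complement

__all__ = [
    "DesignConstraints",
    "CandidateOligo",
    "OffTargetHit",
    "enumerate_candidates",
    "evaluate_candidate",
    "offtarget_scan",
    "design_report",
    "design_pipeline",
]

logger = logging.getLogger(__name__)

MODIFICATION = "3'-biotin-TEG"


@dataclass(frozen=True)
class DesignConstraints:
    """Screening thresholds for capture-oligo candidates."""

    length_range: tuple[int, int] = (22, 25)
    min_tm_c: float = 70.0
    max_dimer_ratio_pct: float = 15.0
    gc_range_pct: tuple[float, float] = (40.0, 60.0)
    min_accessibility: float = 0.5
    offtarget_flag_len: int = 14  # minimum off-target match length to report
    ss_mode: str = "contained"  # or "partial"
    min_ss_overlap: int = 13  # accessible bases required in "partial" mode

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError("length_range must be well-ordered")
        g0, g1 = self.gc_range_pct
        if not (0 <= g0 <= g1 <= 100):
            raise ValueError("gc_range_pct must be well-ordered in [0, 100]")
        if self.min_tm_c <= 0 or self.max_dimer_ratio_pct <= 0:
            raise ValueError("thresholds must be positive")
        if self.ss_mode not in ("contained", "partial"):
            raise ValueError(f"unknown ss_mode {self.ss_mode!r}")


@dataclass(frozen=True)
class OffTargetHit:
    """A complementary match between an oligo and a non-target transcript."""

    transcript_id: str
    match_len: int
    mismatches: int
    oligo_span: Interval
    transcript_span: Interval

    def __post_init__(self) -> None:
        if self.transcript_span.length != self.match_len:
            raise ValueError("transcript span inconsistent with match_len")

    @property
    def label(self) -> str:
        """Table-style complementarity label, e.g. ``18/19 LRP5L``."""
        return f"{self.match_len - self.mismatches}/{self.match_len} {self.transcript_id}"


@dataclass
class CandidateOligo:
    """An antisense capture-oligo candidate with full annotation."""

    sequence: str  # antisense DNA, 5'->3'
    target_interval: Interval
    hybrid: thermo.DuplexThermo | None = None  # DNA:RNA, for Tm
    anneal: thermo.DuplexThermo | None = None  # RNA:RNA, for hybridisation dG
    dimer: thermo.DimerResult | None = None
    dimer_ratio_pct: float | None = None
    gc_pct: float | None = None
    accessibility: float | None = None
    offtargets: list[OffTargetHit] = field(default_factory=list)
    flags: dict[str, bool] = field(default_factory=dict)
    modification: str = MODIFICATION

    @property
    def passes(self) -> bool:
        return bool(self.flags) and all(self.flags.values())


def _ss_cover(interval: Interval, ss_regions) -> int:
    """Number of bases of *interval* inside the union of ss regions."""
    covered = 0
    for region in ss_regions:
        iv = region.interval if isinstance(region, folding.SSRegion) else region
        lo = max(interval.start, iv.start)
        hi = min(interval.end, iv.end)
        if hi >= lo:
            covered += hi - lo + 1
    return covered


def enumerate_candidates(
    transcript: Transcript,
    ss_regions: list[folding.SSRegion],
    constraints: DesignConstraints = DesignConstraints(),
    accessibility_profile: folding.AccessibilityProfile | None = None,
    conditions: thermo.Conditions | None = None,
) -> list[CandidateOligo]:
    """All annotated antisense windows targeting accessible regions.

    In ``contained`` mode a window's target interval must lie fully inside
    one single-stranded region; in ``partial`` mode it needs at least
    ``min_ss_overlap`` accessible bases (the regime in which an oligo can
    straddle short paired interruptions, like the best-performing capture
    oligo of the original screen).  Windows overlapping an N are excluded.
    """
    if not ss_regions:
        logger.warning(
            "no single-stranded regions supplied for %s; no candidates", transcript.id
        )
        return []
    conditions = conditions or thermo.Conditions()
    lo, hi = constraints.length_range
    n = len(transcript)
    candidates: list[CandidateOligo] = []
    for length in range(lo, hi + 1):
        for start in range(1, n - length + 2):
            interval = Interval(start, start + length - 1)
            if constraints.ss_mode == "contained":
                ok = any(
                    r.interval.start <= interval.start and interval.end <= r.interval.end
                    for r in ss_regions
                )
            else:
                ok = _ss_cover(interval, ss_regions) >= constraints.min_ss_overlap
            if not ok:
                continue
            sense = extract_region(transcript, interval)
            if "N" in sense:
                continue
            oligo = as_dna(reverse_complement(sense, transcript.alphabet))
            hybrid = thermo.duplex_thermo(oligo, "dna:rna", conditions)
            anneal = thermo.duplex_thermo(oligo, "rna:rna", conditions)
            dimer = thermo.self_dimer(oligo)
            ratio = thermo.dimer_ratio(dimer, anneal)
            if accessibility_profile is not None:
                window = accessibility_profile.unpaired_prob[
                    interval.start - 1 : interval.end
                ]
                access = float(window.mean())
            else:
                access = _ss_cover(interval, ss_regions) / interval.length
            candidates.append(
                CandidateOligo(
                    sequence=oligo,
                    target_interval=interval,
                    hybrid=hybrid,
                    anneal=anneal,
                    dimer=dimer,
                    dimer_ratio_pct=ratio,
                    gc_pct=100.0 * (oligo.count("G") + oligo.count("C")) / len(oligo),
                    accessibility=access,
                )
            )
    return candidates


def evaluate_candidate(
    candidate: CandidateOligo, constraints: DesignConstraints = DesignConstraints()
) -> CandidateOligo:
    """Attach per-criterion pass/fail flags to an annotated candidate.

    The specificity flag fails only on a perfect (mismatch-free)
    off-target match of at least oligo length - 1; shorter perfect or
    imperfect matches are reported and penalise rank but do not reject.
    """
    g0, g1 = constraints.gc_range_pct
    hard_hit = any(
        h.mismatches == 0 and h.match_len >= len(candidate.sequence) - 1
        for h in candidate.offtargets
    )
    candidate.flags = {
        "tm": candidate.hybrid.tm_c > constraints.min_tm_c,
        "dimer": candidate.dimer_ratio_pct < constraints.max_dimer_ratio_pct,
        "gc": g0 <= candidate.gc_pct <= g1,
        "accessibility": (
            candidate.accessibility is None
            or candidate.accessibility >= constraints.min_accessibility
        ),
        "specificity": not hard_hit,
    }
    return candidate


def _max_segments(match: list[bool], max_mismatches: int, min_len: int):
    """Maximal segments with <= max_mismatches internal mismatches.

    Segments start and end on matches and cannot be extended in either
    direction without exceeding the mismatch budget or the array bounds.
    """
    n = len(match)
    if not any(match):
        return []
    mis_positions = [idx for idx, m in enumerate(match) if not m]
    # a maximal segment spans the gap between two mismatches that are
    # m + 1 apart in the mismatch list (or runs into an array end),
    # trimmed to start and end on matches
    boundaries = [-1] + mis_positions + [n]
    m = max_mismatches
    candidates = set()
    for t in range(len(boundaries) - 1):
        right_b = min(t + m + 1, len(boundaries) - 1)
        left = boundaries[t] + 1
        right = boundaries[right_b] - 1
        while left <= right and not match[left]:
            left += 1
        while right >= left and not match[right]:
            right -= 1
        if left > right:
            continue
        mis = sum(1 for idx in range(left, right + 1) if not match[idx])
        candidates.add((left, right, mis))
    segments = [
        (a, b, mis)
        for a, b, mis in candidates
        if b - a + 1 >= min_len
        and not any(
            a2 <= a and b <= b2 and (a2, b2) != (a, b)
            for a2, b2, _ in candidates
        )
    ]
    return sorted(segments)


def offtarget_scan(
    oligo_dna: str,
    transcript_set: list[Transcript],
    min_report_len: int = 14,
    max_mismatches: int = 0,
    seed_len: int = 8,
) -> list[OffTargetHit]:
    """Maximal complementary matches of an oligo against a transcript set.

    Finds, per transcript, every maximal ungapped stretch where the oligo
    is complementary to the transcript with at most ``max_mismatches``
    internal mismatches and length >= ``min_report_len``.  With
    ``max_mismatches=0`` a single internal mismatch splits a long match
    into two reported segments.  Seeded with exact ``seed_len``-mers and
    extended ungapped; equivalent to a naive scan of every offset.
    """
    oligo = as_dna(oligo_dna)
    if not oligo:
        raise ValueError("empty oligo")
    if not transcript_set:
        raise ValueError("empty transcript set")
    # the oligo is antisense: it matches transcripts containing the
    # reverse complement of itself read as the sense strand
    query = as_dna(reverse_complement(oligo, "DNA"))
    qlen = len(query)
    hits: list[OffTargetHit] = []
    # pigeonhole: any reportable segment contains an exact run of at least
    # (min_report_len - max_mismatches) // (max_mismatches + 1) bases, so a
    # longer seed would miss mismatch-containing segments
    seed_len = max(1, min(seed_len,
                          (min_report_len - max_mismatches) // (max_mismatches + 1)))
    use_seed = qlen >= seed_len
    for tx in transcript_set:
        subject = as_dna(tx.sequence)
        slen = len(subject)
        if slen < min_report_len:
            continue
        diagonals: set[int] = set()
        if use_seed:
            index: dict[str, list[int]] = {}
            for qp in range(qlen - seed_len + 1):
                index.setdefault(query[qp : qp + seed_len], []).append(qp)
            for sp in range(slen - seed_len + 1):
                kmer = subject[sp : sp + seed_len]
                for qp in index.get(kmer, ()):
                    diagonals.add(sp - qp)
        else:
            diagonals = set(range(-qlen + 1, slen))
        for d in sorted(diagonals):
            q_lo = max(0, -d)
            q_hi = min(qlen, slen - d)
            if q_hi - q_lo < min_report_len:
                continue
            match = [query[q] == subject[q + d] for q in range(q_lo, q_hi)]
            for left, right, mis in _max_segments(match, max_mismatches, min_report_len):
                q_start = q_lo + left
                q_end = q_lo + right
                # oligo coordinates run antiparallel to the sense query
                o_start = qlen - 1 - q_end
                o_end = qlen - 1 - q_start
                hits.append(
                    OffTargetHit(
                        transcript_id=tx.id,
                        match_len=q_end - q_start + 1,
                        mismatches=mis,
                        oligo_span=Interval(o_start + 1, o_end + 1),
                        transcript_span=Interval(q_start + d + 1, q_end + d + 1),
                    )
                )
    hits.sort(key=lambda h: (h.transcript_id, h.transcript_span.start, -h.match_len))
    return hits


def _rank_key(c: CandidateOligo):
    return (
        -(c.accessibility if c.accessibility is not None else 0.0),
        -c.hybrid.tm_c,
        len(c.offtargets),
        c.target_interval.start,
        c.sequence,
    )


def design_report(
    candidates: list[CandidateOligo],
    constraints: DesignConstraints = DesignConstraints(),
    top_k: int | None = None,
) -> pd.DataFrame:
    """Ranked table of passing candidates, one design-table row per oligo.

    Candidates failing any hard flag are excluded; survivors are ranked by
    descending accessibility, then descending Tm, then fewest off-target
    hits, then position.  Repeated runs produce identical tables.
    """
    rows = []
    passing = sorted((c for c in candidates if c.passes), key=_rank_key)
    if top_k is not None:
        passing = passing[:top_k]
    for rank, c in enumerate(passing, start=1):
        rows.append(
            {
                "rank": rank,
                "sequence": c.sequence,
                "start": c.target_interval.start,
                "end": c.target_interval.end,
                "length": c.target_interval.length,
                "gc_pct": int(round(c.gc_pct)),
                "tm_c": round(c.hybrid.tm_c, 1),
                "hybridisation_dG": round(c.anneal.dG37, 2),
                "selfdimer_dG": (
                    round(c.dimer.best_dG, 2) if c.dimer.best_dG is not None else "none"
                ),
                "dimer_ratio_pct": round(c.dimer_ratio_pct, 1),
                "accessibility": (
                    round(c.accessibility, 3) if c.accessibility is not None else ""
                ),
                "offtargets": ";".join(h.label for h in c.offtargets),
                "modification": c.modification,
            }
        )
    columns = [
        "rank", "sequence", "start", "end", "length", "gc_pct", "tm_c",
        "hybridisation_dG", "selfdimer_dG", "dimer_ratio_pct",
        "accessibility", "offtargets", "modification",
    ]
    return pd.DataFrame(rows, columns=columns)


def design_pipeline(
    target: Transcript,
    transcriptome: list[Transcript] | None = None,
    constraints: DesignConstraints = DesignConstraints(),
    conditions: thermo.Conditions | None = None,
    window: int = 300,
    step: int = 150,
    min_ss_len: int = 20,
    prob_threshold: float = 0.5,
    top_k: int | None = 10,
) -> tuple[pd.DataFrame, list[CandidateOligo]]:
    """Fold the target, enumerate and screen candidates, return the report.

    ``transcriptome`` is scanned for off-target complementarity; the
    target itself (matched by id) is skipped there.
    """
    rna = Transcript(target.id, target.sequence, alphabet="RNA")
    profile = folding.windowed_accessibility(
        rna.sequence, window=window, step=step
    )
    ss = folding.single_stranded_regions(
        profile, min_len=min_ss_len, prob_threshold=prob_threshold
    )
    candidates = enumerate_candidates(
        rna, ss, constraints, accessibility_profile=profile, conditions=conditions
    )
    others = [t for t in (transcriptome or []) if t.id != target.id]
    for c in candidates:
        if others:
            c.offtargets = offtarget_scan(
                c.sequence, others, min_report_len=constraints.offtarget_flag_len
            )
        evaluate_candidate(c, constraints)
    report = design_report(candidates, constraints, top_k=top_k)
    return report, candidates
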