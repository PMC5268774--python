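"""Accessibility-aware miRNA binding-site discovery and ddG scoring.

Sites are found by seed complementarity anywhere along the transcript
(5'UTR, CDS and 3'UTR alike) and scored with the two-term energy used by
accessibility-based target predictors:

``ddG = dG_duplex + dG_open``

where ``dG_duplex`` (<= 0) is the stacking energy of the best ungapped
miRNA::site duplex anchored at the seed and ``dG_open`` (>= 0) is the cost
of freeing the site from the mRNA's own secondary structure.  More
negative ddG means a stronger, more accessible site.

Seed classes: ``6mer`` = perfect complement of miRNA positions 2-7,
``7mer`` = positions 2-8 (7mer-m8), ``8mer`` = 7mer-m8 plus an adenosine
on the target opposite miRNA position 1.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import folding
from .seqio import Interval, SequenceError, Transcript, as_rna, reverse_complement

__all__ = [
    "MiRNA",
    "SeedSite",
    "SiteScore",
    "MutationRecord",
    "find_seed_sites",
    "score_site",
    "mutate_site",
]

SEED_CLASSES = ("6mer", "7mer", "8mer")


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA, 5'->3' RNA."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = as_rna(self.sequence)
        if set(seq) - set("ACGU"):
            raise SequenceError(f"{self.name}: invalid RNA characters")
        if not 18 <= len(seq) <= 26:
            raise SequenceError(
                f"{self.name}: mature miRNA length {len(seq)} outside 18-26"
            )
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class SeedSite:
    """A seed-complementary site on a transcript.

    ``site_start`` is the 1-based transcript position of the 5'-most
    paired target base (the base pairing the highest-numbered seed
    position of the miRNA).
    """

    mirna: str
    site_start: int
    seed_class: str
    region_label: str
    seed_span: Interval

    def __post_init__(self) -> None:
        if self.seed_class not in SEED_CLASSES:
            raise ValueError(f"unknown seed class {self.seed_class!r}")


@dataclass(frozen=True)
class SiteScore:
    """Energetics of one miRNA::site interaction (kcal/mol)."""

    dG_duplex: float
    dG_open: float
    ddG: float

    def __post_init__(self) -> None:
        if abs(self.ddG - (self.dG_duplex + self.dG_open)) > 1e-9:
            raise ValueError("ddG must equal dG_duplex + dG_open")


@dataclass(frozen=True)
class MutationRecord:
    """Diff record for a site mutation: 1-based changed positions."""

    site_start: int
    positions: tuple[int, ...]
    original: str
    replacement: str


def find_seed_sites(
    mirna: MiRNA,
    transcript: Transcript,
    allowed_classes: tuple[str, ...] = ("7mer", "8mer"),
) -> list[SeedSite]:
    """Scan the whole transcript for seed-complementary sites.

    Each matching position is reported once with the best (longest) seed
    class among ``allowed_classes``; sites are sorted by position and
    labelled with the transcript region when annotation is present.
    """
    for cls in allowed_classes:
        if cls not in SEED_CLASSES:
            raise ValueError(f"unknown seed class {cls!r}")
    seq = as_rna(transcript.sequence)
    mir = mirna.sequence
    # target-side match strings (5'->3' on the transcript)
    match7 = reverse_complement(mir[1:8], "RNA")  # pairs miRNA 8..2
    match6 = reverse_complement(mir[1:7], "RNA")  # pairs miRNA 7..2
    sites: list[SeedSite] = []
    n = len(seq)
    for p in range(n):  # p = 0-based start of the candidate site
        cls = None
        span = None
        if ("7mer" in allowed_classes or "8mer" in allowed_classes) and seq[
            p : p + 7
        ] == match7:
            if "8mer" in allowed_classes and p + 7 < n and seq[p + 7] == "A":
                cls = "8mer"
                span = Interval(p + 1, p + 8)
            elif "7mer" in allowed_classes:
                cls = "7mer"
                span = Interval(p + 1, p + 7)
        if cls is None and "6mer" in allowed_classes and seq[p : p + 6] == match6:
            cls = "6mer"
            span = Interval(p + 1, p + 6)
        if cls is not None:
            sites.append(
                SeedSite(
                    mirna=mirna.name,
                    site_start=p + 1,
                    seed_class=cls,
                    region_label=transcript.region_label(p + 1),
                    seed_span=span,
                )
            )
    return sites


def _duplex_energy(mir: str, seq: str, p: int) -> float:
    """Stacking energy of the ungapped duplex anchored at a seed at p.

    miRNA position m (1-based) is aligned with transcript index
    ``p + 8 - m`` (0-based); paired positions are Watson-Crick or G:U, and
    stacking terms accrue between directly adjacent pairs, using the same
    stack table as the folding model.
    """
    n = len(seq)
    paired: dict[int, int] = {}  # miRNA position -> transcript index
    for m in range(1, len(mir) + 1):
        t = p + 8 - m  # 0-based transcript index
        if 0 <= t < n and folding.can_pair(mir[m - 1], seq[t]):
            paired[m] = t
    total = 0
    for m in sorted(paired):
        if m + 1 in paired:
            # pair at m+1 sits 5' of pair at m along the transcript
            t_hi = paired[m]
            t_lo = paired[m + 1]
            total += folding.stack_energy_cents(
                seq[t_lo], mir[m], seq[t_lo + 1], mir[m - 1]
            ) if t_lo + 1 == t_hi else 0
    return total / 100.0


def score_site(
    mirna: MiRNA,
    transcript: Transcript,
    site: SeedSite,
    open_flank: int = 15,
    context: int = 80,
    temperature_c: float = 37.0,
) -> SiteScore:
    """ddG = dG_duplex + dG_open for one seed site.

    ``dG_open`` is the cost of opening the site extended by
    ``open_flank`` nt on each side, evaluated on a local sequence context
    of ``context`` nt around the opened interval (local structure
    dominates the opening cost and keeps the computation tractable).
    """
    seq = as_rna(transcript.sequence)
    n = len(seq)
    if not (1 <= site.site_start <= n) or site.seed_span.end > n:
        raise ValueError(f"site at {site.site_start} outside transcript")
    dg_duplex = _duplex_energy(mirna.sequence, seq, site.site_start - 1)
    open_start = max(1, site.seed_span.start - open_flank)
    open_end = min(n, site.seed_span.end + open_flank)
    ctx_start = max(1, open_start - context)
    ctx_end = min(n, open_end + context)
    local = seq[ctx_start - 1 : ctx_end]
    local_iv = Interval(open_start - ctx_start + 1, open_end - ctx_start + 1)
    dg_open = folding.delta_g_open(local, local_iv, temperature_c)
    return SiteScore(dg_duplex, dg_open, dg_duplex + dg_open)


def mutate_site(
    region: str | Transcript,
    site_seq: str,
    replacement: tuple[int, str, str] | None,
) -> tuple[str, MutationRecord]:
    """Substitute bases inside a binding site that occurs exactly once.

    ``replacement`` is ``(start_within_site_1based, old, new)``; ``None``
    (or an empty substitution) returns the sequence unchanged.  Raises if
    the site is absent or ambiguous, or if ``old`` does not match.
    """
    seq = region.sequence if isinstance(region, Transcript) else region.upper()
    alphabet_u = "U" in seq and "T" not in seq
    site = site_seq.upper()
    site = site.replace("T", "U") if alphabet_u else site.replace("U", "T")
    first = seq.find(site)
    if first == -1:
        raise ValueError(f"site {site!r} not found in region")
    if seq.find(site, first + 1) != -1:
        raise ValueError(f"site {site!r} occurs more than once in region")
    if replacement is None:
        return seq, MutationRecord(first + 1, (), "", "")
    offset, old, new = replacement
    old = old.upper().replace("T", "U") if alphabet_u else old.upper().replace("U", "T")
    new = new.upper().replace("T", "U") if alphabet_u else new.upper().replace("U", "T")
    if not old and not new:
        return seq, MutationRecord(first + 1, (), "", "")
    if len(old) != len(new):
        raise ValueError("replacement must preserve length")
    if not (1 <= offset and offset + len(old) - 1 <= len(site)):
        raise ValueError("replacement outside the site")
    pos0 = first + offset - 1
    if seq[pos0 : pos0 + len(old)] != old:
        raise ValueError(
            f"expected {old!r} at site position {offset}, "
            f"found {seq[pos0:pos0 + len(old)]!r}"
        )
    mutated = seq[:pos0] + new + seq[pos0 + len(new):]
    changed = tuple(
        pos0 + 1 + k for k in range(len(new)) if old[k] != new[k]
    )
    return mutated, MutationRecord(first + 1, changed, old, new)
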