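"""Consensus Furin cleavage-site detection and prodomain/spacer/ligand splitting.

TGF-beta family proproteins are processed by Furin-type convertases at the
tetrapeptide R-X-[R/K]-R, with cleavage C-terminal to the final arginine.
Everything upstream of (and including) the site is the prodomain; the
biochemically defined ligand is the remainder, itself split into a
hypervariable spacer and the cystine-knot region that begins at the first of
the ligand's six stereotypically spaced cysteines.  A handful of family
members lack the full consensus and present only a single correctly placed
arginine; a fallback rule handles those.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .seqio import ProteinRecord

logger = logging.getLogger("prodomainkit")

#: Consensus proprotein-convertase site: R, any residue, R or K, final R.
FURIN_CONSENSUS = re.compile(r"(?=(R.[RK]R))")

#: Fallback single-R search window upstream of the knot (residues).
FALLBACK_WINDOW = 100

#: Knot-cluster defaults: >=6 cysteines, consecutive C's <= 50 residues apart.
KNOT_MIN_CYS = 6
KNOT_MAX_GAP = 50


class CleaveError(ValueError):
    """Cleavage-site or knot detection failure."""


@dataclass(frozen=True)
class MotifHit:
    """One candidate cleavage site (positions 1-based, end = final R)."""

    start: int
    end: int
    motif_text: str
    kind: str  # "consensus" | "fallback_singleR"

    def __post_init__(self) -> None:
        if self.kind == "consensus" and self.end != self.start + 3:
            raise CleaveError("consensus hit must span exactly 4 residues")
        if self.motif_text[-1] != "R":
            raise CleaveError("cleavage motif must end in R")


@dataclass(frozen=True)
class SplitProtein:
    """A record partitioned into prodomain / spacer / knot at the cleavage site."""

    record_id: str
    cleavage_end: int  # 1-based position of the site's final R
    knot_start: int    # 1-based position of the first knot cysteine
    prodomain: str
    spacer: str
    knot: str
    site: MotifHit

    @property
    def ligand(self) -> str:
        return self.spacer + self.knot

    @property
    def spacer_length(self) -> int:
        return len(self.spacer)

    @property
    def acidic_upstream(self) -> bool:
        """Is the residue immediately upstream of the first knot cysteine D or E?"""
        tail = (self.prodomain + self.spacer)[-1]
        return tail in "DE"


def find_furin_sites(sequence: str) -> list[MotifHit]:
    """All (possibly overlapping) RX[R/K]R matches, ascending by start.

    If the sequence contains no consensus match anywhere, every solitary R is
    reported as a ``fallback_singleR`` hit instead (start == end).
    """
    if not sequence:
        raise CleaveError("empty sequence")
    hits = [
        MotifHit(m.start() + 1, m.start() + 4, m.group(1), "consensus")
        for m in FURIN_CONSENSUS.finditer(sequence)
    ]
    if hits:
        return hits
    return [
        MotifHit(i + 1, i + 1, "R", "fallback_singleR")
        for i, ch in enumerate(sequence)
        if ch == "R"
    ]


def locate_knot_start(
    sequence: str,
    min_cys: int = KNOT_MIN_CYS,
    max_gap: int = KNOT_MAX_GAP,
) -> int:
    """1-based position of the first cysteine of the C-terminal cysteine cluster.

    Scanning from the C-terminus, the maximal run of >= ``min_cys`` cysteines in
    which consecutive cysteines are <= ``max_gap`` residues apart; returns the
    run's first cysteine.
    """
    cys = [i + 1 for i, ch in enumerate(sequence) if ch == "C"]
    if len(cys) < min_cys:
        raise CleaveError(
            f"no knot found: only {len(cys)} cysteines at positions {cys}"
        )
    # Walk back from the last cysteine, extending the run while gaps stay small.
    run_start = len(cys) - 1
    while run_start > 0 and cys[run_start] - cys[run_start - 1] <= max_gap:
        run_start -= 1
    run = cys[run_start:]
    if len(run) < min_cys:
        raise CleaveError(
            f"no knot found: C-terminal cysteine run has {len(run)} cysteines "
            f"(need >= {min_cys}); cysteine positions {cys}"
        )
    return run[0]


def split_record(
    record: ProteinRecord,
    knot_override: Optional[int] = None,
    site_override: Optional[int] = None,
    min_cys: int = KNOT_MIN_CYS,
    max_gap: int = KNOT_MAX_GAP,
) -> SplitProtein:
    """Partition a record at the cleavage site closest to the knot.

    Chooses the hit with the greatest final-R position still upstream of
    ``knot_start``; consensus hits are preferred over single-R fallbacks, and
    fallback hits must lie within :data:`FALLBACK_WINDOW` residues of the knot.
    ``site_override`` (position of the final R) forces the paper-style manual
    pick for proteins with ambiguous sites.
    """
    seq = record.sequence
    knot_start = knot_override if knot_override is not None else locate_knot_start(
        seq, min_cys=min_cys, max_gap=max_gap
    )
    if seq[knot_start - 1] != "C":
        raise CleaveError(f"{record.id}: knot_start {knot_start} is not a cysteine")

    if site_override is not None:
        if not 1 <= site_override < knot_start or seq[site_override - 1] != "R":
            raise CleaveError(
                f"{record.id}: site override {site_override} is not an upstream R"
            )
        hits = [h for h in find_furin_sites(seq) if h.end == site_override]
        site = hits[0] if hits else MotifHit(
            site_override, site_override, "R", "fallback_singleR"
        )
    else:
        candidates = [h for h in find_furin_sites(seq) if h.end < knot_start]
        consensus = [h for h in candidates if h.kind == "consensus"]
        fallback = [
            h for h in candidates
            if h.kind == "fallback_singleR" and knot_start - h.end <= FALLBACK_WINDOW
        ]
        pool = consensus or fallback
        if not pool:
            raise CleaveError(f"{record.id}: no cleavage site upstream of the knot")
        site = max(pool, key=lambda h: h.end)
        if site.kind == "fallback_singleR":
            logger.warning(
                "%s: no consensus RX[R/K]R; fallback single R at %d "
                "(window %d residues upstream of knot)",
                record.id, site.end, FALLBACK_WINDOW,
            )

    split = SplitProtein(
        record_id=record.id,
        cleavage_end=site.end,
        knot_start=knot_start,
        prodomain=seq[: site.end],
        spacer=seq[site.end : knot_start - 1],
        knot=seq[knot_start - 1 :],
        site=site,
    )
    assert split.prodomain + split.ligand == seq
    assert split.knot[0] == "C"
    if "C" in split.spacer:
        raise CleaveError(
            f"{record.id}: spacer contains a cysteine — knot detection inconsistent"
        )
    return split


@dataclass
class SpacerStats:
    """Per-record spacer lengths and acidic-upstream flags with summaries."""

    lengths: dict[str, int]
    acidic_upstream: dict[str, bool]
    min_length: int
    min_id: str
    max_length: int
    max_id: str
    acidic_by_subfamily: dict[str, tuple[int, int]] = field(default_factory=dict)


def spacer_table(
    splits: Iterable[SplitProtein],
    subfamilies: Optional[dict[str, str]] = None,
) -> SpacerStats:
    """Summarise spacer lengths and knot-proximal acidic residues.

    ``subfamilies`` optionally maps record id -> subfamily label to produce
    per-subfamily (acidic count, total) tallies.
    """
    splits = list(splits)
    if not splits:
        raise CleaveError("spacer_table requires at least one split")
    lengths = {s.record_id: s.spacer_length for s in splits}
    acidic = {s.record_id: s.acidic_upstream for s in splits}
    min_id = min(lengths, key=lambda k: (lengths[k], k))
    max_id = max(lengths, key=lambda k: (lengths[k], k))
    stats = SpacerStats(
        lengths=lengths,
        acidic_upstream=acidic,
        min_length=lengths[min_id],
        min_id=min_id,
        max_length=lengths[max_id],
        max_id=max_id,
    )
    if subfamilies:
        tally: dict[str, list[int]] = {}
        for s in splits:
            sub = subfamilies.get(s.record_id, "unassigned")
            cnt = tally.setdefault(sub, [0, 0])
            cnt[0] += int(acidic[s.record_id])
            cnt[1] += 1
        stats.acidic_by_subfamily = {k: (v[0], v[1]) for k, v in tally.items()}
    return stats


def pairwise_spacer_similarity(a: str, b: str, params=None) -> dict:
    """Percent identity and similarity of two spacers from a global alignment.

    Denominators count all alignment columns, gap columns included.  Similarity
    uses the BoxShade residue groups from :mod:`prodomainkit.conserve`.
    """
    from .align import AlignParams, pairwise_global_align
    from .conserve import SIMILARITY_GROUP_OF

    if not a or not b:
        raise CleaveError("empty spacer")
    params = params or AlignParams()
    # canonical argument order: equal-scoring alignments can differ between
    # (a, b) and (b, a) under the aligner's tie-breaking, but the percentages
    # must be symmetric
    if (len(a), a) <= (len(b), b):
        row_a, row_b, _score = pairwise_global_align(a, b, params)
    else:
        row_b, row_a, _score = pairwise_global_align(b, a, params)
    n_cols = len(row_a)
    ident = sim = 0
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            continue
        if x == y:
            ident += 1
            sim += 1
        elif SIMILARITY_GROUP_OF.get(x) is not None and (
            SIMILARITY_GROUP_OF.get(x) == SIMILARITY_GROUP_OF.get(y)
        ):
            sim += 1
    return {
        "identity_pct": 100.0 * ident / n_cols,
        "similarity_pct": 100.0 * sim / n_cols,
        "alignment": (row_a, row_b),
    }


def spacer_containment(a: str, b_window: str) -> int:
    """Size of the multiset intersection of a's residues with b_window's."""
    if not a or not b_window:
        raise CleaveError("empty input to spacer_containment")
    from collections import Counter

    ca, cb = Counter(a), Counter(b_window)
    return sum(min(ca[ch], cb[ch]) for ch in ca)
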