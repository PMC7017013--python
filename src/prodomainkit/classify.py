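"""Core-plus-one greedy subfamily assignment by informative-site loss.

Each subfamily starts from a user-specified "core" of at least four members
known to belong together.  Every pool sequence is aligned into every core
("core plus one"), and the candidate/subfamily pair whose inclusion reduces
the core alignment's parsimony-informative site count least is committed;
the process repeats until the pool is empty.  A reduction is signed — a
candidate that *increases* the informative count sorts ahead of one that
merely preserves it.  Ties break by fewer gap characters, then shorter
alignment, then lexicographic subfamily name.

Alignments are recomputed from sequences at every evaluation (cached by
membership) so the statistic always reflects a fresh alignment, never an
edited one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .align import AlignParams, count_informative, progressive_align
from .seqio import ProteinRecord

logger = logging.getLogger("prodomainkit")

#: Steps whose top two deltas differ by <= this margin are flagged ambiguous.
DEFAULT_AMBIGUITY_MARGIN = 1


class ClassifyError(ValueError):
    pass


@dataclass
class AssignmentStep:
    candidate_id: str
    chosen_subfamily: str
    deltas: dict[str, int]          # subfamily -> informative-site reduction
    tie_break: str
    ambiguous: bool


@dataclass
class AssignmentTrace:
    steps: list[AssignmentStep] = field(default_factory=list)

    def labels(self) -> dict[str, str]:
        return {s.candidate_id: s.chosen_subfamily for s in self.steps}


class _InformativeCache:
    """Memoises (sorted member ids) -> InformativeSiteReport over fresh alignments."""

    def __init__(self, params: AlignParams):
        self.params = params
        self._store: dict[tuple[str, ...], object] = {}

    def report(self, records: Sequence[ProteinRecord]):
        key = tuple(sorted(r.id for r in records))
        if key not in self._store:
            aln = progressive_align(records, self.params)
            self._store[key] = count_informative(aln)
        return self._store[key]


def core_plus_one_delta(
    core: Sequence[ProteinRecord],
    candidate: ProteinRecord,
    params: Optional[AlignParams] = None,
    _cache: Optional[_InformativeCache] = None,
) -> dict:
    """Informative-site reduction caused by adding ``candidate`` to ``core``.

    Returns {"delta_informative", "n_gaps", "aln_length"}; delta is
    informative(core) - informative(core + candidate), so a destructive
    candidate scores high and a compatible one scores <= 0.
    """
    core = list(core)
    if len(core) < 4:
        raise ClassifyError("core must have >= 4 records")
    cache = _cache or _InformativeCache(params or AlignParams())
    base = cache.report(core)
    plus = cache.report(core + [candidate])
    return {
        "delta_informative": base.n_informative - plus.n_informative,
        "n_gaps": plus.n_gap_chars,
        "aln_length": plus.n_cols_with_gaps,
    }


def greedy_assign(
    cores: Mapping[str, Sequence[ProteinRecord]],
    pool: Sequence[ProteinRecord],
    params: Optional[AlignParams] = None,
    ambiguity_margin: int = DEFAULT_AMBIGUITY_MARGIN,
) -> tuple[dict[str, list[ProteinRecord]], AssignmentTrace]:
    """Assign every pool record to a subfamily by global greedy core-plus-one.

    Each round evaluates every remaining (candidate, subfamily) pair and
    commits the pair with the smallest informative-site reduction; cores only
    grow.  Deterministic given inputs (total tie-break order).
    """
    params = params or AlignParams()
    cores_out: dict[str, list[ProteinRecord]] = {
        sub: list(records) for sub, records in cores.items()
    }
    for sub, records in cores_out.items():
        if len(records) < 4:
            raise ClassifyError(f"core {sub!r} has {len(records)} records (< 4)")
    core_ids = {r.id for recs in cores_out.values() for r in recs}
    pool_left = list(pool)
    overlap = core_ids & {r.id for r in pool_left}
    if overlap:
        raise ClassifyError(f"pool ids already in cores: {sorted(overlap)}")

    cache = _InformativeCache(params)
    trace = AssignmentTrace()
    while pool_left:
        evaluations = []  # (sort key, candidate, subfamily, deltas-for-candidate)
        per_candidate: dict[str, dict[str, int]] = {}
        for cand in pool_left:
            for sub in sorted(cores_out):
                res = core_plus_one_delta(cores_out[sub], cand, params, _cache=cache)
                per_candidate.setdefault(cand.id, {})[sub] = res["delta_informative"]
                evaluations.append((
                    (res["delta_informative"], res["n_gaps"], res["aln_length"], sub,
                     cand.id),
                    cand, sub, res,
                ))
        key, cand, sub, res = min(evaluations, key=lambda e: e[0])
        deltas = per_candidate[cand.id]
        others = sorted(v for s, v in deltas.items() if s != sub)
        ambiguous = bool(others) and (others[0] - deltas[sub] <= ambiguity_margin)
        if ambiguous:
            logger.warning(
                "greedy_assign: %s -> %s is ambiguous (deltas %s)",
                cand.id, sub, deltas,
            )
        trace.steps.append(AssignmentStep(
            candidate_id=cand.id,
            chosen_subfamily=sub,
            deltas=deltas,
            tie_break="delta,gaps,length,subfamily,id",
            ambiguous=ambiguous,
        ))
        cores_out[sub].append(cand)
        pool_left = [r for r in pool_left if r.id != cand.id]
    return cores_out, trace
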