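"""Column conservation shading, structural-feature mapping, and the
cysteine-motif scanner.

Shading follows the BoxShade convention: a column is "identical" (black)
when a single residue reaches the cutoff fraction of sequences, "similar"
(gray) when identical-or-similar residues do, using the biochemical
similarity groups D/E, K/R/H, N/Q, S/T, I/L/V, F/W/Y, A/G.  The cutoff
"half of the sequences" includes exactly half (ceiling for odd N).

Structural features (α1, Latency Lasso, α2, β1–β10, α3–α5, β9′, the
LTBP-Association region, and the bowtie β8+β9) are supplied as 1-based
residue ranges on a reference sequence and resolved to alignment columns.
The scanner classifies each row's cysteine motif within a feature region
(solo / CxC / CxxC, read on ungapped row text so alignment gaps inside a
motif do not break it) and groups rows whose first cysteine shares an
alignment column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .seqio import GAP, Alignment

SIMILARITY_GROUPS: tuple[str, ...] = ("DE", "KRH", "NQ", "ST", "ILV", "FWY", "AG")
SIMILARITY_GROUP_OF: dict[str, str] = {
    ch: grp for grp in SIMILARITY_GROUPS for ch in grp
}


class ConserveError(ValueError):
    pass


@dataclass(frozen=True)
class ConservationParams:
    threshold: float = 0.5
    groups: tuple[str, ...] = SIMILARITY_GROUPS

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ConserveError("threshold must be in (0, 1]")
        seen: set[str] = set()
        for grp in self.groups:
            if seen & set(grp):
                raise ConserveError("similarity groups must be disjoint")
            seen |= set(grp)


@dataclass
class ConservationProfile:
    """Per-column conservation class with the consensus residue or group."""

    classes: list[str]          # "identical" | "similar" | "none"
    consensus: list[Optional[str]]  # residue, group string, or None
    counts: list[int]           # winning count per column


def shade_profile(
    aln: Alignment, params: Optional[ConservationParams] = None
) -> ConservationProfile:
    """Classify every column as identical / similar / none at the cutoff.

    A residue's own count decides "identical"; the count of a residue plus
    its similarity-group partners decides "similar".  Gaps never count.
    Group ties resolve to the earlier group in the configured order.
    """
    if aln.n_rows < 2:
        raise ConserveError("shade_profile requires >= 2 rows")
    params = params or ConservationParams()
    import math

    need = math.ceil(params.threshold * aln.n_rows)
    group_of = {ch: grp for grp in params.groups for ch in grp}
    classes: list[str] = []
    consensus: list[Optional[str]] = []
    counts: list[int] = []
    for col in range(1, aln.n_cols + 1):
        column = [ch for ch in aln.column(col) if ch != GAP]
        res_counts: dict[str, int] = {}
        for ch in column:
            res_counts[ch] = res_counts.get(ch, 0) + 1
        best_res, best_res_count = None, 0
        for ch in sorted(res_counts):
            if res_counts[ch] > best_res_count:
                best_res, best_res_count = ch, res_counts[ch]
        if best_res_count >= need:
            classes.append("identical")
            consensus.append(best_res)
            counts.append(best_res_count)
            continue
        best_grp, best_grp_count = None, 0
        for grp in params.groups:  # listed order is the tie-break
            gcount = sum(res_counts.get(ch, 0) for ch in grp)
            if gcount > best_grp_count:
                best_grp, best_grp_count = grp, gcount
        if best_grp_count >= need:
            classes.append("similar")
            consensus.append(best_grp)
            counts.append(best_grp_count)
        else:
            classes.append("none")
            consensus.append(None)
            counts.append(max(best_res_count, best_grp_count))
    return ConservationProfile(classes, consensus, counts)


def render_shading(aln: Alignment, profile: ConservationProfile, width: int = 60) -> str:
    """Plain-text BoxShade-like rendering: UPPER = identical column,
    lower = similar column, '.' marks unconserved residues."""
    marks: list[list[str]] = []
    for row in aln.matrix:
        out = []
        for j, ch in enumerate(row):
            if ch == GAP:
                out.append(GAP)
            elif profile.classes[j] == "identical":
                out.append(ch.upper())
            elif profile.classes[j] == "similar":
                out.append(ch.lower())
            else:
                out.append(".")
        marks.append(out)
    lines = []
    for start in range(0, aln.n_cols, width):
        for rid, out in zip(aln.row_ids, marks):
            lines.append(f"{rid:<20} {''.join(out[start:start + width])}")
        lines.append("")
    return "\n".join(lines)


@dataclass
class FeatureTable:
    """Named structural features as 1-based inclusive residue ranges on a
    reference sequence (e.g. alpha1, latency_lasso, beta1..beta10, ltbp_assoc,
    bowtie)."""

    reference_id: str
    ranges: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        spans = sorted(self.ranges.items(), key=lambda kv: kv[1])
        for (na, (a1, b1)), (nb, (a2, b2)) in zip(spans, spans[1:]):
            if a2 <= b1:
                raise ConserveError(f"features {na!r} and {nb!r} overlap")
        for name, (a, b) in self.ranges.items():
            if not (1 <= a <= b):
                raise ConserveError(f"feature {name!r}: bad range ({a}, {b})")


def load_feature_table(path) -> FeatureTable:
    """Read a feature config (TOML): ``reference_id`` plus a ``[features]``
    table of ``name = [start, end]`` 1-based inclusive residue ranges.

    Ship-your-own coordinates: ranges for real reference proteins come from
    the structure literature and must be completed by the user.
    """
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    try:
        ref = data["reference_id"]
        ranges = {k: (int(v[0]), int(v[1])) for k, v in data["features"].items()}
    except (KeyError, TypeError, IndexError) as exc:
        raise ConserveError(f"{path}: invalid feature config ({exc})") from exc
    return FeatureTable(reference_id=ref, ranges=ranges)


@dataclass
class FeatureMap:
    """FeatureTable resolved to alignment-column ranges (1-based inclusive)."""

    reference_id: str
    residue_ranges: dict[str, tuple[int, int]]
    column_ranges: dict[str, tuple[int, int]]


def map_features(aln: Alignment, reference_id: str, features: FeatureTable) -> FeatureMap:
    """Resolve reference residue ranges to alignment columns.

    Residue range [a, b] maps to the columns holding reference residues a..b
    inclusive (gap columns in between are covered by the span).
    """
    if features.reference_id != reference_id:
        raise ConserveError(
            f"feature table is for {features.reference_id!r}, not {reference_id!r}"
        )
    try:
        row = aln.row(reference_id)
    except KeyError:
        raise ConserveError(f"reference {reference_id!r} not in alignment") from None
    # residue index -> column (both 1-based)
    res_to_col: dict[int, int] = {}
    res = 0
    for col, ch in enumerate(row, start=1):
        if ch != GAP:
            res += 1
            res_to_col[res] = col
    column_ranges: dict[str, tuple[int, int]] = {}
    for name, (a, b) in features.ranges.items():
        if b > res:
            raise ConserveError(
                f"feature {name!r} range ({a}, {b}) exceeds reference length {res}"
            )
        column_ranges[name] = (res_to_col[a], res_to_col[b])
    return FeatureMap(reference_id, dict(features.ranges), column_ranges)


@dataclass
class CysteineReport:
    """Cysteine-motif classification within one feature region."""

    region: str
    columns_with_shared_cys: list[int]            # >= 2 rows carry C
    row_motifs: dict[str, str]                    # id -> none|solo|CxC|CxxC
    row_anchor_columns: dict[str, Optional[int]]  # id -> column of first C
    anchor_groups: dict[int, list[str]]           # anchor column -> row ids


def scan_cysteines(aln: Alignment, feature_map: FeatureMap, region_name: str) -> CysteineReport:
    """Classify each row's cysteine motif inside a mapped feature region.

    Motifs are read on the region's ungapped row text (longest match wins:
    CxxC over CxC over solo); anchors are the alignment column of the motif's
    first cysteine.  Rows sharing an anchor column are grouped — the signature
    of a conserved, alignable cysteine pair.
    """
    if region_name not in feature_map.column_ranges:
        raise ConserveError(f"region {region_name!r} not in feature map")
    c0, c1 = feature_map.column_ranges[region_name]
    if c1 < c0:
        raise ConserveError(f"region {region_name!r} resolves to zero columns")
    row_motifs: dict[str, str] = {}
    anchors: dict[str, Optional[int]] = {}
    for rid in aln.row_ids:
        segment = aln.row(rid)[c0 - 1 : c1]
        cys_cols = [c0 + off for off, ch in enumerate(segment) if ch == "C"]
        ungapped = segment.replace(GAP, "")
        if not cys_cols:
            row_motifs[rid], anchors[rid] = "none", None
            continue
        motif = "solo"
        anchor = cys_cols[0]
        # longest match preferred: scan ungapped text for CxxC, then CxC
        for pattern, name in (("CxxC", "CxxC"), ("CxC", "CxC")):
            span = len(pattern)
            found = None
            for i in range(len(ungapped) - span + 1):
                window = ungapped[i : i + span]
                if window[0] == "C" and window[-1] == "C" and "C" not in window[1:-1]:
                    found = i
                    break
            if found is not None:
                motif = name
                # anchor = column of the motif's first C (the (found+1)-th
                # non-gap C-or-other... count non-gap chars up to `found`)
                n_seen = 0
                for off, ch in enumerate(segment):
                    if ch != GAP:
                        if n_seen == found:
                            anchor = c0 + off
                            break
                        n_seen += 1
                break
        row_motifs[rid], anchors[rid] = motif, anchor
    col_counts: dict[int, int] = {}
    for rid in aln.row_ids:
        seg = aln.row(rid)[c0 - 1 : c1]
        for off, ch in enumerate(seg):
            if ch == "C":
                col_counts[c0 + off] = col_counts.get(c0 + off, 0) + 1
    shared = sorted(c for c, n in col_counts.items() if n >= 2)
    groups: dict[int, list[str]] = {}
    for rid, col in anchors.items():
        if col is not None and row_motifs[rid] != "none":
            groups.setdefault(col, []).append(rid)
    groups = {c: ids for c, ids in groups.items() if len(ids) >= 2}
    return CysteineReport(
        region=region_name,
        columns_with_shared_cys=shared,
        row_motifs=row_motifs,
        row_anchor_columns=anchors,
        anchor_groups=groups,
    )
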