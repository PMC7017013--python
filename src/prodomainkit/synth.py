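"""Synthetic TGF-beta-like protein families with planted ground truth.

The generator emulates the architecture of a TGF-beta family proprotein:

    leader | LTBP-like region | straitjacket (alpha1, Latency Lasso, alpha2,
    beta1) | arm (beta2..beta10 blocks) | RX[R/K]R cleavage motif |
    hypervariable spacer | cystine knot with six invariant cysteines

A family ancestor is drawn from BLOSUM62 background frequencies, evolved
down long stem branches into subfamily ancestors (each receiving its own
cleavage tetrapeptide and, optionally, planted cysteine pairs in the
LTBP-like region and in beta8), then evolved along random bifurcating
within-subfamily trees with gamma-distributed site rates.  Substitutions
are sampled from BLOSUM62-derived conditional frequencies and never create
or destroy cysteines, so planted motifs and the knot stay recoverable —
cysteine turnover is modelled as absent, which is the feature of real
families this generator leans on hardest.  Indels are confined to the
leader and spacer so every planted coordinate remains derivable; truth
stores post-indel coordinates.

A cross-subfamily "convergence" pair can be planted by copying most
non-invariant prodomain residues of one leaf onto a leaf of another
subfamily: strong prodomain-only signal, untouched ligand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

import dendropy

from .align import ALPHABET, AlignParams
from .cleave import FURIN_CONSENSUS
from .conserve import FeatureTable
from .seqio import AMINO_ACIDS, ProteinRecord, Registry

# BLOSUM62 background amino-acid frequencies (Henikoff), order = AMINO_ACIDS
_BG = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047, "G": 0.074,
    "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099, "M": 0.025, "N": 0.045,
    "P": 0.039, "Q": 0.034, "R": 0.052, "S": 0.057, "T": 0.051, "V": 0.073,
    "W": 0.013, "Y": 0.032,
}

SUBFAMILY_NAMES = ("Activin", "TGFB", "BMP")

#: (tag, length, rate multiplier) — segment plan of the ancestral proprotein.
#: Lengths for leader and spacer are ranges resolved per config.  Conserved
#: secondary-structure anchors alternate with fast, indel-prone loops
#: ("armvar" blocks), the loop-length variation that makes cross-subfamily
#: prodomain alignments gap-rich.
SEGMENT_PLAN = (
    ("leader", None, 1.0),
    ("ltbp", 22, 0.3),
    ("linker1", 5, 1.0),
    ("alpha1", 16, 0.1),
    ("latency_lasso", 10, 0.1),
    ("alpha2", 12, 0.1),
    ("beta1", 8, 0.1),
    ("linker2", 6, 1.0),
    ("beta2", 16, 0.25),
    ("armvar1", 20, 1.0),
    ("beta3_4", 20, 0.25),
    ("armvar2", 20, 1.0),
    ("beta5", 12, 0.25),
    ("armvar3", 16, 1.0),
    ("beta6_7", 24, 0.2),
    ("beta8", 12, 0.1),
    ("armvar4", 14, 1.0),
    ("beta9_10", 24, 0.2),
    ("linker3", 8, 1.0),
    ("cleavage", 4, 0.0),
    ("spacer", None, 1.0),
    ("knot", 100, 0.2),
)

#: Offsets (0-based within segment) of invariant knot cysteines.
KNOT_CYS_OFFSETS = (0, 15, 32, 50, 68, 85)

#: Planted cysteine-pair offsets within their segments, per motif class.
MOTIF_OFFSETS = {"CxC": (3, 5), "CxxC": (3, 6), "solo": (3,), "none": ()}


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class SubfamilyTemplate:
    """Per-subfamily planted features."""

    ltbp_motif: str = "none"   # none | solo | CxC | CxxC
    beta8_motif: str = "none"


@dataclass
class SyntheticConfig:
    """Study conditions for the simulator (defaults are the tested baseline)."""

    n_subfamilies: int = 3
    members_per_subfamily: int = 10
    core_size: int = 4                 # "recent duplication" seed clade
    leader_range: tuple[int, int] = (15, 30)
    spacer_range: tuple[int, int] = (12, 28)
    substitution_rate: float = 1.0
    gamma_shape: float = 1.0
    indel_rate: float = 0.3            # expected events per unit branch length
    stem_length: float = 2.5           # family -> subfamily ancestor
    outgroup_stem: float = 2.5
    branch_range: tuple[float, float] = (0.1, 0.3)
    core_branch_range: tuple[float, float] = (0.15, 0.4)
    #: tag -> (indel-rate multiplier, min segment length, max event size).
    #: Stem branches (between-subfamily divergence) also hit the linkers and
    #: the variable loops, which is what makes cross-subfamily alignments
    #: gap-rich; within-subfamily branches mostly confine indels to the
    #: leader, spacer, and (rarely) the loops.
    stem_indel_segments: dict = field(default_factory=lambda: {
        "leader": (3.0, 5, 20), "spacer": (3.0, 10, 8),
        "linker1": (2.5, 2, 12), "linker2": (2.5, 2, 12), "linker3": (2.5, 2, 12),
        "armvar1": (2.5, 6, 25), "armvar2": (2.5, 6, 25),
        "armvar3": (2.5, 6, 20), "armvar4": (2.5, 6, 12),
    })
    branch_indel_segments: dict = field(default_factory=lambda: {
        "leader": (1.5, 5, 4), "spacer": (1.5, 10, 4),
        "armvar1": (0.4, 6, 4), "armvar2": (0.4, 6, 4),
        "armvar3": (0.4, 6, 4), "armvar4": (0.4, 6, 4),
    })
    templates: tuple[SubfamilyTemplate, ...] = (
        SubfamilyTemplate(ltbp_motif="CxxC", beta8_motif="CxxC"),
        SubfamilyTemplate(ltbp_motif="solo", beta8_motif="CxC"),
        SubfamilyTemplate(ltbp_motif="none", beta8_motif="solo"),
    )
    plant_convergent_pair: bool = True
    convergence_fraction: float = 0.8  # prodomain residues copied onto partner
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subfamilies < 1 or self.members_per_subfamily < 2:
            raise SynthError("need >= 1 subfamily with >= 2 members")
        if self.members_per_subfamily <= self.core_size:
            raise SynthError("members_per_subfamily must exceed core_size")
        if self.substitution_rate < 0 or self.indel_rate < 0:
            raise SynthError("rates must be >= 0")
        if self.gamma_shape <= 0:
            raise SynthError("gamma_shape must be > 0")
        if len(self.templates) < self.n_subfamilies:
            raise SynthError("need a template per subfamily")
        gaps = np.diff(KNOT_CYS_OFFSETS)
        if (gaps <= 0).any() or (gaps > 50).any():
            raise SynthError("knot cysteine offsets must increase with gaps <= 50")


@dataclass
class SyntheticTruth:
    labels: dict[str, str] = field(default_factory=dict)
    cleavage_end: dict[str, int] = field(default_factory=dict)
    knot_start: dict[str, int] = field(default_factory=dict)
    motif_class: dict[str, dict[str, str]] = field(default_factory=dict)  # region->id->class
    subfamily_trees: dict[str, str] = field(default_factory=dict)         # newick
    global_tree: str = ""
    planted_pair: Optional[tuple[str, str]] = None
    suggested_cores: dict[str, list[str]] = field(default_factory=dict)
    suggested_pool: list[str] = field(default_factory=list)
    segment_spans: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Site-level machinery
# ---------------------------------------------------------------------------

_AA = list(AMINO_ACIDS)
_AA_NO_C = [a for a in _AA if a != "C"]


def _conditional_tables() -> dict[str, tuple[list[str], np.ndarray]]:
    """P(b | a) ∝ exp(BLOSUM62[a,b] / 2) over b not in {a, C}."""
    blosum = AlignParams().score_matrix
    idx = {ch: i for i, ch in enumerate(ALPHABET)}
    tables = {}
    for a in _AA:
        targets = [b for b in _AA_NO_C if b != a]
        weights = np.array([math.exp(blosum[idx[a], idx[b]] / 2.0) for b in targets])
        tables[a] = (targets, weights / weights.sum())
    return tables


_COND = _conditional_tables()


@dataclass
class _Site:
    char: str
    tag: str
    mult: float      # segment rate multiplier
    gamma: float     # per-site gamma rate
    invariant: bool = False


def _draw_bg(rng: np.random.Generator, no_c: bool = True) -> str:
    pool = _AA_NO_C if no_c else _AA
    probs = np.array([_BG[a] for a in pool])
    probs /= probs.sum()
    return str(rng.choice(pool, p=probs))


def _make_ancestor(cfg: SyntheticConfig, rng: np.random.Generator) -> list[_Site]:
    sites: list[_Site] = []
    for tag, length, mult in SEGMENT_PLAN:
        if tag == "leader":
            length = int(rng.integers(cfg.leader_range[0], cfg.leader_range[1] + 1))
        elif tag == "spacer":
            length = int(rng.integers(cfg.spacer_range[0], cfg.spacer_range[1] + 1))
        for off in range(length):
            gamma = float(rng.gamma(cfg.gamma_shape, 1.0 / cfg.gamma_shape))
            if tag == "knot" and off in KNOT_CYS_OFFSETS:
                sites.append(_Site("C", tag, mult, gamma, invariant=True))
            elif tag == "cleavage":
                sites.append(_Site("A", tag, mult, gamma, invariant=True))
            else:
                sites.append(_Site(_draw_bg(rng), tag, mult, gamma))
    return sites


def _plant_subfamily_features(
    sites: list[_Site], template: SubfamilyTemplate, rng: np.random.Generator
) -> list[_Site]:
    sites = [
        _Site(s.char, s.tag, s.mult, s.gamma, s.invariant) for s in sites
    ]
    # cleavage tetrapeptide: R, x (not R/K/C), R or K, R — invariant
    x = str(rng.choice([a for a in _AA_NO_C if a not in "RK"]))
    third = str(rng.choice(["R", "K"]))
    motif = "R" + x + third + "R"
    cle = [i for i, s in enumerate(sites) if s.tag == "cleavage"]
    for i, ch in zip(cle, motif):
        sites[i] = _Site(ch, "cleavage", 0.0, sites[i].gamma, invariant=True)
    for region, cls in (("ltbp", template.ltbp_motif), ("beta8", template.beta8_motif)):
        seg = [i for i, s in enumerate(sites) if s.tag == region]
        for off in MOTIF_OFFSETS[cls]:
            i = seg[off]
            sites[i] = _Site("C", region, 0.0, sites[i].gamma, invariant=True)
    return sites


def _evolve(
    sites: list[_Site],
    t: float,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    indel_segments: Optional[dict] = None,
) -> list[_Site]:
    """Substitutions + segment-confined indels along a branch of length t."""
    out: list[_Site] = []
    for s in sites:
        if s.invariant or s.mult == 0.0:
            out.append(s)
            continue
        p = 1.0 - math.exp(-cfg.substitution_rate * s.mult * s.gamma * t)
        if rng.random() < p:
            targets, probs = _COND[s.char]
            out.append(_Site(str(rng.choice(targets, p=probs)), s.tag, s.mult, s.gamma))
        else:
            out.append(s)
    segments = indel_segments if indel_segments is not None else cfg.branch_indel_segments
    for tag, (rate_mult, min_len, max_size) in segments.items():
        n_events = rng.poisson(cfg.indel_rate * rate_mult * t)
        for _ in range(n_events):
            idxs = [i for i, s in enumerate(out) if s.tag == tag]
            if not idxs:
                continue
            size = int(rng.integers(1, max_size + 1))
            if rng.random() < 0.5 and len(idxs) - size >= min_len:
                start = int(rng.integers(0, len(idxs) - size + 1))
                drop = set(idxs[start : start + size])
                out = [s for i, s in enumerate(out) if i not in drop]
            else:
                at = int(rng.choice(idxs))
                mult = out[at].mult
                new = [
                    _Site(
                        _draw_bg(rng), tag, mult,
                        float(rng.gamma(cfg.gamma_shape, 1.0 / cfg.gamma_shape)),
                    )
                    for _ in range(size)
                ]
                out = out[:at] + new + out[at:]
    return out


def _neutralize_spurious_motifs(sites: list[_Site], rng: np.random.Generator) -> None:
    """Ensure the planted tetrapeptide is the only consensus match upstream of
    the knot (mutating a non-invariant residue of any other match)."""
    cle_end = max(i for i, s in enumerate(sites) if s.tag == "cleavage")
    knot0 = min(i for i, s in enumerate(sites) if s.tag == "knot")
    for _ in range(100):
        seq = "".join(s.char for s in sites)
        spurious = [
            m.start()
            for m in FURIN_CONSENSUS.finditer(seq)
            if m.start() + 3 < knot0 and m.start() + 3 != cle_end
        ]
        if not spurious:
            return
        q = spurious[0]
        # only positions q, q+2, q+3 constrain the pattern (q+1 is a wildcard)
        for pos in (q, q + 2, q + 3):
            if not sites[pos].invariant:
                s = sites[pos]
                sites[pos] = _Site("Q", s.tag, s.mult, s.gamma)
                break
        else:  # pragma: no cover - planted motif is the only all-invariant match
            raise SynthError("cannot neutralize spurious cleavage motif")
    raise SynthError("spurious-motif neutralization did not converge")


def _grow_clade(
    parent: dendropy.Node,
    n_tips: int,
    branch_range: tuple[float, float],
    rng: np.random.Generator,
) -> list[dendropy.Node]:
    """Random bifurcating subtree under ``parent``: repeatedly split a random
    tip; uniform branch lengths."""

    def blen() -> float:
        return float(rng.uniform(*branch_range))

    tips = []
    for _ in range(2):
        child = dendropy.Node()
        child.edge.length = blen()
        parent.add_child(child)
        tips.append(child)
    while len(tips) < n_tips:
        pick = int(rng.integers(0, len(tips)))
        node = tips.pop(pick)
        for _ in range(2):
            child = dendropy.Node()
            child.edge.length = blen()
            node.add_child(child)
            tips.append(child)
    return tips


def _subfamily_tree(
    core_labels: Sequence[str],
    other_labels: Sequence[str],
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    basal_label: Optional[str] = None,
) -> dendropy.Tree:
    """Subfamily tree with a shallow "recent duplication" core clade plus
    deeper remaining members — the structure core-plus-one assignment relies
    on (a tight seed core that is always distinct from the rest).

    ``basal_label`` (if given, and not a core label) is attached as a lone
    lineage at the subfamily root, without a close sibling: the placement
    used for convergence-pair leaves.
    """
    other_labels = list(other_labels)
    if basal_label is not None and basal_label in other_labels:
        other_labels.remove(basal_label)
    else:
        basal_label = None
    taxa = dendropy.TaxonNamespace(
        list(core_labels) + other_labels + ([basal_label] if basal_label else [])
    )
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    core_parent = dendropy.Node()
    core_parent.edge.length = float(rng.uniform(*cfg.branch_range))
    root.add_child(core_parent)
    core_tips = _grow_clade(core_parent, len(core_labels), cfg.core_branch_range, rng)
    if not other_labels:
        other_tips = []
    elif len(other_labels) == 1:
        only = dendropy.Node()
        only.edge.length = float(rng.uniform(*cfg.branch_range))
        root.add_child(only)
        other_tips = [only]
    else:
        other_parent = dendropy.Node()
        other_parent.edge.length = float(rng.uniform(*cfg.branch_range))
        root.add_child(other_parent)
        other_tips = _grow_clade(other_parent, len(other_labels), cfg.branch_range, rng)
    labels = list(core_labels) + other_labels
    tips = core_tips + other_tips
    if basal_label is not None:
        lone = dendropy.Node()
        lone.edge.length = float(rng.uniform(*cfg.branch_range))
        root.add_child(lone)
        tips.append(lone)
        labels.append(basal_label)
    for tip, label in zip(tips, labels):
        tip.taxon = taxa.get_taxon(label)
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def simulate_family(cfg: Optional[SyntheticConfig] = None) -> tuple[Registry, SyntheticTruth]:
    """Generate a multi-subfamily protein family with full planted truth.

    Deterministic given ``cfg.seed``: same seed, byte-identical sequences.
    """
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    truth = SyntheticTruth()
    ancestor = _make_ancestor(cfg, rng)

    species_cycle = ("Mm", "Dm", "Ce")
    records: list[ProteinRecord] = []
    leaf_sites: dict[str, list[_Site]] = {}
    sub_trees: dict[str, dendropy.Tree] = {}

    for si in range(cfg.n_subfamilies):
        name = SUBFAMILY_NAMES[si] if si < len(SUBFAMILY_NAMES) else f"SUB{si}"
        sub_anc = _evolve(ancestor, cfg.stem_length, cfg, rng,
                          indel_segments=cfg.stem_indel_segments)
        sub_anc = _plant_subfamily_features(sub_anc, cfg.templates[si], rng)
        labels = [f"{name}{k + 1}" for k in range(cfg.members_per_subfamily)]
        basal = labels[-1] if cfg.plant_convergent_pair else None
        tree = _subfamily_tree(labels[: cfg.core_size], labels[cfg.core_size :],
                               cfg, rng, basal_label=basal)
        sub_trees[name] = tree

        node_sites = {id(tree.seed_node): sub_anc}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            parent_sites = node_sites[id(node.parent_node)]
            node_sites[id(node)] = _evolve(parent_sites, node.edge.length, cfg, rng)
        for leaf in tree.leaf_node_iter():
            leaf_sites[leaf.taxon.label] = node_sites[id(leaf)]
            truth.labels[leaf.taxon.label] = name

        truth.suggested_cores[name] = labels[: cfg.core_size]
        # last member stays out of the pool when a chimeric pair is planted
        last = len(labels) - (1 if cfg.plant_convergent_pair else 0)
        truth.suggested_pool.extend(labels[cfg.core_size : last][:5])

    # outgroup from an independent long stem
    out_sites = _evolve(ancestor, cfg.outgroup_stem, cfg, rng,
                        indel_segments=cfg.stem_indel_segments)
    out_sites = _plant_subfamily_features(out_sites, SubfamilyTemplate(), rng)
    leaf_sites["OUTGRP"] = out_sites
    truth.labels["OUTGRP"] = "outgroup"

    # planted convergent pair: copy non-invariant prodomain residues A -> B
    # the chimeric leaves are tree-only: never core seeds, never pool members
    if cfg.plant_convergent_pair and cfg.n_subfamilies >= 2:
        a_id = f"{SUBFAMILY_NAMES[0]}{cfg.members_per_subfamily}"
        b_id = f"{SUBFAMILY_NAMES[1]}{cfg.members_per_subfamily}"
        a_sites, b_sites = leaf_sites[a_id], leaf_sites[b_id]
        prodomain_tags = [t for t, _, _ in SEGMENT_PLAN if t not in ("spacer", "knot")]
        for tag in prodomain_tags:
            a_seg = [s for s in a_sites if s.tag == tag]
            b_idx = [i for i, s in enumerate(b_sites) if s.tag == tag]
            for s_a, ib in zip(a_seg, b_idx):
                s_b = b_sites[ib]
                if s_a.invariant or s_b.invariant:
                    continue
                if rng.random() < cfg.convergence_fraction:
                    b_sites[ib] = _Site(s_a.char, s_b.tag, s_b.mult, s_b.gamma)
        truth.planted_pair = (a_id, b_id)

    # finalize leaves: neutralize spurious motifs, extract truth coordinates
    for rec_id, sites in leaf_sites.items():
        _neutralize_spurious_motifs(sites, rng)
        seq = "".join(s.char for s in sites)
        cle_end = max(i for i, s in enumerate(sites) if s.tag == "cleavage") + 1
        knot0 = min(i for i, s in enumerate(sites) if s.tag == "knot") + 1
        truth.cleavage_end[rec_id] = cle_end
        truth.knot_start[rec_id] = knot0
        spans: dict[str, tuple[int, int]] = {}
        for tag, _, _ in SEGMENT_PLAN:
            idxs = [i + 1 for i, s in enumerate(sites) if s.tag == tag]
            spans[tag] = (idxs[0], idxs[-1])
        truth.segment_spans[rec_id] = spans
        for region in ("ltbp", "beta8"):
            seg = "".join(s.char for s in sites if s.tag == region)
            truth.motif_class.setdefault(region, {})[rec_id] = _classify_motif(seg)
        label = truth.labels[rec_id]
        species = "other" if label == "outgroup" else species_cycle[len(rec_id) % 3]
        records.append(ProteinRecord(
            id=rec_id, sequence=seq, species=species,
            subfamily_label=label, accession="synthetic",
        ))

    for name, tree in sub_trees.items():
        truth.subfamily_trees[name] = tree.as_string(schema="newick").strip()
    global_tree = _join_global(sub_trees, "OUTGRP", cfg)
    truth.global_tree = global_tree.as_string(schema="newick").strip()

    order = [r for r in records if r.subfamily_label != "outgroup"] + [
        r for r in records if r.subfamily_label == "outgroup"
    ]
    return Registry(order, provenance=f"synthetic seed={cfg.seed}"), truth


def _classify_motif(segment: str) -> str:
    for i in range(len(segment) - 3):
        w = segment[i : i + 4]
        if w[0] == "C" and w[3] == "C" and "C" not in w[1:3]:
            return "CxxC"
    for i in range(len(segment) - 2):
        w = segment[i : i + 3]
        if w[0] == "C" and w[2] == "C" and w[1] != "C":
            return "CxC"
    return "solo" if "C" in segment else "none"


def _join_global(
    sub_trees: dict[str, dendropy.Tree], outgroup: str, cfg: SyntheticConfig
) -> dendropy.Tree:
    parts = []
    for name, tree in sub_trees.items():
        nwk = tree.as_string(schema="newick").strip()
        nwk = nwk.replace("[&R] ", "").rstrip(";")
        parts.append(f"{nwk}:{cfg.stem_length}")
    joined = "(" + ",".join(parts + [f"{outgroup}:{cfg.outgroup_stem}"]) + ");"
    return dendropy.Tree.get(data=joined, schema="newick", preserve_underscores=True)


def feature_table_for(truth: SyntheticTruth, record_id: str,
                      scan_flank: int = 8) -> FeatureTable:
    """Structural-feature ranges for one record, from planted segment spans.

    The two cysteine scan regions (LTBP-like and beta8) carry a flank of
    ``scan_flank`` residues so that modest alignment jitter from neighbouring
    indel-prone loops cannot push another row's cysteines outside the mapped
    columns; the flanking segments are cysteine-free by construction, so the
    widened window cannot pick up foreign motifs.  beta6_7 is omitted from
    the table to keep ranges non-overlapping.
    """
    spans = truth.segment_spans[record_id]
    exact = ("alpha1", "latency_lasso", "alpha2", "beta1",
             "beta2", "beta3_4", "beta5", "beta9_10")
    ranges = {name: spans[name] for name in exact}
    s, e = spans["ltbp"]
    ranges["ltbp"] = (max(1, s - scan_flank),
                      min(e + scan_flank, spans["alpha1"][0] - 1))
    s, e = spans["beta8"]
    ranges["beta8"] = (max(s - scan_flank, spans["beta5"][1] + 1),
                       min(e + scan_flank, spans["beta9_10"][0] - 1))
    return FeatureTable(reference_id=record_id, ranges=ranges)


def score_recovery(truth: SyntheticTruth, results: dict) -> dict:
    """Score pipeline outputs against planted truth.

    ``results`` may contain any of:
      labels: {id: subfamily}              (scored over the ids given)
      splits: {id: (cleavage_end, knot_start)}
      motifs: {region: {id: class}}
      subfamily_trees: {subfamily: dendropy.Tree or newick}
      prodomain_only: iterable of frozenset({id, id}) flagged pairs
    Returns a scorecard of fractions (and RF distances per subfamily).
    """
    from . import trees as _trees

    card: dict = {}
    if "labels" in results:
        got = results["labels"]
        unknown = set(got) - set(truth.labels)
        if unknown:
            raise SynthError(f"unknown record ids in labels: {sorted(unknown)}")
        card["label_accuracy"] = (
            sum(truth.labels[i] == lab for i, lab in got.items()) / len(got)
            if got else 1.0
        )
    if "splits" in results:
        got = results["splits"]
        unknown = set(got) - set(truth.cleavage_end)
        if unknown:
            raise SynthError(f"unknown record ids in splits: {sorted(unknown)}")
        card["cleavage_accuracy"] = (
            sum(
                (truth.cleavage_end[i], truth.knot_start[i]) == tuple(v)
                for i, v in got.items()
            ) / len(got) if got else 1.0
        )
    if "motifs" in results:
        per_region = {}
        for region, got in results["motifs"].items():
            ref = truth.motif_class.get(region, {})
            unknown = set(got) - set(ref)
            if unknown:
                raise SynthError(f"unknown ids in motifs[{region}]: {sorted(unknown)}")
            per_region[region] = (
                sum(ref[i] == cls for i, cls in got.items()) / len(got)
                if got else 1.0
            )
        card["motif_accuracy"] = per_region
    if "subfamily_trees" in results:
        rf = {}
        for name, tree in results["subfamily_trees"].items():
            if isinstance(tree, str):
                tree = _trees.from_newick(tree)
            true_tree = _trees.from_newick(truth.subfamily_trees[name])
            rf[name] = _trees.robinson_foulds(tree, true_tree)
        card["rf_distance"] = rf
    if "prodomain_only" in results and truth.planted_pair is not None:
        flagged = {frozenset(p) for p in results["prodomain_only"]}
        card["prodomain_only_detected"] = float(
            frozenset(truth.planted_pair) in flagged
        )
    return card
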