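"""End-to-end orchestration: split -> align -> (classify) -> conserve ->
trees -> cross-partition comparison, with a reproducibility manifest.

Grouping levels mirror a subfamily-resolved family study: each subfamily on
its own, the combined Activin+TGFB subfamily, and all members — the
outgroup is carried into every grouping so every tree can be rooted on it.
All outputs are plain text (TSV, FASTA, Newick, JSON) and are pure
functions of (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from . import __version__
from .align import AlignParams, count_informative, progressive_align
from .cleave import spacer_table, split_record
from .conserve import FeatureTable, map_features, scan_cysteines, shade_profile
from .seqio import Alignment, ProteinRecord, Registry, write_alignment, write_fasta
from .trees import (
    TreeError,
    bootstrap_support,
    compare_partitions,
    root_with_outgroup,
    significance_threshold,
    write_newick,
)

logger = logging.getLogger("prodomainkit")

PARTITIONS = ("prodomain", "ligand", "full_length", "cystine_knot")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    registry: Registry
    out_dir: Path
    partitions: Sequence[str] = PARTITIONS
    bootstrap_reps: int = 100
    seed: int = 0
    align_params: AlignParams = field(default_factory=AlignParams)
    outgroup_id: Optional[str] = None
    feature_table: Optional[FeatureTable] = None
    cysteine_regions: Sequence[str] = ()
    named_clusters: Optional[Mapping[str, Sequence[str]]] = None
    external_alignments: Optional[Mapping[str, Alignment]] = None

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if len(self.registry) == 0:
            raise PipelineError("empty registry")
        bad = set(self.partitions) - set(PARTITIONS)
        if bad:
            raise PipelineError(f"unknown partitions: {sorted(bad)}")


def _partition_record(rec: ProteinRecord, split, partition: str) -> ProteinRecord:
    seq = {
        "prodomain": split.prodomain,
        "ligand": split.ligand,
        "full_length": rec.sequence,
        "cystine_knot": split.knot,
    }[partition]
    return ProteinRecord(
        id=rec.id, sequence=seq, species=rec.species,
        subfamily_label=rec.subfamily_label, accession=rec.accession,
    )


def _groupings(reg: Registry, outgroup_id: Optional[str]) -> dict[str, list[str]]:
    subfam: dict[str, list[str]] = {}
    for rec in reg:
        if rec.id == outgroup_id or rec.subfamily_label == "outgroup":
            continue
        subfam.setdefault(rec.subfamily_label, []).append(rec.id)
    groups = dict(subfam)
    if "Activin" in subfam and "TGFB" in subfam:
        groups["Activin+TGFB"] = subfam["Activin"] + subfam["TGFB"]
    groups["all"] = [i for ids in subfam.values() for i in ids]
    return groups


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis; writes a report bundle and returns it in memory.

    On stage failure partial outputs are retained next to a ``FAILED_<stage>``
    marker file, and the exception propagates.
    """
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"splits": {}, "alignments": {}, "info": {}, "trees": {},
                    "thresholds": {}}
    stage = "split"
    try:
        reg = cfg.registry
        outgroup = cfg.outgroup_id
        if outgroup is None:
            for rec in reg:
                if rec.subfamily_label == "outgroup":
                    outgroup = rec.id
                    break

        # --- stage: cleavage splitting + spacer analytics -------------------
        splits = {rec.id: split_record(rec) for rec in reg}
        bundle["splits"] = splits
        with open(out / "cleavage_sites.tsv", "w") as fh:
            fh.write("# id\tsite_end\tmotif\tkind\tknot_start\n")
            for rid, sp in splits.items():
                fh.write(
                    f"{rid}\t{sp.cleavage_end}\t{sp.site.motif_text}\t"
                    f"{sp.site.kind}\t{sp.knot_start}\n"
                )
        stats = spacer_table(
            splits.values(),
            subfamilies={r.id: r.subfamily_label for r in reg},
        )
        bundle["spacer_stats"] = stats
        with open(out / "spacers.tsv", "w") as fh:
            fh.write("# id\tspacer\tlength\tacidic_upstream\n")
            for rid, sp in splits.items():
                fh.write(
                    f"{rid}\t{sp.spacer}\t{sp.spacer_length}\t"
                    f"{int(sp.acidic_upstream)}\n"
                )
        for part in ("prodomain", "ligand", "cystine_knot"):
            recs = [_partition_record(reg[rid], splits[rid], part) for rid in reg.ids()]
            write_fasta(recs, out / f"{part}.fasta")

        # --- stage: alignments, informative sites, trees --------------------
        stage = "align"
        groups = _groupings(reg, outgroup)
        for gname, ids in groups.items():
            tree_ids = ids + ([outgroup] if outgroup else [])
            for part in cfg.partitions:
                key = f"{gname}.{part}"
                recs = [_partition_record(reg[r], splits[r], part) for r in tree_ids]
                if cfg.external_alignments and key in cfg.external_alignments:
                    aln = cfg.external_alignments[key].subset_rows(
                        [r.id for r in recs]
                    )
                else:
                    aln = progressive_align(recs, cfg.align_params)
                bundle["alignments"][key] = aln
                write_alignment(aln, out / f"aln_{gname}_{part}.fasta")
                if aln.n_rows >= 4:
                    report = count_informative(aln)
                    bundle["info"][key] = report
                    try:
                        bundle["thresholds"][key] = significance_threshold(
                            report.n_informative
                        )
                    except TreeError:
                        bundle["thresholds"][key] = None
                stage = "trees"
                if aln.n_rows >= 3:
                    tree = bootstrap_support(
                        aln, n_reps=cfg.bootstrap_reps, seed=cfg.seed
                    )
                    if outgroup and outgroup in aln.row_ids:
                        tree = root_with_outgroup(tree, outgroup)
                    bundle["trees"][key] = tree
                    write_newick(tree, out / f"tree_{gname}_{part}.nwk")
                stage = "align"

        # --- stage: conservation + cysteine scan ----------------------------
        stage = "conserve"
        if cfg.feature_table is not None:
            aln = bundle["alignments"].get("all.full_length")
            if aln is not None and cfg.feature_table.reference_id in aln.row_ids:
                profile = shade_profile(aln)
                bundle["conservation"] = profile
                with open(out / "conservation.tsv", "w") as fh:
                    fh.write("# column\tclass\tconsensus\tcount\n")
                    for col, (cls, cons, cnt) in enumerate(
                        zip(profile.classes, profile.consensus, profile.counts), 1
                    ):
                        fh.write(f"{col}\t{cls}\t{cons or '.'}\t{cnt}\n")
                fmap = map_features(
                    aln, cfg.feature_table.reference_id, cfg.feature_table
                )
                bundle["feature_map"] = fmap
                bundle["cysteine_reports"] = {}
                with open(out / "cysteine_report.tsv", "w") as fh:
                    fh.write("# region\tid\tmotif\tanchor_column\n")
                    for region in cfg.cysteine_regions:
                        rep = scan_cysteines(aln, fmap, region)
                        bundle["cysteine_reports"][region] = rep
                        for rid in aln.row_ids:
                            fh.write(
                                f"{region}\t{rid}\t{rep.row_motifs[rid]}\t"
                                f"{rep.row_anchor_columns[rid] or '.'}\n"
                            )

        # --- stage: cross-partition comparison ------------------------------
        stage = "compare"
        if cfg.named_clusters:
            part_trees = {
                part: bundle["trees"][f"all.{part}"]
                for part in cfg.partitions
                if f"all.{part}" in bundle["trees"]
            }
            thresholds = {
                part: bundle["thresholds"].get(f"all.{part}")
                for part in part_trees
            }
            thresholds = {p: t for p, t in thresholds.items() if t is not None}
            comparison = compare_partitions(
                part_trees, cfg.named_clusters, thresholds=thresholds,
                allowed_drops={outgroup} if outgroup else None,
            )
            bundle["comparison"] = comparison
            with open(out / "cluster_comparison.tsv", "w") as fh:
                fh.write("# cluster\tpartition\tpresent\tsupport\tprodomain_only\n")
                for name, row in comparison.table.items():
                    flag = int(name in comparison.prodomain_only)
                    for part, entry in row.items():
                        fh.write(
                            f"{name}\t{part}\t{int(entry['present_as_clade'])}\t"
                            f"{entry['support']:.3f}\t{flag}\n"
                        )

        manifest = {
            "prodomainkit_version": __version__,
            "seed": cfg.seed,
            "bootstrap_reps": cfg.bootstrap_reps,
            "partitions": list(cfg.partitions),
            "n_records": len(cfg.registry),
            "outgroup": outgroup,
            "groupings": {g: ids for g, ids in groups.items()},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        bundle["manifest"] = manifest
        return bundle
    except Exception:
        (out / f"FAILED_{stage}").touch()
        logger.exception("pipeline failed at stage %s", stage)
        raise
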