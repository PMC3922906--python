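"""The end-to-end pipeline: filtering -> tree -> clans -> classification.

Stages (each writes its artifact and logs counts to standard error):

1. optional hit filtering against query lengths,
2. gap filtering of the alignment,
3. column trimming,
4. distance matrix + neighbor joining,
5. bootstrap support mapping,
6. monophyly (clan) report per rank,
7. pruning of non-plant leaves and outgroup rooting,
8. group/supergroup classification,
9. per-species member count table.

Any stage failure raises :class:`PipelineError` naming the stage.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

from . import clans, filters, io_formats as io, phylo_core, report
from .classify import classify as _run_classify

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("famclade")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs.

    Thresholds default to the package's standard screening regime (see
    :class:`famclade.filters.FilterConfig`); bootstrap defaults to 1000
    replicates; internal edges at or below 75 % support are collapsed before
    classification; rooting uses the green-algae leaves.
    """

    alignment: str | os.PathLike = ""
    taxonomy: str | os.PathLike = ""
    outdir: str | os.PathLike = "famclade_out"
    hits: str | os.PathLike | None = None
    query_fasta: str | os.PathLike | None = None
    family_name: str = "family"
    filter: filters.FilterConfig = field(default_factory=filters.FilterConfig)
    distance_model: str = "jtt_ml"
    bootstrap_replicates: int = 1000
    seed: int = 0
    collapse_threshold: float | None = 0.75
    outgroup_rank: str = "green_algae"
    root_position: float = 0.5


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        return wrapped

    return deco


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run every stage; returns a map of artifact names to paths."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    taxonomy = _load_taxonomy(cfg)
    aln = _load_alignment(cfg)
    log.info("input: %d sequences x %d columns", len(aln), aln.length)

    if cfg.hits is not None:
        aln = _filter_by_hits(cfg, aln, outdir, artifacts)

    aln = _gap_stage(cfg, aln, outdir, artifacts)
    aln = _trim_stage(cfg, aln, outdir, artifacts)
    tree = _tree_stage(cfg, aln, outdir, artifacts)
    tree = _bootstrap_stage(cfg, aln, tree, outdir, artifacts)
    _monophyly_stage(cfg, tree, taxonomy, outdir, artifacts)
    rooted = _root_stage(cfg, tree, taxonomy, outdir, artifacts)
    result = _classify_stage(cfg, rooted, taxonomy, outdir, artifacts)
    _report_stage(cfg, result, taxonomy, outdir, artifacts)
    return artifacts


@_stage("load-taxonomy")
def _load_taxonomy(cfg: PipelineConfig) -> io.TaxonomyTable:
    return io.read_taxonomy(cfg.taxonomy)


@_stage("load-alignment")
def _load_alignment(cfg: PipelineConfig) -> io.Alignment:
    return io.read_alignment(cfg.alignment)


@_stage("filter-hits")
def _filter_by_hits(cfg, aln, outdir, artifacts) -> io.Alignment:
    hits = io.read_hits(cfg.hits)
    queries = io.read_fasta(cfg.query_fasta)
    qlen = {r.id: len(r.ungapped()) for r in queries}
    accepted, rejected = filters.filter_hits(hits, qlen, cfg.filter)
    artifacts["hits_accepted"] = outdir / "hits_accepted.tsv"
    io.write_hits(accepted, artifacts["hits_accepted"])
    artifacts["hits_rejected"] = outdir / "hits_rejected.tsv"
    with open(artifacts["hits_rejected"], "w") as fh:
        for hit, reason in rejected:
            fh.write("\t".join(hit.to_fields() + [reason]) + "\n")
    log.info("filter-hits: %d accepted, %d rejected", len(accepted), len(rejected))
    keep = {h.subject_id for h in accepted}
    kept = [r for r in aln if r.id in keep]
    if not kept:
        raise ValueError("no aligned sequence matches an accepted hit")
    return io.Alignment(kept)


@_stage("gap-filter")
def _gap_stage(cfg, aln, outdir, artifacts) -> io.Alignment:
    kept, excluded = filters.gap_filter(aln, cfg.filter)
    artifacts["gap_excluded"] = outdir / "gap_excluded.txt"
    Path(artifacts["gap_excluded"]).write_text("".join(x + "\n" for x in excluded))
    log.info("gap-filter: kept %d, excluded %d sequences", len(kept), len(excluded))
    return kept

@_stage("trim-columns")
def _trim_stage(cfg, aln, outdir, artifacts) -> io.Alignment:
    trimmed, kept_cols = filters.trim_columns(aln, cfg.filter)
    artifacts["trimmed_alignment"] = outdir / "trimmed.fasta"
    io.write_fasta(trimmed.records, artifacts["trimmed_alignment"])
    artifacts["kept_columns"] = outdir / "kept_columns.tsv"
    with open(artifacts["kept_columns"], "w") as fh:
        fh.write("column\n")  # 1-based inclusive, reporting convention
        for c in kept_cols:
            fh.write(f"{c + 1}\n")
    log.info("trim: kept %d of %d columns", len(kept_cols), aln.length)
    return trimmed


@_stage("neighbor-joining")
def _tree_stage(cfg, aln, outdir, artifacts) -> io.Tree:
    dm = phylo_core.alignment_distances(aln, model=cfg.distance_model)
    tree = phylo_core.neighbor_joining(dm)
    artifacts["nj_tree"] = outdir / "nj_tree.nwk"
    io.write_newick(tree, artifacts["nj_tree"])
    log.info("nj: %d-leaf tree (%s distances)", len(aln), cfg.distance_model)
    return tree


@_stage("bootstrap")
def _bootstrap_stage(cfg, aln, tree, outdir, artifacts) -> io.Tree:
    bcfg = phylo_core.BootstrapConfig(
        replicates=cfg.bootstrap_replicates, seed=cfg.seed
    )
    supported = phylo_core.bootstrap_support(
        aln, tree, bcfg, dist_model=cfg.distance_model
    )
    artifacts["supported_tree"] = outdir / "supported_tree.nwk"
    io.write_newick(supported, artifacts["supported_tree"])
    supports = [
        n.support
        for n in supported.postorder()
        if n.support is not None and n is not supported.root
    ]
    if supports:
        log.info(
            "bootstrap: %d replicates; support min/median/max = %.2f/%.2f/%.2f",
            bcfg.replicates,
            min(supports),
            sorted(supports)[len(supports) // 2],
            max(supports),
        )
    return supported


@_stage("monophyly-report")
def _monophyly_stage(cfg, tree, taxonomy, outdir, artifacts) -> None:
    rep = clans.monophyly_report(tree, taxonomy)
    artifacts["monophyly"] = outdir / "monophyly.tsv"
    with open(artifacts["monophyly"], "w") as fh:
        fh.write("class\tn_leaves\tis_clan\n")
        for rank, (n, clan) in rep.by_rank.items():
            fh.write(f"{rank}\t{n}\t{str(clan).lower()}\n")
        fh.write(f"plant\t{rep.plant[0]}\t{str(rep.plant[1]).lower()}\n")
    log.info(
        "monophyly: nonplant clan = %s", rep.nonplant_is_clan
    )


@_stage("root")
def _root_stage(cfg, tree, taxonomy, outdir, artifacts) -> io.Tree:
    nonplant = [
        l for l in tree.leaf_labels() if taxonomy.rank_of_sequence(l) == "nonplant"
    ]
    work = tree.prune_leaves(nonplant) if nonplant else tree
    outgroup = {
        l
        for l in work.leaf_labels()
        if taxonomy.rank_of_sequence(l) == cfg.outgroup_rank
    }
    if not outgroup:
        raise ValueError(f"no leaves of outgroup rank {cfg.outgroup_rank!r}")
    if len(outgroup) == len(work.leaf_labels()):
        raise ValueError("outgroup rank covers every leaf; cannot root")
    rooted = clans.root_by_outgroup(work, outgroup, position=cfg.root_position)
    artifacts["rooted_tree"] = outdir / "rooted_tree.nwk"
    io.write_newick(rooted, artifacts["rooted_tree"])
    log.info(
        "root: pruned %d non-plant leaves, rooted on %d %s leaves",
        len(nonplant),
        len(outgroup),
        cfg.outgroup_rank,
    )
    return rooted


@_stage("classify")
def _classify_stage(cfg, rooted, taxonomy, outdir, artifacts):
    result = _run_classify(
        rooted, taxonomy, collapse_threshold=cfg.collapse_threshold
    )
    artifacts["membership"] = outdir / "membership.tsv"
    with open(artifacts["membership"], "w") as fh:
        fh.write("leaf_id\tsupergroup\tgroup\thalf\tlabel\n")
        for leaf_id in sorted(result.leaves):
            lc = result.leaves[leaf_id]
            fh.write(
                "\t".join(
                    [
                        leaf_id,
                        lc.supergroup or "",
                        lc.group or "",
                        lc.half or "",
                        lc.label,
                    ]
                )
                + "\n"
            )
    n_groups = sum(len(g) for g in result.group_roots.values())
    log.info(
        "classify: %d supergroups, %d groups, %d unplaced clades",
        len(result.supergroup_roots),
        n_groups,
        len(result.unplaced),
    )
    return result


@_stage("report")
def _report_stage(cfg, result, taxonomy, outdir, artifacts) -> None:
    assignments = [
        (leaf_id, taxonomy.species_of_sequence(leaf_id), cfg.family_name)
        for leaf_id in result.leaves
    ]
    table = report.count_table(assignments, taxonomy)
    artifacts["count_table"] = outdir / "count_table.tsv"
    report.write_count_table(table, artifacts["count_table"])
    log.info("report: %d members tabulated", table.total())
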