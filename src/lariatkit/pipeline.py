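"""End-to-end orchestration of the knockout-vs-wildtype lariat workflow.

simulate -> classify -> map (both mappers) -> filter -> aggregate ->
analytics, with per-stage logging of read counts in/out and a structured
JSON + TSV report.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import analytics
from .align import build_index, classify_linear, transcript_space
from .io import RunConfig, write_branchpoint_bed, write_calls, write_fasta, write_fastq, write_introns, write_tsv
from .mapping import (
    MapParams,
    aggregate_branchpoints,
    filter_intron_circles,
    map_lariats_split,
    map_lariats_ss,
    rejection_summary,
)
from .synthetic import (
    DebranchKinetics,
    ErrorModel,
    simulate_lariat_abundance,
    simulate_reads,
    make_genome,
    uniform_counts,
)

logger = logging.getLogger(__name__)


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> dict:
    """Run the full simulated knockout-vs-wildtype analysis; returns the report."""
    config.validate()
    stage = "simulate"
    try:
        report = _run(config, write_outputs)
    except Exception as e:  # annotate failures with the failing stage
        raise RuntimeError(f"pipeline failed during stage {getattr(e, '_stage', stage)!r}: {e}") from e
    return report


def _run(config: RunConfig, write_outputs: bool) -> dict:
    out_dir = Path(config.out_dir)
    if write_outputs:
        out_dir.mkdir(parents=True, exist_ok=True)

    logger.info("stage simulate: generating genome with %d genes", config.n_genes)
    genome, introns, genes = make_genome(
        config.n_genes,
        config.intron_len_range,
        config.seed,
        introns_per_gene=config.introns_per_gene,
        u12_fraction=config.u12_fraction,
    )
    kinetics = DebranchKinetics(
        base_survival=config.base_survival,
        branch_rates=dict(config.branch_rates),
        five_ss_g_modifier=config.five_ss_g_modifier,
    )
    expression = config.lariat_reads_null / len(introns)
    abundance = simulate_lariat_abundance(introns, expression, kinetics, config.seed + 1, genome)

    error_model = ErrorModel(
        sub_rate=config.sub_rate,
        rt_branch_misincorporation=config.rt_branch_misincorporation,
    )
    gene_ids = [g.gene_id for g in genes]
    intron_ids = [i.intron_id for i in introns]
    cond_null, cond_active = config.conditions
    read_sets, truths = {}, {}
    for offset, (cond, col) in enumerate([(cond_null, "null"), (cond_active, "active")]):
        counts = {
            "lariat": {iid: int(abundance.loc[iid, col]) for iid in intron_ids},
            "linear_mRNA": uniform_counts(gene_ids, config.linear_reads),
            "pre_mRNA": uniform_counts(gene_ids, config.pre_mrna_reads),
            "intron_circle": uniform_counts(intron_ids, config.circle_reads),
        }
        reads, truth = simulate_reads(
            genome, introns, counts,
            read_len=config.read_len,
            error_model=error_model,
            seed=config.seed + 10 + offset,
            genes=genes,
            min_block=config.min_block,
        )
        read_sets[cond], truths[cond] = reads, truth
        logger.info("stage simulate: %s -> %d reads", cond, len(reads))

    index = build_index(genome, 12)
    tx_space = transcript_space(genes, genome)
    params = MapParams(
        min_segment=config.min_segment,
        circle_tolerance=config.circle_tolerance,
        max_mismatch=config.max_mismatch,
        max_mismatch_rate=config.max_mismatch_rate,
        max_indel_len=config.max_indel_len,
    )

    tables = {}
    call_sets = {}
    stats_rows = []
    for cond in (cond_null, cond_active):
        reads = read_sets[cond]
        mapped_flags = {
            r.read_id: classify_linear(r.seq, index, params.linear, tx_space) for r in reads
        }
        n_mapped = sum(mapped_flags.values())
        unmapped = [r for r in reads if not mapped_flags[r.read_id]]
        logger.info("stage classify (%s): %d mapped / %d unmapped",
                    cond, n_mapped, len(unmapped))
        for mapper, fn in (("split", map_lariats_split), ("ss", map_lariats_ss)):
            calls = fn(unmapped, genome, introns, params, index=index,
                       prefilter_linear=False)
            calls = filter_intron_circles(calls, introns, config.circle_tolerance)
            table = aggregate_branchpoints(
                calls, n_mapped=n_mapped, sample_id=f"{cond}_{mapper}"
            )
            tables[(cond, mapper)] = table
            call_sets[(cond, mapper)] = calls
            stats_rows.append({
                "sample": cond,
                "mapper": mapper,
                "n_reads": len(reads),
                "n_mapped": n_mapped,
                "n_lariat": table.n_lariat,
                "recovery_rate": analytics.recovery_rate(table.n_lariat, n_mapped),
            })
            logger.info("stage map (%s, %s): %d lariat calls; rejections: %s",
                        cond, mapper, table.n_lariat,
                        rejection_summary(calls).to_dict())

    report: dict = {"config": {"seed": config.seed, "n_genes": config.n_genes},
                    "samples": stats_rows}

    # fold changes and composition per mapper
    for mapper in ("split", "ss"):
        t_ko = tables[(cond_null, mapper)]
        t_wt = tables[(cond_active, mapper)]
        fc = analytics.fold_change(t_ko, t_wt, level="intron",
                                   pseudocount=config.pseudocount)
        report[f"global_fold_change_{mapper}"] = analytics.fold_change(
            t_ko, t_wt, level="set"
        )
        comp = {}
        for cond in (cond_null, cond_active):
            passed = [c for c in call_sets[(cond, mapper)] if c.passed]
            if passed:
                comp[cond] = analytics.bp_composition(passed).to_dict()
        report[f"bp_composition_{mapper}"] = comp
        if write_outputs:
            write_tsv(fc.reset_index().rename(columns={"index": "intron_id"}),
                      out_dir / f"fold_change_{mapper}.tsv")

    # cross-mapper concordance on the null (lariat-rich) condition
    report["concordance"] = cross_mapper_concordance(
        call_sets[(cond_null, "split")], call_sets[(cond_null, "ss")]
    )

    if config.u12_fraction > 0:
        fc = analytics.fold_change(tables[(cond_null, "ss")], tables[(cond_active, "ss")],
                                   level="intron", pseudocount=config.pseudocount)
        try:
            report["u12_u2"] = analytics.u12_u2_contrast(fc, introns)
        except ValueError as e:
            logger.warning("u12 contrast skipped: %s", e)

    if write_outputs:
        write_fasta(genome, out_dir / "genome.fa")
        write_introns(introns, out_dir / "introns.tsv")
        for cond in (cond_null, cond_active):
            write_fastq(read_sets[cond], out_dir / f"reads_{cond}.fastq")
            write_tsv(truths[cond].reads, out_dir / f"truth_{cond}.tsv")
            for mapper in ("split", "ss"):
                write_calls(call_sets[(cond, mapper)],
                            out_dir / f"calls_{cond}_{mapper}.tsv")
                write_branchpoint_bed(tables[(cond, mapper)], introns,
                                      out_dir / f"branchpoints_{cond}_{mapper}.bed")
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    return report


def _json_default(obj):
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def cross_mapper_concordance(calls_split, calls_ss) -> dict:
    """Agreement between the two mappers on (intron, branchpoint) read calls."""
    a = {c.read_id: (c.intron_id, c.bp_position) for c in calls_split if c.passed}
    b = {c.read_id: (c.intron_id, c.bp_position) for c in calls_ss if c.passed}
    shared = set(a) & set(b)
    agree = sum(1 for r in shared if a[r] == b[r])
    return {
        "n_split": len(a),
        "n_ss": len(b),
        "n_shared": len(shared),
        "n_agree": agree,
        "fraction_agree": agree / len(shared) if shared else 1.0,
        "identical_sets": set(a.items()) == set(b.items()),
    }
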