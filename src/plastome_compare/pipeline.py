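"""End-to-end comparative pipeline.

Runs partitioning, junction profiling, region extraction, per-region
divergence with hotspot screening, SSR detection/classification, and the
IR-stripped concatenation with NJ + bootstrap, writing one TSV per result
table plus the tree and a run log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .divergence import (DivergenceStats, RegionAlignment, align_region,
                         divergence_stats, hotspot_screen, overall_identity)
from .io import GenomeRecord, gc_content, parse_genbank
from .phylo import ConcatSummary, alignment_summary, bootstrap, write_phylip
from .quadripartite import (GeneCensus, Partition, detect_ir, gene_census,
                            junction_report)
from .regions import RegionSet, extract_regions
from .simulate import SimConfig, simulate
from .ssr import SSRTable, classify_and_summarize

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genome_paths: list = field(default_factory=list)  # GenBank files
    sim: SimConfig | None = None                      # alternative input source
    out_dir: str | Path | None = None
    min_aligned_len: int = 150     # region filter: aligned length must exceed this
    hotspot_threshold: float = 2.0
    ssr_min_units: dict[int, int] | None = None
    min_ir_len: int = 1000
    bootstrap_reps: int = 200
    seed: int = 0
    align_method: str = "auto"

    def validate(self) -> None:
        if self.min_aligned_len <= 0 or self.hotspot_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not self.genome_paths and self.sim is None:
            raise ValueError("either genome_paths or a simulation config is required")


@dataclass
class RunResult:
    partitions: list[Partition]
    censuses: dict[str, GeneCensus]
    region_set: RegionSet
    coding_stats: list[DivergenceStats]
    noncoding_stats: list[DivergenceStats]
    hotspots: list[DivergenceStats]
    ssr_table: SSRTable
    concat: RegionAlignment
    concat_summary: ConcatSummary
    identity_pct: float
    tree_newick: str


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def load_genomes(config: RunConfig) -> list[GenomeRecord]:
    if config.sim is not None:
        return simulate(config.sim).records
    return [parse_genbank(p) for p in config.genome_paths]


def run_all(config: RunConfig) -> RunResult:
    config.validate()
    records = _stage("load")(load_genomes)(config)
    if len(records) < 3:
        raise ValueError("pipeline needs >= 3 genomes")
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    partitions = [_stage("partition")(detect_ir)(r, config.min_ir_len) for r in records]
    censuses = {p.record.id: gene_census(p) for p in partitions}

    if out:
        rows = []
        for p in partitions:
            rows.append({
                "taxon": p.record.id,
                "genome_size": p.genome_length,
                "lsc_length": p.lsc_length,
                "ssc_length": p.ssc_length,
                "ir_length": p.ir_length,
                "gc_content": gc_content(p.record.seq),
                "unique_genes": censuses[p.record.id].unique_total,
            })
        pd.DataFrame(rows).to_csv(out / "table1.tsv", sep="\t", index=False)
        jrows = []
        for p in partitions:
            rep = _stage("junctions")(junction_report)(p)
            for jname, e in rep.entries.items():
                jrows.append({
                    "taxon": p.record.id, "junction": jname, "position": e.position,
                    "spanning_gene": e.spanning_gene or "",
                    "left_len": e.left_len, "right_len": e.right_len,
                    "left_gene": e.left_gene or "", "left_gap": e.left_gap,
                    "right_gene": e.right_gene or "", "right_gap": e.right_gap,
                })
        pd.DataFrame(jrows).to_csv(out / "junctions.tsv", sep="\t", index=False)

    region_set = _stage("regions")(extract_regions)(partitions)

    coding_stats, noncoding_stats = [], []
    for name, region in region_set.regions.items():
        aln = _stage("align")(align_region)(region.seqs, name=name, method=config.align_method)
        st = _stage("divergence")(divergence_stats)(aln, category=region.category)
        if st.aligned_length <= config.min_aligned_len:
            continue
        if region.category == "coding":
            coding_stats.append(st)
        else:
            noncoding_stats.append(st)
    hotspots = hotspot_screen(noncoding_stats, config.hotspot_threshold)

    ssr_table = _stage("ssr")(classify_and_summarize)(partitions, config.ssr_min_units)

    stripped = {
        p.record.id: p.record.seq[: p.genome_length - p.ir_length]
        for p in partitions
    }
    concat = _stage("concat-align")(align_region)(
        stripped, name="concatenation", method=config.align_method)
    summary = _stage("concat-summary")(alignment_summary)(concat)
    identity = overall_identity(concat)
    tree = _stage("tree")(bootstrap)(concat, config.bootstrap_reps, config.seed)
    newick = tree.newick()

    if out:
        _write_divergence(coding_stats, out / "table2.tsv")
        _write_divergence(noncoding_stats, out / "table3.tsv")
        _write_divergence(hotspots, out / "hotspots.tsv")
        _write_ssr(ssr_table, out / "table4.tsv")
        pd.DataFrame([{
            "aligned_length": summary.aligned_length,
            "variable_positions": summary.variable_positions,
            "parsimony_informative": summary.parsimony_informative,
            "substitutions": summary.substitutions,
            "indel_events": summary.indel_events,
            "indel_length": summary.indel_length,
            "percent_variability": summary.percent_variability,
            "mean_pairwise_identity": identity,
        }]).to_csv(out / "concat_summary.tsv", sep="\t", index=False)
        (out / "tree.nwk").write_text(newick + "\n")
        write_phylip(concat, out / "concat.phy")
        (out / "run.log").write_text(_run_log(config, records))

    return RunResult(
        partitions=partitions, censuses=censuses, region_set=region_set,
        coding_stats=coding_stats, noncoding_stats=noncoding_stats,
        hotspots=hotspots, ssr_table=ssr_table, concat=concat,
        concat_summary=summary, identity_pct=identity, tree_newick=newick,
    )


def _write_divergence(stats: list[DivergenceStats], path: Path) -> None:
    pd.DataFrame([{
        "region": s.region,
        "category": s.category,
        "length_bp": s.length_range,
        "aligned_length_bp": s.aligned_length,
        "variable_positions": s.variable_positions,
        "nucleotide_substitutions": s.substitutions,
        "number_of_indels": s.indel_events,
        "total_length_of_indels": s.indel_length,
        "percent_variability": f"{s.percent_variability:.2f}",
    } for s in stats]).to_csv(path, sep="\t", index=False)


def _write_ssr(table: SSRTable, path: Path) -> None:
    rows = []
    for i, ((context, motif), per_taxon) in enumerate(sorted(
            table.loci.items(),
            key=lambda kv: min(l.start for l in kv[1].values())), start=1):
        lengths = sorted({loc.length for loc in per_taxon.values()})
        rep = (str(lengths[0]) if len(lengths) == 1
               else f"{lengths[0]}-{lengths[-1]}")
        rows.append({"no": i, "motif": motif, "location": context,
                     "region": table.regions[(context, motif)],
                     "repeat_length": rep,
                     "n_genomes": len(per_taxon)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _run_log(config: RunConfig, records: list[GenomeRecord]) -> str:
    lines = [
        f"plastome-compare {__version__}",
        f"genomes: {', '.join(r.id for r in records)}",
        f"min_aligned_len: {config.min_aligned_len}",
        f"hotspot_threshold: {config.hotspot_threshold}",
        f"min_ir_len: {config.min_ir_len}",
        f"bootstrap_reps: {config.bootstrap_reps}",
        f"seed: {config.seed}",
        f"align_method: {config.align_method}",
    ]
    if config.sim is not None:
        lines.append(f"sim_seed: {config.sim.seed}")
    return "\n".join(lines) + "\n"
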