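"""Homologous region extraction across plastomes.

Regions are the units of the divergence screen: protein-coding genes
(exon-concatenated), introns, and intergenic spacers.  Spacers and introns are
delimited on the genome with the IRa copy removed, so each single-copy locus
and one IR copy contribute exactly once.  Regions are matched across genomes
by canonical name ("matK", "trnT (UGU)-trnL (UAA)", "rps16 intron",
"ycf3 intron1", ...).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io import extract_subsequence
from .quadripartite import Partition

logger = logging.getLogger(__name__)

CODING = "coding"
INTRON = "intron"
SPACER = "spacer"


@dataclass
class Region:
    name: str
    category: str  # coding | intron | spacer
    seqs: dict[str, str] = field(default_factory=dict)       # taxon -> sequence
    intervals: dict[str, tuple[int, int]] = field(default_factory=dict)


@dataclass
class RegionSet:
    regions: dict[str, Region]
    excluded: list[str] = field(default_factory=list)  # names absent from >=1 genome
    notices: list[str] = field(default_factory=list)

    def by_category(self, category: str) -> list[Region]:
        return [r for r in self.regions.values() if r.category == category]


def _clipped_parts(feature, stripped_len: int, n: int):
    """Exon parts of a feature restricted to the IRa-stripped genome [0, stripped_len)."""
    out = []
    for s, e in feature.parts:
        pieces = [(s, e)] if e >= s else [(s, n), (0, e)]
        for ps, pe in pieces:
            ps2, pe2 = ps, min(pe, stripped_len)
            if ps2 < stripped_len and pe2 > ps2:
                out.append((ps2, pe2))
    return out


def _intron_name(gene: str, idx: int, n_introns: int) -> str:
    return f"{gene} intron" if n_introns == 1 else f"{gene} intron{idx}"


def _regions_of_genome(partition: Partition) -> dict[str, tuple[str, str, tuple[int, int]]]:
    """name -> (category, sequence, interval) for one canonically oriented genome."""
    record = partition.record
    n = record.length
    stripped_len = n - partition.ir_length  # IRa occupies the final ir_length bases
    out: dict[str, tuple[str, str, tuple[int, int]]] = {}

    # --- coding regions: exon-concatenated CDS per unique gene (first occurrence)
    seen_cds: set[str] = set()
    for f in record.features:
        if f.kind != "CDS" or f.name.endswith("_like") or f.name in seen_cds:
            continue
        seen_cds.add(f.name)
        seq = extract_subsequence(record, f)
        out[f.name] = (CODING, seq, (f.start, f.end))

    # --- part inventory on the stripped genome (exons of every feature kind)
    parts = []  # (start, end, gene, plus_order_part_index, n_parts, strand)
    seen_feature_names: set[str] = set()
    for f in record.features:
        clipped = _clipped_parts(f, stripped_len, n)
        if not clipped:
            continue
        # a duplicated IR gene contributes its IRb copy only once by name
        key = (f.name, clipped[0][0])
        if key in seen_feature_names:
            continue
        seen_feature_names.add(key)
        n_parts = len(f.parts)
        for i, (s, e) in enumerate(sorted(clipped)):
            parts.append((s, e, f.name, i, n_parts, f.strand))
    parts.sort()

    # --- introns and spacers from gaps between consecutive parts
    for (s1, e1, g1, i1, np1, st1), (s2, e2, g2, i2, np2, st2) in zip(parts, parts[1:]):
        gap = (e1, s2)
        glen = s2 - e1
        if glen <= 0:
            if glen < 0:
                logger.info("%s: overlap between %s and %s; spacer skipped", record.id, g1, g2)
            continue
        if g1 == g2 and i2 == i1 + 1:
            n_introns = np1 - 1
            idx = i1 + 1 if st1 == 1 else np1 - 1 - i1
            name = _intron_name(g1, idx, n_introns)
            seq = record.seq[e1:s2]
            if st1 == -1:
                seq = extract_subsequence(record, (e1, s2, -1))
            out[name] = (INTRON, seq, gap)
        else:
            name = f"{g1}-{g2}"
            out[name] = (SPACER, record.seq[e1:s2], gap)
    return out


def extract_regions(partitions: list[Partition]) -> RegionSet:
    """Extract named regions from every genome and keep those present in all.

    Coding sequences come from the full annotation (a gene may run into IRa);
    introns and spacers are delimited on the IRa-stripped genome.  Regions
    missing from one or more genomes are listed in ``excluded``.
    """
    per_genome = {}
    for part in partitions:
        per_genome[part.record.id] = _regions_of_genome(part)
    taxa = list(per_genome)
    all_names: list[str] = []
    for regmap in per_genome.values():
        for name in regmap:
            if name not in all_names:
                all_names.append(name)
    regions: dict[str, Region] = {}
    excluded, notices = [], []
    for name in all_names:
        present = [t for t in taxa if name in per_genome[t]]
        if len(present) < len(taxa):
            excluded.append(name)
            notices.append(f"region {name} absent from {len(taxa) - len(present)} genome(s); excluded")
            continue
        category = per_genome[taxa[0]][name][0]
        reg = Region(name=name, category=category)
        for t in taxa:
            _, seq, interval = per_genome[t][name]
            reg.seqs[t] = seq
            reg.intervals[t] = interval
        if any(not s for s in reg.seqs.values()):
            excluded.append(name)
            continue
        regions[name] = reg
    for msg in notices:
        logger.warning(msg)
    return RegionSet(regions=regions, excluded=excluded, notices=notices)
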