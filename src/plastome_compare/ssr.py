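"""Perfect chloroplast microsatellite (cpSSR) detection and classification.

Detection reports maximal perfect tandem runs of 1-6 bp motifs above
per-unit-length minimum repeat counts (defaults: mono >= 10 units, di >= 6,
tri/tetra >= 4, penta/hexa >= 3).  A run is reported only under its smallest
generating unit (a poly-A tract is a mononucleotide locus, never "AA"), the
motif label keeps the observed phase (ATT and TTA are distinct), runs are
broken at N, and the trailing partial unit of a run not divisible by the unit
length is included in the locus length but not in the unit count.

Classification assigns each locus a quadripartite region (the IRa copy is
dropped before scanning, so an IR locus appears once) and a genic context:
the containing gene body, intron, or intergenic spacer.  Loci are matched
across genomes by (context, motif).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .quadripartite import Partition
from .regions import _regions_of_genome

DEFAULT_MIN_UNITS = {1: 10, 2: 6, 3: 4, 4: 4, 5: 3, 6: 3}


@dataclass(frozen=True)
class SSRLocus:
    motif: str
    start: int
    end: int
    n_units: int
    region: str = ""      # LSC | IR | SSC
    context: str = ""     # gene body, intron or spacer name

    @property
    def unit_len(self) -> int:
        return len(self.motif)

    @property
    def length(self) -> int:
        return self.end - self.start


def _is_primitive(motif: str) -> bool:
    """True unless the motif is itself a repeat of a shorter unit."""
    m = len(motif)
    for d in range(1, m):
        if m % d == 0 and motif == motif[:d] * (m // d):
            return False
    return True


def find_ssrs(seq: str, min_units: dict[int, int] | None = None,
              max_unit: int = 6) -> list[SSRLocus]:
    """Maximal perfect tandem repeats in ``seq``, smallest-unit preference,
    sorted by start.  Overlap between surviving candidates is resolved in
    favour of the longer run (then the smaller unit, then the leftmost)."""
    thresholds = dict(DEFAULT_MIN_UNITS if min_units is None else min_units)
    if any(v < 1 for v in thresholds.values()):
        raise ValueError("minimum unit counts must be >= 1")
    s = seq.upper()
    n = len(s)
    candidates = []
    for u in range(1, max_unit + 1):
        if u not in thresholds:
            continue
        i = 0
        while i + u <= n:
            motif = s[i: i + u]
            if "N" in motif:
                i += 1
                continue
            j = i + u
            while j < n and s[j] == s[j - u] and s[j] != "N":
                j += 1
            left_maximal = i == 0 or s[i - 1] == "N" or s[i - 1] != s[i - 1 + u]
            if left_maximal and _is_primitive(motif):
                units = (j - i) // u
                if units >= thresholds[u]:
                    candidates.append(SSRLocus(motif=motif, start=i, end=j, n_units=units))
            # any period-u start before j-u+1 is a sub-run of [i, j)
            i = max(i + 1, j - u + 1) if j - i >= 2 * u else i + 1
    # smallest-unit / overlap deduplication: longer run wins, then smaller unit
    candidates.sort(key=lambda c: (-c.length, c.unit_len, c.start))
    kept: list[SSRLocus] = []
    for c in candidates:
        if all(c.end <= k.start or c.start >= k.end for k in kept):
            kept.append(c)
    return sorted(kept, key=lambda c: c.start)


# ---------------------------------------------------------------------------
# classification against a partitioned, annotated genome

@dataclass
class SSRTable:
    """Cross-genome SSR table keyed by (context, motif), Table-4 style."""

    loci: dict[tuple[str, str], dict[str, SSRLocus]]  # (context, motif) -> taxon -> locus
    regions: dict[tuple[str, str], str] = field(default_factory=dict)
    flagged: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        n = len(self.loci)
        by_unit: dict[int, int] = {}
        mono_motifs: dict[str, int] = {}
        by_region: dict[str, int] = {}
        for key in self.loci:
            _, motif = key
            by_unit[len(motif)] = by_unit.get(len(motif), 0) + 1
            if len(motif) == 1:
                mono_motifs[motif] = mono_motifs.get(motif, 0) + 1
            region = self.regions[key]
            by_region[region] = by_region.get(region, 0) + 1
        mono_total = by_unit.get(1, 0)
        return {
            "total": n,
            "by_unit_length": by_unit,
            "mononucleotide_motifs": mono_motifs,
            "mono_A_share_pct": round(100.0 * mono_motifs.get("A", 0) / mono_total, 2)
            if mono_total else 0.0,
            "mono_T_share_pct": round(100.0 * mono_motifs.get("T", 0) / mono_total, 2)
            if mono_total else 0.0,
            "region_counts": by_region,
            "region_pct": {r: round(100.0 * c / n, 2) for r, c in by_region.items()}
            if n else {},
        }


def _context_map(partition: Partition):
    """Sorted (start, end, name) context intervals on the IRa-stripped genome:
    gene exon bodies, then named introns and spacers."""
    record = partition.record
    n = record.length
    stripped = n - partition.ir_length
    intervals = []
    for f in record.features:
        for s, e in f.parts:
            pieces = [(s, e)] if e >= s else [(s, n), (0, e)]
            for ps, pe in pieces:
                if ps < stripped:
                    intervals.append((ps, min(pe, stripped), f.name))
    for name, (cat, _seq, (s, e)) in _regions_of_genome(partition).items():
        if cat in ("intron", "spacer"):
            intervals.append((s, e, name))
    intervals.sort()
    return intervals


def classify_ssrs(partition: Partition, min_units: dict[int, int] | None = None
                  ) -> list[SSRLocus]:
    """Detect SSRs on the plus strand of the canonically oriented genome with
    the IRa copy removed, and assign region + context to each locus."""
    record = partition.record
    stripped = record.length - partition.ir_length
    loci = find_ssrs(record.seq[:stripped], min_units)
    contexts = _context_map(partition)
    out = []
    for loc in loci:
        region = partition.region_of(loc.start)
        region = "IR" if region in ("IRb", "IRa") else region
        context = ""
        for s, e, name in contexts:
            if s <= loc.start < e:
                context = name
                break
        out.append(SSRLocus(motif=loc.motif, start=loc.start, end=loc.end,
                            n_units=loc.n_units, region=region, context=context))
    return out


def classify_and_summarize(partitions: list[Partition],
                           min_units: dict[int, int] | None = None) -> SSRTable:
    """Detect and classify SSRs in every genome, then match loci across
    genomes by (context, motif)."""
    table: dict[tuple[str, str], dict[str, SSRLocus]] = {}
    regions: dict[tuple[str, str], str] = {}
    flagged: list[str] = []
    for part in partitions:
        taxon = part.record.id
        for loc in classify_ssrs(part, min_units):
            key = (loc.context, loc.motif)
            table.setdefault(key, {})[taxon] = loc
            regions.setdefault(key, loc.region)
            if regions[key] != loc.region:
                flagged.append(f"{key}: region differs between genomes")
    return SSRTable(loci=table, regions=regions, flagged=flagged)
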