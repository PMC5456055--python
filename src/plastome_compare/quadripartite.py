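"""Quadripartite structure of a plastome.

Angiosperm chloroplast genomes carry two identical inverted repeats (IRb,
IRa) separating a large and a small single-copy region (LSC, SSC).  This
module locates the IR pair by exact reverse-complement matching, rotates the
genome to a canonical orientation (position 0 = first LSC base, so the order
reads LSC, IRb, SSC, IRa), profiles the four single-copy/IR junctions, and
censuses the gene content.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .io import Feature, GenomeRecord, extract_subsequence, reverse_complement

JUNCTIONS = ("J_LB", "J_SB", "J_SA", "J_LA")


class NoQuadripartiteStructureError(ValueError):
    """No inverted-repeat pair of the required length was found."""


@dataclass
class Partition:
    """LSC/IRb/SSC/IRa intervals on the canonically oriented sequence."""

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    record: GenomeRecord  # canonically oriented copy

    @property
    def lsc_length(self) -> int:
        return self.lsc[1] - self.lsc[0]

    @property
    def ssc_length(self) -> int:
        return self.ssc[1] - self.ssc[0]

    @property
    def ir_length(self) -> int:
        return self.irb[1] - self.irb[0]

    @property
    def genome_length(self) -> int:
        return self.record.length

    def region_of(self, pos: int) -> str:
        for name, (s, e) in (("LSC", self.lsc), ("IRb", self.irb),
                             ("SSC", self.ssc), ("IRa", self.ira)):
            if s <= pos < e:
                return name
        raise ValueError(f"position {pos} outside genome")

    def validate(self) -> None:
        n = self.genome_length
        assert self.lsc == (0, self.lsc_length)
        assert self.lsc_length + self.ssc_length + 2 * self.ir_length == n
        irb_seq = self.record.seq[self.irb[0]: self.irb[1]]
        ira_seq = self.record.seq[self.ira[0]: self.ira[1]]
        if reverse_complement(irb_seq) != ira_seq:
            raise NoQuadripartiteStructureError("IR copies are not exact reverse complements")
        if self.lsc_length <= self.ssc_length:
            raise NoQuadripartiteStructureError("LSC not longer than SSC")


def _circular_overlap(a: int, la: int, b: int, lb: int, n: int) -> bool:
    return (b - a) % n < la or (a - b) % n < lb


def _maximal_revcomp_pairs(seq: str, min_len: int, k: int = 31):
    """Seed-and-extend search for maximal exact reverse-complement repeats on a
    circular sequence.  Yields (startA, startB, length) with starts mod n."""
    n = len(seq)
    k = min(k, min_len)
    rc = reverse_complement(seq)
    sd = seq + seq
    rd = rc + rc
    index: dict[str, list[int]] = {}
    for q in range(n):
        index.setdefault(rd[q: q + k], []).append(q)
    covered: dict[int, int] = {}  # circular diagonal -> furthest p extended
    out = []
    for p in range(n):
        hits = index.get(sd[p: p + k])
        if not hits:
            continue
        for q in hits:
            diag = (p - q) % n
            if covered.get(diag, -1) >= p:
                continue
            length = k
            while length < n and sd[p + length] == rd[q + length]:
                length += 1
            covered[diag] = p + length
            if length < min_len:
                continue
            a = p % n
            b = (n - q - length) % n  # map back from revcomp coordinates
            out.append((a, b, length))
    return out


def detect_ir(record: GenomeRecord, min_ir_len: int = 1000) -> Partition:
    """Find the longest pair of disjoint exact inverted repeats and return the
    canonical quadripartite partition.

    The genome is rotated so that position 0 is the first LSC base downstream
    of IRa; feature coordinates are rotated along.  Ties between equal-length
    IR candidates are broken by leftmost start in the input orientation.
    """
    if not record.circular:
        raise NoQuadripartiteStructureError("quadripartite detection requires a circular genome")
    n = record.length
    best = None  # (length, startA, startB)
    for a, b, length in _maximal_revcomp_pairs(record.seq, min_ir_len):
        x, y = min(a, b), max(a, b)
        if _circular_overlap(x, length, y, length, n):
            continue
        cand = (-length, x, y)
        if best is None or cand < best:
            best = cand
    if best is None:
        raise NoQuadripartiteStructureError(
            f"no quadripartite structure: no inverted repeat >= {min_ir_len} bp"
        )
    ir_len, ir1, ir2 = -best[0], best[1], best[2]
    # single-copy arcs between the two IR copies
    arc1_start = (ir1 + ir_len) % n
    arc1_len = (ir2 - arc1_start) % n
    arc2_start = (ir2 + ir_len) % n
    arc2_len = (ir1 - arc2_start) % n
    if arc1_len == arc2_len:
        raise NoQuadripartiteStructureError("single-copy regions have equal length; cannot label LSC/SSC")
    if arc1_len > arc2_len:
        lsc_start, lsc_len, ssc_len = arc1_start, arc1_len, arc2_len
    else:
        lsc_start, lsc_len, ssc_len = arc2_start, arc2_len, arc1_len

    rotated = rotate_record(record, lsc_start)
    part = Partition(
        lsc=(0, lsc_len),
        irb=(lsc_len, lsc_len + ir_len),
        ssc=(lsc_len + ir_len, lsc_len + ir_len + ssc_len),
        ira=(lsc_len + ir_len + ssc_len, n),
        record=rotated,
    )
    part.validate()
    return part


def rotate_record(record: GenomeRecord, offset: int) -> GenomeRecord:
    """Rotate a circular genome so old position ``offset`` becomes position 0."""
    n = record.length
    offset %= n
    seq = record.seq[offset:] + record.seq[:offset]
    feats = []
    for f in record.features:
        parts = []
        for s, e in f.parts:
            ns = (s - offset) % n
            ne = (e - offset) % n or n
            parts.append((ns, ne))
        feats.append(replace(f, parts=tuple(parts)))
    out = GenomeRecord(
        id=record.id, seq=seq, circular=record.circular,
        organism=record.organism, features=feats, metadata=dict(record.metadata),
    )
    out.sort_features()
    return out


# ---------------------------------------------------------------------------
# junctions

@dataclass
class JunctionEntry:
    junction: str
    position: int
    spanning_gene: str | None = None
    left_len: int = 0          # bp of the spanning gene before the junction
    right_len: int = 0         # bp after
    left_gene: str | None = None   # nearest gene upstream when none spans
    left_gap: int | None = None
    right_gene: str | None = None
    right_gap: int | None = None


@dataclass
class JunctionReport:
    entries: dict[str, JunctionEntry]
    ir_partials: dict[str, int] = field(default_factory=dict)  # "_like" gene -> bp within IR


def junction_report(partition: Partition) -> JunctionReport:
    """Profile the four LSC/SSC-IR junctions of a canonically oriented genome.

    For each junction the spanning gene (with the bp it contributes on either
    side) is reported, or else the nearest genes on both sides with their gaps.
    Incomplete IR duplicates (names suffixed ``_like``) are reported with their
    within-IR lengths.
    """
    record = partition.record
    if not record.features:
        raise ValueError("junction report requires an annotated genome")
    n = record.length
    positions = {
        "J_LB": partition.irb[0],
        "J_SB": partition.ssc[0],
        "J_SA": partition.ira[0],
        "J_LA": 0,  # IRa/LSC boundary == origin in canonical orientation
    }
    entries: dict[str, JunctionEntry] = {}
    for name, j in positions.items():
        entry = JunctionEntry(junction=name, position=j)
        spanning = None
        for f in record.features:
            left = (j - f.start) % n
            right = (f.end - j) % n
            span = (f.end - f.start) % n or n
            if 0 < left < span and 0 < right <= span and left + right == span:
                spanning = (f, left, right)
                break
        if spanning is not None:
            f, left, right = spanning
            entry.spanning_gene = f.name
            entry.left_len, entry.right_len = left, right
        else:
            up = min(record.features, key=lambda f: (j - f.end) % n)
            down = min(record.features, key=lambda f: (f.start - j) % n)
            entry.left_gene, entry.left_gap = up.name, (j - up.end) % n
            entry.right_gene, entry.right_gap = down.name, (down.start - j) % n
        entries[name] = entry
    partials = {}
    for f in record.features:
        if f.name.endswith("_like"):
            partials[f.name] = max(f.length(n), partials.get(f.name, 0))
    return JunctionReport(entries=entries, ir_partials=partials)


# ---------------------------------------------------------------------------
# gene census

@dataclass
class GeneCensus:
    unique_total: int
    by_kind: dict[str, int]
    duplicated_in_ir: list[str]
    intron_containing: list[str]
    single_intron: list[str]
    two_intron: list[str]

    def as_dict(self) -> dict:
        return {
            "unique_total": self.unique_total,
            "cds": self.by_kind.get("CDS", 0),
            "trna": self.by_kind.get("tRNA", 0),
            "rrna": self.by_kind.get("rRNA", 0),
            "duplicated_in_ir": len(self.duplicated_in_ir),
            "intron_containing": len(self.intron_containing),
            "single_intron": len(self.single_intron),
            "two_intron": len(self.two_intron),
        }


def _within(interval: tuple[int, int], region: tuple[int, int]) -> bool:
    s, e = interval
    return region[0] <= s and e <= region[1] and e >= s


def gene_census(partition: Partition) -> GeneCensus:
    """Census unique genes by kind; IR-duplicated genes are counted once and
    flagged; intron content derives from exon-part counts (k parts = k-1
    introns).  ``_like`` incomplete duplicates are excluded."""
    record = partition.record
    by_name: dict[str, list[Feature]] = {}
    for f in record.features:
        if f.name.endswith("_like"):
            continue
        by_name.setdefault(f.name, []).append(f)
    by_kind: dict[str, int] = {}
    duplicated, intron_genes, single_intron, two_intron = [], [], [], []
    for name, occurrences in by_name.items():
        kind = occurrences[0].kind
        by_kind[kind] = by_kind.get(kind, 0) + 1
        if len(occurrences) >= 2:
            in_ir = sum(
                1 for f in occurrences
                if all(_within(p, partition.irb) or _within(p, partition.ira) for p in f.parts)
            )
            if in_ir >= 2:
                duplicated.append(name)
        n_introns = max(f.n_introns for f in occurrences)
        if n_introns >= 1:
            intron_genes.append(name)
            (single_intron if n_introns == 1 else two_intron).append(name)
    return GeneCensus(
        unique_total=len(by_name),
        by_kind=by_kind,
        duplicated_in_ir=sorted(duplicated),
        intron_containing=sorted(intron_genes),
        single_intron=sorted(single_intron),
        two_intron=sorted(two_intron),
    )


def check_start_codons(record: GenomeRecord) -> list[tuple[str, str]]:
    """List (gene, codon) for every CDS whose first in-frame codon is not ATG."""
    seen: set[str] = set()
    unusual = []
    for f in record.features:
        if f.kind != "CDS" or f.name.endswith("_like") or f.name in seen:
            continue
        seen.add(f.name)
        cds = extract_subsequence(record, f)
        if len(cds) < 3:
            raise ValueError(f"CDS {f.name} shorter than 3 bp")
        codon = cds[:3]
        if codon != "ATG":
            unusual.append((f.name, codon))
    return sorted(unusual)
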