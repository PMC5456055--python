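"""Reading and writing annotated plastomes.

Plastomes are handled as circular sequences with 0-based half-open feature
coordinates internally; GenBank flat files (1-based inclusive, join/complement)
are converted on the way in and out.  Only gene-bearing features (CDS, tRNA,
rRNA) are retained; ``source``, ``misc_feature`` and the like are skipped with
a logged notice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

FEATURE_KINDS = ("CDS", "tRNA", "rRNA")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class PlastomeParseError(ValueError):
    """Raised when a flat file cannot be interpreted as an annotated plastome."""


class PlastomeValidationError(ValueError):
    """Raised when parsed coordinates are inconsistent with the sequence."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """One gene-level feature: name, kind, strand and exon parts.

    ``parts`` are 0-based half-open intervals in ascending plus-strand order.
    A part with start > end wraps the origin (circular genomes only).
    """

    name: str
    kind: str  # CDS | tRNA | rRNA
    strand: int  # +1 / -1
    parts: tuple[tuple[int, int], ...]

    @property
    def start(self) -> int:
        return self.parts[0][0]

    @property
    def end(self) -> int:
        return self.parts[-1][1]

    @property
    def n_introns(self) -> int:
        return len(self.parts) - 1

    def length(self, genome_length: int | None = None) -> int:
        total = 0
        for s, e in self.parts:
            if e >= s:
                total += e - s
            else:
                if genome_length is None:
                    raise PlastomeValidationError(
                        f"feature {self.name}: wrapping part on linear record"
                    )
                total += genome_length - s + e
        return total

    def span_contains(self, pos: int) -> bool:
        """True if ``pos`` falls within [start, end) treating parts as one span."""
        if self.end >= self.start:
            return self.start <= pos < self.end
        return pos >= self.start or pos < self.end


@dataclass
class GenomeRecord:
    """A circular (or linear) annotated plastome."""

    id: str
    seq: str
    circular: bool = True
    organism: str = ""
    features: list[Feature] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.seq)

    def validate(self) -> None:
        n = self.length
        for f in self.features:
            for s, e in f.parts:
                if not (0 <= s < n) or not (0 < e <= n):
                    raise PlastomeValidationError(
                        f"feature {f.name}: part ({s},{e}) outside [0,{n})"
                    )
                if e < s and not self.circular:
                    raise PlastomeValidationError(
                        f"feature {f.name}: origin wrap on a linear record"
                    )

    def sort_features(self) -> None:
        self.features.sort(key=lambda f: (f.start, f.end, f.name))


# ---------------------------------------------------------------------------
# subsequence extraction

def extract_interval(record: GenomeRecord, start: int, end: int, strand: int = 1) -> str:
    """Plus-strand slice [start, end); ``end < start`` wraps the origin on
    circular records.  ``strand == -1`` returns the reverse complement."""
    n = record.length
    if not (0 <= start < n) or not (0 <= end <= n):
        raise PlastomeValidationError(f"interval ({start},{end}) outside [0,{n})")
    if end >= start:
        sub = record.seq[start:end]
    else:
        if not record.circular:
            raise PlastomeValidationError("origin-wrapping interval on linear record")
        sub = record.seq[start:] + record.seq[:end]
    return reverse_complement(sub) if strand == -1 else sub


def extract_subsequence(record: GenomeRecord, feature_or_interval) -> str:
    """Sequence of a Feature (exons concatenated in transcription order,
    reverse-complemented for minus strand) or of a plain interval tuple
    ``(start, end)`` / ``(start, end, strand)``."""
    if isinstance(feature_or_interval, Feature):
        f = feature_or_interval
        exons = [extract_interval(record, s, e, 1) for s, e in f.parts]
        plus = "".join(exons)
        return reverse_complement(plus) if f.strand == -1 else plus
    start, end, *rest = feature_or_interval
    strand = rest[0] if rest else 1
    return extract_interval(record, start, end, strand)


def gc_content(seq: str) -> float:
    """GC percentage over unambiguous bases, to 2 decimals; N is excluded
    from the denominator."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    denom = gc + s.count("A") + s.count("T")
    if denom == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return round(100.0 * gc / denom + 1e-9, 2)


# ---------------------------------------------------------------------------
# GenBank I/O

def _location_to_parts(loc) -> tuple[int, tuple[tuple[int, int], ...]]:
    strand = -1 if loc.strand == -1 else 1
    parts = sorted((int(p.start), int(p.end)) for p in loc.parts)
    return strand, tuple(parts)


def _feature_name(sf: SeqFeature) -> str:
    q = sf.qualifiers
    for key in ("gene", "locus_tag", "product"):
        if key in q and q[key]:
            return q[key][0]
    return f"unnamed_{sf.type}"


def parse_genbank(path) -> GenomeRecord:
    """Read one annotated plastome from a GenBank flat file.

    Coordinates become 0-based half-open; only CDS/tRNA/rRNA features are
    kept (plain ``gene`` features are used solely as a name fallback).
    """
    try:
        rec = SeqIO.read(path, "genbank")
    except ValueError as exc:
        raise PlastomeParseError(f"{path}: {exc}") from exc
    seq = str(rec.seq).upper().replace("U", "T")
    if not seq:
        raise PlastomeParseError(f"{path}: record has no ORIGIN sequence")
    circular = rec.annotations.get("topology", "circular") == "circular"
    organism = rec.annotations.get("organism", "")
    features: list[Feature] = []
    skipped: set[str] = set()
    for sf in rec.features:
        if sf.type not in FEATURE_KINDS:
            if sf.type not in ("gene",):
                skipped.add(sf.type)
            continue
        strand, parts = _location_to_parts(sf.location)
        feat = Feature(name=_feature_name(sf), kind=sf.type, strand=strand, parts=parts)
        features.append(feat)
    if skipped:
        logger.info("%s: ignored feature kinds: %s", rec.id, ", ".join(sorted(skipped)))
    record = GenomeRecord(
        id=rec.id or rec.name,
        seq=seq,
        circular=circular,
        organism=organism,
        features=features,
        metadata={"description": rec.description},
    )
    record.validate()
    record.sort_features()
    return record


def write_genbank(record: GenomeRecord, path) -> None:
    """Write a GenomeRecord as a GenBank flat file (round-trips with
    :func:`parse_genbank` on sequence, names, coordinates and strands)."""
    rec = SeqRecord(
        Seq(record.seq),
        id=record.id,
        name=record.id.split(".")[0][:16] or "PLASTOME",
        description=record.metadata.get("description", f"{record.organism} chloroplast genome"),
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.circular else "linear",
            "organism": record.organism,
        },
    )
    n = record.length
    for f in record.features:
        locs = []
        for s, e in f.parts:
            if e >= s:
                locs.append(SimpleLocation(s, e, strand=f.strand))
            else:  # origin wrap -> two-part join
                locs.append(SimpleLocation(s, n, strand=f.strand))
                locs.append(SimpleLocation(0, e, strand=f.strand))
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        rec.features.append(SeqFeature(loc, type=f.kind, qualifiers={"gene": [f.name]}))
    SeqIO.write([rec], path, "genbank")


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        out[rec.description] = str(rec.seq).upper().replace("U", "T")
    if not out:
        raise PlastomeParseError(f"{path}: no FASTA records")
    return out
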