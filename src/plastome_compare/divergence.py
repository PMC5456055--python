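"""Per-region multiple alignment and divergence statistics.

The divergence screen summarises each aligned region by:

* ``S``  — substitution columns: gap-free columns with >= 2 distinct bases;
* ``I``  — indel events: distinct maximal gap runs, keyed by (start, end)
  column coordinates, so a run shared by several taxa at identical
  coordinates counts once;
* ``G``  — total indel length: sum of the distinct event lengths;
* ``V``  — variable positions: S plus the number of columns containing a gap;
* ``P``  — percent variability: 100 * (S + I) / aligned length, rounded
  half-up to two decimals.

Columns containing any gap are excluded from substitution counting, so a
substitution adjacent to (or inside) a gap contributes only through the gap
term.  Regions whose percent variability strictly exceeds a threshold
(default 2.0%) are flagged as mutational hotspots.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import read_fasta, write_fasta
from ._pairwise import progressive_align


@dataclass
class RegionAlignment:
    name: str
    taxa: list[str]
    rows: list[str]

    @property
    def aligned_length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def validate(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError(f"{self.name}: ragged alignment")
        if len(self.rows) != len(self.taxa):
            raise ValueError(f"{self.name}: taxa/rows mismatch")


@dataclass
class DivergenceStats:
    region: str
    category: str
    min_length: int
    max_length: int
    aligned_length: int
    variable_positions: int
    substitutions: int
    indel_events: int
    indel_length: int
    percent_variability: float

    @property
    def length_range(self) -> str:
        if self.min_length == self.max_length:
            return str(self.min_length)
        return f"{self.min_length}-{self.max_length}"


def round2_half_up(x: float) -> float:
    return math.floor(x * 100 + 0.5) / 100


def percent_variability(substitutions: int, indel_events: int, aligned_length: int) -> float:
    """100 * (S + I) / L, rounded half-up to 2 decimals."""
    if aligned_length <= 0:
        raise ValueError("aligned length must be positive")
    return round2_half_up(100.0 * (substitutions + indel_events) / aligned_length)


# ---------------------------------------------------------------------------
# alignment

def _mafft_available() -> bool:
    return shutil.which("mafft") is not None


def _run_mafft(seqs: dict[str, str], binary: str = "mafft") -> dict[str, str]:
    with tempfile.TemporaryDirectory() as td:
        inp = Path(td) / "in.fa"
        # opaque keys guard against mafft truncating long taxon labels
        keys = {f"s{i}": name for i, name in enumerate(seqs)}
        write_fasta({k: seqs[v] for k, v in keys.items()}, inp)
        res = subprocess.run(
            [binary, "--auto", "--quiet", str(inp)],
            capture_output=True, text=True, check=True,
        )
        out = Path(td) / "out.fa"
        out.write_text(res.stdout)
        aligned = read_fasta(out)
    return {keys[k]: aligned[k].upper() for k in keys}


def align_region(seqs: dict[str, str], name: str = "", method: str = "auto",
                 aligner_path: str | None = None) -> RegionAlignment:
    """Multiple alignment of one region across taxa.

    ``method='auto'`` invokes mafft when it is on PATH (or ``aligner_path``
    when given) and otherwise falls back to the built-in progressive aligner
    (pairwise affine-gap global alignment over a p-distance UPGMA guide tree).
    """
    if not seqs:
        raise ValueError("no sequences to align")
    taxa = list(seqs)
    if len(taxa) == 1:
        return RegionAlignment(name=name, taxa=taxa, rows=[seqs[taxa[0]]])
    if len(set(seqs.values())) == 1:
        return RegionAlignment(name=name, taxa=taxa, rows=[seqs[t] for t in taxa])
    if method == "auto":
        method = "mafft" if (aligner_path or _mafft_available()) else "builtin"
    if method == "mafft":
        aligned = _run_mafft(seqs, aligner_path or "mafft")
        rows = [aligned[t] for t in taxa]
    elif method == "builtin":
        aligned = progressive_align(seqs)
        rows = [aligned[t] for t in taxa]
    else:
        raise ValueError(f"unknown alignment method: {method}")
    aln = RegionAlignment(name=name, taxa=taxa, rows=rows)
    aln.validate()
    return aln


# ---------------------------------------------------------------------------
# statistics

def _column_classes(rows: list[str]) -> tuple[int, int]:
    """(substitution columns, gap-containing columns)."""
    arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(len(rows), -1)
    gap = (arr == ord("-")).any(axis=0)
    variable = (arr != arr[0]).any(axis=0)
    subs = int((variable & ~gap).sum())
    return subs, int(gap.sum())


def _gap_events(rows: list[str]) -> set[tuple[int, int]]:
    """Distinct maximal gap runs over all rows, keyed by (start, end) columns."""
    events: set[tuple[int, int]] = set()
    for row in rows:
        start = None
        for i, c in enumerate(row):
            if c == "-":
                if start is None:
                    start = i
            elif start is not None:
                events.add((start, i))
                start = None
        if start is not None:
            events.add((start, len(row)))
    return events


def divergence_stats(aln: RegionAlignment, category: str = "") -> DivergenceStats:
    """Column-scan divergence summary of one region alignment."""
    if len(aln.rows) < 2:
        raise ValueError(f"{aln.name}: divergence statistics need >= 2 sequences")
    aln.validate()
    L = aln.aligned_length
    subs, gap_cols = _column_classes(aln.rows)
    events = _gap_events(aln.rows)
    n_events = len(events)
    g_total = sum(e - s for s, e in events)
    lengths = [len(r.replace("-", "")) for r in aln.rows]
    return DivergenceStats(
        region=aln.name,
        category=category,
        min_length=min(lengths),
        max_length=max(lengths),
        aligned_length=L,
        variable_positions=subs + gap_cols,
        substitutions=subs,
        indel_events=n_events,
        indel_length=g_total,
        percent_variability=percent_variability(subs, n_events, L),
    )


def hotspot_screen(stats: list[DivergenceStats], threshold: float = 2.0) -> list[DivergenceStats]:
    """Regions with percent variability strictly above ``threshold``, sorted by
    P descending (ties keep input order)."""
    hits = [s for s in stats if s.percent_variability > threshold]
    return sorted(hits, key=lambda s: -s.percent_variability)


def overall_identity(aln: RegionAlignment) -> float:
    """Mean pairwise identity (%) over gap-free pair columns, to 1 decimal."""
    if len(aln.rows) < 2:
        raise ValueError("identity needs >= 2 taxa")
    arr = np.frombuffer("".join(aln.rows).encode(), dtype=np.uint8).reshape(len(aln.rows), -1)
    gap = ord("-")
    idents = []
    for i in range(len(aln.rows)):
        for j in range(i + 1, len(aln.rows)):
            ok = (arr[i] != gap) & (arr[j] != gap)
            denom = int(ok.sum())
            if denom == 0:
                raise ValueError(f"no gap-free columns for pair {aln.taxa[i]}, {aln.taxa[j]}")
            idents.append((arr[i][ok] == arr[j][ok]).sum() / denom)
    return round(100.0 * float(np.mean(idents)), 1)
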