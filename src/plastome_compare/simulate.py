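"""Synthetic annotated plastomes evolved along a known tree.

The generator builds a quadripartite ancestor (LSC + IRb + SSC, with IRa
derived as the reverse complement of IRb), places a realistic gene map —
including intron-containing genes, IR-duplicated genes, a gene spanning each
single-copy/IR junction with its incomplete ``_like`` duplicate, unusual
start codons, and planted SSR tracts — then evolves it along a newick tree
with per-region substitution-rate multipliers, an indel process confined to
noncoding DNA, and SSR unit-slippage.  Mutations falling in the IR are
automatically present in both copies because IRa is regenerated from IRb at
every node (perfect IR homogenization).

Every run returns a ground-truth manifest: the generating tree, per-region
multipliers, planted SSR loci, per-leaf realized partition boundaries, and
per-branch mutation counts, so each downstream pipeline stage can be tested
for exact recovery without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np

from .io import Feature, GenomeRecord, reverse_complement, write_genbank

_BASES = np.array(list("ACGT"))
_BASE_PROBS = np.array([0.31, 0.19, 0.18, 0.32])  # plastome-like, GC ~ 37%

DEFAULT_TREE = (
    "(S_sericans:0.0040,"
    "((S_argentea:0.0020,S_brevipedicellata:0.0020):0.0010,"
    "(S_khasiana:0.0020,(S_noronhae:0.0015,S_wallichii:0.0015):0.0010):0.0010):0.0030,"
    "((S_sinensis:0.0020,S_superba:0.0020):0.0010,"
    "(S_remotiserrata:0.0015,(S_multibracteata:0.0010,S_crenata:0.0010):0.0010):0.0010):0.0030);"
)


@dataclass
class SimConfig:
    tree: str = DEFAULT_TREE
    seed: int = 0
    indel_rate: float = 0.1      # indel events per substitution-unit of branch x length
    indel_mean: float = 2.0      # geometric mean indel length (bp)
    slip_rate: float = 0.02      # slippage events per SSR unit per branch
    scale: float = 1.0           # multiplies all segment lengths (1.0 = ~33 kb genome)
    hotspot_min_mult: float = 4.0


def full_size_config(**kw) -> SimConfig:
    """Preset with genome dimensions near a real plastome (~155 kb)."""
    return SimConfig(scale=4.7, **kw)


@dataclass
class Seg:
    kind: str                # exon | nc | ssr
    seq: str
    zone: str = ""           # LSC | IRB | SSC
    region: str = ""         # nc/ssr: spacer or intron name; exon: gene name
    category: str = ""       # nc: spacer | intron | edge
    mult: float = 1.0
    gene: str = ""
    feat_kind: str = ""      # CDS | tRNA | rRNA
    strand: int = 1
    exon_idx: int = 0        # 0-based plus-strand order
    n_exons: int = 1
    role: str = ""           # "" | "mirror" (ycf1 continuation inside IRb)
    motif: str = ""
    units: int = 0
    protect: tuple[int, int] | None = None  # substitution-free range (start codon)


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class _Builder:
    """Assembles the ancestral segment list from the default gene map."""

    def __init__(self, config: SimConfig, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        self.segs: list[Seg] = []
        self.zone = "LSC"
        self.genes: dict[str, dict] = {}  # name -> {kind, strand, n_exons, zone}
        self.unusual_starts: dict[str, str] = {}

    # -- sequence sampling -------------------------------------------------
    def _L(self, n: int, codon: bool = False) -> int:
        n = max(6, int(round(n * self.cfg.scale)))
        if codon:
            n = max(6, 3 * round(n / 3))
        return n

    def rand_seq(self, n: int) -> str:
        return "".join(self.rng.choice(_BASES, size=n, p=_BASE_PROBS))

    def cds_seq(self, n: int, start: str = "ATG") -> str:
        assert n % 3 == 0
        return start + self.rand_seq(n - 3)

    # -- low-level emitters ------------------------------------------------
    def exon(self, gene: str, kind: str, strand: int, seq: str,
             exon_idx: int, n_exons: int, role: str = "",
             protect: tuple[int, int] | None = None) -> None:
        self.segs.append(Seg(kind="exon", seq=seq, zone=self.zone, region=gene,
                             mult=0.5 if kind == "CDS" else 0.15,
                             gene=gene, feat_kind=kind, strand=strand,
                             exon_idx=exon_idx, n_exons=n_exons, role=role,
                             protect=protect))
        meta = self.genes.setdefault(gene, {"kind": kind, "strand": strand,
                                            "n_exons": n_exons, "zone": self.zone})
        meta["n_exons"] = max(meta["n_exons"], n_exons)

    def nc(self, length: int, mult: float, category: str = "spacer",
           region: str = "", seq: str | None = None) -> None:
        self.segs.append(Seg(kind="nc", seq=seq if seq is not None else self.rand_seq(length),
                             zone=self.zone, region=region, category=category, mult=mult))

    def ssr_seg(self, motif: str, units: int) -> None:
        # guard bases on both sides so the planted run cannot extend into flanks
        prev = self.segs[-1]
        if prev.kind == "nc" and prev.seq and prev.seq[-1] == motif[-1]:
            alt = next(b for b in "CGAT" if b != motif[-1])
            prev.seq = prev.seq[:-1] + alt
        self.segs.append(Seg(kind="ssr", seq=motif * units, zone=self.zone,
                             mult=0.0, motif=motif, units=units))

    def _guard_after_ssr(self) -> None:
        ssr = self.segs[-2] if len(self.segs) >= 2 else None
        if ssr is not None and ssr.kind == "ssr":
            nc = self.segs[-1]
            if nc.seq and nc.seq[0] == ssr.motif[0]:
                alt = next(b for b in "CGAT" if b != ssr.motif[0])
                nc.seq = alt + nc.seq[1:]

    # -- gene-map level ----------------------------------------------------
    def spacer(self, length: int, mult: float, ssr: tuple[str, int] | None = None) -> None:
        L = self._L(length)
        if ssr is None:
            self.nc(L, mult)
            return
        motif, units = ssr
        left = max(10, L // 2)
        self.nc(left, mult)
        self.ssr_seg(motif, units)
        self.nc(max(10, L - left), mult)
        self._guard_after_ssr()

    def gene(self, name: str, kind: str, strand: int, exons: list[int],
             introns: list[tuple[int, float]] | None = None,
             start: str = "ATG",
             intron_ssrs: dict[int, tuple[str, int]] | None = None) -> None:
        """Emit a gene.  ``exons`` are transcription-order lengths; introns are
        (length, mult) for the gaps between them."""
        introns = introns or []
        intron_ssrs = intron_ssrs or {}
        n_ex = len(exons)
        assert len(introns) == n_ex - 1
        lens = [self._L(e, codon=False) for e in exons]
        if kind == "CDS":
            total = 3 * round(sum(lens) / 3) or 3
            lens[-1] += total - sum(lens)
            body = self.cds_seq(total, start)
            if start != "ATG":
                self.unusual_starts[name] = start
        else:
            body = self.rand_seq(sum(lens))
        chunks, off = [], 0
        for ln in lens:
            chunks.append(body[off: off + ln])
            off += ln
        n_introns = n_ex - 1
        if strand == 1:
            plus_chunks = chunks
        else:
            plus_chunks = [reverse_complement(c) for c in reversed(chunks)]
        for i, chunk in enumerate(plus_chunks):
            protect = None
            if kind == "CDS":
                if strand == 1 and i == 0:
                    protect = (0, 3)
                elif strand == -1 and i == n_ex - 1:
                    protect = (len(chunk) - 3, len(chunk))
            self.exon(name, kind, strand, chunk, i, n_ex, protect=protect)
            if i < n_ex - 1:
                tr_idx = i + 1 if strand == 1 else n_ex - 1 - i
                iname = f"{name} intron" if n_introns == 1 else f"{name} intron{tr_idx}"
                ilen, imult = introns[i if strand == 1 else n_ex - 2 - i]
                L = self._L(ilen)
                if tr_idx in intron_ssrs:
                    motif, units = intron_ssrs[tr_idx]
                    left = max(10, L // 2)
                    self.nc(left, imult, "intron", iname)
                    self.ssr_seg(motif, units)
                    self.nc(max(10, L - left), imult, "intron", iname)
                    self._guard_after_ssr()
                else:
                    self.nc(L, imult, "intron", iname)


def _name_spacers(segs: list[Seg]) -> None:
    """Assign spacer region names A-B from flanking feature names; SSR tracts
    inherit the name of their enclosing spacer or intron."""
    def flank_name(seg: Seg) -> str:
        if seg.role == "mirror":
            return f"{seg.gene}_like"
        return seg.gene

    last_gene = None
    pending: list[Seg] = []
    for seg in segs:
        if seg.kind == "exon":
            name = flank_name(seg)
            for p in pending:
                if last_gene is None or p.category == "edge":
                    p.category = "edge"
                    p.region = p.region or "edge"
                elif p.category == "spacer":
                    p.region = f"{last_gene}-{name}"
            pending = []
            last_gene = name
        else:
            if seg.kind == "ssr":
                pending.append(seg)
            elif seg.category == "spacer":
                pending.append(seg)
            else:  # named intron (or edge) segments pass through; SSRs inside
                for p in pending:
                    p.region = seg.region
                pending = []
    for p in pending:  # trailing run (none in the default map)
        p.category = "edge"
        p.region = p.region or "edge"
    # SSR segments inside introns inherit from the following intron segment
    for i, seg in enumerate(segs):
        if seg.kind == "ssr" and not seg.region:
            if i + 1 < len(segs) and segs[i + 1].kind == "nc":
                seg.region = segs[i + 1].region
            elif i > 0:
                seg.region = segs[i - 1].region


def default_gene_map(config: SimConfig, rng: np.random.Generator) -> _Builder:
    """The scaled default plastome template (~33 kb at scale 1.0):
    LSC ~21 kb, IRb ~6.5 kb, SSC ~5.5 kb, with eight designated hotspot
    spacers (rate multipliers >= 4) and fourteen planted SSR tracts."""
    b = _Builder(config, rng)
    b.zone = "LSC"
    b.nc(14, 0.5, "edge", "edge_origin")          # noncoding stretch at J_LA
    b.gene("trnH (GUG)", "tRNA", -1, [75])
    b.spacer(350, 2.0, ssr=("A", 14))             # trnH (GUG)-psbA
    b.gene("psbA", "CDS", -1, [420])
    b.spacer(220, 1.0)
    # trnK with matK nested in its intron
    trnk = b.rand_seq(b._L(37) + b._L(35))
    b.exon("trnK (UUU)", "tRNA", 1, trnk[: b._L(37)], 0, 2)
    b.spacer(270, 1.5)                            # trnK (UUU)-matK
    b.gene("matK", "CDS", 1, [510])
    b.spacer(300, 0.5)                            # matK-trnK (UUU)
    b.exon("trnK (UUU)", "tRNA", 1, trnk[b._L(37):], 1, 2)
    b.spacer(400, 1.5, ssr=("A", 12))             # trnK (UUU)-rps16
    b.gene("rps16", "CDS", -1, [39, 228], [(300, 1.0)], intron_ssrs={1: ("T", 13)})
    b.spacer(380, 2.0, ssr=("T", 12))             # rps16-trnQ (UUG)
    b.gene("trnQ (UUG)", "tRNA", -1, [72])
    b.spacer(200, 1.0)
    b.gene("psbK", "CDS", 1, [186])
    b.spacer(160, 1.0)
    b.gene("psbI", "CDS", 1, [156], start="ATC")
    b.spacer(180, 0.5)
    b.gene("trnG (UCC)", "tRNA", 1, [23, 48], [(250, 1.0)])
    b.spacer(158, 5.0)                            # trnG (UCC)-trnfM (CAU)  HOTSPOT
    b.gene("trnfM (CAU)", "tRNA", 1, [74])
    b.spacer(250, 1.5)
    b.gene("psaB", "CDS", 1, [600])
    b.spacer(160, 0.5)
    b.gene("psaA", "CDS", 1, [600])
    b.spacer(230, 1.0)
    b.gene("rpoB", "CDS", -1, [930])
    b.spacer(320, 1.0)
    b.gene("rpoC1", "CDS", -1, [432, 600], [(300, 0.5)])
    b.spacer(180, 1.0)
    b.gene("rpoC2", "CDS", -1, [1200])
    b.spacer(250, 1.5)
    b.gene("atpI", "CDS", 1, [744])
    b.spacer(240, 1.0, ssr=("A", 13))             # atpI-atpH
    b.gene("atpH", "CDS", 1, [246])
    b.spacer(200, 1.0)
    b.gene("atpF", "CDS", -1, [145, 410], [(290, 1.0)])
    b.spacer(230, 0.5)
    b.gene("atpA", "CDS", -1, [900])
    b.spacer(300, 1.0)
    b.gene("ycf3", "CDS", -1, [124, 230, 153], [(280, 1.0), (270, 0.5)])
    b.spacer(170, 1.0)
    b.gene("trnT (UGU)", "tRNA", 1, [73])
    b.spacer(420, 6.0, ssr=("A", 13))             # trnT (UGU)-trnL (UAA)  HOTSPOT
    b.gene("trnL (UAA)", "tRNA", 1, [35, 50], [(260, 1.0)])
    b.spacer(200, 1.5)
    b.gene("ndhC", "CDS", 1, [363])
    b.spacer(410, 4.5, ssr=("T", 12))             # ndhC-trnV (UAC)  HOTSPOT
    b.gene("trnV (UAC)", "tRNA", -1, [72])
    b.spacer(350, 1.0)
    b.gene("atpB", "CDS", 1, [498])
    b.spacer(300, 1.5, ssr=("T", 12))             # atpB-rbcL
    b.gene("rbcL", "CDS", 1, [570])
    b.spacer(280, 0.5)
    b.gene("psbB", "CDS", 1, [480])
    b.spacer(172, 5.5)                            # psbB-psbT  HOTSPOT
    b.gene("psbT", "CDS", 1, [108], start="ATT")
    b.spacer(200, 1.0)
    b.gene("petB", "CDS", 1, [6, 642], [(300, 1.0)])
    b.spacer(180, 0.5)
    b.gene("petD", "CDS", 1, [9, 474], [(290, 1.0)])
    b.spacer(210, 7.0)                            # petD-rpoA  HOTSPOT
    b.gene("rpoA", "CDS", 1, [480])
    b.spacer(160, 1.0)
    b.gene("trnW (CCA)", "tRNA", -1, [74])
    b.spacer(175, 8.0)                            # trnW (CCA)-trnP (UGG)  HOTSPOT
    b.gene("trnP (UGG)", "tRNA", -1, [74])
    b.spacer(220, 1.0, ssr=("AT", 8))             # trnP (UGG)-clpP
    b.gene("clpP", "CDS", -1, [71, 292, 228], [(300, 1.5), (280, 1.0)],
           intron_ssrs={1: ("A", 12)})
    b.spacer(260, 1.0, ssr=("ATT", 6))            # clpP-rps19
    # rps19 spans J_LB: 5' piece in LSC, 3' piece in IRb
    rps19 = b.cds_seq(b._L(279, codon=True), start="GTG")
    b.unusual_starts["rps19"] = "GTG"
    cut = b._L(180)
    b.exon("rps19", "CDS", 1, rps19[:cut], 0, 1, protect=(0, 3))

    b.zone = "IRB"
    b.exon("rps19", "CDS", 1, rps19[cut:], 0, 1)
    b.spacer(170, 0.25)                           # rps19-rpl2
    b.gene("rpl2", "CDS", -1, [435, 390], [(320, 0.25)])
    b.spacer(250, 0.25)
    b.gene("rrn16", "rRNA", 1, [900])
    b.spacer(180, 0.25)
    b.gene("trnI (GAU)", "tRNA", 1, [37, 35], [(500, 0.25)])
    b.spacer(160, 0.25)
    b.gene("rrn23", "rRNA", 1, [1600])
    b.spacer(155, 0.25)
    b.gene("rrn4.5", "rRNA", 1, [103])
    b.spacer(200, 0.25)
    b.gene("rrn5", "rRNA", 1, [121])
    b.spacer(180, 0.25, ssr=("A", 12))            # rrn5-trnR (ACG)  (the IR locus)
    b.gene("trnR (ACG)", "tRNA", 1, [74])
    b.spacer(160, 0.25)                           # trnR (ACG)-ycf1_like
    # ycf1 spans J_SA: 5' piece at SSC end, 3' piece in IRa == mirror of this segment
    ycf1 = b.cds_seq(b._L(1650, codon=True), start="ATG")
    mirror_len = b._L(450)
    b.exon("ycf1", "CDS", 1, reverse_complement(ycf1[len(ycf1) - mirror_len:]),
           0, 1, role="mirror")

    b.zone = "SSC"
    b.nc(b._L(80), 0.5, "spacer")                 # ycf1_like-ndhF (J_SB gap)
    b.gene("ndhF", "CDS", -1, [630])
    b.spacer(300, 1.5, ssr=("T", 13))             # ndhF-rpl32
    b.gene("rpl32", "CDS", 1, [162])
    b.spacer(350, 4.0)                            # rpl32-trnL (UAG)  HOTSPOT
    b.gene("trnL (UAG)", "tRNA", 1, [80])
    b.spacer(150, 1.0)
    b.gene("ccsA", "CDS", 1, [321])
    b.spacer(180, 1.0)
    b.gene("ndhD", "CDS", -1, [501], start="ACG")
    b.spacer(160, 1.0)
    b.gene("ndhE", "CDS", 1, [306])
    b.spacer(230, 4.2)                            # ndhE-ndhG  HOTSPOT
    b.gene("ndhG", "CDS", 1, [531])
    b.spacer(200, 1.0, ssr=("A", 12))             # ndhG-ndhA
    b.gene("ndhA", "CDS", -1, [300, 303], [(250, 1.0)])
    b.spacer(160, 1.0)
    b.gene("rps15", "CDS", 1, [273])
    b.spacer(170, 1.0)
    b.exon("ycf1", "CDS", 1, ycf1[: len(ycf1) - mirror_len], 0, 1, protect=(0, 3))

    _name_spacers(b.segs)
    _plant_boundary_guards(b.segs)
    return b


def _plant_boundary_guards(segs: list[Seg]) -> None:
    """Adjust the four bases flanking the planted IR so the maximal exact
    repeat in the ancestor coincides with the planted boundaries."""
    core = "".join(s.seq for s in segs)
    lsc_len = sum(len(s.seq) for s in segs if s.zone == "LSC")
    ir_len = sum(len(s.seq) for s in segs if s.zone == "IRB")
    core_len = len(core)
    # LSC side: full[t] vs comp(full[lsc_len-1-t]); break at t=0
    if core[0] == _COMP[core[lsc_len - 1]]:
        _set_core_base(segs, 0, next(x for x in "ACGT" if x != _COMP[core[lsc_len - 1]]))
    # SSC side: full[lsc_len+ir_len] vs comp(full[core_len-1])
    if core[lsc_len + ir_len] == _COMP[core[core_len - 1]]:
        _set_core_base(segs, lsc_len + ir_len,
                       next(x for x in "ACGT" if x != _COMP[core[core_len - 1]]))


def _set_core_base(segs: list[Seg], pos: int, base: str) -> None:
    off = 0
    for s in segs:
        if off <= pos < off + len(s.seq):
            i = pos - off
            s.seq = s.seq[:i] + base + s.seq[i + 1:]
            return
        off += len(s.seq)


# ---------------------------------------------------------------------------
# assembly: segments -> annotated GenomeRecord + per-leaf truth

def _mirror_interval(a: int, bnd: int, irb_s: int, irb_e: int, core_len: int) -> tuple[int, int]:
    return (core_len + (irb_e - bnd), core_len + (irb_e - a))


def assemble(segs: list[Seg], taxon: str, builder: _Builder) -> tuple[GenomeRecord, dict]:
    core = "".join(s.seq for s in segs)
    core_len = len(core)
    offsets = []
    off = 0
    for s in segs:
        offsets.append(off)
        off += len(s.seq)
    lsc_len = sum(len(s.seq) for s in segs if s.zone == "LSC")
    ir_len = sum(len(s.seq) for s in segs if s.zone == "IRB")
    ssc_len = sum(len(s.seq) for s in segs if s.zone == "SSC")
    irb_s, irb_e = lsc_len, lsc_len + ir_len
    ira = reverse_complement(core[irb_s:irb_e])
    full = core + ira
    n = len(full)

    # --- features
    feats: list[Feature] = []
    by_gene: dict[str, list[tuple[int, Seg]]] = {}
    for i, s in enumerate(segs):
        if s.kind == "exon" and s.role != "mirror":
            by_gene.setdefault(s.gene, []).append((i, s))
    mirror_seg = next(((i, s) for i, s in enumerate(segs) if s.role == "mirror"), None)

    for gene, items in by_gene.items():
        meta = builder.genes[gene]
        parts = []
        for i, s in items:
            a, b2 = offsets[i], offsets[i] + len(s.seq)
            if parts and parts[-1][1] == a and segs[i].exon_idx == last_idx:
                parts[-1] = (parts[-1][0], b2)  # piece of a split exon
            else:
                parts.append((a, b2))
            last_idx = s.exon_idx
        if gene == "ycf1" and mirror_seg is not None:
            mi, ms = mirror_seg
            parts[-1] = (parts[-1][0], core_len + len(ms.seq))
        feats.append(Feature(name=gene, kind=meta["kind"], strand=meta["strand"],
                             parts=tuple(sorted(parts))))
        # duplicated copy for genes fully inside IRb
        if all(irb_s <= p[0] and p[1] <= irb_e for p in parts):
            mparts = sorted(_mirror_interval(a, b2, irb_s, irb_e, core_len) for a, b2 in parts)
            feats.append(Feature(name=gene, kind=meta["kind"], strand=-meta["strand"],
                                 parts=tuple(mparts)))
    # incomplete duplicates at the junctions
    if mirror_seg is not None:
        mi, ms = mirror_seg
        a, b2 = offsets[mi], offsets[mi] + len(ms.seq)
        feats.append(Feature(name="ycf1_like", kind="CDS",
                             strand=-builder.genes["ycf1"]["strand"], parts=((a, b2),)))
    rps19_irb = next(((i, s) for i, s in enumerate(segs)
                      if s.gene == "rps19" and s.zone == "IRB"), None)
    if rps19_irb is not None:
        i, s = rps19_irb
        a, b2 = offsets[i], offsets[i] + len(s.seq)
        mpart = _mirror_interval(a, b2, irb_s, irb_e, core_len)
        feats.append(Feature(name="rps19_like", kind="CDS",
                             strand=-builder.genes["rps19"]["strand"], parts=(mpart,)))

    record = GenomeRecord(id=taxon, seq=full, circular=True,
                          organism=taxon.replace("_", " "), features=feats)
    record.sort_features()
    record.validate()

    # --- realized IR boundaries (chance matches may extend the planted IR)
    t1 = 0
    while full[t1] == _COMP[full[lsc_len - 1 - t1]]:
        t1 += 1
    t2 = 0
    while full[irb_e + t2] == _COMP[full[core_len - 1 - t2]]:
        t2 += 1

    truth = {
        "length": n,
        "rotation": t1,
        "partition": {"lsc": lsc_len - 2 * t1, "ssc": ssc_len - 2 * t2,
                      "ir": ir_len + t1 + t2},
        "planted_partition": {"lsc": lsc_len, "ssc": ssc_len, "ir": ir_len},
        "junctions": {
            "J_LB": {"gene": "rps19",
                     "left": len([s for s in segs if s.gene == "rps19" and s.zone == "LSC"][0].seq) - t1,
                     "right": len(rps19_irb[1].seq) + t1},
            "J_SA": {"gene": "ycf1",
                     "left": len([s for i, s in enumerate(segs)
                                  if s.gene == "ycf1" and s.zone == "SSC"][0].seq) - t2,
                     "right": (len(mirror_seg[1].seq) if mirror_seg else 0) + t2},
        },
        "ssrs": [
            {"context": s.region, "motif": s.motif, "units": s.units,
             "start": (offsets[i] - t1) % n}
            for i, s in enumerate(segs) if s.kind == "ssr"
        ],
        "regions": _region_seqs(segs, builder),
    }
    return record, truth


def _region_seqs(segs: list[Seg], builder: _Builder) -> dict[str, dict]:
    out: dict[str, dict] = {}
    # noncoding regions: concatenate nc + ssr segments sharing a region name
    for s in segs:
        if s.kind in ("nc", "ssr") and s.category != "edge" and s.region not in ("", "edge", "edge_origin"):
            e = out.setdefault(s.region, {"category": s.category or "intron", "seq": "",
                                          "mult": s.mult if s.kind == "nc" else None})
            e["seq"] += s.seq
            if e["category"] == "":
                e["category"] = s.category
            if e["mult"] is None and s.kind == "nc":
                e["mult"] = s.mult
    # intron strandedness: minus-strand gene introns are reported 5'->3'
    for name, e in out.items():
        if e["category"] == "intron":
            gene = name.split(" intron")[0]
            if builder.genes.get(gene, {}).get("strand", 1) == -1:
                e["seq"] = reverse_complement(e["seq"])
    # coding regions: transcription-ordered exon concatenation
    for gene, meta in builder.genes.items():
        if meta["kind"] != "CDS":
            continue
        plus_chunks = []
        for s in segs:
            if s.kind == "exon" and s.gene == gene:
                plus_chunks.append(reverse_complement(s.seq) if s.role == "mirror" else s.seq)
        seq = "".join(plus_chunks)
        if gene == "ycf1":  # mirror chunk belongs at the 3' end
            mirror = next(s for s in segs if s.role == "mirror")
            body = "".join(s.seq for s in segs if s.gene == gene and s.role != "mirror")
            seq = body + reverse_complement(mirror.seq)
        if meta["strand"] == -1:
            seq = reverse_complement(seq)
        out[gene] = {"category": "coding", "seq": seq, "mult": None}
    return out


# ---------------------------------------------------------------------------
# evolution

def _mutate_branch(segs: list[Seg], bl: float, cfg: SimConfig,
                   rng: np.random.Generator, events: dict) -> list[Seg]:
    out = []
    for s in segs:
        s = replace(s)
        if s.kind == "ssr":
            k = rng.poisson(cfg.slip_rate * s.units) if bl > 0 else 0
            for _ in range(k):
                s.units = max(3, s.units + int(rng.choice([-1, 1])))
            s.seq = s.motif * s.units
            if k:
                events.setdefault("slippage", {}).setdefault(s.region, 0)
                events["slippage"][s.region] += k
        else:
            L = len(s.seq)
            lam = bl * L * s.mult
            k = rng.poisson(lam) if lam > 0 else 0
            if k:
                seq = list(s.seq)
                pos = rng.integers(0, L, k)
                for p in pos:
                    if s.protect and s.protect[0] <= p < s.protect[1]:
                        continue
                    others = [b for b in "ACGT" if b != seq[p]]
                    seq[p] = others[int(rng.integers(0, 3))]
                s.seq = "".join(seq)
                events.setdefault("substitutions", {}).setdefault(s.region, 0)
                events["substitutions"][s.region] += k
            if s.kind == "nc":
                lam_i = bl * len(s.seq) * s.mult * cfg.indel_rate
                ki = rng.poisson(lam_i) if lam_i > 0 else 0
                for _ in range(ki):
                    g = int(rng.geometric(1.0 / cfg.indel_mean))
                    if rng.random() < 0.5 and len(s.seq) - g >= 20:
                        p = int(rng.integers(0, len(s.seq) - g + 1))
                        s.seq = s.seq[:p] + s.seq[p + g:]
                    else:
                        p = int(rng.integers(0, len(s.seq) + 1))
                        ins = "".join(rng.choice(_BASES, size=g, p=_BASE_PROBS))
                        s.seq = s.seq[:p] + ins + s.seq[p:]
                    events.setdefault("indels", {}).setdefault(s.region, 0)
                    events["indels"][s.region] += 1
        out.append(s)
    return out


@dataclass
class SimResult:
    ancestor: GenomeRecord
    records: list[GenomeRecord]
    truth: dict = field(default_factory=dict)


def build_ancestor(config: SimConfig | None = None) -> GenomeRecord:
    """The annotated quadripartite ancestor genome of the default gene map."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    builder = default_gene_map(cfg, rng)
    record, _ = assemble(builder.segs, "ancestor", builder)
    return record


def simulate(config: SimConfig | None = None, out_dir=None) -> SimResult:
    """Evolve the ancestor along ``config.tree`` and return annotated leaf
    genomes plus the ground-truth manifest.  With ``out_dir``, one GenBank
    file per leaf and ``truth.json`` are written."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    builder = default_gene_map(cfg, rng)
    ancestor, _ = assemble(builder.segs, "ancestor", builder)
    tree = dendropy.Tree.get(data=cfg.tree, schema="newick")
    if len(tree.leaf_nodes()) < 3:
        raise ValueError("tree must have >= 3 leaves")

    census = _planted_census(builder)
    truth: dict = {
        "tree": cfg.tree,
        "seed": cfg.seed,
        "multipliers": {name: e["mult"] for name, e in
                        _region_seqs(builder.segs, builder).items() if e["mult"] is not None},
        "hotspots": sorted(
            (name for name, e in _region_seqs(builder.segs, builder).items()
             if e["mult"] is not None and e["mult"] >= cfg.hotspot_min_mult),
        ),
        "unusual_starts": dict(builder.unusual_starts),
        "census": census,
        "branch_events": {},
        "leaves": {},
    }

    records: list[GenomeRecord] = []

    def walk(node, segs, label_idx=[0]):
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            events: dict = {}
            child_segs = _mutate_branch(segs, bl, cfg, rng, events)
            if child.is_leaf():
                name = child.taxon.label.replace(" ", "_")
                truth["branch_events"][name] = events
                rec, leaf_truth = assemble(child_segs, name, builder)
                truth["leaves"][name] = leaf_truth
                records.append(rec)
            else:
                label_idx[0] += 1
                truth["branch_events"][f"node{label_idx[0]}"] = events
                walk(child, child_segs, label_idx)

    walk(tree.seed_node, builder.segs)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec in records:
            write_genbank(rec, out / f"{rec.id}.gb")
        slim = {k: v for k, v in truth.items() if k != "leaves"}
        slim["leaves"] = {
            t: {k: v for k, v in lv.items() if k != "regions"}
            for t, lv in truth["leaves"].items()
        }
        (out / "truth.json").write_text(json.dumps(slim, indent=1))
    return SimResult(ancestor=ancestor, records=records, truth=truth)


def _planted_census(builder: _Builder) -> dict:
    by_kind: dict[str, int] = {}
    dup, intron1, intron2 = [], [], []
    for gene, meta in builder.genes.items():
        by_kind[meta["kind"]] = by_kind.get(meta["kind"], 0) + 1
        if meta["zone"] == "IRB" and gene not in ("rps19", "ycf1"):
            dup.append(gene)
        n_in = meta["n_exons"] - 1
        if n_in == 1:
            intron1.append(gene)
        elif n_in >= 2:
            intron2.append(gene)
    return {
        "unique_total": sum(by_kind.values()),
        "cds": by_kind.get("CDS", 0),
        "trna": by_kind.get("tRNA", 0),
        "rrna": by_kind.get("rRNA", 0),
        "duplicated_in_ir": sorted(dup),
        "single_intron": sorted(intron1),
        "two_intron": sorted(intron2),
    }
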