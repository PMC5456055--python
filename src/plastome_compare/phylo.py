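"""Distance phylogeny on the IR-stripped whole-genome concatenation.

The concatenated alignment (one IR copy removed) is summarised by the same
column statistics as the per-region divergence screen, plus parsimony-
informative sites.  Tree estimation is neighbor-joining on Jukes-Cantor
distances with pairwise gap deletion, and supports come from column-resampled
bootstrap replicates.  Exports cover Newick (supports as internal node
labels) and relaxed PHYLIP for external ML software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .divergence import RegionAlignment, divergence_stats


# ---------------------------------------------------------------------------
# summary statistics

@dataclass
class ConcatSummary:
    aligned_length: int
    variable_positions: int
    parsimony_informative: int
    substitutions: int
    indel_events: int
    indel_length: int
    percent_variability: float


def parsimony_informative_sites(rows: list[str]) -> int:
    """Columns with >= 2 base states each present in >= 2 taxa; gaps are
    ignored (not a fifth state)."""
    arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(len(rows), -1)
    count = 0
    counts = np.stack([(arr == ord(b)).sum(axis=0) for b in "ACGT"])
    count = int(((counts >= 2).sum(axis=0) >= 2).sum())
    return count


def alignment_summary(aln: RegionAlignment) -> ConcatSummary:
    if len(aln.rows) < 2:
        raise ValueError("summary needs >= 2 taxa")
    st = divergence_stats(aln)
    return ConcatSummary(
        aligned_length=st.aligned_length,
        variable_positions=st.variable_positions,
        parsimony_informative=parsimony_informative_sites(aln.rows),
        substitutions=st.substitutions,
        indel_events=st.indel_events,
        indel_length=st.indel_length,
        percent_variability=st.percent_variability,
    )


# ---------------------------------------------------------------------------
# distances

def jc69_from_p(p: float) -> float:
    if p >= 0.75:
        raise ValueError(f"p-distance {p} >= 0.75: JC69 undefined")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def jc69_distance(aln: RegionAlignment) -> np.ndarray:
    """Jukes-Cantor distance matrix with pairwise deletion of gap columns."""
    if len(aln.rows) < 2:
        raise ValueError("distances need >= 2 taxa")
    arr = np.frombuffer("".join(aln.rows).encode(), dtype=np.uint8).reshape(len(aln.rows), -1)
    gap = ord("-")
    n = len(aln.rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arr[i] != gap) & (arr[j] != gap)
            denom = int(ok.sum())
            if denom == 0:
                raise ValueError(f"no comparable columns for pair {aln.taxa[i]}, {aln.taxa[j]}")
            p = float((arr[i][ok] != arr[j][ok]).sum()) / denom
            try:
                d[i, j] = d[j, i] = jc69_from_p(p)
            except ValueError as exc:
                raise ValueError(f"pair ({aln.taxa[i]}, {aln.taxa[j]}): {exc}") from exc
    return d


# ---------------------------------------------------------------------------
# trees

@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out

    def newick(self, with_support: bool = True) -> str:
        return self._nwk(with_support) + ";"

    def _nwk(self, ws: bool) -> str:
        if not self.children:
            return self.name
        inner = ",".join(f"{c._nwk(ws)}:{bl:.6f}" for c, bl in self.children)
        label = ""
        if ws and self.support is not None:
            label = f"{self.support:g}"
        return f"({inner}){label}"


def bipartitions(root: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions (as the smaller/lexicographic side leaf set)
    of an unrooted tree rooted arbitrarily at ``root``."""
    all_leaves = frozenset(root.leaves())
    out: set[frozenset[str]] = set()

    def walk(node: TreeNode):
        if not node.children:
            return frozenset([node.name])
        below = frozenset()
        for c, _ in node.children:
            below = below | walk(c)
        if 1 < len(below) < len(all_leaves) - 1:
            other = all_leaves - below
            out.add(min(below, other, key=lambda s: (len(s), sorted(s))))
        return below

    walk(root)
    return out


def robinson_foulds(a: TreeNode, b: TreeNode) -> int:
    ba, bb = bipartitions(a), bipartitions(b)
    return len(ba ^ bb)


def neighbor_joining(dist: np.ndarray, labels: list[str]) -> TreeNode:
    """Standard neighbor-joining.  Negative branch lengths are clamped to 0
    with the deficit shifted to the sibling edge; ties in the Q criterion are
    broken by the lowest (i, j) index pair."""
    d = np.asarray(dist, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor-joining needs >= 3 taxa")
    if len(labels) != n:
        raise ValueError("labels/matrix size mismatch")
    nodes: dict[int, TreeNode] = {i: TreeNode(name=labels[i]) for i in range(n)}
    D = {(i, j): d[i, j] for i in range(n) for j in range(n) if i != j}
    active = list(range(n))
    nxt = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[(i, k)] for k in active if k != i) for i in active}
        best, best_pair = None, None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[(i, j)] - r[i] - r[j]
                if best is None or q < best - 1e-12:
                    best, best_pair = q, (i, j)
        i, j = best_pair
        li = 0.5 * D[(i, j)] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[(i, j)] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        nodes[nxt] = new
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (D[(i, k)] + D[(j, k)] - D[(i, j)])
            D[(nxt, k)] = D[(k, nxt)] = max(dk, 0.0)
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    i, j, k = active
    li = 0.5 * (D[(i, j)] + D[(i, k)] - D[(j, k)])
    lj = 0.5 * (D[(i, j)] + D[(j, k)] - D[(i, k)])
    lk = 0.5 * (D[(i, k)] + D[(j, k)] - D[(i, j)])
    root = TreeNode(children=[(nodes[i], max(li, 0.0)),
                              (nodes[j], max(lj, 0.0)),
                              (nodes[k], max(lk, 0.0))])
    return root


def nj_tree(aln: RegionAlignment) -> TreeNode:
    return neighbor_joining(jc69_distance(aln), list(aln.taxa))


def bootstrap(aln: RegionAlignment, n_reps: int, seed: int) -> TreeNode:
    """NJ tree from the full alignment with bootstrap supports (%) on internal
    edges, from ``n_reps`` column-resampled replicates under a fixed seed.
    Replicates whose distances saturate (p >= 3/4 for some pair) yield no
    tree; supports are percentages of the completed replicates."""
    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    main = nj_tree(aln)
    main_bips = bipartitions(main)
    counts = {bp: 0 for bp in main_bips}
    rng = np.random.default_rng(seed)
    arr = np.frombuffer("".join(aln.rows).encode(), dtype=np.uint8).reshape(len(aln.rows), -1)
    L = arr.shape[1]
    completed = 0
    for _ in range(n_reps):
        idx = rng.integers(0, L, L)
        rep_rows = ["".join(map(chr, arr[i, idx])) for i in range(arr.shape[0])]
        rep = RegionAlignment(name=aln.name, taxa=aln.taxa, rows=rep_rows)
        try:
            rep_bips = bipartitions(nj_tree(rep))
        except ValueError:  # saturated replicate pair yields no tree
            continue
        completed += 1
        for bp in main_bips:
            if bp in rep_bips:
                counts[bp] += 1
    if completed == 0:
        raise ValueError("all bootstrap replicates were saturated")

    def annotate(node: TreeNode, seen: frozenset | None = None):
        for c, _ in node.children:
            if c.children:
                below = frozenset(c.leaves())
                other = frozenset(main.leaves()) - below
                key = min(below, other, key=lambda s: (len(s), sorted(s)))
                if key in counts:
                    c.support = round(100.0 * counts[key] / completed, 1)
            annotate(c)

    annotate(main)
    return main


# ---------------------------------------------------------------------------
# export

def write_phylip(aln: RegionAlignment, path) -> None:
    """Relaxed PHYLIP (name, two spaces, full row)."""
    with open(path, "w") as fh:
        fh.write(f" {len(aln.rows)} {aln.aligned_length}\n")
        for name, row in zip(aln.taxa, aln.rows):
            fh.write(f"{name.replace(' ', '_')}  {row}\n")
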