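"""Distances, neighbor-joining trees and sequence-logo profiles.

Consumes pre-computed multiple alignments (alignment construction is
out of scope; a basic Needleman-Wunsch pairwise aligner is included as
plumbing only, not as a substitute for a proper MSA tool).  Provides
p-distances with pairwise gap deletion, a deterministic neighbor-
joining implementation with Newick output, and per-column residue
frequency / information-content matrices of the kind rendered as
sequence logos.

Neighbor joining here is the standard Q-criterion agglomeration
(Saitou-Nei with the Studier-Keppler update).  Ties in Q are broken by
the lexicographically smallest label pair, so the topology is
reproducible across runs; negative branch lengths are clamped to zero
and logged.  On additive matrices NJ is consistent: the output tree's
leaf-to-leaf path lengths reproduce the input distances exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

logger = logging.getLogger(__name__)

STD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"


@dataclass(frozen=True)
class Alignment:
    """A gapped multiple alignment: equal-length rows keyed by id."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows are not equal length: {sorted(lengths)}")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distances with zero diagonal.

    p-distances after pairwise gap deletion need not satisfy the
    triangle inequality; no such guarantee is made or checked.
    """

    labels: tuple[str, ...]
    d: np.ndarray = field(compare=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
            raise ValueError("matrix must be symmetric, nonnegative, zero-diagonal")
        object.__setattr__(self, "d", d)


def p_distance(
    alignment: Alignment, gap_mode: str = "pairwise", correction: str = "none"
) -> DistanceMatrix:
    """Pairwise mismatch fraction over comparable (non-gap) sites.

    ``gap_mode='pairwise'`` (default) drops, per pair, every column
    where either row has a gap; ``'complete'`` drops columns with a gap
    in any row before comparing.  ``correction='poisson'`` applies
    d = -ln(1 - p).  A pair with zero comparable sites is an error.
    """
    rows = alignment.rows
    if gap_mode == "complete":
        keep = [j for j in range(alignment.n_cols) if all(r[j] != GAP for r in rows)]
        rows = tuple("".join(r[j] for j in keep) for r in rows)
    elif gap_mode != "pairwise":
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sites = mism = 0
            for a, b in zip(rows[i], rows[j]):
                if a == GAP or b == GAP:
                    continue
                sites += 1
                mism += a != b
            if sites == 0:
                raise ValueError(
                    f"no comparable sites between {alignment.ids[i]!r} and {alignment.ids[j]!r}"
                )
            p = mism / sites
            if correction == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"Poisson correction undefined at p=1 for pair "
                        f"({alignment.ids[i]!r}, {alignment.ids[j]!r})"
                    )
                p = -math.log(1.0 - p)
            elif correction != "none":
                raise ValueError(f"unknown correction {correction!r}")
            d[i, j] = d[j, i] = p
    return DistanceMatrix(alignment.ids, d)


# ---------------------------------------------------------------------------
# neighbor joining


def _clamp(x: float) -> float:
    if x < 0:
        logger.info("negative branch length %.6g clamped to 0", x)
        return 0.0
    return x


def neighbor_joining(matrix: DistanceMatrix) -> TreeNode:
    """Build an unrooted NJ tree (stored with a trifurcating root).

    Deterministic: among joins with equal Q the lexicographically
    smallest (label, label) pair wins.  For n=2 the result is a single
    edge split into two half-lengths d/2.
    """
    labels = list(matrix.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: dict[str, TreeNode] = {lab: TreeNode(name=lab) for lab in labels}
    if n == 2:
        d = matrix.d[0, 1]
        root = TreeNode()
        for lab in labels:
            nodes[lab].length = _clamp(d / 2)
            root.append(nodes[lab])
        return root

    # active distance map keyed by node name (internal nodes get fresh names)
    dist: dict[frozenset[str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((labels[i], labels[j]))] = matrix.d[i, j]
    active = sorted(labels)
    # sort key: leaf names directly; internal nodes by creation index tag
    next_internal = 0

    def d_of(a: str, b: str) -> float:
        return dist[frozenset((a, b))]

    while len(active) > 3:
        m = len(active)
        r = {a: sum(d_of(a, b) for b in active if b != a) for a in active}
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = active[i], active[j]
                q = (m - 2) * d_of(a, b) - r[a] - r[b]
                pair = tuple(sorted((a, b)))
                if best is None or q < best[0] - 1e-12 or (abs(q - best[0]) <= 1e-12 and pair < best[1]):
                    best = (q, pair)
        a, b = best[1]
        dab = d_of(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        new_name = f"\x00internal{next_internal}"
        next_internal += 1
        parent = TreeNode()
        nodes[a].length = _clamp(la)
        nodes[b].length = _clamp(lb)
        parent.append(nodes[a])
        parent.append(nodes[b])
        nodes[new_name] = parent
        for c in active:
            if c in (a, b):
                continue
            dist[frozenset((new_name, c))] = 0.5 * (d_of(a, c) + d_of(b, c) - dab)
        active = sorted(x for x in active if x not in (a, b)) + [new_name]
        active.sort()

    # final trifurcation
    a, b, c = active
    la = 0.5 * (d_of(a, b) + d_of(a, c) - d_of(b, c))
    lb = 0.5 * (d_of(a, b) + d_of(b, c) - d_of(a, c))
    lc = 0.5 * (d_of(a, c) + d_of(b, c) - d_of(a, b))
    root = TreeNode()
    for name, length in ((a, la), (b, lb), (c, lc)):
        nodes[name].length = _clamp(length)
        root.append(nodes[name])
    for node in root.traverse():
        if node.name and node.name.startswith("\x00internal"):
            node.name = None
    return root


def _needs_quoting(label: str) -> bool:
    return any(ch in label for ch in " \t()[]:;,'")


def _newick_label(label: str) -> str:
    if _needs_quoting(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: TreeNode) -> str:
    """Serialise a tree to Newick with branch lengths to 6 decimals.

    Labels containing Newick metacharacters or spaces are quoted.
    Re-parsing the string yields an isomorphic tree.
    """

    def render(node: TreeNode) -> str:
        if node.is_tip():
            s = _newick_label(node.name or "")
        else:
            s = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.name:
                s += _newick_label(node.name)
        if node.length is not None:
            s += f":{node.length:.6f}"
        return s

    return render(tree) + ";"


def tree_distances(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (for consistency checks)."""
    tips = sorted(tree.tips(), key=lambda t: t.name)
    labels = tuple(t.name for t in tips)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tips[i].distance(tips[j])
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# pairwise global alignment (plumbing only)


def needleman_wunsch(
    a: str, b: str, match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0
) -> tuple[str, str, float]:
    """Basic global alignment with linear gap penalties.

    Convenience plumbing for aligning an unaligned pair; not a
    replacement for a proper multiple-alignment tool.
    """
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = gap * np.arange(n + 1)
    score[0, :] = gap * np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            score[i, j] = max(diag, score[i - 1, j] + gap, score[i, j - 1] + gap)
    ra, rb = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + (
            match if a[i - 1] == b[j - 1] else mismatch
        ):
            ra.append(a[i - 1]); rb.append(b[j - 1]); i -= 1; j -= 1
        elif i > 0 and score[i, j] == score[i - 1, j] + gap:
            ra.append(a[i - 1]); rb.append(GAP); i -= 1
        else:
            ra.append(GAP); rb.append(b[j - 1]); j -= 1
    return "".join(reversed(ra)), "".join(reversed(rb)), float(score[n, m])


# ---------------------------------------------------------------------------
# sequence-logo profile


def profile_matrix(
    alignment: Alignment, small_sample_correction: bool = False
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Per-column residue frequencies and information content.

    Returns ``(freqs, info, all_gap_columns)`` where ``freqs`` is
    (n_cols, 20) with gaps excluded from the denominator, and
    ``info[j] = log2(20) - H_j`` in bits (the stack height of a
    sequence logo).  All-gap columns get NaN frequencies and are listed
    in ``all_gap_columns`` (0-based).  The optional small-sample
    correction subtracts the Miller-Madow bias term (19 / (2 ln2 N)).
    """
    idx = {res: k for k, res in enumerate(STD_RESIDUES)}
    n_cols = alignment.n_cols
    freqs = np.full((n_cols, 20), np.nan)
    info = np.full(n_cols, np.nan)
    all_gap: list[int] = []
    for j in range(n_cols):
        counts = np.zeros(20)
        for row in alignment.rows:
            res = row[j]
            if res == GAP:
                continue
            if res not in idx:
                raise ValueError(f"unknown residue {res!r} in column {j + 1}")
            counts[idx[res]] += 1
        total = counts.sum()
        if total == 0:
            all_gap.append(j)
            continue
        p = counts / total
        nz = p[p > 0]
        h = -np.sum(nz * np.log2(nz))
        r = math.log2(20) - h
        if small_sample_correction:
            r -= 19.0 / (2.0 * math.log(2) * total)
        freqs[j] = p
        info[j] = max(r, 0.0)
    return freqs, info, all_gap
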