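"""Tree reconstruction: internal distance-based path (Jukes-Cantor +
neighbor-joining + column bootstrap) and an adapter for an external
maximum-likelihood tool.

The ML stage itself is delegated: the internal NJ path exists so the full
pipeline is testable offline, and the external adapter shells out to a
RAxML-compatible binary when one is available.
"""

from __future__ import annotations

import math
import os
import shutil
import subprocess
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np

from .compare import split_set
from .datamodel import Alignment, leaf_labels, read_tree, write_alignment, write_tree
from .errors import CapabilityError, PhylograftError, ToolError

JC_MAX_DISTANCE = 5.0


@dataclass
class TreeBuildConfig:
    backend: str = "internal_nj"  # or "external_ml"
    bootstrap_replicates: int = 100
    starting_tree: dendropy.Tree | None = None
    rng_seed: int = 0
    binary: str = "raxmlHPC"

    def __post_init__(self):
        if self.bootstrap_replicates < 0:
            raise PhylograftError("bootstrap_replicates must be >= 0")
        if self.backend not in ("internal_nj", "external_ml"):
            raise PhylograftError(f"unknown backend {self.backend!r}")


def jc_distance_matrix(
    alignment: Alignment, max_distance: float = JC_MAX_DISTANCE
) -> tuple[np.ndarray, list[str]]:
    """Pairwise Jukes-Cantor distances d = -(3/4) ln(1 - (4/3) p) over columns
    where both rows carry an unambiguous non-gap base. Saturated pairs
    (p >= 3/4) get ``max_distance``."""
    labels = alignment.labels
    if len(labels) < 3:
        raise PhylograftError("need at least 3 rows for a distance matrix")
    # encode: 0..3 = ACGT, -1 = anything else (gap, missing, ambiguity)
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    mat = np.stack([
        lut[np.frombuffer(alignment[l].encode(), dtype=np.uint8)] for l in labels
    ])
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (mat[i] >= 0) & (mat[j] >= 0)
            total = int(ok.sum())
            if total == 0:
                raise PhylograftError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                )
            p = float((mat[i][ok] != mat[j][ok]).sum()) / total
            if p >= 0.75:
                d = max_distance
            else:
                d = -0.75 * math.log(1.0 - (4.0 / 3.0) * p)
            D[i, j] = D[j, i] = d
    return D, labels


def nj_tree(distances: np.ndarray, labels: Sequence[str]) -> dendropy.Tree:
    """Neighbor-joining. On additive matrices the generating topology is
    recovered exactly. Ties in the Q criterion break on the lexicographically
    smallest (min-label, min-label) pair; negative branch lengths are clamped
    to zero. The result is unrooted (trifurcating root node)."""
    D = np.asarray(distances, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise PhylograftError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T, atol=1e-9):
        raise PhylograftError("distance matrix is not symmetric")
    if n < 3:
        raise PhylograftError("need at least 3 labels")

    nodes = [f"{l}" for l in labels]  # newick fragments
    minlab = list(labels)
    active = list(range(n))
    D = D.copy()

    def fmt(x: float) -> str:
        return f"{max(x, 0.0):.10g}"

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                key = (q, tuple(sorted((minlab[i], minlab[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        new_idx = len(nodes)
        nodes.append(f"({nodes[i]}:{fmt(li)},{nodes[j]}:{fmt(lj)})")
        minlab.append(min(minlab[i], minlab[j]))
        newD = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            newD[new_idx, k] = newD[k, new_idx] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        D = newD
        active = [k for k in active if k not in (i, j)] + [new_idx]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    newick = (
        f"({nodes[a]}:{fmt(la)},{nodes[b]}:{fmt(lb)},{nodes[c]}:{fmt(lc)});"
    )
    return read_tree(newick, from_string=True)


def bootstrap_trees(alignment: Alignment, config: TreeBuildConfig) -> list[dendropy.Tree]:
    """Column bootstrap: resample columns with replacement (same width), then
    JC distances + NJ, once per replicate. Deterministic under the seed."""
    rng = np.random.default_rng(config.rng_seed)
    W = alignment.width
    labels = alignment.labels
    cols = np.stack([
        np.frombuffer(alignment[l].encode(), dtype=np.uint8) for l in labels
    ])
    trees = []
    for _ in range(config.bootstrap_replicates):
        idx = rng.integers(0, W, size=W)
        rows = {
            l: cols[i, idx].tobytes().decode() for i, l in enumerate(labels)
        }
        D, labs = jc_distance_matrix(Alignment(rows, alignment.locus_name))
        trees.append(nj_tree(D, labs))
    return trees


def summarize_support(
    best: dendropy.Tree, replicates: list[dendropy.Tree]
) -> dendropy.Tree:
    """Annotate each internal edge of ``best`` with 100 x the fraction of
    replicates containing the same bipartition, rounded to one decimal, as the
    internal node's label."""
    leaves = leaf_labels(best)
    for t in replicates:
        other = leaf_labels(t)
        if other != leaves:
            diff = sorted(leaves ^ other)
            raise PhylograftError(f"replicate leaf set differs: {diff}")
    rep_splits = [split_set(t, leaves) for t in replicates]
    out = best.clone(depth=1)
    for node in out.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        split = frozenset({below, frozenset(leaves - below)})
        if len(below) < 2 or len(leaves - below) < 2:
            continue
        frac = sum(1 for s in rep_splits if split in s) / max(len(replicates), 1)
        node.label = f"{round(100.0 * frac, 1):g}"
    return out


def internal_pipeline(
    alignment: Alignment, config: TreeBuildConfig
) -> tuple[dendropy.Tree, list[dendropy.Tree]]:
    """JC + NJ best tree with bootstrap support summarized onto it."""
    D, labels = jc_distance_matrix(alignment)
    best = nj_tree(D, labels)
    reps = bootstrap_trees(alignment, config)
    if reps:
        best = summarize_support(best, reps)
    return best, reps


def write_relaxed_phylip(alignment: Alignment, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(alignment)} {alignment.width}\n")
        for label, seq in alignment.rows.items():
            safe = label.replace(" ", "_").replace(":", "_")
            fh.write(f"{safe}  {seq}\n")


def external_ml_adapter(
    alignment: Alignment, config: TreeBuildConfig, workdir="."
) -> tuple[dendropy.Tree, list[dendropy.Tree]]:
    """Shell out to a RAxML-compatible binary (GTRCAT, optional starting
    tree, rapid bootstrap) and parse the resulting newicks."""
    binary = shutil.which(config.binary)
    if binary is None:
        raise CapabilityError(
            f"external ML binary {config.binary!r} not found; use the internal_nj backend"
        )
    os.makedirs(workdir, exist_ok=True)
    phy = os.path.join(workdir, "input.phy")
    write_relaxed_phylip(alignment, phy)
    name = "phylograft"
    cmd = [binary, "-s", phy, "-n", name, "-m", "GTRCAT",
           "-p", str(config.rng_seed), "-w", os.path.abspath(workdir)]
    if config.starting_tree is not None:
        start = os.path.join(workdir, "start.nwk")
        write_tree(config.starting_tree, start)
        cmd += ["-t", start]
    if config.bootstrap_replicates > 0:
        cmd += ["-f", "a", "-x", str(config.rng_seed),
                "-N", str(config.bootstrap_replicates)]
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise ToolError(
            f"{config.binary} exited {proc.returncode}", proc.stdout + proc.stderr
        )
    best_path = os.path.join(workdir, f"RAxML_bestTree.{name}")
    boot_path = os.path.join(workdir, f"RAxML_bootstrap.{name}")
    best = read_tree(best_path)
    reps = []
    if os.path.exists(boot_path):
        with open(boot_path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    reps.append(read_tree(line, from_string=True))
    return best, reps
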