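"""Synthetic aligned families evolved along simulated trees.

These generators stand in for a curated Pfam family plus externally
computed tree/ancestor files: sequences evolve along a pure-birth (Yule)
tree under a Jukes-Cantor model over the 20 amino-acid states, so patristic
distances, true ancestral sequences, and subclass structure are all known
exactly.  Gaps are only introduced deliberately (two-subclass generator) so
that query-centric column removal has a controlled, known effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from famgeo.alphabet import Alphabet, PROTEIN
from famgeo.families import AlignedFamily, write_alignment


@dataclass
class SimulatedFamily:
    """Leaves, true ancestors, and the generating tree of a simulation."""

    family: AlignedFamily
    ancestors: AlignedFamily
    tree: str  # Newick with branch lengths and internal-node labels
    params: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_alignment(self.family, outdir / "leaves.fasta")
        write_alignment(self.ancestors, outdir / "ancestors.fasta")
        (outdir / "tree.nwk").write_text(self.tree + "\n")
        (outdir / "manifest.json").write_text(json.dumps(self.params, indent=2) + "\n")


class _Node:
    __slots__ = ("name", "length", "children")

    def __init__(self, name=None, length=None):
        self.name = name
        self.length = length
        self.children = []

    def newick(self) -> str:
        if self.children:
            inner = ",".join(c.newick() for c in self.children)
            s = f"({inner}){self.name or ''}"
        else:
            s = self.name
        if self.length is not None:
            s += f":{self.length:.6f}"
        return s


def _yule_topology(n_leaves: int, rng: np.random.Generator) -> _Node:
    root = _Node()
    leaves = [_Node(), _Node()]
    root.children = list(leaves)
    while len(leaves) < n_leaves:
        k = int(rng.integers(len(leaves)))
        parent = leaves.pop(k)
        kids = [_Node(), _Node()]
        parent.children = kids
        leaves.extend(kids)
    return root


def _label_and_lengths(root: _Node, rng, branch_mean, leaf_prefix="T", int_prefix="A"):
    li = ii = 0
    stack = [root]
    order = []
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(reversed(node.children))
    for node in order:
        if node.children:
            node.name = f"{int_prefix}{ii}"
            ii += 1
        else:
            node.name = f"{leaf_prefix}{li}"
            li += 1
        if node is not root:
            node.length = float(rng.exponential(branch_mean))
    return root


def simulate_tree(n_leaves: int, seed: int = 0, branch_mean: float = 0.1) -> str:
    """Yule-topology Newick tree with exponential branch lengths.

    Leaves are labeled T0..T{n-1}, internal nodes A0.. (root A0); every
    non-root edge gets an Exp(mean=`branch_mean`) length.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    root = _yule_topology(n_leaves, rng)
    _label_and_lengths(root, rng, branch_mean)
    return root.newick() + ";"


def _jc_evolve(parent: np.ndarray, blen: float, rate: float, n_states: int, rng):
    """Jukes-Cantor transition along one branch: with probability
    1 - exp(-S/(S-1)*rate*b) a site is redrawn uniformly over all S states,
    which reproduces the JC closed form for the substitution probability."""
    event_p = 1.0 - np.exp(-n_states / (n_states - 1.0) * rate * blen)
    child = parent.copy()
    hit = rng.random(parent.shape[0]) < event_p
    child[hit] = rng.integers(n_states, size=int(hit.sum()))
    return child


def jc_expected_difference(blen: float, rate: float, n_states: int = 20) -> float:
    """Closed-form per-site probability that child differs from parent."""
    S = n_states
    return (S - 1.0) / S * (1.0 - np.exp(-S / (S - 1.0) * rate * blen))


def evolve_family(
    tree: str,
    L: int,
    rate: float = 1.0,
    alphabet: Alphabet = PROTEIN,
    seed: int = 0,
) -> SimulatedFamily:
    """Evolve an aligned family of length L along a Newick tree.

    The root sequence is uniform over the non-gap states; each branch applies
    an independent Jukes-Cantor substitution process at the given rate.
    Internal-node states are retained as the true ancestors.
    """
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    dtree = dendropy.Tree.get(data=tree, schema="newick")
    rng = np.random.default_rng(seed)
    n_states = alphabet.C - 1  # evolve over amino acids only; gaps are deliberate
    seqs: dict = {}
    root = dtree.seed_node
    root_seq = rng.integers(n_states, size=L)
    seqs[id(root)] = root_seq
    for node in dtree.preorder_node_iter():
        if node is root:
            continue
        if node.edge.length is None:
            raise ValueError("tree has a branch without a length")
        seqs[id(node)] = _jc_evolve(
            seqs[id(node.parent_node)], float(node.edge.length), rate, n_states, rng
        )

    def _name(node):
        if node.taxon is not None:
            return node.taxon.label.replace(" ", "-")
        return node.label

    leaf_ids, leaf_rows, anc_ids, anc_rows = [], [], [], []
    for node in dtree.preorder_node_iter():
        if node.is_leaf():
            leaf_ids.append(_name(node))
            leaf_rows.append(seqs[id(node)])
        else:
            anc_ids.append(_name(node) or f"A{len(anc_ids)}")
            anc_rows.append(seqs[id(node)])
    family = AlignedFamily(leaf_ids, np.stack(leaf_rows), alphabet)
    ancestors = AlignedFamily(anc_ids, np.stack(anc_rows), alphabet)
    params = {"L": L, "rate": rate, "seed": seed, "n_leaves": len(leaf_ids)}
    return SimulatedFamily(family, ancestors, tree, params)


def two_subclass_family(
    n_per_class,
    L: int,
    n_diff_regions: int = 3,
    gap_block_in_query: tuple | None = None,
    seed: int = 0,
    rate: float = 1.0,
    branch_mean: float = 0.1,
    class_divergence: float = 1.0,
    region_len: int = 5,
) -> SimulatedFamily:
    """Family with two clades showing consistent region differences and a
    designated query whose gap block triggers query-centric column removal.

    `n_per_class` is an int (equal classes) or a (n_class1, n_class2) pair;
    an underrepresented second class emulates a query-centric alignment of a
    family whose distant subclass is a minority.
    Leaves are c1-* (query's subclass) and c2-*; the query is c1-0.  Columns
    in `gap_block_in_query` = (start, length) are gaps in every class-1
    sequence and carry a conserved class-2 motif, so query-centric reduction
    deletes exactly that block.  `n_diff_regions` further blocks get
    class-specific consensus letters.  `class_divergence` scales class-2
    branch lengths (a more diverse, harder-to-reconstruct subclass).
    With zero regions, no gap block and unit divergence the two classes are
    statistically exchangeable.
    """
    n1, n2 = (n_per_class, n_per_class) if np.isscalar(n_per_class) else tuple(n_per_class)
    if n1 < 2 or n2 < 2 or L < 1:
        raise ValueError("parameters must be positive (class sizes >= 2)")
    rng = np.random.default_rng(seed)
    block = tuple(gap_block_in_query) if gap_block_in_query is not None else None
    if block is not None and (block[0] < 0 or block[0] + block[1] > L):
        raise ValueError("gap block exceeds alignment length")

    root = _Node()
    stems = []
    for prefix, n_class in (("c1", n1), ("c2", n2)):
        sub = _yule_topology(n_class, rng)
        _label_and_lengths(sub, rng, branch_mean, leaf_prefix=f"{prefix}-", int_prefix=f"{prefix}anc-")
        sub.length = 0.5  # stem separating the two classes
        stems.append(sub)
        root.children.append(sub)
    root.name = "root"
    if class_divergence != 1.0:
        stack = [stems[1]]
        while stack:
            node = stack.pop()
            if node.length is not None and node is not stems[1]:
                node.length *= class_divergence
            stack.extend(node.children)
    newick = root.newick() + ";"

    sim = evolve_family(newick, L, rate, PROTEIN, seed=int(rng.integers(2**31)))
    fam = sim.family
    class1 = np.array([i.startswith("c1-") for i in fam.ids])
    n_states = fam.alphabet.C - 1
    gap = fam.alphabet.gap_index

    # choose non-overlapping difference regions avoiding the gap block
    forbidden = set(range(block[0], block[0] + block[1])) if block else set()
    regions = []
    attempts = 0
    while len(regions) < n_diff_regions:
        attempts += 1
        if attempts > 10000:
            raise ValueError("difference regions exceed alignment length")
        start = int(rng.integers(0, L - region_len + 1))
        cols = set(range(start, start + region_len))
        if cols & forbidden:
            continue
        regions.append(start)
        forbidden |= cols
    for start in regions:
        for col in range(start, start + region_len):
            a = int(rng.integers(n_states))
            b = (a + 1 + int(rng.integers(n_states - 1))) % n_states
            fam.rows[class1, col] = a
            fam.rows[~class1, col] = b

    if block is not None:
        for col in range(block[0], block[0] + block[1]):
            fam.rows[class1, col] = gap
            fam.rows[~class1, col] = int(rng.integers(n_states))

    fam.query_id = "c1-0"
    params = {
        "n_per_class": [n1, n2],
        "L": L,
        "n_diff_regions": n_diff_regions,
        "gap_block": block,
        "rate": rate,
        "branch_mean": branch_mean,
        "class_divergence": class_divergence,
        "region_len": region_len,
        "regions": [int(r) for r in regions],
        "seed": seed,
    }
    return SimulatedFamily(fam, sim.ancestors, newick, params)
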