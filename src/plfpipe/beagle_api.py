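"""Instance-based likelihood API over the per-site kernel.

Mirrors the shape of the BEAGLE library's C API: create an instance
sized for a tree and a set of site patterns, load tip states, base
frequencies and pattern weights, derive per-edge transition matrices
from a 4x4 eigen-system (``P(t) = E diag(e^{lambda t}) E^{-1}``), drive
the kernel over a postorder traversal, and ask for the root
log-likelihood.  Trees are strictly rooted and binary with mandatory
branch lengths; rescaling runs at every internal node and the cumulative
scale buffer is reset at the start of each full traversal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import AlignIO, SeqIO

from . import plf_kernel as kernel
from .log_approx import LogApproxTable
from .plf_kernel import (DegenerateSiteError, NumericMode, PartialsTable,
                         PatternWeights, ScaleBuffers, StateFrequencies,
                         TransitionMatrix, ValidationError)

__all__ = [
    "EigenSystem",
    "Instance",
    "Tree",
    "TreeParseError",
    "create_instance",
    "set_instance_data",
    "transition_probability",
    "update_transition_matrix",
    "update_all_transition_matrices",
    "update_partials",
    "calculate_root_log_likelihood",
    "compress_patterns",
    "parse_newick",
    "write_newick",
    "read_alignment",
    "jc69_eigen_system",
    "reversible_eigen_system",
    "jc69_rate_matrix",
]

STATES = "ACGT"
#: IUPAC-ish tip codes the kernel accepts: the four bases one-hot, and N
#: or a gap as full ambiguity.
_CODE_PARTIALS = {
    "A": (1.0, 0.0, 0.0, 0.0),
    "C": (0.0, 1.0, 0.0, 0.0),
    "G": (0.0, 0.0, 1.0, 0.0),
    "T": (0.0, 0.0, 0.0, 1.0),
    "N": (1.0, 1.0, 1.0, 1.0),
    "-": (1.0, 1.0, 1.0, 1.0),
}


class TreeParseError(ValueError):
    """Malformed newick, polytomy, or missing branch length."""


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    id: int
    name: str = ""
    length: float | None = None  # branch length to the parent
    children: tuple[int, ...] = ()


@dataclass
class Tree:
    """Rooted binary tree with buffer-index node ids.

    Tips occupy ids ``0 .. n_tips-1`` (in newick order), internal nodes
    ``n_tips .. 2 n_tips - 2`` in postorder; the root is the last id.
    ``postorder_ops`` lists one ``(parent, left, right)`` triple per
    internal node, children strictly before parents.
    """

    nodes: dict[int, TreeNode]
    tip_ids: list[int]
    root_id: int
    postorder_ops: list[tuple[int, int, int]]

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    def tip_names(self) -> list[str]:
        return [self.nodes[i].name for i in self.tip_ids]


def parse_newick(text: str) -> Tree:
    """Strict parser front-end: rooted, binary, branch lengths mandatory
    on every non-root edge."""
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True)
    except Exception as exc:
        raise TreeParseError(f"newick parse failed: {exc}") from exc
    leaves = [lf for lf in dtree.leaf_node_iter()]
    n_tips = len(leaves)
    if n_tips < 2:
        raise TreeParseError("tree must have at least two tips")

    nodes: dict[int, TreeNode] = {}
    tip_ids: list[int] = []
    ops: list[tuple[int, int, int]] = []
    next_tip = 0
    next_internal = n_tips

    def build(dnode) -> int:
        nonlocal next_tip, next_internal
        ch = dnode.child_nodes()
        if not ch:
            nid = next_tip
            next_tip += 1
            name = dnode.taxon.label if dnode.taxon else ""
            if dnode.edge.length is None:
                raise TreeParseError(f"tip {name!r} is missing a branch length")
            nodes[nid] = TreeNode(nid, name=name, length=float(dnode.edge.length))
            tip_ids.append(nid)
            return nid
        if len(ch) != 2:
            raise TreeParseError(
                f"non-binary node with {len(ch)} children (polytomies are rejected)")
        left = build(ch[0])
        right = build(ch[1])
        nid = next_internal
        next_internal += 1
        length = dnode.edge.length
        if length is None and dnode.parent_node is not None:
            raise TreeParseError("internal node is missing a branch length")
        nodes[nid] = TreeNode(nid, length=None if length is None else float(length),
                              children=(left, right))
        ops.append((nid, left, right))
        return nid

    root = build(dtree.seed_node)
    return Tree(nodes=nodes, tip_ids=tip_ids, root_id=root, postorder_ops=ops)


def write_newick(tree: Tree) -> str:
    def render(nid: int) -> str:
        n = tree.nodes[nid]
        if not n.children:
            body = n.name
        else:
            body = "(" + ",".join(render(c) for c in n.children) + ")"
        if n.length is not None:
            body += f":{n.length:.10g}"
        return body

    return render(tree.root_id) + ";"


# ---------------------------------------------------------------------------
# eigen-systems
# ---------------------------------------------------------------------------

@dataclass
class EigenSystem:
    """Eigendecomposition of a substitution rate matrix Q = E L E^-1."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    inverse_eigenvectors: np.ndarray

    def __post_init__(self):
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=np.float64)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=np.float64)
        self.inverse_eigenvectors = np.asarray(self.inverse_eigenvectors, dtype=np.float64)
        if np.max(np.abs(self.eigenvectors @ self.inverse_eigenvectors - np.eye(4))) > 1e-8:
            raise ValidationError("eigenvectors and inverse are not mutually inverse")


def jc69_rate_matrix() -> np.ndarray:
    """JC69 rate matrix normalised to one expected substitution per unit
    branch length: off-diagonals 1/3, diagonal -1."""
    q = np.full((4, 4), 1.0 / 3.0)
    np.fill_diagonal(q, -1.0)
    return q


def reversible_eigen_system(q: np.ndarray, pi: np.ndarray) -> EigenSystem:
    """Real eigen-system of a reversible rate matrix via the symmetric
    similarity transform B = D^{1/2} Q D^{-1/2}, D = diag(pi)."""
    d = np.sqrt(np.asarray(pi, dtype=np.float64))
    b = (q * d[:, None]) / d[None, :]
    lam, u = np.linalg.eigh(0.5 * (b + b.T))
    ev = u / d[:, None]
    inv = u.T * d[None, :]
    return EigenSystem(eigenvalues=lam, eigenvectors=ev, inverse_eigenvectors=inv)


def jc69_eigen_system() -> EigenSystem:
    return reversible_eigen_system(jc69_rate_matrix(), np.full(4, 0.25))


# ---------------------------------------------------------------------------
# instance lifecycle
# ---------------------------------------------------------------------------

@dataclass
class Instance:
    n_tips: int
    n_patterns: int
    mode: NumericMode
    partials: list[PartialsTable | None] = field(default_factory=list)
    matrices: dict[int, TransitionMatrix] = field(default_factory=dict)
    pi: StateFrequencies | None = None
    weights: PatternWeights | None = None
    scale: ScaleBuffers | None = None
    log_table: LogApproxTable | None = None

    @property
    def n_buffers(self) -> int:
        return 2 * self.n_tips - 1

    def reset_scale_factors(self):
        self.scale = ScaleBuffers.zeros(self.n_patterns, self.mode)

    def dump_text(self) -> str:
        lines = [f"# instance n_tips={self.n_tips} n_patterns={self.n_patterns} "
                 f"mode={self.mode.value}"]
        if self.pi is not None:
            lines.append("pi\t" + "\t".join(repr(float(v)) for v in self.pi.pi))
        if self.weights is not None:
            lines.append("weights\t" + "\t".join(str(int(v)) for v in self.weights.w))
        for i, tbl in enumerate(self.partials):
            if tbl is None:
                continue
            for k in range(tbl.n_sites):
                lines.append(f"partials\t{i}\t{k}\t" +
                             "\t".join(repr(float(v)) for v in tbl.values[k]))
        if self.scale is not None:
            for k in range(self.n_patterns):
                lines.append(f"scale\t{k}\t{self.scale.scP[k]!r}\t{self.scale.lnScaler[k]!r}")
        return "\n".join(lines) + "\n"


def create_instance(n_tips: int, n_patterns: int,
                    mode: NumericMode = NumericMode.EXACT) -> Instance:
    if n_tips < 2:
        raise ValidationError("an instance needs at least two tips")
    if n_patterns < 1:
        raise ValidationError("an instance needs at least one pattern")
    inst = Instance(n_tips=n_tips, n_patterns=n_patterns, mode=mode,
                    partials=[None] * (2 * n_tips - 1))
    inst.reset_scale_factors()
    return inst


def _tip_partials(entry, n_patterns: int) -> PartialsTable:
    if isinstance(entry, str):
        if len(entry) != n_patterns:
            raise ValidationError("tip sequence length does not match n_patterns")
        try:
            vals = np.array([_CODE_PARTIALS[c] for c in entry.upper()])
        except KeyError as exc:
            raise ValidationError(f"unknown state code {exc.args[0]!r}") from exc
    else:
        vals = np.asarray(entry, dtype=np.float64)
    return PartialsTable(values=vals, role="tip")


def set_instance_data(inst: Instance, tips, pi, w) -> Instance:
    """Load tip states/partials, base frequencies and pattern weights.

    ``tips`` is ordered by tip buffer id (= newick tip order): each entry
    is either a state-code string over {A, C, G, T, N, -} or an
    ``(n_patterns, 4)`` partials array.
    """
    if len(tips) != inst.n_tips:
        raise ValidationError(f"expected {inst.n_tips} tip entries, got {len(tips)}")
    for i, entry in enumerate(tips):
        inst.partials[i] = _tip_partials(entry, inst.n_patterns)
    inst.pi = pi if isinstance(pi, StateFrequencies) else StateFrequencies(np.asarray(pi))
    inst.weights = w if isinstance(w, PatternWeights) else PatternWeights(np.asarray(w))
    if len(inst.weights.w) != inst.n_patterns:
        raise ValidationError("pattern weight vector length does not match n_patterns")
    return inst


def transition_probability(eigen: EigenSystem, t: float) -> TransitionMatrix:
    """P(t) = E diag(e^{lambda t}) E^{-1}, cleaned of rounding noise.

    Entries in (-1e-12, 0) are clamped to 0 and entries in (1, 1+1e-12)
    to 1; anything further out is a genuine numerical failure.
    """
    if t < 0:
        raise ValidationError("branch length must be non-negative")
    p = (eigen.eigenvectors * np.exp(eigen.eigenvalues * t)) @ eigen.inverse_eigenvectors
    if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
        raise ValidationError(f"transition probabilities out of [0,1] beyond "
                              f"tolerance at t={t}")
    return TransitionMatrix(np.clip(p, 0.0, 1.0))


def update_transition_matrix(inst: Instance, eigen: EigenSystem, t: float,
                             node: int | None = None) -> TransitionMatrix:
    """Compute P(t) and, when a node id is given, store it on the
    instance as that node's (edge's) transition matrix."""
    m = transition_probability(eigen, t)
    if node is not None:
        inst.matrices[node] = m
    return m


def update_all_transition_matrices(inst: Instance, eigen: EigenSystem,
                                   tree: Tree) -> Instance:
    for nid, node in tree.nodes.items():
        if node.length is not None:
            update_transition_matrix(inst, eigen, node.length, node=nid)
    return inst


def update_partials(inst: Instance, tree: Tree) -> Instance:
    """Run the kernel over every postorder (parent, left, right) triple.

    The cumulative scale buffer is reset first, then accumulates the
    per-node log-scalers across all internal nodes of the traversal.
    """
    if tree.n_tips != inst.n_tips:
        raise ValidationError("tree and instance disagree on the number of tips")
    for i in range(inst.n_tips):
        if inst.partials[i] is None:
            raise ValidationError(f"tip buffer {i} has no partials")
    inst.reset_scale_factors()
    for parent, left, right in tree.postorder_ops:
        for child in (left, right):
            if child not in inst.matrices:
                raise ValidationError(f"no transition matrix set for node {child}")
        try:
            inst.partials[parent] = kernel.update_partials_node(
                inst.matrices[left], inst.matrices[right],
                inst.partials[left], inst.partials[right],
                inst.scale, inst.mode, inst.log_table)
        except DegenerateSiteError as exc:
            raise DegenerateSiteError(f"node {parent}: {exc}") from exc
    return inst


def calculate_root_log_likelihood(inst: Instance, tree: Tree) -> float:
    root = inst.partials[tree.root_id]
    if root is None:
        raise ValidationError("root partials not computed; run update_partials first")
    return kernel.root_log_likelihood(
        PartialsTable(root.values, role="root"), inst.pi, inst.scale,
        inst.weights, inst.mode, inst.log_table)


# ---------------------------------------------------------------------------
# alignments and site patterns
# ---------------------------------------------------------------------------

def read_alignment(path, fmt: str = "fasta") -> dict[str, str]:
    """FASTA or relaxed-PHYLIP alignment reader (taxon -> sequence)."""
    if fmt == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        out = {r.id: str(r.seq).upper() for r in records}
    elif fmt == "phylip":
        aln = AlignIO.read(str(path), "phylip-relaxed")
        out = {r.id: str(r.seq).upper() for r in aln}
    else:
        raise ValidationError(f"unknown alignment format {fmt!r}")
    if not out:
        raise ValidationError(f"no sequences found in {path}")
    lengths = {len(s) for s in out.values()}
    if len(lengths) != 1:
        raise ValidationError("alignment is ragged (unequal sequence lengths)")
    return out


def compress_patterns(alignment):
    """Collapse identical alignment columns into site patterns.

    ``alignment`` is a list of equal-length state-code strings (one per
    taxon, a fixed taxon order).  Returns ``(patterns, weights)`` where
    ``patterns`` is the list of per-taxon pattern strings and the weights
    are column multiplicities summing to the alignment length.
    """
    if not alignment:
        raise ValidationError("empty alignment")
    lengths = {len(row) for row in alignment}
    if len(lengths) != 1:
        raise ValidationError("alignment is ragged (unequal row lengths)")
    mat = np.array([list(row.upper()) for row in alignment])
    for c in np.unique(mat):
        if c not in _CODE_PARTIALS:
            raise ValidationError(f"unknown state code {c!r}")
    cols, counts = np.unique(mat.T, axis=0, return_counts=True)
    patterns = ["".join(cols[:, i]) for i in range(cols.shape[1])]
    return patterns, PatternWeights(counts)
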