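"""Typed data-flow-graph IR for the likelihood kernel's arithmetic.

A :class:`DataFlowGraph` is a flat list of typed nodes (input, const,
add, mul, div, cmp, select, output) with ordered operand references.  Two
canonical builders are provided: the single-column expression used to
introduce pipeline synthesis (8 inputs, 9 multiplications, 6 additions)
and the full per-site kernel (10 logical inputs, 6 outputs, and exactly
38 additions, 55 multiplications, 4 divisions and 11 comparisons under
the normative construction conventions):

* sums of four products are chained (3 additions, no add-to-zero);
* the max of four values is a chain of 3 compare/select pairs;
* each log block spends 4 comparisons on the unrolled segment search
  (thresholds and coefficients arrive through uncounted select networks),
  3 multiplications on the power chain x^2..x^4, 4 on the coefficient
  products (the constant term needs none) and 4 additions on the
  accumulation;
* the root dot product costs 4 multiplications and 3 additions, and the
  site tail costs 3 additions (cumulative scaler, site log-likelihood,
  the lnL feedback accumulator) and 1 multiplication (pattern weight).

Transition-matrix entries, base frequencies, search thresholds and
polynomial coefficients are graph constants.  The interpreter
:func:`evaluate_dfg` is the bit-level oracle for the pipeline simulator:
in device mode every arithmetic result is rounded to binary32.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .log_approx import LogApproxTable, N_COEFFS
from .plf_kernel import NumericMode, default_log_table

__all__ = [
    "DfgNode",
    "DataFlowGraph",
    "GraphBuilder",
    "build_column_dfg",
    "build_kernel_dfg",
    "count_ops",
    "evaluate_dfg",
    "dfg_to_text",
    "dfg_to_dot",
    "dfg_from_text",
]

ARITH_OPS = ("add", "mul", "div", "cmp")
_ARITY = {"add": 2, "mul": 2, "div": 2, "cmp": 2, "select": 3, "output": 1}


@dataclass
class DfgNode:
    id: int
    op: str  # input | const | add | mul | div | cmp | select | output
    operands: tuple[int, ...] = ()
    value: float | None = None  # const payload
    name: str = ""
    feedback: bool = False  # designated accumulator (self-referencing add)

    def __post_init__(self):
        if self.op in _ARITY and len(self.operands) != _ARITY[self.op]:
            raise ValueError(f"node {self.id}: op {self.op} wants "
                             f"{_ARITY[self.op]} operands, got {len(self.operands)}")
        if self.op in ("input", "const") and self.operands:
            raise ValueError(f"node {self.id}: {self.op} takes no operands")


@dataclass
class DataFlowGraph:
    nodes: dict[int, DfgNode] = field(default_factory=dict)
    inputs: list[int] = field(default_factory=list)   # ordered logical ports
    outputs: list[int] = field(default_factory=list)  # ordered output nodes

    @property
    def feedback_node(self) -> int | None:
        for n in self.nodes.values():
            if n.feedback:
                return n.id
        return None

    def topo_order(self) -> list[int]:
        """Topological order ignoring the feedback self-edge."""
        indeg = {i: 0 for i in self.nodes}
        succ: dict[int, list[int]] = {i: [] for i in self.nodes}
        for n in self.nodes.values():
            for o in n.operands:
                if n.feedback and o == n.id:
                    continue
                indeg[n.id] += 1
                succ[o].append(n.id)
        ready = deque(sorted(i for i, d in indeg.items() if d == 0))
        order = []
        while ready:
            i = ready.popleft()
            order.append(i)
            for j in succ[i]:
                indeg[j] -= 1
                if indeg[j] == 0:
                    ready.append(j)
        if len(order) != len(self.nodes):
            raise ValueError("data-flow graph contains a cycle beyond the "
                             "designated accumulator feedback")
        return order

    def validate(self):
        ids = set(self.nodes)
        for n in self.nodes.values():
            for o in n.operands:
                if o not in ids:
                    raise ValueError(f"node {n.id} references missing node {o}")
        self.topo_order()


class GraphBuilder:
    """Incremental construction with constant de-duplication."""

    def __init__(self):
        self.g = DataFlowGraph()
        self._next = 0
        self._const_pool: dict[float, int] = {}

    def _add(self, op, operands=(), value=None, name="", feedback=False) -> int:
        nid = self._next
        self._next += 1
        self.g.nodes[nid] = DfgNode(nid, op, tuple(operands), value, name, feedback)
        return nid

    def input(self, name: str) -> int:
        nid = self._add("input", name=name)
        self.g.inputs.append(nid)
        return nid

    def const(self, value: float, name: str = "") -> int:
        v = float(value)
        if v not in self._const_pool:
            self._const_pool[v] = self._add("const", value=v, name=name)
        return self._const_pool[v]

    def add(self, a, b):
        return self._add("add", (a, b))

    def mul(self, a, b):
        return self._add("mul", (a, b))

    def div(self, a, b):
        return self._add("div", (a, b))

    def cmp(self, a, b):
        """Boolean a >= b (the hardware comparator)."""
        return self._add("cmp", (a, b))

    def select(self, cond, a, b):
        """a if cond else b."""
        return self._add("select", (cond, a, b))

    def output(self, src, name=""):
        nid = self._add("output", (src,), name=name)
        self.g.outputs.append(nid)
        return nid

    def chain_sum(self, terms):
        acc = terms[0]
        for t in terms[1:]:
            acc = self.add(acc, t)
        return acc

    def select_tree(self, conds, leaves):
        """Binary select tree: conds[0] is the most significant bit; leaves
        are ordered by the induced index (leaves[0] = all-false path)."""
        if not conds:
            assert len(leaves) == 1
            return leaves[0]
        half = len(leaves) // 2
        lo = self.select_tree(conds[1:], leaves[:half])
        hi = self.select_tree(conds[1:], leaves[half:])
        return self.select(conds[0], hi, lo)


def _log_block(b: GraphBuilder, x: int, table: LogApproxTable, tag: str) -> int:
    """Unrolled segment search + power-chain polynomial for ln(x)."""
    # thresholds of the 4 search levels: level j compares x against
    # 10**(-16 +- 8 +- 4 ... ) as determined by the previous outcomes
    conds: list[int] = []
    for level in range(4):
        n_paths = 1 << level
        leaves = []
        for path in range(n_paths):  # path bits: earlier outcome = higher bit
            e = -16
            for j in range(level):
                bit = (path >> (level - 1 - j)) & 1
                e += (8 >> j) if bit else -(8 >> j)
            leaves.append(b.const(10.0 ** e, name=f"thr_1e{e}"))
        thr = b.select_tree(conds, leaves)
        conds.append(b.cmp(x, thr))
    # coefficient selection: segment index bits are the four outcomes
    coeff_sel = []
    for i in range(N_COEFFS):
        leaves = [b.const(float(table.coeffs[s, i]), name=f"c{s}_{i}")
                  for s in range(16)]
        coeff_sel.append(b.select_tree(conds, leaves))
    # power chain and accumulation
    x2 = b.mul(x, x)
    x3 = b.mul(x2, x)
    x4 = b.mul(x3, x)
    powers = [x, x2, x3, x4]
    acc = coeff_sel[0]
    for i in range(1, N_COEFFS):
        acc = b.add(acc, b.mul(coeff_sel[i], powers[i - 1]))
    return acc


def _sum_of_products(b: GraphBuilder, consts, inputs):
    return b.chain_sum([b.mul(c, v) for c, v in zip(consts, inputs)])


def build_column_dfg(tip_row_L=None, tip_row_R=None) -> DataFlowGraph:
    """The single-column expression: clP[0] = (tipL row . clL) * (tipR row
    . clR) with the eight tip entries as constants -> 8 inputs, 1 output,
    9 multiplications, 6 additions."""
    if tip_row_L is None:
        tip_row_L = (0.25, 0.25, 0.25, 0.25)
    if tip_row_R is None:
        tip_row_R = (0.25, 0.25, 0.25, 0.25)
    b = GraphBuilder()
    clL = [b.input(f"clL_{s}") for s in "ACGT"]
    clR = [b.input(f"clR_{s}") for s in "ACGT"]
    cl = [b.const(v, name=f"tipL_A{s}") for v, s in zip(tip_row_L, "ACGT")]
    cr = [b.const(v, name=f"tipR_A{s}") for v, s in zip(tip_row_R, "ACGT")]
    sopL = _sum_of_products(b, cl, clL)
    sopR = _sum_of_products(b, cr, clR)
    b.output(b.mul(sopL, sopR), name="clP_0")
    b.g.validate()
    return b.g


def build_kernel_dfg(tipL=None, tipR=None, pi=None,
                     table: LogApproxTable | None = None) -> DataFlowGraph:
    """The full per-site kernel: 10 logical inputs (clL x4, clR x4,
    lnScaler, numSites), 6 outputs (normalised clP x4, scP, updated
    lnScaler) and an internal lnL feedback accumulator."""
    tipL = np.asarray(tipL if tipL is not None else np.full((4, 4), 0.25), dtype=float)
    tipR = np.asarray(tipR if tipR is not None else np.full((4, 4), 0.25), dtype=float)
    pi = np.asarray(pi if pi is not None else (0.25, 0.25, 0.25, 0.25), dtype=float)
    table = table or default_log_table()

    b = GraphBuilder()
    clL = [b.input(f"clL_{s}") for s in "ACGT"]
    clR = [b.input(f"clR_{s}") for s in "ACGT"]
    ln_scaler_in = b.input("lnScaler")
    num_sites = b.input("numSites")

    # PLF columns: 36 mul + 24 add
    clP = []
    for s in range(4):
        cl = [b.const(tipL[s, x], name=f"tipL_{s}{x}") for x in range(4)]
        cr = [b.const(tipR[s, x], name=f"tipR_{s}{x}") for x in range(4)]
        sopL = _sum_of_products(b, cl, clL)
        sopR = _sum_of_products(b, cr, clR)
        clP.append(b.mul(sopL, sopR))

    # max of four: 3 cmp + 3 select, ties keep the earlier column
    m = clP[0]
    for s in range(1, 4):
        c = b.cmp(m, clP[s])
        m = b.select(c, m, clP[s])
    scaler = m

    # normalisation: 4 div
    norm = [b.div(p, scaler) for p in clP]

    # two log blocks: 2 x (4 cmp + 7 mul + 4 add)
    scP = _log_block(b, scaler, table, "scaler")

    # root dot product: 4 mul + 3 add
    bs = [b.const(pi[s], name=f"bs_{s}") for s in range(4)]
    cond_like = _sum_of_products(b, bs, norm)
    ln_cond = _log_block(b, cond_like, table, "condLike")

    # site tail: 3 add + 1 mul (one add is the lnL feedback)
    ln_scaler_out = b.add(ln_scaler_in, scP)
    site_ll = b.add(ln_scaler_out, ln_cond)
    contrib = b.mul(num_sites, site_ll)
    lnl_id = b._add("add", (0, 0), feedback=True, name="lnL")
    b.g.nodes[lnl_id].operands = (lnl_id, contrib)

    for s in range(4):
        b.output(norm[s], name=f"clP_{s}")
    b.output(scP, name="scP")
    b.output(ln_scaler_out, name="lnScaler_out")
    b.g.validate()
    return b.g


def count_ops(g: DataFlowGraph) -> dict[str, int]:
    """Histogram of floating-point operation nodes (selects, constants,
    inputs and outputs are not arithmetic and are excluded)."""
    counts = {op: 0 for op in ARITH_OPS}
    for n in g.nodes.values():
        if n.op in counts:
            counts[n.op] += 1
    return counts


def evaluate_dfg(g: DataFlowGraph, inputs, mode: NumericMode = NumericMode.EXACT,
                 state: dict[int, float] | None = None):
    """Interpret the graph on one input tuple.

    Returns ``(outputs, state)`` where ``state`` carries feedback
    accumulator values across calls (pass the returned state back in to
    chain sites; accumulators start at zero).  Device mode rounds every
    node result — constants and inputs included — to binary32.
    """
    if len(inputs) != len(g.inputs):
        raise ValueError(f"expected {len(g.inputs)} inputs, got {len(inputs)}")
    dt = mode.dtype
    state = dict(state or {})
    vals: dict[int, object] = {}
    for nid, v in zip(g.inputs, inputs):
        vals[nid] = dt(v)
    _order = g.topo_order()
    with np.errstate(over="ignore"):
        return _evaluate_nodes(g, _order, vals, dt, state), state


def _evaluate_nodes(g, order, vals, dt, state):
    for nid in order:
        n = g.nodes[nid]
        if n.op == "input":
            continue
        elif n.op == "const":
            vals[nid] = dt(n.value)
        elif n.op in ("add", "mul", "div"):
            if n.feedback:
                a = dt(state.get(nid, 0.0))
                bb = vals[n.operands[1]]
            else:
                a, bb = vals[n.operands[0]], vals[n.operands[1]]
            if n.op == "add":
                r = a + bb
            elif n.op == "mul":
                r = a * bb
            else:
                if bb == 0:
                    raise ZeroDivisionError(f"division by zero at node {nid}")
                r = a / bb
            vals[nid] = dt(r)
            if n.feedback:
                state[nid] = vals[nid]
        elif n.op == "cmp":
            vals[nid] = bool(vals[n.operands[0]] >= vals[n.operands[1]])
        elif n.op == "select":
            c, a, bb = (vals[o] for o in n.operands)
            vals[nid] = a if c else bb
        elif n.op == "output":
            vals[nid] = vals[n.operands[0]]
        else:  # pragma: no cover
            raise ValueError(f"unknown op {n.op!r}")
    return [float(vals[o]) for o in g.outputs]


# ---------------------------------------------------------------------------
# structured-text serialization
# ---------------------------------------------------------------------------

def dfg_to_text(g: DataFlowGraph) -> str:
    lines = ["# data-flow graph"]
    lines.append("inputs\t" + "\t".join(map(str, g.inputs)))
    lines.append("outputs\t" + "\t".join(map(str, g.outputs)))
    for nid in sorted(g.nodes):
        n = g.nodes[nid]
        cols = [f"node {nid}", n.op, ",".join(map(str, n.operands))]
        cols.append(repr(n.value) if n.value is not None else "-")
        cols.append(n.name or "-")
        cols.append("1" if n.feedback else "0")
        lines.append("\t".join(cols))
    return "\n".join(lines) + "\n"


def dfg_to_dot(g: DataFlowGraph) -> str:
    """Graphviz rendering of the graph for visual inspection."""
    shape = {"input": "invhouse", "const": "plaintext", "output": "house",
             "select": "trapezium", "cmp": "diamond"}
    lines = ["digraph dfg {", "  rankdir=TB;"]
    for nid in sorted(g.nodes):
        n = g.nodes[nid]
        label = n.name or (f"{n.value:g}" if n.op == "const" else n.op)
        sh = shape.get(n.op, "circle")
        lines.append(f'  n{nid} [label="{label}" shape={sh}];')
    for nid in sorted(g.nodes):
        for o in g.nodes[nid].operands:
            style = " [style=dashed]" if g.nodes[nid].feedback and o == nid else ""
            lines.append(f"  n{o} -> n{nid}{style};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def dfg_from_text(text: str) -> DataFlowGraph:
    g = DataFlowGraph()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "inputs":
            g.inputs = [int(v) for v in parts[1:] if v]
        elif parts[0] == "outputs":
            g.outputs = [int(v) for v in parts[1:] if v]
        elif parts[0].startswith("node "):
            nid = int(parts[0].split()[1])
            op = parts[1]
            operands = tuple(int(v) for v in parts[2].split(",") if v)
            value = None if parts[3] == "-" else float(parts[3])
            name = "" if parts[4] == "-" else parts[4]
            feedback = parts[5] == "1"
            g.nodes[nid] = DfgNode(nid, op, operands, value, name, feedback)
    g.validate()
    return g
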