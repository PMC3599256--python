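"""Cycle-accurate simulation of a synthesized pipeline.

The simulator advances a global cycle counter and, each cycle, fires
every functional unit whose modulo-DII slot holds an operation, steering
operands through the schedule's routing tables (not the original graph —
so a corrupted mux entry is faithfully simulated and caught by the
equivalence checker).  Values wait in idealized delay lines between
producer and consumer; a new site's input group enters every DII cycles;
the model is stall-free (memory behaviour lives in the platform model).

Correctness contract: for every site the six outputs are bit-identical
to the data-flow-graph interpreter in the same numeric mode, the first
output tuple completes at the pipeline latency, and one tuple follows
every DII cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dfg import DataFlowGraph, evaluate_dfg
from .plf_kernel import NumericMode
from .synth import UNIT_TYPE, OperatorSpec, PipelineSchedule

__all__ = ["SimTrace", "EquivalenceReport", "simulate_pipeline", "verify_equivalence"]


@dataclass
class SimTrace:
    """Per-cycle record of unit activity and I/O groups."""

    dii: int
    latency: int
    n_cycles: int = 0
    events: list[tuple[int, str, str]] = field(default_factory=list)  # (cycle, kind, text)
    max_events: int = 10000
    #: final value of each feedback accumulator after the last site
    feedback_values: dict[int, float] = field(default_factory=dict)

    def log(self, cycle: int, kind: str, text: str):
        if len(self.events) < self.max_events:
            self.events.append((cycle, kind, text))

    def to_text(self) -> str:
        lines = [f"# pipeline trace dii={self.dii} latency={self.latency} "
                 f"cycles={self.n_cycles}"]
        for cycle, kind, text in self.events:
            lines.append(f"{cycle}\t{kind}\t{text}")
        return "\n".join(lines) + "\n"


@dataclass
class EquivalenceReport:
    n_sites: int
    passed: bool
    max_site_checked: int = -1
    mismatch: dict | None = None

    def __str__(self):
        if self.passed:
            return (f"equivalence PASS: {self.n_sites} sites, "
                    f"max site checked {self.max_site_checked}")
        return f"equivalence FAIL: {self.mismatch}"


def simulate_pipeline(sched: PipelineSchedule, g: DataFlowGraph, site_stream,
                      mode: NumericMode = NumericMode.DEVICE,
                      trace_cap: int = 10000):
    """Stream ``site_stream`` (sequence of 10-value tuples for the kernel
    graph) through the pipeline; returns (outputs per site, SimTrace)."""
    sites = [tuple(s) for s in site_stream]
    n_inputs = len(g.inputs)
    for s in sites:
        if len(s) != n_inputs:
            raise ValueError(f"input tuple arity {len(s)} != {n_inputs}")
    for nid in sched.node_start:
        if nid not in g.nodes:
            raise ValueError(f"schedule names node {nid} absent from the graph")
    for nid, n in g.nodes.items():
        if n.op != "const" and nid not in sched.node_start:
            raise ValueError(f"graph node {nid} is unscheduled")

    dt = mode.dtype
    dii = sched.dii
    n_sites = len(sites)
    trace = SimTrace(dii=dii, latency=sched.latency, max_events=trace_cap)
    if n_sites == 0:
        return [], trace

    # group nodes by start-cycle offset within a site; within one cycle,
    # zero-latency muxes chain combinationally, so fire in dependency order
    topo_rank = {nid: i for i, nid in enumerate(g.topo_order())}
    by_start: dict[int, list[int]] = {}
    for nid in sched.node_start:
        if nid in sched.input_slots:
            continue
        by_start.setdefault(sched.node_start[nid], []).append(nid)
    for nodes in by_start.values():
        nodes.sort(key=lambda i: topo_rank[i])

    with np.errstate(over="ignore"):
        const_val = {nid: dt(n.value) for nid, n in g.nodes.items() if n.op == "const"}
    input_pos = {nid: k for k, nid in enumerate(g.inputs)}

    vals: dict[tuple[int, int], object] = {}  # (site, node) -> value

    def fetch(site, src, consumer):
        n = g.nodes[src]
        if n.op == "const":
            return const_val[src]
        if n.op == "input":
            return dt(sites[site][input_pos[src]])
        if consumer == sched.feedback_node and src == consumer:
            return vals[(site - 1, src)] if site > 0 else dt(0.0)
        # a value not yet produced reads as an uninitialised register:
        # a corrupted mux table is simulated, not rejected
        return vals.get((site, src), dt(0.0))

    total_cycles = sched.latency + (n_sites - 1) * dii
    # internal nodes (the feedback accumulator in particular) may fire a
    # few cycles after the last output tap; run the clock out for them
    last_fire = max(sched.node_start.values()) + (n_sites - 1) * dii
    outputs: list[list[float]] = [[None] * len(sched.outputs) for _ in range(n_sites)]

    for cycle in range(max(total_cycles, last_fire) + 1):
        # input groups enter on their slot cycles
        for nid, (slot_cycle, port) in sched.input_slots.items():
            site = (cycle - slot_cycle) // dii
            if (cycle - slot_cycle) % dii == 0 and 0 <= site < n_sites:
                trace.log(cycle, "IN", f"site={site} port={port} "
                                       f"node={nid} value={sites[site][input_pos[nid]]!r}")
        # fire every node whose start cycle lands here for some live site
        for offset, nodes in by_start.items():
            if (cycle - offset) % dii != 0:
                continue
            site = (cycle - offset) // dii
            if not (0 <= site < n_sites):
                continue
            for nid in nodes:
                op = sched.node_op[nid]
                ops = sched.routing[nid]
                if op == "select":
                    c = fetch(site, ops[0], nid)
                    r = fetch(site, ops[1], nid) if c else fetch(site, ops[2], nid)
                elif op == "output":
                    r = fetch(site, ops[0], nid)
                elif op == "cmp":
                    r = bool(fetch(site, ops[0], nid) >= fetch(site, ops[1], nid))
                elif op in ("add", "mul", "div"):
                    a = fetch(site, ops[0], nid)
                    b = fetch(site, ops[1], nid)
                    r = dt(a + b) if op == "add" else \
                        dt(a * b) if op == "mul" else dt(a / b)
                else:
                    raise ValueError(f"unexpected op {op!r} at node {nid}")
                vals[(site, nid)] = r
                if nid in sched.node_unit:
                    ut, ui = sched.node_unit[nid]
                    trace.log(cycle, "EX", f"site={site} {ut}:{ui} node={nid} "
                                           f"{op}={r!r}")
    trace.n_cycles = total_cycles

    if sched.feedback_node is not None and n_sites:
        trace.feedback_values = {sched.feedback_node:
                                 float(vals[(n_sites - 1, sched.feedback_node)])}
    for site in range(n_sites):
        for j, onid in enumerate(sched.outputs):
            outputs[site][j] = float(vals[(site, onid)])
        done = sched.latency + site * dii
        trace.log(done, "OUT", f"site={site} tuple={outputs[site]!r}")
    return outputs, trace


def verify_equivalence(sched: PipelineSchedule, g: DataFlowGraph, n_sites: int,
                       seed: int = 0, mode: NumericMode = NumericMode.DEVICE,
                       trace_cap: int = 0) -> EquivalenceReport:
    """Random-stream bit-equivalence of the simulated pipeline against the
    DFG interpreter.  Inputs are log-uniform positive values (likelihoods
    in (1e-3, 1]) with small positive integers in any input slot whose
    name marks it as a pattern weight."""
    rng = np.random.default_rng(seed)
    stream = []
    for _ in range(n_sites):
        tup = []
        for nid in g.inputs:
            name = g.nodes[nid].name
            if "numSites" in name:
                tup.append(float(rng.integers(1, 10)))
            elif "lnScaler" in name:
                tup.append(float(-rng.uniform(0.0, 5.0)))
            else:
                tup.append(float(np.exp(rng.uniform(np.log(1e-3), 0.0))))
        stream.append(tuple(tup))
    sim_out, _ = simulate_pipeline(sched, g, stream, mode, trace_cap=trace_cap)
    state: dict = {}
    for k, tup in enumerate(stream):
        ref, state = evaluate_dfg(g, list(tup), mode, state)
        if sim_out[k] != ref:
            for j, (a, b) in enumerate(zip(sim_out[k], ref)):
                if a != b:
                    onid = sched.outputs[j]
                    return EquivalenceReport(
                        n_sites=n_sites, passed=False, max_site_checked=k,
                        mismatch={"site": k, "output": j, "node": onid,
                                  "cycle": sched.latency + k * sched.dii,
                                  "unit": sched.node_unit.get(
                                      sched.routing[onid][0], ("-", -1)),
                                  "sim": a, "ref": b})
    return EquivalenceReport(n_sites=n_sites, passed=True,
                             max_site_checked=n_sites - 1)
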