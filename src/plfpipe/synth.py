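"""Throughput- and resource-constrained pipeline synthesis.

Given a data-flow graph and the port geometry of the target platform,
the synthesizer computes the data introduction interval ``DII =
ceil(logical ports / physical ports)``, the per-operation functional-unit
lower bound ``R = ceil(M / DII)``, and an ASAP (as soon as possible)
schedule with modulo-DII functional-unit sharing: a new site enters the
pipeline every DII cycles, so two operations may share a unit exactly
when their start cycles differ modulo DII.  Ready operations are
scheduled first-come-first-served (ordered by ready cycle, then node
id); when every unit of a type is busy in the required cycle slot and
the unit count has reached the lower bound, the operation is deferred to
the next cycle with a free slot — this is what makes the ``ceil(M/DII)``
bound achievable, and the greedy schedule always attains it exactly.

Operator latencies and register costs default to the Xilinx
single-precision floating-point core table: fadd 3 cycles / 139
registers (low) or 12 / 547 (max), fmul 3 / 87 or 8 / 361, fdiv 11 / 499
or 28 / 1377, fcomp 1 / 2 or 2 / 8.  Compare/select pairs occupy one
comparator; the select itself is a zero-latency mux that costs
registers, not units.  The designated feedback accumulator (the running
log-likelihood) is legal only if its unit latency fits inside the DII.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

from .dfg import DataFlowGraph

__all__ = [
    "OperatorSpec",
    "PipelineSchedule",
    "SynthesisError",
    "compute_dii",
    "min_functional_units",
    "asap_schedule",
    "estimate_registers",
    "check_schedule",
    "emit_netlist",
    "parse_netlist",
]

#: DFG op -> functional unit type
UNIT_TYPE = {"add": "fadd", "mul": "fmul", "div": "fdiv", "cmp": "fcomp"}
#: bits per operand alignment register
_REG_WIDTH_COST = 32


class SynthesisError(RuntimeError):
    pass


@dataclass
class OperatorSpec:
    """(low latency, low registers, max latency, max registers) per unit."""

    table: dict[str, tuple[int, int, int, int]] = field(default_factory=lambda: {
        "fadd": (3, 139, 12, 547),
        "fmul": (3, 87, 8, 361),
        "fdiv": (11, 499, 28, 1377),
        "fcomp": (1, 2, 2, 8),
    })

    def latency(self, unit_type: str, profile: str = "low") -> int:
        low, _, high, _ = self.table[unit_type]
        return low if profile == "low" else high

    def registers(self, unit_type: str, profile: str = "low") -> int:
        _, low, _, high = self.table[unit_type]
        return low if profile == "low" else high

    def override(self, updates: dict) -> "OperatorSpec":
        """New spec with entries replaced from ``updates`` (unit ->
        4-tuple or mapping with low_latency/low_registers/... keys)."""
        table = dict(self.table)
        for unit, val in updates.items():
            if isinstance(val, dict):
                low, lr, high, hr = table[unit]
                low = val.get("low_latency", low)
                lr = val.get("low_registers", lr)
                high = val.get("max_latency", high)
                hr = val.get("max_registers", hr)
                table[unit] = (low, lr, high, hr)
            else:
                table[unit] = tuple(val)
        return OperatorSpec(table=table)


def compute_dii(logical_ports: int, physical_ports: int) -> int:
    """Cycles the pipeline needs to read one full input set."""
    if logical_ports < 1 or physical_ports < 1:
        raise ValueError("port counts must be >= 1")
    return math.ceil(logical_ports / physical_ports)


def min_functional_units(op_count: int, dii: int) -> int:
    """Lower bound on units of one type: R >= ceil(M / DII)."""
    if dii < 1:
        raise ValueError("DII must be >= 1")
    return math.ceil(op_count / dii)


@dataclass
class PipelineSchedule:
    """Result of synthesis: timing, binding and routing of one DFG.

    ``node_start`` maps every non-const node to its start cycle;
    arithmetic nodes additionally get a ``(unit_type, unit_index)``
    binding in ``node_unit``.  ``routing`` copies the operand lists so a
    simulator (or a fault-injection test) steers data without consulting
    the graph.  ``latency`` counts from the first input cycle to the
    cycle the last output value is available.
    """

    dii: int
    latency_profile: str
    physical_ports: int
    node_start: dict[int, int] = field(default_factory=dict)
    node_unit: dict[int, tuple[str, int]] = field(default_factory=dict)
    node_op: dict[int, str] = field(default_factory=dict)
    routing: dict[int, tuple[int, ...]] = field(default_factory=dict)
    input_slots: dict[int, tuple[int, int]] = field(default_factory=dict)  # id -> (cycle, port)
    outputs: list[int] = field(default_factory=list)
    feedback_node: int | None = None
    latency: int = 0
    resource_usage: dict[str, int] = field(default_factory=dict)
    skew_cycles: int = 0
    register_estimate: int = 0

    def key_fields(self):
        return (self.dii, self.latency_profile, self.physical_ports,
                self.node_start, self.node_unit, self.node_op, self.routing,
                self.input_slots, self.outputs, self.feedback_node,
                self.latency, self.resource_usage, self.skew_cycles,
                self.register_estimate)


def asap_schedule(g: DataFlowGraph, dii: int, spec: OperatorSpec | None = None,
                  latency_profile: str = "low",
                  physical_ports: int | None = None) -> PipelineSchedule:
    """ASAP schedule with modulo-DII unit sharing at the resource bound."""
    spec = spec or OperatorSpec()
    if latency_profile not in ("low", "max"):
        raise ValueError("latency_profile must be 'low' or 'max'")
    n_inputs = len(g.inputs)
    if physical_ports is None:
        physical_ports = math.ceil(n_inputs / dii) if n_inputs else 1
    if n_inputs and math.ceil(n_inputs / physical_ports) > dii:
        raise SynthesisError(f"{n_inputs} inputs cannot be read through "
                             f"{physical_ports} ports within DII={dii}")

    caps = {ut: 0 for ut in spec.table}
    for n in g.nodes.values():
        if n.op in UNIT_TYPE:
            caps[UNIT_TYPE[n.op]] = caps.get(UNIT_TYPE[n.op], 0) + 1
    caps = {ut: min_functional_units(m, dii) for ut, m in caps.items()}

    sched = PipelineSchedule(dii=dii, latency_profile=latency_profile,
                             physical_ports=physical_ports,
                             outputs=list(g.outputs),
                             feedback_node=g.feedback_node)
    # unit occupancy: units[ut] = list of {slot: node}
    units: dict[str, list[dict[int, int]]] = {ut: [] for ut in caps}
    completion: dict[int, int] = {}

    def node_latency(n):
        if n.op in UNIT_TYPE:
            return spec.latency(UNIT_TYPE[n.op], latency_profile)
        return 0

    # dependency counts (feedback self-edge excluded)
    deps: dict[int, int] = {}
    succ: dict[int, list[int]] = {i: [] for i in g.nodes}
    ready_at: dict[int, int] = {}
    heap: list[tuple[int, int]] = []
    for n in g.nodes.values():
        count = 0
        for o in n.operands:
            if n.feedback and o == n.id:
                continue
            if g.nodes[o].op == "const":
                continue
            count += 1
            succ[o].append(n.id)
        deps[n.id] = count
        if n.op != "const":
            sched.node_op[n.id] = n.op
            if n.op != "input":
                sched.routing[n.id] = n.operands

    for idx, nid in enumerate(g.inputs):
        cyc, port = idx // physical_ports, idx % physical_ports
        sched.input_slots[nid] = (cyc, port)
        sched.node_start[nid] = cyc
        completion[nid] = cyc

    for n in g.nodes.values():
        if n.op in ("input", "const"):
            continue
        if deps[n.id] == 0:
            ready_at[n.id] = 0
            heapq.heappush(heap, (0, n.id))

    # propagate readiness from inputs
    scheduled = set(g.inputs)
    for nid in g.inputs:
        for s in succ[nid]:
            deps[s] -= 1
            if deps[s] == 0:
                r = max((completion[o] for o in g.nodes[s].operands
                         if o in completion), default=0)
                ready_at[s] = r
                heapq.heappush(heap, (r, s))

    def operand_ready(n):
        r = 0
        for o in n.operands:
            if n.feedback and o == n.id:
                continue
            if g.nodes[o].op == "const":
                continue
            r = max(r, completion[o])
        return r

    while heap:
        _, nid = heapq.heappop(heap)
        n = g.nodes[nid]
        ready = operand_ready(n)
        lat = node_latency(n)
        if n.op in UNIT_TYPE:
            ut = UNIT_TYPE[n.op]
            start = ready
            while True:
                slot = start % dii
                unit_idx = None
                for ui, occ in enumerate(units[ut]):
                    if slot not in occ:
                        unit_idx = ui
                        break
                if unit_idx is None and len(units[ut]) < caps[ut]:
                    units[ut].append({})
                    unit_idx = len(units[ut]) - 1
                if unit_idx is not None:
                    units[ut][unit_idx][slot] = nid
                    break
                start += 1  # defer: every unit busy in this cycle slot
            sched.node_unit[nid] = (ut, unit_idx)
        else:
            start = ready
        if n.feedback:
            if lat > dii:
                raise SynthesisError(
                    f"feedback accumulator {n.name or nid} needs latency "
                    f"{lat} > DII {dii}: no legal pipeline exists")
        sched.node_start[nid] = start
        completion[nid] = start + lat
        scheduled.add(nid)
        for s in succ[nid]:
            deps[s] -= 1
            if deps[s] == 0:
                r = operand_ready(g.nodes[s])
                ready_at[s] = r
                heapq.heappush(heap, (r, s))

    sched.latency = max((completion[o] for o in g.outputs), default=0)
    sched.resource_usage = {ut: len(us) for ut, us in units.items() if us}
    # operand alignment skew: cycles a produced value waits in delay
    # registers before its consumer samples it
    skew = 0
    for nid, n in g.nodes.items():
        if n.op in ("input", "const"):
            continue
        for o in n.operands:
            if n.feedback and o == n.id:
                continue
            if g.nodes[o].op == "const":
                continue
            skew += sched.node_start[nid] - completion[o]
    sched.skew_cycles = skew
    sched.register_estimate = estimate_registers(sched, spec)
    return sched


def estimate_registers(sched: PipelineSchedule, spec: OperatorSpec | None = None) -> int:
    """Model-level register cost: the bound units' own pipeline registers
    plus one 32-bit register per cycle of operand alignment skew."""
    spec = spec or OperatorSpec()
    total = 0
    for ut, count in sched.resource_usage.items():
        total += count * spec.registers(ut, sched.latency_profile)
    total += _REG_WIDTH_COST * sched.skew_cycles
    return total


def check_schedule(sched: PipelineSchedule, g: DataFlowGraph,
                   spec: OperatorSpec | None = None) -> list[str]:
    """Independent legality walker; returns a list of violations (empty =
    legal).  Checks dependencies, modulo-DII unit exclusivity, the port
    budget, and feedback feasibility."""
    spec = spec or OperatorSpec()
    errors = []

    def completion(nid):
        n = g.nodes[nid]
        lat = spec.latency(UNIT_TYPE[n.op], sched.latency_profile) if n.op in UNIT_TYPE else 0
        return sched.node_start[nid] + lat

    for nid, n in g.nodes.items():
        if n.op in ("input", "const"):
            continue
        start = sched.node_start.get(nid)
        if start is None:
            errors.append(f"node {nid} unscheduled")
            continue
        for o in n.operands:
            if g.nodes[o].op == "const":
                continue
            if n.feedback and o == n.id:
                lat = spec.latency(UNIT_TYPE[n.op], sched.latency_profile)
                if lat > sched.dii:
                    errors.append(f"feedback node {nid} latency {lat} exceeds DII")
                continue
            if completion(o) > start:
                errors.append(f"node {nid} starts at {start} before operand "
                              f"{o} completes at {completion(o)}")
    # modulo-resource exclusivity
    seen: dict[tuple[str, int, int], int] = {}
    for nid, (ut, ui) in sched.node_unit.items():
        slot = sched.node_start[nid] % sched.dii
        key = (ut, ui, slot)
        if key in seen:
            errors.append(f"unit {ut}:{ui} slot {slot} shared by nodes "
                          f"{seen[key]} and {nid}")
        seen[key] = nid
    # port budget
    per_cycle: dict[int, int] = {}
    for nid, (cyc, port) in sched.input_slots.items():
        per_cycle[cyc] = per_cycle.get(cyc, 0) + 1
        if not (0 <= port < sched.physical_ports):
            errors.append(f"input {nid} on illegal port {port}")
    for cyc, cnt in per_cycle.items():
        if cnt > sched.physical_ports:
            errors.append(f"{cnt} inputs in cycle {cyc} exceed "
                          f"{sched.physical_ports} ports")
    return errors


# ---------------------------------------------------------------------------
# structured-text netlist
# ---------------------------------------------------------------------------

def emit_netlist(sched: PipelineSchedule) -> str:
    """Deterministic textual pipeline description: functional units, the
    per-cycle-slot mux tables steering operands, input port assignments
    and delay-line summary.  Parses back into an equivalent schedule."""
    lines = [f"pipeline\tdii={sched.dii}\tlatency={sched.latency}"
             f"\tprofile={sched.latency_profile}\tports={sched.physical_ports}"
             f"\tskew={sched.skew_cycles}\tregisters={sched.register_estimate}"]
    for ut in sorted(sched.resource_usage):
        lines.append(f"unit\t{ut}\tcount={sched.resource_usage[ut]}")
    for nid in sorted(sched.input_slots):
        cyc, port = sched.input_slots[nid]
        lines.append(f"input\t{nid}\tcycle={cyc}\tport={port}")
    for nid in sorted(sched.node_start):
        if nid in sched.input_slots:
            continue
        op = sched.node_op[nid]
        start = sched.node_start[nid]
        unit = sched.node_unit.get(nid)
        ustr = f"{unit[0]}:{unit[1]}" if unit else "-"
        ops = ",".join(map(str, sched.routing.get(nid, ())))
        fb = "\tfeedback" if nid == sched.feedback_node else ""
        lines.append(f"node\t{nid}\t{op}\tstart={start}\tunit={ustr}"
                     f"\toperands={ops}{fb}")
    lines.append("outputs\t" + ",".join(map(str, sched.outputs)))
    return "\n".join(lines) + "\n"


def parse_netlist(text: str) -> PipelineSchedule:
    sched = PipelineSchedule(dii=1, latency_profile="low", physical_ports=1)
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        kind = parts[0]
        kv = {}
        for p in parts[1:]:
            if "=" in p:
                k, v = p.split("=", 1)
                kv[k] = v
        if kind == "pipeline":
            sched.dii = int(kv["dii"])
            sched.latency = int(kv["latency"])
            sched.latency_profile = kv["profile"]
            sched.physical_ports = int(kv["ports"])
            sched.skew_cycles = int(kv["skew"])
            sched.register_estimate = int(kv["registers"])
        elif kind == "unit":
            sched.resource_usage[parts[1]] = int(kv["count"])
        elif kind == "input":
            nid = int(parts[1])
            sched.input_slots[nid] = (int(kv["cycle"]), int(kv["port"]))
            sched.node_start[nid] = int(kv["cycle"])
            sched.node_op[nid] = "input"
        elif kind == "node":
            nid = int(parts[1])
            sched.node_op[nid] = parts[2]
            sched.node_start[nid] = int(kv["start"])
            if kv["unit"] != "-":
                ut, ui = kv["unit"].split(":")
                sched.node_unit[nid] = (ut, int(ui))
            ops = tuple(int(v) for v in kv["operands"].split(",") if v)
            sched.routing[nid] = ops
            if "feedback" in parts:
                sched.feedback_node = nid
        elif kind == "outputs":
            sched.outputs = [int(v) for v in parts[1].split(",") if v]
    return sched
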