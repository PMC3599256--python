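"""Bandwidth-bound performance model of the multi-FPGA coprocessor.

The target platform couples four application engines (AEs, one FPGA
each, eight kernel pipelines per AE) to eight memory controllers, each
moving 16 bytes per 150 MHz cycle: 2.4 GB/s per controller, 19.2 GB/s
per AE, 76.8 GB/s aggregate (the platform's own accounting, adopted
verbatim).  The kernel performs 130 single-precision flops per site
against 64 bytes of I/O (10 input + 6 output words), an arithmetic
intensity of 2.03 ops/byte, so predicted throughput follows the roofline
product ``intensity x peak bandwidth x memory efficiency`` — 78 Gflops
at the ~50% efficiency the hardware reaches on large inputs.

Also here: the strided scatter/gather that lays host arrays out across
AEs and processing elements (64-byte blocks per PE, 512-byte stride
between AEs), and an idealized trace generator for the memory FSM
(LD1 clL / LD2 clR / LD3 lnScaler+numSites, interrupted by store bursts
when the output FIFO nears full).  Real efficiencies are depressed by
DRAM bank contention and scheduler behaviour that this model
deliberately does not simulate; its trace is an upper bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlatformConfig",
    "LayoutSpec",
    "AddressMap",
    "FsmTrace",
    "peak_bandwidth",
    "memory_efficiency",
    "arithmetic_intensity",
    "predicted_throughput",
    "scatter_to_coprocessor",
    "gather_from_coprocessor",
    "fsm_trace",
]

#: flops per site as counted for the hardware datapath, and the I/O bytes
#: per site (10 reads + 6 writes, 4 bytes each) — the inputs of the
#: roofline arithmetic.
FLOPS_PER_SITE = 130
IO_BYTES_PER_SITE = 64


@dataclass
class PlatformConfig:
    n_ae: int = 4
    pes_per_ae: int = 8
    n_mc: int = 8
    clock_hz: float = 150e6
    bytes_per_mc_cycle: int = 16
    input_fifo_depth: int = 512
    output_fifo_depth_n: int = 2048
    output_fifo_depth_m: int = 512
    element_bytes: int = 4

    def __post_init__(self):
        for name in ("n_ae", "pes_per_ae", "n_mc", "clock_hz",
                     "bytes_per_mc_cycle", "input_fifo_depth",
                     "output_fifo_depth_n", "output_fifo_depth_m", "element_bytes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class LayoutSpec:
    pe_block_bytes: int = 64      # 16 elements x 4 bytes per PE block
    ae_stride_bytes: int = 512    # pes_per_ae x pe_block_bytes
    sites_per_pe_round: int = 4

    def elements_per_block(self, cfg: PlatformConfig) -> int:
        return self.pe_block_bytes // cfg.element_bytes


def peak_bandwidth(cfg: PlatformConfig, scope: str = "board") -> float:
    """Peak theoretical bandwidth in GB/s at controller, AE or board scope.

    Per controller: bytes/cycle x clock.  The platform's accounting
    credits every AE with all controllers (full crossbar) and the board
    with four AEs.
    """
    mc = cfg.bytes_per_mc_cycle * cfg.clock_hz / 1e9
    if scope == "mc":
        return mc
    if scope == "ae":
        return cfg.n_mc * mc
    if scope == "board":
        return cfg.n_ae * cfg.n_mc * mc
    raise ValueError(f"unknown scope {scope!r}")


def memory_efficiency(reads: int, writes: int, cycles: int) -> float:
    """(memory reads + memory writes) / execution cycles."""
    if cycles < 1:
        raise ValueError("cycle count must be >= 1")
    return (reads + writes) / cycles


def arithmetic_intensity(flops_per_site: int = FLOPS_PER_SITE,
                         io_bytes_per_site: int = IO_BYTES_PER_SITE) -> float:
    """Flops per byte of memory traffic (130 / 64 = 2.03 ops/byte)."""
    return flops_per_site / io_bytes_per_site


def predicted_throughput(ai: float, peak_gb_s: float, eff: float) -> float:
    """Roofline throughput in Gflops: intensity x peak bandwidth x
    efficiency."""
    if ai < 0 or peak_gb_s < 0 or not (0 <= eff <= 1):
        raise ValueError("arguments must be non-negative with eff <= 1")
    return ai * peak_gb_s * eff


# ---------------------------------------------------------------------------
# strided data layout
# ---------------------------------------------------------------------------

@dataclass
class AddressMap:
    """Bijection host element index <-> (ae, pe, coprocessor byte offset)."""

    ae: np.ndarray
    pe: np.ndarray
    offset: np.ndarray  # global byte offset in the coprocessor layout
    layout: LayoutSpec
    n_elements: int

    def to_tsv(self) -> str:
        lines = ["host_index\tae\tpe\toffset"]
        for i in range(self.n_elements):
            lines.append(f"{i}\t{self.ae[i]}\t{self.pe[i]}\t{self.offset[i]}")
        return "\n".join(lines) + "\n"


def scatter_to_coprocessor(host_array, layout: LayoutSpec | None = None,
                           cfg: PlatformConfig | None = None) -> AddressMap:
    """Distribute a host array across AEs and PEs with the standard
    strides: consecutive 16-element (64-byte) blocks go to successive
    PEs, first within an AE (64-byte stride) then across AEs (512-byte
    stride for the same PE slot), wrapping to the next round after all
    32 PEs are served.  The element count must fill whole rounds —
    ``n_ae x pes_per_ae x 16`` elements, i.e. the 4-state partials of
    128 sites."""
    layout = layout or LayoutSpec()
    cfg = cfg or PlatformConfig()
    host = np.asarray(host_array)
    n = host.shape[0]
    epb = layout.elements_per_block(cfg)
    round_elements = cfg.n_ae * cfg.pes_per_ae * epb
    if n == 0 or n % round_elements != 0:
        raise ValueError(f"element count {n} must be a positive multiple of "
                         f"{round_elements} (PE blocks of {epb} across "
                         f"{cfg.n_ae * cfg.pes_per_ae} PEs)")
    idx = np.arange(n)
    block = idx // epb
    within = idx % epb
    rnd = block // (cfg.n_ae * cfg.pes_per_ae)
    slot = block % (cfg.n_ae * cfg.pes_per_ae)
    ae = slot // cfg.pes_per_ae
    pe = slot % cfg.pes_per_ae
    round_bytes = cfg.n_ae * layout.ae_stride_bytes
    offset = (rnd * round_bytes + ae * layout.ae_stride_bytes
              + pe * layout.pe_block_bytes + within * cfg.element_bytes)
    return AddressMap(ae=ae, pe=pe, offset=offset, layout=layout, n_elements=n)


def gather_from_coprocessor(device_array, amap: AddressMap,
                            cfg: PlatformConfig | None = None) -> np.ndarray:
    """Inverse of :func:`scatter_to_coprocessor`: reassemble the host
    order from a device image indexed by ``amap.offset``."""
    cfg = cfg or PlatformConfig()
    device = np.asarray(device_array)
    elem_index = amap.offset // cfg.element_bytes
    return device[elem_index]


def apply_scatter(host_array, amap: AddressMap,
                  cfg: PlatformConfig | None = None) -> np.ndarray:
    """Materialise the device-side image (element-indexed) of a host
    array under an address map."""
    cfg = cfg or PlatformConfig()
    host = np.asarray(host_array)
    device = np.empty_like(host)
    device[amap.offset // cfg.element_bytes] = host
    return device


# ---------------------------------------------------------------------------
# memory FSM trace (idealized)
# ---------------------------------------------------------------------------

@dataclass
class FsmTrace:
    requests: list[tuple[int, str, str, int]] = field(default_factory=list)
    # (cycle, state, array, n_values)
    n_cycles: int = 0
    read_values: int = 0
    write_values: int = 0
    read_cycles: int = 0
    write_cycles: int = 0
    interruptions: int = 0

    @property
    def efficiency(self) -> float:
        if self.n_cycles == 0:
            return 1.0
        return memory_efficiency(self.read_cycles, self.write_cycles, self.n_cycles)

    def to_text(self) -> str:
        lines = [f"# fsm trace cycles={self.n_cycles} reads={self.read_values} "
                 f"writes={self.write_values} interruptions={self.interruptions} "
                 f"efficiency={self.efficiency:.4f}"]
        for cyc, state, array, nv in self.requests:
            lines.append(f"{cyc}\t{state}\t{array}\t{nv}")
        return "\n".join(lines) + "\n"


def fsm_trace(n_sites: int, cfg: PlatformConfig | None = None,
              output_fifo_almost_full: int | None = None) -> FsmTrace:
    """Idealized load/store request trace of the memory state machine.

    Per site the controller requests the clL quad (LD1), the clR quad
    (LD2) and the lnScaler + numSites pair (LD3) — 3 read cycles for 10
    values — while the pipeline's 6 outputs accumulate in the output
    FIFO.  When the FIFO reaches the almost-full threshold the current
    load sequence is interrupted and the FIFO drains at 4 values per
    store cycle; remaining outputs are drained at the end.  Every input
    is requested exactly once and every output stored exactly once; in
    this stall-free model every cycle issues a request, so the
    efficiency estimate is the upper bound 1.0.
    """
    cfg = cfg or PlatformConfig()
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    threshold = output_fifo_almost_full
    if threshold is None:
        threshold = cfg.output_fifo_depth_m - 8
    trace = FsmTrace()
    cycle = 0
    fifo = 0

    def store_burst(state: str):
        nonlocal cycle, fifo
        while fifo > 0:
            nv = min(4, fifo)
            trace.requests.append((cycle, state, "out", nv))
            trace.write_values += nv
            trace.write_cycles += 1
            fifo -= nv
            cycle += 1

    load_states = (("LD1", "clL", 4), ("LD2", "clR", 4),
                   ("LD3", "lnScaler+numSites", 2))
    for _ in range(n_sites):
        for state, array, nv in load_states:
            if fifo >= threshold:
                trace.interruptions += 1
                store_burst("ST")
            trace.requests.append((cycle, state, array, nv))
            trace.read_values += nv
            trace.read_cycles += 1
            cycle += 1
        fifo += 6  # the site's outputs land in the output FIFO
    store_burst("ST_FINAL")
    trace.n_cycles = cycle
    return trace
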