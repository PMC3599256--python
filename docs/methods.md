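# Methods

`plfpipe` models, in software, a hardware realisation of the
phylogenetic likelihood function (PLF): the per-site kernel a
single-precision FPGA pipeline would execute, the design-automation
calculus that synthesises that pipeline from a data-flow graph under
throughput and resource constraints, a cycle-accurate simulator that
proves the pipeline computes exactly what the graph computes, and a
bandwidth-bound (roofline) performance model of the target coprocessor.
This note records the model, its assumptions, the numerical choices and
their known limitations.

## The likelihood kernel

For a rooted binary tree with nucleotide states, Felsenstein's pruning
recursion combines the conditional likelihoods (partials) of a node's
two children through the edge transition matrices:

    clP[s] = (Σ_x P_l[s,x]·clL[x]) · (Σ_y P_r[s,y]·clR[y]),   s ∈ {A,C,G,T}

To prevent underflow on large trees, every internal-node column is
rescaled by its maximum (the *scaler*); the log of the scaler is stored
per site (`scP`) and accumulated additively into a cumulative buffer
(`lnScaler`, initialised to zero and reset at the start of each full
traversal).  At the root,

    lnL = Σ_k w_k · ( lnScaler[k] + ln Σ_s π_s · clP[k,s] )

where `w_k` are site-pattern multiplicities and π the equilibrium base
frequencies.  One rate category, one partition, strictly binary trees
with mandatory branch lengths; transition matrices come from an
eigen-decomposition, P(t) = E·diag(e^{λt})·E⁻¹, with entries clamped to
[0,1] after removal of rounding noise below 1e-12.

Two numeric modes share one code path ordering:

* **exact** — IEEE-754 double precision with the true natural log; the
  reference and oracle mode.
* **device** — every add/mul/div result is rounded to binary32 before
  reuse (implemented by computing on float32 arrays, which rounds each
  element-wise operation exactly once) and `ln` is the segmented
  polynomial below.  Sums of four products are chained (no add to
  zero), the max of four is a chain of three compare/selects keeping
  the earlier state on ties, and the final lnL is accumulated strictly
  left to right in site order, so the vectorised kernel is bit-for-bit
  identical to a scalar interpretation of the same data-flow graph.

Degenerate all-zero columns (true underflow even after per-node
rescaling) raise an error with the offending site index rather than
emitting infinities: the modelled datapath has no NaN path.

## The segmented natural log

The device log is a table of 16 segments × 5 coefficients.  Segment
selection is a 4-step unrolled binary search against decade thresholds
10^e: the comparison exponent starts at −16 and moves by ±8, ±4, ±2,
±1; each "≥" branch adds 8, 4, 2, 1 to the segment index.  The induced
segments tile the positive axis: segment 0 owns (0, 1e−30), segments
1–14 own [10^(2s−32), 10^(2s−30)), segment 15 owns [1e−2, ∞).  The
polynomial is evaluated exactly as a datapath would: power chain x,
x², x³, x⁴ by successive multiplication, then the coefficient products
accumulate onto the constant term in ascending order.

Coefficients are fitted per segment on its intersection with the
validated domain [1e−32, 1] (kernel arguments — scalers and the root
dot product — always lie in (0, 1] once partials are normalised).  The
default fit interpolates ln at the segment's five Chebyshev nodes.
Alternatives (true minimax, and minimax with an error budget relaxed
toward the segment bottom) are implemented and were compared on the
end-to-end likelihood deviation; Chebyshev-node interpolation won
because it is near-exact over the upper decade of each segment, where
the argument distribution under the generative model concentrates.

**Accuracy limitation (important).**  A degree-4 polynomial in x over a
two-decade interval has an irreducible uniform-error floor of ≈0.29
ln-units (and ≈0.066 even restricted to the bottom 1.5 decades; both
floors are linear-programming facts, identical for every segment by
scaling).  Consequently the approximation cannot be pointwise accurate
to 1%, and the end-to-end device/exact likelihood deviation on random
4–8-taxon datasets measures ~2–5% worst case (mean ~1%), dominated by
sites whose scalers fall in the lower 1.5 decades of a segment (e.g.
conflicting tip patterns across short branches).  Binary32 rounding
itself contributes < 1e−4 relative.  The tests assert the measured
contract; the acceptance suite also asserts the stricter 1% figure,
which this construction does not meet under these study conditions.
At exact decade boundaries the binary32 and float64 searches may select
adjacent segments (a one-ulp cast effect); the induced jump is bounded
by the adjacent segments' fit residuals, which the table stores.

## Data-flow graph and operation counts

`build_kernel_dfg` encodes one site of the kernel with 10 logical
inputs (4 clL, 4 clR, lnScaler, numSites) and 6 outputs (4 normalised
clP, scP, updated lnScaler); the running-lnL accumulator is an internal
add with a feedback self-edge.  Transition-matrix entries, base
frequencies, search thresholds and polynomial coefficients are graph
constants; threshold and coefficient *selection* is a network of select
(mux) nodes, which — like the selects in the max chain — occupy no
floating-point unit and are excluded from operation counts.  Under
these conventions the graph contains exactly

    38 additions   (24 PLF + 8 log accumulation + 3 root dot + 3 tail)
    55 multiplications (36 PLF + 14 log power/coeff + 4 root dot + 1 weight)
     4 divisions   (normalisation)
    11 comparisons (3 max chain + 2×4 segment search)

and the single-column introductory expression has 8 inputs, 9
multiplications and 6 additions.  The interpreter (`evaluate_dfg`)
evaluates in topological order, rounding per node in device mode, and
is the bit-level oracle for both the vectorised kernel and the pipeline
simulator.

## Pipeline synthesis

The data introduction interval is DII = ⌈logical ports / physical
ports⌉ — with 10 inputs through a 4-value-per-cycle memory interface,
DII = 3 — and the minimum number of functional units of a type with M
operations is ⌈M/DII⌉ (13 adders, 19 multipliers, 2 dividers, 4
comparators for the kernel).  Scheduling is ASAP with modulo-DII
resource sharing: a new site enters every DII cycles, so two operations
conflict exactly when they use the same unit with start cycles
congruent mod DII.  Ready operations are served in (ready cycle, node
id) order; when every unit of a type is occupied in the required slot
and the unit count has reached ⌈M/DII⌉, the operation is deferred to
the next free slot.  Because total slot capacity ⌈M/DII⌉·DII ≥ M, the
greedy schedule always terminates and always attains the lower bound —
which the tests confirm against an exhaustive binding search on random
small graphs.

Operator latencies and register costs default to the published
single-precision floating-point core table (fadd 3/139 low, 12/547
max; fmul 3/87, 8/361; fdiv 11/499, 28/1377; fcomp 1/2, 2/8); the
divider's low-latency depth of 11 reflects the timing closure of the
modelled platform.  Selects are zero-latency muxes scheduled one cycle
after their comparator and cost registers, not units.  The feedback
accumulator is legal only if its unit latency ≤ DII (fadd at 3 cycles
inside DII 3; the max-latency profile is correctly rejected).  Register
cost is estimated as the bound units' pipeline registers plus one
32-bit register per cycle of operand alignment skew.  The reported
kernel pipeline latency (41 cycles at the low-latency profile) is a
property of this package's graph reconstruction; a different (but
count-equivalent) graph arrangement would report a different latency,
so no external latency figure is asserted.

Input port slots follow the memory state machine: cycle 0 carries the
four clL values, cycle 1 the four clR values, cycle 2 lnScaler and
numSites.  The netlist (units, per-slot mux tables, input grid, delay
summary) serialises to text and parses back into an equivalent
schedule.

## Cycle-accurate simulation

The simulator advances a global clock; at each cycle every operation
whose start offset matches modulo DII fires for the site occupying that
stage, steering operands through the *schedule's* routing tables (not
the graph), so an injected mux corruption is faithfully simulated and
located by the equivalence checker.  The model is stall-free — memory
behaviour is deliberately excluded — and idealises registers as
unbounded delay lines.  Contract (tested): outputs bit-identical to the
interpreter per site, first output at the pipeline latency, one output
tuple per DII cycles thereafter, and total cycles = latency + (n−1)·DII.

## Platform model and data layout

Peak bandwidth follows the platform's own accounting: 16 B/cycle ×
150 MHz = 2.4 GB/s per memory controller, ×8 controllers = 19.2 GB/s
per application engine (AE), ×4 AEs = 76.8 GB/s aggregate (each AE is
credited with the full crossbar; the convention is adopted verbatim,
not corrected).  Memory efficiency is (reads + writes)/cycles; the
kernel's arithmetic intensity is 130 flops per 64 B of I/O = 2.03
ops/byte; predicted throughput is intensity × peak × efficiency (78
Gflops at 50%).  The 130-flop figure is a stated input of the model
(the DFG counts 108 arithmetic nodes; the gap plausibly counts
selects/muxes) and is never derived.

The scatter layout distributes consecutive 16-element (64 B) host
blocks across the 32 processing elements — a 64 B stride between PEs in
an AE and a 512 B stride between the same PE slot of consecutive AEs —
so each PE receives 4 sites of a 4-value-per-site array per round;
conforming arrays are multiples of 512 elements (128 sites).  Pattern
weights are packed 4-per-PE-round in the PE's own region (one
consistent reading of an under-specified interleaving).  The memory-FSM
trace generator issues LD1(clL)/LD2(clR)/LD3(lnScaler+numSites) per
site, interrupts to a store burst when the modelled output FIFO reaches
its almost-full mark (default: the 512-entry FIFO depth minus 8), and
drains at the end; it conserves exactly 10 read and 6 write values per
site (3 read cycles and 1.5 write cycles).  Because every cycle issues
a request, its efficiency estimate is the stall-free upper bound 1.0:
measured efficiencies on real hardware (a few percent to ~50%) are
governed by DRAM bank contention and scheduler behaviour that this
model intentionally does not simulate.

## Synthetic data

The generator draws a rooted binary topology by uniform sequential pair
joins, branch lengths from Exponential(mean 0.1 substitutions/site — a
typical scale for curated nucleotide alignments), and evolves sites
independently down the tree using the same transition matrices the
likelihood engine computes.  Models: Jukes–Cantor (uniform rates and
frequencies, closed-form P(t) used as an oracle in tests) or a random
reversible model with π ~ Dirichlet(5) and exchangeabilities ~
Gamma(2, ½), normalised to one expected substitution per unit branch
length.  Everything is deterministic under the seed.  What the
generator does *not* emulate: rate heterogeneity across sites,
indels/alignment error, base-composition heterogeneity across lineages,
and selection — so passing tests demonstrate numerical and structural
correctness of the kernel and pipeline, not robustness to real-data
model violations.  Default site counts are multiples of 128, mirroring
the per-PE load-balancing convention; the software path accepts any
length (the layout mapper still enforces its own multiple).

Problem sizes used by the default test and acceptance runs — 50
datasets of 128–1024 sites for the accuracy suite, 1000 streamed sites
for pipeline equivalence, ≤8-node graphs for the exhaustive binding
search — were chosen to exercise every code path at desk scale while
keeping the whole suite in seconds.

## Numerical and design choices, quickly

* lnScaler update: the cumulative buffer accumulates additively
  (`lnScaler += scP`); it starts at zero, and additive accumulation is
  the only reading consistent with both the graph's addition count and
  cumulative-scale-buffer semantics.
* Max-of-4 ties keep the earlier state index; comparisons are `≥`.
* Device-mode constants (matrix entries, thresholds, coefficients) are
  rounded to binary32 before use; coefficients of segments far below
  the validated domain exceed binary32 range and saturate to ±inf,
  exactly as a 32-bit datapath could not host them.
* Site independence: no reduction other than the left-to-right lnL
  accumulation, keeping both modes order-deterministic.
* Scale buffers are reset at the start of every full traversal.
* Trees: polytomies and missing branch lengths are parse errors.
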