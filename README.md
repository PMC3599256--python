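# plfpipe

**The phylogenetic likelihood function, the way a pipeline computes it.**

Likelihood-based phylogenetics (RAxML, MrBayes, BEAST, GARLI, and the
BEAGLE library underneath them) spends nearly all of its time in one
kernel: Felsenstein's pruning recursion

```
clP[s] = (Σ_x P_l[s,x]·clL[x]) · (Σ_y P_r[s,y]·clR[y]),  s ∈ {A,C,G,T}
lnL    = Σ_k w_k · ( lnScaler[k] + ln Σ_s π_s·clP[k,s] )
```

with per-site max-rescaling against underflow and a cumulative
log-scaler buffer.  This kernel is data-parallel, memory-bound, and a
natural target for deep floating-point pipelines.  `plfpipe` is a
library + CLI for people studying that mapping: computational
phylogeneticists who want a reference kernel with a *device-faithful*
single-precision mode, and hardware/HLS-minded folks who want the
synthesis calculus, the cycle-accurate simulation, and the roofline
arithmetic in executable form.

What's inside, in execution order:

| module | what it does |
|---|---|
| `plfpipe.log_approx` | 16-segment × 5-coefficient polynomial `ln` selected by an unrolled logarithmic binary search |
| `plfpipe.plf_kernel` | the per-site kernel: PLF columns, max-rescaling, scaler bookkeeping, weighted root lnL — in `exact` (float64, true `ln`) and `device` (per-operation binary32 rounding, segmented `ln`) modes |
| `plfpipe.beagle_api` | BEAGLE-style instance lifecycle: tips, frequencies, weights, eigen-system transition matrices `P(t)=E·diag(e^{λt})·E⁻¹`, postorder traversal, root likelihood |
| `plfpipe.dfg` | data-flow-graph IR of the kernel (10 inputs, 6 outputs, exactly 38 add / 55 mul / 4 div / 11 cmp) with a bit-level interpreter |
| `plfpipe.synth` | pipeline synthesis: DII = ⌈logical/physical ports⌉, unit lower bound ⌈M/DII⌉, ASAP scheduling with modulo-DII sharing, register model, text netlists |
| `plfpipe.pipesim` | cycle-accurate simulation proving the pipeline is bit-identical to the interpreter at one site per DII cycles |
| `plfpipe.perf_model` | coprocessor bandwidth chain (2.4 → 19.2 → 76.8 GB/s), memory efficiency, roofline throughput, the 64 B/512 B strided scatter layout, an idealized memory-FSM trace |
| `plfpipe.workbench` | synthetic trees + alignments (JC69 or random reversible models) and end-to-end drivers |

## Worked example

Simulate a 4-taxon, 128-site JC69 dataset and score it in both numeric
modes:

```
$ plfpipe simulate --taxa 4 --sites 128 --seed 1 \
      --tree-out t.nwk --alignment-out a.fasta
$ plfpipe likelihood t.nwk a.fasta --mode both
lnL_device      -361.4207763671875
lnL_exact       -372.6103456960533
relative_deviation      0.030030216439543986
...
```

`lnL_exact` is the double-precision pruning likelihood of the tree;
`lnL_device` is what the single-precision datapath computes — the ~3%
gap here is the segmented-log approximation at work (see
`docs/methods.md` for why a degree-4 polynomial over two-decade
segments cannot do much better on sites with small scalers).

Synthesize the kernel pipeline for a platform that delivers four
32-bit words per cycle:

```
$ plfpipe synthesize kernel --ports 4
inputs  10
outputs 6
ops_add 38
ops_mul 55
ops_div 4
ops_cmp 11
dii     3
latency 41
units_fadd      13
units_fcomp     4
units_fdiv      2
units_fmul      19
registers       19122
```

Ten logical inputs through four ports force a data introduction
interval of 3 cycles, and the resource bound ⌈M/DII⌉ maps 38 additions
onto 13 adders and 55 multiplications onto 19 multipliers; `latency` is
the depth of this package's graph reconstruction at the low-latency
operator profile.  `plfpipe simulate-pipeline --sites 1000` then checks
the schedule bit-for-bit against the graph interpreter.

The platform arithmetic:

```
$ plfpipe perfmodel
peak_mc_gb_s    2.4
peak_ae_gb_s    19.2
peak_board_gb_s 76.8
arithmetic_intensity_ops_per_byte       2.031250
throughput_gflops       78.000
```

i.e. 130 flops per 64 bytes of I/O ≈ 2.03 ops/byte, and at 50% memory
efficiency a 76.8 GB/s platform sustains ≈78 Gflops.  `plfpipe layout N`
prints the host→coprocessor address map (64-byte blocks per processing
element, 512-byte stride between application engines).

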