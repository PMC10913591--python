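"""Time the naive and optimized LIF pipelines and print the speed-up.

Small version of the timing experiment: N=500 neurons, 100 steps, 3
replicates per variant.  The optimized pipeline (src-major layout, indexed
transmission, mesh STDP, masked clipping, f32) should come out well ahead
of the naive one (dst-major, full product, outer-product STDP, full-matrix
clipping, f64); the exact factor depends on the machine.
"""

from spikemesh import BenchmarkGrid, run_grid, speedup_table

grid = BenchmarkGrid(model_kinds=("lif_onestep",), sizes=(500,),
                     steps=100, replicates=3, master_seed=0)
results = run_grid(grid)
table = speedup_table(results)
print(table.to_string(index=False))
ratio = table["speedup"].max() / table["speedup"].min()
print(f"\noptimized is {ratio:.0f}x faster than naive on this machine")
# 'speedup' is each cell's mean time divided into the slowest cell's mean
# time, so the slowest row always reads 1.0.
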