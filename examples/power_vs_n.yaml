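# Full power-vs-sample-size experiment, all scenarios and designs.
# Run with:  nof1sim run --config examples/power_vs_n.yaml --out results/
# Reduce n_reps (>= 100) for a quick look.
experiment: power_vs_n
scenarios: [1, 2, 3, 4]
designs: [nof1, crossover, rct]
n_grid: [10, 20, 30, 40, 50, 100, 150, 200]
tau: 0.25
n_reps: 5000
seed: 1
out_dir: results
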