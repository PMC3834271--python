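"""Search the f grid for the value that best balances link and node knowledge.

Uses a scaled-down dataset 4 (root genes have both slightly better node
weights and slightly heavier links), where neither extreme of f is optimal.
"""

from kngp import SyntheticSpec, find_best_f, generate

net, roots = generate(SyntheticSpec(dataset_id=4, seed=0, n_nodes=400))
best_f, results = find_best_f(
    net, roots, F=(0.0, 1.0, 15.0, 100.0, 10_000.0, 1e10),
    beta=0.5, k=10, L=50, seed=0,
)

print(f"{'f':>12}  {'AUC':>6}")
for f in sorted(results):
    marker = "  <- best" if f == best_f else ""
    print(f"{f:>12g}  {results[f].auc:.3f}{marker}")

print(
    f"\nbest f = {best_f:g}: an intermediate value, because this network"
    "\nbiases both its node weights and its link weights toward the roots."
)
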