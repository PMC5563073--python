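"""Arbor morphometry: branch orders, counts, lengths and the ACI.

Builds a random arbor trace (as produced by semi-automatic tracing),
assigns branch orders (primary off the shaft, order + 1 below), and
computes the axon complexity index with its simple/complex classification.
"""

import axodyn as ax

trace = ax.synthetic_arbor(seed=9)
orders = ax.assign_orders(trace)
stats = ax.branch_stats(trace)
value = ax.aci(trace)

print(f"branches: {stats['n_branches']}, total length "
      f"{stats['total_length_um']:.0f} um")
for order, count in stats["counts_per_order"].items():
    label = {1: "primary", 2: "secondary", 3: "tertiary", 4: "quaternary"}.get(
        order, f"order {order}")
    print(f"  {label:>10}: {count}")
print(f"ACI = {value:.2f} -> {ax.classify_arbor(value)} arbor")

# ACI is the mean branch order: 1.0 for a purely primary arbor; arbors at
# or above 1.4 are classed complex (elaborate higher-order branching).
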