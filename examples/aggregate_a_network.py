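"""Flatten a small causal network model into one aggregated HYP.

A reference node A activates B and inhibits C; each node carries downstream
genes.  Signs below the inhibited node C are inverted in the aggregate, and
a gene asserted with contradictory adjusted signs is dropped.
"""

from npascore import CausalNetwork, DownstreamEdge, Hyp, aggregate_network, check_consistency

net = CausalNetwork(
    nodes={"A", "B", "C"},
    edges=[("A", "B", +1), ("A", "C", -1)],
    node_hyps={
        "B": Hyp("B", [DownstreamEdge("IL6", +1), DownstreamEdge("CXCL1", +1)]),
        "C": Hyp("C", [DownstreamEdge("CXCL1", +1), DownstreamEdge("CCL2", +1)]),
    },
    reference="A",
)

print("node signs relative to reference:", check_consistency(net))
agg = aggregate_network(net)
print("aggregated HYP (upstream =", agg.upstream + "):")
for d in agg.downstreams:
    print(f"  {d.gene:<8} sign {d.sign:+d}")
print("dropped as ambiguous:", agg.dropped_ambiguous)
print("\nCCL2 flips to -1 (it sits below the inhibited node C); CXCL1 is")
print("asserted +1 via B but -1 via C after adjustment, so it is dropped.")
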