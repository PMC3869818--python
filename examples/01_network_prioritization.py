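"""Rank candidate disease genes by random walk with restart.

Builds a small weighted functional linkage network, seeds the walk at two
confirmed disease genes, and prints the candidate ranking.  Scores are
stationary visiting probabilities: higher means closer, in the
weighted-topology sense, to the seed set.
"""

from netconverge import FunctionalLinkageNetwork, RwrParameters, prioritize

net = FunctionalLinkageNetwork.from_edges([
    ("SNCA", "MAPT", 0.9), ("SNCA", "APP", 0.7), ("MAPT", "APP", 0.6),
    ("SNCA", "RAF1", 0.4), ("MAPT", "PKN1", 0.3), ("RAF1", "CDK1", 0.5),
    ("APP", "IDE", 0.8), ("IDE", "TCF7L2", 0.9), ("APP", "LAMA1", 0.5),
    ("TCF7L2", "LAMA1", 0.4), ("GCKR", "TCF7L2", 0.7), ("ACTB", "GAPDH", 0.3),
])

result = prioritize(net, seeds=["SNCA", "MAPT"], params=RwrParameters(alpha=0.5))
print("candidates ranked by proximity to the {SNCA, MAPT} seed set:")
print(result.candidate_table.to_string(index=False,
                                       formatters={"score": "{:.3e}".format}))
print(f"\nwalk converged in {result.rwr.iterations} iterations; "
      f"scores over all {net.n_nodes} genes sum to "
      f"{result.full_table['score'].sum():.6f}")
print("APP outranks the other candidates because it neighbors both seeds "
      "with high weight; weakly attached neighbors rank below it.")
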