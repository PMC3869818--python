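"""Intersect two diseases' candidate neighborhoods on a synthetic network.

Generates the default planted two-module network (two diseases whose gene
modules overlap), prioritizes candidates for each disease from 10 seed
genes, intersects the neighborhoods, and checks recovery of the planted
overlap.
"""

from netconverge import (evaluate_shared_recovery, make_paperlike_bundle,
                         rank_shared)

bundle = make_paperlike_bundle(seed=17)
metrics = evaluate_shared_recovery(bundle.network, bundle.module_truth,
                                   bundle.seeds_a, bundle.seeds_b)

print("Venn decomposition of the two candidate neighborhoods:")
print("  disease A only:", metrics["venn"]["a_only"],
      "| shared:", metrics["venn"]["shared"],
      "| disease B only:", metrics["venn"]["b_only"])
print(f"planted-overlap recovery: AUC = {metrics['recovery_auc']:.3f}, "
      f"membership = {100 * metrics['membership_fraction']:.1f}% "
      f"of {metrics['n_target']} non-seed overlap genes")

ranked = rank_shared(bundle.network, bundle.seeds_a, bundle.seeds_b,
                     metrics["shared"])
print("\ntop 5 shared genes by union-seeded walk:")
print(ranked.head(5).to_string(index=False,
                               formatters={"score": "{:.3e}".format}))
print("\nHigh AUC means union-walk scores cleanly separate planted overlap "
      "genes from background; the shared set is where both diseases' "
      "neighborhoods converge.")
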