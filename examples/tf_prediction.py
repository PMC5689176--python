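"""Transcription-factor prediction: refine terminals before reconstruction.

When terminals come from differential expression, the direct signal
often ends at transcription factors.  This example asks which TFs are
enriched for the terminals among their known targets (hypergeometric
test, BH-corrected) and shows how the terminal set is refined.
"""

from anchornet import predict_tfs

universe = {f"g{i}" for i in range(50)} | {"TF_A", "TF_B"}
tf_targets = {
    "TF_A": {"g0", "g1", "g2", "g3", "g40"},   # covers 4 of 5 terminals
    "TF_B": {f"g{i}" for i in range(20, 45)},  # broad, unspecific regulon
}
terminals = {"g0", "g1", "g2", "g3", "g10"}

results, refined, tf_terminals = predict_tfs(tf_targets, terminals, universe, fdr=0.05)

print("TF enrichment:")
for r in results:
    flag = "*" if r.enriched else " "
    print(f" {flag} {r.tf}: targets={r.n_targets} overlap={r.overlap} "
          f"p={r.p_value:.3g} q={r.q_value:.3g}")
print(f"enriched TFs (new terminals for the anchored search): {sorted(tf_terminals)}")
print(f"refined terminals (covered by an enriched TF): {sorted(refined)}")
print(f"eliminated as likely expression noise: {sorted(terminals - refined)}")

# TF_A's tight regulon is enriched; g10, covered by no enriched TF, is
# dropped, reducing measurement noise in the downstream reconstruction.
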