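"""Compare signature panels with the Hellinger distance.

Mutational signatures are probability distributions over the 96 SBS
channels, so they are compared with a metric made for distributions:
H(p, q) = (1/sqrt 2) * ||sqrt(p) - sqrt(q)||_2, which is 0 for identical
profiles and 1 for disjoint ones. The printed matrix shows all pairwise
distances within the six-signature panel; low off-diagonal values flag the
signature pairs a fitting procedure can confuse.
"""

from sigsolve import distance_matrix, hellinger, six_signature_panel

panel = six_signature_panel()
D = distance_matrix(panel, panel)
print("pairwise Hellinger distances:")
print(D.round(2).to_string())

closest = min(
    ((q, r, D.loc[q, r]) for q in D.index for r in D.columns if q != r),
    key=lambda t: t[2],
)
print(f"\nmost confusable pair: {closest[0]} vs {closest[1]} "
      f"(HDS = {closest[2]:.2f})")
print(f"sanity: self-distance of {panel.names[0]} = "
      f"{hellinger(panel.probs[0], panel.probs[0]):.1f}, "
      f"disjoint point masses = {hellinger([1, 0], [0, 1]):.1f}")
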