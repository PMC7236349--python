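"""Topology distances between phylogenies.

Compares two trees that differ by one leaf move, with Robinson-Foulds
(counts mismatched splits) and Matching Split (pairs up the splits and
sums how many leaves each pair disagrees on — more sensitive to small
rearrangements).  Normalized MS divides by the expected distance between
random Yule trees of the same size, giving a 0..~1 similarity scale.
"""

import aamodel as am

a = am.parse_newick("((((A,B),C),(D,E)),(F,(G,H)));")
b = am.parse_newick("((((A,C),B),(D,E)),(F,(G,H)));")  # B and C swapped

print("tree 1:", am.to_newick(a).strip())
print("tree 2:", am.to_newick(b).strip())
print("Robinson-Foulds:", am.robinson_foulds(a, b))
print("Matching Split: ", am.matching_split_distance(a, b))
print("normalized MS (Yule baseline):",
      round(am.normalized_ms(a, b, null_model="yule", n_samples=200, seed=1), 4))

far = am.random_tree(8, seed=5, labels=[*"ABCDEFGH"])
print("\nagainst an unrelated random tree:")
print("Robinson-Foulds:", am.robinson_foulds(a, far))
print("Matching Split: ", am.matching_split_distance(a, far))
print("normalized MS:  ",
      round(am.normalized_ms(a, far, null_model="yule", n_samples=200, seed=1), 4))
print("\nnear 0 = almost identical topologies; near 1 = as different as random trees")
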