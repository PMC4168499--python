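"""Fuzzy-similarity retrieval from a small entropy-profile case library.

Uses the four-profile worked-example library. The query duplicates the
library's relaxed profile (case4); retrieval must rank case4 first with
similarity 1, its near neighbor case14 second, and the two low-entropy
stressed profiles (case13, case15) last.
"""

from physiofuse import Case, local_fuzzy_similarity, reference_case_library, retrieve

lib = reference_case_library()
query = Case(case_id="new-recording", features=lib.cases[0].features)

print("local fuzzy similarity of single values (fuzz fraction 0.5):")
for a, b in [(1.7, 1.7), (1.6929, 1.6420), (1.6929, 1.2992)]:
    print(f"  sim({a}, {b}) = {local_fuzzy_similarity(a, b):.4f}")

result = retrieve(query, lib, k=2)
print("\nranking of the library against the query profile:")
for rank, (cid, sim, label) in enumerate(result.ranked, start=1):
    print(f"  {rank}. {cid:<8} similarity={sim:.4f}  class={label}")

top2 = [cid for cid, _, _ in result.top]
print(f"\nK=2 retrieval returns {top2}; with the top-1 class as the point "
      f"prediction the query is classified {result.top[0][2]}.")
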