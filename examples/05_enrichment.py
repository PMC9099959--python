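"""Hypergeometric over-representation analysis of a top-protein list.

For each pathway: given N universe proteins, K pathway members, n
selected proteins and k of them in the pathway, the enrichment p-value
is the upper tail P(X >= k) of the hypergeometric distribution.
"""

from toxsig.enrichment import (
    PathwayMap,
    enrich_pathways,
    hypergeom_tail,
    results_to_frame,
)

# direct tail computation: 4 marked proteins in a universe of 10,
# drawing 5, seeing at least 2
print(f"P(X >= 2 | N=10, K=4, n=5) = {hypergeom_tail(10, 4, 5, 2):.4f}")

pmap = PathwayMap(
    pathways={
        "dna_repair": {f"P{i:02d}" for i in range(0, 12)},
        "inflammation": {f"P{i:02d}" for i in range(10, 24)},
        "metabolism": {f"P{i:02d}" for i in range(24, 60)},
    },
    universe_size=60,
)
top = [f"P{i:02d}" for i in (0, 1, 2, 3, 4, 30, 45)]  # 5 repair + 2 metabolic hits
results = enrich_pathways(top, pmap, min_overlap=2)
print(results_to_frame(results, bh=True).to_string(index=False))
# dna_repair is heavily over-represented (5 of its 12 members in a
# 7-protein selection from 60), metabolism is consistent with chance.
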