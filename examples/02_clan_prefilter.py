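"""Pfam-clan pre-filtering and clan clustering on a toy annotation set.

Shows the three retention rules: shared clan, the no-domain fallback, and
the unmatched-clan fallback — plus the transitive clan clusters.
"""

from plmhomology import (
    ClanMap,
    DomainAnnotation,
    assign_clans,
    cluster_by_clan,
    prefilter_pairs,
)

ann = lambda pid, *fams: DomainAnnotation(pid, frozenset(fams))
clan_map = ClanMap({"PF00001": "CL0001", "PF00002": "CL0001", "PF00003": "CL0002"})

queries = assign_clans(
    [ann("q_kinase", "PF00001"), ann("q_orphan"), ann("q_rare", "PF00099")],
    clan_map,
)
targets = assign_clans(
    [ann("t1", "PF00002"), ann("t2", "PF00003"), ann("t3", "PF00003")],
    clan_map,
)

pairs = prefilter_pairs(queries, targets)
print(f"retained {len(pairs)} of {3 * 3} possible pairs:")
for q, t in pairs.pairs:
    print(f"  {q:9s} -> {t}   [{pairs.provenance[(q, t)]}]")
print("q_kinase matches t1 through clan CL0001 (different families, same clan);")
print("q_orphan (no domain) and q_rare (clan absent from targets) keep all pairs.")

clusters = cluster_by_clan(queries + targets)
print("\nclan clusters (largest first):")
for c in clusters:
    print(f"  size {len(c)}: {sorted(c)}")
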