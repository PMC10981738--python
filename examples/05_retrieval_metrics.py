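"""Retrieval metrics on a hand-built ranked result.

Demonstrates the SCOP-level TP/FP/ignore judging rules and the four
metrics: sensitivity to the first FP (averaged: AUROC), weighted AUPR, MAP
and P@K.
"""

from plmhomology import metric_report, judge_results, stratum_sizes
from plmhomology.pipeline import SearchHit, SearchResult
from plmhomology.records import FoldLabel

labels = {
    "q": FoldLabel("q", "fam.a", "sf.a", "foldA"),
    "t_samefam": FoldLabel("t_samefam", "fam.a", "sf.a", "foldA"),
    "t_samesf": FoldLabel("t_samesf", "fam.b", "sf.a", "foldA"),
    "t_samefold": FoldLabel("t_samefold", "fam.c", "sf.b", "foldA"),
    "t_other": FoldLabel("t_other", "fam.d", "sf.c", "foldB"),
}

hits = (
    SearchHit("t_samefam", 0.95, 1),
    SearchHit("t_samefold", 0.80, 2),
    SearchHit("t_other", 0.60, 3),
    SearchHit("t_samesf", 0.40, 4),
)
results = [SearchResult("q", hits)]

for level in ("family", "superfamily", "fold"):
    judged = judge_results(results, level, fold_labels=labels)
    print(f"{level:12s}:",
          {h.target_id: h.label for h in judged["q"]})

judged = judge_results(results, "fold", fold_labels=labels)
sizes = stratum_sizes(labels, "fold")
report = metric_report(judged, ks=(1, 2), weights={"q": 1.0 / sizes["q"]})
print(f"fold-level AUROC = {report['auroc']:.3f}  "
      "(the one fold-level TP is ranked above the first FP)")
print(f"fold-level MAP   = {report['map']:.3f}")
print(f"P@1 = {report['p_at_k'][1]:.1f}, P@2 = {report['p_at_k'][2]:.1f}")
print("same-family and same-superfamily hits are 'ignore' at fold level: they")
print("count neither for nor against the method.")
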