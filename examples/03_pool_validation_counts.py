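"""Micro-average diagnostic metrics over several validation cohorts.

Per-cohort results reported as correct/total tallies are pooled by summing
confusion counts before computing metrics — the convention for multi-dataset
validation of a diagnostic signature. The tallies below are the validation
cohorts of the liver-cancer gene-pair signature study this package
implements: seven HCC cohorts (truth positive) and two cirrhosis cohorts
(truth negative).
"""

import numpy as np

import reosig as rs

hcc_tallies = [(29, 29), (245, 245), (44, 140), (183, 183),
               (152, 152), (70, 70), (371, 371)]
cwohcc_tallies = [(44, 44), (18, 18)]


def counts_from_tally(name, correct, total, truth_positive):
    ids = [f"{name}_{i}" for i in range(total)]
    truth = rs.SampleLabels(ids, np.full(total, truth_positive, dtype=bool))
    pred_vals = np.empty(total, dtype=bool)
    pred_vals[:correct] = truth_positive
    pred_vals[correct:] = not truth_positive
    return rs.confusion(rs.SampleLabels(ids, pred_vals), truth)


counts = [counts_from_tally(f"hcc{i}", c, t, True)
          for i, (c, t) in enumerate(hcc_tallies)]
counts += [counts_from_tally(f"cwo{i}", c, t, False)
           for i, (c, t) in enumerate(cwohcc_tallies)]

pooled = rs.micro_average(counts)
pct = pooled.as_percent(2)
c = pooled.counts
print(f"pooled confusion counts: TP={c.tp} FN={c.fn} TN={c.tn} FP={c.fp}")
print(f"pooled sensitivity: {pct['sensitivity']}%  "
      f"({c.tp}/{c.n_pos_truth} HCC samples recognised)")
print(f"pooled specificity: {pct['specificity']}%  "
      f"({c.tn}/{c.n_neg_truth} cirrhosis samples recognised)")

# Micro-averaging weights every sample equally, so large cohorts dominate;
# the one weak cohort (44/140) pulls pooled sensitivity below the per-cohort
# median of 100%.
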