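"""Score FFMQ-39 item responses and compare group score distributions.

Builds a small random response table, scores it with the packaged item map,
then reproduces a summary-statistics group comparison (Welch t-test and
pooled Cohen's d) between two samples.
"""

import numpy as np
import pandas as pd

from mindcpm import GroupSummary, cohens_d, score_ffmq, welch_t
from mindcpm.ffmq import ITEM_COLUMNS

rng = np.random.default_rng(0)
items = pd.DataFrame(
    rng.integers(1, 6, size=(5, 39)), columns=ITEM_COLUMNS,
    index=[f"s{i}" for i in range(5)],
)
scores = score_ffmq(items)
print(scores.round(1))
# Each row: facet sums (AA, NJ, NR, D, O), the total (39..195) and the
# total without the observing facet.

a = GroupSummary(n=206, mean=134.8, sd=17.8)
b = GroupSummary(n=82, mean=126.8, sd=17.4)
t, df, p = welch_t(a, b)
d = cohens_d(a, b)
print(f"\nWelch t({df:.2f}) = {t:.2f}, p = {p:.4g}, Cohen's d = {d:.3f}")
# The first sample scores ~8 points higher in trait mindfulness; t ~ 3.50
# marks that difference as highly reliable, with a small-to-medium d.
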