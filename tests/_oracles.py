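"""Independent reference implementations used only by the test suite.

These deliberately re-derive each statistic the slow, literal way so the
package implementations are checked against something that shares no code
with them.
"""

import itertools

import numpy as np
from scipy.stats import rankdata


def running_sum_es(values, in_set_mask, alpha):
    """Positional ssGSEA running sum, walked gene by gene.

    Exact for untied data (ranks from the average-rank statistic).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    ranks = rankdata(values, method="average")
    order = np.argsort(-values, kind="stable")
    w = np.where(in_set_mask, ranks**alpha, 0.0)
    w_total = w.sum()
    n_out = n - in_set_mask.sum()
    es, p_in, p_out = 0.0, 0.0, 0.0
    for pos in order:
        if in_set_mask[pos]:
            p_in += w[pos] / w_total
        else:
            p_out += 1.0 / n_out
        es += p_in - p_out
    return es


def brute_force_auc(y_true, scores):
    """All-pairs ranking AUC with half-credit for ties."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))
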