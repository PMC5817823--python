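"""Shared test utilities: independent oracles and parameter variants."""

import numpy as np

import naranjo as na


def mann_whitney_auc(pos, neg):
    """Brute-force tie-corrected Mann-Whitney statistic.

    P(S+ > S-) + 0.5 P(S+ = S-) over all positive/negative pairs; an
    O(n^2) oracle independent of the ROC staircase implementation.
    """
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    gt = (pos[:, None] > neg[None, :]).mean()
    eq = (pos[:, None] == neg[None, :]).mean()
    return float(gt + 0.5 * eq)


def moderate_params(shrink=0.5):
    """Calibrated parameters with class separation shrunk toward the
    marginal mixture, giving a moderate-discrimination cohort (model AUC
    around 0.83 at the default shrink) where normal-approximation
    confidence intervals are far from the boundary."""
    p = na.calibrate()
    prev = p.prevalence
    counts = {}
    for cid in range(1, 11):
        pa = p.probabilities(cid, True)
        pn = p.probabilities(cid, False)
        mix = {a: prev * pa[a] + (1 - prev) * pn[a] for a in pa}
        counts[cid] = {
            "ADR": {
                a: p.n_adr * ((1 - shrink) * pa[a] + shrink * mix[a]) for a in pa
            },
            "NOT_ADR": {
                a: p.n_not_adr * ((1 - shrink) * pn[a] + shrink * mix[a]) for a in pa
            },
        }
    return na.CohortParameters(class_counts=counts)
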