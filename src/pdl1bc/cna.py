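"""Copy-number calls at a single locus and their association with expression.

Input is a per-sample log2 DNA copy ratio versus normal DNA (segmentation is
upstream of this module).  States follow symmetric fold-change thresholds:
1.5x for gain/loss and 2x for amplification/homozygous deletion, boundaries
assigned to the altered state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

GAIN_THRESHOLD = math.log2(1.5)
AMP_THRESHOLD = 1.0  # log2(2)

STATES = ("homozygous_deletion", "loss", "neutral", "gain", "amplification")
GAINED_STATES = ("gain", "amplification")


@dataclass
class CnaCall:
    sample_id: str
    log2_ratio: float
    state: str


def call_cna(log2_ratio: float) -> str:
    """Discretize one log2 copy ratio into the five-state vocabulary."""
    r = float(log2_ratio)
    if not np.isfinite(r):
        raise ValueError("log2 ratio must be finite")
    if r >= AMP_THRESHOLD:
        return "amplification"
    if r >= GAIN_THRESHOLD:
        return "gain"
    if r <= -AMP_THRESHOLD:
        return "homozygous_deletion"
    if r <= -GAIN_THRESHOLD:
        return "loss"
    return "neutral"


def call_cna_vector(log2_ratios) -> np.ndarray:
    return np.array([call_cna(r) for r in np.asarray(log2_ratios, float)])


def cna_expression_association(states, expression,
                               equal_var: bool = True) -> tuple[float, float]:
    """Two-sided t-test of expression in gained/amplified vs other samples.

    Pooled-variance (Student) t by default; set ``equal_var=False`` for
    Welch.  Returns (t, p); t > 0 means higher expression in the gained
    group.
    """
    states = np.asarray(states)
    expr = np.asarray(expression, dtype=float)
    gained = np.isin(states, GAINED_STATES)
    if gained.sum() < 2 or (~gained).sum() < 2:
        raise ValueError("need at least 2 samples in each group")
    res = stats.ttest_ind(expr[gained], expr[~gained], equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)
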