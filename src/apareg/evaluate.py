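"""Scoring caller output against a simulation truth ledger.

A pair is called positive when its adjusted p-value falls below alpha;
the ground-truth positives are the condition-driven APA pairs
('condition-APA').  Pairs whose ratio is moved only by a nuisance
covariate ('covariate-APA') are null with respect to the condition, so
calling them is a false positive.  The Matthews Correlation Coefficient
summarizes the confusion matrix in one balanced number in [-1, 1].
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd


@dataclass
class EvaluationReport:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def mcc(self) -> float:
        denom = ((self.tp + self.fp) * (self.tp + self.fn)
                 * (self.tn + self.fp) * (self.tn + self.fn))
        if denom == 0:
            return 0.0
        return (self.tp * self.tn - self.fp * self.fn) / math.sqrt(denom)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(sensitivity=self.sensitivity, specificity=self.specificity,
                 mcc=self.mcc)
        return d

    def write_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def evaluate(results: pd.DataFrame, truth: pd.DataFrame,
             alpha: float = 0.05) -> EvaluationReport:
    """Confusion matrix of calls (p_adjusted < alpha) against the ledger.

    Every tested pair must appear in the truth table; pairs with no
    p-value (filtered/untestable) count as negative calls.
    """
    t = truth.set_index("pair_id")["truth"]
    missing = set(results["pair_id"]) - set(t.index)
    if missing:
        raise ValueError(f"pairs absent from truth ledger: {sorted(missing)[:5]} ...")
    labels = t.loc[results["pair_id"]].to_numpy()
    called = (results["p_adjusted"].to_numpy() < alpha) & np.isfinite(
        results["p_adjusted"].to_numpy())
    is_pos = labels == "condition-APA"
    tp = int(np.sum(called & is_pos))
    fp = int(np.sum(called & ~is_pos))
    fn = int(np.sum(~called & is_pos))
    tn = int(np.sum(~called & ~is_pos))
    return EvaluationReport(tp=tp, fp=fp, tn=tn, fn=fn)
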