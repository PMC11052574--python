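"""Sign/magnitude taxonomy of significant interaction models.

The signs of the genotype (b1), accessibility (b2) and interaction (b3)
coefficients classify how the two regulatory inputs combine:

* all three signs equal -> **synergy**: the pair pushes expression further
  than the sum of the marginals;
* main effects agree, interaction opposes them -> **redundancy_interference**:
  an 'or'-like logic where the combined result falls short of additivity;
* main effects disagree -> **mixed**: the interaction moves the additive
  expectation toward one of the two marginal outcomes;
* any of the three terms absent from the retained set -> **incomplete**.

Coefficients within 1e-12 of zero take sign 0, class mixed, and are flagged
(OLS on float data never yields exact zeros outside degenerate constructions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

ZERO_TOL = 1e-12
LABELS = ("synergy", "redundancy_interference", "mixed", "incomplete")


@dataclass(frozen=True)
class EffectClass:
    """Taxonomy label plus the sign pattern and magnitude-ordering flags."""

    label: str
    sign_pattern: tuple[int, int, int]
    magnitude_flags: tuple[bool, bool, bool]  # |b3|>|b2|, |b3|>|b1|, |b3|>both
    zero_flagged: bool = False

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


def _sign(x: float) -> int:
    if abs(x) <= ZERO_TOL:
        return 0
    return 1 if x > 0 else -1


def classify_signs(betas, retained: Iterable[str]) -> EffectClass:
    """Classify one model's (b0, b1, b2, b3) by coefficient sign pattern.

    ``retained`` is the AIC-retained term set; any of x1, x2, x1x2 missing
    gives label ``incomplete``.
    """
    b = np.asarray(betas, dtype=float)
    if b.shape != (4,):
        raise ValueError("betas must be (b0, b1, b2, b3)")
    if not np.all(np.isfinite(b)):
        raise ValueError("betas must be finite")
    _, b1, b2, b3 = b
    s = (_sign(b1), _sign(b2), _sign(b3))
    mags = (abs(b3) > abs(b2), abs(b3) > abs(b1), abs(b3) > abs(b2) and abs(b3) > abs(b1))

    r = frozenset(retained)
    if not {"x1", "x2", "x1x2"} <= r:
        return EffectClass("incomplete", s, mags)
    if 0 in s:
        return EffectClass("mixed", s, mags, zero_flagged=True)
    if s[0] == s[1] == s[2]:
        return EffectClass("synergy", s, mags)
    if s[0] == s[1] and s[2] == -s[0]:
        return EffectClass("redundancy_interference", s, mags)
    return EffectClass("mixed", s, mags)


def _select(model_table: pd.DataFrame, interacting_only: bool) -> pd.DataFrame:
    t = model_table[model_table["significant"]]
    if interacting_only:
        t = t[t["model_class"] == "interacting"]
    return t


def magnitude_summary(model_table: pd.DataFrame, interacting_only: bool = True) -> dict:
    """Proportions of significant (interacting) models where the interaction
    coefficient dominates: |b3|>|b2|, |b3|>|b1|, |b3|>both; plus the fraction
    of models whose accessibility main effect is negative (b2 < 0).
    """
    t = _select(model_table, interacting_only)
    if t.empty:
        raise ValueError("no significant models to summarise (empty input)")
    b1 = t["beta1"].abs().to_numpy()
    b2 = t["beta2"].abs().to_numpy()
    b3 = t["beta3"].abs().to_numpy()
    n = len(t)
    return {
        "n_models": n,
        "p_interaction_gt_atac": float((b3 > b2).mean()),
        "p_interaction_gt_genotype": float((b3 > b1).mean()),
        "p_interaction_gt_both": float(((b3 > b2) & (b3 > b1)).mean()),
        "p_negative_atac_effect": float((t["beta2"] < 0).mean()),
    }


def classify_table(model_table: pd.DataFrame, interacting_only: bool = True) -> pd.DataFrame:
    """Attach an ``effect_label`` column to the significant-model subset."""
    t = _select(model_table, interacting_only).copy()
    labels = []
    for _, row in t.iterrows():
        retained = set(str(row["retained"]).split(",")) if row["retained"] else set()
        labels.append(
            classify_signs(
                (row["beta0"], row["beta1"], row["beta2"], row["beta3"]), retained
            ).label
        )
    t["effect_label"] = labels
    return t


def sign_class_distribution(model_table: pd.DataFrame, interacting_only: bool = True) -> dict:
    """Counts and fractions per taxonomy label over classified models.

    Empty input returns zero counts and no fractions.
    """
    if model_table.empty or not model_table["significant"].any():
        return {"counts": {lab: 0 for lab in LABELS}, "fractions": {}}
    t = classify_table(model_table, interacting_only)
    counts = t["effect_label"].value_counts().reindex(LABELS, fill_value=0)
    total = int(counts.sum())
    fractions = {lab: counts[lab] / total for lab in LABELS} if total else {}
    return {"counts": {lab: int(counts[lab]) for lab in LABELS}, "fractions": fractions}
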