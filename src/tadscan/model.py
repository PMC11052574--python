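"""Model/Results objects over the trio regression and the genome scan.

``TrioInteractionModel`` mirrors the fit-one-model workflow: construct from
the three sample-aligned vectors (or a tidy DataFrame), call ``fit()``, read
coefficients, standard errors and the interaction F-test off the results.
``InteractionScan`` is the genome-scale counterpart whose ``fit()`` returns a
:class:`tadscan.scan.ScanResults`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import SyntheticDataset
from .scan import ScanPlan, ScanResults, TrioFit, fit_and_classify, run_scan

PARAM_NAMES = ("Intercept", "genotype", "atac", "genotype:atac")


class TrioInteractionResults:
    """Results of one trio fit: estimates, uncertainties, selection, test."""

    def __init__(self, fit: TrioFit):
        self._fit = fit

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._fit.betas, index=PARAM_NAMES)

    @property
    def bse(self) -> pd.Series:
        if self._fit.bse is None:
            return pd.Series(np.nan, index=PARAM_NAMES)
        return pd.Series(self._fit.bse, index=PARAM_NAMES)

    @property
    def retained(self):
        return self._fit.retained

    @property
    def model_class(self):
        return self._fit.model_class

    @property
    def f_stat(self) -> float:
        return self._fit.f_stat

    @property
    def p_value(self) -> float:
        return self._fit.p_raw

    @property
    def df_resid(self) -> int:
        return self._fit.n - 4

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.t.ppf(1 - alpha / 2, self.df_resid)
        lo = self.params - q * self.bse
        hi = self.params + q * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Trio interaction model (OLS)",
            "=" * 58,
            f"n = {self._fit.n}    df_resid = {self.df_resid}",
            f"model class (AIC retention): {self.model_class}",
            f"interaction F(1, {self.df_resid}) = {self.f_stat:.4g}"
            f"   p = {self.p_value:.3g}",
            "-" * 58,
            f"{'term':<16}{'coef':>10}{'se':>10}{'[0.025':>10}{'0.975]':>10}",
        ]
        for name in PARAM_NAMES:
            lines.append(
                f"{name:<16}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}"
                f"{ci.loc[name, 'lower']:>10.4f}{ci.loc[name, 'upper']:>10.4f}"
            )
        return "\n".join(lines)


class TrioInteractionModel:
    """y = b0 + b1*genotype + b2*atac + b3*genotype*atac + eps."""

    def __init__(self, y, genotype, atac):
        self.y = np.asarray(y, dtype=float)
        self.genotype = np.asarray(genotype, dtype=float)
        self.atac = np.asarray(atac, dtype=float)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, y: str = "expression",
                       genotype: str = "genotype", atac: str = "atac"):
        return cls(data[y], data[genotype], data[atac])

    def fit(self) -> TrioInteractionResults:
        return TrioInteractionResults(fit_and_classify(self.y, self.genotype, self.atac))


class InteractionScan:
    """Genome-scale scan model: a dataset plus an enumeration plan."""

    def __init__(self, dataset: SyntheticDataset, plan: ScanPlan | None = None):
        self.dataset = dataset
        self.plan = plan or ScanPlan()

    def fit(self, chunk_size: int = 8192) -> ScanResults:
        return run_scan(self.dataset, self.plan, chunk_size=chunk_size)
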