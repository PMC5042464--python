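"""Shared result container for mixed-model fits."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MixedFitResult:
    """Fixed effects, random-effect variances and the LRT of a mixed fit.

    ``params``/``cov`` cover the fixed effects only; ``ranef_var`` maps
    random-term name to its variance.  ``chi2``/``df``/``p`` refer to
    the likelihood-ratio test of the stated null (the model without the
    focal fixed term).  ``contrasts`` is filled by
    :func:`symsel.assays.pairwise_contrasts`.
    """

    params: pd.Series
    cov: pd.DataFrame
    ranef_var: dict[str, float]
    loglik: float
    chi2: float | None = None
    df: int | None = None
    p: float | None = None
    converged: bool = True
    degenerate: str | None = None
    model: str = ""
    contrasts: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())),
                         index=self.params.index)

    def z(self) -> pd.Series:
        return self.params / self.se()
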