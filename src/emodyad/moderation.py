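"""Conditional-effect (simple-slopes) curves for mean x diversity interactions.

For a fitted APIM with path b1 (focal predictor), b3 (focal x moderator
product) and robust covariance V, the effect of the focal predictor at
centered moderator value x is ``b1 + b3 * x`` with delta-method variance
``V11 + x^2 V33 + 2 x V13``; the pointwise band is +/- z * SD at the
requested confidence level (0.95 for tables, 0.99 for the curve figure).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .apim import PRODUCTS, ApimFit, DesignMatrix


@dataclass
class ConditionalEffectCurve:
    moderator: str
    focal: str
    outcome: str
    level: float
    grid: np.ndarray
    effect: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    b_focal: float
    b_product: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "moderator_centered": self.grid, "effect": self.effect,
            "ci_low": self.lower, "ci_high": self.upper,
        })

    def plot(self, path) -> None:
        """Optional single-curve line plot written to ``path``."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(self.grid, self.effect, color="tab:red",
                label=f"effect of {self.focal}")
        for band in (self.lower, self.upper):
            ax.plot(self.grid, band, color="tab:blue", linewidth=0.8)
        ax.axhline(0.0, color="gray", linewidth=0.6, linestyle=":")
        ax.set_xlabel(f"{self.moderator} (centered)")
        ax.set_ylabel(f"effect on {self.outcome}")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _product_path(focal: str, moderator: str) -> str:
    for name, factors in PRODUCTS.items():
        if set(factors) == {focal, moderator}:
            return name
    raise ValueError(f"no product path for factors {focal!r} x {moderator!r}")


def conditional_effect(fit: ApimFit, focal: str, moderator: str,
                       outcome: str = "y_cg", grid: np.ndarray | None = None,
                       level: float = 0.95,
                       design: DesignMatrix | None = None) -> ConditionalEffectCurve:
    """Effect of ``focal`` on ``outcome`` across centered moderator values.

    The default grid spans moderator mean +/- 2 SD in 41 steps (the SD
    taken from ``design`` when given, else from the SDs recorded at
    standardization).
    """
    if fit.cov_robust is None:
        raise ValueError("fit has no robust covariance block; run robust_se first")
    product = _product_path(focal, moderator)
    b1 = fit.coef(outcome, focal)
    b3 = fit.coef(outcome, product)
    i1, i3 = fit.param_index(outcome, focal), fit.param_index(outcome, product)
    v1 = fit.cov_robust[i1, i1]
    v3 = fit.cov_robust[i3, i3]
    c13 = fit.cov_robust[i1, i3]

    if grid is None:
        if design is not None:
            sd = float(design.xcol(moderator).std(ddof=1))
        elif moderator in fit.sd_x:
            sd = fit.sd_x[moderator]
        else:
            raise ValueError("cannot infer a moderator grid; pass grid or design")
        grid = np.linspace(-2 * sd, 2 * sd, 41)
    grid = np.asarray(grid, dtype=float)

    effect = b1 + b3 * grid
    var = v1 + grid ** 2 * v3 + 2 * grid * c13
    sdv = np.sqrt(np.clip(var, 0.0, None))
    z = stats.norm.ppf(0.5 + level / 2)
    return ConditionalEffectCurve(
        moderator=moderator, focal=focal, outcome=outcome, level=level,
        grid=grid, effect=effect, lower=effect - z * sdv, upper=effect + z * sdv,
        b_focal=b1, b_product=b3)
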