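"""Allometric body-condition analysis by nested model comparison.

Following the regression approach to fish condition (rather than ratio
indices), mass is regressed on length on the log scale and four nested
grouped models are compared:

* ``M_shared``      — one intercept and one slope for both groups;
* ``M_intercepts``  — group-specific intercepts, common slope;
* ``M_slopes``      — common intercept, group-specific slopes;
* ``M_full``        — group-specific intercepts and slopes.

Models are ranked by the small-sample Akaike information criterion

    AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1),

with k counting the residual variance as a parameter (so k = 3, 4, 4, 5),
and compared through Akaike weights w_i = exp(-d_i/2) / sum_j exp(-d_j/2)
where d_i is the AICc difference to the best model.

Group length distributions are compared with Bartlett's variance-
homogeneity test as a gate: one-way ANOVA (plus Tukey HSD for more than
two groups) when variances are homogeneous, the Kruskal–Wallis rank test
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MODEL_IDS",
    "ConditionDataset",
    "ConditionFit",
    "LengthComparison",
    "fit_condition_model",
    "aicc",
    "akaike_weights",
    "compare_condition",
    "compare_lengths",
    "round_half_up",
]

MODEL_IDS = ("M_shared", "M_intercepts", "M_slopes", "M_full")

#: number of regression coefficients per model (residual variance excluded)
_N_COEF = {"M_shared": 2, "M_intercepts": 3, "M_slopes": 3, "M_full": 4}

_TRANSFORMS = {
    "log10": np.log10,
    "ln": np.log,
    "none": lambda x: np.asarray(x, dtype=float),
}


@dataclass
class ConditionDataset:
    """Per-fish group label, fork length (mm) and wet mass (g)."""

    group: np.ndarray  # of str labels
    length_mm: np.ndarray
    mass_g: np.ndarray

    def __post_init__(self):
        self.group = np.asarray(self.group)
        self.length_mm = np.asarray(self.length_mm, dtype=float)
        self.mass_g = np.asarray(self.mass_g, dtype=float)
        if not (len(self.group) == len(self.length_mm) == len(self.mass_g)):
            raise ValueError("group, length_mm, mass_g must have equal length")
        if (self.length_mm <= 0).any() or (self.mass_g <= 0).any():
            raise ValueError("lengths and masses must be strictly positive")

    @property
    def labels(self) -> list:
        return list(dict.fromkeys(self.group))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ConditionDataset":
        return cls(
            group=df["group"].to_numpy(),
            length_mm=df["length_mm"].to_numpy(),
            mass_g=df["mass_g"].to_numpy(),
        )


@dataclass
class ConditionFit:
    model_id: str
    coefficients: dict  # named coefficients on the model scale
    n: int
    k: int  # parameter count including the residual variance
    rss: float
    transform: str
    aicc: Optional[float] = None
    delta_aicc: Optional[float] = None
    weight: Optional[float] = None

    def predict(self, group, length_mm) -> np.ndarray:
        """Predicted (transformed) mass for given group labels and lengths."""
        X, _ = _design(self.model_id, np.asarray(group),
                       _TRANSFORMS[self.transform](np.asarray(length_mm, float)),
                       self._group_order)
        beta = np.array([self.coefficients[name] for name in self._coef_names])
        return X @ beta

    _group_order: tuple = ()
    _coef_names: tuple = ()


def _design(model_id, group, x, labels):
    """Design matrix and coefficient names for one of the four models.

    With a single group label every model collapses to the shared line.
    """
    ones = np.ones_like(x)
    if len(labels) == 1:
        return np.column_stack([ones, x]), ("B0", "B1")
    if len(labels) != 2:
        raise ValueError(f"condition models need exactly 2 groups, got {list(labels)}")
    g1, g2 = labels
    i1 = (group == g1).astype(float)
    i2 = (group == g2).astype(float)
    if model_id == "M_shared":
        return np.column_stack([ones, x]), ("B0", "B1")
    if model_id == "M_intercepts":
        return np.column_stack([i1, i2, x]), ("B01", "B02", "B1")
    if model_id == "M_slopes":
        return np.column_stack([ones, x * i1, x * i2]), ("B0", "B11", "B12")
    if model_id == "M_full":
        return np.column_stack([i1, i2, x * i1, x * i2]), ("B01", "B02", "B11", "B12")
    raise ValueError(f"unknown model id {model_id!r}")


def fit_condition_model(
    data: ConditionDataset,
    model_id: str,
    transform: str = "log10",
    count_sigma: bool = True,
) -> ConditionFit:
    """Ordinary least squares fit of one grouped length–mass model.

    ``transform`` maps both mass and length (default log10–log10, the usual
    allometric scale).  ``count_sigma`` includes the residual variance in
    the parameter count k (default), giving k = 3, 4, 4, 5 for the four
    models.
    """
    labels = data.labels
    if len(labels) > 2:
        raise ValueError(f"condition models need at most 2 groups, got {labels}")
    f = _TRANSFORMS[transform]
    x = f(data.length_mm)
    y = f(data.mass_g)
    for lab in labels:
        mask = data.group == lab
        if mask.sum() < 3:
            raise ValueError(f"group {lab!r} has fewer than 3 fish")
        if model_id in ("M_slopes", "M_full") and np.ptp(x[mask]) == 0:
            raise ValueError(
                f"group {lab!r} has zero length variance; slope not identifiable"
            )
    X, names = _design(model_id, data.group, x, labels)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError(f"design matrix for {model_id} is rank deficient")
    resid = y - X @ beta
    rss = float(resid @ resid)
    k = X.shape[1] + (1 if count_sigma else 0)
    fit = ConditionFit(
        model_id=model_id,
        coefficients=dict(zip(names, beta.tolist())),
        n=len(y),
        k=k,
        rss=rss,
        transform=transform,
    )
    fit._group_order = tuple(labels)
    fit._coef_names = names
    return fit


def aicc(rss: float, n: int, k: int) -> float:
    """Small-sample Akaike information criterion for a Gaussian OLS fit."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    if rss < 0:
        raise ValueError("rss must be non-negative")
    return float(n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1))


def akaike_weights(aicc_values: Sequence[float]):
    """AICc differences and Akaike weights; weights sum to exactly 1."""
    vals = np.asarray(aicc_values, dtype=float)
    if vals.size == 0 or not np.isfinite(vals).all():
        raise ValueError("need at least one finite criterion value")
    delta = vals - vals.min()
    rel = np.exp(-delta / 2.0)
    return delta, rel / rel.sum()


def compare_condition(
    data: ConditionDataset,
    transform: str = "log10",
    count_sigma: bool = True,
) -> list:
    """Fit all four models on the same data and rank them by AICc."""
    fits = [
        fit_condition_model(data, mid, transform=transform, count_sigma=count_sigma)
        for mid in MODEL_IDS
    ]
    for fit in fits:
        fit.aicc = aicc(fit.rss, fit.n, fit.k)
    delta, weights = akaike_weights([fit.aicc for fit in fits])
    for fit, d, w in zip(fits, delta, weights):
        fit.delta_aicc = float(d)
        fit.weight = float(w)
    return sorted(fits, key=lambda fit: fit.aicc)


def comparison_table(fits: Sequence[ConditionFit]) -> pd.DataFrame:
    """Ranked model table with weights rounded to 2 dp (half-up) as printed."""
    return pd.DataFrame(
        {
            "model": [f.model_id for f in fits],
            "k": [f.k for f in fits],
            "aicc": [f.aicc for f in fits],
            "delta_aicc": [f.delta_aicc for f in fits],
            "weight": [f.weight for f in fits],
            "weight_2dp": [round_half_up(f.weight, 2) for f in fits],
        }
    )


def round_half_up(value: float, ndigits: int) -> float:
    """Decimal half-up rounding, as used for printed model weights."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class LengthComparison:
    bartlett_stat: Optional[float]
    bartlett_p: Optional[float]
    chosen_test: str  # "ANOVA" or "Kruskal-Wallis"
    statistic: float
    df: tuple  # (between df, residual df) for ANOVA; (df,) for Kruskal-Wallis
    p_value: float
    pairwise: Optional[pd.DataFrame] = None  # Tukey HSD, ANOVA with >2 groups
    note: Optional[str] = None


def compare_lengths(
    data: ConditionDataset, alpha: float = 0.05
) -> LengthComparison:
    """Compare group length distributions with a variance-gated test.

    Bartlett's test decides between one-way ANOVA (homoscedastic, with
    Tukey HSD pairwise comparisons when more than two groups) and the
    Kruskal–Wallis rank test (heteroscedastic).  A group with zero length
    variance makes Bartlett undefined; the comparison then falls through to
    Kruskal–Wallis with a note.
    """
    labels = data.labels
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [data.length_mm[data.group == lab] for lab in labels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least 2 fish")

    note = None
    if any(np.ptp(s) == 0 for s in samples):
        b_stat = b_p = None
        heteroscedastic = True
        note = "a group has zero length variance; Bartlett undefined, using Kruskal-Wallis"
    else:
        b_stat, b_p = stats.bartlett(*samples)
        heteroscedastic = b_p < alpha

    if heteroscedastic:
        stat, p = stats.kruskal(*samples)
        return LengthComparison(
            bartlett_stat=b_stat,
            bartlett_p=b_p,
            chosen_test="Kruskal-Wallis",
            statistic=float(stat),
            df=(len(labels) - 1,),
            p_value=float(p),
            note=note,
        )

    stat, p = stats.f_oneway(*samples)
    df_between = len(labels) - 1
    df_resid = sum(len(s) for s in samples) - len(labels)
    pairwise = None
    if len(labels) > 2:
        tk = stats.tukey_hsd(*samples)
        rows = []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                lo, hi = tk.confidence_interval().low[i, j], tk.confidence_interval().high[i, j]
                rows.append(
                    {
                        "group_a": labels[i],
                        "group_b": labels[j],
                        "mean_diff": float(tk.statistic[i, j]),
                        "p_value": float(tk.pvalue[i, j]),
                        "ci_low": float(lo),
                        "ci_high": float(hi),
                    }
                )
        pairwise = pd.DataFrame(rows)
    return LengthComparison(
        bartlett_stat=float(b_stat),
        bartlett_p=float(b_p),
        chosen_test="ANOVA",
        statistic=float(stat),
        df=(df_between, df_resid),
        p_value=float(p),
        pairwise=pairwise,
    )
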