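"""QSPR layer: embedded property data and entropy-based regression models.

The property table records, for each of the 29 catalog molecules: boiling
point BP (deg C), octanol-water LogP, molar refractivity MR (cm^3/mol),
enthalpy of vaporization E (kJ/mol), flash point FP (deg C), polarizability
P (A^3), molecular weight MW (g/mol), XLogP3, PubChem complexity C, and
total Hückel pi-electronic energy PE (units of the resonance integral beta).
PE is consumed as tabulated data, never recomputed from molecular-orbital
theory.  Values are a frozen transcription of the published compilation
(original experimental sources: PubChem / ChemSpider); where the published
row disagrees with the standard value (e.g. the BH27 molecular weight), the
published number is kept, since the table is consumed as data.

Models are ordinary least squares with intercept:

* simple linear,   property = alpha + beta * entropy;
* multilinear on the five predictors E_DABC, E_DM2, E_DHM, E_DM2*, E_DM3*.

Reported statistics follow QSPR conventions: r is the magnitude of the
(multiple) correlation coefficient, SE = sqrt(RSS / (n - k - 1)) the residual
standard error, F the overall F statistic with (k, n - k - 1) degrees of
freedom and p its tail probability.  The five entropy predictors are strongly
collinear on benzenoids, which makes individual multilinear coefficients
ill-determined (huge, opposite-signed) even though the fit itself is stable;
fits therefore carry a condition-number diagnostic of the standardized
design, and r/SE/F — not coefficients — are the quantities to compare across
implementations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .entropy import ENTROPY_COLUMNS, entropy_table

PROPERTY_COLUMNS = ("BP", "LogP", "MR", "E", "FP", "P", "MW", "XLogP3", "C", "PE")

#: Predictors of the multilinear model.
MULTILINEAR_PREDICTORS = ("E_DABC", "E_DM2", "E_DHM", "E_DM2*", "E_DM3*")

#: Condition number of the standardized design above which a fit is annotated
#: as collinear.
COLLINEARITY_THRESHOLD = 30.0

_PROPERTY_DATA = {
    #        BP     LogP   MR      E     FP     P     MW      XLogP3  C    PE
    "BH1": (80.1, 2.03, 25.28, 30.7, -11.1, 10.4, 78.11, 2.1, 15.5, 8.0),
    "BH2": (218.0, 3.03, 42.45, 43.9, 78.9, 17.5, 128.17, 3.3, 80.6, 13.6832),
    "BH3": (340.0, 4.03, 59.62, 55.8, 146.6, 24.6, 178.23, 4.4, 154.0, 19.3137),
    "BH4": (340.0, 4.03, 59.62, 55.8, 146.6, 24.6, 178.23, 4.5, 174.0, 19.4483),
    "BH5": (432.02, 5.9, 76.79, 66.7, 209.1, 31.6, 228.3, 5.9, 236.0, 24.9308),
    "BH6": (436.7, 5.03, 76.79, 66.7, 209.1, 31.6, 228.3, 5.7, 266.0, 25.1875),
    "BH7": (438.0, 5.03, 76.79, 66.7, 209.1, 31.6, 228.3, 5.8, 294.0, 25.1012),
    "BH8": (448.0, 5.03, 76.79, 67.9, 209.1, 31.6, 228.3, 5.7, 264.0, 25.1922),
    "BH9": (438.0, 5.03, 76.79, 65.3, 209.1, 31.6, 228.3, 4.9, 217.0, 25.2745),
    "BH10": (404.0, 5.08, 68.36, 63.0, 168.8, 28.7, 202.25, 4.9, 217.0, 22.5055),
    "BH11": (524.6, 6.02, 93.96, 76.9, 264.5, 38.7, 278.3, 6.7, 325.0, 30.544),
    "BH12": (547.5, 6.02, 93.96, 76.9, 264.5, 38.7, 278.3, 6.7, 399.0, 30.7255),
    "BH13": (524.0, 6.02, 93.96, 76.9, 264.5, 38.7, 278.3, 6.5, 361.0, 30.8805),
    "BH14": (524.7, 6.02, 93.96, 76.9, 264.5, 38.7, 278.3, 6.5, 363.0, 30.8795),
    "BH15": (547.5, 6.02, 93.96, 76.9, 264.5, 38.7, 278.3, 6.7, 361.0, 30.7627),
    "BH16": (525.0, 6.02, 93.96, 76.9, 264.5, 38.7, 278.3, 7.0, 399.0, 30.999),
    "BH17": (524.7, 6.02, 93.96, 76.9, 264.5, 38.7, 278.3, 7.0, 361.0, 30.9362),
    "BH18": (524.7, 6.02, 93.96, 76.9, 264.5, 38.7, 278.3, 7.0, 399.0, 30.9386),
    "BH19": (520.0, 6.02, 93.96, 76.2, 264.5, 38.7, 278.3, 7.0, 361.0, 30.9432),
    "BH20": (524.7, 6.02, 93.96, 76.9, 264.5, 38.7, 278.3, 6.5, 399.0, 30.839),
    "BH21": (518.0, 6.02, 93.96, 76.1, 264.5, 38.7, 278.3, 6.7, 361.0, 30.9418),
    "BH22": (524.7, 6.02, 93.96, 76.1, 264.5, 38.7, 278.3, 6.5, 399.0, 30.8336),
    "BH23": (400.0, 5.34, 85.53, 70.2, 228.6, 35.8, 252.3, 5.8, 304.0, 28.2453),
    "BH24": (467.5, 5.34, 85.53, 70.2, 228.6, 35.8, 252.3, 6.4, 336.0, 28.3361),
    "BH25": (495.0, 5.34, 85.53, 73.4, 228.6, 35.8, 252.3, 6.0, 372.0, 28.222),
    "BH26": (604.1, 7.45, 115.5, 86.5, 314.6, 45.8, 328.4, 7.9, 464.0, 36.6814),
    "BH27": (500.0, 5.66, 94.28, 74.1, 247.2, 40.0, 328.4, 6.6, 411.0, 31.4251),
    "BH28": (604.0, 7.02, 111.13, 86.5, 314.6, 45.8, 328.4, 8.2, 418.0, 36.1557),
    "BH29": (525.0, 5.98, 103.02, 77.0, 265.2, 44.1, 300.4, 7.2, 376.0, 34.5718),
}


def property_table() -> pd.DataFrame:
    """The embedded physicochemical property / PE table (29 rows)."""
    return pd.DataFrame.from_dict(
        _PROPERTY_DATA, orient="index", columns=list(PROPERTY_COLUMNS)
    )


@dataclass(frozen=True)
class RegressionFit:
    """An OLS fit with the statistics used in QSPR reporting."""

    response: str
    predictors: tuple[str, ...]
    intercept: float
    slopes: tuple[float, ...]
    r: float                #: magnitude of the (multiple) correlation
    se: float               #: residual standard error sqrt(RSS/(n-k-1))
    f: float                #: overall F statistic
    p: float                #: Prob(F)
    n: int
    condition_number: float  #: of the standardized design (1.0 for k=1)
    warnings: tuple[str, ...] = field(default=())

    @property
    def k(self) -> int:
        return len(self.predictors)

    def equation(self) -> str:
        terms = " + ".join(
            f"{b:.5g} {name}" for b, name in zip(self.slopes, self.predictors)
        )
        return f"{self.response} = {self.intercept:.5g} + {terms}"


def _fit(X: np.ndarray, y: np.ndarray, response: str,
         predictors: tuple[str, ...]) -> RegressionFit:
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 observations, got n={n}, k={k}")
    if np.ptp(X, axis=0).min() == 0:
        raise ValueError("a predictor has zero variance")
    res = sm.OLS(y, sm.add_constant(X)).fit()
    warns: list[str] = []
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    cond = float(np.linalg.cond(Z)) if k > 1 else 1.0
    if cond > COLLINEARITY_THRESHOLD:
        warns.append(
            f"collinear design (condition number {cond:.3g}); individual "
            "coefficients are ill-determined, compare r/SE/F instead"
        )
    se = math.sqrt(res.ssr / (n - k - 1)) if n > k + 1 else 0.0
    return RegressionFit(
        response=response,
        predictors=predictors,
        intercept=float(res.params[0]),
        slopes=tuple(float(b) for b in res.params[1:]),
        r=math.sqrt(max(res.rsquared, 0.0)),
        se=se,
        f=float(res.fvalue),
        p=float(res.f_pvalue),
        n=n,
        condition_number=cond,
        warnings=tuple(warns),
    )


def fit_linear(x, y, x_name: str = "x", y_name: str = "y") -> RegressionFit:
    """Simple linear OLS fit ``y = alpha + beta x`` with QSPR statistics."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    return _fit(x[:, None], y, y_name, (x_name,))


def fit_multilinear(X, y, x_names: tuple[str, ...] | None = None,
                    y_name: str = "y") -> RegressionFit:
    """Multilinear OLS fit with intercept and collinearity diagnostic."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be n x k with one row per observation of y")
    if x_names is None:
        x_names = tuple(f"x{i + 1}" for i in range(X.shape[1]))
    return _fit(X, y, y_name, tuple(x_names))


def qspr_report(entropies: pd.DataFrame | None = None,
                properties: pd.DataFrame | None = None) -> pd.DataFrame:
    """All 100 simple fits (10 entropies x 10 properties) plus the 10
    multilinear fits, as a tidy table of statistics.

    Columns: model ("linear"/"multilinear"), property, entropy (predictor
    name, or "+".join of the five for multilinear), r, SE, F, p, intercept,
    slopes.
    """
    if entropies is None:
        entropies = entropy_table()
    if properties is None:
        properties = property_table()
    common = [c for c in properties.index if c in entropies.index]
    if len(common) < 3:
        raise ValueError("entropy and property tables share too few molecules")
    E = entropies.loc[common]
    P = properties.loc[common]
    records = []
    for prop in PROPERTY_COLUMNS:
        for ent in ENTROPY_COLUMNS:
            fit = fit_linear(E[ent], P[prop], ent, prop)
            records.append(_record("linear", fit))
        mfit = fit_multilinear(
            E[list(MULTILINEAR_PREDICTORS)].to_numpy(), P[prop].to_numpy(),
            MULTILINEAR_PREDICTORS, prop,
        )
        records.append(_record("multilinear", mfit))
    return pd.DataFrame.from_records(records)


def _record(model: str, fit: RegressionFit) -> dict:
    return {
        "model": model,
        "property": fit.response,
        "entropy": "+".join(fit.predictors),
        "r": fit.r,
        "SE": fit.se,
        "F": fit.f,
        "p": fit.p,
        "intercept": fit.intercept,
        "slopes": fit.slopes,
    }
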