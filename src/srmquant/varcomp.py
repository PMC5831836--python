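"""Variance-component analysis of serial-dilution linearity on unbalanced data.

Measured protein concentrations are regressed on theoretical (dilution)
concentrations on the log2-log2 scale with a fixed-effects line per factor
level (day-couple for SRM, reading order for ELISA) under sum-to-zero
contrasts:

    Model 1S:  y_ijr = b0 + b0j + b1 x_ijr + b1j x_ijr + e     (full)
    Model 2S:  y_ijr = b0 + b1 x_ijr + e                       (no factor)
    Model 3S:  y_ijr = b0 + b0j + e                            (no dilution)
    Model 4S:  y_ijr = b0 + b0j + b1 x_ijr + e                 (no interaction)

Because excluded zero/missing readings leave the data unbalanced, the
components of variance are computed as ADJUSTED sums of squares — RSS
differences between the full model and the nested model omitting the term
and its interaction:

    dilution (x + x:D | D)   = RSS(3S) - RSS(1S)      df J
    two-day  (D + x:D | x)   = RSS(2S) - RSS(1S)      df 2(J-1)
    interaction (x:D | x, D) = RSS(4S) - RSS(1S)      df J-1
    residual = RSS(1S)                                df n - 2J

and the residual is split into pure measurement error (within-cell
replicate scatter around the cell mean, cell = sample x factor level) and
lack of fit (cell means off the fitted surface).  Each SS is reported as
a percentage of the total sum of squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "EmptyDatasetError",
    "SingularFitError",
    "prepare_log2",
    "fit_linear_model",
    "variance_decomposition",
    "mean_slope",
    "LinearFitResult",
    "VarianceDecomposition",
    "DilutionLinearityModel",
]

_WITH_SLOPE = {"1S", "2S", "4S", "1E", "2E", "4E"}
_WITH_FACTOR = {"1S", "3S", "4S", "1E", "3E", "4E"}
_WITH_INTERACTION = {"1S", "1E"}
_KNOWN_MODELS = {"1S", "2S", "3S", "4S", "1E", "2E", "3E", "4E"}


class EmptyDatasetError(ValueError):
    """All rows were excluded at the log2 step."""


class SingularFitError(ValueError):
    """The requested design matrix is rank-deficient on the data."""


def prepare_log2(
    table: pd.DataFrame,
    value_column: str = "estimate",
    dilution_column: str = "dilution",
    factor_column: str = "day_couple",
    sample_column: str = "sample_id",
) -> pd.DataFrame:
    """Build the regression dataset: log2 measured vs log2 theoretical.

    Zero and missing measured values are dropped (null intensities have
    no log2 and their unequal spread across factor levels is exactly what
    makes the data unbalanced), as are rows without a theoretical
    dilution (the serum pool).  Returns columns ``y`` (log2 measured),
    ``x`` (log2 theoretical), ``level`` (factor), ``sample_id``.
    """
    for col in (value_column, dilution_column, factor_column, sample_column):
        if col not in table.columns:
            raise KeyError(f"concentration table lacks column {col!r}")
    v = pd.to_numeric(table[value_column], errors="coerce")
    x = pd.to_numeric(table[dilution_column], errors="coerce")
    keep = v.notna() & (v > 0) & x.notna() & (x > 0)
    sub = table.loc[keep]
    if sub.empty:
        raise EmptyDatasetError(
            "no usable rows: every measurement is zero, missing, or has no "
            "theoretical dilution"
        )
    data = pd.DataFrame(
        {
            "y": np.log2(v[keep].to_numpy(dtype=float)),
            "x": np.log2(x[keep].to_numpy(dtype=float)),
            "level": sub[factor_column].to_numpy(),
            "sample_id": sub[sample_column].to_numpy(),
        }
    )
    if data["x"].nunique() < 2:
        raise EmptyDatasetError("need at least 2 distinct theoretical concentrations")
    return data.reset_index(drop=True)


def _design_matrix(data: pd.DataFrame, model_id: str):
    """Sum-to-zero-coded design matrix for one of the named models."""
    if model_id not in _KNOWN_MODELS:
        raise ValueError(f"unknown model {model_id!r}")
    levels = sorted(pd.unique(data["level"]))
    J = len(levels)
    n = len(data)
    lev_ix = np.asarray([levels.index(v) for v in data["level"]])
    cols = [np.ones(n)]
    names = ["beta0"]
    if model_id in _WITH_FACTOR and J > 1:
        for k in range(J - 1):
            z = np.where(lev_ix == k, 1.0, np.where(lev_ix == J - 1, -1.0, 0.0))
            cols.append(z)
            names.append(f"beta0j[{levels[k]}]")
    if model_id in _WITH_SLOPE:
        cols.append(data["x"].to_numpy(dtype=float))
        names.append("beta1")
    if model_id in _WITH_INTERACTION and J > 1:
        x = data["x"].to_numpy(dtype=float)
        for k in range(J - 1):
            z = np.where(lev_ix == k, 1.0, np.where(lev_ix == J - 1, -1.0, 0.0))
            cols.append(z * x)
            names.append(f"beta1j[{levels[k]}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # diagnose: a level with a single distinct x cannot carry its own slope
        for lev in levels:
            if (
                data.loc[data["level"] == lev, "x"].nunique() < 2
                and model_id in _WITH_INTERACTION
            ):
                raise SingularFitError(
                    f"model {model_id}: factor level {lev!r} has a single "
                    "distinct theoretical concentration; its slope is not "
                    "estimable"
                )
        raise SingularFitError(f"model {model_id}: design matrix is rank-deficient")
    return X, names, levels


@dataclass
class LinearFitResult:
    """OLS fit of one of the nested dilution-linearity models."""

    model_id: str
    coefficients: dict
    rss: float
    n_params: int
    nobs: int
    fitted: np.ndarray
    levels: list

    @property
    def beta0(self) -> float:
        return self.coefficients["beta0"]

    @property
    def beta1(self) -> float:
        if "beta1" not in self.coefficients:
            raise ValueError(f"model {self.model_id} has no slope")
        return self.coefficients["beta1"]

    def level_offsets(self, which: str = "beta0j") -> dict:
        """Full sum-to-zero offset vector (last level = -sum of others)."""
        got = {
            lev: self.coefficients.get(f"{which}[{lev}]", 0.0)
            for lev in self.levels[:-1]
        }
        if any(f"{which}[{lev}]" in self.coefficients for lev in self.levels[:-1]):
            got[self.levels[-1]] = -sum(got.values())
        else:
            got = {lev: 0.0 for lev in self.levels}
        return got


def fit_linear_model(data: pd.DataFrame, model_id: str = "1S") -> LinearFitResult:
    """Ordinary least squares under sum-to-zero contrasts.

    ``model_id`` selects the terms (see module docstring); the E-family
    ids are structurally identical with the reading order as the factor
    (the factor is whatever the ``level`` column holds).
    """
    X, names, levels = _design_matrix(data, model_id)
    y = data["y"].to_numpy(dtype=float)
    res = sm.OLS(y, X).fit()
    fitted = np.asarray(res.fittedvalues, dtype=float)
    return LinearFitResult(
        model_id=model_id,
        coefficients=dict(zip(names, np.asarray(res.params, dtype=float))),
        rss=float(np.sum((y - fitted) ** 2)),
        n_params=X.shape[1],
        nobs=len(y),
        fitted=fitted,
        levels=levels,
    )


def mean_slope(fit: LinearFitResult) -> float:
    """Across-level mean slope beta1 (the sum-to-zero average slope)."""
    return fit.beta1


@dataclass
class VarianceDecomposition:
    """Adjusted-SS variance decomposition of the full dilution model."""

    table: pd.DataFrame  # component, ss, df, percent
    fits: dict
    total_ss: float
    total_kind: str
    venn_discrepancy: float  # dilution% + two-day% - interaction% + residual% - 100

    @property
    def mean_slope(self) -> float:
        return self.fits["1S"].beta1

    def percent(self, component: str) -> float:
        row = self.table.loc[self.table["component"] == component]
        if row.empty:
            raise KeyError(component)
        return float(row["percent"].iloc[0])

    def ss(self, component: str) -> float:
        row = self.table.loc[self.table["component"] == component]
        if row.empty:
            raise KeyError(component)
        return float(row["ss"].iloc[0])

    def summary(self) -> pd.DataFrame:
        out = self.table.copy()
        out.attrs["mean_slope"] = self.mean_slope
        out.attrs["total_ss"] = self.total_ss
        return out


def variance_decomposition(
    data: pd.DataFrame,
    family: str = "S",
    total: str = "corrected",
) -> VarianceDecomposition:
    """Adjusted sums of squares of the four nested fits, with percentages.

    ``total`` selects the denominator: the corrected (mean-centred) total
    SS (default; percentages then measure shares of variation) or the
    uncorrected raw sum of squares.
    """
    if family not in ("S", "E"):
        raise ValueError("family must be 'S' or 'E'")
    ids = [f"{k}{family}" for k in (1, 2, 3, 4)]
    fits = {mid: fit_linear_model(data, mid) for mid in ids}
    full = fits[f"1{family}"]
    rss = {mid: fits[mid].rss for mid in ids}
    y = data["y"].to_numpy(dtype=float)
    n = len(y)
    J = len(full.levels)

    ss_dilution = max(rss[f"3{family}"] - rss[f"1{family}"], 0.0)
    ss_twoday = max(rss[f"2{family}"] - rss[f"1{family}"], 0.0)
    ss_inter = max(rss[f"4{family}"] - rss[f"1{family}"], 0.0)
    ss_resid = rss[f"1{family}"]

    cell = pd.DataFrame(
        {"sample_id": data["sample_id"], "level": data["level"], "y": y}
    )
    cell_mean = cell.groupby(["sample_id", "level"])["y"].transform("mean")
    ss_measure = float(np.sum((y - cell_mean.to_numpy()) ** 2))
    ss_lof = max(ss_resid - ss_measure, 0.0)
    cell_sizes = cell.groupby(["sample_id", "level"]).size().to_numpy()
    df_measure = int(np.sum(cell_sizes - 1))
    df_resid = n - full.n_params  # balanced complete data: n - 2J
    df_lof = df_resid - df_measure

    if total == "corrected":
        total_ss = float(np.sum((y - y.mean()) ** 2))
    elif total == "uncorrected":
        total_ss = float(np.sum(y * y))
    else:
        raise ValueError("total must be 'corrected' or 'uncorrected'")

    def pct(ss: float) -> float:
        return 100.0 * ss / total_ss if total_ss > 0 else float("nan")

    rows = [
        ("dilution", ss_dilution, J),
        ("two_day", ss_twoday, 2 * (J - 1)),
        ("interaction", ss_inter, J - 1),
        ("residual", ss_resid, df_resid),
        ("measurement_error", ss_measure, df_measure),
        ("lack_of_fit", ss_lof, df_lof),
        ("total", total_ss, n - 1 if total == "corrected" else n),
    ]
    table = pd.DataFrame(
        [
            {"component": name, "ss": ss, "df": df, "percent": pct(ss)}
            for name, ss, df in rows
        ]
    )
    venn = (
        pct(ss_dilution) + pct(ss_twoday) - pct(ss_inter) + pct(ss_resid) - 100.0
        if total_ss > 0
        else float("nan")
    )
    return VarianceDecomposition(
        table=table,
        fits=fits,
        total_ss=total_ss,
        total_kind=total,
        venn_discrepancy=venn,
    )


class DilutionLinearityModel:
    """Fixed-effects dilution-linearity model on the log2-log2 scale.

    Statsmodels-style entry point: build from a per-reading concentration
    table (``from_concentrations``) or directly from a prepared dataset,
    then ``fit(model_id)`` for a single nested model or ``decompose()``
    for the full adjusted-SS variance-component table.
    """

    def __init__(self, data: pd.DataFrame, family: str = "S"):
        required = {"y", "x", "level", "sample_id"}
        missing = required - set(data.columns)
        if missing:
            raise KeyError(f"prepared dataset lacks columns {sorted(missing)}")
        if data.empty:
            raise EmptyDatasetError("empty regression dataset")
        self.data = data.reset_index(drop=True)
        self.family = family

    @classmethod
    def from_concentrations(
        cls,
        table: pd.DataFrame,
        factor: str = "day_couple",
        value_column: str = "estimate",
        dilution_column: str = "dilution",
        sample_column: str = "sample_id",
    ) -> "DilutionLinearityModel":
        family = "E" if factor in ("reading_order", "order") else "S"
        data = prepare_log2(
            table,
            value_column=value_column,
            dilution_column=dilution_column,
            factor_column=factor,
            sample_column=sample_column,
        )
        return cls(data, family=family)

    def fit(self, model_id: str | None = None) -> LinearFitResult:
        return fit_linear_model(self.data, model_id or f"1{self.family}")

    def decompose(self, total: str = "corrected") -> VarianceDecomposition:
        return variance_decomposition(self.data, family=self.family, total=total)

    def plot(self, ax=None):
        """Measured vs theoretical log2 concentrations with the fitted
        per-level regression lines of the full model (one line per
        day-couple or reading-order level) and the diagonal."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fit = self.fit()
        b0j = fit.level_offsets("beta0j")
        b1j = fit.level_offsets("beta1j")
        xs = np.linspace(self.data["x"].min(), self.data["x"].max(), 50)
        for lev, sub in self.data.groupby("level"):
            pts = ax.scatter(sub["x"], sub["y"], s=12, label=f"level {lev}")
            color = pts.get_facecolor()[0]
            ax.plot(
                xs,
                fit.beta0 + b0j[lev] + (fit.beta1 + b1j[lev]) * xs,
                color=color,
                lw=1,
            )
        ax.plot(xs, xs, color="black", lw=1, ls="--", label="diagonal")
        ax.set_xlabel("log2 theoretical concentration")
        ax.set_ylabel("log2 measured concentration")
        ax.legend(fontsize="small")
        return ax
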