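"""Linearity models and the adjusted-SS variance decomposition."""

import numpy as np
import pandas as pd
import pytest

from srmquant.design import DesignSpec, build_design
from srmquant.simulate import Model1SParams, simulate_concentrations
from srmquant.varcomp import (
    DilutionLinearityModel,
    EmptyDatasetError,
    SingularFitError,
    fit_linear_model,
    mean_slope,
    prepare_log2,
    variance_decomposition,
)


def _dataset(y, x, level, sample=None):
    return pd.DataFrame(
        {
            "y": np.asarray(y, dtype=float),
            "x": np.asarray(x, dtype=float),
            "level": level,
            "sample_id": sample if sample is not None else np.asarray(x).astype(str),
        }
    )


def _random_unbalanced(rng, J=4, n_x=5, reps=4, drop=0.2, sigma=0.3):
    rows = []
    b0j = rng.normal(0, 0.3, J)
    b0j -= b0j.mean()
    b1j = rng.normal(0, 0.1, J)
    b1j -= b1j.mean()
    for k in range(n_x):
        x = -float(k)
        for j in range(J):
            for r in range(reps):
                y = 0.2 + b0j[j] + (1.0 + b1j[j]) * x + rng.normal(0, sigma)
                rows.append((y, x, j + 1, f"s{k}"))
    data = pd.DataFrame(rows, columns=["y", "x", "level", "sample_id"])
    keep = rng.random(len(data)) >= drop
    # never empty a whole level x sample cell set below estimability
    out = data[keep]
    counts = out.groupby("level")["x"].nunique()
    if (counts < 2).any():
        return _random_unbalanced(rng, J, n_x, reps, drop, sigma)
    return out.reset_index(drop=True)


class TestPrepareLog2:
    def test_log2_values(self):
        table = pd.DataFrame(
            {
                "estimate": [4.0, 0.0, np.nan, 2.0],
                "dilution": [1.0, 1.0, 0.5, 1 / 16],
                "day_couple": [1, 1, 2, 2],
                "sample_id": ["a", "a", "b", "c"],
            }
        )
        data = prepare_log2(table)
        assert len(data) == 2  # zero and missing rows dropped
        assert data["y"].tolist() == pytest.approx([2.0, 1.0])
        assert data["x"].tolist() == pytest.approx([0.0, -4.0])

    def test_pool_rows_dropped(self):
        table = pd.DataFrame(
            {
                "estimate": [4.0, 2.0, 1.0],
                "dilution": [np.nan, 1.0, 0.5],
                "day_couple": [1, 1, 1],
                "sample_id": ["pool", "a", "b"],
            }
        )
        assert len(prepare_log2(table)) == 2

    def test_all_excluded_errors(self):
        table = pd.DataFrame(
            {
                "estimate": [0.0, np.nan],
                "dilution": [1.0, 0.5],
                "day_couple": [1, 1],
                "sample_id": ["a", "b"],
            }
        )
        with pytest.raises(EmptyDatasetError):
            prepare_log2(table)


class TestModelFits:
    def test_exact_line_model_2s(self):
        x = np.tile([0.0, -1.0, -2.0], 4)
        data = _dataset(0.3 + 0.5 * x, x, np.repeat([1, 2], 6))
        fit = fit_linear_model(data, "2S")
        assert fit.rss == pytest.approx(0.0, abs=1e-18)
        assert fit.beta1 == pytest.approx(0.5)
        assert mean_slope(fit) == pytest.approx(0.5)

    def test_single_level_1s_equals_2s(self):
        rng = np.random.default_rng(0)
        x = np.tile([0.0, -1.0, -2.0], 3)
        data = _dataset(x + rng.normal(0, 0.1, len(x)), x, np.ones(len(x), dtype=int))
        f1 = fit_linear_model(data, "1S")
        f2 = fit_linear_model(data, "2S")
        assert f1.rss == pytest.approx(f2.rss, rel=1e-12)
        assert f1.beta1 == pytest.approx(f2.beta1, rel=1e-12)

    def test_balanced_two_level_cell_mean_oracle(self):
        """With two levels and two x values the 1S fit interpolates the
        cell means; coefficients follow from them in closed form."""
        # cells: (level, x) -> mean
        means = {(1, 0.0): 1.0, (1, -1.0): 0.1, (2, 0.0): 0.6, (2, -1.0): -0.7}
        rows = []
        for (lev, x), m in means.items():
            rows += [(m + d, x, lev, f"s{x}") for d in (-0.05, 0.05)]
        data = pd.DataFrame(rows, columns=["y", "x", "level", "sample_id"])
        fit = fit_linear_model(data, "1S")
        slope = {lev: means[(lev, 0.0)] - means[(lev, -1.0)] for lev in (1, 2)}
        inter = {lev: means[(lev, 0.0)] for lev in (1, 2)}
        assert fit.beta1 == pytest.approx(np.mean(list(slope.values())))
        assert fit.beta0 == pytest.approx(np.mean(list(inter.values())))
        offs = fit.level_offsets("beta0j")
        assert offs[1] == pytest.approx(inter[1] - np.mean(list(inter.values())))
        assert sum(offs.values()) == pytest.approx(0.0, abs=1e-12)

    def test_mean_slope_is_average_of_level_slopes(self):
        x = np.tile([0.0, -1.0, -2.0], 2)
        y = np.concatenate([0.8 * x[:3], 1.2 * x[3:]])
        data = _dataset(y, x, np.repeat([1, 2], 3))
        fit = fit_linear_model(data, "1S")
        assert fit.beta1 == pytest.approx(1.0)

    def test_no_slope_model_rejects_mean_slope(self):
        data = _dataset([1.0, 2.0, 1.5, 2.5], [0.0, -1.0, 0.0, -1.0], [1, 1, 2, 2])
        fit = fit_linear_model(data, "3S")
        with pytest.raises(ValueError, match="no slope"):
            mean_slope(fit)

    def test_singular_fit_names_offending_level(self):
        # level 2 observed at a single x: its slope is not estimable
        data = _dataset(
            [0.0, -1.0, -2.0, 0.5, 0.6],
            [0.0, -1.0, -2.0, -1.0, -1.0],
            [1, 1, 1, 2, 2],
        )
        with pytest.raises(SingularFitError, match="2"):
            fit_linear_model(data, "1S")


class TestDecomposition:
    def test_pure_dilution_line(self):
        x = np.tile([0.0, -1.0, -2.0, -3.0], 4)
        data = _dataset(1.0 + x, x, np.repeat([1, 2], 8))
        dec = variance_decomposition(data)
        assert dec.percent("dilution") == pytest.approx(100.0)
        for comp in ("two_day", "interaction", "residual"):
            assert dec.percent(comp) == pytest.approx(0.0, abs=1e-9)

    def test_balanced_matches_sequential_oracle(self):
        """On balanced complete data the adjusted SS of each term equals
        the sequential-ANOVA SS from an independent dummy-coded
        nested-fit oracle, and the Venn closure holds."""
        rng = np.random.default_rng(5)
        design = build_design(DesignSpec())
        params = Model1SParams(
            beta0=0.1,
            beta1=1.0,
            beta0j=np.array([0.2, -0.1, 0.05, -0.15]),
            beta1j=np.array([0.05, -0.05, 0.02, -0.02]),
            sigma=0.2,
        )
        conc = simulate_concentrations(params, design, seed=3)
        data = prepare_log2(conc)
        dec = variance_decomposition(data)

        # independent oracle: sequential RSS drops with raw dummy coding
        def rss(cols):
            X = np.column_stack(cols)
            beta, *_ = np.linalg.lstsq(X, data["y"].to_numpy(), rcond=None)
            r = data["y"].to_numpy() - X @ beta
            return float(r @ r)

        ones = np.ones(len(data))
        x = data["x"].to_numpy()
        D = pd.get_dummies(data["level"]).to_numpy(dtype=float)
        xD = D * x[:, None]
        rss_D = rss([D])
        rss_Dx = rss([D, x])
        rss_x = rss([ones, x])
        rss_full = rss([D, x[:, None] * 0 + xD])  # D + x:D spans the full model
        seq_dilution = rss_D - rss_full  # x then x:D entered after D
        seq_twoday = rss_x - rss_full  # D then x:D entered after x
        seq_inter = rss_Dx - rss_full
        assert dec.ss("dilution") == pytest.approx(seq_dilution, rel=1e-9)
        assert dec.ss("two_day") == pytest.approx(seq_twoday, rel=1e-9)
        assert dec.ss("interaction") == pytest.approx(seq_inter, rel=1e-9)
        assert dec.ss("residual") == pytest.approx(rss_full, rel=1e-9)
        assert dec.venn_discrepancy == pytest.approx(0.0, abs=1e-8)

    def test_residual_split_identity_random_unbalanced(self):
        """measurement error + lack of fit = RSS(full model), and every SS
        stays non-negative, on 50 random unbalanced datasets."""
        rng = np.random.default_rng(12)
        for _ in range(50):
            data = _random_unbalanced(rng)
            dec = variance_decomposition(data)
            me = dec.ss("measurement_error")
            lof = dec.ss("lack_of_fit")
            resid = dec.ss("residual")
            assert me + lof == pytest.approx(resid, rel=1e-9)
            assert (dec.table["ss"] >= 0).all()

    def test_replicate_constant_cells(self):
        """Cells whose replicates agree exactly put the whole residual
        into lack of fit."""
        # two cells per level off any single line, zero within-cell scatter
        rows = []
        for lev in (1, 2):
            for x, m in [(0.0, 0.3 * lev), (-1.0, -0.9 * lev + 0.4)]:
                rows += [(m, x, lev, f"s{x}")] * 3
        # add curvature so the line cannot interpolate the cell means: use
        # a third x level with shifted means
        for lev in (1, 2):
            rows += [(1.5, -2.0, lev, "s-2.0")] * 3
        data = pd.DataFrame(rows, columns=["y", "x", "level", "sample_id"])
        dec = variance_decomposition(data)
        assert dec.ss("measurement_error") == pytest.approx(0.0, abs=1e-18)
        assert dec.ss("lack_of_fit") == pytest.approx(dec.ss("residual"), rel=1e-12)
        assert dec.ss("lack_of_fit") > 0

    def test_balanced_df_match_reference_formulas(self):
        design = build_design(DesignSpec())
        conc = simulate_concentrations(Model1SParams(sigma=0.1), design, seed=1)
        data = prepare_log2(conc)
        dec = variance_decomposition(data)
        I, J, R = 5, 4, 4  # samples, day-couples, digestion-injections
        df = dict(zip(dec.table["component"], dec.table["df"]))
        assert df["dilution"] == J
        assert df["two_day"] == 2 * (J - 1)
        assert df["interaction"] == J - 1
        assert df["residual"] == I * J * R - 2 * J
        assert df["measurement_error"] == (R - 1) * I * J
        assert df["lack_of_fit"] == I * J - 2 * J

    def test_unbalanced_df_bookkeeping(self):
        rng = np.random.default_rng(3)
        data = _random_unbalanced(rng)
        dec = variance_decomposition(data)
        df = dict(zip(dec.table["component"], dec.table["df"]))
        n = len(data)
        J = data["level"].nunique()
        cells = data.groupby(["sample_id", "level"]).size()
        assert df["residual"] == n - 2 * J
        assert df["measurement_error"] == int((cells - 1).sum())
        assert df["lack_of_fit"] == df["residual"] - df["measurement_error"]

    def test_uncorrected_total_switch(self):
        rng = np.random.default_rng(9)
        data = _random_unbalanced(rng)
        corr = variance_decomposition(data, total="corrected")
        raw = variance_decomposition(data, total="uncorrected")
        y = data["y"].to_numpy()
        assert corr.total_ss == pytest.approx(float(((y - y.mean()) ** 2).sum()))
        assert raw.total_ss == pytest.approx(float((y**2).sum()))


def test_model_results_workflow():
    """from_concentrations -> fit/decompose mirrors the functional API."""
    design = build_design(DesignSpec())
    conc = simulate_concentrations(Model1SParams(sigma=0.15), design, seed=7)
    model = DilutionLinearityModel.from_concentrations(conc)
    fit = model.fit()
    assert fit.model_id == "1S"
    dec = model.decompose()
    assert dec.mean_slope == pytest.approx(fit.beta1)
    assert dec.table["percent"].iloc[:4].sum() > 0
    summary = dec.summary()
    assert "component" in summary.columns
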