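"""Method-comparison machinery: correlation screen and exact Wilcoxon test.

Proteins enter the statistical comparison only if the Pearson correlation
between log2 theoretical and log2 measured concentration reaches a
threshold (default 0.7) for at least one quantification method — below
that, the protein is assumed to sit under the detection limit.

The paired comparison of variance-component percentages between two
methods uses the Wilcoxon signed-rank test.  At the scale of interest
(a handful of proteins) the exact null distribution matters: zero
differences are dropped, tied absolute differences receive midranks, and
the exact two-sided p-value enumerates all 2^n sign assignments of the
observed ranks (by convolution; a brute-force enumeration is used as the
oracle in the test-suite).  Above ``n = 20`` the normal approximation
with continuity and tie corrections takes over.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["correlation_filter", "wilcoxon_signed_rank", "WilcoxonResult"]


def correlation_filter(
    values: pd.DataFrame,
    threshold: float = 0.7,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Per-protein, per-method Pearson r with a retain-if-any rule.

    ``values`` must hold columns ``protein, method, x, y`` with paired
    log2 theoretical (x) and measured (y) concentrations.  A protein is
    retained when r >= threshold for at least one method.  Proteins with
    fewer than ``min_pairs`` pairs or a zero-variance series in every
    method are flagged not-evaluable and dropped.

    Returns one row per (protein, method): ``protein, method, n, r,
    evaluable`` plus a protein-level boolean ``retained``.
    """
    rows = []
    for (protein, method), sub in values.groupby(["protein", "method"], sort=True):
        x = sub["x"].to_numpy(dtype=float)
        y = sub["y"].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if len(x) < min_pairs:
            rows.append((protein, method, len(x), np.nan, False))
            continue
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((protein, method, len(x), np.nan, False))
            continue
        r = float(stats.pearsonr(x, y).statistic)
        rows.append((protein, method, len(x), r, True))
    out = pd.DataFrame(rows, columns=["protein", "method", "n", "r", "evaluable"])
    retained = (
        out.assign(hit=lambda d: d["evaluable"] & (d["r"] >= threshold))
        .groupby("protein")["hit"]
        .any()
    )
    out["retained"] = out["protein"].map(retained)
    return out


@dataclass(frozen=True)
class WilcoxonResult:
    """Signed-rank statistic and two-sided p-value."""

    w_plus: float
    p: float
    n: int  # pairs after zero removal
    method: str  # "exact" | "normal" | "degenerate"

    def as_dict(self) -> dict:
        return {"W_plus": self.w_plus, "p": self.p, "n": self.n, "method": self.method}


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact tail probability by convolution over sign assignments.

    Midranks are doubled so every attainable statistic is an integer;
    the distribution of 2*W+ is built by convolving {0, 2r_k} terms.
    """
    r2 = np.round(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2.0 * w_plus))
    p_le = float(counts[: w2 + 1].sum())
    p_ge = float(counts[w2:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def _normal_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Normal approximation with continuity and tie corrections."""
    n = len(ranks)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    if var <= 0:
        return 1.0
    d = w_plus - mean
    cc = 0.5 * np.sign(d)
    z = (d - cc) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def wilcoxon_signed_rank(
    a: np.ndarray,
    b: np.ndarray | None = None,
    method: str = "auto",
    exact_limit: int = 20,
) -> WilcoxonResult:
    """Wilcoxon signed-rank test of paired samples (or of differences).

    Zero differences are dropped; tied absolute differences share
    midranks; ``W+`` is the rank sum of the positive differences.  With
    ``method="auto"`` the exact enumeration is used for up to
    ``exact_limit`` nonzero pairs, else the normal approximation.  All
    differences zero is a degenerate result with p = 1.
    """
    a = np.asarray(a, dtype=float)
    d = a if b is None else a - np.asarray(b, dtype=float)
    if d.size < 1:
        raise ValueError("need at least one pair")
    if not np.all(np.isfinite(d)):
        raise ValueError("differences must be finite")
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(w_plus=0.0, p=1.0, n=0, method="degenerate")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if method == "auto":
        method = "exact" if n <= exact_limit else "normal"
    if method == "exact":
        p = _exact_two_sided_p(ranks, w_plus)
    elif method == "normal":
        p = _normal_two_sided_p(ranks, w_plus)
    else:
        raise ValueError(f"unknown method {method!r}")
    return WilcoxonResult(w_plus=w_plus, p=p, n=n, method=method)
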