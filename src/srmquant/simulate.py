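"""Forward simulation of the SRM analytical chain and of concentration tables.

Two generators live here:

``simulate_traces``
    The mechanistic forward model of the acquisition chain.  For each
    reading, the peptide concentration is ``kappa_i = H_i(y) + e`` with
    ``e ~ N(0, 1/gamma_kappa)``; the native transition signal at time
    ``t_n`` is ``kappa_i * xi_il * C(tau_i, lam_i)(t_n)`` plus i.i.d.
    Gaussian noise of inverse variance ``gamma_n``, and the labeled
    (AQUA) signal replaces ``kappa_i`` by the known spike ``kappa*_i``
    and the gain by ``xi_il * phi*_il`` with noise precision
    ``gamma*_n``.  ``C`` is a unit-area chromatographic peak shape
    (Gaussian by default, pluggable).

``simulate_concentrations``
    The phenomenological generator of per-reading protein-concentration
    tables on the serial-dilution design: a fixed-effects line on the
    log2-log2 scale with per-day-couple intercept and slope offsets
    (sum-to-zero) and i.i.d. Gaussian residuals, returned on the linear
    scale so that the downstream log2 step is exercised.

Day-to-day technical variability enters the trace simulator through
per-day-couple digestion-yield factors (the mechanism the Bayesian
quantifier calibrates) and optional per-day-couple gain multipliers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignSpec, build_design
from .peptides import MappingError, PeptideProteinMap

__all__ = [
    "GaussianPeak",
    "GroundTruth",
    "Model1SParams",
    "TraceSet",
    "default_truth",
    "default_grid",
    "reading_rng",
    "simulate_traces",
    "simulate_concentrations",
    "model1s_params_for_components",
    "apply_missingness",
]

TRACE_COLUMNS = [
    "reading_id",
    "sample_id",
    "day_couple",
    "aliquot",
    "digestion",
    "injection",
    "protein",
    "peptide",
    "transition",
    "channel",
    "time",
    "intensity",
]


def reading_rng(master_seed: int, reading_id: str) -> np.random.Generator:
    """Independent substream for one reading.

    The substream key is a stable hash of the reading id, so adding or
    removing readings never perturbs the noise of existing ones.
    """
    digest = hashlib.sha256(reading_id.encode()).digest()
    sub = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.default_rng([int(master_seed) % (2**31), sub])


class GaussianPeak:
    """Unit-area Gaussian chromatographic peak C(tau, lam)(t).

    ``tau`` is the retention-time position, ``lam`` the width (SD) in the
    same time units; the peak integrates to 1 over the real line.
    """

    def __call__(self, t: np.ndarray, tau: float, lam: float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        z = (t - tau) / lam
        return np.exp(-0.5 * z * z) / (lam * np.sqrt(2.0 * np.pi))


@dataclass
class GroundTruth:
    """All latent quantities of the forward model, for test assertions.

    ``xi`` and ``phi_star`` are lists of per-peptide transition-gain
    arrays (one entry per transition of that peptide).  ``day_yield_factors``
    multiply the base yields g_ip on each day-couple (clipped to stay in
    (0, 1]); ``day_gain_factors`` optionally multiply the gains.
    """

    pep_map: PeptideProteinMap
    y: np.ndarray  # (P,) parent-solution protein concentrations
    tau: np.ndarray  # (S,) peak positions
    lam: np.ndarray  # (S,) peak widths, > 0
    xi: list  # per-peptide arrays of transition gains
    phi_star: list  # per-peptide arrays of AQUA gain corrections
    gamma_n: float = 25.0
    gamma_star_n: float = 25.0
    gamma_kappa: float = 1e4
    pool_y: np.ndarray | None = None  # endogenous pool levels, default 0
    day_yield_factors: np.ndarray | None = None  # (J,)
    day_gain_factors: np.ndarray | None = None  # (J,)
    peak_shape: object = field(default_factory=GaussianPeak)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        self.xi = [np.atleast_1d(np.asarray(x, dtype=float)) for x in self.xi]
        self.phi_star = [
            np.atleast_1d(np.asarray(x, dtype=float)) for x in self.phi_star
        ]
        S = self.pep_map.n_peptides
        if not (len(self.tau) == len(self.lam) == len(self.xi) == len(self.phi_star) == S):
            raise ValueError("per-peptide arrays do not match the peptide map")
        if np.any(self.y < 0):
            raise ValueError("protein concentrations must be >= 0")
        if np.any(self.lam <= 0):
            raise ValueError("peak widths must be > 0")
        if min(self.gamma_n, self.gamma_star_n, self.gamma_kappa) <= 0:
            raise ValueError("noise inverse variances must be > 0")
        if self.pool_y is None:
            self.pool_y = np.zeros_like(self.y)
        self.pool_y = np.asarray(self.pool_y, dtype=float)

    def yield_factor(self, day_couple: int) -> float:
        if self.day_yield_factors is None:
            return 1.0
        return float(self.day_yield_factors[int(day_couple) - 1])

    def gain_factor(self, day_couple: int) -> float:
        if self.day_gain_factors is None:
            return 1.0
        return float(self.day_gain_factors[int(day_couple) - 1])

    def effective_map(self, day_couple: int) -> PeptideProteinMap:
        """Peptide map with the day-couple's effective digestion yields."""
        g = np.clip(self.pep_map.g * self.yield_factor(day_couple), None, 1.0)
        return self.pep_map.with_yields(g)

    def sample_y(self, sample_id: str, dilution: float) -> np.ndarray:
        """True protein concentrations of one sample."""
        if sample_id == "pool" or not np.isfinite(dilution):
            return self.pool_y.copy()
        return self.y * float(dilution)

    def transitions_of(self, i: int) -> list[str]:
        pep = self.pep_map.peptides[i]
        return [f"{pep}.t{l + 1}" for l in range(len(self.xi[i]))]

    def to_json(self) -> str:
        payload = {
            "peptides": list(self.pep_map.peptides),
            "proteins": list(self.pep_map.proteins),
            "d": self.pep_map.d.tolist(),
            "g": self.pep_map.g.tolist(),
            "kappa_star": self.pep_map.kappa_star.tolist(),
            "y": self.y.tolist(),
            "pool_y": self.pool_y.tolist(),
            "tau": self.tau.tolist(),
            "lam": self.lam.tolist(),
            "xi": [x.tolist() for x in self.xi],
            "phi_star": [x.tolist() for x in self.phi_star],
            "gamma_n": self.gamma_n,
            "gamma_star_n": self.gamma_star_n,
            "gamma_kappa": self.gamma_kappa,
            "day_yield_factors": (
                None
                if self.day_yield_factors is None
                else np.asarray(self.day_yield_factors).tolist()
            ),
            "day_gain_factors": (
                None
                if self.day_gain_factors is None
                else np.asarray(self.day_gain_factors).tolist()
            ),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        p = json.loads(text)
        pep_map = PeptideProteinMap(
            tuple(p["peptides"]),
            tuple(p["proteins"]),
            np.asarray(p["d"]),
            np.asarray(p["g"]),
            np.asarray(p["kappa_star"]),
        )
        return cls(
            pep_map=pep_map,
            y=np.asarray(p["y"]),
            pool_y=np.asarray(p["pool_y"]),
            tau=np.asarray(p["tau"]),
            lam=np.asarray(p["lam"]),
            xi=[np.asarray(x) for x in p["xi"]],
            phi_star=[np.asarray(x) for x in p["phi_star"]],
            gamma_n=p["gamma_n"],
            gamma_star_n=p["gamma_star_n"],
            gamma_kappa=p["gamma_kappa"],
            day_yield_factors=(
                None
                if p["day_yield_factors"] is None
                else np.asarray(p["day_yield_factors"])
            ),
            day_gain_factors=(
                None
                if p["day_gain_factors"] is None
                else np.asarray(p["day_gain_factors"])
            ),
        )


class TraceSet:
    """Long-format container of native/labeled transition chromatograms.

    One row per (reading, peptide, transition, channel, time point); the
    native and labeled channels of a reading share a strictly increasing
    time grid.
    """

    def __init__(self, frame: pd.DataFrame, validate: bool = True):
        missing = [c for c in TRACE_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"trace table missing columns: {missing}")
        self.frame = frame.reset_index(drop=True)
        if validate and len(frame):
            self._validate()

    def _validate(self) -> None:
        if not np.isfinite(self.frame["intensity"]).all():
            raise ValueError("intensities must be finite")
        bad = set(self.frame["channel"]) - {"native", "labeled"}
        if bad:
            raise ValueError(f"unknown channels: {sorted(bad)}")
        for rid, sub in self.frame.groupby("reading_id", sort=False):
            grids = {
                tuple(np.asarray(s["time"], dtype=float))
                for _, s in sub.groupby(["peptide", "transition", "channel"], sort=False)
            }
            if len(grids) != 1:
                raise ValueError(f"reading {rid!r}: traces do not share one time grid")
            (grid,) = grids
            if np.any(np.diff(grid) <= 0):
                raise ValueError(f"reading {rid!r}: time grid not strictly increasing")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def reading_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["reading_id"]))

    @property
    def proteins(self) -> list[str]:
        return list(dict.fromkeys(self.frame["protein"]))

    def reading(self, reading_id: str) -> pd.DataFrame:
        sub = self.frame[self.frame["reading_id"] == reading_id]
        if sub.empty:
            raise KeyError(f"no reading {reading_id!r}")
        return sub

    def grid(self, reading_id: str) -> np.ndarray:
        sub = self.reading(reading_id)
        first = next(iter(sub.groupby(["peptide", "transition", "channel"], sort=False)))
        return np.asarray(first[1]["time"], dtype=float)

    def reading_arrays(self, reading_id: str):
        """(grid, {peptide: {transition: {channel: intensity array}}})."""
        sub = self.reading(reading_id)
        grid = None
        out: dict[str, dict[str, dict[str, np.ndarray]]] = {}
        for (pep, tr, ch), s in sub.groupby(["peptide", "transition", "channel"], sort=False):
            t = np.asarray(s["time"], dtype=float)
            if grid is None:
                grid = t
            out.setdefault(pep, {}).setdefault(tr, {})[ch] = np.asarray(
                s["intensity"], dtype=float
            )
        return grid, out

    def reading_meta(self, reading_id: str) -> dict:
        row = self.reading(reading_id).iloc[0]
        return {
            k: row[k]
            for k in ("sample_id", "day_couple", "aliquot", "digestion", "injection")
            if k in row
        }


def default_truth(
    spec: DesignSpec | None = None,
    seed: int = 0,
    n_transitions: int = 3,
    snr_scale: float = 1.0,
) -> GroundTruth:
    """Reference ground truth: three proteins with 3, 2 and 1 peptides.

    Mirrors the panel structure of interest (quantifier behaviour depends
    strongly on peptide multiplicity): protein ``P3pep`` has three
    proteotypic peptides, ``P2pep`` two, ``P1pep`` one; each peptide has
    ``n_transitions`` transitions.  Concentrations are in arbitrary amount
    units with parent-solution levels of order 10, AQUA spikes at a
    comparable level, retention times spread over a 10-15 min window and
    peak widths ~0.1 min.
    """
    spec = spec or DesignSpec()
    rng = np.random.default_rng([int(seed) % (2**31), 90210])
    proteins = ("P3pep", "P2pep", "P1pep")
    pep_counts = (3, 2, 1)
    peptides = tuple(
        f"{prot}_pep{k + 1}" for prot, c in zip(proteins, pep_counts) for k in range(c)
    )
    S, P = len(peptides), len(proteins)
    d = np.zeros((S, P))
    i = 0
    for p, c in enumerate(pep_counts):
        for _ in range(c):
            d[i, p] = 1
            i += 1
    g = np.where(d > 0, rng.uniform(0.55, 0.8, size=(S, P)), 1.0)
    y = rng.uniform(6.0, 14.0, size=P)
    kappa_star = (g * d) @ y * rng.uniform(0.6, 1.2, size=S) * 0.25
    pep_map = PeptideProteinMap(peptides, proteins, d, g, kappa_star)
    tau = rng.uniform(10.5, 14.5, size=S)
    lam = rng.uniform(0.08, 0.12, size=S)
    xi = [rng.uniform(0.7, 1.4, size=n_transitions) for _ in range(S)]
    phi_star = [rng.uniform(0.9, 1.1, size=n_transitions) for _ in range(S)]
    factors = rng.uniform(0.9, 1.1, size=spec.n_day_couples)
    factors = factors / factors.mean()
    return GroundTruth(
        pep_map=pep_map,
        y=y,
        tau=tau,
        lam=lam,
        xi=xi,
        phi_star=phi_star,
        gamma_n=25.0 * snr_scale**2,
        gamma_star_n=25.0 * snr_scale**2,
        gamma_kappa=1e4,
        day_yield_factors=factors,
    )


def default_grid(truth: GroundTruth, spacing: float = 0.05) -> np.ndarray:
    """Time grid covering every peptide's peak +/- 4 widths."""
    lo = float(np.min(truth.tau - 4 * truth.lam)) - spacing
    hi = float(np.max(truth.tau + 4 * truth.lam)) + spacing
    return np.round(np.arange(lo, hi + spacing / 2, spacing), 6)


def _primary_protein(pep_map: PeptideProteinMap, i: int) -> str:
    p = int(np.argmax(pep_map.d[i] > 0))
    return pep_map.proteins[p]


def simulate_traces(
    design: pd.DataFrame,
    truth: GroundTruth,
    grid: np.ndarray | None = None,
    seed: int = 0,
) -> TraceSet:
    """Generate native and labeled transition chromatograms for a design.

    Each reading draws from its own hash-derived RNG substream; fixing
    ``seed`` reproduces the traces exactly.  Raises ``MappingError`` if a
    peptide has no digestion-factor entry (checked by PeptideProteinMap).
    """
    grid = default_grid(truth) if grid is None else np.asarray(grid, dtype=float)
    if np.any(grid[1:] <= grid[:-1]):
        raise ValueError("time grid must be strictly increasing")
    lo, hi = grid[0], grid[-1]
    if np.any(truth.tau - 4 * truth.lam < lo) or np.any(truth.tau + 4 * truth.lam > hi):
        raise ValueError("time grid must cover every peak +/- 4 widths")

    peak = truth.peak_shape
    S = truth.pep_map.n_peptides
    C = np.stack([peak(grid, truth.tau[i], truth.lam[i]) for i in range(S)])
    N = len(grid)
    sd_n = 1.0 / np.sqrt(truth.gamma_n)
    sd_s = 1.0 / np.sqrt(truth.gamma_star_n)
    sd_k = 1.0 / np.sqrt(truth.gamma_kappa)

    chunks: list[pd.DataFrame] = []
    for row in design.itertuples(index=False):
        rng = reading_rng(seed, row.reading_id)
        j = int(row.day_couple)
        pmap = truth.effective_map(j)
        gain = truth.gain_factor(j)
        y_s = truth.sample_y(row.sample_id, row.dilution)
        kappa = pmap.h(y_s) + rng.normal(0.0, sd_k, size=S)

        peps, trs, chans, times, intens = [], [], [], [], []
        prots = []
        for i in range(S):
            pep = truth.pep_map.peptides[i]
            prot = _primary_protein(truth.pep_map, i)
            for l, tr in enumerate(truth.transitions_of(i)):
                xi_il = truth.xi[i][l] * gain
                native = kappa[i] * xi_il * C[i] + rng.normal(0.0, sd_n, size=N)
                labeled = (
                    truth.pep_map.kappa_star[i]
                    * xi_il
                    * truth.phi_star[i][l]
                    * C[i]
                    + rng.normal(0.0, sd_s, size=N)
                )
                for ch, sig in (("native", native), ("labeled", labeled)):
                    peps.append(np.full(N, pep, dtype=object))
                    prots.append(np.full(N, prot, dtype=object))
                    trs.append(np.full(N, tr, dtype=object))
                    chans.append(np.full(N, ch, dtype=object))
                    times.append(grid)
                    intens.append(sig)

        n_rows = N * sum(len(x) for x in truth.xi) * 2
        chunk = pd.DataFrame(
            {
                "reading_id": np.full(n_rows, row.reading_id, dtype=object),
                "sample_id": np.full(n_rows, row.sample_id, dtype=object),
                "day_couple": np.full(n_rows, j),
                "aliquot": np.full(n_rows, int(row.aliquot)),
                "digestion": np.full(n_rows, int(row.digestion)),
                "injection": np.full(n_rows, int(row.injection)),
                "protein": np.concatenate(prots),
                "peptide": np.concatenate(peps),
                "transition": np.concatenate(trs),
                "channel": np.concatenate(chans),
                "time": np.concatenate(times),
                "intensity": np.concatenate(intens),
            }
        )
        if "day" in design.columns:
            chunk["day"] = int(row.day)
        if "is_qc" in design.columns:
            chunk["is_qc"] = bool(row.is_qc)
        chunks.append(chunk)

    frame = pd.concat(chunks, ignore_index=True) if chunks else pd.DataFrame(
        columns=TRACE_COLUMNS
    )
    return TraceSet(frame, validate=False)


@dataclass
class Model1SParams:
    """Generative fixed-effects line on the log2-log2 scale.

    log2(y_ijr) = beta0 + beta0j[j] + (beta1 + beta1j[j]) * log2(x_ijr) + eps,
    eps ~ N(0, sigma^2); the per-day-couple offsets sum to zero.
    """

    beta0: float = 0.0
    beta1: float = 1.0
    beta0j: np.ndarray = field(default_factory=lambda: np.zeros(4))
    beta1j: np.ndarray = field(default_factory=lambda: np.zeros(4))
    sigma: float = 0.1

    def __post_init__(self) -> None:
        self.beta0j = np.asarray(self.beta0j, dtype=float)
        self.beta1j = np.asarray(self.beta1j, dtype=float)
        for name, v in (("beta0j", self.beta0j), ("beta1j", self.beta1j)):
            if abs(v.sum()) > 1e-9 * max(1.0, np.abs(v).max()):
                raise ValueError(f"{name} must sum to zero (sum-to-zero contrasts)")
        if self.sigma < 0:
            raise ValueError("residual SD must be >= 0")


def simulate_concentrations(
    params: Model1SParams,
    design: pd.DataFrame,
    seed: int = 0,
    protein: str = "protein",
) -> pd.DataFrame:
    """Per-reading protein concentrations from the generative dilution line.

    Only non-QC dilution samples are generated (the pool carries no
    theoretical spike level and the QC rows are a trace-level concept).
    Output columns: ``reading_id, sample_id, day_couple, dilution,
    protein, estimate`` with the estimate on the LINEAR scale.
    """
    sub = design[(~design["is_qc"]) & np.isfinite(design["dilution"])].reset_index(
        drop=True
    )
    J = int(design["day_couple"].max())
    if len(params.beta0j) != J or len(params.beta1j) != J:
        raise ValueError(f"day-couple offsets must have length {J}")
    rng = np.random.default_rng([int(seed) % (2**31), 777])
    x = np.log2(sub["dilution"].to_numpy(dtype=float))
    j = sub["day_couple"].to_numpy(dtype=int) - 1
    log2y = (
        params.beta0
        + params.beta0j[j]
        + (params.beta1 + params.beta1j[j]) * x
        + rng.normal(0.0, params.sigma, size=len(sub))
    )
    return pd.DataFrame(
        {
            "reading_id": sub["reading_id"],
            "sample_id": sub["sample_id"],
            "day_couple": sub["day_couple"],
            "dilution": sub["dilution"],
            "protein": protein,
            "estimate": np.exp2(log2y),
        }
    )


def model1s_params_for_components(
    design: pd.DataFrame,
    pct_dilution: float = 80.0,
    pct_technical: float = 15.0,
    pct_noise: float = 5.0,
    beta1: float = 1.0,
    beta0: float = 0.0,
) -> Model1SParams:
    """Choose generative parameters hitting target variance shares.

    The shares are the expected fractions (in %) of the corrected total
    sum of squares on the analysed (non-pool, non-QC) rows attributable
    to the dilution line, to the per-day-couple intercept offsets, and to
    replicate noise.  The interaction offsets are left at zero; the
    dilution share is anchored by the design's spread in log2(x) at the
    requested slope.
    """
    if abs(pct_dilution + pct_technical + pct_noise - 100.0) > 1e-6:
        raise ValueError("component percentages must sum to 100")
    sub = design[(~design["is_qc"]) & np.isfinite(design["dilution"])]
    x = np.log2(sub["dilution"].to_numpy(dtype=float))
    n = len(x)
    sxx = float(np.sum((x - x.mean()) ** 2))
    J = int(design["day_couple"].max())
    total = beta1**2 * sxx / (pct_dilution / 100.0)
    # evenly spaced sum-to-zero intercept pattern
    c = np.arange(1, J + 1, dtype=float) - (J + 1) / 2.0
    n_j = sub.groupby("day_couple").size().reindex(range(1, J + 1), fill_value=0)
    ss_d_target = total * pct_technical / 100.0
    scale_sq = ss_d_target / float((n_j.to_numpy() * c**2).sum()) if c.any() else 0.0
    beta0j = np.sqrt(scale_sq) * c
    sigma = np.sqrt(total * pct_noise / 100.0 / max(n - 1, 1))
    return Model1SParams(
        beta0=beta0, beta1=beta1, beta0j=beta0j, beta1j=np.zeros(J), sigma=sigma
    )


def apply_missingness(
    table: pd.DataFrame,
    p_missing: float = 0.0,
    p_zero: float = 0.0,
    seed: int = 0,
    value_column: str = "estimate",
) -> pd.DataFrame:
    """Censor a concentration table: drop rows (missing) or zero them out.

    Each row is independently made missing with probability ``p_missing``;
    otherwise its value is set to 0 with probability ``p_zero``.  Zeros are
    kept as explicit 0 rows (they vanish later at the log2 step); missing
    rows are removed from the table.
    """
    for p in (p_missing, p_zero):
        if not 0.0 <= p <= 1.0:
            raise ValueError("censoring probabilities must lie in [0, 1]")
    rng = np.random.default_rng([int(seed) % (2**31), 424242])
    u = rng.random(len(table))
    v = rng.random(len(table))
    keep = u >= p_missing
    out = table.loc[keep].copy()
    out.loc[v[keep] < p_zero, value_column] = 0.0
    return out.reset_index(drop=True)
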