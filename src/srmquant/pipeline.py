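"""End-to-end wiring: simulate -> quantify -> variance components -> compare.

The pipeline reproduces the whole study on synthetic data: it builds the
serial-dilution design, simulates transition chromatograms from a known
ground truth, quantifies every reading with the classical (NLP) and/or
Bayesian (BHI) quantifier — the latter after calibrating the daily
digestion yields on the QC readings — then fits the dilution-linearity
models per protein, decomposes the variance, and compares the two
methods' dilution and technical variance shares with exact Wilcoxon
signed-rank tests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bhi import BHIModel, MCMCConfig, default_priors
from .design import DesignSpec, build_design, design_counts
from .evaluate import correlation_filter, wilcoxon_signed_rank
from .io import config_hash, write_table, write_traces
from .nlp import NLPQuantifier
from .simulate import GroundTruth, TraceSet, default_grid, default_truth, simulate_traces
from .varcomp import DilutionLinearityModel, EmptyDatasetError, SingularFitError

log = logging.getLogger("srmquant")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything a full synthetic run needs."""

    design: DesignSpec = field(default_factory=DesignSpec)
    quantifier: str = "both"  # "nlp" | "bhi" | "both"
    factor: str = "day_couple"  # or "reading_order"
    iterations: int = 600
    warmup: int | None = None
    seed: int = 0
    out_dir: str = "srmquant_out"
    yields_per_day: int | None = None  # cap on yield calibrations used per day
    write_trace_csv: bool = False  # the trace table is large; opt in
    correlation_threshold: float = 0.7

    def __post_init__(self) -> None:
        if self.quantifier not in ("nlp", "bhi", "both"):
            raise ValueError(f"unknown quantifier {self.quantifier!r}")
        if self.factor not in ("day_couple", "reading_order"):
            raise ValueError(f"unknown factor {self.factor!r}")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


@_stage("simulate")
def _simulate(config: PipelineConfig, truth: GroundTruth):
    design = build_design(config.design)
    grid = default_grid(truth)
    traces = simulate_traces(design, truth, grid, seed=config.seed)
    return design, traces


@_stage("quantify-nlp")
def _quantify_nlp(traces: TraceSet, truth: GroundTruth, sample_rids: list[str]):
    quant = NLPQuantifier(truth.pep_map, nominal_width=float(np.mean(truth.lam)))
    sub = TraceSet(
        traces.frame[traces.frame["reading_id"].isin(sample_rids)], validate=False
    )
    return quant.quantify(sub)


@_stage("calibrate-yield")
def _calibrate_yields(
    config: PipelineConfig, design: pd.DataFrame, traces: TraceSet, truth: GroundTruth
):
    """EAP digestion-yield matrix per (day_couple, day, calibration index)."""
    qc = design[design["is_qc"]]
    known_y = truth.sample_y("qc", qc["dilution"].iloc[0])
    grid = traces.grid(qc["reading_id"].iloc[0])
    priors = default_priors(truth.pep_map, grid)
    yields: dict[tuple[int, int], list[np.ndarray]] = {}
    for (j, day), day_rows in qc.groupby(["day_couple", "day"]):
        rids = list(day_rows["reading_id"])
        if config.yields_per_day is not None:
            rids = rids[: config.yields_per_day]
        g_list = []
        for k, rid in enumerate(rids):
            model = BHIModel(
                traces,
                truth.pep_map,
                priors=priors,
                mode="calibrate",
                known_y=known_y,
                reading_ids=[rid],
            )
            res = model.fit(
                MCMCConfig(
                    iterations=config.iterations,
                    warmup=config.warmup,
                    seed=(config.seed + 7919 * (13 * j + 3 * day + k)) % (2**31),
                    mode="calibrate",
                )
            )
            g = truth.pep_map.g.copy()
            g[truth.pep_map.d > 0] = np.clip(res.eap["g"], 1e-3, 1.0)
            g_list.append(g)
        yields[(int(j), int(day))] = g_list
    return yields


@_stage("quantify-bhi")
def _quantify_bhi(
    config: PipelineConfig,
    design: pd.DataFrame,
    traces: TraceSet,
    truth: GroundTruth,
    yields: dict,
):
    """Quantify every sample reading once per same-day yield calibration."""
    grid = traces.grid(design["reading_id"].iloc[0])
    priors = default_priors(truth.pep_map, grid)
    rows = []
    sample_rows = design[~design["is_qc"]]
    for row in sample_rows.itertuples(index=False):
        day_yields = yields[(int(row.day_couple), int(row.day))]
        for k, g in enumerate(day_yields):
            pmap = truth.pep_map.with_yields(g)
            model = BHIModel(
                traces, pmap, priors=priors, mode="quantify", reading_ids=[row.reading_id]
            )
            res = model.fit(
                MCMCConfig(
                    iterations=config.iterations,
                    warmup=config.warmup,
                    seed=(config.seed + 104729 + 31 * k) % (2**31),
                    mode="quantify",
                )
            )
            est = res.protein_estimates
            for prot_row in est.itertuples(index=False):
                rows.append(
                    {
                        "reading_id": f"{row.reading_id}#y{k + 1}",
                        "sample_id": row.sample_id,
                        "day_couple": row.day_couple,
                        "protein": prot_row.protein,
                        "estimate": prot_row.estimate,
                        "posterior_sd": prot_row.posterior_sd,
                        "ci_low": prot_row.ci_low,
                        "ci_high": prot_row.ci_high,
                        "status": "ok",
                    }
                )
    return pd.DataFrame(rows)


def _with_dilution(conc: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    dil = design[~design["is_qc"]][["sample_id", "dilution"]].drop_duplicates()
    return conc.merge(dil, on="sample_id", how="left")


def _add_reading_order(conc: pd.DataFrame) -> pd.DataFrame:
    conc = conc.copy()
    order = {rid: k + 1 for k, rid in enumerate(dict.fromkeys(conc["reading_id"]))}
    conc["reading_order"] = conc["reading_id"].map(order)
    return conc


@_stage("varcomp")
def _varcomp_all(config: PipelineConfig, conc: pd.DataFrame) -> pd.DataFrame:
    tables = []
    for protein, sub in conc.groupby("protein", sort=True):
        try:
            model = DilutionLinearityModel.from_concentrations(sub, factor=config.factor)
            decomp = model.decompose()
        except (EmptyDatasetError, SingularFitError) as exc:
            log.warning("protein %s: %s", protein, exc)
            continue
        tab = decomp.table.copy()
        tab.insert(0, "protein", protein)
        tab.attrs = {}
        tab["mean_slope"] = decomp.mean_slope
        tables.append(tab)
    if not tables:
        raise EmptyDatasetError("no protein could be decomposed")
    return pd.concat(tables, ignore_index=True)


def _component_pairs(varcomps: dict[str, pd.DataFrame], component) -> pd.DataFrame:
    """Per-protein percentage of a component (or sum of components) per method."""
    if isinstance(component, str):
        component = [component]
    merged = None
    for method, tab in varcomps.items():
        sub = tab[tab["component"].isin(component)]
        agg = sub.groupby("protein")["percent"].sum().rename(method)
        merged = agg if merged is None else pd.concat([merged, agg], axis=1)
    return merged.dropna()


@_stage("compare")
def _compare(varcomps: dict[str, pd.DataFrame], retained: list) -> dict:
    out = {}
    # dilution share: theoretical concentration + interaction
    # technical share: two-day process + interaction, plus measurement error
    for name, comps in (
        ("dilution", ["dilution"]),
        ("technical", ["two_day", "measurement_error"]),
    ):
        pairs = _component_pairs(varcomps, comps)
        pairs = pairs.loc[pairs.index.isin(retained)]
        methods = list(pairs.columns)
        if len(methods) != 2 or pairs.empty:
            continue
        a = pairs[methods[0]].to_numpy()
        b = pairs[methods[1]].to_numpy()
        exact = wilcoxon_signed_rank(a, b, method="exact")
        normal = wilcoxon_signed_rank(a, b, method="normal")
        out[name] = {
            "component": name,
            "methods": methods,
            "n": exact.n,
            "W_plus": exact.w_plus,
            "p_exact": exact.p,
            "p_normal_cc": normal.p,
            "reported": "exact",
        }
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full synthetic study; returns the paths and key tables.

    Writes, under ``config.out_dir``: the design table, the ground-truth
    dump, per-method concentration and variance-component CSVs, the
    correlation screen, the Wilcoxon comparison JSON and a run manifest.
    Partial outputs are kept if a later stage fails.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # hash only the scientific configuration, not the output location
    hashable = {k: v for k, v in config.as_dict().items() if k != "out_dir"}
    meta = {"seed": config.seed, "config": config_hash(hashable),
            "srmquant": __version__}

    truth = default_truth(config.design, seed=config.seed)
    design, traces = _simulate(config, truth)
    write_table(design, out_dir / "design.csv", meta)
    (out_dir / "ground_truth.json").write_text(truth.to_json())
    if config.write_trace_csv:
        write_traces(traces, out_dir / "traces.csv", meta)

    sample_rids = list(design.loc[~design["is_qc"], "reading_id"])
    conc_tables: dict[str, pd.DataFrame] = {}
    if config.quantifier in ("nlp", "both"):
        nlp_conc = _quantify_nlp(traces, truth, sample_rids)
        conc_tables["nlp"] = nlp_conc
    if config.quantifier in ("bhi", "both"):
        yields = _calibrate_yields(config, design, traces, truth)
        conc_tables["bhi"] = _quantify_bhi(config, design, traces, truth, yields)

    varcomps: dict[str, pd.DataFrame] = {}
    corr_frames = []
    for method, conc in conc_tables.items():
        conc = _with_dilution(conc, design)
        if config.factor == "reading_order":
            conc = _add_reading_order(conc)
        write_table(conc, out_dir / f"concentrations_{method}.csv", meta)
        varcomps[method] = _varcomp_all(config, conc)
        write_table(varcomps[method], out_dir / f"varcomp_{method}.csv", meta)
        ok = conc["estimate"].notna() & (conc["estimate"] > 0) & conc["dilution"].notna()
        corr_frames.append(
            pd.DataFrame(
                {
                    "protein": conc.loc[ok, "protein"],
                    "method": method,
                    "x": np.log2(conc.loc[ok, "dilution"].astype(float)),
                    "y": np.log2(conc.loc[ok, "estimate"].astype(float)),
                }
            )
        )

    screen = correlation_filter(
        pd.concat(corr_frames, ignore_index=True),
        threshold=config.correlation_threshold,
    )
    write_table(screen, out_dir / "correlation_screen.csv", meta)
    retained = sorted(screen.loc[screen["retained"].fillna(False), "protein"].unique())

    comparison: dict = {}
    if len(varcomps) == 2:
        comparison = _compare(varcomps, retained)
        (out_dir / "comparison.json").write_text(
            json.dumps(comparison, indent=1, sort_keys=True)
        )

    manifest = {
        "seed": config.seed,
        "config": config.as_dict(),
        "config_hash": config_hash(config.as_dict()),
        "version": __version__,
        "design_counts": design_counts(config.design),
        "retained_proteins": retained,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str)
    )
    return {
        "out_dir": out_dir,
        "design": design,
        "truth": truth,
        "concentrations": conc_tables,
        "varcomp": varcomps,
        "screen": screen,
        "comparison": comparison,
    }
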