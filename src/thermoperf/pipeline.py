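"""End-to-end orchestration: validate inputs, run every stage, emit tables.

The pipeline mirrors the analysis order of the study design: tolerance
summaries -> anchored TPC fits and derived metrics -> respirometry reduction
-> Q10 table -> per-species mixed-model selection -> cross-species
mass-adjusted comparison.  Every run is deterministic given the inputs and
``seed``, records a manifest with row counts at each stage, and never
silently overwrites a previous run's outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .errors import SelectionError, ThermoperfError, ValidationError
from .kinematics import trial_max_speed
from .metabolic_stats import (
    fit_candidates,
    log10_prepare,
    rank_group_tests,
    species_adjusted_comparison,
)
from .respirometry import q10_table, rmr_from_trace
from .tpc import (
    derive_metrics,
    fit_all_families,
    select_tpc,
    summarize_tolerance,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_all"]


@dataclass
class RunConfig:
    """Paths, options and the seed for one pipeline run."""

    out_dir: str
    speeds: str | None = None
    trials: str | None = None
    tolerance: str | None = None
    traces: str | None = None
    rmr: str | None = None
    seed: int = 0
    # tpc options
    r2_floor: float = 0.9
    b_level: float = 0.8
    anchor_weight: float = 1.0
    grid_step_c: float = 0.01
    fit_mode: str = "means"  # or "individuals"
    # respirometry options
    window_s: float = 100.0
    flow_ml_min: float = 100.0
    fi_co2: float = 0.0
    # model options
    reference_treatment: int = 15
    alpha: float = 0.05
    interaction: str = "auto"
    overwrite: bool = False

    def __post_init__(self):
        if self.fit_mode not in ("means", "individuals"):
            raise ValidationError(f"bad fit_mode {self.fit_mode!r}")
        has_speed_input = self.speeds or self.trials
        has_rmr_input = self.traces or self.rmr
        if not (has_speed_input or has_rmr_input):
            raise ValidationError("no analysis inputs configured")
        if has_speed_input and not self.tolerance:
            raise ValidationError("TPC analysis requires a tolerance file")


@dataclass
class RunResult:
    """In-memory copies of everything the pipeline wrote."""

    tolerance_summaries: pd.DataFrame | None = None
    tpc_fits: pd.DataFrame | None = None
    tpc_metrics: pd.DataFrame | None = None
    rmr: pd.DataFrame | None = None
    q10: pd.DataFrame | None = None
    model_selection: pd.DataFrame | None = None
    coefficients: pd.DataFrame | None = None
    species_contrasts: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def _write(df: pd.DataFrame, path: Path, manifest: dict, name: str,
           index: bool = False) -> None:
    df.to_csv(path, index=index, float_format="%.10g", lineterminator="\n")
    manifest["row_counts"][name] = int(df.shape[0])


def run_all(config: RunConfig) -> RunResult:
    """Run every configured stage and write the result bundle to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not config.overwrite:
        raise ValidationError(
            f"{manifest_path} exists; refusing to overwrite a previous run "
            "(pass overwrite=True)"
        )

    cfg = asdict(config)
    manifest = {
        "thermoperf_version": __version__,
        "seed": config.seed,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()[:16],
        "row_counts": {},
        "notes": [],
    }
    result = RunResult(manifest=manifest)

    # -- tolerance ---------------------------------------------------------
    summaries = {}
    if config.tolerance:
        records = io.read_tolerance(config.tolerance)
        manifest["row_counts"]["tolerance_in"] = len(records)
        by_species = {}
        for r in records:
            by_species.setdefault(r.species, []).append(r)
        for sp, recs in sorted(by_species.items()):
            summaries[sp] = summarize_tolerance(recs)
        df = pd.DataFrame(
            [
                {
                    "species": s.species,
                    "ct_min_mean": s.ct_min_mean,
                    "ct_min_sd": s.ct_min_sd,
                    "ct_max_mean": s.ct_max_mean,
                    "ct_max_sd": s.ct_max_sd,
                    "ttb_c": s.ttb,
                    "n": s.n,
                }
                for s in summaries.values()
            ]
        )
        result.tolerance_summaries = df
        _write(df, out / "tolerance_summary.csv", manifest, "tolerance_summary")

    # -- speeds ------------------------------------------------------------
    speeds = None
    if config.speeds:
        speeds = io.read_speeds(config.speeds)
    elif config.trials:
        trials = io.read_trials(config.trials)
        manifest["row_counts"]["trials_in"] = len(trials)
        speeds = [trial_max_speed(t) for t in trials]
    if speeds is not None:
        manifest["row_counts"]["speed_observations"] = len(speeds)

    # -- TPC ---------------------------------------------------------------
    if speeds is not None:
        fits_rows, metric_rows = [], []
        sdf = pd.DataFrame(
            [
                {
                    "species": o.species,
                    "treatment": o.treatment_temp,
                    "speed": o.max_speed,
                }
                for o in speeds
            ]
        )
        for sp, grp in sdf.groupby("species"):
            if sp not in summaries:
                manifest["notes"].append(f"no tolerance summary for {sp}; skipped")
                continue
            anchors = summaries[sp]
            n_reported = int(
                len({o.individual_id for o in speeds if o.species == sp})
            )
            if config.fit_mode == "means":
                pts = (
                    grp.groupby("treatment")["speed"].mean().reset_index().values
                )
            else:
                pts = grp[["treatment", "speed"]].values
            fits = fit_all_families(
                pts, anchors,
                n_reported=max(n_reported, len(pts)),
                anchor_weight=config.anchor_weight,
                seed=config.seed,
            )
            for f in fits:
                fits_rows.append(
                    {
                        "species": sp,
                        "family": f.family,
                        "params": ";".join(f"{p:.8g}" for p in f.params),
                        "rss": f.rss,
                        "r2": f.r2,
                        "aicc": f.aicc,
                        "n_fit_points": f.n_fit_points,
                        "n_reported": f.n_reported,
                        "converged": f.converged,
                    }
                )
            try:
                best = select_tpc(fits, r2_floor=config.r2_floor)
            except SelectionError as exc:
                manifest["notes"].append(f"TPC selection failed for {sp}: {exc}")
                continue
            m = derive_metrics(
                best, anchors, level=config.b_level, grid_step=config.grid_step_c
            )
            metric_rows.append(
                {
                    "species": sp,
                    "family": best.family,
                    "ct_min_c": anchors.ct_min_mean,
                    "ct_max_c": anchors.ct_max_mean,
                    "ttb_c": m.ttb,
                    "t_o_c": m.t_o,
                    "tsm_c": m.tsm,
                    "v_max_cm_s": m.v_max,
                    "b80_low_c": m.b80_low,
                    "b80_high_c": m.b80_high,
                    "r2": best.r2,
                    "aicc": best.aicc,
                }
            )
        result.tpc_fits = pd.DataFrame(fits_rows)
        result.tpc_metrics = pd.DataFrame(metric_rows)
        _write(result.tpc_fits, out / "tpc_fits.csv", manifest, "tpc_fits")
        _write(result.tpc_metrics, out / "tpc_metrics.csv", manifest, "tpc_metrics")

    # -- respirometry ------------------------------------------------------
    rmr_records = None
    if config.rmr:
        rmr_records = io.read_rmr(config.rmr)
    elif config.traces:
        traces = io.read_traces(
            config.traces, flow_ml_min=config.flow_ml_min, fi_co2=config.fi_co2
        )
        manifest["row_counts"]["traces_in"] = len(traces)
        rmr_records = [rmr_from_trace(t, window=config.window_s) for t in traces]
    if rmr_records is not None:
        rdf = pd.DataFrame(
            [
                {
                    "individual_id": r.individual_id,
                    "species": r.species,
                    "sex": r.sex,
                    "treatment_c": r.treatment_temp,
                    "body_mass_g": r.body_mass,
                    "vco2_ml_min": r.vco2,
                }
                for r in rmr_records
            ]
        )
        result.rmr = rdf
        _write(rdf, out / "rmr.csv", manifest, "rmr")

        q10 = q10_table(rmr_records)
        q10 = q10.dropna(axis=1, how="all")  # absent treatments drop their columns
        result.q10 = q10
        _write(q10, out / "q10.csv", manifest, "q10", index=True)

        # -- per-species model selection ----------------------------------
        table = log10_prepare(rmr_records)
        dropped = table.attrs.get("n_dropped", 0)
        if dropped:
            manifest["notes"].append(f"log10_prepare dropped {dropped} row(s)")
        sel_rows, coef_rows = [], []
        for sp, grp in table.groupby("species"):
            try:
                fits, best = fit_candidates(
                    grp, reference=config.reference_treatment
                )
            except ThermoperfError as exc:
                manifest["notes"].append(f"model selection failed for {sp}: {exc}")
                continue
            for f in fits:
                sel_rows.append(
                    {
                        "species": sp,
                        "model": f.spec.name,
                        "aicc": f.aicc,
                        "conditional_r2": f.conditional_r2,
                        "converged": f.converged,
                        "best": f.spec.name == best.spec.name,
                    }
                )
            for row in best.coefficients.itertuples():
                coef_rows.append(
                    {
                        "species": sp,
                        "model": best.spec.name,
                        "term": row.term,
                        "estimate": row.estimate,
                        "se": row.se,
                        "z": row.z,
                        "p": row.p,
                    }
                )
        result.model_selection = pd.DataFrame(sel_rows)
        result.coefficients = pd.DataFrame(coef_rows)
        _write(result.model_selection, out / "model_selection.csv", manifest,
               "model_selection")
        _write(result.coefficients, out / "coefficients.csv", manifest,
               "coefficients")

        # -- cross-species comparison -------------------------------------
        if table["species"].nunique() >= 2:
            comp = species_adjusted_comparison(
                table, alpha=config.alpha, interaction=config.interaction
            )
            cdf = comp.contrasts.copy()
            cdf["interaction_retained"] = comp.interaction_retained
            result.species_contrasts = cdf
            _write(cdf, out / "species_contrasts.csv", manifest,
                   "species_contrasts")
            means = comp.adjusted_means.rename_axis("species").reset_index()
            _write(means, out / "adjusted_means.csv", manifest, "adjusted_means")

            kw = rank_group_tests(
                {
                    sp: grp["vco2"].to_numpy()
                    for sp, grp in table.groupby("species")
                }
            )
            manifest["rank_test"] = {"h": kw.h, "p": kw.p}

    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    result.manifest = manifest
    return result
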