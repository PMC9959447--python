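"""End-to-end orchestration: accounting -> DEA -> index -> regressions.

``run_pipeline`` executes the four analysis stages in dependency order on
either simulated or user-supplied inputs, writes every stage output as CSV
with a content hash, and returns a manifest (stage outputs, hashes, seeds,
package version). Reruns with the same configuration are bit-identical;
``verify_manifest`` recomputes the hashes and raises on tampering.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .carbon import (PollutionRecord, activities_from_amounts, chemical_composite,
                     crop_records_from_yields, emission, impute_labor,
                     nps_pollution, sequestration)
from .dea import DMU, score_panel
from .econometrics import (lagged_regressor_fit, moderation_fit, pooled_ols,
                           subsample_fit, threshold_fit, tobit_fit, TobitSpec)
from .exceptions import ConfigurationError, IntegrityError, EcoeffError
from .index import composite_ndi, coupling_coordination, entropy_index
from .synthetic import (SyntheticConfig, generate_activity_panel,
                        generate_indicator_panel, generate_regression_panel)

__all__ = ["PipelineConfig", "run_pipeline", "verify_manifest",
           "accounts_from_activity", "dmus_from_accounts", "ndi_from_indicators"]

logger = logging.getLogger(__name__)

STAGES = ("account", "dea", "index", "fit")

DEFAULT_CONFIG = {
    "simulate": {},              # SyntheticConfig overrides
    "hi_mode": "divide",
    "dea": {"rts": ["vrs", "crs"], "frontier": "pooled"},
    "entropy_epsilon": 1e-4,
    "composite_weights": [0.4, 0.3, 0.3],
    "winsor": 0.01,
    "models": ["baseline"],
    "seed": 0,
    "outdir": "results/pipeline",
}


class PipelineConfig(dict):
    """Validated pipeline configuration (a dict with defaults filled in)."""

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def __init__(self, overrides: dict | None = None):
        merged = {**DEFAULT_CONFIG, **(overrides or {})}
        merged["dea"] = {**DEFAULT_CONFIG["dea"], **merged.get("dea", {})}
        w = merged["composite_weights"]
        if len(w) != 3 or abs(sum(w) - 1.0) > 1e-9:
            raise ConfigurationError("composite_weights must be 3 values summing to 1")
        if merged["hi_mode"] not in ("divide", "multiply"):
            raise ConfigurationError("hi_mode must be 'divide' or 'multiply'")
        super().__init__(merged)


def accounts_from_activity(activity, hi_mode: str = "divide") -> pd.DataFrame:
    """Per unit-year carbon accounts and derived DEA inputs/outputs."""
    rows = []
    crops_by = activity.crops.groupby(["unit", "year"])
    acts_by = activity.activities.groupby(["unit", "year"])
    for (unit, year), q in activity.quantities.groupby(["unit", "year"]):
        q = q.iloc[0]
        crop_yields = dict(
            zip(crops_by.get_group((unit, year))["crop"],
                crops_by.get_group((unit, year))["yield_t"]))
        acts = dict(
            zip(acts_by.get_group((unit, year))["source"],
                acts_by.get_group((unit, year))["activity"]))
        csa = sequestration(crop_records_from_yields(crop_yields), hi_mode=hi_mode)
        ce = emission(activities_from_amounts(acts), out_unit="t")
        nps = nps_pollution(PollutionRecord(q["cod"], q["nh"], q["tn"], q["tp"]))
        labor = impute_labor(q["primary_employment"], q["agri_output"], q["afah_output"])
        chem = chemical_composite(q["pesticide_t"], q["fertilizer_t"], q["film_t"])
        rows.append({
            "unit": unit, "year": year,
            "sown_area": q["sown_area"], "irrigated_area": q["irrigated_area"],
            "labor": labor, "machinery_power": q["machinery_power"],
            "diesel_t": q["diesel_t"], "chemical_t": chem,
            "gross_output": q["gross_output"], "csa": csa,
            "ce": ce, "nps": nps,
        })
    return pd.DataFrame(rows)


_INPUT_COLS = ["sown_area", "irrigated_area", "labor", "machinery_power",
               "diesel_t", "chemical_t"]
_GOOD_COLS = ["gross_output", "csa"]
_BAD_COLS = ["ce", "nps"]


def dmus_from_accounts(accounts: pd.DataFrame) -> list[DMU]:
    return [
        DMU(id=(row["unit"], row["year"]),
            inputs_x=[row[c] for c in _INPUT_COLS],
            good_outputs_yd=[row[c] for c in _GOOD_COLS],
            bad_outputs_yu=[row[c] for c in _BAD_COLS])
        for _, row in accounts.iterrows()
    ]


def ndi_from_indicators(blocks: dict, epsilon: float = 1e-4,
                        weights=(0.4, 0.3, 0.3)) -> pd.DataFrame:
    """Sub-dimension and composite indices per unit-year row.

    Information and innovation are entropy-weighted block composites;
    convergence is the coupled-coordination degree of the entropy-scored
    traditional-infrastructure and informatization subsystems.
    """
    infi = entropy_index(blocks["information"], epsilon=epsilon)
    trad = entropy_index(blocks["traditional"], epsilon=epsilon)
    info_deg = entropy_index(blocks["informatization"], epsilon=epsilon)
    ci = coupling_coordination(trad, info_deg).coordination_D
    inni = entropy_index(blocks["innovation"], epsilon=epsilon)
    records = [composite_ndi(a, b, c, weights=weights)
               for a, b, c in zip(infi, ci, inni)]
    units = blocks["information"].units
    return pd.DataFrame({
        "unit": [u for u, _ in units], "year": [y for _, y in units],
        "infi": [r.infi for r in records], "ci": [r.ci for r in records],
        "inni": [r.inni for r in records], "ndi": [r.ndi for r in records],
    })


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_stage(df: pd.DataFrame, outdir: Path, name: str, manifest: dict):
    path = outdir / f"{name}.csv"
    df.to_csv(path, index=False, float_format="%.10g")
    manifest["stages"][name] = {
        "path": path.name, "rows": int(len(df)), "sha256": _sha256(path)}
    logger.info("stage %s: %d rows -> %s", name, len(df), path)


def run_pipeline(cfg: PipelineConfig | dict) -> dict:
    """Run the full synthetic study; returns the manifest (also written to
    ``outdir/manifest.json``)."""
    if not isinstance(cfg, PipelineConfig):
        cfg = PipelineConfig(cfg)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": cfg["seed"], "stages": {}}

    sim_cfg = SyntheticConfig(**{"seed": cfg["seed"], **cfg["simulate"]})
    activity = generate_activity_panel(sim_cfg)
    blocks = generate_indicator_panel(sim_cfg)
    covariates = generate_regression_panel(sim_cfg).data[
        ["unit", "year", "lu", "aed", "ps", "adr", "rhc", "fsa"]]

    accounts = accounts_from_activity(activity, hi_mode=cfg["hi_mode"])
    _write_stage(accounts, outdir, "account", manifest)

    dmus = dmus_from_accounts(accounts)
    scores = pd.DataFrame({
        "unit": [d.id[0] for d in dmus], "year": [d.id[1] for d in dmus]})
    for rts in cfg["dea"]["rts"]:
        res = score_panel(dmus, rts=rts, frontier=cfg["dea"]["frontier"])
        scores[f"aee_{rts}"] = [round(r.score, 4) for r in res]
        scores[f"status_{rts}"] = [r.status for r in res]
    _write_stage(scores, outdir, "dea", manifest)

    ndi = ndi_from_indicators(blocks, epsilon=cfg["entropy_epsilon"],
                              weights=tuple(cfg["composite_weights"]))
    _write_stage(ndi, outdir, "index", manifest)

    panel = (scores.merge(ndi, on=["unit", "year"])
                   .merge(covariates, on=["unit", "year"]))
    fits = []
    mid_year = int(np.median(panel["year"]))
    primary = "vrs" if "aee_vrs" in panel else "crs"
    for model in cfg["models"]:
        try:
            if model == "baseline":
                for outcome in ("vrs", "crs"):
                    if f"aee_{outcome}" in panel:
                        fit = pooled_ols(panel, outcome=outcome, winsor=cfg["winsor"])
                        fits.append(_fit_rows(fit))
            elif model == "threshold":
                tf = threshold_fit(panel, seed=cfg["seed"], outcome=primary)
                fits.append(_fit_rows(tf.fit, theta=tf.theta_hat,
                                      f_stat=tf.f_stat, boot_p=tf.boot_p))
            elif model == "moderation":
                fits.append(_fit_rows(moderation_fit(panel, outcome=primary)))
            elif model == "lag":
                fits.append(_fit_rows(lagged_regressor_fit(panel, outcome=primary)))
            elif model == "tobit":
                fits.append(_fit_rows(tobit_fit(panel, TobitSpec(0.0), outcome=primary)))
            elif model == "subsample":
                a, b = subsample_fit(panel, lambda df: df["year"] <= mid_year,
                                     outcome=primary, winsor=cfg["winsor"])
                fits.append(_fit_rows(a, side="early"))
                fits.append(_fit_rows(b, side="late"))
            else:
                raise ConfigurationError(f"unknown model {model!r}")
        except EcoeffError as exc:
            raise type(exc)(f"stage fit/{model} failed: {exc}") from exc
    _write_stage(pd.concat(fits, ignore_index=True), outdir, "fit", manifest)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _fit_rows(fit, **extra) -> pd.DataFrame:
    df = pd.DataFrame({
        "model": fit.model, "term": fit.params.index,
        "coef": fit.params.values, "se": fit.se.values,
        "t": fit.tvalues.values, "n_obs": fit.n_obs,
    })
    for k, v in extra.items():
        df[k] = v
    return df


def verify_manifest(outdir) -> dict:
    """Recompute stage-output hashes against the stored manifest; raises
    :class:`IntegrityError` on any mismatch."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    for name, info in manifest["stages"].items():
        path = outdir / info["path"]
        if not path.exists():
            raise IntegrityError(f"stage {name}: missing output {path}")
        actual = _sha256(path)
        if actual != info["sha256"]:
            raise IntegrityError(
                f"stage {name}: hash mismatch ({actual[:12]} != {info['sha256'][:12]})")
    return manifest
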