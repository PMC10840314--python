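"""End-to-end SEC-SAXS processing: load -> ranges -> subtract -> analyze.

``run_workflow`` strings the library modules into the standard decision
path: load the series, pick (or accept) a buffer range, subtract, compute
sliding Rg/MW traces, optionally baseline-correct and recompute, pick (or
accept) a sample range, build the final averaged subtracted profile, and run
Guinier, molecular-weight and BIFT P(r) analysis on it.  Pre-subtracted
series skip the buffer step.  Every automated decision is logged at info
level and every stage outcome is recorded in the result bundle; a failed
stage marks its dependents skipped rather than raising.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import ift, series_lc
from .config import RunConfig
from .exceptions import ValidationError
from .guinier import auto_guinier
from .mw import porod_volume_mw, vc_mw
from .sasdata import (FrameRange, Series, read_dat, read_series_h5,
                      write_dat, write_series_h5, _json_sanitize)

__all__ = ["run_workflow", "summarize", "validate_summary", "load_series"]

log = logging.getLogger("saskit")


def load_series(source) -> Series:
    """Build a Series from an HDF5 path, a list of .dat paths, or pass one
    through unchanged."""
    if isinstance(source, Series):
        return source
    if isinstance(source, (list, tuple)):
        profiles = [read_dat(p) for p in source]
        return Series(profiles)
    path = Path(source)
    if path.suffix in (".h5", ".hdf5"):
        return read_series_h5(path)
    raise ValidationError(f"cannot load a series from {source!r}")


def _guinier_dict(res) -> dict:
    return {k: v for k, v in dataclasses.asdict(res).items()}


def _mw_dict(res) -> dict:
    return dataclasses.asdict(res)


def _pr_dict(pr) -> dict:
    return {"dmax": pr.dmax, "alpha": pr.alpha, "chi2": pr.chi2,
            "evidence": pr.evidence, "i0_extrap": pr.i0_extrap,
            "rg_pr": pr.rg_pr, "force_zero": pr.force_zero,
            "converged": pr.converged, "mc_replicates": pr.mc_replicates}


def run_workflow(source, config: RunConfig | None = None, outdir=None,
                 presubtracted: bool = False, buffer_ranges=None,
                 sample_ranges=None, baseline=None) -> dict:
    """Run the full LC analysis; returns a result bundle dict.

    ``baseline`` is an optional ('linear'|'integral', start FrameRange,
    end FrameRange) triple.  Explicit buffer/sample ranges bypass the
    automated searches but are still validated and reported.
    """
    cfg = config or RunConfig()
    bundle = {"stages": {}, "config": cfg.to_dict(), "status": "ok"}

    def stage(name, status, **extra):
        bundle["stages"][name] = {"status": status, **extra}
        if status == "failed":
            bundle["status"] = "failed"
        log.info("stage %s: %s %s", name, status, extra if extra else "")

    series = load_series(source)
    stage("load", "ok", n_frames=series.n_frames, n_q=len(series.q))

    # ----- buffer selection and subtraction -----
    if presubtracted:
        series.subtracted_i = series.intensity_matrix()
        series.subtracted_sigma = series.sigma_matrix()
        stage("buffer", "skipped", reason="input is pre-subtracted")
    else:
        if buffer_ranges is None:
            buffer_ranges, rep = series_lc.find_buffer_range(series, cfg.series)
            bundle["buffer_report"] = rep.to_dict()
            if not buffer_ranges:
                stage("buffer", "failed", reason="no valid buffer range found")
                return _finish(bundle, series, cfg, outdir)
            log.info("auto buffer range: %s", [r.as_list() for r in buffer_ranges])
        else:
            rep = series_lc.validate_buffer_range(series, buffer_ranges, cfg.series)
            bundle["buffer_report"] = rep.to_dict()
        series_lc.subtract_series(series, buffer_ranges)
        stage("buffer", "ok", ranges=[r.as_list() for r in buffer_ranges],
              valid=bundle["buffer_report"]["valid"])

    # ----- traces -----
    traces = series_lc.sliding_rg_mw(series, config=cfg.series)
    stage("traces", "ok", n_valid=int(np.sum(np.isfinite(traces.rg))))

    # ----- baseline -----
    if baseline is not None:
        kind, b_start, b_end = baseline
        if kind == "linear":
            bl = series_lc.baseline_linear(series, b_start, b_end)
        elif kind == "integral":
            bl = series_lc.baseline_integral(series, b_start, b_end)
        else:
            raise ValidationError(f"unknown baseline kind {kind!r}")
        series_lc.apply_baseline(series, bl)
        traces = series_lc.sliding_rg_mw(series, config=cfg.series)
        stage("baseline", "ok", kind=kind, converged=bl.converged)

    # ----- sample selection -----
    if sample_ranges is None:
        sample_ranges, rep = series_lc.find_sample_range(series, cfg.series)
        bundle["sample_report"] = rep.to_dict()
        if not sample_ranges:
            stage("sample", "failed", reason="no valid sample range found")
            return _finish(bundle, series, cfg, outdir)
        log.info("auto sample range: %s", [r.as_list() for r in sample_ranges])
    else:
        rep = series_lc.validate_sample_range(series, sample_ranges, cfg.series)
        bundle["sample_report"] = rep.to_dict()
    series.analysis["sample_ranges"] = [r.as_list() for r in sample_ranges]
    stage("sample", "ok", ranges=[r.as_list() for r in sample_ranges],
          valid=bundle["sample_report"]["valid"])

    # ----- final profile -----
    if presubtracted:
        sel = series_lc.frames_of(sample_ranges)
        from .sasdata import average_profiles
        final = average_profiles([series.profiles[int(k)] for k in sel])
    else:
        final = series_lc.final_profile(series, sample_ranges=sample_ranges)
    bundle["final_profile"] = final
    stage("final_profile", "ok", n_points=len(final))

    # ----- Guinier -----
    gres = auto_guinier(final, cfg.guinier)
    bundle["guinier"] = gres
    if not gres.success:
        stage("guinier", "failed", reason=gres.reason)
        return _finish(bundle, series, cfg, outdir)
    stage("guinier", "ok", rg=gres.rg, stage_used=gres.stage)

    # ----- molecular weight -----
    mw_vc = vc_mw(final, gres.rg, gres.i0, molecule=cfg.mw_molecule)
    mw_porod = porod_volume_mw(final, gres.rg, gres.i0)
    bundle["mw"] = {"vc": mw_vc, "porod": mw_porod}
    stage("mw", "ok" if mw_vc.success else "failed", mw_vc=mw_vc.mw)

    # ----- BIFT -----
    try:
        pr = ift.bift_auto(final, config=cfg.bift)
        if cfg.refine_dmax and pr.converged:
            dmax = ift.auto_dmax(final, start=pr.dmax, config=cfg.bift)
            if abs(dmax - pr.dmax) > 0.5:
                pr = ift._best_alpha(final, float(dmax), True, cfg.bift)
        if cfg.mc_replicates >= 2:
            pr = ift.mc_errors(final, pr, cfg.mc_replicates, seed=cfg.seed)
        bundle["pr"] = pr
        stage("bift", "ok" if pr.converged else "failed", dmax=pr.dmax)
    except ValidationError as exc:
        stage("bift", "failed", reason=str(exc))
    return _finish(bundle, series, cfg, outdir)


def _finish(bundle, series, cfg, outdir):
    bundle["series"] = series
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if bundle.get("final_profile") is not None:
            write_dat(bundle["final_profile"], outdir / "final_profile.dat")
        t = series.analysis.get("traces")
        if t:
            df = pd.DataFrame({"frame": np.arange(series.n_frames),
                               "scattergram": t["scattergram"], "rg": t["rg"],
                               "rg_err": t["rg_err"], "i0": t["i0"],
                               "mw": t["mw"]})
            df.to_csv(outdir / "traces.csv", index=False)
        for key in ("buffer_report", "sample_report"):
            if key in bundle:
                with open(outdir / f"{key}.json", "w") as fh:
                    json.dump(bundle[key], fh, indent=2)
        write_series_h5(series, outdir / "series.h5")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summarize(bundle), fh, indent=2)
    return bundle


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize(bundle: dict) -> dict:
    """Machine-readable stable-schema summary of a result bundle."""
    doc = {"schema_version": 1,
           "status": bundle.get("status", "ok"),
           "stages": bundle.get("stages", {}),
           "config": bundle.get("config", {})}
    if "guinier" in bundle:
        doc["guinier"] = _guinier_dict(bundle["guinier"])
    if "mw" in bundle:
        doc["mw"] = {k: _mw_dict(v) for k, v in bundle["mw"].items()}
    if "pr" in bundle:
        doc["pr"] = _pr_dict(bundle["pr"])
    for key in ("buffer_report", "sample_report"):
        if key in bundle:
            doc[key] = bundle[key]
    doc = _json_sanitize(doc)
    validate_summary(doc)
    return doc


def _load_schema() -> dict:
    res = importlib.resources.files("saskit") / "resources" / "summary_schema.json"
    return json.loads(res.read_text())


_TYPES = {"object": dict, "number": (int, float), "string": str,
          "integer": int, "boolean": bool, "array": list}


def validate_summary(doc: dict) -> None:
    """Structural check of a summary document against the shipped schema."""
    schema = _load_schema()
    for key in schema["required"]:
        if key not in doc:
            raise ValidationError(f"summary missing required key {key!r}")
    for key, typename in schema["properties"].items():
        if key in doc and doc[key] is not None:
            if not isinstance(doc[key], _TYPES[typename]):
                raise ValidationError(
                    f"summary key {key!r} should be {typename}")
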