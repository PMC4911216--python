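"""End-to-end orchestration: simulate → stats, synth stack → extract → stats, units → fits.

A run is described by a RunConfig (stage list + master seed); every stage gets
a deterministic seed spawned from the master seed unless it sets its own, so a
re-run with the same config reproduces the same summary.  Each run directory
contains a copy of the config, a log file, the declared intermediates (HDF5 /
CSV) and a machine-readable ``summary.json``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import elastic_net as en
from . import esd, io, map_stats, synth, tuning

logger = logging.getLogger(__name__)


def _clean(obj):
    """JSON-serializable copy (numpy scalars/arrays → python)."""
    if isinstance(obj, dict):
        return {str(k): _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def summarize_maps(op: map_stats.OPMap, od: map_stats.ODMap,
                   sine_period: float = 90.0,
                   crossing: bool = True) -> dict:
    """Standard statistics bundle for one OP/OD map pair."""
    out: dict = {}
    pins = map_stats.detect_pinwheels(op)
    out["n_pinwheels"] = len(pins)
    try:
        lam = map_stats.map_wavelength(op)
        out["wavelength_px"] = lam
        if pins:
            out["pinwheel_density"] = len(pins) / float(op.mask.sum()) * lam ** 2
    except ValueError:
        lam = None
    props = map_stats.orientation_proportions(op)
    out["orientation_proportions"] = props
    fit = map_stats.fit_sine_distribution(props, sine_period)
    out["orientation_sine_fit"] = {"amplitude": fit.amplitude, "phase": fit.phase,
                                   "offset": fit.offset, "period": fit.period,
                                   "r_squared": fit.r_squared,
                                   "peak_angles": list(fit.peak_angles)}
    has_both = (od.field[od.mask] > 0).any() and (od.field[od.mask] < 0).any()
    if pins and has_both:
        counts, prop5 = map_stats.pinwheel_od_histogram(pins, od)
        out["pinwheel_od_counts"] = counts
        out["pinwheel_od_proportions"] = prop5
        out["selectivity_by_od_bin"] = map_stats.selectivity_by_od_bin(op, od)
    if crossing and has_both:
        ang = map_stats.crossing_angles(op, od)
        out["n_crossings"] = len(ang)
        if len(ang):
            out["crossing_angle_mean"] = float(np.mean(ang))
            out["crossing_angle_median"] = float(np.median(ang))
    return out


def _stage_simulate(params: dict, seed: int, run_dir: Path) -> dict:
    fields = {f.name for f in dataclasses.fields(en.SimulationConfig)}
    sched_keys = {"K0", "decay", "K_end"}
    sched = en.AnnealSchedule(**{k: params[k] for k in sched_keys if k in params})
    kwargs = {k: v for k, v in params.items() if k in fields and k != "schedule"}
    kwargs.setdefault("seed", seed)
    if "cortex_shape" in kwargs:
        kwargs["cortex_shape"] = tuple(kwargs["cortex_shape"])
    config = en.SimulationConfig(schedule=sched, **kwargs)
    sheet = en.run_simulation(config)
    op, od = en.extract_maps(sheet)
    out = run_dir / params.get("out", "maps.h5")
    ks = sched.k_values()
    attrs = {f.name: getattr(config, f.name)
             for f in dataclasses.fields(en.SimulationConfig)
             if f.name not in ("schedule", "over_assignments", "cortex_shape")}
    attrs["cortex_shape"] = list(config.cortex_shape)
    attrs["over_assignments"] = json.dumps(sorted(config.over_assignments))
    attrs.update(K0=sched.K0, decay=sched.decay, K_end=sched.K_end,
                 n_iterations=len(ks),
                 final_K=float(ks[-1] * sched.decay) if len(ks) else sched.K0)
    io.save_maps(out, op, od, attrs=attrs)
    return {"maps": str(out), "n_iterations": int(sched.n_iterations)}


def _stage_synth_maps(params: dict, seed: int, run_dir: Path) -> dict:
    truth = synth.synth_maps(mode=params.get("mode", "parametric"),
                             seed=params.get("seed", seed),
                             size=params.get("size", 192),
                             wavelength=params.get("wavelength", 44.0),
                             coupling=params.get("coupling", 0.0))
    out = run_dir / params.get("out", "truth_maps.h5")
    io.save_maps(out, truth.op, truth.od,
                 attrs={"provenance": truth.provenance, "seed": truth.seed})
    return {"maps": str(out)}


def _stage_synth_stack(params: dict, seed: int, run_dir: Path) -> dict:
    src = run_dir / params.get("maps", "truth_maps.h5")
    op, od, _ = io.load_maps(src)
    truth = synth.GroundTruth(op, od, "loaded", seed)
    fields = {f.name for f in dataclasses.fields(synth.StackRecipe)}
    recipe_kwargs = {k: v for k, v in params.items() if k in fields}
    if "stim_frames" in recipe_kwargs:
        recipe_kwargs["stim_frames"] = tuple(recipe_kwargs["stim_frames"])
    recipe = synth.StackRecipe(**recipe_kwargs)
    stack = synth.synth_stack(truth, recipe, seed=params.get("seed", seed))
    out = run_dir / params.get("out", "stack.h5")
    io.save_stack(out, stack)
    return {"stack": str(out)}


def _stage_extract(params: dict, seed: int, run_dir: Path) -> dict:
    stack = io.load_stack(run_dir / params.get("stack", "stack.h5"))
    if params.get("align", False):
        stack = esd.align_frames(stack, stack.data[0, 0],
                                 max_shift=params.get("max_shift", 10))
    cstack = esd.average_conditions(stack)
    cstack = esd.preprocess_frames(cstack,
                                   hp_sigma=params.get("hp_sigma", 20.0),
                                   lp_sigma=params.get("lp_sigma", 2.0))
    op, od = esd.extract_maps_esd(cstack, mode=params.get("mode", "binocular"),
                                  shift=tuple(params.get("shift", (5, 5))),
                                  final_lp_sigma=params.get("final_lp_sigma", 12.0))
    out = run_dir / params.get("out", "maps_esd.h5")
    io.save_maps(out, op, od, attrs={"method": "esd",
                                     "mode": params.get("mode", "binocular")})
    return {"maps": str(out)}


def _stage_stats(params: dict, seed: int, run_dir: Path) -> dict:
    op, od, _ = io.load_maps(run_dir / params.get("maps", "maps.h5"))
    if params.get("mask_percentile") is not None:
        mask = map_stats.selectivity_mask(op, params["mask_percentile"])
        op = map_stats.OPMap(op.field, mask)
        od = map_stats.ODMap(od.field, mask)
    stats = summarize_maps(op, od, sine_period=params.get("sine_period", 90.0),
                           crossing=params.get("crossing", True))
    out = run_dir / params.get("out", "stats.json")
    with open(out, "w") as fh:
        json.dump(_clean(stats), fh, indent=1, sort_keys=True)
    write_stats_csv(stats, out.with_suffix(".csv"))
    return {"stats": str(out), **_clean(stats)}


def write_stats_csv(stats: dict, path) -> None:
    """Flat key,value table of the statistics bundle (arrays one row per entry)."""
    rows = []
    for k, v in sorted(_clean(stats).items()):
        if isinstance(v, list):
            rows += [(f"{k}[{i}]", x) for i, x in enumerate(v)]
        elif isinstance(v, dict):
            rows += [(f"{k}.{kk}", vv) for kk, vv in sorted(v.items())
                     if not isinstance(vv, (list, dict))]
        else:
            rows.append((k, v))
    import pandas as pd

    pd.DataFrame(rows, columns=["statistic", "value"]).to_csv(path, index=False)


def _stage_synth_units(params: dict, seed: int, run_dir: Path) -> dict:
    units = synth.synth_units(n=params.get("n", 50),
                              population=params.get("population", "control"),
                              seed=params.get("seed", seed),
                              noise_sigma=params.get("noise_sigma", 0.1))
    out = run_dir / params.get("out", "units.csv")
    synth.units_to_dataframe(units).to_csv(out, index=False)
    return {"units": str(out)}


def _stage_fit_units(params: dict, seed: int, run_dir: Path) -> dict:
    import pandas as pd

    df = pd.read_csv(run_dir / params.get("units", "units.csv"))
    fits = fit_unit_table(df)
    out = run_dir / params.get("out", "fits.json")
    if str(out).endswith(".csv"):
        pd.json_normalize(_clean(fits)).to_csv(out, index=False)
    else:
        with open(out, "w") as fh:
            json.dump(_clean(fits), fh, indent=1, sort_keys=True)
    return {"fits": str(out), "n_units": len(fits)}


def fit_unit_table(df) -> list[dict]:
    """Fit every (unit, eye) curve set of a long-format response table."""
    out = []
    for (uid, eye), grp in df.groupby(["unit_id", "eye"], sort=True):
        rec: dict = {"unit_id": int(uid), "eye": str(eye)}
        ori = grp[grp.stimulus_type == "orientation"]
        if len(ori):
            o, r = tuning.average_opposite_directions(
                ori.stimulus_value.values, ori.rate.values)
            f = tuning.fit_von_mises(o, r)
            rec["von_mises"] = {"Rp": f.Rp, "theta_p": f.theta_p, "k": f.k,
                                "R0": f.R0, "r_squared": f.r_squared,
                                "bandwidth": f.bandwidth}
        for stim, domain in (("sf", "spatial"), ("tf", "temporal")):
            sub = grp[grp.stimulus_type == stim]
            if len(sub):
                f = tuning.fit_skewed_gaussian(sub.stimulus_value.values,
                                               sub.rate.values, domain)
                rec[stim] = {"Rp": f.Rp, "fp": f.fp, "k": f.k, "lam": f.lam,
                             "R0": f.R0, "r_squared": f.r_squared,
                             "bandwidth": f.bandwidth}
        con = grp[grp.stimulus_type == "contrast"]
        if len(con):
            f = tuning.fit_contrast_response(con.stimulus_value.values,
                                             con.rate.values)
            rec["contrast"] = {"Rm": f.Rm, "sigma": f.sigma, "n": f.n,
                               "R0": f.R0, "r_squared": f.r_squared,
                               "saturating": f.saturating}
        out.append(rec)
    return out


_STAGES = {
    "simulate": _stage_simulate,
    "synth_maps": _stage_synth_maps,
    "synth_stack": _stage_synth_stack,
    "extract": _stage_extract,
    "stats": _stage_stats,
    "synth_units": _stage_synth_units,
    "fit_units": _stage_fit_units,
}


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yml", ".yaml")):
        return yaml.safe_load(text)
    return json.loads(text)


def run_pipeline(config: dict, out_dir) -> Path:
    """Execute the configured stages in order; halts on the first failure.

    Per-stage seeds are spawned deterministically from the master seed (stage
    params may override with an explicit ``seed``).  Returns the run directory
    containing config copy, log, intermediates and summary.json.
    """
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("cortexmaps")
    root.addHandler(handler)
    root.setLevel(config.get("log_level", "INFO"))
    try:
        with open(run_dir / "config.json", "w") as fh:
            json.dump(_clean(config), fh, indent=1, sort_keys=True)
        master = int(config.get("seed", 0))
        summary: dict = {"seed": master, "stages": []}
        for i, stage in enumerate(config.get("stages", [])):
            name = stage["name"]
            if name not in _STAGES:
                raise ValueError(f"unknown stage {name!r}")
            params = {k: v for k, v in stage.items() if k != "name"}
            stage_seed = int(np.random.SeedSequence([master, i]).generate_state(1)[0]
                             % (2 ** 31))
            logger.info("stage %d: %s (seed %d)", i, name, stage_seed)
            try:
                result = _STAGES[name](params, stage_seed, run_dir)
            except Exception:
                logger.exception("stage %s failed", name)
                with open(run_dir / "summary.json", "w") as fh:
                    json.dump(_clean(summary), fh, indent=1, sort_keys=True)
                raise RuntimeError(f"pipeline halted: stage {i} ({name}) failed")
            summary["stages"].append({"name": name, **_clean(result)})
        with open(run_dir / "summary.json", "w") as fh:
            json.dump(_clean(summary), fh, indent=1, sort_keys=True)
        return run_dir
    finally:
        root.removeHandler(handler)
        handler.close()
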