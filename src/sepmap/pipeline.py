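"""End-to-end orchestration: scenario config → analysis report.

``run_pipeline`` takes a validated configuration mapping (usually loaded
from YAML), synthesizes or loads each scenario, runs the preprocessing and
topography stages, computes cross-modality comparisons against the reference
(BC) scenario, optionally runs the laminar branch and a developmental
cohort, and returns an ``AnalysisReport``: one long-format table plus a
provenance block (config hash, seed, version) sufficient to regenerate the
report bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import laminar as lam
from . import preprocessing as pp
from . import stats as st
from . import synthetic as syn
from . import topography as topo
from .geometry import GridGeometry, ProbeGeometry

__all__ = ["ConfigError", "AnalysisReport", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """Raised with the exhaustive list of schema violations."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" +
                         "\n".join(f"  - {e}" for e in errors))


@dataclass
class AnalysisReport:
    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def to_dir(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "report.tsv", sep="\t", index=False,
                          float_format="%.6g")
        (out / "report.meta.json").write_text(json.dumps(self.meta, indent=1))
        return out


_BUILTINS = ("bc", "asw", "ablated")


def validate_config(config: dict) -> list[str]:
    """Exhaustive schema check; returns all violations, not just the first."""
    errors: list[str] = []
    if not isinstance(config, dict):
        return ["configuration root must be a mapping"]
    seed = config.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        errors.append("seed must be a non-negative integer")
    for key, lo in (("fs_hz", 2000.0), ("target_fs_hz", 1.0),
                    ("step_um", 0.0)):
        v = config.get(key)
        if v is not None and (not isinstance(v, (int, float)) or v <= lo - 1):
            errors.append(f"{key} must be a number >= {lo}")
    scenarios = config.get("scenarios")
    if not isinstance(scenarios, list) or not scenarios:
        errors.append("scenarios must be a non-empty list")
        scenarios = []
    for i, sc in enumerate(scenarios):
        where = f"scenarios[{i}]"
        if not isinstance(sc, dict):
            errors.append(f"{where} must be a mapping")
            continue
        if "builtin" in sc:
            if sc["builtin"] not in _BUILTINS:
                errors.append(
                    f"{where}.builtin must be one of {_BUILTINS}"
                )
        elif "config" in sc:
            try:
                syn.ScenarioConfig.from_dict(sc["config"])
            except (TypeError, ValueError, KeyError) as exc:
                errors.append(f"{where}.config is invalid: {exc}")
        else:
            errors.append(f"{where} needs either 'builtin' or 'config'")
        nt = sc.get("n_trials")
        if nt is not None and (not isinstance(nt, int) or nt < 1):
            errors.append(f"{where}.n_trials must be a positive integer")
        age = sc.get("age")
        if age is not None and (not isinstance(age, int) or age < 6):
            errors.append(f"{where}.age must be an integer >= 6")
    lam_cfg = config.get("laminar")
    if lam_cfg is not None:
        if not isinstance(lam_cfg, dict):
            errors.append("laminar must be a mapping")
        else:
            nt = lam_cfg.get("n_trials")
            if nt is not None and (not isinstance(nt, int) or nt < 1):
                errors.append("laminar.n_trials must be a positive integer")
    cohort = config.get("cohort")
    if cohort is not None:
        if not isinstance(cohort, dict) or not isinstance(
            cohort.get("ages"), list
        ):
            errors.append("cohort must be a mapping with an 'ages' list")
    return errors


def _build_scenario(sc: dict, seed: int, geometry: GridGeometry
                    ) -> syn.ScenarioConfig:
    kwargs = {}
    for k in ("age", "n_trials", "noise_sd", "latency_jitter_sd"):
        if k in sc:
            kwargs[k] = sc[k]
    noise_free = bool(sc.get("noise_free", False))
    builtin = sc.get("builtin")
    if builtin == "bc":
        return syn.bc_scenario(seed=seed, geometry=geometry,
                               noise_free=noise_free, **kwargs)
    if builtin == "asw":
        return syn.asw_scenario(seed=seed, geometry=geometry,
                                noise_free=noise_free, **kwargs)
    if builtin == "ablated":
        base = syn.bc_scenario(seed=seed, geometry=geometry,
                               noise_free=noise_free, **kwargs)
        return syn.ablated_scenario(base, seed=seed)
    cfg = syn.ScenarioConfig.from_dict(sc["config"])
    return dataclasses.replace(cfg, rng_seed=seed)


def _analyze_scenario(cfg: syn.ScenarioConfig, geometry: GridGeometry,
                      fs: float, target_fs: float, step: float) -> dict:
    rec = syn.simulate_grid_session(cfg, geometry, fs)
    avg = pp.preprocess(rec, target_fs=target_fs)
    peaks = topo.find_component_peaks(avg)
    result = {"config": cfg, "avg": avg, "peaks": peaks,
              "locations": {}, "regions": {}}
    for label in ("P", "N"):
        pk = peaks[label]
        if pk:
            _, loc, region = topo.analyze_component(avg, pk, step=step)
            result["locations"][label] = loc
            result["regions"][label] = region
    return result


def _scenario_rows(name: str, res: dict) -> list[dict]:
    rows = []
    cfg = res["config"]
    for label in ("P", "N"):
        pk = res["peaks"][label]
        base = {"row_kind": "component", "scenario": name,
                "modality": cfg.modality, "age_pnd": cfg.age,
                "component": label}
        if not pk:
            rows.append({**base, "row_kind": "no_response",
                         "detection_floor_uv": pk.floor})
            continue
        loc = res["locations"][label]
        region = res["regions"][label]
        rows.append({
            **base,
            "channel": pk.channel,
            "latency_ms": pk.latency,
            "amplitude_uv": pk.amplitude,
            "peak_x_um": loc.x,
            "peak_y_um": loc.y,
            "half_width_area_mm2": region.area,
            "area_truncated": region.truncated,
        })
    if res["peaks"]["P"] and res["peaks"]["N"]:
        disp = topo.displacement(res["locations"]["P"],
                                 res["locations"]["N"])
        ov = topo.overlap(res["regions"]["P"], res["regions"]["N"])
        rows.append({
            "row_kind": "pn_displacement", "scenario": name,
            "modality": cfg.modality, "age_pnd": cfg.age,
            "r_um": disp.r, "theta_deg": disp.theta,
            "intersection_mm2": ov.intersection_area,
            "overlap_frac_of_p": ov.frac_of_a,
            "overlap_frac_of_n": ov.frac_of_b,
        })
    return rows


def _cross_modality_rows(name: str, res: dict, ref_name: str,
                         ref: dict) -> list[dict]:
    rows = []
    for label in ("P", "N"):
        if not (res["peaks"][label] and ref["peaks"][label]):
            continue
        disp = topo.displacement(ref["locations"][label],
                                 res["locations"][label])
        ov = topo.overlap(ref["regions"][label], res["regions"][label])
        rows.append({
            "row_kind": "cross_modality", "scenario": name,
            "reference_scenario": ref_name,
            "modality": res["config"].modality, "component": label,
            "r_um": disp.r, "theta_deg": disp.theta,
            "overlap_frac_of_reference": ov.frac_of_a,
        })
    return rows


def _ablation_rows(name: str, res: dict, ref: dict | None) -> list[dict]:
    avg = res["avg"]
    post = avg.data[:, avg.stim_index:]
    resid = float(np.max(np.abs(post)))
    row = {"row_kind": "ablation", "scenario": name,
           "max_post_stimulus_uv": resid}
    if ref is not None and ref["peaks"]["P"]:
        row["amplitude_ratio_vs_reference"] = (
            resid / abs(ref["peaks"]["P"].amplitude)
        )
    return [row]


def _laminar_rows(config: dict, seed: int) -> list[dict]:
    probe = ProbeGeometry()
    spec = syn.LaminarSpec()
    cfg = syn.ScenarioConfig(
        n_trials=int(config.get("n_trials", 5)),
        noise_sd=float(config.get("noise_sd", 5.0)),
        rng_seed=seed,
        laminar=spec,
        components=(),
    )
    fs = float(config.get("fs_hz", 20000.0))
    rec = syn.simulate_laminar_session(cfg, probe, fs)
    mua = lam.bandpass_mua(rec)
    trains = lam.detect_spikes(mua)
    hist = lam.psth(trains, rec.event_times)
    lfp = lam.extract_lfp(rec)
    ep = pp.epoch(lfp, pre=0.5, post=1.0)
    ep = pp.baseline_correct(ep)
    avg = pp.average_epochs(ep)
    csd_map = lam.csd(avg)
    sink_depth, sink_time = csd_map.sink()
    rates = hist.rate_hz()
    best_bin, best_ch = np.unravel_index(int(np.argmax(rates)), rates.shape)
    return [{
        "row_kind": "laminar", "scenario": "laminar",
        "true_sink_depth_um": spec.sink_depth,
        "csd_sink_depth_um": sink_depth,
        "csd_sink_time_ms": sink_time,
        "mua_peak_depth_um": float(probe.depths[best_ch]),
        "mua_peak_rate_hz": float(rates[best_bin, best_ch]),
        "n_spikes_total": int(sum(t.n_spikes for t in trains)),
    }]


def _cohort_rows(cohort: dict, geometry: GridGeometry, seed: int,
                 fs: float, target_fs: float) -> list[dict]:
    ages = [int(a) for a in cohort["ages"]]
    n_trials = int(cohort.get("n_trials", 4))
    p_lat, n_lat = [], []
    for i, age in enumerate(ages):
        cfg = syn.bc_scenario(age=age, seed=seed + 1000 + i,
                              n_trials=n_trials, geometry=geometry,
                              noise_free=bool(cohort.get("noise_free", True)))
        rec = syn.simulate_grid_session(cfg, geometry, fs)
        avg = pp.preprocess(rec, target_fs=target_fs)
        peaks = topo.find_component_peaks(avg)
        if peaks["P"]:
            p_lat.append((age, peaks["P"].latency))
        if peaks["N"]:
            n_lat.append((age, peaks["N"].latency))
    rows = []
    for label, pairs in (("P", p_lat), ("N", n_lat)):
        if len(pairs) < 4:
            continue
        a = np.array([p[0] for p in pairs], dtype=float)
        v = np.array([p[1] for p in pairs], dtype=float)
        rho = st.spearman(a, v)
        fit = st.fit_exponential_trend(a, v)
        rows.append({
            "row_kind": "cohort_trend", "component": label,
            "n_animals": len(pairs),
            "spearman_rho": rho.statistic, "spearman_p": rho.p,
            "exp_a_ms": fit.a, "exp_b_per_day": fit.b, "exp_c_ms": fit.c,
            "residual_rms_ms": fit.residual_rms,
        })
    return rows


def run_pipeline(config: dict) -> AnalysisReport:
    """Execute the configured scenarios end to end and build the report."""
    errors = validate_config(config)
    if errors:
        raise ConfigError(errors)
    seed = int(config.get("seed", 0))
    fs = float(config.get("fs_hz", 4000.0))
    target_fs = float(config.get("target_fs_hz", 2000.0))
    step = float(config.get("step_um", 10.0))
    geometry = GridGeometry()

    rows: list[dict] = []
    results: dict[str, dict] = {}
    ref_name = None
    for i, sc in enumerate(config["scenarios"]):
        name = sc.get("name", f"scenario{i}")
        cfg = _build_scenario(sc, seed + i, geometry)
        res = _analyze_scenario(cfg, geometry, fs, target_fs, step)
        results[name] = res
        rows.extend(_scenario_rows(name, res))
        if ref_name is None and cfg.modality == "BC" and not cfg.ablated:
            ref_name = name
    for name, res in results.items():
        if name == ref_name or ref_name is None:
            continue
        cfg = res["config"]
        if cfg.ablated:
            rows.extend(_ablation_rows(name, res, results[ref_name]))
        else:
            rows.extend(_cross_modality_rows(name, res, ref_name,
                                             results[ref_name]))
    if config.get("laminar"):
        rows.extend(_laminar_rows(config["laminar"], seed + 500))
    if config.get("cohort"):
        rows.extend(_cohort_rows(config["cohort"], geometry, seed,
                                 fs, target_fs))

    table = pd.DataFrame(rows)
    canonical = json.dumps(config, sort_keys=True).encode()
    meta = {
        "config": config,
        "config_sha256": hashlib.sha256(canonical).hexdigest(),
        "seed": seed,
        "software_version": __version__,
    }
    return AnalysisReport(table=table, meta=meta)
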