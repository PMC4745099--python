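"""End-to-end orchestration: simulate/load -> classical stats -> Bayes ->
energetics -> mechanics -> activity, bundled into one deterministic JSON report.

Each stage receives its own seed derived from the master seed by a fixed
counter offset (stage index), so a stage re-run in isolation with that seed
reproduces its slice of the bundle, and identical seed + config yield a
byte-identical JSON document.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np

from claysub import activity as act
from claysub import stats as st
from claysub.bayes import run_substitution_inference
from claysub.core import (
    AnalysisConfig,
    ExperimentDataset,
    Scale,
    filter_included,
    read_dataset,
)
from claysub.energetics import MineralProfile, make_budget
from claysub.mechanics import WallSpec, load_capacity, rigidity_ratio
from claysub.synth import SynthSpec, generate_dataset, generate_timelines

logger = logging.getLogger("claysub")

__all__ = ["STAGES", "stage_seed", "analyze_dataset", "run_pipeline", "write_bundle"]

STAGES = ("simulate", "analyze", "bayes", "energetics", "mechanics", "activity")

# Imposed loads of the two experimental designs (kg): four wood blocks under
# pavers plus water barrels in the field, a single paver in the lab.
_IMPOSED_LOAD_KG = {"field": 245.0, "lab": 1.6}
_WALL_STRENGTH_MPA = 0.22
_WALL_AREA_CM2 = 236.0


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed: master seed advanced by the stage's fixed index."""
    return int(master_seed) + STAGES.index(stage)


def analyze_dataset(ds: ExperimentDataset, cfg: AnalysisConfig, seed: int) -> dict:
    """Classical test battery on one experiment's included replicates.

    Balanced one-way ANOVAs on clay mass, clay per unit volume, leftover wood
    and normalized consumption; Lilliefors normality of the percent
    clay-per-volume data; per-arm beta fits and bootstrap joint models with a
    kurtosis comparison.  Leftover wood is expressed as percent of initial
    wood, clay per volume as percent of the across-arm maximum.
    """
    included = filter_included(ds)
    if len(included) < 2:
        raise ValueError("need at least two included replicates for the test battery")
    unloaded = [r.unloaded for r in included.replicates]
    loaded = [r.loaded for r in included.replicates]

    def arr(units, fn):
        return np.array([fn(u) for u in units])

    clay_u, clay_l = arr(unloaded, lambda u: u.clay_mass), arr(loaded, lambda u: u.clay_mass)
    cpv_u = arr(unloaded, st.clay_per_volume)
    cpv_l = arr(loaded, st.clay_per_volume)
    left_u = arr(unloaded, lambda u: u.leftover_wood)
    left_l = arr(loaded, lambda u: u.leftover_wood)
    cons_u = arr(unloaded, st.normalized_consumption)
    cons_l = arr(loaded, st.normalized_consumption)

    anovas = {
        "clay_mass": st.anova_oneway([clay_u, clay_l]),
        "clay_per_volume": st.anova_oneway([cpv_u, cpv_l]),
        "leftover_wood": st.anova_oneway([left_u, left_l]),
        "normalized_consumption": st.anova_oneway([cons_u, cons_l]),
    }

    # Percent scaling: leftover wood relative to initial wood; clay per
    # volume relative to the maximum across both arms (scale-invariant).
    cpv_ref = float(max(cpv_u.max(), cpv_l.max()))
    pct_left_u = st.to_percent(left_u / arr(unloaded, lambda u: u.initial_wood), reference=1.0)
    pct_left_l = st.to_percent(left_l / arr(loaded, lambda u: u.initial_wood), reference=1.0)
    pct_cpv_u = st.to_percent(cpv_u, reference=cpv_ref)
    pct_cpv_l = st.to_percent(cpv_l, reference=cpv_ref)

    lilliefors = {
        "clay_per_volume_loaded_p": st.lilliefors_normality(pct_cpv_l, seed=seed),
        "clay_per_volume_unloaded_p": st.lilliefors_normality(pct_cpv_u, seed=seed + 1),
    }

    joints = {}
    for name, pct_cpv, pct_left, sub_seed in (
        ("loaded", pct_cpv_l, pct_left_l, seed + 2),
        ("unloaded", pct_cpv_u, pct_left_u, seed + 3),
    ):
        clay_fit = st.fit_beta_moments(pct_cpv)
        wood_fit = st.fit_beta_moments(pct_left)
        if cfg.coupling_model == "gaussian_copula":
            from scipy.stats import spearmanr

            rho = float(np.clip(spearmanr(pct_cpv, pct_left).statistic, -0.999, 0.999))
            coupling = st.CouplingSpec(kind="gaussian_copula", rho=rho)
        else:
            coupling = st.CouplingSpec(kind="independent")
        joints[name] = st.bootstrap_joint(
            clay_fit, wood_fit, coupling, n=cfg.n_bootstrap, seed=sub_seed
        )

    kurt = st.compare_kurtosis(joints["loaded"], joints["unloaded"])

    def joint_doc(m: st.JointDistributionModel) -> dict:
        return {
            "marginal_clay": asdict(m.marginal_clay),
            "marginal_wood": asdict(m.marginal_wood),
            "coupling": asdict(m.coupling),
            "n_bootstrap": int(m.bootstrap_samples.shape[0]),
            "rank_correlation": m.rank_correlation,
            "excess_kurtosis": list(m.excess_kurtosis),
            "joint_excess_kurtosis": m.joint_excess_kurtosis,
        }

    return {
        "n_included": len(included),
        "anova": {k: asdict(v) for k, v in anovas.items()},
        "lilliefors": lilliefors,
        "joint_models": {k: joint_doc(v) for k, v in joints.items()},
        "kurtosis_comparison": asdict(kurt),
        "means": {
            "clay_unloaded_g": float(clay_u.mean()),
            "clay_loaded_g": float(clay_l.mean()),
            "clay_per_volume_unloaded": float(cpv_u.mean()),
            "clay_per_volume_loaded": float(cpv_l.mean()),
            "leftover_unloaded_g": float(left_u.mean()),
            "leftover_loaded_g": float(left_l.mean()),
            "consumption_unloaded": float(cons_u.mean()),
            "consumption_loaded": float(cons_l.mean()),
        },
    }


def run_pipeline(
    cfg: AnalysisConfig,
    scale: Scale | str = Scale.LAB,
    *,
    simulate: bool = True,
    data_path: str | Path | None = None,
    timelines_path: str | Path | None = None,
    synth_spec: SynthSpec | None = None,
) -> dict:
    """Run every stage and return the JSON-serializable report bundle.

    With ``simulate=True`` (default) the datasets come from the synthetic
    generator at the scale's default study conditions; otherwise
    ``data_path`` (and optionally ``timelines_path``) are read.  Identical
    config and seed produce a byte-identical bundle.
    """
    scale = Scale(scale)
    t0 = time.perf_counter()
    timings: dict[str, float] = {}
    bundle: dict = {}

    def mark(stage: str, start: float) -> None:
        timings[stage] = round(time.perf_counter() - start, 6)

    # --- simulate / load ---------------------------------------------------
    s = time.perf_counter()
    if simulate:
        if synth_spec is None:
            maker = SynthSpec.field_defaults if scale is Scale.FIELD else SynthSpec.lab_defaults
            synth_spec = maker(seed=stage_seed(cfg.seed, "simulate"))
        ds = generate_dataset(synth_spec)
        timelines = generate_timelines(
            synth_spec, duration_days=min(synth_spec.duration_days, 30)
        )
        bundle["simulate"] = {
            "scale": scale.value,
            "n_pairs": synth_spec.n_pairs,
            "n_included": filter_included(ds).n_included,
            "seed": synth_spec.seed,
        }
    else:
        if data_path is None:
            raise FileNotFoundError("data_path is required when simulate=False")
        data_path = Path(data_path)
        if not data_path.exists():
            raise FileNotFoundError(f"input dataset not found: {data_path}")
        ds = read_dataset(data_path, scale)
        timelines = None
        if timelines_path is not None:
            timelines_path = Path(timelines_path)
            if not timelines_path.exists():
                raise FileNotFoundError(f"timelines file not found: {timelines_path}")
            timelines = act.read_timelines(timelines_path)
        bundle["simulate"] = {
            "scale": scale.value,
            "n_pairs": len(ds),
            "n_included": filter_included(ds).n_included,
            "source": str(data_path),
        }
    mark("simulate", s)

    # --- classical stats ---------------------------------------------------
    s = time.perf_counter()
    try:
        bundle["analyze"] = analyze_dataset(ds, cfg, seed=stage_seed(cfg.seed, "analyze"))
    except Exception as exc:
        raise RuntimeError(f"stage 'analyze' failed on {scale.value} dataset: {exc}") from exc
    mark("analyze", s)

    # --- Bayesian substitution ---------------------------------------------
    s = time.perf_counter()
    try:
        report = run_substitution_inference(ds, cfg)
    except Exception as exc:
        raise RuntimeError(f"stage 'bayes' failed on {scale.value} dataset: {exc}") from exc
    bundle["bayes"] = {
        "prior": report.prior_kind,
        "mean_clay_g": report.mean_clay,
        "successes": [bool(x) for x in report.successes],
        "n_successes": report.n_successes,
        "median": report.median,
        "hdr_lower": report.interval.lower,
        "hdr_upper": report.interval.upper,
        "credibility_mass": report.interval.mass,
        "interval_method": report.interval.method,
        "trajectory": list(report.trajectory),
    }
    mark("bayes", s)

    # --- energetics ---------------------------------------------------------
    s = time.perf_counter()
    means = bundle["analyze"]["means"]
    extra_clay_kg = max(means["clay_loaded_g"] - means["clay_unloaded_g"], 0.0) / 1000.0
    wood_consumed_g = means["consumption_loaded"] * float(
        np.mean([r.loaded.initial_wood for r in filter_included(ds).replicates])
    )
    budget = make_budget(
        clay_mass_kg=extra_clay_kg,
        wood_consumed_g=wood_consumed_g,
        profile=MineralProfile.mound_default(),
        gross_energy_kj_per_g=cfg.gross_energy_wood,
        lignin_fraction=cfg.lignin_fraction,
        g=cfg.gravity,
        normalize_fractions=cfg.normalize_mineral_fractions,
    )
    bundle["energetics"] = asdict(budget)
    mark("energetics", s)

    # --- mechanics -----------------------------------------------------------
    s = time.perf_counter()
    wall = WallSpec(
        compressive_strength_mpa=_WALL_STRENGTH_MPA,
        cross_section_cm2=_WALL_AREA_CM2,
        imposed_load_kg=_IMPOSED_LOAD_KG[scale.value],
    )
    cap = load_capacity(wall, g=cfg.gravity)
    bundle["mechanics"] = {
        "wall": asdict(wall),
        "capacity": asdict(cap),
        "rigidity_ratio_half_hollow": rigidity_ratio(1.0, 0.5**0.5),
    }
    mark("mechanics", s)

    # --- activity -------------------------------------------------------------
    s = time.perf_counter()
    if timelines:
        segs = [act.segment_periods(t) for t in timelines]
        days, freq_loaded = act.contact_histogram(timelines, "loaded")
        _, freq_unloaded = act.contact_histogram(timelines, "unloaded")
        grid, dens = act.kernel_activity_estimate(days, freq_loaded)
        bundle["activity"] = {
            "onsets": act.summarize_onsets(segs),
            "histogram": {
                "days": days.tolist(),
                "full_contact_unloaded": freq_unloaded.tolist(),
                "full_contact_loaded": freq_loaded.tolist(),
            },
            "kernel_loaded": {"days": grid.tolist(), "density": dens.tolist()},
        }
    else:
        bundle["activity"] = {"onsets": None, "note": "no timelines supplied"}
    mark("activity", s)

    config_doc = asdict(cfg)
    bundle["meta"] = {
        "config": config_doc,
        "config_hash": hashlib.sha256(
            json.dumps(config_doc, sort_keys=True).encode()
        ).hexdigest()[:16],
        "seed": cfg.seed,
        "stage_seconds": timings,
    }
    logger.info("pipeline complete in %.2fs", time.perf_counter() - t0)
    return bundle


def write_bundle(bundle: dict, path: str | Path) -> None:
    """Write the bundle as deterministic JSON (sorted keys, fixed separators).

    Stage timings vary run to run, so they are dropped from the persisted
    document to keep identical seed + config byte-identical.
    """
    doc = {k: v for k, v in bundle.items()}
    meta = dict(doc.get("meta", {}))
    meta.pop("stage_seconds", None)
    doc["meta"] = meta
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n", encoding="utf-8")
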