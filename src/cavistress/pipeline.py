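"""End-to-end orchestration: synthesis -> optical quantification -> fitting
-> trait table and threshold-coincidence report.

`run_pipeline` reproduces, on synthetic bundles, the analysis of a
whole-plant dehydration study: thirteen replicate leaves monitored for
cavitation and width, six plants for Fv/Fm and stem cavitation, plus
rehydration-kinetics, mass-loss and pressure-volume side experiments.  The
output is a trait table (one row per trait, pooled mean +/- sd with
per-replicate provenance) and a threshold comparison contrasting the water
potentials of the candidate damage triggers: breakpoint of leaf width,
breakpoint of Fv/Fm, 20% HOV cavitation, the closed-form runaway point,
turgor loss and deep stem cavitation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from . import fitting, hydraulics, optical, synthesis

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "compare_groups",
    "write_trait_table",
    "write_report",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Run configuration; every field has a study-condition default.

    ``couple_thresholds`` generates the width and Fv/Fm breakpoints at the
    runaway water potential of the configured hydraulic parameters instead
    of their independently measured defaults, emulating the hypothesis
    that one mechanism underlies all three thresholds.
    ``optical_mode`` selects whether leaf events are rendered to an image
    stack and re-detected ("render") or taken from the generator's ground
    truth ("schedule"); the downstream analysis is identical.
    """

    seed: int = 0
    n_leaves: int = 13
    n_fvfm_plants: int = 6
    n_gmin_leaves: int = 5
    n_pv_leaves: int = 5

    # drydown
    psi0: float = -0.5
    psi_end: float = -6.0
    days: float = 5.0
    cadence_min: float = 5.0
    psi_noise_sd: float = 0.03

    # hydraulics
    kmax: float = 5.77
    p50_leaf: float = -3.73
    alpha: float = 0.09
    gmin: float = 10.02
    temp_c: float = 24.31
    rh_pct: float = 35.86
    patm_kpa: float = 101.3
    capacitance: float = 40.0

    # thresholds for the scalar series
    bp_width_mpa: float = -3.62
    bp_fvfm_mpa: float = -3.53
    fvfm_plateau: float = 0.80
    fvfm_noise_sd: float = 0.02
    width_noise_sd: float = 0.5
    post_runaway_multiplier: float = 3.0
    couple_thresholds: bool = False

    # per-order cavitation sigmoids (defaults = study means)
    order_p50: dict = field(default_factory=lambda: dict(synthesis.ORDER_P50))
    order_alpha: dict = field(default_factory=lambda: dict(synthesis.ORDER_ALPHA))
    p50_stem: float = -3.97
    alpha_stem: float = 0.743
    n_stem_events: int = 80

    # optical
    optical_mode: str = "render"      # "render" | "schedule"
    threshold_rule: object = "otsu"
    min_area: int = 4
    merge_window: int = 2
    tlp: float = -2.01

    out_dir: str | None = None

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        flat: dict = {}
        for section in ("synthesis", "hydraulics", "optical", "fitting", "report"):
            flat.update(raw.pop(section, {}))
        flat.update(raw)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)


@dataclass
class PipelineResult:
    trait_table: pd.DataFrame
    replicates: pd.DataFrame
    residuals_mpa: pd.DataFrame
    residuals_min: pd.DataFrame
    anova: dict
    provenance: dict


# --------------------------------------------------------------------------
# group statistics
# --------------------------------------------------------------------------

def compare_groups(values_by_group: dict[str, "np.ndarray"]) -> dict:
    """One-way ANOVA with Tukey HSD post hoc comparison.

    Returns ``{"F", "p", "tukey": [{"group1", "group2", "meandiff",
    "p_adj", "reject"}, ...]}``.  Identical groups give F = 0; zero
    within-group variance everywhere is a degenerate design and raises.
    """
    names = list(values_by_group)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if any(a.size < 2 for a in arrays):
        raise ValueError("need at least two values per group")
    if all(np.var(a) == 0 for a in arrays):
        raise ValueError("zero within-group variance in every group")
    F, p = stats.f_oneway(*arrays)
    flat = np.concatenate(arrays)
    labels = np.concatenate([[g] * a.size for g, a in zip(names, arrays)])
    tk = pairwise_tukeyhsd(flat, labels)
    pairs = [
        {
            "group1": str(r[0]), "group2": str(r[1]),
            "meandiff": float(r[2]), "p_adj": float(r[3]),
            "reject": bool(r[6]),
        }
        for r in tk.summary().data[1:]
    ]
    return {"F": float(F), "p": float(p), "tukey": pairs}


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def _leaf_events(cfg: PipelineConfig, geometry, psi_series, psi_true, seed):
    """Events for one leaf: ground-truth schedule, optionally rendered to a
    stack and re-detected.

    Trigger potentials are mapped to frames through the noiseless ramp
    (events fire when the plant truly reaches the trigger potential);
    detections are later joined to the noisy psychrometer record, as they
    would be for real data.
    """
    s1, s2, s3 = seed.spawn(3) if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed).spawn(3)
    schedule = synthesis.schedule_cavitation_events(
        geometry, psi_true,
        order_p50=cfg.order_p50, order_alpha=cfg.order_alpha,
        seed=np.random.default_rng(s1),
    )
    if cfg.optical_mode == "schedule":
        events = []
        for _, ev in schedule.events.iterrows():
            rr, cc = schedule.footprints[int(ev["event_id"])]
            events.append(optical.CavitationEvent(
                event_id=int(ev["event_id"]),
                start_frame=int(ev["frame"]), end_frame=int(ev["frame"]),
                rows=rr, cols=cc, area_px=int(rr.size),
                centroid=(float(rr.mean()), float(cc.mean())),
            ))
    elif cfg.optical_mode == "render":
        stack = synthesis.render_stack(
            geometry, schedule, config=synthesis.RenderConfig(),
            seed=np.random.default_rng(s2),
        )
        diff = optical.difference_stack(stack)
        del stack
        events = optical.detect_events(
            diff, threshold=cfg.threshold_rule,
            min_area=cfg.min_area, merge_window=cfg.merge_window,
        )
        del diff
    else:
        raise ValueError(f"unknown optical_mode {cfg.optical_mode!r}")
    events = optical.assign_vein_order(
        events, geometry.order_mask, geometry.segment_map
    )
    events = optical.join_psi(events, psi_series, cfg.cadence_min)
    return schedule, events


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full synthetic study and assemble the trait table.

    Deterministic under ``config.seed``; artifacts are written under
    ``config.out_dir`` when set.
    """
    cfg = config or PipelineConfig()
    root = np.random.SeedSequence(cfg.seed)
    (ss_leaves, ss_fvfm, ss_stem, ss_side) = root.spawn(4)

    env = hydraulics.Environment(
        temp_c=cfg.temp_c, rh_pct=cfg.rh_pct,
        patm_kpa=cfg.patm_kpa, gmin=cfg.gmin,
    )
    prov: dict[str, object] = {"config": asdict(cfg)}
    ramp_per_min = (cfg.psi_end - cfg.psi0) / (cfg.days * 1440.0)

    def psi_to_min(psi: float) -> float:
        return (psi - cfg.psi0) / ramp_per_min

    bp_width = cfg.bp_width_mpa
    bp_fvfm = cfg.bp_fvfm_mpa

    # ---- side experiments -------------------------------------------------
    side_rngs = ss_side.spawn(4)

    # K_leaf rehydration kinetics -> fitted vulnerability curve
    true_curve = hydraulics.VulnerabilityCurve(cfg.kmax, cfg.p50_leaf, cfg.alpha)
    rec = synthesis.generate_rehydration_samples(
        true_curve, n=14, noise_rel=0.02, seed=np.random.default_rng(side_rngs[0])
    )
    ks = [
        fitting.kleaf_instance(
            r.fmax, r.f2, r.psi_init_mpa, r.psi_fin_mpa, r.area_m2, r.temp_c
        )
        for r in rec.itertuples()
    ]
    kfit = fitting.fit_kleaf_curve(rec["psi_init_mpa"], [k.k_mean for k in ks])
    fitted_curve = hydraulics.VulnerabilityCurve(
        kmax=kfit.kmax, p50=kfit.p50, alpha=kfit.alpha
    )
    runaway = hydraulics.runaway_point(fitted_curve, env.ec)
    if cfg.couple_thresholds:
        bp_width = runaway.psi_runaway
        bp_fvfm = runaway.psi_runaway
    prov["kleaf_fit"] = {"kmax": kfit.kmax, "p50": kfit.p50, "alpha": kfit.alpha}

    # g_min from mass-loss traces
    gmin_rng = np.random.default_rng(side_rngs[1])
    gmins = []
    for _ in range(cfg.n_gmin_leaves):
        tr = synthesis.generate_gmin_trace(
            gmin=cfg.gmin, env=env, noise_sd_g=5e-5, seed=gmin_rng
        )
        g, _ = fitting.gmin_from_trace(
            tr["time_s"], tr["mass_g"], 1.5e-3, cfg.temp_c, cfg.rh_pct,
            cfg.patm_kpa,
        )
        gmins.append(g)

    # TLP from PV curves
    pv_rng = np.random.default_rng(side_rngs[2])
    tlps = []
    for _ in range(cfg.n_pv_leaves):
        pv = synthesis.generate_pv_series(
            tlp=cfg.tlp, noise_sd_mpa=0.005, seed=pv_rng
        )
        tlps.append(fitting.tlp_from_pv(pv["psi_mpa"], pv["mass_g"], 2.0)["tlp"])

    # stem vulnerability (per Fv/Fm-subset plant)
    stem_rng = np.random.default_rng(side_rngs[3])
    p50_stem, p88_stem = [], []
    for _ in range(cfg.n_fvfm_plants):
        trig = synthesis.generate_stem_event_potentials(
            cfg.n_stem_events, cfg.p50_stem, cfg.alpha_stem, seed=stem_rng
        )
        psi_sorted = np.sort(trig)[::-1]
        cum = np.arange(1, trig.size + 1) / trig.size
        sfit = fitting.fit_cavitation_curve(psi_sorted, cum)
        p50_stem.append(fitting.extract_px(sfit, 50))
        p88_stem.append(fitting.extract_px(sfit, 88))

    # ---- leaf replicates: cavitation + width ------------------------------
    leaf_rows = []
    for i, ss in enumerate(ss_leaves.spawn(cfg.n_leaves)):
        s_geo, s_psi, s_ev, s_w = ss.spawn(4)
        geometry = synthesis.build_leaf_geometry(
            seed=np.random.default_rng(s_geo)
        )
        psi_series = synthesis.generate_psychrometer_series(
            cfg.psi0, cfg.psi_end, cfg.days, cfg.cadence_min,
            noise_sd=cfg.psi_noise_sd, seed=np.random.default_rng(s_psi),
        )
        psi_true = synthesis.generate_psychrometer_series(
            cfg.psi0, cfg.psi_end, cfg.days, cfg.cadence_min, noise_sd=0.0
        )
        _, events = _leaf_events(cfg, geometry, psi_series, psi_true, s_ev)
        curves = optical.cumulative_cavitation(events)
        row: dict[str, float] = {"leaf": i + 1}
        for order, curve in curves.items():
            fit = fitting.fit_cavitation_curve(
                curve["psi_stem_mpa"], curve["cum_area_frac"]
            )
            row[f"p50_{order}"] = fitting.extract_px(fit, 50)
            if order == "hov":
                row["p20_hov"] = fitting.extract_px(fit, 20)
        # whole-leaf curve: all orders pooled by area
        psi_all = np.array([e.psi_stem_mpa for e in events])
        area_all = np.array(
            [e.area_vein_px if e.area_vein_px else e.area_px for e in events],
            dtype=float,
        )
        idx = np.argsort(-psi_all, kind="stable")
        cum_all = np.cumsum(area_all[idx]) / area_all.sum()
        lfit = fitting.fit_cavitation_curve(psi_all[idx], cum_all)
        row["p50_leaf"] = fitting.extract_px(lfit, 50)

        counts = optical.events_per_segment(events, geometry.segments)
        for _, r in counts.iterrows():
            row[f"events_{r['order']}"] = r["mean"]

        # leaf width vs stem potential, with post-breakpoint acceleration
        psi_stem = psi_series["psi_stem_mpa"].to_numpy()
        psi_leafv = synthesis.piecewise_psi_leaf(
            psi_stem, bp_width, cfg.post_runaway_multiplier
        )
        width = synthesis.generate_width_series(
            psi_leafv, noise_sd=cfg.width_noise_sd,
            seed=np.random.default_rng(s_w),
        )
        bfit = fitting.fit_breakpoint(psi_stem, width)
        row["bp_width_mpa"] = bfit.breakpoint
        row["bp_width_min"] = psi_to_min(bfit.breakpoint) if bfit.breakpoint else np.nan
        leaf_rows.append(row)
    replicates = pd.DataFrame(leaf_rows)

    # ---- Fv/Fm plants ------------------------------------------------------
    fvfm_bps = []
    for ss in ss_fvfm.spawn(cfg.n_fvfm_plants):
        s_psi, s_f = ss.spawn(2)
        psi_series = synthesis.generate_psychrometer_series(
            cfg.psi0, cfg.psi_end, cfg.days, cfg.cadence_min,
            noise_sd=cfg.psi_noise_sd, seed=np.random.default_rng(s_psi),
        )
        psi_stem = psi_series["psi_stem_mpa"].to_numpy()
        fv = synthesis.generate_fvfm_series(
            psi_stem, breakpoint_mpa=bp_fvfm, plateau=cfg.fvfm_plateau,
            noise_sd=cfg.fvfm_noise_sd, seed=np.random.default_rng(s_f),
        )
        bf = fitting.fit_breakpoint(psi_stem, fv)
        if bf.has_breakpoint:
            fvfm_bps.append(bf.breakpoint)
    fvfm_bps = np.asarray(fvfm_bps)

    # ---- trait table -------------------------------------------------------
    def pooled(name, values, unit):
        v = np.asarray([x for x in values if x is not None and np.isfinite(x)])
        return {
            "trait": name, "unit": unit,
            "mean": float(v.mean()) if v.size else np.nan,
            "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            "n": int(v.size),
        }

    rows = [
        pooled("bp_fvfm_min", [psi_to_min(b) for b in fvfm_bps], "min"),
        pooled("bp_fvfm_mpa", fvfm_bps, "MPa"),
        pooled("bp_width_min", replicates["bp_width_min"], "min"),
        pooled("bp_width_mpa", replicates["bp_width_mpa"], "MPa"),
        pooled("tlp", tlps, "MPa"),
        pooled("p20_hov", replicates.get("p20_hov", []), "MPa"),
        pooled("p50_leaf", replicates.get("p50_leaf", []), "MPa"),
        pooled("p50_midrib", replicates.get("p50_midrib", []), "MPa"),
        pooled("p50_major", replicates.get("p50_major", []), "MPa"),
        pooled("p50_hov", replicates.get("p50_hov", []), "MPa"),
        pooled("p50_stem", p50_stem, "MPa"),
        pooled("p88_stem", p88_stem, "MPa"),
        pooled("vpd", [env.vpd_kpa], "kPa"),
        pooled("gmin", gmins, "mmol m-2 s-1"),
        pooled("ec", [env.ec], "mmol m-2 s-1"),
        pooled("kmax", [kfit.kmax], "mmol s-1 m-2 MPa-1"),
        pooled("psi_runaway", [runaway.psi_runaway], "MPa"),
        pooled("plc_runaway", [runaway.plc_runaway], "%"),
        pooled("events_midrib", replicates.get("events_midrib", []), "per segment"),
        pooled("events_major", replicates.get("events_major", []), "per segment"),
        pooled("events_hov", replicates.get("events_hov", []), "per segment"),
    ]
    table = pd.DataFrame(rows)
    table["provenance"] = [
        "fvfm_breakpoints", "fvfm_breakpoints", "leaf_replicates",
        "leaf_replicates", "pv_curves", "leaf_replicates", "leaf_replicates",
        "leaf_replicates", "leaf_replicates", "leaf_replicates",
        "stem_curves", "stem_curves", "environment", "gmin_traces",
        "environment", "kleaf_fit", "runaway_closed_form",
        "runaway_closed_form", "leaf_replicates", "leaf_replicates",
        "leaf_replicates",
    ]

    # ---- threshold comparison ---------------------------------------------
    def mean_of(name):
        return float(table.loc[table["trait"] == name, "mean"].iloc[0])

    thresholds = {
        "bp_width": mean_of("bp_width_mpa"),
        "bp_fvfm": mean_of("bp_fvfm_mpa"),
        "p20_hov": mean_of("p20_hov"),
        "runaway": runaway.psi_runaway,
        "tlp": mean_of("tlp"),
        "p88_stem": mean_of("p88_stem"),
    }
    names = list(thresholds)
    res_mpa = pd.DataFrame(
        [[thresholds[a] - thresholds[b] for b in names] for a in names],
        index=names, columns=names,
    )
    res_min = pd.DataFrame(
        [[psi_to_min(thresholds[a]) - psi_to_min(thresholds[b]) for b in names]
         for a in names],
        index=names, columns=names,
    )
    anova = {}
    try:
        anova["p50_orders"] = compare_groups({
            o: replicates[f"p50_{o}"].to_numpy()
            for o in ("midrib", "major", "hov")
            if f"p50_{o}" in replicates
        })
    except ValueError as e:
        anova["p50_orders"] = {"error": str(e)}
    try:
        anova["event_counts"] = compare_groups({
            o: replicates[f"events_{o}"].to_numpy()
            for o in ("midrib", "major", "hov")
            if f"events_{o}" in replicates
        })
    except ValueError as e:
        anova["event_counts"] = {"error": str(e)}

    result = PipelineResult(
        trait_table=table, replicates=replicates,
        residuals_mpa=res_mpa, residuals_min=res_min,
        anova=anova, provenance=prov,
    )
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_trait_table(result, out / "trait_table")
        write_report(result, out / "threshold_report")
    return result


# --------------------------------------------------------------------------
# serialisation
# --------------------------------------------------------------------------

def write_trait_table(result: PipelineResult, path) -> None:
    """Trait table as CSV (fixed column order, units in headers) + JSON."""
    path = Path(path)
    tab = result.trait_table.copy()
    tab.to_csv(path.with_suffix(".csv"), index=False,
               columns=["trait", "unit", "mean", "sd", "n", "provenance"])
    payload = {
        "traits": tab.to_dict(orient="records"),
        "replicates": result.replicates.where(
            result.replicates.notna(), None
        ).to_dict(orient="records"),
        "provenance": _jsonable(result.provenance),
    }
    path.with_suffix(".json").write_text(json.dumps(payload, indent=2))


def write_report(result: PipelineResult, path) -> None:
    """Threshold residual matrices and group statistics, CSV + JSON."""
    path = Path(path)
    result.residuals_mpa.to_csv(path.with_suffix(".mpa.csv"))
    result.residuals_min.to_csv(path.with_suffix(".min.csv"))
    payload = {
        "residuals_mpa": result.residuals_mpa.to_dict(),
        "residuals_min": result.residuals_min.to_dict(),
        "anova": _jsonable(result.anova),
    }
    path.with_suffix(".json").write_text(json.dumps(payload, indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
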