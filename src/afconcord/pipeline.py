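"""Configuration, orchestration and the reproduction report.

``run_pipeline`` executes the full virtual-patient workflow — substrate
generation, multi-site AF induction, phase analysis, synthetic ECGI
observation, region classification, optional two-round virtual ablation —
and persists deterministic CSV/JSON artifacts stamped with the config
hash.  ``repro_study`` recomputes every region-level statistic from the
packaged fixture tables.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import stats as st
from .ablation import make_plan, reinducibility_study
from .fixtures import load_study_tables, table2_stage_counts
from .induction import PacingProtocol, induce_all
from .ionic import CAF_SCALINGS, FIBROSIS_SCALINGS, SURROGATE_PARAMS, IonicParams
from .substrate import generate_ecgi_observation, make_virtual_patient
from .tissue import save_grid

DEFAULT_CONFIG = {
    "seed": 1,
    "n_patients": 1,
    "grid": {"nx": 120, "ny": 120, "dx": 0.5, "d_long": 0.1,
             "anisotropy": 0.25, "fiber_angle": 0.0},
    "substrate": {"density": 0.30, "correlation_length": 5.0,
                  "fibrosis_d_factor": 0.5},
    "ionic": {"backend": "surrogate",
              "caf_scalings": dict(CAF_SCALINGS),
              "fibrosis_scalings": dict(FIBROSIS_SCALINGS),
              "surrogate": dict(SURROGATE_PARAMS)},
    "protocol": {"n_sites": 30, "beats_per_train": 6,
                 "cycle_lengths": [200.0, 150.0, 120.0],
                 "stim_amplitude": 30.0, "stim_duration": 2.0,
                 "stim_radius_mm": 1.0, "free_run_ms": 2500.0},
    "ecgi": {"p_manifest": 0.7, "p_extra": 0.1, "window_s": 15.0},
    "ablation": {"radius": 3.5, "rounds": 2},
    "version": "0.1.0",
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge a YAML config file and/or override dict over the defaults."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as f:
            user = yaml.safe_load(f) or {}
        _deep_update(cfg, user)
    if overrides:
        _deep_update(cfg, overrides)
    return cfg


def _deep_update(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def ionic_from_config(cfg: dict) -> IonicParams:
    ic = cfg["ionic"]
    return IonicParams(backend=ic["backend"],
                       caf_scalings=dict(ic["caf_scalings"]),
                       fibrosis_scalings=dict(ic["fibrosis_scalings"]),
                       surrogate=dict(ic["surrogate"]))


def protocol_from_config(cfg: dict) -> PacingProtocol:
    pc = cfg["protocol"]
    return PacingProtocol(n_sites=int(pc["n_sites"]),
                          beats_per_train=int(pc["beats_per_train"]),
                          cycle_lengths=tuple(float(c) for c in pc["cycle_lengths"]),
                          stim_amplitude=float(pc["stim_amplitude"]),
                          stim_duration=float(pc["stim_duration"]),
                          stim_radius_mm=float(pc["stim_radius_mm"]),
                          free_run_ms=float(pc["free_run_ms"]))


def patient_from_config(cfg: dict, patient_index: int = 0):
    g, s = cfg["grid"], cfg["substrate"]
    seed = int(cfg["seed"]) + patient_index
    return make_virtual_patient(
        patient_id=f"vp{patient_index:02d}", density=float(s["density"]),
        nx=int(g["nx"]), ny=int(g["ny"]), dx=float(g["dx"]),
        correlation_length=float(s["correlation_length"]), seed=seed,
        d_long=float(g["d_long"]), anisotropy=float(g["anisotropy"]),
        fibrosis_d_factor=float(s["fibrosis_d_factor"]),
        fiber_angle=float(g["fiber_angle"]))


def rds_to_frame(patient_id, rds) -> pd.DataFrame:
    rows = []
    for k, rd in enumerate(rds):
        cx, cy = rd.trajectory.centroid()
        rows.append({
            "patient_id": patient_id, "rd_id": k, "region_id": rd.region_id,
            "t_start_ms": rd.trajectory.t_start, "t_end_ms": rd.trajectory.t_end,
            "duration_ms": rd.duration, "rotations": round(rd.rotations, 3),
            "confinement_mm": round(rd.confinement_radius, 3),
            "chirality": rd.trajectory.chirality,
            "centroid_x_mm": round(cx, 3), "centroid_y_mm": round(cy, 3),
        })
    cols = ["patient_id", "rd_id", "region_id", "t_start_ms", "t_end_ms",
            "duration_ms", "rotations", "confinement_mm", "chirality",
            "centroid_x_mm", "centroid_y_mm"]
    return pd.DataFrame(rows, columns=cols)


def run_pipeline(cfg: dict, out_dir) -> dict:
    """Full workflow; idempotent given the config (seed included)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    ionic_params = ionic_from_config(cfg)
    protocol = protocol_from_config(cfg)
    ec = cfg["ecgi"]

    classifications = []
    rd_frames = []
    stage_rows = []
    report: dict = {"config_hash": chash, "patients": []}
    for idx in range(int(cfg["n_patients"])):
        patient = patient_from_config(cfg, idx)
        save_grid(out / f"{patient.patient_id}.h5", patient.grid)
        induced = induce_all(patient, ionic_params, protocol)
        sim_regions = set(induced.rd_regions)
        obs = generate_ecgi_observation(
            sim_regions, p_manifest=float(ec["p_manifest"]),
            p_extra=float(ec["p_extra"]), seed=patient.seed + 10_000,
            patient_id=patient.patient_id, window_s=float(ec["window_s"]))
        ecgi_regions = set(obs.observed_regions)
        cl = st.classify_patient(sim_regions, ecgi_regions,
                                 patient_id=patient.patient_id)
        classifications.append(cl)
        rd_frames.append(rds_to_frame(patient.patient_id, induced.rds))
        stage_rows.append((patient.patient_id, "ecgi", ecgi_regions))
        stage_rows.append((patient.patient_id, "pre", sim_regions))

        pat_report = {"patient_id": patient.patient_id,
                      "fibrosis_burden": round(patient.fibrosis_burden, 4),
                      "sim_regions": sorted(sim_regions),
                      "ecgi_regions": sorted(ecgi_regions)}

        if int(cfg["ablation"]["rounds"]) >= 1:
            radius = float(cfg["ablation"]["radius"])
            pp_regions = {r for r in sim_regions if r in ecgi_regions}
            round1_rds = [rd for rd in induced.rds if rd.region_id in pp_regions]
            plan1 = make_plan([rd.trajectory for rd in round1_rds],
                              patient.grid, radius)
            res1 = reinducibility_study(patient, plan1, ionic_params, protocol,
                                        rd_regions_pre=sim_regions)
            stage_rows.append((patient.patient_id, "post1",
                               set(res1["rd_regions_post"])))
            pat_report["post1_regions"] = sorted(res1["rd_regions_post"])
            pat_report["post1_de_novo"] = sorted(res1["de_novo_regions"])
            if int(cfg["ablation"]["rounds"]) >= 2:
                plan2 = make_plan([rd.trajectory for rd in induced.rds],
                                  patient.grid, radius)
                res2 = reinducibility_study(patient, plan2, ionic_params,
                                            protocol, rd_regions_pre=sim_regions)
                stage_rows.append((patient.patient_id, "post2",
                                   set(res2["rd_regions_post"])))
                pat_report["post2_regions"] = sorted(res2["rd_regions_post"])
                pat_report["post2_de_novo"] = sorted(res2["de_novo_regions"])
        report["patients"].append(pat_report)

    table = st.pool_concordance(classifications)
    kappa, k_flag = st.cohen_kappa(table)
    kappa0, k0_flag = st.kraemer_kappa0(table)
    report["concordance"] = {
        "a": table.a, "b": table.b, "c": table.c, "d": table.d,
        "percent_agreement": table.percent_agreement,
        "cohen_kappa": kappa, "cohen_kappa_degenerate": k_flag,
        "kraemer_kappa0": kappa0, "kraemer_kappa0_degenerate": k0_flag,
    }

    cls_rows = []
    for cl in classifications:
        for r in sorted(cl.labels):
            lab = cl.labels[r]
            cls_rows.append({"patient_id": cl.patient_id, "region_id": r,
                             "ecgi": int(lab.startswith("ECGI+")),
                             "sim": int("Sim+" in lab), "label": lab,
                             "config_hash": chash})
    pd.DataFrame(cls_rows).to_csv(out / "classification.csv", index=False)
    if rd_frames:
        rd_df = pd.concat(rd_frames, ignore_index=True)
        rd_df["config_hash"] = chash
        rd_df.to_csv(out / "rds.csv", index=False)
    occ_rows = []
    for pid, stage, regions in stage_rows:
        row = {"patient_id": pid, "stage": stage,
               "n_regions": len(regions)}
        for r in range(1, 8):
            row[f"r{r}"] = int(r in regions)
        row["config_hash"] = chash
        occ_rows.append(row)
    pd.DataFrame(occ_rows).to_csv(out / "region_stage.csv", index=False)
    with open(out / "report.json", "w") as f:
        json.dump(report, f, indent=1, sort_keys=True)
    return report


# ---------------------------------------------------------------------------
# Reproduction of the printed region-level statistics
# ---------------------------------------------------------------------------

def repro_study() -> dict:
    """Recompute every region-level statistic from the packaged fixtures.

    Returns a flat dict of computed quantities (percentages on the 0-100
    scale, medians/IQRs one-decimal rounded) plus the two kappa variants.
    """
    fx = load_study_tables()

    conc = dict(zip(fx.concordance["cell"], fx.concordance["count"].astype(int)))
    table = st.ConcordanceTable(a=conc["ecgi_pos_sim_pos"],
                                b=conc["ecgi_pos_sim_neg"],
                                c=conc["ecgi_neg_sim_pos"],
                                d=conc["ecgi_neg_sim_neg"])
    kappa, _ = st.cohen_kappa(table)
    kappa0, _ = st.kraemer_kappa0(table)

    reg = fx.regional_counts.set_index("modality")
    out: dict = {}
    for modality in ("ecgi", "sim"):
        la, ra, iag = (int(reg.loc[modality, c]) for c in ("la", "ra", "iag"))
        total = la + ra + iag
        out[f"{modality}_total_regions"] = total
        out[f"{modality}_la_pct"] = round(100.0 * la / total, 1)
        out[f"{modality}_ra_pct"] = round(100.0 * ra / total, 1)
        out[f"{modality}_iag_pct"] = round(100.0 * iag / total, 1)

    t1 = fx.table1
    out["table1_rows_sum_to_7"] = bool(((t1["agree"] + t1["differ"]) == 7).all())
    out["agree_total"] = int(t1["agree"].sum())
    out["differ_total"] = int(t1["differ"].sum())

    out["concordance_table"] = [table.a, table.b, table.c, table.d]
    out["n_regions_total"] = table.n
    out["percent_agreement"] = table.percent_agreement
    out["cohen_kappa"] = kappa
    out["kraemer_kappa0"] = kappa0

    oc = fx.outcome_counts.set_index("region_class")
    pp = oc.loc["ECGI+/Sim+"]
    pm = oc.loc["ECGI+/Sim-"]
    out["positive_rate_pp_pct"] = st.percent(int(pp["positive_response"]),
                                             int(pp["n_targets"]))
    out["positive_rate_pm_pct"] = st.percent(int(pm["positive_response"]),
                                             int(pm["n_targets"]))
    out["termination_rate_pp_pct"] = st.percent(int(pp["terminated"]),
                                                int(pp["n_targets"]))
    out["termination_rate_pm_pct"] = st.percent(int(pm["terminated"]),
                                                int(pm["n_targets"]))
    out["n_targets_total"] = int(oc["n_targets"].sum())
    out["outcome_fisher_p_positive"] = st.fisher_exact(
        int(pp["positive_response"]), int(pp["n_targets"]),
        int(pm["positive_response"]), int(pm["n_targets"]))
    out["outcome_fisher_p_termination"] = st.fisher_exact(
        int(pp["terminated"]), int(pp["n_targets"]),
        int(pm["terminated"]), int(pm["n_targets"]))

    cw = fx.classwise_regional
    pp_lpv = int(cw.loc[(cw["region_class"] == "ECGI+/Sim+")
                        & (cw["region"] == "lpv"), "count"].iloc[0])
    pp_pla = int(cw.loc[(cw["region_class"] == "ECGI+/Sim+")
                        & (cw["region"] == "pla"), "count"].iloc[0])
    out["pp_lpv_share_pct"] = st.percent(pp_lpv, table.a)
    out["pp_pla_share_pct"] = st.percent(pp_pla, table.a)

    pre = table2_stage_counts(fx, "pre")
    post1 = table2_stage_counts(fx, "post1")
    post2 = table2_stage_counts(fx, "post2")
    out["table2_pre_median_iqr"] = list(st.median_iqr(pre))
    out["table2_post1_median_iqr"] = list(st.median_iqr(post1))
    out["table2_post2_median_iqr"] = list(st.median_iqr(post2))
    out["wilcoxon_p_pre_post1"] = st.wilcoxon_signed_rank(pre, post1)
    out["wilcoxon_p_post1_post2"] = st.wilcoxon_signed_rank(post1, post2)
    return out


#: Printed reference values for the pass/fail reproduction table.
REFERENCE_VALUES = {
    "ecgi_total_regions": 42,
    "sim_total_regions": 28,
    "ecgi_la_pct": 78.6, "ecgi_ra_pct": 11.9, "ecgi_iag_pct": 9.5,
    "sim_la_pct": 60.7, "sim_ra_pct": 32.1, "sim_iag_pct": 7.1,
    "differ_total": 32,
    "concordance_table": [19, 23, 9, 33],
    "n_regions_total": 84,
    "positive_rate_pp_pct": 57, "positive_rate_pm_pct": 41,
    "termination_rate_pp_pct": 30, "termination_rate_pm_pct": 18,
    "n_targets_total": 45,
    "pp_lpv_share_pct": 37, "pp_pla_share_pct": 21,
    "table2_pre_median_iqr": [3.0, 2.8, 3.3],
    "table2_post1_median_iqr": [2.5, 1.8, 3.5],
    "table2_post2_median_iqr": [2.5, 1.8, 3.3],
}


def repro_study_report() -> pd.DataFrame:
    """Pass/fail table: computed fixture statistics vs printed values."""
    computed = repro_study()
    rows = []
    for key, expected in REFERENCE_VALUES.items():
        got = computed[key]
        ok = got == expected if not isinstance(expected, float) else (
            abs(got - expected) < 0.05)
        rows.append({"quantity": key, "computed": got, "printed": expected,
                     "pass": bool(ok)})
    return pd.DataFrame(rows)
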