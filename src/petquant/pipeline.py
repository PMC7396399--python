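"""End-to-end orchestration of the two study workflows.

``run_quantification`` covers the brain test–retest study: per subject and
session it builds the metabolite-corrected input, fits 1TCM / 2TCM / Logan
for every region, then assembles the reliability tables (per-region V_T by
estimator, plus the AUC/f_P diagnostics) and an optional gray-matter V_T
time-stability table.

``run_dosimetry`` covers the whole-body study: organ %ID curves (urine
added back to the bladder) → retention fits → residence times → absorbed
doses through an S-value matrix → effective dose.

Every intermediate is a file; outputs carry a provenance header (version,
config hash, seed) and identical configs yield byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .blood import build_input, fit_parent_fraction
from .curves import StudyRecord, TimeActivityCurve
from .dosimetry import (
    OrganRetention,
    absorbed_doses,
    bladder_with_urine,
    effective_dose,
    fit_retention,
    residence_time,
    residence_time_from_series,
)
from .io import read_blood_table, read_tac_table, write_blood_table, write_tac_table
from .kinetics import fit_compartment, logan_vt, time_stability
from .reliability import reliability_table
from .synthetic import CohortSpec, gen_biodistribution, gen_cohort

logger = logging.getLogger("petquant")

__all__ = [
    "run_quantification",
    "run_dosimetry",
    "write_cohort_files",
    "write_biodistribution_files",
    "fit_all_regions",
]


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        path = Path(config)
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        cfg["_base_dir"] = path.parent
        return cfg
    cfg = dict(config)
    cfg.setdefault("_base_dir", Path("."))
    return cfg


def _config_hash(cfg: dict) -> str:
    clean = {k: v for k, v in cfg.items() if not k.startswith("_")}
    blob = yaml.safe_dump(clean, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(cfg: dict) -> str:
    return (
        f"# petquant {__version__} | config_sha256={_config_hash(cfg)} "
        f"| seed={cfg.get('seed', 0)}\n"
    )


def _write_csv(df: pd.DataFrame, path: Path, header: str, index: bool = False):
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=index, float_format="%.8g", lineterminator="\n")


def _load_record(entry: dict, session: str, base: Path) -> StudyRecord:
    tacs = read_tac_table(base / entry["tac"])
    blood = read_blood_table(base / entry["blood"])
    return StudyRecord(
        subject_id=entry["_subject_id"],
        session=session,
        injected_dose_mbq=float(entry.get("injected_dose_mbq", 100.0)),
        tacs=tacs,
        blood=blood,
        body_weight_kg=entry.get("body_weight_kg"),
        f_p=entry.get("fp"),
    )


def fit_all_regions(
    record: StudyRecord, t_star: float = 30.0, weights: str = "frame_duration",
    seed: int = 0,
) -> pd.DataFrame:
    """Fit 1TCM, 2TCM and Logan for every region of one subject-session."""
    pf = fit_parent_fraction(record.blood["parent_fraction"])
    input_fn = build_input(record.blood["plasma"], pf)
    rows = []
    for region, tac in record.tacs.items():
        f1 = fit_compartment(tac, input_fn, "1tcm", weights=weights, seed=seed)
        f2 = fit_compartment(tac, input_fn, "2tcm", weights=weights, seed=seed,
                             init_1tcm=f1.params if f1.converged else None)
        lg = logan_vt(tac, input_fn, t_star=t_star)
        for fit in (f1, f2):
            rows.append(
                dict(subject=record.subject_id, session=record.session, region=region,
                     model=fit.model, K1=fit.params.K1, k2=fit.params.k2,
                     k3=fit.params.k3, k4=fit.params.k4, VT=fit.vt, WRSS=fit.wrss,
                     AIC=fit.aic, converged=fit.converged)
            )
        rows.append(
            dict(subject=record.subject_id, session=record.session, region=region,
                 model="ga", K1=np.nan, k2=np.nan, k3=np.nan, k4=np.nan,
                 VT=lg.vt, WRSS=np.nan, AIC=np.nan, converged=True)
        )
        if not f2.converged:
            logger.info("non-converged 2TCM fit excluded: %s %s %s",
                        record.subject_id, record.session, region)
    return pd.DataFrame(rows)


def _gm_mean_tac(record: StudyRecord) -> TimeActivityCurve:
    tacs = list(record.tacs.values())
    conc = np.mean([t.conc for t in tacs], axis=0)
    return TimeActivityCurve("GM", tacs[0].frame_start, tacs[0].frame_end, conc)


def _session_metrics(record: StudyRecord, fits: pd.DataFrame, t_star: float) -> dict:
    """Table-4-style diagnostics for one session: AUCs, their ratio, GM V_T, f_P."""
    gm = _gm_mean_tac(record)
    pf = fit_parent_fraction(record.blood["parent_fraction"])
    input_fn = build_input(record.blood["plasma"], pf)
    t0, t1 = float(gm.frame_mid[0]), min(float(gm.frame_mid[-1]), 120.0)
    auc_gm = gm.auc(t0, t1)
    auc_input = input_fn.auc(t0, t1)
    sel = fits[(fits.model == "2tcm") & fits.converged]
    out = {
        "AUC_GM": auc_gm,
        "AUC_input": auc_input,
        "AUC_ratio": auc_gm / auc_input,
        "GM_VT": float(sel.VT.mean()) if len(sel) else np.nan,
    }
    if record.f_p is not None:
        out["f_P"] = float(record.f_p)
    return out


def run_quantification(config, outdir) -> Dict[str, Path]:
    """Run the full quantification + reliability workflow; returns output paths."""
    cfg = _load_config(config)
    base = Path(cfg["_base_dir"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = _provenance(cfg)
    model_cfg = cfg.get("model", {})
    t_star = float(model_cfg.get("t_star", 30.0))
    weights = model_cfg.get("weights", "frame_duration")
    seed = int(cfg.get("seed", 0))

    records: List[StudyRecord] = []
    excluded = []
    for subj in cfg["subjects"]:
        sessions = subj.get("sessions", {})
        if not {"test", "retest"} <= set(sessions):
            excluded.append(subj["id"])
            logger.info("excluded from reliability (incomplete sessions): %s", subj["id"])
        for session, entry in sessions.items():
            entry = dict(entry)
            entry["_subject_id"] = subj["id"]
            records.append(_load_record(entry, session, base))

    all_fits = pd.concat(
        [fit_all_regions(r, t_star=t_star, weights=weights, seed=seed) for r in records],
        ignore_index=True,
    )
    paths = {"fits": outdir / "fits.csv"}
    _write_csv(all_fits, paths["fits"], header)

    complete = sorted(
        {r.subject_id for r in records if r.session == "test"}
        & {r.subject_id for r in records if r.session == "retest"}
    )
    complete = [s for s in complete if s not in excluded]
    if len(complete) >= 3:
        regions = list(records[0].tacs.keys())
        for model in ("1tcm", "2tcm", "ga"):
            values = {}
            for region in regions:
                mat = np.full((len(complete), 2), np.nan)
                for i, sid in enumerate(complete):
                    for j, session in enumerate(("test", "retest")):
                        sel = all_fits[
                            (all_fits.subject == sid) & (all_fits.session == session)
                            & (all_fits.region == region) & (all_fits.model == model)
                            & all_fits.converged
                        ]
                        if len(sel):
                            mat[i, j] = sel.VT.iloc[0]
                values[region] = mat
            table = reliability_table(values)
            path = outdir / f"reliability_vt_{model}.csv"
            _write_csv(table, path, header, index=True)
            paths[f"reliability_vt_{model}"] = path

        # Table-4-style diagnostics
        metric_rows: Dict[str, dict] = {}
        for r in records:
            fits_r = all_fits[(all_fits.subject == r.subject_id)
                              & (all_fits.session == r.session)]
            metric_rows[(r.subject_id, r.session)] = _session_metrics(r, fits_r, t_star)
        metric_names = sorted({k for v in metric_rows.values() for k in v})
        aux = {}
        for name in metric_names:
            mat = np.full((len(complete), 2), np.nan)
            for i, sid in enumerate(complete):
                for j, session in enumerate(("test", "retest")):
                    mat[i, j] = metric_rows.get((sid, session), {}).get(name, np.nan)
            aux[name] = mat
        aux_table = reliability_table(aux)
        paths["reliability_aux"] = outdir / "reliability_aux.csv"
        _write_csv(aux_table, paths["reliability_aux"], header, index=True)
    else:
        logger.warning("fewer than 3 complete test-retest subjects: reliability skipped")

    if cfg.get("time_stability", False):
        rows = []
        for r in records:
            pf = fit_parent_fraction(r.blood["parent_fraction"])
            input_fn = build_input(r.blood["plasma"], pf)
            for row in time_stability(_gm_mean_tac(r), input_fn, seed=seed):
                rows.append(dict(subject=r.subject_id, session=r.session, **row))
        paths["time_stability"] = outdir / "time_stability.csv"
        _write_csv(pd.DataFrame(rows), paths["time_stability"], header)

    return paths


def run_dosimetry(config, outdir) -> Dict[str, Path]:
    """Run the biodistribution → residence time → dose workflow."""
    cfg = _load_config(config)
    base = Path(cfg["_base_dir"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = _provenance(cfg)

    organs_df = pd.read_csv(base / cfg["organs"], comment="#")
    organs: Dict[str, OrganRetention] = {}
    for organ, grp in organs_df.groupby("organ", sort=False):
        grp = grp.sort_values("t_h")
        vol = float(grp.volume_cm3.iloc[0]) if "volume_cm3" in grp else None
        organs[organ] = OrganRetention(organ, grp.t_h.to_numpy(),
                                       grp.pid.to_numpy(), vol)
    if not organs:
        raise ValueError("no organ retention data found")

    if "urine" in cfg and "bladder" in organs:
        urine = pd.read_csv(base / cfg["urine"], comment="#")
        organs["bladder"] = bladder_with_urine(
            organs["bladder"], urine.t_h.to_numpy(), urine.pid.to_numpy()
        )

    tau_rows = []
    taus = {}
    for organ, ret in organs.items():
        fit = fit_retention(ret, seed=int(cfg.get("seed", 0)))
        if fit.converged:
            tau = residence_time(fit)
            method = f"{fit.n_exp}-exp"
        else:
            tau = residence_time_from_series(ret)
            method = "trapezoid+tail"
            logger.info("retention fit fell back to trapezoid for %s", organ)
        taus[organ] = tau
        tau_rows.append(dict(organ=organ, residence_time_h=tau, method=method))
    tau_df = pd.DataFrame(tau_rows)
    paths = {"residence_times": outdir / "residence_times.csv"}
    _write_csv(tau_df, paths["residence_times"], header)

    doses = absorbed_doses(taus, base / cfg["s_matrix"])
    weights_path = cfg.get("weights")
    ed = effective_dose(doses, weights_path if weights_path is None
                        else base / weights_path)
    dose_df = pd.DataFrame(
        [dict(organ=o, dose_uSv_per_MBq=d) for o, d in sorted(doses.items())]
        + [dict(organ="effective_dose", dose_uSv_per_MBq=ed["ed"])]
    )
    paths["dose_report"] = outdir / "dose_report.csv"
    _write_csv(
        dose_df, paths["dose_report"],
        header + f"# weighting scheme: {ed['scheme']} | "
        f"remainder splitting applied: {ed['splitting_applied']}\n",
    )
    return paths


def write_cohort_files(outdir, spec: Optional[CohortSpec] = None) -> Path:
    """Simulate a cohort and write its per-session files + a pipeline config.

    Returns the path of the written config YAML.
    """
    spec = spec or CohortSpec()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = gen_cohort(spec)
    subjects: Dict[str, dict] = {}
    for r in records:
        tac_name = f"{r.subject_id}_{r.session}_tac.csv"
        blood_name = f"{r.subject_id}_{r.session}_blood.csv"
        write_tac_table(r.tacs, outdir / tac_name)
        write_blood_table(r.blood, outdir / blood_name)
        entry = {
            "tac": tac_name,
            "blood": blood_name,
            "injected_dose_mbq": float(r.injected_dose_mbq),
            "body_weight_kg": float(r.body_weight_kg),
            "fp": float(r.f_p),
        }
        subjects.setdefault(r.subject_id, {"id": r.subject_id, "sessions": {}})
        subjects[r.subject_id]["sessions"][r.session] = entry
    cfg = {
        "seed": int(spec.seed),
        "model": {"weights": "frame_duration", "t_star": 30.0},
        "subjects": list(subjects.values()),
    }
    cfg_path = outdir / "cohort.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return cfg_path


def write_biodistribution_files(outdir, seed: int = 0) -> Path:
    """Simulate whole-body data and write organ/urine CSVs + a dose config."""
    from .dosimetry import default_weights_path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bio = gen_biodistribution(seed=seed)
    rows = []
    for ret in bio["organs"] + [bio["bladder_voi"]]:
        for t, p in zip(ret.t_h, ret.pid):
            rows.append(dict(organ=ret.organ, t_h=t, pid=p,
                             volume_cm3=ret.volume_cm3))
    pd.DataFrame(rows).to_csv(outdir / "organs.csv", index=False,
                              float_format="%.8g")
    pd.DataFrame({"t_h": bio["void_times_h"], "pid": bio["void_pid"]}).to_csv(
        outdir / "urine.csv", index=False, float_format="%.8g"
    )
    cfg = {
        "seed": int(seed),
        "organs": "organs.csv",
        "urine": "urine.csv",
        "s_matrix": "s_matrix.csv",
    }
    from importlib import resources
    s_src = resources.files("petquant").joinpath("data/s_matrix_toy.csv")
    (outdir / "s_matrix.csv").write_text(s_src.read_text())
    cfg_path = outdir / "dose.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return cfg_path
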