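"""End-to-end pipeline: generate -> simulate -> estimate -> compare.

``run_pipeline`` executes one fully seeded study replication: a calibrated
synthetic cohort, three occlusion tests and a QC'd oscillometry session per
participant, and the method-comparison statistics, optionally plus the
three-condition cheek-hold experiment.  ``run_replicates`` repeats the whole
study R times with independent sub-seeds and aggregates the per-replicate
results (the repeated-cohort experiment used to characterise the pipeline's
sampling behaviour).

Seed policy: the master seed feeds a ``numpy.random.SeedSequence``; every
participant, test, replicate and analysis stage receives its own spawned
substream, so any subset of the run reproduces identically.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as _io
from .cohort import Participant, generate_cohort
from .compare import (
    FriedmanResult,
    MethodComparison,
    MethodComparisonResults,
    friedman_posthoc,
)
from .config import RunConfig
from .fot import FotSessionResult, replicate_qc_session
from .reom import aggregate_session, aggregate_test, analyze_breath
from .simulate import (
    CHEEK_HOLD_SCALES,
    DeviceModel,
    NoiseSpec,
    apply_cheek_hold,
    simulate_reom_test,
)

__all__ = ["RunReport", "run_pipeline", "run_replicates",
           "simulate_reom_session", "simulate_sessions"]

log = logging.getLogger("reomsim")


def _merge_device(participant: Participant, shared: DeviceModel) -> DeviceModel:
    """Shared device settings + this participant's calibrated couplings."""
    import dataclasses
    return dataclasses.replace(
        shared, sensor_fc=participant.device.sensor_fc,
        p_overshoot=participant.device.p_overshoot,
    )


def simulate_reom_session(participant: Participant, device: DeviceModel,
                          noise: NoiseSpec, seed):
    """Three occlusion tests (5-11 breaths each) -> session aggregate."""
    ss = np.random.SeedSequence(entropy=seed) if isinstance(seed, int) else seed
    rng = np.random.default_rng(ss.spawn(1)[0])
    tests = []
    for test_seed in ss.spawn(3):
        n_breaths = int(rng.integers(5, 12))
        rec = simulate_reom_test(participant.model, device, noise,
                                 n_breaths, test_seed)
        breaths = [analyze_breath(b.flow, b.release_index, b.P_peak,
                                  device.fs_reom) for b in rec.breaths]
        tests.append(aggregate_test(breaths))
    return aggregate_session(tests)


def simulate_sessions(participants: list[Participant], device: DeviceModel,
                      noise: NoiseSpec, seed,
                      modalities: tuple[str, ...] = ("reom", "fot")) -> pd.DataFrame:
    """Per-participant session table for the requested modalities.

    Participants whose occlusion session is invalid or whose oscillometry
    session fails QC keep their row with NaN measurements and a flag; they
    are excluded pairwise (and counted) by downstream analyses.
    """
    ss = np.random.SeedSequence(entropy=seed) if isinstance(seed, int) else seed
    rows = []
    for p, sub in zip(participants, ss.spawn(len(participants))):
        reom_ss, fot_ss = sub.spawn(2)
        dev = _merge_device(p, device)
        row = {
            "participant_id": p.id, "group": p.group,
            "age": p.demographics.age, "sex": p.demographics.sex,
            "bmi": p.demographics.bmi, "pack_years": p.demographics.pack_years,
            "R5": np.nan, "R19": np.nan, "Reo_s": np.nan, "Reo_f": np.nan,
            "reom_valid": np.nan, "fot_accepted": np.nan,
            "fot_n_replicates": np.nan, "fot_cv_pct": np.nan,
            "n_valid_breaths": np.nan,
        }
        if "reom" in modalities:
            session = simulate_reom_session(p, dev, noise, reom_ss)
            row["reom_valid"] = session.session_valid
            row["n_valid_breaths"] = sum(t.n_valid_breaths
                                         for t in session.test_values)
            if session.session_valid:
                row["Reo_s"] = session.session_reos
                row["Reo_f"] = session.session_reof
        if "fot" in modalities:
            fot: FotSessionResult = replicate_qc_session(p.model, dev, noise, fot_ss)
            row["fot_accepted"] = fot.accepted
            row["fot_n_replicates"] = fot.n_replicates
            row["fot_cv_pct"] = fot.cv_lowest_freq
            if fot.accepted:
                row["R5"] = fot.session_R5
                row["R19"] = fot.session_R19
        rows.append(row)
    return pd.DataFrame(rows)


def _cheek_hold_experiment(participants: list[Participant], device: DeviceModel,
                           noise: NoiseSpec, seed) -> dict:
    """Repeat the occlusion session under the three cheek-hold conditions
    and test for a condition effect (Friedman, Bonferroni post-hocs)."""
    ss = np.random.SeedSequence(entropy=seed) if isinstance(seed, int) else seed
    conditions = list(CHEEK_HOLD_SCALES)
    values: dict[str, list[list[float]]] = {"Reo_s": [], "Reo_f": []}
    for p, sub in zip(participants, ss.spawn(len(participants))):
        dev = _merge_device(p, device)
        per_cond_s, per_cond_f = [], []
        for cond, cond_seed in zip(conditions, sub.spawn(len(conditions))):
            model_c = apply_cheek_hold(p.model, cond, p.c0_shunt)
            p_c = Participant(**{**p.__dict__, "model": model_c})
            session = simulate_reom_session(p_c, dev, noise, cond_seed)
            if not session.session_valid:
                per_cond_s = per_cond_f = None
                break
            per_cond_s.append(session.session_reos)
            per_cond_f.append(session.session_reof)
        if per_cond_s is not None:
            values["Reo_s"].append(per_cond_s)
            values["Reo_f"].append(per_cond_f)
    out = {"conditions": conditions}
    for key, rows in values.items():
        data = np.asarray(rows)
        out[key] = friedman_posthoc(data) if len(rows) >= 3 else None
        out[f"n_{key}"] = len(rows)
    return out


@dataclass
class RunReport:
    """Everything one pipeline run produced, plus provenance."""

    cohort: list[Participant]
    cohort_table: pd.DataFrame
    session_table: pd.DataFrame
    results: MethodComparisonResults
    cheek_hold: dict | None
    provenance: dict
    paths: dict


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in order, deterministically in ``config.seed``.

    Writes the cohort table, session table and report JSON under
    ``config.out_dir`` when set.
    """
    spec1, spec4 = config.gold1_spec, config.gold4_spec  # validates early
    noise = config.noise_spec
    device = config.device_model
    ss = np.random.SeedSequence(entropy=config.seed)
    cohort_ss, session_ss, stats_ss, cheek_ss = ss.spawn(4)

    t0 = time.perf_counter()
    cohort = generate_cohort(spec1, spec4, cohort_ss)
    log.info("cohort: %d participants (%.1fs)", len(cohort), time.perf_counter() - t0)

    t0 = time.perf_counter()
    sessions = simulate_sessions(cohort, device, noise, session_ss)
    n_reom_invalid = int((sessions["reom_valid"] == False).sum())  # noqa: E712
    n_fot_failed = int((sessions["fot_accepted"] == False).sum())  # noqa: E712
    log.info("sessions: %d rows, %d invalid occlusion sessions, "
             "%d failed oscillometry QC (%.1fs)",
             len(sessions), n_reom_invalid, n_fot_failed,
             time.perf_counter() - t0)

    model = MethodComparison(sessions.dropna(subset=["R5", "R19", "Reo_s", "Reo_f"]))
    results = model.fit(bootstrap=config.bootstrap,
                        seed=int(stats_ss.generate_state(1)[0] % 2**31))

    cheek = None
    if config.cheek_hold:
        cheek = _cheek_hold_experiment(cohort, device, noise, cheek_ss)

    provenance = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "package_version": __import__("reomsim").__version__,
        "n_participants": len(cohort),
        "n_reom_invalid": n_reom_invalid,
        "n_fot_failed_qc": n_fot_failed,
        "n_calibration_flagged": sum(not p.calibration_ok for p in cohort),
    }
    paths = {}
    if config.out_dir:
        from pathlib import Path
        out = Path(config.out_dir)
        paths["cohort"] = str(_io.write_cohort_csv(out / "cohort.csv", cohort))
        sess_path = out / "sessions.csv"
        sessions.to_csv(sess_path, index=False)
        paths["sessions"] = str(sess_path)
        report = {"provenance": provenance, "results": results.to_dict()}
        if cheek is not None:
            report["cheek_hold"] = {
                k: (v if not isinstance(v, FriedmanResult) else {
                    "statistic": v.statistic, "p_value": v.p_value,
                    "posthoc_performed": v.posthoc_performed,
                    "posthoc_p": v.posthoc_p,
                }) for k, v in cheek.items()
            }
        paths["report"] = str(_io.write_json(out / "report.json", report))
        (out / "summary.txt").write_text(results.summary() + "\n")
        paths["summary"] = str(out / "summary.txt")
        agr_rows = []
        for key, rep in results.agreement.items():
            agr_rows.append({
                "pair": key, "rho_unadjusted": results.unadjusted[key].rho,
                "rho_adjusted": rep.rho,
                "rho_ci_lower": rep.rho_ci[0], "rho_ci_upper": rep.rho_ci[1],
                "mean_difference": rep.mean_difference,
                "loa_lower": rep.loa_lower, "loa_upper": rep.loa_upper,
            })
        pd.DataFrame(agr_rows).to_csv(out / "agreement.csv", index=False)
        results.group_table.to_csv(out / "group_comparison.csv")
        pd.concat({m: cm.to_frame() for m, cm in results.confusion.items()},
                  names=["measure"]).to_csv(out / "confusion_matrices.csv")
        paths["agreement"] = str(out / "agreement.csv")
        paths["group_comparison"] = str(out / "group_comparison.csv")
        paths["confusion"] = str(out / "confusion_matrices.csv")
        if cheek is not None:
            cheek_rows = []
            for m in ("Reo_s", "Reo_f"):
                fr = cheek.get(m)
                if fr is None:
                    continue
                cheek_rows.append({
                    "measure": m, "n_participants": cheek[f"n_{m}"],
                    "friedman_statistic": fr.statistic,
                    "friedman_p": fr.p_value,
                    "posthoc_performed": fr.posthoc_performed,
                    **{f"posthoc_p_{k}": v
                       for k, v in (fr.posthoc_p or {}).items()},
                })
            pd.DataFrame(cheek_rows).to_csv(out / "cheek_hold.csv", index=False)
            paths["cheek_hold"] = str(out / "cheek_hold.csv")
    return RunReport(cohort=cohort, cohort_table=_io.cohort_to_frame(cohort),
                     session_table=sessions, results=results,
                     cheek_hold=cheek, provenance=provenance, paths=paths)


def _replicate_row(rep_index: int, report: RunReport) -> dict:
    res = report.results
    row = {"replicate": rep_index}
    for key, agr in res.agreement.items():
        tag = key.replace("~", "_")
        row[f"rho_adj_{tag}"] = agr.rho
        row[f"rho_unadj_{tag}"] = res.unadjusted[key].rho
        row[f"mean_diff_{tag}"] = agr.mean_difference
        row[f"loa_lower_{tag}"] = agr.loa_lower
        row[f"loa_upper_{tag}"] = agr.loa_upper
    gt = res.group_table
    for m in gt.index:
        for col in gt.columns:
            row[f"{col}_{m}"] = gt.loc[m, col]
    for m, cm in res.confusion.items():
        row[f"misclassified_{m}"] = cm.n_misclassified
    if report.cheek_hold is not None:
        for key in ("Reo_s", "Reo_f"):
            fr = report.cheek_hold.get(key)
            row[f"cheek_friedman_p_{key}"] = fr.p_value if fr else np.nan
    row["n_analysed"] = res.n
    return row


def run_replicates(config: RunConfig, R: int | None = None) -> pd.DataFrame:
    """Run R independent full-pipeline cohorts; one row per replicate.

    Sub-seeds derive from the master seed, so the table is deterministic.
    Bootstrap CIs are skipped inside replicates (the across-replicate
    spread itself characterises the sampling variability).
    """
    R = config.replicates if R is None else R
    if R < 1:
        raise ValueError("R must be >= 1")
    ss = np.random.SeedSequence(entropy=config.seed)
    rows = []
    for i, sub in enumerate(ss.spawn(R), start=1):
        rep_seed = int(sub.generate_state(1)[0] % 2**31)
        rep_config = config.model_copy(
            update={"seed": rep_seed, "out_dir": None, "bootstrap": 0})
        report = run_pipeline(rep_config)
        rows.append(_replicate_row(i, report))
        log.info("replicate %d/%d done", i, R)
    return pd.DataFrame(rows)
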