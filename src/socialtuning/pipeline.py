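"""Seeded end-to-end orchestration of the full synthetic study.

``run_study`` walks the whole pipeline: build trial tables, simulate the
stimuli (for mean inter-agent distance features), sample an observer
cohort, generate two sessions of responses, fit tuning curves per
participant/session, run the reliability, group-model and association
stages, and write a machine-readable report that includes parameter
recovery diagnostics against the cohort's ground truth.

A single global seed fans out into per-stage child seeds derived from
``(seed, stage name)``, so changing one stage's seed leaves the other
stages' outputs unchanged.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, cohort as cohort_mod, curves, design, groupstats, reliability, sim

__all__ = ["StudyConfig", "run_study", "child_seed", "fit_cohort", "StageError"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def child_seed(seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed; stable across runs."""
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class StudyConfig:
    seed: int = 0
    n_participants: int = 30
    detection_reps: int = 12
    discrimination_reps: int = 10
    bootstrap_reps: int = 200
    permutation_reps: int = 2000
    out_dir: str | None = None
    world_detection: sim.WorldConfig = field(default_factory=lambda: sim.WorldConfig(duration=6.0))
    world_discrimination: sim.WorldConfig = field(
        default_factory=lambda: sim.WorldConfig(duration=8.0)
    )
    kinematics: sim.KinematicsConfig = field(default_factory=sim.KinematicsConfig)
    cohort: cohort_mod.CohortConfig | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("seed", "n_participants", "detection_reps", "discrimination_reps",
                    "bootstrap_reps", "permutation_reps", "out_dir"):
            if key in raw:
                kwargs[key] = raw[key]
        if "world_detection" in raw:
            kwargs["world_detection"] = sim.WorldConfig(**raw["world_detection"])
        if "world_discrimination" in raw:
            kwargs["world_discrimination"] = sim.WorldConfig(**raw["world_discrimination"])
        if "kinematics" in raw:
            kwargs["kinematics"] = sim.KinematicsConfig(**raw["kinematics"])
        if "cohort" in raw:
            kwargs["cohort"] = cohort_mod.CohortConfig(**raw["cohort"])
        return cls(**kwargs)


def fit_cohort(
    data: pd.DataFrame, task: str, family: str | None = None
) -> tuple[dict, dict, pd.DataFrame]:
    """Fit every participant/session in ``data`` for one task.

    Returns ``(fits, points, summary_table)`` where ``fits[(p, s)]`` is the
    task's preferred-family FitResult (sigmoid for detection, linear for
    discrimination unless overridden), ``points[(p, s)]`` the level means,
    and the summary table holds the derived parameters and flags.
    """
    family = family or ("sigmoid" if task == "detection" else "linear")
    fits: dict = {}
    points: dict = {}
    rows = []
    sub = data[data["task"] == task]
    for (p, s), grp in sub.groupby(["participant", "session"]):
        try:
            x, y = curves.level_means(grp)
        except curves.UnfittableError:
            rows.append(dict(participant=p, session=s, task=task, unfittable=True))
            continue
        ok = grp.dropna(subset=["rating"])
        trials = (
            curves.normalize_attribute(ok["attribute_value"].to_numpy(), task),
            ok["rating"].to_numpy(),
        )
        both = curves.fit_both(x, y, trials=trials)
        fit = both["fit_sigmoid"] if family == "sigmoid" else both["fit_linear"]
        summ = curves.summarize(fit)
        fits[(p, s)] = fit
        points[(p, s)] = (x, y)
        row = dict(
            participant=p,
            session=s,
            task=task,
            family=family,
            unfittable=False,
            rss=fit.rss,
            aic_sigmoid=both["fit_sigmoid"].aic,
            aic_linear=both["fit_linear"].aic,
            delta_aic=both["delta_aic"],
            preferred=both["preferred"],
            lb=summ.lb,
            ub=summ.ub,
            bias=summ.bias,
            range_=summ.range_,
            pse=summ.pse,
            subj_center=summ.subj_center,
            sigma=summ.sigma,
            excluded=summ.excluded,
            flags=";".join(sorted(summ.flags)),
        )
        if fit.family == "sigmoid":
            row.update(zip(("gamma", "lam", "alpha", "beta"), fit.params))
        else:
            row.update(zip(("c", "m"), fit.params))
        rows.append(row)
    return fits, points, pd.DataFrame(rows)


def _recovery(cohort, summary: pd.DataFrame, task: str) -> dict:
    """Truth-vs-fit diagnostics for PSE, bias and range (session 1)."""
    s1 = summary[(summary["session"] == 1) & (~summary.get("unfittable", False))]
    s1 = s1[~s1["excluded"]].set_index("participant")
    truth = {p.id: cohort_mod.truth_summary(p, task) for p in cohort}
    common = [p for p in s1.index if p in truth]
    out = {"n": len(common)}
    for name, attr in (("pse", "pse"), ("bias", "bias"), ("range", "range_")):
        t = np.array([getattr(truth[p], attr) for p in common])
        f = s1.loc[common, attr].to_numpy()
        err = np.abs(f - t)
        out[name] = {
            "median_abs_error": float(np.median(err)),
            "pearson_r": float(np.corrcoef(t, f)[0, 1]) if len(common) > 2 and t.std() > 0 else float("nan"),
            "truth": t.tolist(),
            "fit": f.tolist(),
        }
    return out


def _config_hash(config: "StudyConfig") -> str:
    import hashlib

    payload = json.dumps(
        {
            "seed": config.seed,
            "n_participants": config.n_participants,
            "detection_reps": config.detection_reps,
            "discrimination_reps": config.discrimination_reps,
            "world_detection": asdict(config.world_detection),
            "world_discrimination": asdict(config.world_discrimination),
            "kinematics": asdict(config.kinematics),
            "cohort": None if config.cohort is None else str(config.cohort),
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_study(config: StudyConfig) -> dict:
    """Execute the full synthetic study; returns (and optionally writes) the report."""
    report: dict = {"config_seed": config.seed, "config_hash": _config_hash(config)}
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def save(df: pd.DataFrame, name: str) -> None:
        if out_dir is not None:
            df.to_csv(out_dir / name, index=False, lineterminator="\n")

    stage = "design"
    try:
        det_tables = {
            s: design.build_detection_design(config.detection_reps, child_seed(config.seed, f"design_det_s{s}"))
            for s in (1, 2)
        }
        dis_tables = {
            s: design.build_discrimination_design(
                config.discrimination_reps, child_seed(config.seed, f"design_dis_s{s}")
            )
            for s in (1, 2)
        }
        # distinct stimulus sets per session, as in repeat testing
        for s in (1, 2):
            det_tables[s]["stim_id"] = det_tables[s]["stim_id"] + f"_s{s}"
            dis_tables[s]["stim_id"] = dis_tables[s]["stim_id"] + f"_s{s}"
        save(det_tables[1], "design_detection_s1.csv")
        save(dis_tables[1], "design_discrimination_s1.csv")

        stage = "simulate"
        features: dict[str, float] = {}
        for s in (1, 2):
            features.update(
                cohort_mod.compute_features(
                    det_tables[s],
                    {"detection": config.world_detection, "discrimination": config.world_discrimination},
                    config.kinematics,
                )
            )
            features.update(
                cohort_mod.compute_features(
                    dis_tables[s],
                    {"detection": config.world_detection, "discrimination": config.world_discrimination},
                    config.kinematics,
                )
            )
        report["n_stimuli"] = len(features)

        stage = "cohort"
        ccfg = config.cohort or cohort_mod.CohortConfig(
            n_participants=config.n_participants, seed=child_seed(config.seed, "cohort")
        )
        cohort = cohort_mod.sample_cohort(ccfg)

        stage = "generate_sessions"
        chunks = []
        base = child_seed(config.seed, "sessions")
        for s in (1, 2):
            for table in (det_tables[s], dis_tables[s]):
                for prof in cohort:
                    chunks.append(cohort_mod.generate_session(prof, table, s, features, seed=base))
        data = pd.concat(chunks, ignore_index=True)
        save(data, "ratings.csv")
        report["n_trials"] = len(data)

        stage = "fit"
        det_fits, det_points, det_summary = fit_cohort(data, "detection")
        dis_fits, dis_points, dis_summary = fit_cohort(data, "discrimination")
        save(det_summary, "fits_detection.csv")
        save(dis_summary, "fits_discrimination.csv")
        report["aic_sigmoid_preferred_detection"] = float(
            (det_summary["preferred"] == "sigmoid").mean()
        )
        report["aic_linear_preferred_discrimination"] = float(
            (dis_summary["preferred"] == "linear").mean()
        )

        stage = "reliability"
        rel = {}
        for task, (fits, points, summary) in (
            ("detection", (det_fits, det_points, det_summary)),
            ("discrimination", (dis_fits, dis_points, dis_summary)),
        ):
            ok = summary[~summary["excluded"] & ~summary["unfittable"]]
            both = set(ok[ok.session == 1].participant) & set(ok[ok.session == 2].participant)
            f1 = {p: fits[(p, 1)] for p in both}
            f2 = {p: fits[(p, 2)] for p in both}
            pt1 = {p: points[(p, 1)] for p in both}
            pt2 = {p: points[(p, 2)] for p in both}
            comps = reliability.within_vs_across(f1, f2, pt1, pt2)
            iccs = {}
            s1 = ok[ok.session == 1].set_index("participant")
            s2 = ok[ok.session == 2].set_index("participant")
            for par in ("pse", "bias", "range_"):
                iccs[par] = reliability.icc2(
                    s1.loc[sorted(both), par], s2.loc[sorted(both), par]
                )
            rel[task] = {
                "icc2": iccs,
                "nrmse": [
                    dict(direction=c.direction, mean_within=float(c.within.mean()),
                         mean_across=float(c.across.mean()),
                         mean_difference=c.mean_difference, t=c.t_statistic, p=c.p_value)
                    for c in comps
                ],
            }
        report["reliability"] = rel

        stage = "group"
        det_data = data[data["task"] == "detection"]
        rating_model = groupstats.fit_rating_model(det_data)
        acc_model = groupstats.fit_accuracy_model(det_data)
        report["group"] = {
            "rating_directness_b": rating_model.coef("x"),
            "rating_directness_p": rating_model.pvalue("x"),
            "rating_aic": rating_model.aic,
            "accuracy_directness_b": acc_model.coef("x"),
            "accuracy_directness_p": acc_model.pvalue("x"),
        }

        stage = "associate"
        det_s1 = det_summary[(det_summary.session == 1) & ~det_summary.excluded].set_index("participant")
        dis_s1 = dis_summary[(dis_summary.session == 1) & ~dis_summary.excluded].set_index("participant")
        xtask = association.cross_task_correlations(det_s1, dis_s1)
        if out_dir is not None:
            xtask.cross_cells.to_csv(out_dir / "cross_task.csv", index=False, lineterminator="\n")
        traits = cohort_mod.sample_traits(cohort, ccfg, seed=child_seed(config.seed, "traits"))
        common = det_s1.index.intersection(dis_s1.index).intersection(traits.index)
        comp = association.composite_bias_minus_pse(
            det_s1.loc[common, "bias"], det_s1.loc[common, "pse"]
        )
        tr = association.bootstrap_cis(
            comp, traits.loc[common], reps=config.bootstrap_reps,
            seed=child_seed(config.seed, "bootstrap"),
        )
        perm_p = association.permutation_r2(
            comp, traits.loc[common], reps=config.permutation_reps,
            seed=child_seed(config.seed, "permutation"),
        )
        report["association"] = {
            "cross_task_significant_cells": int(xtask.cross_cells["significant"].sum()),
            "detection_biaspse_r2": tr.r2,
            "detection_biaspse_perm_p": perm_p,
            "n_significant_traits": int(tr.significant.sum()),
        }

        stage = "recovery"
        report["recovery"] = {
            "detection": _recovery(cohort, det_summary, "detection"),
            "discrimination": _recovery(cohort, dis_summary, "discrimination"),
        }
    except Exception as exc:  # partial outputs above are already on disk
        raise StageError(stage, exc) from exc

    if out_dir is not None:
        (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    return report
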