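"""Delimited-text I/O for cohorts, configs and fitted rules.

Cohorts are exchanged as long-format CSVs: ``biopsies.csv``
(subject_id, biopsy_time, result), ``covariates.csv``
(subject_id, time, z1..zp) and, optionally, ``truth.csv``
(subject_id, T, C). Configs are flat YAML key-value files mirroring the
dataclass field names.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .experiments import StudyConfig
from .policy import LinearRule
from .simulate import Cohort, ObservedSubject, ScenarioConfig, SubjectLatent

__all__ = [
    "write_cohort",
    "read_cohort",
    "read_scenario_config",
    "read_study_config",
    "write_rule",
    "read_rule",
]


def write_cohort(cohort: Cohort, directory) -> dict[str, Path]:
    """Write biopsies.csv, covariates.csv and (when truth is present)
    truth.csv under ``directory``; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bio_rows, cov_rows = [], []
    for i, subj in enumerate(cohort.subjects):
        for t, r in zip(subj.biopsy_times, subj.results):
            bio_rows.append({"subject_id": i, "biopsy_time": t, "result": int(r)})
        for t in sorted(subj.covariates_at):
            z = subj.covariates_at[t]
            row = {"subject_id": i, "time": t}
            row.update({f"z{l + 1}": z[l] for l in range(len(z))})
            cov_rows.append(row)
    paths = {
        "biopsies": directory / "biopsies.csv",
        "covariates": directory / "covariates.csv",
    }
    pd.DataFrame.from_records(
        bio_rows, columns=["subject_id", "biopsy_time", "result"]
    ).to_csv(paths["biopsies"], index=False)
    pd.DataFrame.from_records(cov_rows).to_csv(paths["covariates"], index=False)
    if cohort.truth is not None:
        paths["truth"] = directory / "truth.csv"
        pd.DataFrame(
            {
                "subject_id": range(cohort.n),
                "T": [lat.T_true for lat in cohort.truth],
                "C": [lat.C for lat in cohort.truth],
            }
        ).to_csv(paths["truth"], index=False)
    return paths


def read_cohort(
    biopsies_csv,
    covariates_csv,
    truth_csv=None,
    config: ScenarioConfig | None = None,
) -> Cohort:
    """Rebuild a Cohort from the CSV schema written by write_cohort.

    Subjects present only in covariates.csv (no observed biopsy) are kept
    with an empty biopsy record. Truth rows, when given, must cover every
    subject; latent slopes are not stored in the text schema, so truth
    carries event/censoring times only.
    """
    bio = pd.read_csv(biopsies_csv, float_precision="round_trip")
    cov = pd.read_csv(covariates_csv, float_precision="round_trip")
    zcols = [c for c in cov.columns if c.startswith("z")]
    ids = sorted(set(bio["subject_id"]) | set(cov["subject_id"]))
    id_pos = {sid: k for k, sid in enumerate(ids)}
    times = [[] for _ in ids]
    results = [[] for _ in ids]
    for row in bio.itertuples(index=False):
        times[id_pos[row.subject_id]].append(float(row.biopsy_time))
        results[id_pos[row.subject_id]].append(int(row.result))
    covariates: list[dict[float, np.ndarray]] = [{} for _ in ids]
    zvals = cov[zcols].to_numpy(dtype=float)
    for k, row in enumerate(cov.itertuples(index=False)):
        covariates[id_pos[row.subject_id]][float(row.time)] = zvals[k]
    subjects = []
    for k in range(len(ids)):
        order = np.argsort(times[k])
        subjects.append(
            ObservedSubject(
                biopsy_times=np.asarray(times[k])[order],
                results=np.asarray(results[k], dtype=int)[order],
                covariates_at=covariates[k],
                dropped_out=bool(results[k] and sorted(results[k])[-1] == 1),
            )
        )
    truth = None
    if truth_csv is not None:
        tdf = pd.read_csv(truth_csv, float_precision="round_trip").set_index("subject_id")
        p = len(zcols)
        truth = [
            SubjectLatent(
                a0=np.full(p, np.nan),
                a1=np.full(p, np.nan),
                T_true=float(tdf.loc[sid, "T"]),
                C=float(tdf.loc[sid, "C"]),
            )
            for sid in ids
        ]
    return Cohort(subjects=subjects, truth=truth, config=config)


def _load_flat(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat key-value mapping")
    return data


def _coerce(cls, data: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    for key in ("landmarks", "r_grid", "beta", "slope_mean"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    if "slope_cov" in data:
        data["slope_cov"] = tuple(tuple(row) for row in data["slope_cov"])
    return cls(**data)


def read_scenario_config(path) -> ScenarioConfig:
    return _coerce(ScenarioConfig, _load_flat(path))


def read_study_config(path) -> StudyConfig:
    return _coerce(StudyConfig, _load_flat(path))


def write_rule(rule: LinearRule, path, **extra) -> Path:
    path = Path(path)
    path.write_text(rule.to_json(**extra))
    return path


def read_rule(path) -> LinearRule:
    return LinearRule.from_json(Path(path).read_text())
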