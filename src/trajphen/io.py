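"""File-format contracts for every pipeline artifact.

Adherence data travel as long-format CSV (participant_id, mission, week,
score) with an empty score cell meaning missing; covariates and outcomes as
wide CSV keyed by participant_id; smooth-curve sets as JSON (basis spec +
coefficient matrix); ground truth as JSON.  Readers validate strictly and
name the offending line; writers emit RFC-4180 CSV and pretty-printed JSON
so that identical inputs give byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import AdherencePanel
from .smoothing import SmoothCurveSet, SplineBasis
from .synthetic import COVARIATE_COLUMNS, SimTruth

ADHERENCE_COLUMNS = ["participant_id", "mission", "week", "score"]


def read_adherence(path: str | Path) -> AdherencePanel:
    """Read a long-format adherence CSV into a panel.

    Cells may be missing either as empty score fields or as absent rows; the
    panel grid is the cross product of the observed participants, missions and
    weeks.  Duplicate (participant, mission, week) keys and scores outside
    [1, 5] are rejected with the CSV line number.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "mission": str})
    missing_cols = [c for c in ADHERENCE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    df["_line"] = np.arange(2, len(df) + 2)  # header is line 1
    dup = df.duplicated(subset=["participant_id", "mission", "week"], keep=False)
    if dup.any():
        lines = df.loc[dup, "_line"].tolist()
        raise ValueError(f"{path}: duplicate (participant, mission, week) keys at lines {lines}")
    present = df["score"].notna()
    bad = present & ((df["score"] < 1) | (df["score"] > 5))
    if bad.any():
        lines = df.loc[bad, "_line"].tolist()
        raise ValueError(f"{path}: score outside [1, 5] at lines {lines}")

    participants = sorted(df["participant_id"].unique())
    missions = sorted(df["mission"].unique())
    weeks = np.sort(df["week"].unique().astype(float))
    n, w, m = len(participants), len(weeks), len(missions)
    values = np.full((n, w, m), np.nan)
    mask = np.zeros((n, w, m), dtype=bool)
    pi = {p: i for i, p in enumerate(participants)}
    mi = {s: j for j, s in enumerate(missions)}
    wi = {t: j for j, t in enumerate(weeks)}
    rows = df[present]
    ii = rows["participant_id"].map(pi).to_numpy(dtype=int)
    tt = rows["week"].astype(float).map(wi).to_numpy(dtype=int)
    jj = rows["mission"].map(mi).to_numpy(dtype=int)
    values[ii, tt, jj] = rows["score"].to_numpy(dtype=float)
    mask[ii, tt, jj] = True
    values[~mask] = 1.0  # placeholder under the mask; no shadow truth in files
    return AdherencePanel(
        participant_ids=participants, mission_ids=missions, obs_weeks=weeks,
        values=values, mask=mask,
    )


def write_adherence(panel: AdherencePanel, path: str | Path) -> None:
    """Write the full grid in long format; masked cells get empty score fields."""
    records = []
    for i, p in enumerate(panel.participant_ids):
        for j, mission in enumerate(panel.mission_ids):
            for t, week in enumerate(panel.obs_weeks):
                score = panel.values[i, t, j] if panel.mask[i, t, j] else np.nan
                records.append((p, mission, _fmt_week(week), score))
    df = pd.DataFrame(records, columns=ADHERENCE_COLUMNS)
    df.to_csv(path, index=False, lineterminator="\n")


def _fmt_week(week: float) -> float | int:
    return int(week) if float(week).is_integer() else float(week)


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str}).set_index("participant_id")
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing covariate columns {missing}")
    if df.isna().any().any():
        raise ValueError(f"{path}: covariate table has missing values")
    return df


def write_covariates(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, lineterminator="\n")


def read_outcome(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, dtype={"participant_id": str}).set_index("participant_id")
    col = df.columns[0]
    s = df[col]
    if s.isna().any() or not np.all(np.isfinite(s.to_numpy(dtype=float))):
        raise ValueError(f"{path}: outcome must be finite with no missing values")
    return s


def write_outcome(s: pd.Series, path: str | Path) -> None:
    s.to_frame().to_csv(path, lineterminator="\n")


def write_curves(curves: SmoothCurveSet, path: str | Path) -> None:
    payload = {
        "mission": curves.mission,
        "lambda_smooth": curves.lambda_smooth,
        "order": curves.basis.order,
        "knots": curves.basis.knots.tolist(),
        "domain": list(curves.basis.domain),
        "participant_ids": curves.participant_ids,
        "coefficients": curves.coefficients.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_curves(path: str | Path) -> SmoothCurveSet:
    payload = json.loads(Path(path).read_text())
    knots = np.asarray(payload["knots"], dtype=float)
    order = int(payload["order"])
    basis = SplineBasis(
        knots=knots, order=order, n_basis=len(knots) - order,
        domain=tuple(payload["domain"]),
    )
    return SmoothCurveSet(
        basis=basis,
        coefficients=np.asarray(payload["coefficients"], dtype=float),
        mission=payload["mission"],
        lambda_smooth=float(payload["lambda_smooth"]),
        participant_ids=payload["participant_ids"],
    )


def write_truth(truth: SimTruth, path: str | Path) -> None:
    payload = {
        "latent_scores": truth.latent_scores.tolist(),
        "true_eigenfunctions": truth.true_eigenfunctions.tolist(),
        "true_outcome_betas": truth.true_outcome_betas.tolist(),
        "mean_profile": truth.mean_profile.tolist(),
        "participant_ids": list(truth.covariates.index),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
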