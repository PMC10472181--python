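"""Cohort filtering and linear-interpolation imputation.

Participants are excluded when more than a threshold fraction (default 20%)
of their adherence cells are missing, or when any mission lacks its first or
last observation; remaining interior gaps are filled by straight-line
interpolation in week coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import AdherencePanel


@dataclass
class FilterReport:
    kept_ids: list[str]
    excluded_ids: list[str]
    missing_fraction: dict[str, float]
    endpoints_present: dict[str, bool]
    threshold: float
    per_mission: bool

    def __post_init__(self) -> None:
        overlap = set(self.kept_ids) & set(self.excluded_ids)
        if overlap:
            raise ValueError(f"participants both kept and excluded: {sorted(overlap)}")

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "per_mission": self.per_mission,
            "n_kept": len(self.kept_ids),
            "n_excluded": len(self.excluded_ids),
            "kept_ids": self.kept_ids,
            "excluded_ids": self.excluded_ids,
            "missing_fraction": self.missing_fraction,
            "endpoints_present": self.endpoints_present,
        }


def exclusion_filter(
    panel: AdherencePanel, threshold: float = 0.20, per_mission: bool = False
) -> FilterReport:
    """Apply the missing-data exclusion rule.

    A participant is excluded iff their missing fraction exceeds ``threshold``
    (strictly: exactly 20% missing is kept) or any mission lacks its first or
    last observation.  The missing fraction is pooled over all mission x week
    cells by default; with ``per_mission=True`` a participant is excluded as
    soon as any single mission exceeds the threshold.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    if panel.n_participants == 0:
        raise ValueError("empty panel")
    pooled = panel.missing_fraction()
    endpoints_ok = panel.endpoints_observed()
    if per_mission:
        exceeds = (panel.missing_fraction(per_mission=True) > threshold).any(axis=1)
    else:
        exceeds = pooled > threshold
    excluded = exceeds | ~endpoints_ok
    ids = panel.participant_ids
    return FilterReport(
        kept_ids=[p for p, e in zip(ids, excluded) if not e],
        excluded_ids=[p for p, e in zip(ids, excluded) if e],
        missing_fraction={p: float(f) for p, f in zip(ids, pooled)},
        endpoints_present={p: bool(b) for p, b in zip(ids, endpoints_ok)},
        threshold=threshold,
        per_mission=per_mission,
    )


def interpolate_linear(values: np.ndarray, observed: np.ndarray, weeks: np.ndarray) -> np.ndarray:
    """Fill missing entries of one series by linear interpolation in week units.

    Requires the first and last entries to be observed (series failing that
    should have been excluded upstream).  Observed values are untouched.
    """
    values = np.asarray(values, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    weeks = np.asarray(weeks, dtype=float)
    if values.shape != observed.shape or values.shape != weeks.shape:
        raise ValueError("values, observed and weeks must have matching shapes")
    if not (observed[0] and observed[-1]):
        raise ValueError("series endpoints must be observed before interpolation")
    out = values.copy()
    if observed.all():
        return out
    out[~observed] = np.interp(weeks[~observed], weeks[observed], values[observed])
    return out


def impute_panel(panel: AdherencePanel) -> AdherencePanel:
    """Interpolate every participant x mission series; result fully observed."""
    out = panel.copy()
    for i in range(out.n_participants):
        for j in range(out.n_missions):
            out.values[:, :, j][i] = interpolate_linear(
                panel.values[i, :, j], panel.mask[i, :, j], panel.obs_weeks
            )
    out.mask[:] = True
    return out


def preprocess(
    panel: AdherencePanel, threshold: float = 0.20, per_mission: bool = False
) -> tuple[AdherencePanel, FilterReport]:
    """Exclusion filter followed by linear-interpolation imputation."""
    report = exclusion_filter(panel, threshold=threshold, per_mission=per_mission)
    clean = impute_panel(panel.subset(report.kept_ids))
    return clean, report
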