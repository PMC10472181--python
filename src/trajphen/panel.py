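"""Longitudinal adherence panel: participants x observation weeks x missions.

The panel is the raw input of the pipeline: biweekly 5-point Likert adherence
ratings for each behavioral goal ("mission"), with an explicit observed/missing
mask.  Values are kept even where the mask says missing (a shadow copy), so
imputation accuracy can be checked against the masked truth on synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class AdherencePanel:
    """Adherence values on a fixed week grid.

    Attributes
    ----------
    participant_ids : list of str
    mission_ids : list of str
    obs_weeks : (w,) float array, strictly increasing week numbers
    values : (n, w, m) float array, Likert-scale adherence (reals in [1, 5]
        after imputation; integers 1-5 when raw). May hold shadow values in
        cells flagged missing.
    mask : (n, w, m) bool array, True where observed
    """

    participant_ids: list[str]
    mission_ids: list[str]
    obs_weeks: np.ndarray
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.obs_weeks = np.asarray(self.obs_weeks, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        n, w, m = len(self.participant_ids), len(self.obs_weeks), len(self.mission_ids)
        if self.values.shape != (n, w, m):
            raise ValueError(
                f"values shape {self.values.shape} != (participants, weeks, missions) = {(n, w, m)}"
            )
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values shape")
        if np.any(np.diff(self.obs_weeks) <= 0):
            raise ValueError("obs_weeks must be strictly increasing")
        observed = self.values[self.mask]
        if observed.size and (np.nanmin(observed) < 1 or np.nanmax(observed) > 5):
            raise ValueError("observed adherence values must lie in [1, 5]")

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    @property
    def n_weeks(self) -> int:
        return len(self.obs_weeks)

    @property
    def n_missions(self) -> int:
        return len(self.mission_ids)

    def missing_fraction(self, per_mission: bool = False) -> np.ndarray:
        """Fraction of missing cells per participant.

        Pooled over all missions and weeks by default; per mission when
        ``per_mission`` is True (returns an (n, m) array).
        """
        miss = ~self.mask
        if per_mission:
            return miss.mean(axis=1)
        return miss.reshape(self.n_participants, -1).mean(axis=1)

    def endpoints_observed(self) -> np.ndarray:
        """(n,) bool: first AND last week observed for every mission."""
        return (self.mask[:, 0, :] & self.mask[:, -1, :]).all(axis=1)

    def copy(self) -> "AdherencePanel":
        return replace(
            self,
            participant_ids=list(self.participant_ids),
            mission_ids=list(self.mission_ids),
            obs_weeks=self.obs_weeks.copy(),
            values=self.values.copy(),
            mask=self.mask.copy(),
        )

    def subset(self, keep_ids: list[str]) -> "AdherencePanel":
        """Panel restricted to ``keep_ids`` (order preserved as given)."""
        index = {p: i for i, p in enumerate(self.participant_ids)}
        missing = [p for p in keep_ids if p not in index]
        if missing:
            raise KeyError(f"unknown participant ids: {missing}")
        rows = [index[p] for p in keep_ids]
        return AdherencePanel(
            participant_ids=list(keep_ids),
            mission_ids=list(self.mission_ids),
            obs_weeks=self.obs_weeks.copy(),
            values=self.values[rows].copy(),
            mask=self.mask[rows].copy(),
        )

    def mission_matrix(self, mission: str) -> tuple[np.ndarray, np.ndarray]:
        """(values, mask) of shape (n, w) for a single mission."""
        j = self.mission_ids.index(mission)
        return self.values[:, :, j], self.mask[:, :, j]
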