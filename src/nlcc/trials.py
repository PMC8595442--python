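"""Per-trial containers for simulated or recorded experiments.

A :class:`TrialTable` holds one row per trial of a perceptual experiment:
the task-relevant stimulus value ``s``, an optional nuisance variable
``nu`` (e.g. spatial phase, polarity, or orientation in a variance task),
the population response vector ``r`` (typically spike counts), and the
behavioral estimate or choice ``choice`` once a decoder has run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TrialTable"]


@dataclass
class TrialTable:
    """Trial-by-trial record of stimulus, nuisance, responses, and choice.

    Parameters
    ----------
    s : ndarray, shape (n_trials,)
        Task-relevant stimulus per trial. Continuous (task units) or a
        binary category label coded as -1/+1.
    r : ndarray, shape (n_trials, n_neurons)
        Population response per trial. Spike counts are nonnegative.
    nu : ndarray, shape (n_trials,) or (n_trials, k), optional
        Nuisance variable(s) per trial.
    choice : ndarray, shape (n_trials,), optional
        Behavioral estimate (continuous) or binary choice (-1/+1).
    meta : dict
        Free-form provenance (generator name, parameters, seed).
    """

    s: np.ndarray
    r: np.ndarray
    nu: np.ndarray | None = None
    choice: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.r = np.atleast_2d(np.asarray(self.r, dtype=float))
        if self.r.shape[0] != self.s.shape[0]:
            raise ValueError(
                f"r has {self.r.shape[0]} trials but s has {self.s.shape[0]}"
            )
        if self.nu is not None:
            self.nu = np.asarray(self.nu, dtype=float)
            if self.nu.shape[0] != self.n_trials:
                raise ValueError("nu length does not match trial count")
        if self.choice is not None:
            self.choice = np.asarray(self.choice, dtype=float)
            if self.choice.shape[0] != self.n_trials:
                raise ValueError("choice length does not match trial count")

    @property
    def n_trials(self) -> int:
        return self.s.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.r.shape[1]

    def with_choice(self, choice: np.ndarray) -> "TrialTable":
        """Return a copy of the table with the behavioral choice filled in."""
        return replace(self, choice=np.asarray(choice, dtype=float))

    def with_responses(self, r: np.ndarray) -> "TrialTable":
        """Return a copy with the response matrix replaced (same trials)."""
        return replace(self, r=np.asarray(r, dtype=float))

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Flatten to a tidy DataFrame: trial, s, nu, choice, r_0..r_{N-1}."""
        data: dict[str, np.ndarray] = {"trial": np.arange(self.n_trials)}
        data["s"] = self.s
        if self.nu is not None:
            nu = np.atleast_2d(self.nu.T).T
            if nu.ndim == 1 or nu.shape[1] == 1:
                data["nu"] = nu.ravel()
            else:
                for j in range(nu.shape[1]):
                    data[f"nu_{j}"] = nu[:, j]
        if self.choice is not None:
            data["choice"] = self.choice
        for k in range(self.n_neurons):
            data[f"r_{k}"] = self.r[:, k]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: dict | None = None) -> "TrialTable":
        rcols = sorted(
            (c for c in df.columns if c.startswith("r_")),
            key=lambda c: int(c.split("_")[1]),
        )
        nucols = [c for c in df.columns if c == "nu" or c.startswith("nu_")]
        nu = df[nucols].to_numpy().squeeze() if nucols else None
        choice = df["choice"].to_numpy() if "choice" in df.columns else None
        return cls(
            s=df["s"].to_numpy(),
            r=df[rcols].to_numpy(),
            nu=nu,
            choice=choice,
            meta=meta or {},
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialTable":
        return cls.from_frame(pd.read_csv(path))

    def to_parquet(self, path: str | Path) -> None:
        """Binary container with the same schema as the CSV layout."""
        self.to_frame().to_parquet(path, index=False)

    @classmethod
    def from_parquet(cls, path: str | Path) -> "TrialTable":
        return cls.from_frame(pd.read_parquet(path))
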