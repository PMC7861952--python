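"""Core in-memory containers shared by every pipeline stage.

Two containers travel through the pipeline: :class:`LabeledSignalSet` holds raw
multichannel recordings with their trial annotations, and :class:`FeatureTable`
holds real-valued feature rows with class labels plus a per-column
continuous/discrete flag (the flag drives the degenerate eta^2 = 0 rule of the
virtual-sample generator).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["Trial", "LabeledSignalSet", "FeatureTable"]

#: reserved column names when a FeatureTable round-trips through pandas
_META_COLUMNS = ("class_label", "subject_id", "trial_id")


@dataclass(frozen=True)
class Trial:
    """One recording: ``signal`` is channels x samples at ``sampling_rate`` Hz."""

    signal: np.ndarray
    subject_id: int
    class_label: int
    repetition: int
    sampling_rate: float
    force_level: int = 0
    trial_id: int = -1

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 2:
            raise ValueError(f"trial signal must be channels x samples, got ndim={sig.ndim}")
        object.__setattr__(self, "signal", sig)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class LabeledSignalSet:
    """A homogeneous collection of labeled trials.

    Invariants: every trial shares the channel count and sampling rate, and
    class labels come from the finite set ``classes``.
    """

    trials: list[Trial]

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValueError("LabeledSignalSet needs at least one trial")
        ch = {t.n_channels for t in self.trials}
        fs = {t.sampling_rate for t in self.trials}
        if len(ch) != 1:
            raise ValueError(f"trials disagree on channel count: {sorted(ch)}")
        if len(fs) != 1:
            raise ValueError(f"trials disagree on sampling rate: {sorted(fs)}")
        # assign stable ids in insertion order where missing
        fixed = []
        for i, t in enumerate(self.trials):
            fixed.append(replace(t, trial_id=i) if t.trial_id < 0 else t)
        self.trials = fixed

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def n_channels(self) -> int:
        return self.trials[0].n_channels

    @property
    def sampling_rate(self) -> float:
        return self.trials[0].sampling_rate

    @property
    def classes(self) -> np.ndarray:
        return np.unique([t.class_label for t in self.trials])

    @property
    def subjects(self) -> np.ndarray:
        return np.unique([t.subject_id for t in self.trials])

    def subset(self, trial_ids: Iterable[int]) -> "LabeledSignalSet":
        wanted = set(int(i) for i in trial_ids)
        return LabeledSignalSet([t for t in self.trials if t.trial_id in wanted])

    # -- text serialization: one delimited file per trial plus a manifest -----

    def write_text(self, out_dir: str | Path) -> Path:
        """Write one whitespace-free CSV per trial (columns = channels) and a
        JSON manifest recording subject/class/repetition/force/path/rate."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = []
        for t in self.trials:
            name = f"trial_{t.trial_id:05d}.csv"
            np.savetxt(out / name, t.signal.T, delimiter=",", fmt="%.10g")
            manifest.append(
                {
                    "path": name,
                    "subject_id": int(t.subject_id),
                    "class_label": int(t.class_label),
                    "repetition": int(t.repetition),
                    "force_level": int(t.force_level),
                    "sampling_rate": float(t.sampling_rate),
                    "trial_id": int(t.trial_id),
                }
            )
        mpath = out / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=1))
        return mpath

    @classmethod
    def read_text(cls, manifest_path: str | Path) -> "LabeledSignalSet":
        mpath = Path(manifest_path)
        entries = json.loads(mpath.read_text())
        trials = []
        for e in entries:
            sig = np.loadtxt(mpath.parent / e["path"], delimiter=",", ndmin=2).T
            trials.append(
                Trial(
                    signal=sig,
                    subject_id=e["subject_id"],
                    class_label=e["class_label"],
                    repetition=e["repetition"],
                    force_level=e.get("force_level", 0),
                    sampling_rate=e["sampling_rate"],
                    trial_id=e["trial_id"],
                )
            )
        return cls(trials)


@dataclass
class FeatureTable:
    """Feature rows with labels; ``discrete[j]`` marks integer-coded columns.

    ``subject_id`` and ``trial_id`` are optional per-row annotations that the
    cross-validation and reporting layers rely on; virtual (augmented) rows
    carry ``trial_id = -1``.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    discrete: np.ndarray | None = None
    subject_id: np.ndarray | None = None
    trial_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (rows x features)")
        self.y = np.asarray(self.y)
        if self.y.shape[0] != self.X.shape[0]:
            raise ValueError("y length must match row count")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.X.shape[1])]
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must match column count")
        if self.discrete is None:
            self.discrete = np.zeros(self.X.shape[1], dtype=bool)
        else:
            self.discrete = np.asarray(self.discrete, dtype=bool)
            if self.discrete.shape[0] != self.X.shape[1]:
                raise ValueError("discrete flags must match column count")
        for name, arr in (("subject_id", self.subject_id), ("trial_id", self.trial_id)):
            if arr is not None and np.asarray(arr).shape[0] != self.X.shape[0]:
                raise ValueError(f"{name} length must match row count")
        if self.subject_id is not None:
            self.subject_id = np.asarray(self.subject_id)
        if self.trial_id is not None:
            self.trial_id = np.asarray(self.trial_id)

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)

    def select(self, mask: np.ndarray) -> "FeatureTable":
        mask = np.asarray(mask)
        return FeatureTable(
            X=self.X[mask],
            y=self.y[mask],
            feature_names=list(self.feature_names),
            discrete=self.discrete.copy(),
            subject_id=None if self.subject_id is None else self.subject_id[mask],
            trial_id=None if self.trial_id is None else self.trial_id[mask],
        )

    def select_trials(self, trial_ids: Iterable[int]) -> "FeatureTable":
        if self.trial_id is None:
            raise ValueError("table has no trial ids")
        wanted = set(int(i) for i in trial_ids)
        mask = np.array([int(t) in wanted for t in self.trial_id])
        return self.select(mask)

    @staticmethod
    def concat(tables: Sequence["FeatureTable"]) -> "FeatureTable":
        if not tables:
            raise ValueError("nothing to concatenate")
        first = tables[0]
        for t in tables[1:]:
            if t.feature_names != first.feature_names:
                raise ValueError("feature_names mismatch in concat")
        has_subj = all(t.subject_id is not None for t in tables)
        has_tid = all(t.trial_id is not None for t in tables)
        return FeatureTable(
            X=np.vstack([t.X for t in tables]),
            y=np.concatenate([t.y for t in tables]),
            feature_names=list(first.feature_names),
            discrete=first.discrete.copy(),
            subject_id=np.concatenate([t.subject_id for t in tables]) if has_subj else None,
            trial_id=np.concatenate([t.trial_id for t in tables]) if has_tid else None,
        )

    # -- pandas / delimited-text round trip -----------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df["class_label"] = self.y
        if self.subject_id is not None:
            df["subject_id"] = self.subject_id
        if self.trial_id is not None:
            df["trial_id"] = self.trial_id
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, discrete: Sequence[str] | None = None) -> "FeatureTable":
        feat_cols = [c for c in df.columns if c not in _META_COLUMNS]
        return cls(
            X=df[feat_cols].to_numpy(dtype=float),
            y=df["class_label"].to_numpy(),
            feature_names=feat_cols,
            discrete=np.array([c in set(discrete or ()) for c in feat_cols]),
            subject_id=df["subject_id"].to_numpy() if "subject_id" in df else None,
            trial_id=df["trial_id"].to_numpy() if "trial_id" in df else None,
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, discrete: Sequence[str] | None = None) -> "FeatureTable":
        return cls.from_dataframe(pd.read_csv(path), discrete=discrete)
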