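"""Synthetic experiment-shaped data with known ground truth.

Emulates the laboratory design — sessions of 18-25 subjects, each
playing all five network treatments in a randomized order, trials
capped at 10 rounds — by running the agent model with known behavior
parameters and flattening the trial logs into per-subject per-round
decision records. Subject heterogeneity enters as a Normal random
offset on the giving-probability intercept, which induces the
within-subject correlation the clustered-error analyses assume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .networks import LABELS, standard_treatments
from .simulate import BehaviorParams, TrialLog, run_trial, trial_records

RECORD_COLUMNS = (
    "session",
    "subject",
    "treatment",
    "round",
    "X",
    "R",
    "L",
    "K",
    "gave",
    "amount",
    "received_prev",
)


@dataclass
class SessionSpec:
    """Template for one synthetic session.

    ``sigma_subj`` is the standard deviation of the per-subject random
    intercept offset on the probability part (tokens of behavioral
    heterogeneity, not an empirical estimate). ``treatments`` is the
    canonical label set; the play order is reshuffled per session.
    """

    n_subjects: int = 25
    sigma_subj: float = 0.3
    lo: int = 10
    hi: int = 200
    params: BehaviorParams = field(default_factory=BehaviorParams)
    treatments: tuple[str, ...] = LABELS

    def __post_init__(self) -> None:
        if sorted(self.treatments) != sorted(LABELS):
            raise ValueError("treatments must be a permutation of the five labels")
        if not 2 <= self.n_subjects:
            raise ValueError("need at least 2 subjects")
        if self.sigma_subj < 0:
            raise ValueError("sigma_subj must be non-negative")

    def to_json(self) -> str:
        doc = asdict(self)
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SessionSpec":
        doc = json.loads(text)
        doc["params"] = BehaviorParams(**doc["params"])
        doc["treatments"] = tuple(doc["treatments"])
        return cls(**doc)


def generate_sessions(
    n_sessions: int, spec: SessionSpec, seed: int
) -> tuple[pd.DataFrame, list[TrialLog]]:
    """Run ``n_sessions`` independent sessions from one spec template.

    Session s derives all its randomness (network draws, subject
    offsets, treatment order, within-trial decisions) from seed + s.
    Returns the flat decision-record table and the underlying trial logs.
    """
    if n_sessions < 1:
        raise ValueError("need n_sessions >= 1")
    frames, logs = [], []
    for s in range(n_sessions):
        rng = np.random.default_rng(seed + s)
        offsets = rng.normal(0.0, spec.sigma_subj, size=spec.n_subjects)
        topos = standard_treatments(spec.n_subjects, spec.lo, spec.hi, rng)
        order = [spec.treatments[i] for i in rng.permutation(len(spec.treatments))]
        for label in order:
            log = run_trial(topos[label], spec.params, rng, offsets, session=s)
            logs.append(log)
            frames.append(trial_records(log))
    records = pd.concat(frames, ignore_index=True)[list(RECORD_COLUMNS)]
    return records, logs


def drop_trials(
    logs: list[TrialLog], k: int, rng: np.random.Generator | int | None = None
) -> list[TrialLog]:
    """Uniformly remove k trials (emulating failed sessions' trials)."""
    if not 0 <= k <= len(logs):
        raise ValueError("k must be between 0 and the number of trials")
    if k == 0:
        return list(logs)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    drop = set(rng.choice(len(logs), size=k, replace=False).tolist())
    return [log for i, log in enumerate(logs) if i not in drop]


def write_records(records: pd.DataFrame, path) -> None:
    """Write the decision-record table with the fixed CSV header."""
    records.to_csv(path, index=False, columns=list(RECORD_COLUMNS))


def read_records(path) -> pd.DataFrame:
    """Read and validate a decision-record CSV."""
    df = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records CSV missing columns: {sorted(missing)}")
    bad = df[(df["amount"] > 0) != (df["gave"] == 1)]
    if len(bad):
        raise ValueError(f"rows where amount>0 disagrees with gave: {bad.index[:5].tolist()}")
    if (df["amount"] > df["X"]).any():
        raise ValueError("amount exceeds round-start income in some rows")
    return df[list(RECORD_COLUMNS)]
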