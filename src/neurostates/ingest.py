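"""Assembly, motion screening, and standardisation of parcel time series.

Subjects are screened on two framewise-displacement (FD) rules — mean FD
above 0.3 mm, or more than 15% of volumes with FD above the per-volume
scrub threshold (0.5 mm by default) — then each retained subject's parcel
series is z-scored per parcel and the subjects are concatenated in order
into the group matrix the HMM consumes. Inputs are assumed to be already
cleaned (confound-regressed, band-pass filtered) parcel averages; no
image-space processing happens here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ParcelTimeSeries",
    "MotionTrace",
    "GroupMatrix",
    "ExclusionThresholds",
    "apply_exclusion",
    "standardise_and_concatenate",
    "load_timeseries_dir",
    "load_motion_csv",
]

FD_MEAN_MAX_MM = 0.3
BAD_FRACTION_MAX = 0.15


@dataclass
class ParcelTimeSeries:
    subject_id: str
    values: np.ndarray  # (T, P)
    tr_seconds: float = 3.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 2:
            raise ValueError(
                f"{self.subject_id}: need a (T>=2, P) parcel matrix")
        if not np.isfinite(self.values).all():
            raise ValueError(f"{self.subject_id}: missing values in time series")


@dataclass
class MotionTrace:
    subject_id: str
    fd_mm: np.ndarray  # per volume, non-negative
    scrub_threshold_mm: float = 0.5

    def __post_init__(self) -> None:
        self.fd_mm = np.asarray(self.fd_mm, dtype=float)
        if (self.fd_mm < 0).any():
            raise ValueError(f"{self.subject_id}: negative FD values")

    @property
    def mean_fd(self) -> float:
        return float(self.fd_mm.mean())

    @property
    def bad_fraction(self) -> float:
        return float((self.fd_mm > self.scrub_threshold_mm).mean())


@dataclass
class ExclusionThresholds:
    """Motion screening thresholds; boundaries are exclusive (strict >)."""

    fd_mean_max_mm: float = FD_MEAN_MAX_MM
    scrub_threshold_mm: float = 0.5
    bad_fraction_max: float = BAD_FRACTION_MAX


@dataclass
class GroupMatrix:
    """Standardised, concatenated group time series.

    values : (sum of retained subjects' T) x P; per subject and parcel the
        block has mean 0 and (population) SD 1.
    """

    values: np.ndarray
    retained_ids: list[str]
    timepoints: list[int]  # per retained subject, in order

    @property
    def n_parcels(self) -> int:
        return self.values.shape[1]

    def as_subject_arrays(self) -> list[np.ndarray]:
        out, start = [], 0
        for T in self.timepoints:
            out.append(self.values[start:start + T])
            start += T
        return out

    def subject_of_row(self, row: int) -> str:
        start = 0
        for sid, T in zip(self.retained_ids, self.timepoints):
            if row < start + T:
                return sid
            start += T
        raise IndexError(row)


def apply_exclusion(subjects, thresholds: ExclusionThresholds | None = None):
    """Screen subjects on the two FD rules.

    subjects : list of (ParcelTimeSeries, MotionTrace) pairs with matching
        subject IDs.

    Returns (retained ParcelTimeSeries list, exclusion report). The report
    records, for every subject, mean FD, the flagged-volume fraction, and —
    for exclusions — which rule(s) fired.
    """
    thr = thresholds or ExclusionThresholds()
    retained, report = [], []
    for ts, motion in subjects:
        if motion is None:
            raise ValueError(f"missing motion trace for subject {ts.subject_id}")
        if ts.subject_id != motion.subject_id:
            raise ValueError(
                f"subject ID mismatch: {ts.subject_id} vs {motion.subject_id}")
        if len(motion.fd_mm) != ts.values.shape[0]:
            raise ValueError(
                f"{ts.subject_id}: motion trace length {len(motion.fd_mm)} "
                f"!= {ts.values.shape[0]} timepoints")
        mean_fd = motion.mean_fd
        bad_frac = float((motion.fd_mm > thr.scrub_threshold_mm).mean())
        rules = []
        if mean_fd > thr.fd_mean_max_mm:
            rules.append("mean_fd")
        if bad_frac > thr.bad_fraction_max:
            rules.append("bad_fraction")
        report.append({
            "subject_id": ts.subject_id,
            "mean_fd_mm": mean_fd,
            "bad_fraction": bad_frac,
            "excluded": bool(rules),
            "rules": rules,
        })
        if not rules:
            retained.append(ts)
    return retained, report


def standardise_and_concatenate(retained: list[ParcelTimeSeries]) -> GroupMatrix:
    """Per-subject per-parcel z-scoring, then row-wise concatenation.

    Standardisation uses the population SD (divisor n). A parcel with zero
    variance within a subject is an error, named explicitly.
    """
    if not retained:
        raise ValueError("no retained subjects")
    P = retained[0].values.shape[1]
    blocks = []
    for ts in retained:
        if ts.values.shape[1] != P:
            raise ValueError(
                f"{ts.subject_id}: parcel count {ts.values.shape[1]} != {P}")
        mu = ts.values.mean(axis=0)
        sd = ts.values.std(axis=0)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            raise ValueError(
                f"zero variance in subject {ts.subject_id}, parcel {dead[0] + 1}")
        blocks.append((ts.values - mu) / sd)
    return GroupMatrix(values=np.concatenate(blocks, axis=0),
                       retained_ids=[ts.subject_id for ts in retained],
                       timepoints=[b.shape[0] for b in blocks])


# ---------------------------------------------------------------------------
# I/O for the synth disk layout

def load_timeseries_dir(ts_dir: str | Path, tr_seconds: float = 3.0) -> list[ParcelTimeSeries]:
    """Read all per-subject TSV parcel matrices (sorted by subject ID)."""
    paths = sorted(Path(ts_dir).glob("*.tsv"))
    if not paths:
        raise FileNotFoundError(f"no .tsv time series in {ts_dir}")
    return [ParcelTimeSeries(subject_id=p.stem,
                             values=pd.read_csv(p, sep="\t").to_numpy(),
                             tr_seconds=tr_seconds)
            for p in paths]


def load_motion_csv(path: str | Path, scrub_threshold_mm: float = 0.5) -> dict[str, MotionTrace]:
    """Read the long-format motion CSV (subject_id, volume, fd_mm)."""
    df = pd.read_csv(path)
    out = {}
    for sid, grp in df.groupby("subject_id", sort=True):
        fd = grp.sort_values("volume")["fd_mm"].to_numpy()
        out[str(sid)] = MotionTrace(subject_id=str(sid), fd_mm=fd,
                                    scrub_threshold_mm=scrub_threshold_mm)
    return out


def save_group_matrix(group: GroupMatrix, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = [f"parcel_{p + 1:02d}" for p in range(group.n_parcels)]
    pd.DataFrame(group.values, columns=cols).to_csv(
        out / "group_matrix.tsv", sep="\t", index=False, float_format="%.6f")
    (out / "group_index.json").write_text(json.dumps(
        {"retained_ids": group.retained_ids, "timepoints": group.timepoints}))


def load_group_matrix(in_dir: str | Path) -> GroupMatrix:
    in_dir = Path(in_dir)
    values = pd.read_csv(in_dir / "group_matrix.tsv", sep="\t").to_numpy()
    idx = json.loads((in_dir / "group_index.json").read_text())
    return GroupMatrix(values=values, retained_ids=idx["retained_ids"],
                       timepoints=idx["timepoints"])
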