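"""Kin-discrimination (KD) scoring: from blinded observer calls to social
identity labels.

Each assayed isolate pair is scored independently by an odd panel of
observers (default three).  A score of 1 records a colony-interface
phenotype visibly altered relative to self-self control interfaces (a KD
phenotype); 0 records free merger.  The strict majority call is adopted,
and two isolates belong to the same social allotype exactly when their pair
shows no KD phenotype, so social identity = 1 - majority call.  Self-self
control pairs must never score a KD majority.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .pairs import PairSet

__all__ = [
    "KDRecord",
    "KDScoringError",
    "majority_call",
    "social_identity",
    "score_table",
    "read_kd_table",
    "write_kd_table",
]


class KDScoringError(ValueError):
    """Raised for malformed observer panels or missing records."""


def majority_call(scores: Sequence[int]) -> tuple[int, bool]:
    """Strict majority of binary observer scores, plus a unanimity flag.

    Requires an odd panel (ties are undefined otherwise).
    """
    n = len(scores)
    if n < 1 or n % 2 == 0:
        raise KDScoringError(f"observer panel must be odd-sized and non-empty, got {n}")
    bad = [s for s in scores if s not in (0, 1)]
    if bad:
        raise KDScoringError(f"observer scores must be 0 or 1, got {bad}")
    total = sum(scores)
    return (1 if total * 2 > n else 0), (total in (0, n))


def pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class KDRecord:
    """Observer scores and majority KD call for one assayed pair.

    A pair with ``isolate_a == isolate_b`` is a self-self control and must
    carry a majority call of 0.
    """

    isolate_a: str
    isolate_b: str
    observer_scores: tuple[int, ...]

    @property
    def majority(self) -> int:
        return majority_call(self.observer_scores)[0]

    @property
    def unanimous(self) -> bool:
        return majority_call(self.observer_scores)[1]

    @property
    def is_control(self) -> bool:
        return self.isolate_a == self.isolate_b

    @property
    def key(self) -> tuple[str, str]:
        return pair_key(self.isolate_a, self.isolate_b)

    def validate(self) -> None:
        if self.is_control and self.majority != 0:
            raise KDScoringError(
                f"self-self control {self.isolate_a} scored a KD majority; "
                "classification is defined relative to self-self interfaces"
            )


def _record_map(records: Iterable[KDRecord]) -> dict[tuple[str, str], KDRecord]:
    out: dict[tuple[str, str], KDRecord] = {}
    for rec in records:
        rec.validate()
        if rec.key in out and not rec.is_control:
            raise KDScoringError(f"duplicate KD record for pair {rec.key}")
        out[rec.key] = rec
    return out


def social_identity(
    pairset: PairSet, records: Iterable[KDRecord] | Mapping[tuple[str, str], KDRecord]
) -> dict[tuple[str, str], int]:
    """Per-pair social-identity labels for every pair in ``pairset``.

    Social identity is 1 when the pair shows no majority KD phenotype (same
    allotype) and 0 otherwise.  Every pair must have a record; missing pairs
    are reported together in the error.
    """
    recmap = records if isinstance(records, Mapping) else _record_map(records)
    out: dict[tuple[str, str], int] = {}
    missing = []
    for e in pairset.entries:
        key = pair_key(e.isolate_a, e.isolate_b)
        rec = recmap.get(key)
        if rec is None:
            missing.append(key)
            continue
        out[key] = 1 - rec.majority
    if missing:
        raise KDScoringError(f"pairs without KD scores: {missing}")
    return out


def score_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Add majority, unanimous and social_identity columns to a KD table.

    Input columns: isolate_a, isolate_b, obs1, obs2, obs3 (any odd number of
    ``obs*`` columns is accepted).
    """
    obs_cols = sorted(c for c in frame.columns if c.startswith("obs"))
    if not obs_cols:
        raise KDScoringError("no observer columns (obs1, obs2, ...) found")
    out = frame.copy()
    majorities, unanimities = [], []
    for _, row in frame.iterrows():
        m, u = majority_call([int(row[c]) for c in obs_cols])
        majorities.append(m)
        unanimities.append(u)
    out["majority"] = majorities
    out["unanimous"] = unanimities
    out["social_identity"] = 1 - out["majority"]
    for rec in records_from_table(out):
        rec.validate()
    return out


def records_from_table(frame: pd.DataFrame) -> list[KDRecord]:
    obs_cols = sorted(c for c in frame.columns if c.startswith("obs"))
    return [
        KDRecord(
            isolate_a=str(row["isolate_a"]),
            isolate_b=str(row["isolate_b"]),
            observer_scores=tuple(int(row[c]) for c in obs_cols),
        )
        for _, row in frame.iterrows()
    ]


def read_kd_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"isolate_a", "isolate_b"}
    if not required <= set(frame.columns):
        raise KDScoringError(f"KD table {path} missing columns: {sorted(required - set(frame.columns))}")
    return frame


def write_kd_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)
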