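"""Quasi-random sampling of fully independent isolate pairs.

The identity-decay analysis requires, for each of the five spatial-scale
categories, R replicate sets of k isolate pairs, with the defining
constraint that no isolate occurs in more than one pair anywhere in the
whole collection (all replicates, all scales).  Pairs are therefore
statistically independent of one another both within and across scales.

The sampler fills scales from most constrained (micrometre, which needs two
clones from one fruiting body) to least constrained (kilometre).  Within a
scale it first tries a randomised greedy pass over the eligible-pair list
and falls back to a maximum-cardinality matching on the eligible-pair graph;
if a later scale cannot be filled, the whole construction restarts with
fresh randomisation, up to a configurable cap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .design import (
    SCALES,
    HierarchicalAddress,
    Scale,
    addresses_from_sheet,
    pair_scale,
)

__all__ = [
    "PairSet",
    "PairSamplingError",
    "sample_independent_pairs",
    "feasibility_report",
    "write_pairs",
    "read_pairs",
]


class PairSamplingError(RuntimeError):
    """Raised when no valid pair set can be constructed."""


@dataclass(frozen=True)
class PairEntry:
    replicate: int
    scale: Scale
    isolate_a: str
    isolate_b: str


@dataclass
class PairSet:
    """Replicate-structured, globally disjoint isolate pairs.

    ``entries`` holds (replicate, scale, isolate_a, isolate_b) records; no
    isolate ID appears in more than one entry across the entire set, and
    each entry's pair is at its labelled scale.
    """

    entries: list[PairEntry]
    n_replicates: int
    n_per_scale: int
    seed: int | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            for iso in (e.isolate_a, e.isolate_b):
                if iso in seen:
                    raise PairSamplingError(f"isolate {iso} reused across pairs")
                seen.add(iso)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def isolates(self) -> set[str]:
        out: set[str] = set()
        for e in self.entries:
            out.add(e.isolate_a)
            out.add(e.isolate_b)
        return out

    def by_scale(self, scale: Scale) -> list[PairEntry]:
        return [e for e in self.entries if e.scale is scale]

    def by_replicate_scale(self, replicate: int, scale: Scale) -> list[PairEntry]:
        return [e for e in self.entries if e.replicate == replicate and e.scale is scale]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": [e.replicate for e in self.entries],
                "scale": [e.scale.label for e in self.entries],
                "isolate_a": [e.isolate_a for e in self.entries],
                "isolate_b": [e.isolate_b for e in self.entries],
            }
        )


def _eligible_edges(
    free: Sequence[str], addrs: dict[str, HierarchicalAddress], scale: Scale
) -> list[tuple[str, str]]:
    edges = []
    for i, a in enumerate(free):
        for b in free[i + 1 :]:
            if pair_scale(addrs[a], addrs[b]) is scale:
                edges.append((a, b))
    return edges


def _greedy_disjoint(
    edges: list[tuple[str, str]], need: int, rng: np.random.Generator
) -> list[tuple[str, str]] | None:
    order = rng.permutation(len(edges))
    used: set[str] = set()
    chosen: list[tuple[str, str]] = []
    for k in order:
        a, b = edges[k]
        if a in used or b in used:
            continue
        chosen.append((a, b))
        used.update((a, b))
        if len(chosen) == need:
            return chosen
    return None


def _matching_disjoint(
    edges: list[tuple[str, str]], need: int, rng: np.random.Generator
) -> list[tuple[str, str]] | None:
    g = nx.Graph()
    for a, b in edges:
        g.add_edge(a, b, weight=1.0 + rng.random())
    matching = nx.max_weight_matching(g, maxcardinality=True)
    if len(matching) < need:
        return None
    pairs = [tuple(sorted(m)) for m in matching]
    idx = rng.choice(len(pairs), size=need, replace=False)
    return [pairs[k] for k in idx]


def sample_independent_pairs(
    sample_sheet: pd.DataFrame,
    n_per_scale: int = 4,
    n_replicates: int = 3,
    seed: int | None = None,
    max_restarts: int = 1000,
) -> PairSet:
    """Draw R x k disjoint isolate pairs per scale category.

    Deterministic given ``seed``.  Raises :class:`PairSamplingError` naming
    the first scale that could not be filled if the design is infeasible
    after ``max_restarts`` randomised restarts.
    """
    addrs = addresses_from_sheet(sample_sheet)
    need = n_per_scale * n_replicates
    rng = np.random.default_rng(seed)
    last_failure: tuple[Scale, int] | None = None

    for _ in range(max_restarts):
        free = list(addrs)
        chosen: dict[Scale, list[tuple[str, str]]] = {}
        failed = False
        for scale in SCALES:  # micrometre first: scarcest resource
            edges = _eligible_edges(free, addrs, scale)
            sel = _greedy_disjoint(edges, need, rng) if edges else None
            if sel is None and edges:
                sel = _matching_disjoint(edges, need, rng)
            if sel is None:
                eligible = {i for e in edges for i in e}
                last_failure = (scale, len(eligible))
                failed = True
                break
            chosen[scale] = sel
            used = {i for p in sel for i in p}
            free = [i for i in free if i not in used]
        if failed:
            continue
        entries: list[PairEntry] = []
        for scale in SCALES:
            order = rng.permutation(need)
            for slot, k in enumerate(order):
                a, b = chosen[scale][k]
                entries.append(
                    PairEntry(
                        replicate=slot // n_per_scale + 1,
                        scale=scale,
                        isolate_a=a,
                        isolate_b=b,
                    )
                )
        entries.sort(key=lambda e: (e.replicate, e.scale.rank))
        return PairSet(
            entries=entries,
            n_replicates=n_replicates,
            n_per_scale=n_per_scale,
            seed=seed,
        )

    scale, n_eligible = last_failure if last_failure else (Scale.MICROMETRE, 0)
    raise PairSamplingError(
        f"could not fill {need} disjoint pairs at the {scale.label} scale "
        f"after {max_restarts} restarts ({n_eligible} eligible isolates remained)"
    )


def feasibility_report(
    sample_sheet: pd.DataFrame, n_per_scale: int = 4, n_replicates: int = 3
) -> pd.DataFrame:
    """Per-scale upper bound on the number of disjoint pairs available.

    Capacity is the maximum-cardinality matching of the per-scale eligible
    pair graph over all isolates (an upper bound, since scales compete for
    isolates); scales whose capacity falls below demand are flagged.
    """
    addrs = addresses_from_sheet(sample_sheet)
    ids = list(addrs)
    demand = n_per_scale * n_replicates
    rows = []
    for scale in SCALES:
        edges = _eligible_edges(ids, addrs, scale)
        if edges:
            g = nx.Graph(edges)
            capacity = len(nx.max_weight_matching(g, maxcardinality=True))
        else:
            capacity = 0
        rows.append(
            {
                "scale": scale.label,
                "capacity": capacity,
                "demand": demand,
                "feasible": capacity >= demand,
            }
        )
    return pd.DataFrame(rows)


def write_pairs(pairset: PairSet, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# seed={pairset.seed}\n")
        fh.write(
            f"# n_replicates={pairset.n_replicates} n_per_scale={pairset.n_per_scale}\n"
        )
        pairset.to_frame().to_csv(fh, sep="\t", index=False)


def read_pairs(path: str | Path) -> PairSet:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for token in line[1:].split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
    frame = pd.read_csv(path, sep="\t", comment="#")
    entries = [
        PairEntry(
            replicate=int(r.replicate),
            scale=Scale.from_label(r.scale),
            isolate_a=str(r.isolate_a),
            isolate_b=str(r.isolate_b),
        )
        for r in frame.itertuples(index=False)
    ]
    seed = meta.get("seed")
    return PairSet(
        entries=entries,
        n_replicates=int(meta.get("n_replicates", frame["replicate"].max())),
        n_per_scale=int(
            meta.get(
                "n_per_scale",
                len(entries) // (frame["replicate"].max() * len(SCALES)),
            )
        ),
        seed=None if seed in (None, "None") else int(seed),
    )
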