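"""Synthetic landscape generator.

Produces complete pipeline inputs — a nested sample sheet, per-locus
alignments, ground-truth sequence-type and clade maps, and noisy
kin-discrimination observations — with the statistical structure the
analysis assumes: mostly-clonal fruiting bodies, sequence-type sharing that
decays with spatial scale, clade clustering across sites, and
kin-discrimination probability that rises with genetic distance.

The colonisation model is a hierarchical "stay-or-escalate" lineage draw
rather than an explicit coalescent.  Lineage pools are materialised top-down
(regional pool -> site -> transect -> core -> fruiting-body founders ->
clones).  Each unit draws every pool member from its parent's pool with
probability 1 - migration, otherwise the draw escalates recursively to the
next level up; every materialised copy accumulates a Poisson number of
substitutions plus, at a fixed rate relative to mutation, homologous
recombination tracts copied from a donor lineage of the same site.  Clade
structure is imposed by seeding deeply divergent founder haplotypes, so
clade labels are exact ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import HierarchicalAddress
from .genotypes import (
    DEFAULT_LOCI,
    LocusAlignmentSet,
    SequenceTypeAssignment,
    assign_sequence_types,
)
from .kd import pair_key
from .pairs import PairSet

__all__ = [
    "LandscapeConfig",
    "EvolutionConfig",
    "KDModelConfig",
    "SimulatedLandscape",
    "simulate_landscape",
    "simulate_kd",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class LandscapeConfig:
    """Shape of the nested design and the colonisation process.

    The default 3x3x3x3x3 grid yields 243 clones, truncated to 147 retained
    isolates to mimic a realistically incomplete field campaign.
    ``founder_clonality`` is the probability that a fruiting body is founded
    by a single lineage; migration probabilities control how often a lineage
    draw escapes its parent unit's pool toward the regional pool.
    """

    n_sites: int = 3
    transects_per_site: int = 3
    cores_per_transect: int = 3
    fruiting_bodies_per_core: int = 3
    clones_per_fruiting_body: int = 3
    founder_clonality: float = 0.82
    mig_site: float = 0.3
    mig_transect: float = 0.5
    mig_core: float = 0.12
    mig_fruiting_body: float = 0.15
    mig_clone: float = 0.01
    site_pool_size: int = 8
    transect_pool_size: int = 2
    core_pool_size: int = 1
    truncate_to: int | None = 147
    locus_names: tuple[str, ...] = DEFAULT_LOCI
    locus_lengths: tuple[int, ...] = (289, 289, 289, 289, 289)

    def __post_init__(self) -> None:
        for name in (
            "n_sites",
            "transects_per_site",
            "cores_per_transect",
            "fruiting_bodies_per_core",
            "clones_per_fruiting_body",
            "site_pool_size",
            "transect_pool_size",
            "core_pool_size",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in (
            "founder_clonality",
            "mig_site",
            "mig_transect",
            "mig_core",
            "mig_fruiting_body",
            "mig_clone",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if len(self.locus_names) != len(self.locus_lengths) or not self.locus_names:
            raise ValueError("locus_names and locus_lengths must be equal-length and non-empty")
        if any(l < 1 for l in self.locus_lengths):
            raise ValueError("locus lengths must be positive")

    @property
    def total_length(self) -> int:
        return int(sum(self.locus_lengths))


@dataclass(frozen=True)
class EvolutionConfig:
    """Sequence evolution along the colonisation hierarchy.

    ``copy_mutation_means`` give the expected substitutions added per
    materialised lineage copy at each level; recombination events occur at
    ``rec_to_mut_ratio`` times the mutation event rate, each replacing a
    tract of geometric length (mean ``tract_length_mean`` nt) with donor
    sequence from the same site.  ``clade_divergence`` substitutions
    separate each clade founder from the common ancestor.
    """

    clade_count: int = 3
    clade_divergence: int = 40
    pool_size_per_clade: int = 10
    pool_diversity_mean: float = 8.0
    mut_site: float = 1.5
    mut_transect: float = 1.0
    mut_core: float = 0.3
    mut_fruiting_body: float = 0.1
    mut_clone: float = 0.02
    rec_to_mut_ratio: float = 0.26
    tract_length_mean: float = 12.0

    def __post_init__(self) -> None:
        if self.clade_count < 1:
            raise ValueError("clade_count must be >= 1")
        if self.tract_length_mean < 1:
            raise ValueError("tract_length_mean must be >= 1 nt")
        for name in (
            "clade_divergence",
            "pool_diversity_mean",
            "mut_site",
            "mut_transect",
            "mut_core",
            "mut_fruiting_body",
            "mut_clone",
            "rec_to_mut_ratio",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class KDModelConfig:
    """Kin-discrimination dose-response and observer noise.

    The probability that a pair at genetic distance d expresses a KD
    phenotype is logistic(intercept + slope * d); with the defaults the
    probability is near zero at d = 0 and saturates within the observed
    range of between-clade distances.  Each of the three observer calls is
    flipped independently with probability ``observer_error`` (default 0.02,
    the rate implied by 3 disagreements in 150 assays).
    """

    intercept: float = -3.5
    slope: float = 350.0
    observer_error: float = 0.02
    n_observers: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.observer_error <= 1.0:
            raise ValueError("observer_error must be a probability")
        if self.n_observers < 1 or self.n_observers % 2 == 0:
            raise ValueError("n_observers must be odd and positive")

    def kd_probability(self, distance: float) -> float:
        return float(1.0 / (1.0 + np.exp(-(self.intercept + self.slope * distance))))


# ---------------------------------------------------------------------------
# Lineages


@dataclass
class _Lineage:
    seq: np.ndarray  # uint8 codes 0..3
    clade: int


def _mutate(seq: np.ndarray, mean: float, rng: np.random.Generator) -> np.ndarray:
    n = rng.poisson(mean)
    if n == 0:
        return seq.copy()
    out = seq.copy()
    pos = rng.integers(0, len(seq), size=n)
    shift = rng.integers(1, 4, size=n)
    out[pos] = (out[pos] + shift) % 4  # always a different base
    return out


def _recombine(
    seq: np.ndarray,
    donors: Sequence[_Lineage],
    mut_mean: float,
    evo: EvolutionConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    if not donors or evo.rec_to_mut_ratio == 0:
        return seq
    n_events = rng.poisson(evo.rec_to_mut_ratio * mut_mean)
    out = seq
    for _ in range(n_events):
        donor = donors[rng.integers(len(donors))]
        length = min(len(seq), 1 + rng.geometric(1.0 / evo.tract_length_mean))
        start = rng.integers(0, len(seq) - length + 1)
        if out is seq:
            out = seq.copy()
        out[start : start + length] = donor.seq[start : start + length]
    return out


def _copy_lineage(
    src: _Lineage,
    mut_mean: float,
    donors: Sequence[_Lineage],
    evo: EvolutionConfig,
    rng: np.random.Generator,
) -> _Lineage:
    seq = _mutate(src.seq, mut_mean, rng)
    seq = _recombine(seq, donors, mut_mean, evo, rng)
    return _Lineage(seq=seq, clade=src.clade)


def _draw(
    pools: Sequence[Sequence[_Lineage]],
    migrations: Sequence[float],
    level: int,
    rng: np.random.Generator,
) -> _Lineage:
    """Stay-or-escalate draw: pick from pools[level] with probability
    1 - migrations[level], else recurse one level up (level 0 = top pool,
    always uniform)."""
    if level == 0 or rng.random() >= migrations[level]:
        pool = pools[level]
        return pool[rng.integers(len(pool))]
    return _draw(pools, migrations, level - 1, rng)


# ---------------------------------------------------------------------------
# Landscape


@dataclass
class SimulatedLandscape:
    """Complete synthetic input bundle plus ground truth."""

    sample_sheet: pd.DataFrame
    concatemers: dict[str, str]
    alignments: LocusAlignmentSet
    true_st: SequenceTypeAssignment
    true_clade: dict[str, int]
    landscape: LandscapeConfig
    evolution: EvolutionConfig
    seed: int | None

    def write(self, out_dir: str | Path) -> dict[str, object]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fasta = self.alignments.to_fasta(out_dir / "loci")
        self.sample_sheet.to_csv(out_dir / "sample_sheet.tsv", sep="\t", index=False)
        self.true_st.to_frame().to_csv(out_dir / "true_st.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"isolate_id": list(self.true_clade), "clade": list(self.true_clade.values())}
        ).to_csv(out_dir / "true_clade.tsv", sep="\t", index=False)
        manifest = {
            "seed": self.seed,
            "landscape": asdict(self.landscape),
            "evolution": asdict(self.evolution),
            "n_isolates": len(self.concatemers),
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        return {"fasta": fasta, "out_dir": out_dir}


def simulate_landscape(
    landscape: LandscapeConfig | None = None,
    evolution: EvolutionConfig | None = None,
    seed: int | None = None,
) -> SimulatedLandscape:
    """Generate a clade-structured, dispersal-limited synthetic landscape.

    Fully deterministic given ``seed``: all randomness flows from one
    generator, so equal seeds give byte-identical outputs.
    """
    lc = landscape or LandscapeConfig()
    evo = evolution or EvolutionConfig()
    rng = np.random.default_rng(seed)
    L = lc.total_length

    ancestor = rng.integers(0, 4, size=L, dtype=np.uint8)
    founders = []
    for clade in range(evo.clade_count):
        seq = _mutate(ancestor, 0.0, rng)
        if evo.clade_divergence:
            pos = rng.choice(L, size=min(evo.clade_divergence, L), replace=False)
            seq[pos] = (seq[pos] + rng.integers(1, 4, size=len(pos))) % 4
        founders.append(_Lineage(seq=seq, clade=clade + 1))

    top_pool: list[_Lineage] = []
    for f in founders:
        for _ in range(evo.pool_size_per_clade):
            top_pool.append(
                _Lineage(seq=_mutate(f.seq, evo.pool_diversity_mean, rng), clade=f.clade)
            )

    rows: list[dict] = []
    seqs: dict[str, np.ndarray] = {}
    clade_of: dict[str, int] = {}

    for s in range(lc.n_sites):
        site = _site_label(s)
        # site-specific clade weighting creates clade clustering across sites
        weights = rng.dirichlet(np.ones(evo.clade_count))
        site_pool: list[_Lineage] = []
        for _ in range(lc.site_pool_size):
            if rng.random() >= lc.mig_site:
                clade = 1 + rng.choice(evo.clade_count, p=weights)
                candidates = [l for l in top_pool if l.clade == clade]
            else:
                candidates = top_pool
            src = candidates[rng.integers(len(candidates))]
            site_pool.append(_copy_lineage(src, evo.mut_site, site_pool, evo, rng))
        for t in range(1, lc.transects_per_site + 1):
            transect_pool = [
                _copy_lineage(
                    _draw([top_pool, site_pool], [0.0, lc.mig_transect], 1, rng),
                    evo.mut_transect,
                    site_pool,
                    evo,
                    rng,
                )
                for _ in range(lc.transect_pool_size)
            ]
            for c in range(1, lc.cores_per_transect + 1):
                pools3 = [top_pool, site_pool, transect_pool]
                core_pool = [
                    _copy_lineage(
                        _draw(pools3, [0.0, lc.mig_site, lc.mig_core], 2, rng),
                        evo.mut_core,
                        site_pool,
                        evo,
                        rng,
                    )
                    for _ in range(lc.core_pool_size)
                ]
                for f in range(1, lc.fruiting_bodies_per_core + 1):
                    pools4 = [top_pool, site_pool, transect_pool, core_pool]
                    migs4 = [0.0, lc.mig_site, lc.mig_transect, lc.mig_fruiting_body]
                    n_founders = 1 if rng.random() < lc.founder_clonality else 2
                    fb_pool = [
                        _copy_lineage(
                            _draw(pools4, migs4, 3, rng),
                            evo.mut_fruiting_body,
                            site_pool,
                            evo,
                            rng,
                        )
                    ]
                    if n_founders == 2:
                        # second founder forced distinct where possible
                        for _ in range(20):
                            cand = _copy_lineage(
                                _draw(pools4, [0.0, lc.mig_site, lc.mig_transect, 0.6], 3, rng),
                                evo.mut_fruiting_body,
                                site_pool,
                                evo,
                                rng,
                            )
                            if not np.array_equal(cand.seq, fb_pool[0].seq):
                                break
                        fb_pool.append(cand)
                    pools5 = pools4 + [fb_pool]
                    migs5 = migs4 + [lc.mig_clone]
                    for k in range(lc.clones_per_fruiting_body):
                        clone = chr(ord("A") + k)
                        src = _draw(pools5, migs5, 4, rng)
                        lin = _copy_lineage(src, evo.mut_clone, site_pool, evo, rng)
                        isolate = str(
                            HierarchicalAddress(site, t, c, f, clone)
                        )
                        rows.append(
                            {
                                "isolate_id": isolate,
                                "site": site,
                                "transect": t,
                                "core": c,
                                "fruiting_body": f,
                                "clone": clone,
                            }
                        )
                        seqs[isolate] = lin.seq
                        clade_of[isolate] = lin.clade

    sheet = pd.DataFrame(rows)
    if lc.truncate_to is not None and lc.truncate_to < len(sheet):
        keep = _truncate(sheet, lc.truncate_to, rng)
        sheet = sheet[sheet["isolate_id"].isin(keep)].reset_index(drop=True)
        seqs = {i: seqs[i] for i in sheet["isolate_id"]}
        clade_of = {i: clade_of[i] for i in sheet["isolate_id"]}

    concatemers = {i: _decode(s) for i, s in seqs.items()}
    alignments = _split_loci(concatemers, lc)
    return SimulatedLandscape(
        sample_sheet=sheet,
        concatemers=concatemers,
        alignments=alignments,
        true_st=assign_sequence_types(concatemers),
        true_clade=clade_of,
        landscape=lc,
        evolution=evo,
        seed=seed,
    )


def _site_label(index: int) -> str:
    # AA-free short labels: S1 -> "SA", "SB", ... keeps sites free-form
    letters = ""
    index += 1
    while index:
        index, r = divmod(index - 1, 26)
        letters = chr(ord("A") + r) + letters
    return "S" + letters


def _truncate(sheet: pd.DataFrame, target: int, rng: np.random.Generator) -> set[str]:
    """Randomly drop clones (never emptying a fruiting body) down to
    ``target`` isolates, mimicking incomplete field recovery."""
    keep = set(sheet["isolate_id"])
    fb_of = {
        r.isolate_id: (r.site, r.transect, r.core, r.fruiting_body)
        for r in sheet.itertuples(index=False)
    }
    while len(keep) > target:
        counts: dict[tuple, int] = {}
        for i in keep:
            counts[fb_of[i]] = counts.get(fb_of[i], 0) + 1
        droppable = sorted(i for i in keep if counts[fb_of[i]] >= 2)
        if not droppable:
            break
        keep.discard(droppable[rng.integers(len(droppable))])
    return keep


def _decode(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode("ascii")


def _split_loci(concatemers: Mapping[str, str], lc: LandscapeConfig) -> LocusAlignmentSet:
    bounds = np.cumsum((0,) + tuple(lc.locus_lengths))
    alignments = {
        locus: {
            iso: seq[bounds[k] : bounds[k + 1]] for iso, seq in concatemers.items()
        }
        for k, locus in enumerate(lc.locus_names)
    }
    return LocusAlignmentSet(loci=lc.locus_names, alignments=alignments)


# ---------------------------------------------------------------------------
# KD phenotype simulation


def simulate_kd(
    pairs: PairSet,
    distances: pd.DataFrame | Mapping[tuple[str, str], float],
    kd: KDModelConfig | None = None,
    seed: int | None = None,
    n_controls_per_replicate: int = 5,
) -> pd.DataFrame:
    """Simulate observer-scored KD assays for every pair in a pair set.

    The true phenotype is Bernoulli with logistic-in-distance probability;
    each observer call is then flipped independently with probability
    ``observer_error``.  Self-self control plates (true phenotype 0, scored
    without flips, since observers define alteration relative to these very
    interfaces) are appended per replicate.  Returns a KD table with
    ``obs1..obsK`` plus a ``true_kd`` ground-truth column.
    """
    kd = kd or KDModelConfig()
    rng = np.random.default_rng(seed)

    def dist(a: str, b: str) -> float:
        if isinstance(distances, pd.DataFrame):
            return float(distances.loc[a, b])
        return float(distances[pair_key(a, b)])

    rows = []
    for e in pairs.entries:
        d = dist(e.isolate_a, e.isolate_b)
        true = int(rng.random() < kd.kd_probability(d))
        obs = [
            true ^ int(rng.random() < kd.observer_error) for _ in range(kd.n_observers)
        ]
        row = {
            "isolate_a": e.isolate_a,
            "isolate_b": e.isolate_b,
            "replicate": e.replicate,
            "scale": e.scale.label,
            "true_kd": true,
        }
        row.update({f"obs{i + 1}": o for i, o in enumerate(obs)})
        rows.append(row)
    if n_controls_per_replicate:
        isolates = sorted(pairs.isolates)
        for rep in range(1, pairs.n_replicates + 1):
            chosen = rng.choice(len(isolates), size=min(n_controls_per_replicate, len(isolates)), replace=False)
            for k in chosen:
                row = {
                    "isolate_a": isolates[k],
                    "isolate_b": isolates[k],
                    "replicate": rep,
                    "scale": "control",
                    "true_kd": 0,
                }
                row.update({f"obs{i + 1}": 0 for i in range(kd.n_observers)})
                rows.append(row)
    return pd.DataFrame(rows)
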