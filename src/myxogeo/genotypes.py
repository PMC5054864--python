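"""Multilocus genotypes: concatemers, sequence types, nucleotide diversity
and pairwise genetic distances.

Each isolate is genotyped at five highly variable chromosomal loci; the
per-locus alignments are concatenated in a fixed locus order into a single
concatemer (gaps included).  Isolates sharing an identical concatemer string
belong to the same sequence type (ST) and are treated as genetically
identical.  Nucleotide diversity (pi) is the mean proportion of differing
sites over all unordered sequence pairs; sites with a gap or ambiguous base
in either member of a pair are excluded from that pair's comparison by
default (pairwise deletion).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import addresses_from_sheet

__all__ = [
    "DEFAULT_LOCI",
    "LocusAlignmentSet",
    "SequenceTypeAssignment",
    "NucleotideDiversity",
    "concatenate_loci",
    "assign_sequence_types",
    "nucleotide_diversity",
    "pairwise_distance",
    "distance_matrix",
    "diversity_table",
]

#: Fixed concatenation order of the five marker loci.
DEFAULT_LOCI: tuple[str, ...] = (
    "Mxan_0128",
    "Mxan_0533",
    "Mxan_1277",
    "Mxan_4405",
    "Mxan_5783",
)

_VALID_BASES = np.frombuffer(b"ACGT", dtype="S1")
_PURINES = np.frombuffer(b"AG", dtype="S1")


class AlignmentError(ValueError):
    """Raised for ragged alignments or isolates missing a locus."""


@dataclass
class LocusAlignmentSet:
    """Per-locus aligned sequences for a common set of isolates.

    ``alignments[locus][isolate_id]`` is the aligned nucleotide string
    (characters A/C/G/T/N/-).  Within a locus all strings share one length;
    every retained isolate is present at every locus.  Isolates missing any
    locus are dropped on construction via :meth:`from_fasta` and recorded in
    ``excluded``.
    """

    loci: tuple[str, ...]
    alignments: dict[str, dict[str, str]]
    excluded: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.loci = tuple(self.loci)
        if not self.loci:
            raise AlignmentError("no loci")
        isolates = None
        for locus in self.loci:
            if locus not in self.alignments:
                raise AlignmentError(f"no alignment supplied for locus {locus}")
            aln = self.alignments[locus]
            if not aln:
                raise AlignmentError(f"locus {locus}: empty alignment")
            lengths = {len(s) for s in aln.values()}
            if len(lengths) != 1:
                raise AlignmentError(f"locus {locus}: ragged alignment, lengths {sorted(lengths)}")
            ids = set(aln)
            if isolates is None:
                isolates = ids
            elif ids != isolates:
                missing = sorted((isolates | ids) - (isolates & ids))
                raise AlignmentError(
                    f"isolate set differs at locus {locus}; symmetric difference: {missing}"
                )

    @property
    def isolates(self) -> list[str]:
        # Order follows the first locus' insertion order.
        return list(self.alignments[self.loci[0]])

    def locus_length(self, locus: str) -> int:
        return len(next(iter(self.alignments[locus].values())))

    @property
    def total_length(self) -> int:
        return sum(self.locus_length(l) for l in self.loci)

    @classmethod
    def from_fasta(
        cls, paths: Mapping[str, str | Path], loci: Sequence[str] | None = None
    ) -> "LocusAlignmentSet":
        """Load one FASTA file per locus (record IDs are isolate IDs).

        Isolates absent from any locus are excluded from the set, mirroring
        the rule that clones lacking a sequence at any locus are dropped
        before analysis.
        """
        loci = tuple(loci) if loci is not None else tuple(paths)
        per_locus: dict[str, dict[str, str]] = {}
        for locus in loci:
            records: dict[str, str] = {}
            for rec in SeqIO.parse(str(paths[locus]), "fasta"):
                if rec.id in records:
                    raise AlignmentError(f"locus {locus}: duplicate record {rec.id}")
                records[rec.id] = str(rec.seq).upper()
            per_locus[locus] = records
        common = set.intersection(*(set(per_locus[l]) for l in loci))
        excluded = sorted(set.union(*(set(per_locus[l]) for l in loci)) - common)
        kept = {
            locus: {i: s for i, s in per_locus[locus].items() if i in common} for locus in loci
        }
        return cls(loci=loci, alignments=kept, excluded=tuple(excluded))

    def to_fasta(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        out = {}
        for locus in self.loci:
            path = directory / f"{locus}.fasta"
            recs = [
                SeqRecord(Seq(s), id=i, description="")
                for i, s in self.alignments[locus].items()
            ]
            SeqIO.write(recs, str(path), "fasta")
            out[locus] = path
        return out


def concatenate_loci(aligned: LocusAlignmentSet) -> dict[str, str]:
    """Concatenate per-locus alignments in fixed locus order.

    Returns an ordered mapping isolate_id -> concatemer string; gaps are
    preserved, so all concatemers share length ``aligned.total_length``.
    """
    out: dict[str, str] = {}
    for isolate in aligned.isolates:
        parts = []
        for locus in aligned.loci:
            try:
                parts.append(aligned.alignments[locus][isolate])
            except KeyError:
                raise AlignmentError(f"isolate {isolate} missing at locus {locus}") from None
        out[isolate] = "".join(parts)
    return out


@dataclass(frozen=True)
class SequenceTypeAssignment:
    """Partition of isolates into sequence types by exact concatemer identity.

    Labels are positive integers assigned in order of first occurrence in the
    input; gap and ambiguity characters are compared literally.
    """

    st_of: dict[str, int]
    n_types: int

    def members(self, st: int) -> list[str]:
        return [i for i, s in self.st_of.items() if s == st]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"isolate_id": list(self.st_of), "st": list(self.st_of.values())}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SequenceTypeAssignment":
        st_of = dict(zip(frame["isolate_id"].astype(str), frame["st"].astype(int)))
        return cls(st_of=st_of, n_types=len(set(st_of.values())))


def assign_sequence_types(concatemers: Mapping[str, str]) -> SequenceTypeAssignment:
    """Group isolates by exact string identity of their concatemers."""
    if not concatemers:
        raise ValueError("no concatemers supplied")
    lengths = {len(s) for s in concatemers.values()}
    if len(lengths) != 1:
        raise AlignmentError(f"concatemers of unequal length: {sorted(lengths)}")
    labels: dict[str, int] = {}
    st_of: dict[str, int] = {}
    for isolate, seq in concatemers.items():
        if seq not in labels:
            labels[seq] = len(labels) + 1
        st_of[isolate] = labels[seq]
    return SequenceTypeAssignment(st_of=st_of, n_types=len(labels))


# ---------------------------------------------------------------------------
# Distances and diversity


def _encode(seqs: Sequence[str]) -> np.ndarray:
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype="S1")
    return arr.reshape(len(seqs), -1)


def _pair_site_counts(
    a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None
) -> tuple[int, int, int, int]:
    """(comparable sites, mismatches, transitions, transversions) for a pair.

    A site is comparable when both bases are unambiguous A/C/G/T (and, with
    complete deletion, when the site survives the global mask)."""
    valid = np.isin(a, _VALID_BASES) & np.isin(b, _VALID_BASES)
    if mask is not None:
        valid &= mask
    comp = int(valid.sum())
    diff = (a != b) & valid
    mism = int(diff.sum())
    ap = np.isin(a, _PURINES)
    bp = np.isin(b, _PURINES)
    ts = int((diff & (ap == bp)).sum())  # same chemical class => transition
    return comp, mism, ts, mism - ts


def _complete_deletion_mask(arr: np.ndarray) -> np.ndarray:
    return np.isin(arr, _VALID_BASES).all(axis=0)


@dataclass(frozen=True)
class NucleotideDiversity:
    """Average pairwise proportion of differing sites (dimensionless)."""

    pi: float
    n: int
    site_handling: str
    mean_sites_compared: float


def nucleotide_diversity(
    sequences: Mapping[str, str] | Sequence[str], site_handling: str = "pairwise"
) -> NucleotideDiversity:
    """Nucleotide diversity pi over all unordered pairs of sequences.

    ``site_handling`` is ``"pairwise"`` (default; per-pair exclusion of
    gap/ambiguous sites) or ``"complete"`` (drop any site that is gapped or
    ambiguous in any sequence).  Requires at least two equal-length
    sequences; a pair with zero comparable sites is an error.
    """
    if isinstance(sequences, Mapping):
        names = list(sequences)
        seqs = [sequences[k] for k in names]
    else:
        seqs = list(sequences)
        names = [str(i) for i in range(len(seqs))]
    if len(seqs) < 2:
        raise ValueError(f"need at least 2 sequences, got {len(seqs)}")
    if len({len(s) for s in seqs}) != 1:
        raise AlignmentError("sequences of unequal length")
    if site_handling not in ("pairwise", "complete"):
        raise ValueError(f"unknown site_handling: {site_handling!r}")
    arr = _encode([s.upper() for s in seqs])
    mask = _complete_deletion_mask(arr) if site_handling == "complete" else None
    props, comps = [], []
    for i, j in itertools.combinations(range(len(seqs)), 2):
        comp, mism, _, _ = _pair_site_counts(arr[i], arr[j], mask)
        if comp == 0:
            raise ValueError(
                f"pair ({names[i]}, {names[j]}) has zero comparable sites"
            )
        props.append(mism / comp)
        comps.append(comp)
    return NucleotideDiversity(
        pi=float(np.mean(props)),
        n=len(seqs),
        site_handling=site_handling,
        mean_sites_compared=float(np.mean(comps)),
    )


class SaturationError(ValueError):
    """Raised when a distance transform is undefined for the observed p."""


def _transform(p: float, ts: float, tv: float, model: str, saturation: str) -> float:
    if model == "p":
        return p
    if model == "jc69":
        arg = 1.0 - 4.0 * p / 3.0
        if arg <= 0:
            if saturation == "inf":
                return math.inf
            raise SaturationError(f"JC69 undefined at p={p:.4f} (>= 0.75)")
        return -0.75 * math.log(arg)
    if model == "k2p":
        a1 = 1.0 - 2.0 * ts - tv
        a2 = 1.0 - 2.0 * tv
        if a1 <= 0 or a2 <= 0:
            if saturation == "inf":
                return math.inf
            raise SaturationError(f"K2P undefined at P={ts:.4f}, Q={tv:.4f}")
        return -0.5 * math.log(a1) - 0.25 * math.log(a2)
    raise ValueError(f"unknown model: {model!r} (expected p, jc69 or k2p)")


def pairwise_distance(
    a: str,
    b: str,
    model: str = "p",
    site_handling: str = "pairwise",
    saturation: str = "error",
) -> float:
    """Pairwise genetic distance between two aligned sequences.

    Models: ``p`` (mismatch proportion over comparable sites, the default),
    ``jc69`` (d = -(3/4) ln(1 - 4p/3)) and ``k2p`` (two-parameter correction
    from transition/transversion proportions).  ``saturation`` selects the
    policy for log-of-nonpositive arguments: ``"error"`` or ``"inf"``.
    """
    if len(a) != len(b):
        raise AlignmentError("sequences of unequal length")
    arr = _encode([a.upper(), b.upper()])
    mask = _complete_deletion_mask(arr) if site_handling == "complete" else None
    comp, mism, ts, tv = _pair_site_counts(arr[0], arr[1], mask)
    if comp == 0:
        raise ValueError("pair has zero comparable sites")
    return _transform(mism / comp, ts / comp, tv / comp, model, saturation)


def distance_matrix(
    concatemers: Mapping[str, str],
    model: str = "p",
    site_handling: str = "pairwise",
    saturation: str = "error",
) -> pd.DataFrame:
    """Symmetric zero-diagonal matrix of pairwise distances (DataFrame
    indexed by isolate ID).  Metadata (model, site handling) is stored in
    ``DataFrame.attrs``."""
    names = list(concatemers)
    seqs = [concatemers[k].upper() for k in names]
    if len({len(s) for s in seqs}) != 1:
        raise AlignmentError("concatemers of unequal length")
    arr = _encode(seqs)
    mask = _complete_deletion_mask(arr) if site_handling == "complete" else None
    n = len(names)
    d = np.zeros((n, n))
    valid = np.isin(arr, _VALID_BASES)
    if mask is not None:
        valid = valid & mask
    purine = np.isin(arr, _PURINES)
    for i in range(n):
        vi = valid[i]
        for j in range(i + 1, n):
            v = vi & valid[j]
            comp = int(v.sum())
            if comp == 0:
                raise ValueError(f"pair ({names[i]}, {names[j]}) has zero comparable sites")
            diff = (arr[i] != arr[j]) & v
            mism = int(diff.sum())
            ts = int((diff & (purine[i] == purine[j])).sum())
            d[i, j] = d[j, i] = _transform(
                mism / comp, ts / comp, (mism - ts) / comp, model, saturation
            )
    out = pd.DataFrame(d, index=names, columns=names)
    out.attrs["model"] = model
    out.attrs["site_handling"] = site_handling
    return out


# ---------------------------------------------------------------------------
# Grouped diversity table


def diversity_table(
    sample_sheet: pd.DataFrame,
    concatemers: Mapping[str, str],
    assignment: SequenceTypeAssignment | None = None,
    site_handling: str = "pairwise",
) -> pd.DataFrame:
    """Sample size, ST count and pi for every nested grouping level.

    One row per group at each level: overall, site, transect, core and
    fruiting body (the scale probed within a group is one level finer than
    the group itself).  Groups with fewer than two members report pi as NA.
    """
    assignment = assignment or assign_sequence_types(concatemers)
    addrs = addresses_from_sheet(sample_sheet)
    missing = [i for i in addrs if i not in concatemers]
    if missing:
        raise ValueError(f"isolates without genotypes: {missing}")

    levels: list[tuple[str, str, object]] = [("overall", "kilometre", lambda a: "all")]
    levels += [
        ("site", "metre", lambda a: a.site_label),
        ("transect", "centimetre", lambda a: a.transect_label),
        ("core", "millimetre", lambda a: a.core_label),
        ("fruiting_body", "micrometre", lambda a: a.fruiting_body_label),
    ]
    rows = []
    for level, probed, keyfn in levels:
        groups: dict[str, list[str]] = {}
        for isolate, addr in addrs.items():
            groups.setdefault(keyfn(addr), []).append(isolate)
        for group in sorted(groups):
            members = groups[group]
            sts = {assignment.st_of[i] for i in members}
            if len(members) >= 2:
                pi = nucleotide_diversity(
                    {i: concatemers[i] for i in members}, site_handling
                ).pi
            else:
                pi = float("nan")
            rows.append(
                {
                    "level": level,
                    "scale_probed": probed,
                    "group": group,
                    "n": len(members),
                    "n_st": len(sts),
                    "pi": pi,
                }
            )
    return pd.DataFrame(rows)
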