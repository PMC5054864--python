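"""Population-structure statistics across the nested landscape.

Implements the isolation-by-distance Mantel permutation test,
mean-genetic-distance-by-scale curves with least-squares fits, exact
binomial tests of clade distribution across km-scale sites, the
nearest-sequence-type co-site concordance test, and within- vs among-site
Wilcoxon rank-sum comparisons on quasi-randomly resampled distances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import (
    SCALES,
    Scale,
    ScaleGeometry,
    addresses_from_sheet,
    pair_scale,
    scale_distance,
)
from .genotypes import SequenceTypeAssignment

__all__ = [
    "MantelResult",
    "mantel_test",
    "geographic_distance_matrix",
    "ScaleDistanceCurve",
    "scale_distance_curve",
    "clade_absence_test",
    "clade_frequency_test",
    "NearestSTResult",
    "nearest_st_concordance",
    "within_vs_among_site_test",
    "st_site_map",
    "st_clade_map",
]


# ---------------------------------------------------------------------------
# Mantel test


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_permutations: int
    method: str


def _as_square(m) -> np.ndarray:
    a = m.to_numpy(dtype=float) if isinstance(m, pd.DataFrame) else np.asarray(m, float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"distance matrix must be square, got shape {a.shape}")
    if not np.allclose(a, a.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(a), 0):
        raise ValueError("distance matrix must have a zero diagonal")
    return a


def mantel_test(
    geo,
    gen,
    n_perm: int | str = 9999,
    seed: int | None = None,
    method: str = "permutation",
) -> MantelResult:
    """Mantel matrix-correlation test of isolation by distance.

    r is the Pearson correlation of the upper-triangle entries; the null
    distribution is generated by simultaneous row/column permutation of one
    matrix.  The two-sided p-value uses the add-one estimator
    (count of |r_perm| >= |r_obs|, + 1) / (n_perm + 1).  ``n_perm="exact"``
    enumerates all n! permutations (n <= 8) and reports the exact tail
    fraction.  ``method="parametric"`` instead reports the two-sided t-test
    p-value of the upper-triangle Pearson correlation (for comparison only;
    pair distances are not independent).
    """
    a = _as_square(geo)
    b = _as_square(gen)
    if a.shape != b.shape:
        raise ValueError(f"matrix sizes differ: {a.shape} vs {b.shape}")
    n = a.shape[0]
    iu = np.triu_indices(n, 1)
    x = a[iu]
    y = b[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")

    yz = (y - y.mean()) / y.std()

    def corr(v: np.ndarray) -> float:
        return float(((v - v.mean()) / v.std() * yz).mean())

    r_obs = corr(x)
    if method == "parametric":
        _, p = stats.pearsonr(x, y)
        return MantelResult(r=r_obs, p=float(p), n_permutations=0, method="parametric")
    if method != "permutation":
        raise ValueError(f"unknown method: {method!r}")

    if n_perm == "exact":
        if n > 8:
            raise ValueError("exact enumeration supported only for n <= 8")
        count = total = 0
        for perm in itertools.permutations(range(n)):
            idx = np.array(perm)
            rp = corr(a[np.ix_(idx, idx)][iu])
            if abs(rp) >= abs(r_obs) - 1e-12:
                count += 1
            total += 1
        return MantelResult(r=r_obs, p=count / total, n_permutations=total, method="exact")

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(int(n_perm)):
        idx = rng.permutation(n)
        rp = corr(a[np.ix_(idx, idx)][iu])
        if abs(rp) >= abs(r_obs) - 1e-12:
            count += 1
    p = (count + 1) / (int(n_perm) + 1)
    return MantelResult(r=r_obs, p=p, n_permutations=int(n_perm), method="permutation")


def geographic_distance_matrix(
    sample_sheet: pd.DataFrame, geometry: ScaleGeometry | None = None
) -> pd.DataFrame:
    """Pairwise representative geographic distances from the nested design."""
    geometry = geometry or ScaleGeometry()
    addrs = addresses_from_sheet(sample_sheet)
    ids = list(addrs)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = scale_distance(pair_scale(addrs[ids[i]], addrs[ids[j]]), geometry)
    return pd.DataFrame(d, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Mean distance by scale


@dataclass
class ScaleDistanceCurve:
    """Mean pairwise genetic distance per scale, with a polynomial fit in
    log10 representative distance.  ``scope`` is "overall" or a clade label;
    scales with no qualifying pair are listed in ``omitted``."""

    scope: str
    means: dict[Scale, float]
    n_pairs: dict[Scale, int]
    fit_order: int
    fit_coefficients: np.ndarray
    omitted: tuple[Scale, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scale": [s.label for s in SCALES],
                "scope": self.scope,
                "mean_distance": [self.means.get(s, math.nan) for s in SCALES],
                "n_pairs": [self.n_pairs.get(s, 0) for s in SCALES],
            }
        )


def scale_distance_curve(
    distances: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    scope: str = "overall",
    clades: Mapping[str, object] | None = None,
    fit_order: int = 2,
    geometry: ScaleGeometry | None = None,
) -> ScaleDistanceCurve:
    """Mean pairwise genetic distance at each scale over ALL qualifying
    pairs (the exhaustive set, not the independent subsample).

    With a clade ``scope``, both members of a pair must carry that clade
    label.  The least-squares polynomial fit (order 1 or 2) is computed
    against log10 of the representative scale distances.
    """
    geometry = geometry or ScaleGeometry()
    addrs = addresses_from_sheet(sample_sheet)
    if scope != "overall":
        if clades is None:
            raise ValueError("clade scope requires a clade assignment")
        ids = [i for i in addrs if i in distances.index and str(clades.get(i)) == str(scope)]
    else:
        ids = [i for i in addrs if i in distances.index]
    if len(ids) < 2:
        raise ValueError(f"fewer than 2 isolates in scope {scope!r}")
    dsub = distances.loc[ids, ids].to_numpy()
    sums: dict[Scale, float] = {s: 0.0 for s in SCALES}
    counts: dict[Scale, int] = {s: 0 for s in SCALES}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            sc = pair_scale(addrs[ids[i]], addrs[ids[j]])
            sums[sc] += dsub[i, j]
            counts[sc] += 1
    means = {s: sums[s] / counts[s] for s in SCALES if counts[s] > 0}
    omitted = tuple(s for s in SCALES if counts[s] == 0)
    if fit_order not in (1, 2):
        raise ValueError("fit_order must be 1 or 2")
    xs = np.array([math.log10(scale_distance(s, geometry)) for s in means])
    ys = np.array([means[s] for s in means])
    if len(xs) >= fit_order + 1:
        coeff = np.polyfit(xs, ys, fit_order)
    else:
        coeff = np.full(fit_order + 1, math.nan)
    return ScaleDistanceCurve(
        scope=str(scope),
        means=means,
        n_pairs={s: counts[s] for s in SCALES},
        fit_order=fit_order,
        fit_coefficients=coeff,
        omitted=omitted,
    )


# ---------------------------------------------------------------------------
# Clade distribution binomial tests


def _clade_site_counts(
    clades: Mapping[str, object], sample_sheet: pd.DataFrame
) -> pd.DataFrame:
    addrs = addresses_from_sheet(sample_sheet)
    rows = []
    for isolate, addr in addrs.items():
        if isolate not in clades:
            raise ValueError(f"isolate {isolate} has no clade label")
        rows.append({"isolate_id": isolate, "site": addr.site, "clade": str(clades[isolate])})
    return pd.DataFrame(rows)


def clade_absence_test(
    clades: Mapping[str, object],
    sample_sheet: pd.DataFrame,
    clade: object,
    site: str,
) -> float:
    """Exact binomial probability of seeing at most the observed count of a
    clade at a focal site, at the clade's pooled frequency across all sites.

    For a clade absent from the site this is (1 - f)^n.
    """
    table = _clade_site_counts(clades, sample_sheet)
    f = float((table["clade"] == str(clade)).mean())
    if f == 0:
        raise ValueError(f"clade {clade!r} absent from the pooled sample: test undefined")
    at_site = table[table["site"] == site]
    if at_site.empty:
        raise ValueError(f"no isolates at site {site!r}")
    n = len(at_site)
    k = int((at_site["clade"] == str(clade)).sum())
    return float(stats.binom.cdf(k, n, f))


def clade_frequency_test(
    clades: Mapping[str, object],
    sample_sheet: pd.DataFrame,
    site: str,
    clade_pair: tuple[object, object],
) -> float:
    """Two-sided exact binomial test of a site's two-clade split against the
    pooled two-clade proportion across all sites."""
    c1, c2 = (str(c) for c in clade_pair)
    table = _clade_site_counts(clades, sample_sheet)
    pooled = table[table["clade"].isin([c1, c2])]
    if pooled.empty:
        raise ValueError(f"no isolates in clades {clade_pair}")
    p1 = float((pooled["clade"] == c1).mean())
    at_site = pooled[pooled["site"] == site]
    if at_site.empty:
        raise ValueError(f"site {site!r} has no members of clades {clade_pair}")
    k = int((at_site["clade"] == c1).sum())
    n = len(at_site)
    return float(stats.binomtest(k, n, p1, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# Nearest-ST co-site concordance


def st_site_map(
    assignment: SequenceTypeAssignment, sample_sheet: pd.DataFrame
) -> dict[int, frozenset[str]]:
    """Map each sequence type to the set of km-scale sites where it occurs."""
    addrs = addresses_from_sheet(sample_sheet)
    out: dict[int, set[str]] = {}
    for isolate, st in assignment.st_of.items():
        out.setdefault(st, set()).add(addrs[isolate].site)
    return {st: frozenset(sites) for st, sites in out.items()}


def st_clade_map(
    assignment: SequenceTypeAssignment, clades: Mapping[str, object]
) -> dict[int, str]:
    """Map each sequence type to its (necessarily unique) clade label."""
    out: dict[int, set[str]] = {}
    for isolate, st in assignment.st_of.items():
        out.setdefault(st, set()).add(str(clades[isolate]))
    conflicted = {st: lab for st, lab in out.items() if len(lab) > 1}
    if conflicted:
        raise ValueError(f"sequence types with conflicting clade labels: {conflicted}")
    return {st: next(iter(lab)) for st, lab in out.items()}


@dataclass(frozen=True)
class NearestSTResult:
    observed_fraction: float
    expected_fraction: float
    p_binomial: float
    p_permutation: float | None
    n_st: int
    pairings: tuple[tuple[object, object], ...]


def _nearest_partners(
    dist: pd.DataFrame, rng: np.random.Generator
) -> list[tuple[object, object]]:
    out = []
    for st in dist.index:
        row = dist.loc[st].drop(index=st)
        m = row.min()
        nearest = [o for o in row.index if row[o] <= m + 1e-15]
        partner = nearest[rng.integers(len(nearest))] if len(nearest) > 1 else nearest[0]
        out.append((st, partner))
    return out


def nearest_st_concordance(
    st_distance: pd.DataFrame,
    st_sites: Mapping[object, frozenset[str] | set[str]],
    seed: int | None = None,
    alternative: str = "greater",
    n_perm: int | None = 9999,
) -> NearestSTResult:
    """Do phylogenetically nearest sequence types co-occur at a km-site more
    often than expected without spatial structure?

    Each ST is paired with its nearest distinct ST by genetic distance (ties
    broken uniformly at random under ``seed``); a pairing is concordant when
    the two STs share a site.  The no-structure expectation is the fraction
    of all unordered distinct ST pairs that share a site, tested by an exact
    binomial test.  A label-permutation alternative (shuffling the ST-site
    assignment) is also reported when ``n_perm`` is set.
    """
    sts = list(st_distance.index)
    if len(sts) < 2:
        raise ValueError("need at least two sequence types")
    missing = [st for st in sts if st not in st_sites]
    if missing:
        raise ValueError(f"sequence types without site information: {missing}")
    rng = np.random.default_rng(seed)
    pairings = _nearest_partners(st_distance, rng)

    def concordant(sites: Mapping) -> int:
        return sum(1 for a, b in pairings if set(sites[a]) & set(sites[b]))

    obs_k = concordant(st_sites)
    n = len(sts)
    all_pairs = list(itertools.combinations(sts, 2))
    expected = float(
        np.mean([bool(set(st_sites[a]) & set(st_sites[b])) for a, b in all_pairs])
    )
    if expected in (0.0, 1.0):
        p_binom = 1.0 if obs_k == round(expected * n) else 0.0
    else:
        p_binom = float(stats.binomtest(obs_k, n, expected, alternative=alternative).pvalue)

    p_perm = None
    if n_perm:
        site_lists = [st_sites[st] for st in sts]
        count = 0
        for _ in range(n_perm):
            idx = rng.permutation(n)
            shuffled = {st: site_lists[idx[i]] for i, st in enumerate(sts)}
            if concordant(shuffled) >= obs_k:
                count += 1
        p_perm = (count + 1) / (n_perm + 1)
    return NearestSTResult(
        observed_fraction=obs_k / n,
        expected_fraction=expected,
        p_binomial=p_binom,
        p_permutation=p_perm,
        n_st=n,
        pairings=tuple(pairings),
    )


# ---------------------------------------------------------------------------
# Within- vs among-site distances


def within_vs_among_site_test(
    st_distance: pd.DataFrame,
    st_sites: Mapping[object, frozenset[str] | set[str]],
    st_clades: Mapping[object, object],
    clade: object,
    n_draws: int,
    seed: int | None = None,
) -> dict:
    """Wilcoxon rank-sum comparison of within- vs among-site genetic
    distances among sequence types of one clade.

    Draws ``n_draws`` distinct within-site ST-pair distances and ``n_draws``
    distinct among-site ST-pair distances (no ST pair reused; quasi-random
    under ``seed``) and applies a two-sided rank-sum test (exact null for
    small samples without ties, normal approximation with tie correction
    otherwise, via `scipy.stats.mannwhitneyu`).
    """
    members = [st for st in st_distance.index if str(st_clades.get(st)) == str(clade)]
    if len(members) < 2:
        raise ValueError(f"clade {clade!r} has fewer than two sequence types")
    sites_of = {st: set(st_sites[st]) for st in members}
    if len(set().union(*sites_of.values())) < 2:
        raise ValueError(f"clade {clade!r} present at fewer than two sites")
    within, among = [], []
    for a, b in itertools.combinations(members, 2):
        (within if sites_of[a] & sites_of[b] else among).append((a, b))
    if len(within) < n_draws or len(among) < n_draws:
        raise ValueError(
            f"insufficient distinct ST pairs for {n_draws} draws: "
            f"{len(within)} within-site, {len(among)} among-site available"
        )
    rng = np.random.default_rng(seed)
    wi = [within[k] for k in rng.choice(len(within), n_draws, replace=False)]
    am = [among[k] for k in rng.choice(len(among), n_draws, replace=False)]
    x = np.array([st_distance.loc[a, b] for a, b in wi])
    y = np.array([st_distance.loc[a, b] for a, b in am])
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return {
        "clade": str(clade),
        "n_draws": n_draws,
        "within_mean": float(x.mean()),
        "among_mean": float(y.mean()),
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
    }
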