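"""Identity-decay curves: per-scale probabilities of genetic and social
identity, their comparison across scales, and the correlation between the
genetic and social decay curves.

A pair is genetically identical when both members share a sequence type and
socially identical when the pair shows no kin-discrimination phenotype.
The unit of analysis is the replicate-level proportion (k pairs per scale
per replicate from the independent pair sampler), compared across scales by
one-way ANOVA with post hoc Tukey HSD on the studentized-range
distribution.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .design import SCALES, Scale
from .genotypes import SequenceTypeAssignment
from .kd import pair_key
from .pairs import PairSet

__all__ = [
    "IdentityCurve",
    "ScaleComparison",
    "genetic_identity_curve",
    "social_identity_curve",
    "identity_curve_from_labels",
    "anova_tukey",
    "curve_correlation",
    "tukey_hsd",
]


@dataclass
class IdentityCurve:
    """Per-scale identity probabilities with replicate breakdown.

    ``replicate_props[scale]`` holds the R per-replicate proportions (each
    over ``n_per_scale`` pairs); ``pooled`` is total identical pairs / total
    pairs at the scale, which equals the mean of replicate proportions for
    equal-sized replicates.
    """

    kind: str  # "genetic" | "social"
    replicate_props: dict[Scale, np.ndarray]
    pooled: dict[Scale, float]
    sd: dict[Scale, float]
    n_per_scale: int
    n_replicates: int

    @property
    def pooled_vector(self) -> np.ndarray:
        return np.array([self.pooled[s] for s in SCALES])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for scale in SCALES:
            for r, p in enumerate(self.replicate_props[scale], start=1):
                rows.append(
                    {"scale": scale.label, "replicate": r, "proportion": float(p)}
                )
        return pd.DataFrame(rows)


def identity_curve_from_labels(
    pairset: PairSet, labels: Mapping[tuple[str, str], int], kind: str
) -> IdentityCurve:
    """Assemble an identity curve from per-pair binary identity labels."""
    replicate_props: dict[Scale, np.ndarray] = {}
    pooled: dict[Scale, float] = {}
    sd: dict[Scale, float] = {}
    for scale in SCALES:
        props = []
        total = ident = 0
        for rep in range(1, pairset.n_replicates + 1):
            entries = pairset.by_replicate_scale(rep, scale)
            vals = [labels[pair_key(e.isolate_a, e.isolate_b)] for e in entries]
            props.append(float(np.mean(vals)) if vals else math.nan)
            total += len(vals)
            ident += sum(vals)
        arr = np.array(props)
        replicate_props[scale] = arr
        pooled[scale] = ident / total if total else math.nan
        sd[scale] = float(np.std(arr, ddof=1)) if len(arr) > 1 else math.nan
    return IdentityCurve(
        kind=kind,
        replicate_props=replicate_props,
        pooled=pooled,
        sd=sd,
        n_per_scale=pairset.n_per_scale,
        n_replicates=pairset.n_replicates,
    )


def genetic_identity_curve(
    pairset: PairSet, assignment: SequenceTypeAssignment
) -> IdentityCurve:
    """Probability that paired isolates share a sequence type, per scale."""
    labels: dict[tuple[str, str], int] = {}
    for e in pairset.entries:
        for iso in (e.isolate_a, e.isolate_b):
            if iso not in assignment.st_of:
                raise ValueError(f"isolate {iso} has no sequence type")
        labels[pair_key(e.isolate_a, e.isolate_b)] = int(
            assignment.st_of[e.isolate_a] == assignment.st_of[e.isolate_b]
        )
    return identity_curve_from_labels(pairset, labels, kind="genetic")


def social_identity_curve(
    pairset: PairSet, social_labels: Mapping[tuple[str, str], int]
) -> IdentityCurve:
    """Probability that paired isolates share a social allotype, per scale.

    ``social_labels`` comes from :func:`myxogeo.kd.social_identity`.
    """
    return identity_curve_from_labels(pairset, social_labels, kind="social")


# ---------------------------------------------------------------------------
# ANOVA + Tukey HSD


@dataclass
class ScaleComparison:
    """One-way ANOVA across scales plus Tukey HSD pairwise comparisons.

    ``exact_separation`` is set (and F left as NaN) when every group has
    zero within-group variance while group means differ, in which case the
    F ratio is undefined.
    """

    f_statistic: float
    p_value: float
    tukey: pd.DataFrame  # scale_i, scale_j, mean_diff, p_adj
    exact_separation: bool = False


def tukey_hsd(groups: list[np.ndarray], names: list[str]) -> pd.DataFrame:
    """Tukey HSD adjusted p-values from the studentized-range distribution.

    Uses the pooled within-group mean square with N - k error degrees of
    freedom; unequal group sizes fall back to the Tukey-Kramer form.
    """
    k = len(groups)
    ns = [len(g) for g in groups]
    n_total = sum(ns)
    df_w = n_total - k
    if df_w <= 0:
        raise ValueError("Tukey HSD needs at least one residual degree of freedom")
    ms_w = sum(((g - g.mean()) ** 2).sum() for g in groups) / df_w
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = groups[j].mean() - groups[i].mean()
        if ms_w == 0:
            p_adj = 1.0 if diff == 0 else 0.0
        else:
            se = math.sqrt(ms_w / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, k, df_w))
        rows.append(
            {
                "scale_i": names[i],
                "scale_j": names[j],
                "mean_diff": float(diff),
                "p_adj": p_adj,
            }
        )
    return pd.DataFrame(rows)


def anova_tukey(curve: IdentityCurve) -> ScaleComparison:
    """Compare replicate-level identity proportions across scale categories.

    One-way ANOVA (F = MS_between / MS_within) on the R replicate
    proportions per scale, followed by Tukey HSD with k = 5 groups.
    Requires at least two replicates per scale.
    """
    groups = []
    names = []
    for scale in SCALES:
        g = np.asarray(curve.replicate_props[scale], dtype=float)
        g = g[~np.isnan(g)]
        if len(g) < 2:
            raise ValueError(f"scale {scale.label} has fewer than 2 replicates")
        groups.append(g)
        names.append(scale.label)

    grand = np.concatenate(groups)
    ss_w = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ss_b = sum(len(g) * (g.mean() - grand.mean()) ** 2 for g in groups)
    df_b = len(groups) - 1
    df_w = len(grand) - len(groups)
    if ss_w == 0:
        if ss_b == 0:
            # all proportions identical everywhere: no variation to explain
            tk = tukey_hsd(groups, names)
            return ScaleComparison(f_statistic=0.0, p_value=1.0, tukey=tk)
        tk = tukey_hsd(groups, names)
        return ScaleComparison(
            f_statistic=math.nan, p_value=0.0, tukey=tk, exact_separation=True
        )
    f = (ss_b / df_b) / (ss_w / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return ScaleComparison(f_statistic=float(f), p_value=p, tukey=tukey_hsd(groups, names))


# ---------------------------------------------------------------------------
# Curve correlation


def curve_correlation(
    genetic: IdentityCurve | np.ndarray,
    social: IdentityCurve | np.ndarray,
    permutation: bool = True,
) -> dict:
    """Pearson correlation of the two five-point pooled decay curves.

    Optionally attaches a two-sided permutation p-value from the exhaustive
    5! orderings of one curve (count of |r_perm| >= |r_obs| over 120).
    Zero variance in either curve leaves r undefined (NaN).
    """
    g = genetic.pooled_vector if isinstance(genetic, IdentityCurve) else np.asarray(genetic, float)
    s = social.pooled_vector if isinstance(social, IdentityCurve) else np.asarray(social, float)
    if g.shape != s.shape:
        raise ValueError("curves must cover the same scales")
    if np.std(g) == 0 or np.std(s) == 0:
        return {"r": math.nan, "p_permutation": math.nan, "defined": False}
    r = float(np.corrcoef(g, s)[0, 1])
    out = {"r": r, "defined": True}
    if permutation:
        count = 0
        total = 0
        for perm in itertools.permutations(s):
            rp = float(np.corrcoef(g, np.array(perm))[0, 1])
            if abs(rp) >= abs(r) - 1e-12:
                count += 1
            total += 1
        out["p_permutation"] = count / total
    return out


def plot_identity_curves(
    genetic: IdentityCurve,
    social: IdentityCurve,
    geometry=None,
    path: str | None = None,
):
    """Plot both decay curves against log10 representative distance with
    across-replicate SD error bars.  Returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .design import ScaleGeometry, scale_distance

    geometry = geometry or ScaleGeometry()
    x = [math.log10(scale_distance(s, geometry)) for s in SCALES]
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, curve, title in ((axes[0], genetic, "genetic"), (axes[1], social, "social")):
        y = [curve.pooled[s] for s in SCALES]
        err = [curve.sd[s] for s in SCALES]
        ax.errorbar(x, y, yerr=err, marker="o", capsize=3)
        ax.set_title(f"{title} identity")
        ax.set_xlabel("log10 distance (m)")
        ax.set_ylim(-0.05, 1.05)
    axes[0].set_ylabel("probability of identity")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
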