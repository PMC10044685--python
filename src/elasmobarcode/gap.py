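"""Barcoding-gap analysis: inter-rank distance categories and their stats.

Every unordered pair of individuals is sorted into one of eight ordered
categories named after the most specific taxonomic rank at which the two
lineages differ: intraspecific, interspecific, inter-genus, inter-subfamily,
inter-family, inter-order, inter-infraclass, inter-class.  A usable barcode
marker shows distances increasing with category order and a gap between the
intraspecific and interspecific distributions.

Category distributions are compared with one-way ANOVA and Tukey's HSD.
Distance pairs share individuals and are therefore not independent; the
tests are reported as routinely done in barcoding studies, without a
dependence correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy import stats

from .distances import DistanceMatrix
from .taxonomy import Lineage


class RankCategory(IntEnum):
    """Eight ordered inter-rank distance categories."""

    INTRASPECIFIC = 0
    INTERSPECIFIC = 1
    INTER_GENUS = 2
    INTER_SUBFAMILY = 3
    INTER_FAMILY = 4
    INTER_ORDER = 5
    INTER_INFRACLASS = 6
    INTER_CLASS = 7

    @property
    def label(self) -> str:
        return self.name.lower().replace("_", "-", 1) if "_" in self.name \
            else self.name.lower()


@dataclass(frozen=True)
class CategorySummary:
    category: RankCategory
    n_pairs: int
    mean: float
    sd: float
    min: float
    max: float


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p_value: float


@dataclass(frozen=True)
class TukeyPair:
    i: int
    j: int
    mean_diff: float
    q: float
    p_adj: float


def categorize_pair(a: Lineage, b: Lineage) -> RankCategory:
    """Category named by the most specific rank at which ``a``/``b`` differ."""
    if a.class_ != b.class_:
        return RankCategory.INTER_CLASS
    if a.infraclass != b.infraclass:
        return RankCategory.INTER_INFRACLASS
    if a.order != b.order:
        return RankCategory.INTER_ORDER
    if a.family != b.family:
        return RankCategory.INTER_FAMILY
    if a.subfamily != b.subfamily:
        return RankCategory.INTER_SUBFAMILY
    if a.genus != b.genus:
        return RankCategory.INTER_GENUS
    if a.species != b.species:
        return RankCategory.INTERSPECIFIC
    return RankCategory.INTRASPECIFIC


def categorized_distances(
    m: DistanceMatrix, lineages: dict[str, Lineage]
) -> dict[RankCategory, list[float]]:
    """Pool each unordered pair's distance into its rank category."""
    missing = [i for i in m.ids if i not in lineages]
    if missing:
        raise KeyError(f"no lineage for ids: {', '.join(missing)}")
    pools: dict[RankCategory, list[float]] = {}
    for x, y in itertools.combinations(range(len(m.ids)), 2):
        cat = categorize_pair(lineages[m.ids[x]], lineages[m.ids[y]])
        pools.setdefault(cat, []).append(float(m.values[x, y]))
    return pools


def category_summaries(
    m: DistanceMatrix, lineages: dict[str, Lineage]
) -> list[CategorySummary]:
    """Mean/sd/range per category; pair counts sum to n(n-1)/2."""
    pools = categorized_distances(m, lineages)
    out = []
    for cat in sorted(pools):
        v = np.asarray(pools[cat])
        out.append(CategorySummary(
            category=cat, n_pairs=v.size, mean=float(v.mean()),
            sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
            min=float(v.min()), max=float(v.max())))
    return out


def anova_oneway(groups: list[list[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA across groups."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    if n_total <= k:
        raise ValueError("ANOVA needs more observations than groups")
    f, p = stats.f_oneway(*arrays)
    return AnovaResult(
        f=float(f), df_between=k - 1, df_within=n_total - k,
        p_value=float(p))


def tukey_hsd(groups: list[list[float]]) -> list[TukeyPair]:
    """Tukey honestly-significant-difference pairwise comparisons.

    q_ij = |mean_i - mean_j| / sqrt(MS_within * (1/n_i + 1/n_j) / 2),
    with p-values from the studentized-range distribution on k groups and
    the within-group degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("Tukey HSD needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    df_w = n_total - k
    if df_w < 1:
        raise ValueError("not enough observations for a within-group MS")
    ss_w = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ms_w = ss_w / df_w
    out = []
    for i, j in itertools.combinations(range(k), 2):
        diff = arrays[i].mean() - arrays[j].mean()
        if ms_w == 0.0:
            q = 0.0 if diff == 0.0 else np.inf
        else:
            se = np.sqrt(
                ms_w * (1.0 / arrays[i].size + 1.0 / arrays[j].size) / 2.0)
            q = abs(diff) / se
        p = float(stats.studentized_range.sf(q, k, df_w)) \
            if np.isfinite(q) else 0.0
        out.append(TukeyPair(
            i=i, j=j, mean_diff=float(diff), q=float(q), p_adj=min(p, 1.0)))
    return out


def write_category_summaries(summaries, path) -> None:
    with open(path, "w") as fh:
        fh.write("category\tn\tmean\tsd\tmin\tmax\n")
        for s in summaries:
            fh.write(
                f"{s.category.label}\t{s.n_pairs}\t{s.mean:.6f}\t"
                f"{s.sd:.6f}\t{s.min:.6f}\t{s.max:.6f}\n")


def write_tukey(pairs, labels, path) -> None:
    with open(path, "w") as fh:
        fh.write("group_i\tgroup_j\tmean_diff\tq\tp_adj\n")
        for t in pairs:
            fh.write(
                f"{labels[t.i]}\t{labels[t.j]}\t{t.mean_diff:.6f}\t"
                f"{t.q:.6f}\t{t.p_adj:.6g}\n")
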