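"""Spatial/habitat niche axis: selectivity, overlap, association, clustering.

* Jacobs selectivity D contrasts proportional use r with availability p:
  D = (r - p) / (r + p - 2 r p), +1 preference, -1 avoidance.
* Pianka's symmetric niche overlap O between two resource-use proportion
  vectors, 0 (none) to 1 (total), computed here over camera-trap stations
  (renormalized RAI rows) or habitat classes.
* Spearman rank correlation measures temporal association (paired hourly
  activity percentages) and spatial association (paired per-station RAI).
* Hierarchical clustering (UPGMA by default) on the correspondence-analysis
  chi-square distance between species' habitat-abundance profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from camtrap_niche.records import (
    HABITAT_CLASSES,
    HabitatProfile,
    RAIMatrix,
    StationDeployment,
)
from camtrap_niche.circular import HourlyProfile


@dataclass(frozen=True)
class JacobsResult:
    species: str
    habitat: str
    D: float | None          # None when degenerate (r = p in {0, 1})
    used: float              # proportional use r
    available: float         # availability p


@dataclass(frozen=True)
class PiankaResult:
    pair: tuple[str, str]
    O: float
    resource_axis: str       # "stations" or "habitats"


@dataclass(frozen=True)
class SpearmanResult:
    pair: tuple[str, str]
    axis: str                # "hourly" or "site"
    r_s: float | None        # None when a vector is constant
    p: float | None
    n: int


def jacobs_index(r: float, p: float) -> float | None:
    """Jacobs selectivity D = (r - p)/(r + p - 2 r p).

    ``r`` is the species' proportional use of the resource state, ``p`` its
    availability.  Returns None (degenerate denominator) when r = p = 0 or
    r = p = 1.
    """
    if not (0.0 <= r <= 1.0 and 0.0 <= p <= 1.0):
        raise ValueError("r and p must be proportions in [0, 1]")
    denom = r + p - 2.0 * r * p
    if denom == 0.0:
        return None
    return float(np.clip((r - p) / denom, -1.0, 1.0))


def habitat_preference(
    profile: HabitatProfile, stations: list[StationDeployment]
) -> list[JacobsResult]:
    """Jacobs D per species x habitat.

    Use r is the species' event proportion in the habitat; availability p is
    the habitat's share of total trap-nights (effort-weighted).
    """
    effort = pd.Series(0.0, index=list(HABITAT_CLASSES))
    for s in stations:
        effort[s.habitat] += s.trap_nights
    if (effort == 0).any():
        zero = list(effort.index[effort == 0])
        raise ValueError(f"habitats with zero trap-nights: {zero}")
    avail = effort / effort.sum()
    out: list[JacobsResult] = []
    for sp, row in profile.counts.iterrows():
        total = row.sum()
        for hab in HABITAT_CLASSES:
            r = float(row[hab] / total)
            p = float(avail[hab])
            out.append(JacobsResult(species=sp, habitat=hab,
                                    D=jacobs_index(r, p), used=r, available=p))
    return out


def pianka(p1, p2, pair: tuple[str, str] = ("a", "b"),
           resource_axis: str = "stations") -> PiankaResult:
    """Pianka's niche overlap O = sum(p1 p2) / sqrt(sum(p1^2) sum(p2^2)).

    Inputs are non-negative resource-use vectors; they are renormalized to
    sum to 1 (the index is scale-invariant, so this only validates intent).
    """
    a = np.asarray(p1, dtype=float)
    b = np.asarray(p2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("p1 and p2 must be 1-D vectors of equal length")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("proportions must be non-negative")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("zero resource-use vector")
    a = a / a.sum()
    b = b / b.sum()
    o = float(np.dot(a, b) / np.sqrt(np.dot(a, a) * np.dot(b, b)))
    return PiankaResult(pair=pair, O=float(np.clip(o, 0.0, 1.0)),
                        resource_axis=resource_axis)


def spearman(x, y, pair: tuple[str, str] = ("x", "y"),
             axis: str = "site") -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties.

    r_s is the Pearson correlation of the rank vectors; the two-sided
    p-value uses the t approximation t = r_s sqrt((n-2)/(1-r_s^2)) on n-2
    degrees of freedom (minimal p when |r_s| = 1).  A constant vector makes
    the correlation undefined (returned as None).
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = xv.size
    if n < 3:
        raise ValueError("Spearman requires n >= 3")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return SpearmanResult(pair=pair, axis=axis, r_s=None, p=None, n=n)
    rx = stats.rankdata(xv)
    ry = stats.rankdata(yv)
    r_s = float(np.corrcoef(rx, ry)[0, 1])
    r_s = float(np.clip(r_s, -1.0, 1.0))
    if abs(r_s) >= 1.0 - 1e-15:
        p = float(2.0 * stats.t.sf(np.inf, n - 2))  # 0; report smallest float
        p = max(p, np.finfo(float).tiny)
    else:
        t = r_s * np.sqrt((n - 2) / (1.0 - r_s**2))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return SpearmanResult(pair=pair, axis=axis, r_s=r_s, p=min(p, 1.0), n=n)


def temporal_association(
    h1: HourlyProfile, h2: HourlyProfile, pair: tuple[str, str] = ("a", "b")
) -> SpearmanResult:
    """Spearman association of two 24-bin percent hourly activity profiles."""
    return spearman(h1.percent, h2.percent, pair=pair, axis="hourly")


def spatial_association(
    rai: RAIMatrix, s1: str, s2: str
) -> SpearmanResult:
    """Spearman association of two species' per-station RAI vectors."""
    for sp in (s1, s2):
        if sp not in rai.values.index:
            raise KeyError(f"species {sp!r} not in RAI matrix")
    if len(rai.stations) < 3:
        raise ValueError("need >= 3 stations")
    return spearman(rai.row(s1), rai.row(s2), pair=(s1, s2), axis="site")


def chisq_distance(a, b, column_mass) -> float:
    """Correspondence-analysis chi-square distance between two count rows.

    With row profiles p_a = a/sum(a) and p_b = b/sum(b):
    d = sqrt( sum_j (p_aj - p_bj)^2 / mass_j ).  Scale-invariant in each row.
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    mass = np.asarray(column_mass, dtype=float)
    if not (av.shape == bv.shape == mass.shape) or av.ndim != 1:
        raise ValueError("a, b, column_mass must be 1-D of equal length")
    if (mass <= 0).any() or not np.isclose(mass.sum(), 1.0, atol=1e-9):
        raise ValueError("column_mass must be strictly positive and sum to 1")
    if av.sum() <= 0 or bv.sum() <= 0:
        raise ValueError("rows must have positive totals")
    pa = av / av.sum()
    pb = bv / bv.sum()
    return float(np.sqrt(np.sum((pa - pb) ** 2 / mass)))


def chisq_distance_matrix(abundance: pd.DataFrame) -> pd.DataFrame:
    """Pairwise chi-square distances between rows of a count table.

    Column masses come from the pooled table (column sums / grand total).
    """
    counts = abundance.to_numpy(dtype=float)
    if (counts.sum(axis=1) <= 0).any():
        raise ValueError("every row needs a positive total")
    mass = counts.sum(axis=0) / counts.sum()
    if (mass <= 0).any():
        raise ValueError("every column needs a positive total")
    rows = list(abundance.index)
    d = np.zeros((len(rows), len(rows)))
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            d[i, j] = d[j, i] = chisq_distance(counts[i], counts[j], mass)
    return pd.DataFrame(d, index=rows, columns=rows)


def hcluster(abundance: pd.DataFrame, method: str = "average"):
    """Agglomerative clustering of species habitat-abundance profiles.

    UPGMA (average linkage) by default, on the pairwise chi-square distance
    matrix with pooled column masses; single/complete are available.  Rows
    are sorted lexicographically first so ties break deterministically.
    Returns ``(linkage_matrix, labels)`` in scipy's linkage format.
    """
    if abundance.shape[0] < 2:
        raise ValueError("need >= 2 species rows")
    if method not in ("average", "single", "complete"):
        raise ValueError(f"unsupported linkage {method!r}")
    table = abundance.sort_index()
    dm = chisq_distance_matrix(table)
    condensed = dm.to_numpy()[np.triu_indices(len(dm), k=1)]
    link = hierarchy.linkage(condensed, method=method)
    return link, list(table.index)


def dendrogram_newick(link: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(link)

    def render(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            length = parent_height
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.get_left(), node.dist)
        right = render(node.get_right(), node.dist)
        blen = parent_height - node.dist
        return f"({left},{right}):{blen:.6g}"

    body = render(tree, tree.dist)
    # root branch length is 0 by construction; strip the trailing ":0"
    if body.endswith(":0"):
        body = body[:-2]
    return body + ";"
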