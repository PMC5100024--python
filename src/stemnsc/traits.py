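"""Stem-carbohydrate trait formulas and multivariate contrast selection.

Covers the derived quantities used when phenotyping stem non-structural
carbohydrates (NSC) in a replicated rice trial: total NSC (TNC = starch +
sucrose), the remobilisation index TNC_RMB (the fraction of heading-stage
TNC mass lost by maturity), maturity grouping by growth duration, a trait
correlation matrix with significance stars, and the PCA + hierarchical-
clustering procedure for picking multivariate-contrasting genotypes out of
a panel.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

__all__ = [
    "StemSample",
    "tnc",
    "tnc_remobilized",
    "maturity_group",
    "correlation_matrix",
    "select_contrasting",
]


@dataclass
class StemSample:
    """Stem TNC (% dry weight) and stem dry weight at heading and maturity."""

    tnc_hd: float
    tnc_mt: float
    stm_hd: float
    stm_mt: float

    def __post_init__(self) -> None:
        for v, name in ((self.tnc_hd, "tnc_hd"), (self.tnc_mt, "tnc_mt")):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be a percentage in [0, 100]")
        for v, name in ((self.stm_hd, "stm_hd"), (self.stm_mt, "stm_mt")):
            if v <= 0:
                raise ValueError(f"{name} must be a positive weight")


def tnc(starch_pct: float, sucrose_pct: float) -> float:
    """Total non-structural carbohydrate: starch + sucrose (same units)."""
    if starch_pct < 0 or sucrose_pct < 0:
        raise ValueError("constituent percentages must be >= 0")
    return starch_pct + sucrose_pct


def tnc_remobilized(sample: StemSample, as_printed: bool = False) -> float:
    """Percentage of heading-stage TNC mass remobilised by maturity.

    Default (mass-balance) form::

        100 * (TNC_hd * STM_hd - TNC_mt * STM_mt) / (TNC_hd * STM_hd)

    i.e. the net loss of TNC mass between heading and maturity relative to
    the heading stock. ``as_printed=True`` instead uses the heading stem
    weight in both numerator terms (an alternative definition comparing
    concentrations at fixed heading biomass). The result can be negative —
    net re-accumulation of TNC late in grain-filling — and, being a net
    difference between two sampling points, says nothing about turnover in
    between.
    """
    heading_mass = sample.tnc_hd * sample.stm_hd
    if heading_mass <= 0:
        raise ValueError("heading TNC mass must be positive")
    stm = sample.stm_hd if as_printed else sample.stm_mt
    return 100.0 * (heading_mass - sample.tnc_mt * stm) / heading_mass


def maturity_group(growth_duration_days: float) -> str:
    """Maturity class from growth duration: Early (<120 d), Medium
    (120–129 d), Late (>=130 d)."""
    if growth_duration_days <= 0:
        raise ValueError("growth duration must be positive")
    if growth_duration_days < 120:
        return "Early"
    if growth_duration_days < 130:
        return "Medium"
    return "Late"


def correlation_matrix(table: pd.DataFrame, stars: tuple[float, ...] = (0.05, 0.01, 0.001)):
    """Pairwise Pearson correlations with two-sided p-values and star marks.

    Missing values are handled pairwise-complete; each pair needs at least
    3 complete rows. Constant columns yield missing correlations.

    Returns
    -------
    (r, p, annot) : three DataFrames (correlation, p-value, star string).
    """
    cols = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    n = len(cols)
    r = pd.DataFrame(np.eye(n), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((n, n)), index=cols, columns=cols)
    annot = pd.DataFrame("", index=cols, columns=cols)
    for i, j in itertools.combinations(range(n), 2):
        x, y = table[cols[i]], table[cols[j]]
        mask = x.notna() & y.notna()
        if mask.sum() < 3:
            raise ValueError(f"fewer than 3 complete rows for pair ({cols[i]}, {cols[j]})")
        xv, yv = x[mask].to_numpy(float), y[mask].to_numpy(float)
        if xv.std() == 0 or yv.std() == 0:
            rij, pij = float("nan"), float("nan")
        else:
            res = pearsonr(xv, yv)
            rij, pij = float(res.statistic), float(res.pvalue)
        r.iloc[i, j] = r.iloc[j, i] = rij
        p.iloc[i, j] = p.iloc[j, i] = pij
        star = "".join("*" for thr in sorted(stars, reverse=True) if pij < thr) \
            if np.isfinite(pij) else ""
        annot.iloc[i, j] = annot.iloc[j, i] = star
    return r, p, annot


def _greedy_maximin(points: np.ndarray, n_select: int, groups: np.ndarray) -> list[int]:
    """Greedy maximin in the PC plane, preferring uncovered joint clusters.

    While some joint (complete-linkage, average-linkage) cluster is not yet
    represented, candidates are restricted to uncovered clusters; ties break
    to the lowest index, making the selection deterministic.
    """
    n = points.shape[0]
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(n, k=1)
    k = int(np.argmax(d[iu]))
    selected = [int(iu[0][k]), int(iu[1][k])]
    chosen = np.zeros(n, dtype=bool)
    chosen[selected] = True
    mind = np.minimum(d[:, selected[0]], d[:, selected[1]])
    while len(selected) < n_select:
        covered = {groups[i] for i in selected}
        uncovered_mask = ~np.isin(groups, list(covered))
        pool = uncovered_mask & ~chosen if (uncovered_mask & ~chosen).any() else ~chosen
        cand = np.where(pool, mind, -np.inf)
        nxt = int(np.argmax(cand))
        selected.append(nxt)
        chosen[nxt] = True
        np.minimum(mind, d[:, nxt], out=mind)
    return selected


def select_contrasting(
    table: pd.DataFrame,
    n_select: int,
    n_clusters: int = 4,
) -> tuple[list[str], pd.DataFrame]:
    """Pick multivariate-contrasting lines from per-line trait means.

    Traits are standardised; a PCA gives the PC1–PC2 plane (variance
    explained reported in the diagnostics); Euclidean hierarchical trees
    under complete and average linkage are each cut at ``n_clusters``.
    Lines are then chosen greedily to cover distinct joint cluster
    memberships (consistent across both trees) while maximising pairwise
    spread in the PC plane. Deterministic given the lowest-index tie rule.

    Returns
    -------
    (selected_ids, diagnostics)
        ``diagnostics`` has one row per line: PC coordinates, both cluster
        labels, and a ``selected`` flag; PCA variance fractions are stored
        in ``diagnostics.attrs['explained_variance_ratio']``.
    """
    num = table.select_dtypes("number")
    if num.shape[1] < 2:
        raise ValueError("at least two traits are required")
    if n_select > len(num):
        raise ValueError("n_select exceeds the number of lines")
    if n_clusters > len(num):
        raise ValueError("n_clusters exceeds the number of lines")
    x = (num - num.mean()) / num.std(ddof=1)
    x = x.to_numpy(float)
    # PCA on the correlation scale (standardised traits)
    u, s, _ = np.linalg.svd(x - x.mean(axis=0), full_matrices=False)
    scores = u * s
    evr = s**2 / np.sum(s**2)

    dist = pdist(x, metric="euclidean")
    lab_c = fcluster(linkage(dist, method="complete"), n_clusters, criterion="maxclust")
    lab_a = fcluster(linkage(dist, method="average"), n_clusters, criterion="maxclust")
    joint = pd.factorize(list(zip(lab_c, lab_a)))[0]

    if n_select == len(num):
        sel_idx = list(range(len(num)))
    else:
        sel_idx = _greedy_maximin(scores[:, :2], n_select, joint)
    ids = list(num.index.astype(str))
    selected = [ids[i] for i in sorted(sel_idx)]
    diag = pd.DataFrame(
        {
            "PC1": scores[:, 0],
            "PC2": scores[:, 1] if scores.shape[1] > 1 else 0.0,
            "cluster_complete": lab_c,
            "cluster_average": lab_a,
            "joint_cluster": joint,
            "selected": [i in set(sel_idx) for i in range(len(num))],
        },
        index=pd.Index(ids, name="line"),
    )
    diag.attrs["explained_variance_ratio"] = evr
    return selected, diag
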