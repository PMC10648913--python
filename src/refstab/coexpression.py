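"""Gene-metabolite co-expression screening.

Two complementary screens link candidate pathway genes to metabolite
accumulation:

* **Tissue screen** — hierarchically cluster candidate sequences'
  tissue expression profiles together with the metabolite's relative
  tissue content (distance 1 - Pearson r, average linkage), then keep
  the candidates that fall in the metabolite's cluster, ordered by
  cophenetic proximity, after discarding those essentially silent in
  the leaf (the tissue assayed in the time courses).
* **Time-course correlation** — Pearson correlation between a gene's
  per-time relative-expression means and the metabolite content means
  over the shared time points, with two-sided p from the t
  distribution (df = n - 2) and star classes at 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .expression import significance_stars

logger = logging.getLogger(__name__)

TISSUES = ("root", "stem", "leaf", "flower")

# Rank-weight encoding of the qualitative tissue ordering of gelsenicine
# content (root > flower > stem > leaf), used when no quantitative
# tissue contents are supplied.
DEFAULT_METABOLITE_TISSUE_WEIGHTS = dict(root=4.0, stem=2.0, leaf=1.0, flower=3.0)


@dataclass
class TissueProfile:
    """Abundance of one sequence or analyte across tissues (all >= 0)."""

    entity: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        bad = {t: v for t, v in self.values.items() if not (math.isfinite(v) and v >= 0)}
        if bad:
            raise ValueError(f"{self.entity}: nonnegative finite abundances required, got {bad}")
        if len(self.values) < 3:
            raise ValueError(f"{self.entity}: need >= 3 tissues")

    def vector(self, tissues: tuple[str, ...]) -> np.ndarray:
        return np.array([self.values[t] for t in tissues], dtype=float)


@dataclass
class CorrelationRecord:
    """Pearson correlation of one gene's time course with metabolite content."""

    gene: str
    r: float
    p: float
    sign_class: str
    direction: str
    n: int

    @property
    def defined(self) -> bool:
        return math.isfinite(self.r)


@dataclass
class TissueScreenResult:
    selected: list[str]                 # in metabolite's cluster, leaf-expressed
    excluded_low_leaf: list[str]
    dropped_constant: list[str]
    cophenetic_distance: dict[str, float]   # candidate -> distance to metabolite
    linkage: np.ndarray
    labels: list[str]                   # leaf order of the linkage input


def tissue_screen(candidates: list[TissueProfile], metabolite: TissueProfile,
                  leaf_min: float = 0.0) -> TissueScreenResult:
    """Select candidate sequences whose tissue profile tracks the metabolite.

    Candidates plus the metabolite profile are clustered with average
    linkage on 1 - Pearson r.  A candidate is selected when it (a) sits
    in the metabolite's branch when the tree is cut into two clusters,
    (b) is positively correlated with the metabolite profile, and (c)
    has leaf abundance >= ``leaf_min``.  Selected candidates are
    returned closest-first by cophenetic distance to the metabolite.
    Zero-variance profiles are dropped with a warning (their
    correlation is undefined).
    """
    if len(candidates) < 2:
        raise ValueError("need >= 2 candidate profiles")
    tissues = tuple(metabolite.values)
    for c in candidates:
        if set(c.values) < set(tissues):
            raise ValueError(f"{c.entity}: tissue set does not cover {tissues}")

    kept, dropped = [], []
    for c in candidates:
        if np.std(c.vector(tissues)) == 0:
            dropped.append(c.entity)
            logger.warning("dropping %s: constant tissue profile", c.entity)
        else:
            kept.append(c)
    if np.std(metabolite.vector(tissues)) == 0:
        raise ValueError("metabolite profile is constant; correlation undefined")
    if not kept:
        return TissueScreenResult([], [], dropped, {}, np.empty((0, 4)), [])

    profiles = kept + [metabolite]
    labels = [p.entity for p in profiles]
    mat = np.vstack([p.vector(tissues) for p in profiles])
    corr = np.corrcoef(mat)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")

    coph = squareform(hierarchy.cophenet(link))
    met_i = len(labels) - 1
    coph_to_met = {labels[i]: float(coph[i, met_i]) for i in range(len(kept))}

    if len(kept) == 1:
        # nothing to cut: membership reduces to the sign of the correlation
        in_cluster = [kept[0]] if corr[0, met_i] > 0 else []
    else:
        two_clusters = hierarchy.fcluster(link, t=2, criterion="maxclust")
        met_cluster = two_clusters[met_i]
        in_cluster = [
            kept[i] for i in range(len(kept))
            if two_clusters[i] == met_cluster and corr[i, met_i] > 0
        ]
    in_cluster.sort(key=lambda c: coph_to_met[c.entity])

    selected, excluded = [], []
    for c in in_cluster:
        if c.values.get("leaf", 0.0) >= leaf_min:
            selected.append(c.entity)
        else:
            excluded.append(c.entity)
            logger.info("excluding %s: leaf abundance %.3g below threshold %.3g",
                        c.entity, c.values.get("leaf", 0.0), leaf_min)
    if not selected:
        logger.warning("tissue screen selected no candidate co-clustering with %s",
                       metabolite.entity)
    return TissueScreenResult(selected, excluded, dropped, coph_to_met, link, labels)


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p from the t distribution with n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def timecourse_correlation(expr: pd.DataFrame, content: pd.Series,
                           method: str = "pearson") -> list[CorrelationRecord]:
    """Correlate per-time expression means with metabolite content means.

    ``expr``: DataFrame indexed by gene, columns = time points (RQ
    means); ``content``: Series indexed by time point.  Only shared time
    points are used (>= 3 required).  Zero-variance series yield a
    flagged record with undefined r that downstream tables omit.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    shared = [t for t in expr.columns if t in content.index]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared time points, have {len(shared)}")
    y = content.loc[shared].to_numpy(dtype=float)
    records = []
    for gene, row in expr.iterrows():
        x = row.loc[shared].to_numpy(dtype=float)
        if method == "spearman":
            if np.std(x) == 0 or np.std(y) == 0:
                r, p = float("nan"), float("nan")
            else:
                r, p = (float(v) for v in stats.spearmanr(x, y))
        else:
            r, p = pearson_with_p(x, y)
        if math.isfinite(r):
            rec = CorrelationRecord(
                gene=str(gene), r=r, p=p,
                sign_class=significance_stars(p),
                direction="positive" if r >= 0 else "negative",
                n=len(shared),
            )
        else:
            logger.warning("gene %s: zero-variance series, correlation undefined", gene)
            rec = CorrelationRecord(str(gene), float("nan"), float("nan"),
                                    "ns", "positive", len(shared))
        records.append(rec)
    return records


def correlation_heatmap_table(records: list[CorrelationRecord],
                              analyte: str = "metabolite") -> pd.DataFrame:
    """Long-format (gene, analyte, r, p, stars) table for heatmap rendering.

    Genes are ordered by hierarchical clustering on |r| when three or
    more defined records exist, else by input order.  Records with
    undefined r are omitted (count logged).
    """
    if not records:
        raise ValueError("no correlation records")
    defined = [rec for rec in records if rec.defined]
    n_dropped = len(records) - len(defined)
    if n_dropped:
        logger.info("omitting %d record(s) with undefined correlation", n_dropped)
    if not defined:
        return pd.DataFrame(columns=["gene", "analyte", "r", "p", "stars"])
    if len(defined) >= 3:
        vals = np.array([[abs(rec.r)] for rec in defined])
        link = hierarchy.linkage(vals, method="average")
        order = hierarchy.leaves_list(link)
    else:
        order = range(len(defined))
    rows = [
        dict(gene=defined[i].gene, analyte=analyte, r=defined[i].r,
             p=defined[i].p, stars=defined[i].sign_class)
        for i in order
    ]
    return pd.DataFrame(rows)
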