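"""Reference-gene stability estimators.

Four estimators commonly used to rank candidate reference genes for
RT-qPCR normalization, each applied to one sample group at a time:

* **GeNorm** — a gene's M value is the mean, over all other candidates,
  of the standard deviation of the per-sample log2 expression ratio.
  Genes are iteratively excluded (largest M first) until two remain;
  those two share rank 1.  The pairwise-variation statistic
  ``V(n/n+1)`` (SD of log2 of the ratio of normalization factors built
  from the top n vs n+1 genes) decides how many references are needed.
* **NormFinder** — a variance-components style score combining
  inter-subgroup deviation and intra-subgroup variance of the
  gene-centered log2 quantities.
* **BestKeeper** — descriptive dispersion of the raw Ct: the mean
  absolute deviation (its "SD") and the percent coefficient of
  variation.  Unlike the other three it is *not* invariant to shared
  per-sample loading offsets.
* **ΔCT method** — mean, over partner genes, of the SD of pairwise Ct
  differences.  Algebraically identical to the full-set GeNorm M when
  quantities are exact base-2 transforms of Ct.

All methods score *instability*: lower is more stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CtMatrix

logger = logging.getLogger(__name__)

LOG2 = np.log(2.0)


@dataclass
class RelativeQuantityMatrix:
    """Genes x samples matrix of relative quantities Q = 2^-dCT.

    dCT is taken per gene against that gene's minimum Ct (its most
    expressed sample), so 0 < Q <= 1 and each gene attains Q = 1.  The
    calibrator choice is immaterial to every ratio-based statistic
    downstream.
    """

    genes: list[str]
    samples: list[str]
    q: np.ndarray

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def log2q(self) -> np.ndarray:
        return np.log2(self.q)


def to_relative_quantity(m: CtMatrix) -> RelativeQuantityMatrix:
    """Convert Ct to relative quantities Q = 2^-(Ct - min Ct) per gene.

    Requires a complete matrix (resolve missing values first) with at
    least two samples.  No efficiency correction: base 2 exactly.
    """
    if not m.is_complete():
        raise ValueError("Ct matrix has missing values; resolve them first "
                         "(CtMatrix.drop_incomplete_samples)")
    if m.n_samples < 2:
        raise ValueError("need >= 2 samples")
    dct = m.ct - m.ct.min(axis=1, keepdims=True)
    return RelativeQuantityMatrix(list(m.genes), list(m.samples), 2.0 ** (-dct))


# ---------------------------------------------------------------------------
# GeNorm
# ---------------------------------------------------------------------------

@dataclass
class GenormResult:
    genes: list[str]
    m_full: dict[str, float]
    m_stepwise: dict[str, float]
    exclusion_rank: dict[str, int]
    exclusion_order: list[str]     # most stable first; final pair leads
    v_values: list[float] = field(default_factory=list)

    def ranking(self) -> list[str]:
        return list(self.exclusion_order)


def _pairwise_log_ratio_sd(log2q: np.ndarray) -> np.ndarray:
    """Matrix V[j, k] = sample SD (ddof=1) of log2(Q_j / Q_k)."""
    g = log2q.shape[0]
    v = np.zeros((g, g))
    for j in range(g):
        for k in range(j + 1, g):
            sd = np.std(log2q[j] - log2q[k], ddof=1)
            v[j, k] = v[k, j] = sd
    return v


def _m_values(log2q: np.ndarray) -> np.ndarray:
    v = _pairwise_log_ratio_sd(log2q)
    g = v.shape[0]
    return v.sum(axis=1) / (g - 1)


def genorm(q: RelativeQuantityMatrix) -> GenormResult:
    """GeNorm stability analysis with stepwise exclusion.

    At each step the gene with the largest M is excluded and M values are
    recomputed on the remaining set; each gene's reported M is the value
    it had at its exclusion step, and the final two genes share both the
    final-step M and rank 1.  Ties on the exclusion criterion are broken
    toward the later gene in input order (logged).
    """
    if q.n_genes < 3:
        raise ValueError("GeNorm requires >= 3 genes")
    log2q = q.log2q()
    m_full = {g: float(m) for g, m in zip(q.genes, _m_values(log2q))}

    active = list(range(q.n_genes))
    m_stepwise: dict[str, float] = {}
    excluded_order: list[str] = []  # least stable first
    while len(active) > 2:
        m = _m_values(log2q[active])
        worst_local = int(np.flatnonzero(m == m.max())[-1])  # later gene on ties
        if int((m == m.max()).sum()) > 1:
            logger.info("GeNorm exclusion tie at M=%.6f; excluding later gene in input order",
                        float(m.max()))
        worst = active[worst_local]
        m_stepwise[q.genes[worst]] = float(m[worst_local])
        excluded_order.append(q.genes[worst])
        active.remove(worst)

    final_m = _m_values(log2q[active])
    for local, gi in enumerate(active):
        m_stepwise[q.genes[gi]] = float(final_m[local])
    final_pair = [q.genes[gi] for gi in active]

    exclusion_order = final_pair + excluded_order[::-1]
    exclusion_rank = {g: 1 for g in final_pair}
    for pos, g in enumerate(exclusion_order[2:], start=3):
        exclusion_rank[g] = pos

    result = GenormResult(
        genes=list(q.genes),
        m_full=m_full,
        m_stepwise=m_stepwise,
        exclusion_rank=exclusion_rank,
        exclusion_order=exclusion_order,
    )
    result.v_values = genorm_pairwise_variation(q, result)
    return result


def genorm_pairwise_variation(q: RelativeQuantityMatrix, r: GenormResult) -> list[float]:
    """Pairwise variation V(n/n+1) for n = 2 .. G-1.

    NF_n(sample) is the geometric mean of Q over the n most stable genes
    (exclusion order); V(n/n+1) is the sample SD of log2(NF_n/NF_{n+1}).
    """
    if q.n_genes < 3:
        raise ValueError("pairwise variation requires >= 3 genes")
    order = [q.genes.index(g) for g in r.exclusion_order]
    log2q = q.log2q()
    v_values = []
    for n in range(2, q.n_genes):
        log_nf_n = log2q[order[:n]].mean(axis=0)
        log_nf_n1 = log2q[order[: n + 1]].mean(axis=0)
        v_values.append(float(np.std(log_nf_n - log_nf_n1, ddof=1)))
    return v_values


# ---------------------------------------------------------------------------
# NormFinder (basic variant)
# ---------------------------------------------------------------------------

@dataclass
class NormfinderResult:
    genes: list[str]
    stability: dict[str, float]
    intergroup_deviation: pd.DataFrame   # genes x subgroups, log2 units
    intragroup_sd: pd.DataFrame          # genes x subgroups, log2 units
    subgroups: list[str]

    def ranking(self) -> list[str]:
        return sorted(self.genes, key=lambda g: (self.stability[g], self.genes.index(g)))


def normfinder(q: RelativeQuantityMatrix,
               subgroups: dict[str, str] | None = None) -> NormfinderResult:
    """Model-based stability score from intra- and inter-subgroup variation.

    Works on gene-centered log2 quantities z (each sample's gene-mean is
    subtracted, removing sample loading).  With subgroups g of size n_g:

        d_ig = subgroup mean of z  -  size-weighted grand mean
        stability_i = mean over g of ( |d_ig| + sqrt(var_ig / n_g) )

    Without subgroups (or a single label) the score reduces to the sample
    SD of z for the gene.  Lower = more stable.
    """
    if q.n_genes < 3:
        raise ValueError("NormFinder requires >= 3 genes")
    x = q.log2q()
    z = x - x.mean(axis=0, keepdims=True)  # center per sample over genes

    if subgroups is None:
        labels = ["all"] * q.n_samples
    else:
        missing = [s for s in q.samples if s not in subgroups]
        if missing:
            raise ValueError(f"samples without subgroup label: {missing}")
        labels = [subgroups[s] for s in q.samples]
    uniq = list(dict.fromkeys(labels))
    idx = {u: [j for j, l in enumerate(labels) if l == u] for u in uniq}
    sizes = {u: len(js) for u, js in idx.items()}
    small = [u for u, n in sizes.items() if n < 2]
    if small:
        raise ValueError(f"subgroups with < 2 samples: {small}")

    if len(uniq) == 1:
        sd = np.std(z, ddof=1, axis=1)
        stability = {g: float(s) for g, s in zip(q.genes, sd)}
        d = pd.DataFrame(0.0, index=q.genes, columns=uniq)
        v = pd.DataFrame(sd, index=q.genes, columns=uniq)
        return NormfinderResult(list(q.genes), stability, d, v, uniq)

    n_total = q.n_samples
    means = {u: z[:, idx[u]].mean(axis=1) for u in uniq}
    variances = {u: z[:, idx[u]].var(ddof=1, axis=1) for u in uniq}
    grand = sum(sizes[u] * means[u] for u in uniq) / n_total

    d = pd.DataFrame({u: means[u] - grand for u in uniq}, index=q.genes)
    v = pd.DataFrame({u: np.sqrt(variances[u]) for u in uniq}, index=q.genes)
    per_group = {
        u: np.abs(d[u].to_numpy()) + np.sqrt(variances[u] / sizes[u]) for u in uniq
    }
    score = sum(per_group.values()) / len(uniq)
    stability = {g: float(s) for g, s in zip(q.genes, score)}
    return NormfinderResult(list(q.genes), stability, d, v, uniq)


# ---------------------------------------------------------------------------
# BestKeeper
# ---------------------------------------------------------------------------

@dataclass
class BestkeeperResult:
    genes: list[str]
    ct_mean: dict[str, float]
    sd: dict[str, float]       # mean absolute deviation from the mean Ct
    cv_pct: dict[str, float]

    def ranking(self) -> list[str]:
        return sorted(
            self.genes,
            key=lambda g: (self.sd[g], self.cv_pct[g], self.genes.index(g)),
        )

    def format_cv_sd(self, gene: str) -> str:
        return f"{self.cv_pct[gene]:.2f} ± {self.sd[gene]:.2f}"


def bestkeeper(m: CtMatrix, use_sample_sd: bool = False) -> BestkeeperResult:
    """BestKeeper descriptive dispersion of raw Ct per gene.

    The original tool's "SD" is the mean absolute deviation from the
    arithmetic mean Ct (default); ``use_sample_sd=True`` switches to the
    n-1 sample SD.  CV% = 100 * sd / mean.  Ranking is ascending by sd,
    ties by CV%.
    """
    if not m.is_complete():
        raise ValueError("Ct matrix has missing values; resolve them first")
    if m.n_samples < 2:
        raise ValueError("need >= 2 samples")
    ct_mean, sd, cv = {}, {}, {}
    for i, g in enumerate(m.genes):
        x = m.ct[i]
        mu = float(np.mean(x))
        s = float(np.std(x, ddof=1)) if use_sample_sd else float(np.mean(np.abs(x - mu)))
        ct_mean[g], sd[g], cv[g] = mu, s, 100.0 * s / mu
    return BestkeeperResult(list(m.genes), ct_mean, sd, cv)


# ---------------------------------------------------------------------------
# Comparative dCT method
# ---------------------------------------------------------------------------

@dataclass
class DeltaCtResult:
    genes: list[str]
    score: dict[str, float]   # mean over partners of SD of pairwise dCT

    def ranking(self) -> list[str]:
        return sorted(self.genes, key=lambda g: (self.score[g], self.genes.index(g)))


def delta_ct_method(m: CtMatrix) -> DeltaCtResult:
    """Comparative dCT stability: mean pairwise SD of Ct differences.

    For each ordered pair (i, j) compute the sample SD of Ct_i - Ct_j;
    a gene's score is the mean over its partners.  Identical to the
    full-set GeNorm M value on base-2 relative quantities.
    """
    if not m.is_complete():
        raise ValueError("Ct matrix has missing values; resolve them first")
    if m.n_genes < 3:
        raise ValueError("the dCT method requires >= 3 genes")
    if m.n_samples < 2:
        raise ValueError("need >= 2 samples")
    v = _pairwise_log_ratio_sd(-m.ct)  # SD of Ct_i - Ct_j == SD of (-Ct_j) - (-Ct_i)
    g = m.n_genes
    scores = v.sum(axis=1) / (g - 1)
    return DeltaCtResult(list(m.genes), {g_: float(s) for g_, s in zip(m.genes, scores)})


# ---------------------------------------------------------------------------
# convenience: all four methods on one group
# ---------------------------------------------------------------------------

def run_all_methods(m: CtMatrix,
                    subgroups: dict[str, str] | None = None) -> dict[str, object]:
    """Run GeNorm, NormFinder, BestKeeper and the dCT method on one group.

    Returns a dict with keys ``genorm``, ``normfinder``, ``bestkeeper``,
    ``deltact``.  ``subgroups`` is passed to NormFinder.
    """
    q = to_relative_quantity(m)
    return dict(
        genorm=genorm(q),
        normfinder=normfinder(q, subgroups),
        bestkeeper=bestkeeper(m),
        deltact=delta_ct_method(m),
    )
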