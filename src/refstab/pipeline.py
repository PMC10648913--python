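"""End-to-end orchestration: per-group stability reports and validation.

``run_stability`` reproduces the standard reference-gene workflow on a
Ct matrix: for each sample group it runs the four estimators, the
rank consensus, and the V-statistic recommendation, returning one tidy
report table plus per-group detail.  ``run_validation`` quantifies how
target-gene quantification shifts between a stable and an unstable
reference set.

NormFinder subgrouping follows the experimental structure: within a
hormone group samples are subgrouped by time point; in the Total group
by treatment; the Control group (time-0 samples only) runs in
single-subgroup mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .consensus import (
    ConsensusRanking,
    MethodRanking,
    V_CUTOFF,
    recommend,
    recommended_count,
    reffinder,
)
from .expression import ReferenceSensitivity, reference_choice_sensitivity
from .io import CtMatrix, GroupSpec, select_group
from .stability import run_all_methods

logger = logging.getLogger(__name__)


def normfinder_subgroups(m: CtMatrix, group_name: str) -> dict[str, str] | None:
    """Subgroup labels for NormFinder given the analyzed group."""
    if group_name == "Control":
        return None
    if group_name == "Total":
        return {s: m.meta[s].treatment for s in m.samples}
    return {s: f"{m.meta[s].time_h:g}h" for s in m.samples}


@dataclass
class GroupStabilityReport:
    group: str
    methods: dict[str, object]
    rankings: list[MethodRanking]
    consensus: ConsensusRanking
    v_values: list[float]
    recommended_n: int
    recommendation: dict[str, object] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        """Tidy per-gene table: rank, per-method scores, consensus value."""
        gn = self.methods["genorm"]
        nf = self.methods["normfinder"]
        bk = self.methods["bestkeeper"]
        dc = self.methods["deltact"]
        rows = []
        for rank, gene in enumerate(self.consensus.order, start=1):
            rows.append(dict(
                group=self.group, rank=rank, gene=gene,
                genorm_m=round(gn.m_stepwise[gene], 3),
                normfinder=round(nf.stability[gene], 3),
                bestkeeper_cv_sd=bk.format_cv_sd(gene),
                deltact_sd=round(dc.score[gene], 2),
                consensus=round(self.consensus.geomean_rank[gene], 2),
            ))
        return pd.DataFrame(rows)


def analyze_group(m: CtMatrix, group: GroupSpec,
                  cutoff: float = V_CUTOFF) -> GroupStabilityReport:
    sub = select_group(m, group).drop_incomplete_samples()
    if sub.n_samples < 2:
        raise ValueError(f"group {group.name!r}: fewer than 2 complete samples")
    methods = run_all_methods(sub, normfinder_subgroups(sub, group.name))
    rankings = [
        MethodRanking.from_genorm(methods["genorm"]),
        MethodRanking.from_normfinder(methods["normfinder"]),
        MethodRanking.from_bestkeeper(methods["bestkeeper"]),
        MethodRanking.from_deltact(methods["deltact"]),
    ]
    consensus = reffinder(rankings)
    v_values = methods["genorm"].v_values
    n = recommended_count(v_values, cutoff)
    return GroupStabilityReport(
        group=group.name, methods=methods, rankings=rankings,
        consensus=consensus, v_values=v_values, recommended_n=n,
        recommendation=recommend(consensus, min(n, len(consensus.genes))),
    )


def run_stability(m: CtMatrix, groups: list[GroupSpec] | None = None,
                  cutoff: float = V_CUTOFF) -> dict[str, GroupStabilityReport]:
    """Stability analysis for every requested group (default: all six).

    Raises with a message naming the failing group so batch runs are
    diagnosable.
    """
    if groups is None:
        groups = GroupSpec.standard_groups()
    reports: dict[str, GroupStabilityReport] = {}
    for g in groups:
        try:
            reports[g.name] = analyze_group(m, g, cutoff)
        except Exception as exc:
            raise RuntimeError(f"stability analysis failed for group {g.name!r}: {exc}") from exc
    return reports


def stability_table(reports: dict[str, GroupStabilityReport]) -> pd.DataFrame:
    return pd.concat([r.table() for r in reports.values()], ignore_index=True)


def recommendation_table(reports: dict[str, GroupStabilityReport]) -> pd.DataFrame:
    rows = []
    for name, r in reports.items():
        rows.append(dict(
            group=name,
            recommended_n=r.recommended_n,
            most_stable=" ".join(r.recommendation["most_stable"]),
            least_stable=r.recommendation["least_stable"],
        ))
    return pd.DataFrame(rows)


def run_validation(m: CtMatrix, target: str, stable_refs: list[str],
                   unstable_refs: list[str],
                   treatment: str | None = None) -> ReferenceSensitivity:
    """RQ series of ``target`` under stable vs unstable references.

    When ``treatment`` is given the matrix is first restricted to that
    hormone group and the calibrator is its 0 h samples.
    """
    if treatment is not None:
        m = select_group(m, GroupSpec.treatment(treatment)).drop_incomplete_samples()
    return reference_choice_sensitivity(m, target, stable_refs, unstable_refs)
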