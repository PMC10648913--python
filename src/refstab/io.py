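"""Data model and I/O for cycle-threshold (Ct) tables.

RT-qPCR experiments produce a table of Ct values — the PCR cycle at which
each (gene, sample) reaction crosses the fluorescence threshold.  This
module defines the in-memory containers used throughout the package
(:class:`CtMatrix`, :class:`SampleMeta`, :class:`GroupSpec`,
:class:`MetaboliteSeries`) and CSV readers/writers for them.

Conventions
-----------
* Long CSV: one row per measurement with columns
  ``sample_id, gene, ct, treatment, time_h, bio_replicate`` (and an
  optional ``tech_replicate``).  Technical replicates of the same
  (sample, gene) are averaged on read.
* Wide CSV: genes as rows, samples as columns, with a sidecar metadata
  CSV (``sample_id, treatment, time_h, bio_replicate``).
* Missing Ct values are held as NaN and must be resolved (via
  :meth:`CtMatrix.drop_incomplete_samples`) before stability analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TREATMENTS = ("Control", "SA", "MeJA", "ETH", "ABA")
TIME_POINTS_H = (0.0, 2.0, 4.0, 8.0, 24.0, 48.0)
GROUP_NAMES = ("Control", "SA", "MeJA", "ETH", "ABA", "Total")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one biological sample.

    ``treatment`` is the applied hormone (or ``Control``), ``time_h`` the
    sampling time in hours after application, ``bio_replicate`` the
    biological replicate index (1-based).
    """

    sample_id: str
    treatment: str
    time_h: float
    bio_replicate: int

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(
                f"unknown treatment {self.treatment!r}; expected one of {TREATMENTS}"
            )
        if self.time_h < 0:
            raise ValueError(f"time_h must be nonnegative, got {self.time_h}")
        if self.treatment == "Control" and self.time_h != 0:
            raise ValueError("Control samples must have time_h = 0")
        if self.bio_replicate < 1:
            raise ValueError("bio_replicate must be a positive integer")


@dataclass
class CtMatrix:
    """Genes x samples matrix of cycle-threshold values with sample metadata.

    ``ct`` is a float array of shape ``(len(genes), len(samples))``;
    missing measurements are NaN and must be resolved before analysis.
    """

    genes: list[str]
    samples: list[str]
    ct: np.ndarray
    meta: dict[str, SampleMeta]

    def __post_init__(self) -> None:
        self.ct = np.asarray(self.ct, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicated gene names")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicated sample ids")
        if self.ct.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"ct shape {self.ct.shape} does not match "
                f"({len(self.genes)}, {len(self.samples)})"
            )
        missing_meta = [s for s in self.samples if s not in self.meta]
        if missing_meta:
            raise ValueError(f"samples without metadata: {missing_meta}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def gene_row(self, gene: str) -> np.ndarray:
        return self.ct[self.gene_index(gene)]

    def is_complete(self) -> bool:
        return bool(np.isfinite(self.ct).all())

    def subset_samples(self, sample_ids: Iterable[str]) -> "CtMatrix":
        ids = list(sample_ids)
        idx = [self.samples.index(s) for s in ids]
        return CtMatrix(
            genes=list(self.genes),
            samples=ids,
            ct=self.ct[:, idx].copy(),
            meta={s: self.meta[s] for s in ids},
        )

    def subset_genes(self, genes: Iterable[str]) -> "CtMatrix":
        names = list(genes)
        idx = [self.gene_index(g) for g in names]
        return CtMatrix(
            genes=names,
            samples=list(self.samples),
            ct=self.ct[idx, :].copy(),
            meta=dict(self.meta),
        )

    def drop_incomplete_samples(self) -> "CtMatrix":
        """Drop samples with any missing gene, logging a warning per sample.

        The stability estimators assume complete matrices; imputing Ct
        would invent data, so incomplete samples are removed instead.
        """
        keep = []
        for j, s in enumerate(self.samples):
            if np.isfinite(self.ct[:, j]).all():
                keep.append(s)
            else:
                bad = [g for i, g in enumerate(self.genes) if not np.isfinite(self.ct[i, j])]
                logger.warning("dropping sample %s: missing Ct for %s", s, bad)
        return self.subset_samples(keep)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ct, index=self.genes, columns=self.samples)


@dataclass(frozen=True)
class GroupSpec:
    """A named sample group: Control (time 0), one hormone, or Total.

    ``Control`` selects every time-0 biological replicate regardless of
    treatment batch; each hormone group selects that treatment across all
    time points; ``Total`` selects all samples.
    """

    name: str
    predicate: Callable[[SampleMeta], bool] = field(compare=False)

    @staticmethod
    def control() -> "GroupSpec":
        return GroupSpec("Control", lambda m: m.time_h == 0)

    @staticmethod
    def treatment(name: str) -> "GroupSpec":
        if name not in ("SA", "MeJA", "ETH", "ABA"):
            raise ValueError(f"unknown hormone treatment {name!r}")
        return GroupSpec(name, lambda m, _t=name: m.treatment == _t)

    @staticmethod
    def total() -> "GroupSpec":
        return GroupSpec("Total", lambda m: True)

    @staticmethod
    def by_name(name: str) -> "GroupSpec":
        if name == "Control":
            return GroupSpec.control()
        if name == "Total":
            return GroupSpec.total()
        return GroupSpec.treatment(name)

    @staticmethod
    def standard_groups() -> list["GroupSpec"]:
        return [GroupSpec.by_name(n) for n in GROUP_NAMES]


@dataclass
class MetaboliteSeries:
    """Metabolite content per (treatment, time) with optional replicates.

    ``values`` maps ``(treatment, time_h)`` to mean content (mg per g dry
    weight); ``replicates`` optionally maps the same keys to the
    individual replicate measurements.
    """

    analyte: str
    values: dict[tuple[str, float], float]
    replicates: dict[tuple[str, float], list[float]] | None = None

    def __post_init__(self) -> None:
        for key, v in self.values.items():
            if not v > 0:
                raise ValueError(f"content must be strictly positive; {key} -> {v}")

    def restrict(self, treatment: str) -> "pd.Series":
        """Time-indexed content series for one treatment, sorted by time."""
        items = {t: v for (trt, t), v in self.values.items() if trt == treatment}
        return pd.Series(items, name=self.analyte).sort_index()


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_REQUIRED_LONG = ("sample_id", "gene", "ct")
_META_COLS = ("treatment", "time_h", "bio_replicate")


def _meta_from_row(row: pd.Series) -> SampleMeta:
    return SampleMeta(
        sample_id=str(row["sample_id"]),
        treatment=str(row["treatment"]),
        time_h=float(row["time_h"]),
        bio_replicate=int(row["bio_replicate"]),
    )


def read_ct_long(path: str | Path) -> CtMatrix:
    """Read a long-format Ct CSV into a :class:`CtMatrix`.

    Technical replicates (multiple rows for one (sample, gene)) are
    averaged into a single Ct.  Gene/sample order is first-appearance
    order.  A (sample, gene) combination absent from the file becomes an
    explicit NaN with a logged warning.

    Raises
    ------
    ValueError
        on missing columns, non-numeric Ct, or conflicting metadata for
        the same sample_id.
    """
    df = pd.read_csv(path)
    missing = [c for c in (*_REQUIRED_LONG, *_META_COLS) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    ct_numeric = pd.to_numeric(df["ct"], errors="coerce")
    bad = df.index[ct_numeric.isna() & df["ct"].notna()]
    if len(bad):
        raise ValueError(
            f"{path}: non-numeric ct at row(s) {list(bad + 2)} (1-based incl. header)"
        )
    df = df.assign(ct=ct_numeric)

    meta: dict[str, SampleMeta] = {}
    for _, row in df.iterrows():
        m = _meta_from_row(row)
        prev = meta.get(m.sample_id)
        if prev is None:
            meta[m.sample_id] = m
        elif prev != m:
            raise ValueError(
                f"{path}: conflicting metadata for sample {m.sample_id!r}: {prev} vs {m}"
            )

    genes = list(dict.fromkeys(df["gene"].astype(str)))
    samples = list(dict.fromkeys(df["sample_id"].astype(str)))
    mean_ct = df.groupby(["gene", "sample_id"], sort=False)["ct"].mean()

    ct = np.full((len(genes), len(samples)), np.nan)
    for (g, s), v in mean_ct.items():
        ct[genes.index(str(g)), samples.index(str(s))] = v
    n_missing = int(np.isnan(ct).sum())
    if n_missing:
        logger.warning("%s: %d (gene, sample) cells missing; stored as NaN", path, n_missing)
    return CtMatrix(genes=genes, samples=samples, ct=ct, meta=meta)


def write_ct_long(m: CtMatrix, path: str | Path) -> None:
    """Write a :class:`CtMatrix` as long CSV (inverse of :func:`read_ct_long`)."""
    rows = []
    for j, s in enumerate(m.samples):
        sm = m.meta[s]
        for i, g in enumerate(m.genes):
            if np.isfinite(m.ct[i, j]):
                rows.append(
                    dict(sample_id=s, gene=g, ct=m.ct[i, j], treatment=sm.treatment,
                         time_h=sm.time_h, bio_replicate=sm.bio_replicate)
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ct_wide(ct_path: str | Path, meta_path: str | Path) -> CtMatrix:
    """Read a wide Ct CSV (genes as rows) plus a sidecar metadata CSV."""
    wide = pd.read_csv(ct_path, index_col=0)
    mdf = pd.read_csv(meta_path)
    missing = [c for c in ("sample_id", *_META_COLS) if c not in mdf.columns]
    if missing:
        raise ValueError(f"{meta_path}: missing required columns {missing}")
    meta = {str(r["sample_id"]): _meta_from_row(r) for _, r in mdf.iterrows()}
    samples = [str(c) for c in wide.columns]
    return CtMatrix(
        genes=[str(g) for g in wide.index],
        samples=samples,
        ct=wide.to_numpy(dtype=float),
        meta={s: meta[s] for s in samples},
    )


def write_ct_wide(m: CtMatrix, ct_path: str | Path, meta_path: str | Path) -> None:
    m.to_frame().to_csv(ct_path)
    pd.DataFrame(
        [dict(sample_id=s, treatment=m.meta[s].treatment, time_h=m.meta[s].time_h,
              bio_replicate=m.meta[s].bio_replicate) for s in m.samples]
    ).to_csv(meta_path, index=False)


def read_metabolite_csv(path: str | Path, analyte: str = "content") -> MetaboliteSeries:
    """Read a metabolite content CSV with columns treatment, time_h, content
    (optional replicate column; replicate rows are averaged for ``values``
    and retained in ``replicates``)."""
    df = pd.read_csv(path)
    for c in ("treatment", "time_h", "content"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    grouped = df.groupby(["treatment", "time_h"], sort=False)["content"]
    values = {(str(t), float(h)): float(v) for (t, h), v in grouped.mean().items()}
    reps = {
        (str(t), float(h)): [float(x) for x in g]
        for (t, h), g in grouped
    }
    return MetaboliteSeries(analyte=analyte, values=values, replicates=reps)


def write_metabolite_csv(series: MetaboliteSeries, path: str | Path) -> None:
    rows = []
    for (trt, t), reps in (series.replicates or {}).items():
        for r, v in enumerate(reps, start=1):
            rows.append(dict(treatment=trt, time_h=t, replicate=r, content=v))
    if not rows:
        rows = [dict(treatment=trt, time_h=t, replicate=1, content=v)
                for (trt, t), v in series.values.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def select_group(m: CtMatrix, g: GroupSpec) -> CtMatrix:
    """Restrict a Ct matrix to the samples selected by a group.

    Raises ``ValueError`` if the group selects fewer than two samples.
    """
    ids = [s for s in m.samples if g.predicate(m.meta[s])]
    if len(ids) < 2:
        raise ValueError(f"group {g.name!r} selects {len(ids)} sample(s); need >= 2")
    return m.subset_samples(ids)


def ct_summary(m: CtMatrix) -> pd.DataFrame:
    """Per-gene summary of Ct: mean, sd (n-1 denominator), min, max, median.

    Mirrors the descriptive "mean ± sd" reporting used to compare raw
    expression levels of candidate reference genes.
    """
    if m.n_samples < 2:
        raise ValueError("ct_summary requires >= 2 samples")
    rows = {}
    for i, g in enumerate(m.genes):
        x = m.ct[i]
        x = x[np.isfinite(x)]
        if x.size == 0:
            raise ValueError(f"gene {g!r} has no finite Ct values")
        rows[g] = dict(
            mean=float(np.mean(x)),
            sd=float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
            min=float(np.min(x)),
            max=float(np.max(x)),
            median=float(np.median(x)),
        )
    return pd.DataFrame.from_dict(rows, orient="index")[["mean", "sd", "min", "max", "median"]]
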