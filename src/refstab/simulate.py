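"""Synthetic RT-qPCR data with known ground truth.

The generator emulates a hormone-induction time-course experiment on
leaf tissue: candidate reference genes and pathway genes measured by
qPCR over 4 hormone treatments (SA, MeJA, ETH, ABA) x 6 time points
(0, 2, 4, 8, 24, 48 h) x 3 biological replicates, plus 5-fold dilution
series for standard curves and a metabolite content series coupled
log-linearly to designated pathway genes.

The Ct model is additive on the cycle (log2 expression) scale:

    Ct[i, s] = baseline_i + L_s + A_i * profile_i(treatment_s, time_s) + eps

with ``L_s ~ N(0, sigma_load^2)`` a loading offset shared by every gene
within sample ``s`` (RNA input / RT yield), ``eps ~ N(0, sigma_rep^2)``
per-well noise, and ``A_i`` the gene's designed instability amplitude in
cycles.  ``profile_i`` maps (treatment, time) to a multiplier in
[-1, 1] and is 0 at time 0 (no response before induction).  Genes with
A = 0 are the designed-stable reference candidates; the per-gene A
table ships with every simulated dataset as ground truth.

Default study conditions: 10 reference candidates with amplitudes
{0, 0, 0, 0, 1, 1, 2, 2, 3, 3} cycles, sigma_load = 0.5,
sigma_rep = 0.2, 3 replicates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CtMatrix, MetaboliteSeries, SampleMeta
from .standard_curve import DilutionSeries

HORMONES = ("SA", "MeJA", "ETH", "ABA")
TIMES = (0.0, 2.0, 4.0, 8.0, 24.0, 48.0)

REFERENCE_GENES = ("UBC", "PP2A", "Actin", "CDC25", "EF1a", "TUA",
                   "SAND", "GAPDH", "TUB", "18S")
PATHWAY_GENES = ("GES", "G8H", "8-HGO", "ISY", "7-DLS", "LAMT", "SLS",
                 "AS", "AnPRT", "PRAI", "IGPS", "TSA", "TSB", "STR", "SGD")

# base response shape over the five post-induction time points; each
# gene uses a cyclic shift of this, so profiles differ between genes
_BASE_SHAPE = (1.0, 0.5, -0.5, -1.0, 0.6)

# shared response of the metabolite-coupled pathway trio: sustained
# suppression after induction, nearly uncorrelated with every cyclic
# shift of _BASE_SHAPE so uncoupled genes do not track content by accident
_COUPLED_SHAPE = (-1.0, -0.7, -0.95, -0.9, -0.7)


@dataclass
class GeneSpec:
    """One simulated gene: baseline Ct, instability amplitude, response."""

    name: str
    baseline_ct: float
    amplitude: float
    profile: dict[tuple[str, float], float] = field(default_factory=dict)

    def response(self, treatment: str, time_h: float) -> float:
        return self.profile.get((treatment, time_h), 0.0)


def make_profile(shift: int, treatments: tuple[str, ...] = HORMONES,
                 times: tuple[float, ...] = TIMES) -> dict[tuple[str, float], float]:
    """Deterministic per-(treatment, time) multipliers in [-1, 1].

    The post-induction shape is a cyclic shift of a fixed pattern; the
    sign alternates across treatments so no two treatments respond
    identically.  Time 0 is always 0.
    """
    n = len(_BASE_SHAPE)
    profile: dict[tuple[str, float], float] = {}
    for t_i, trt in enumerate(treatments):
        sign = 1.0 if (t_i + shift) % 2 == 0 else -1.0
        for k, time in enumerate(times):
            if time == 0:
                profile[(trt, time)] = 0.0
            else:
                profile[(trt, time)] = sign * _BASE_SHAPE[(k - 1 + shift) % n]
    return profile


@dataclass
class DilutionConfig:
    factor: float = 5.0
    steps: int = 5
    efficiency_pct: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0


@dataclass
class SimulationConfig:
    """Full description of one simulated experiment (reproducible by seed)."""

    seed: int = 0
    genes: list[GeneSpec] = field(default_factory=list)
    sigma_load: float = 0.5
    sigma_rep: float = 0.2
    replicates: int = 3
    treatments: tuple[str, ...] = HORMONES
    times: tuple[float, ...] = TIMES
    coupling: dict[str, float] = field(default_factory=dict)
    content_baseline: float = 0.25          # mg per g dry weight
    sigma_content: float = 0.0              # log2 units
    dilution: DilutionConfig = field(default_factory=DilutionConfig)

    def __post_init__(self) -> None:
        if self.sigma_load < 0 or self.sigma_rep < 0 or self.sigma_content < 0:
            raise ValueError("noise SDs must be nonnegative")
        for g in self.genes:
            if g.amplitude < 0:
                raise ValueError(f"{g.name}: amplitude must be nonnegative")

    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]

    # -- JSON round trip (profiles keyed "treatment@time") ------------------
    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        for g in d["genes"]:
            g["profile"] = {f"{trt}@{t}": v for (trt, t), v in g["profile"].items()}
        d["treatments"] = list(self.treatments)
        d["times"] = list(self.times)
        Path(path).write_text(json.dumps(d, indent=1))

    @staticmethod
    def from_json(path: str | Path) -> "SimulationConfig":
        d = json.loads(Path(path).read_text())
        genes = []
        for g in d.pop("genes"):
            prof = {}
            for key, v in g.pop("profile").items():
                trt, t = key.split("@")
                prof[(trt, float(t))] = v
            genes.append(GeneSpec(profile=prof, **g))
        dil = DilutionConfig(**d.pop("dilution"))
        return SimulationConfig(
            genes=genes,
            treatments=tuple(d.pop("treatments")),
            times=tuple(d.pop("times")),
            dilution=dil,
            **d,
        )


DEFAULT_AMPLITUDES = (0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 2.0, 2.0, 3.0, 3.0)


def default_config(seed: int = 0) -> SimulationConfig:
    """Reference-candidate panel under the default study conditions.

    Ten candidates, four designed-stable (A = 0) and six with designed
    instability of 1-3 cycles; baselines span the realistic qPCR window
    (17-28 cycles).
    """
    baselines = (21.0, 22.6, 19.5, 24.0, 18.4, 23.1, 25.8, 19.3, 22.0, 17.0)
    genes = [
        GeneSpec(name, bl, amp, make_profile(shift=i))
        for i, (name, bl, amp) in enumerate(zip(REFERENCE_GENES, baselines, DEFAULT_AMPLITUDES))
    ]
    eff = {g.name: e for g, e in zip(genes, (99.6, 105.9, 109.3, 109.8, 110.1,
                                             107.6, 108.5, 109.8, 102.8, 97.9))}
    return SimulationConfig(seed=seed, genes=genes,
                            dilution=DilutionConfig(efficiency_pct=eff))


def coupled_profile(treatments: tuple[str, ...] = HORMONES,
                    times: tuple[float, ...] = TIMES) -> dict[tuple[str, float], float]:
    """Common response profile of the metabolite-coupled pathway genes."""
    profile: dict[tuple[str, float], float] = {}
    for trt in treatments:
        for k, time in enumerate(times):
            profile[(trt, time)] = 0.0 if time == 0 else _COUPLED_SHAPE[k - 1]
    return profile


def pathway_config(seed: int = 0) -> SimulationConfig:
    """Reference panel plus 15 pathway genes with metabolite coupling.

    Three pathway genes (8-HGO, LAMT, STR) are positively coupled to the
    metabolite and share one co-regulated response profile; the
    remainder respond to the treatments (A of 1-2 cycles) with profiles
    uncorrelated to the coupled trio's, so only the trio tracks content.
    """
    cfg = default_config(seed)
    n0 = len(cfg.genes)
    coupled = {"8-HGO": 0.4, "LAMT": 0.3, "STR": 0.3}
    for i, name in enumerate(PATHWAY_GENES):
        if name in coupled:
            spec = GeneSpec(name, 23.0 + (i % 5) * 0.8, 1.5, coupled_profile())
        else:
            spec = GeneSpec(name, 23.0 + (i % 5) * 0.8, 1.0 + (i % 3) * 0.5,
                            make_profile(shift=n0 + i))
        cfg.genes.append(spec)
    cfg.coupling = coupled
    cfg.sigma_content = 0.1
    return cfg


def _designed_effect(cfg: SimulationConfig) -> pd.DataFrame:
    """A_i * profile_i per (gene, treatment, time): the noiseless signal."""
    rows = []
    for g in cfg.genes:
        for trt in cfg.treatments:
            for t in cfg.times:
                rows.append(dict(gene=g.name, treatment=trt, time_h=t,
                                 effect_ct=g.amplitude * g.response(trt, t)))
    return pd.DataFrame(rows)


def simulate_ct(cfg: SimulationConfig) -> tuple[CtMatrix, pd.DataFrame]:
    """Simulate a Ct matrix plus its ground-truth table.

    Returns ``(matrix, truth)`` where ``truth`` has one row per gene with
    its designed baseline and instability amplitude.  Identical configs
    produce bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    samples, meta = [], {}
    conditions = []
    for trt in cfg.treatments:
        for t in cfg.times:
            for rep in range(1, cfg.replicates + 1):
                sid = f"{trt}_{t:g}h_r{rep}"
                samples.append(sid)
                meta[sid] = SampleMeta(sid, trt, t, rep)
                conditions.append((trt, t))

    n_genes, n_samples = len(cfg.genes), len(samples)
    load = rng.normal(0.0, cfg.sigma_load, size=n_samples)
    eps = rng.normal(0.0, cfg.sigma_rep, size=(n_genes, n_samples))

    ct = np.empty((n_genes, n_samples))
    for i, g in enumerate(cfg.genes):
        signal = np.array([g.amplitude * g.response(trt, t) for trt, t in conditions])
        ct[i] = g.baseline_ct + load + signal + eps[i]

    truth = pd.DataFrame(
        [dict(gene=g.name, baseline_ct=g.baseline_ct, amplitude=g.amplitude,
              coupling=cfg.coupling.get(g.name, 0.0)) for g in cfg.genes]
    )
    return CtMatrix(cfg.gene_names(), samples, ct, meta), truth


def simulate_dilution(cfg: SimulationConfig) -> dict[str, DilutionSeries]:
    """Simulate one dilution series per gene with known efficiency.

    Ct(step) = baseline + slope * (-step * log10(factor)) with
    slope = -1 / log10(1 + E/100); optional Gaussian Ct noise.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    out = {}
    lf = np.log10(cfg.dilution.factor)
    for g in cfg.genes:
        e_pct = cfg.dilution.efficiency_pct.get(g.name, 100.0)
        if e_pct <= -100:
            raise ValueError(f"{g.name}: efficiency must exceed -100%")
        slope = -1.0 / np.log10(1.0 + e_pct / 100.0)
        pts = []
        for step in range(cfg.dilution.steps):
            x = -step * lf
            noise = rng.normal(0.0, cfg.dilution.noise_sd) if cfg.dilution.noise_sd else 0.0
            pts.append((x, g.baseline_ct + slope * x + noise))
        out[g.name] = DilutionSeries(g.name, pts, cfg.dilution.factor)
    return out


def simulate_content(cfg: SimulationConfig, analyte: str = "gelsenicine") -> MetaboliteSeries:
    """Simulate metabolite content coupled to designated pathway genes.

    On the log2 scale:

        log2 c(trt, t) = log2 c0 + sum_i w_i * (-A_i * profile_i(trt, t)) + noise

    so a gene with positive coupling w has a relative-expression series
    positively correlated with content by construction (a drop in Ct is
    a rise in expression and a rise in content).  Replicate values carry
    independent noise; ``values`` stores the replicate means.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    by_name = {g.name: g for g in cfg.genes}
    for name in cfg.coupling:
        if name not in by_name:
            raise ValueError(f"coupled gene {name!r} not in config")
    values: dict[tuple[str, float], float] = {}
    reps: dict[tuple[str, float], list[float]] = {}
    for trt in cfg.treatments:
        for t in cfg.times:
            log2c = float(np.log2(cfg.content_baseline))
            for name, w in cfg.coupling.items():
                g = by_name[name]
                log2c += w * (-g.amplitude * g.response(trt, t))
            vals = [
                float(2.0 ** (log2c + (rng.normal(0.0, cfg.sigma_content)
                                       if cfg.sigma_content else 0.0)))
                for _ in range(cfg.replicates)
            ]
            reps[(trt, t)] = vals
            values[(trt, t)] = float(np.mean(vals))
    return MetaboliteSeries(analyte=analyte, values=values, replicates=reps)
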