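"""Synthetic Ct data with the tMCAO study design.

The generator draws one Ct value per sample and gene from an additive
error model on the cycle scale (multiplicative on transcript abundance):

    Ct = baseline + sample_loading + group_shift + technical_noise

* baseline — the gene's typical quantification cycle;
* sample loading — a Gaussian effect shared by all genes of a sample
  (RNA input / RT efficiency), which is what the per-sample centering of
  geNorm/NormFinder removes and what gives BestKeeper its index
  correlation structure;
* group shift — condition x time x region specific regulation in cycles
  (a fold change F corresponds to -log2(F) cycles at efficiency 2);
* technical noise — per-gene Gaussian noise, optionally scaled per region
  (the ischaemic core is uniformly noisier than periinfarct tissue).

Realized values are truncated to the instrument-plausible (10, 40) cycle
window; truncation is logged if it ever triggers.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .io import CONDITIONS, DEFAULT_GENES, REGIONS, TIME_POINTS, CtMatrix

logger = logging.getLogger("refstab")

CT_TRUNC = (10.0, 40.0)

#: Typical quantification cycles for the six-gene rat brain panel.
DEFAULT_BASELINES = {
    "Ywhaz": 22.5, "Ppia": 20.5, "Gapdh": 19.0,
    "Hprt1": 24.0, "Actb": 18.0, "B2m": 22.0,
}

#: Per-gene technical noise SD in cycles.
DEFAULT_GENE_NOISE = {
    "Ywhaz": 0.22, "Ppia": 0.20, "Gapdh": 0.40,
    "Hprt1": 0.22, "Actb": 0.30, "B2m": 0.35,
}


def fold_to_shift(fold: float) -> float:
    """Ct shift (cycles) for an expression fold change at efficiency 2.

    Increased expression means fewer cycles: shift = -log2(fold).
    """
    if fold <= 0:
        raise ValueError("fold change must be positive")
    return -float(np.log2(fold))


@dataclass(frozen=True)
class Effect:
    """A condition/time/region-specific expression shift for one gene."""

    gene: str
    condition: str
    time_points: tuple[str, ...]
    regions: tuple[str, ...]
    shift: float  # cycles; negative = increased expression

    def applies(self, condition: str, time_point: str, region: str) -> bool:
        return (self.condition == condition
                and time_point in self.time_points
                and region in self.regions)


@dataclass(frozen=True)
class SimulationDesign:
    """Full parameterization of a synthetic tMCAO Ct experiment."""

    baselines: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    gene_noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_GENE_NOISE))
    loading_sd: float = 0.3
    effects: tuple = ()
    n_per_group: int = 8
    regions: tuple = REGIONS
    time_points: tuple = TIME_POINTS
    conditions: tuple = CONDITIONS
    region_noise_scale: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.baselines) != set(self.gene_noise_sd):
            raise ValueError("baselines and gene_noise_sd must cover the same genes")
        for g, b in self.baselines.items():
            if not 10.0 < b < 40.0:
                raise ValueError(f"baseline Ct for {g} must lie in (10, 40), got {b}")
        if any(sd < 0 for sd in self.gene_noise_sd.values()) or self.loading_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.n_per_group < 2:
            raise ValueError("need n >= 2 per condition x time group")
        for eff in self.effects:
            if eff.gene not in self.baselines:
                raise ValueError(f"effect on unknown gene {eff.gene!r}")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.baselines)

    def noise_scale(self, region: str) -> float:
        return float(self.region_noise_scale.get(region, 1.0))

    def with_seed(self, seed: int) -> "SimulationDesign":
        return replace(self, seed=int(seed))

    # -- YAML round-trip ---------------------------------------------------
    def to_yaml(self, path=None) -> str:
        payload = asdict(self)
        payload["effects"] = [asdict(e) for e in self.effects]
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "SimulationDesign":
        if hasattr(source, "read") or "\n" not in str(source):
            try:
                with open(source) as fh:  # type: ignore[arg-type]
                    payload = yaml.safe_load(fh)
            except (OSError, TypeError):
                payload = yaml.safe_load(source)
        else:
            payload = yaml.safe_load(source)
        payload["effects"] = tuple(
            Effect(**{**e, "time_points": tuple(e["time_points"]),
                      "regions": tuple(e["regions"])})
            for e in payload.get("effects", ())
        )
        for key in ("regions", "time_points", "conditions"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


def simulate(design: SimulationDesign, seed: int | None = None) -> CtMatrix:
    """Draw a complete synthetic study (deterministic for a fixed seed).

    One row per animal x region; ``n_per_group`` animals per condition x
    time group in every region, so the default design yields
    2 x 4 x 3 x 8 = 192 samples.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    genes = list(design.genes)
    rows, meta_rows, ids = [], [], []
    truncated = 0
    for region in design.regions:
        scale = design.noise_scale(region)
        for tp in design.time_points:
            for cond in design.conditions:
                shifts = np.zeros(len(genes))
                for eff in design.effects:
                    if eff.applies(cond, tp, region):
                        shifts[genes.index(eff.gene)] += eff.shift
                base = np.array([design.baselines[g] for g in genes])
                noise_sd = np.array([design.gene_noise_sd[g] for g in genes]) * scale
                n = design.n_per_group
                loading = rng.normal(0.0, design.loading_sd, size=(n, 1))
                noise = rng.normal(0.0, 1.0, size=(n, len(genes))) * noise_sd
                ct = base + shifts + loading + noise
                clipped = np.clip(ct, *CT_TRUNC)
                truncated += int((clipped != ct).sum())
                rows.append(clipped)
                for i in range(n):
                    ids.append(f"{region}_{tp}_{cond}_{i + 1:02d}")
                    meta_rows.append((cond, tp, region))
    if truncated:
        logger.warning("simulate: %d Ct value(s) truncated to %s", truncated, CT_TRUNC)
    ct = pd.DataFrame(np.vstack(rows), index=pd.Index(ids, name="sample_id"),
                      columns=genes)
    meta = pd.DataFrame(meta_rows, index=ct.index,
                        columns=["condition", "time_point", "region"])
    return CtMatrix(ct=ct, meta=meta)


def tmcao_preset(seed: int = 0) -> SimulationDesign:
    """Design encoding the destabilization pattern reported after tMCAO.

    Ppia, Hprt1 and Ywhaz carry no injected shift anywhere.  Actb is
    up-regulated ~5-fold in cortex and striatum at the delayed time points
    (3 and 7 days); B2m ~7-fold at the same delayed time points in cortex
    and, reflecting the striatum's position in the ischaemic core, at every
    time point there; Gapdh rises moderately at late cortical time points
    and is strongly destabilized in the striatum at 24 h.  The striatum
    additionally carries a global 1.75x technical-noise scale — tissue from
    the infarct core is uniformly harder to measure.
    """
    delayed = ("3d", "7d")
    effects = (
        Effect("Actb", "tMCAO", delayed, ("CX", "DS"), fold_to_shift(5.0)),
        Effect("B2m", "tMCAO", delayed, ("CX",), fold_to_shift(7.07)),
        Effect("B2m", "tMCAO", TIME_POINTS, ("DS",), fold_to_shift(7.07)),
        Effect("Gapdh", "tMCAO", delayed, ("CX",), fold_to_shift(1.74)),
        Effect("Gapdh", "tMCAO", ("24h",), ("DS",), fold_to_shift(2.83)),
    )
    return SimulationDesign(
        effects=effects,
        region_noise_scale={"DS": 1.75},
        seed=seed,
    )


#: Genes the preset never perturbs (the expected stable trio).
PRESET_STABLE_GENES = ("Ppia", "Hprt1", "Ywhaz")
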