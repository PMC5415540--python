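"""Synthetic mountain-lake districts and metacommunities.

The generator emulates the statistical structure that the analysis chain
assumes, so that every stage can be exercised against known ground truth:

* a district of lakes spanning a bounded altitudinal gradient (defaults:
  82 lakes between 1,620 and 2,990 m a.s.l.), with lake density either
  uniform or concentrated at mid elevations (a symmetric Beta profile),
  as is typical of glacial lake districts;
* environmental variables constructed as noisy monotone functions of
  altitude, with per-variable correlation, noise and measurement kind
  (concentration variables get a skewed positive scale, percentages a
  logistic squash, pH an affine map, fish presence a threshold);
* species of three archetypes — *filtered* (occurrence follows a Gaussian
  altitudinal niche), *range_cohesive* (all lakes inside a random
  altitudinal window, the classic mid-domain construction of overlapping
  cohesive ranges between hard boundaries), and *neutral* (a uniformly
  random k-subset of lakes, independent of altitude).

Filtered species are conditioned on an exact target occupancy k by
weighted sampling without replacement, so the range null's conditioning
on k is honored by construction.  Abundances on occupied lakes are drawn
from a geometric law (skewed, many singletons) — they matter only to the
Hellinger-transformed analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .community import CommunityMatrix, SiteTable


@dataclass
class EnvVarSpec:
    """Recipe for one synthetic environmental variable.

    The latent signal is ``rho * z + noise_sd * eps`` with z the
    standardized altitude; ``noise_sd`` defaults to sqrt(1 - rho^2) so the
    latent has unit variance and correlation ``rho`` with altitude.
    """

    name: str
    kind: str  # {concentration, percentage, ph, nominal}
    correlation: float
    noise_sd: float | None = None
    loc: float = 0.0
    scale: float = 1.0

    def latent_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        return float(np.sqrt(max(1.0 - self.correlation**2, 0.0)))


def default_env_spec() -> list[EnvVarSpec]:
    """A small bank of variables with altitude collinearity typical of
    mountain-lake surveys: temperature and solutes decline or rise with
    altitude; habitat percentages and fish occurrence track it loosely."""
    return [
        EnvVarSpec("temperature", "ph", correlation=-0.85, loc=9.0, scale=3.0),
        EnvVarSpec("calcium", "concentration", correlation=-0.4, loc=0.5, scale=0.9),
        EnvVarSpec("doc", "concentration", correlation=-0.5, loc=-0.3, scale=0.8),
        EnvVarSpec("nitrate", "concentration", correlation=0.45, loc=-1.0, scale=0.7),
        EnvVarSpec("conductivity", "concentration", correlation=-0.35, loc=2.5, scale=0.6),
        EnvVarSpec("ph", "ph", correlation=-0.3, loc=6.8, scale=0.6),
        EnvVarSpec("fine_substrate", "percentage", correlation=-0.55, loc=0.0, scale=1.2),
        EnvVarSpec("macrophytes", "percentage", correlation=-0.6, loc=-1.0, scale=1.5),
        EnvVarSpec("salmonids", "nominal", correlation=-0.4),
        EnvVarSpec("loi", "concentration", correlation=-0.45, loc=1.5, scale=0.5),
    ]


@dataclass
class DistrictConfig:
    n_lakes: int = 82
    alt_min: float = 1620.0
    alt_max: float = 2990.0
    density: str = "mid_concentrated"  # or "uniform"
    concentration: float = 2.0  # Beta(c, c) shape for mid_concentrated
    env_spec: list[EnvVarSpec] = field(default_factory=default_env_spec)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.alt_min >= self.alt_max:
            raise ValueError("alt_min must be below alt_max")
        if self.n_lakes < 10:
            raise ValueError("need at least 10 lakes")
        if self.density not in {"uniform", "mid_concentrated"}:
            raise ValueError(f"unknown density {self.density!r}")
        for v in self.env_spec:
            if not -1.0 <= v.correlation <= 1.0:
                raise ValueError(f"correlation out of [-1, 1] for {v.name!r}")


@dataclass
class SpeciesArchetype:
    """A block of species sharing a generating mechanism.

    ``occupancy`` bounds the uniform draw of the target occupancy k for
    filtered and neutral species; range_cohesive species instead draw a
    window width (m) uniformly from ``range_width`` and occupy every lake
    inside a uniformly placed window, so their occupancy is emergent.
    """

    kind: str  # {filtered, range_cohesive, neutral}
    n_species: int
    occupancy: tuple[int, int] = (4, 40)
    niche_mu: float | None = None  # filtered: fixed optimum; None = random
    niche_sigma: float = 150.0
    range_width: tuple[float, float] = (200.0, 900.0)

    def __post_init__(self) -> None:
        if self.kind not in {"filtered", "range_cohesive", "neutral"}:
            raise ValueError(f"unknown archetype kind {self.kind!r}")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.kind == "filtered" and self.niche_sigma <= 0:
            raise ValueError("niche_sigma must be positive")


def generate_lakes(cfg: DistrictConfig, rng: np.random.Generator | None = None) -> SiteTable:
    """Sample a lake district: altitudes plus environmental variables."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    span = cfg.alt_max - cfg.alt_min
    if cfg.density == "uniform":
        u = rng.random(cfg.n_lakes)
    else:
        u = rng.beta(cfg.concentration, cfg.concentration, cfg.n_lakes)
    alt = cfg.alt_min + span * u
    z = (alt - alt.mean()) / alt.std(ddof=0) if alt.std(ddof=0) > 0 else np.zeros_like(alt)
    data = {"altitude": alt}
    var_kind: dict[str, str] = {}
    for v in cfg.env_spec:
        latent = v.correlation * z + v.latent_noise_sd() * rng.standard_normal(cfg.n_lakes)
        if v.kind == "concentration":
            vals = np.exp(v.loc + v.scale * latent)
        elif v.kind == "percentage":
            vals = 100.0 / (1.0 + np.exp(-(v.loc + v.scale * latent)))
        elif v.kind == "ph":
            vals = v.loc + v.scale * latent
        elif v.kind == "nominal":
            vals = (latent > 0).astype(float)
        else:
            raise ValueError(f"unknown variable kind {v.kind!r}")
        data[v.name] = vals
        var_kind[v.name] = v.kind
    ids = [f"L{i + 1:03d}" for i in range(cfg.n_lakes)]
    return SiteTable(pd.DataFrame(data, index=pd.Index(ids, name="site_id")), var_kind=var_kind)


def _geometric_abundance(rng: np.random.Generator, size: int, mean: float) -> np.ndarray:
    return rng.geometric(p=1.0 / max(mean, 1.0), size=size)


def generate_species(
    archetypes: list[SpeciesArchetype],
    sites: SiteTable,
    seed: int | np.random.Generator | None = None,
    group: str = "synthetic",
    mean_abundance: float = 3.0,
) -> tuple[CommunityMatrix, pd.DataFrame]:
    """Generate a community matrix and its ground-truth table.

    The truth table records, per species, the archetype and the generating
    parameters (niche optimum/breadth, window bounds, target occupancy).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alt = sites.altitude.to_numpy(dtype=float)
    n = alt.size
    counts = {}
    truth_rows = []
    idx = 0
    for arch in archetypes:
        lo_k, hi_k = arch.occupancy
        if arch.kind in {"filtered", "neutral"} and hi_k > n:
            raise ValueError(f"target occupancy up to {hi_k} infeasible with {n} lakes")
        for _ in range(arch.n_species):
            idx += 1
            name = f"sp{idx:03d}_{arch.kind}"
            mu = sigma = wlo = whi = np.nan
            k_target = np.nan
            if arch.kind == "filtered":
                mu = arch.niche_mu if arch.niche_mu is not None else float(
                    rng.uniform(alt.min(), alt.max()))
                sigma = arch.niche_sigma
                k = int(rng.integers(lo_k, hi_k + 1))
                w = np.exp(-((alt - mu) ** 2) / (2 * sigma**2))
                w = np.maximum(w, 1e-300)
                occ_idx = rng.choice(n, size=k, replace=False, p=w / w.sum())
                k_target = k
            elif arch.kind == "neutral":
                k = int(rng.integers(lo_k, hi_k + 1))
                occ_idx = rng.choice(n, size=k, replace=False)
                k_target = k
            else:  # range_cohesive
                width = float(rng.uniform(*arch.range_width))
                wlo = float(rng.uniform(alt.min(), max(alt.max() - width, alt.min())))
                whi = wlo + width
                occ_idx = np.flatnonzero((alt >= wlo) & (alt <= whi))
            col = np.zeros(n, dtype=np.int64)
            if occ_idx.size:
                col[occ_idx] = _geometric_abundance(rng, occ_idx.size, mean_abundance)
            counts[name] = col
            truth_rows.append((name, arch.kind, mu, sigma, wlo, whi, k_target))
    cm = CommunityMatrix(group, pd.DataFrame(counts, index=sites.data.index))
    truth = pd.DataFrame(
        truth_rows,
        columns=["species", "kind", "niche_mu", "niche_sigma", "window_lo", "window_hi", "target_k"],
    )
    return cm, truth


def make_fixture_bundle(out_dir, seed: int = 0) -> dict[str, Path]:
    """Write a small fixed district (12 lakes, 3 groups x 8 species).

    Deterministic for a given seed: the same seed writes byte-identical
    files.  Returns the paths keyed by ``sites`` and each group name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    cfg = DistrictConfig(n_lakes=12, env_spec=default_env_spec()[:4])
    sites = generate_lakes(cfg, rng)
    paths: dict[str, Path] = {"sites": out / "sites.csv"}
    sites.to_csv(paths["sites"])
    specs = {
        "groupA": SpeciesArchetype("filtered", 8, occupancy=(4, 9), niche_sigma=250.0),
        "groupB": SpeciesArchetype("range_cohesive", 8, range_width=(300.0, 900.0)),
        "groupC": SpeciesArchetype("neutral", 8, occupancy=(4, 9)),
    }
    for gname, arch in specs.items():
        cm, _ = generate_species([arch], sites, seed=rng, group=gname)
        paths[gname] = out / f"community_{gname}.csv"
        cm.to_csv(paths[gname])
    return paths
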