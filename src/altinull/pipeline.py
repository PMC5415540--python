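"""End-to-end orchestration of the altitudinal null-model analysis.

Runs, per taxonomic group: occupancy filter -> altitudinal bias tests ->
range-randomization null with narrow-ranging calls -> between-group exact
contrasts -> Hellinger RDA with forward selection and altitude vector
fitting -> linear/quadratic richness models under AICc.  All tables are
returned in a :class:`ReportBundle` and optionally written as CSV.

Reproducibility: a single run seed is declared in the config; each stage
draws from its own substream derived from (seed, stage-name hash), so
re-running any stage in isolation reproduces its output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bias as bias_mod
from . import ordination as ord_mod
from . import range_null as rn_mod
from . import richness as rich_mod
from .community import (CommunityMatrix, SiteTable, filter_by_occupancy,
                        load_community_matrix, load_site_table, to_presence_absence)


@dataclass
class RunConfig:
    site_csv: str | None = None
    community_csvs: dict[str, str] = field(default_factory=dict)  # group -> path
    var_kind: dict[str, str] = field(default_factory=dict)
    zero_substitutes: dict[str, float] = field(default_factory=dict)
    min_sites: int = 4
    alpha: float = 0.05
    n_perm: int = 9999
    n_rep: int = 9999
    seed: int = 0
    response_mode: str = "abundance"  # or "presence"
    ks_variant: str = "lilliefors"
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 99 or self.n_rep < 99:
            raise ValueError("n_perm and n_rep must be >= 99")
        if self.response_mode not in {"abundance", "presence"}:
            raise ValueError(f"unknown response_mode {self.response_mode!r}")


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage substream: seed plus a stage-name hash."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode()) & 0x7FFFFFFF])
    )


@dataclass
class GroupReport:
    group: str
    filtered: CommunityMatrix
    summary: pd.DataFrame       # species, k, mean_alt, range_alt
    mean_span: float
    bias_table: pd.DataFrame    # species, t, df, p, biased, direction, testable
    narrow_table: pd.DataFrame  # species, k, range_alt, null_lower, null_upper, narrow
    selection_trace: pd.DataFrame
    global_adj_r2: float
    global_p: float
    vector_fit: pd.DataFrame    # variable, r2, perm_p
    richness_table: pd.DataFrame


@dataclass
class ReportBundle:
    groups: dict[str, GroupReport]
    contrasts: pd.DataFrame
    bias_direction_summary: dict


@dataclass
class BiasDirectionSummary:
    defined: bool
    proportion_low: float | None
    n_low: int
    n_biased: int


def summarize_bias_directions(bias_tables: list[pd.DataFrame]) -> BiasDirectionSummary:
    """Fraction of biased species shifted toward low altitude, pooled over groups."""
    biased = pd.concat(bias_tables, ignore_index=True)
    biased = biased[biased["biased"]]
    n_biased = int(len(biased))
    n_low = int((biased["direction"] == "low").sum())
    if n_biased == 0:
        return BiasDirectionSummary(False, None, 0, 0)
    return BiasDirectionSummary(True, n_low / n_biased, n_low, n_biased)


def analyze_group(
    group: str,
    cm: CommunityMatrix,
    sites: SiteTable,
    env_transformed: SiteTable,
    cfg: RunConfig,
) -> GroupReport:
    cm = cm.align_to(sites)
    filtered, _report = filter_by_occupancy(cm, cfg.min_sites)

    summaries = rn_mod.species_altitude_summary(filtered, sites)
    summary_df = rn_mod.summaries_to_frame(summaries)
    mean_span = rn_mod.group_mean_span(summaries) if summaries else float("nan")

    bias_table = bias_mod.bias_test_table(filtered, sites, alpha=cfg.alpha)

    alt = sites.altitude.to_numpy(dtype=float)
    calls = rn_mod.classify_narrow_ranging(
        summaries, alt, n_rep=cfg.n_rep, alpha=cfg.alpha,
        seed=stage_rng(cfg.seed, f"range_null:{group}"),
    )
    narrow_table = summary_df.merge(
        pd.DataFrame(
            [(c.species, c.null_lower, c.narrow) for c in calls],
            columns=["species", "null_lower", "narrow"],
        ),
        on="species", how="left",
    )

    # ordination: Hellinger-transformed (or presence) response on selected predictors
    response = filtered if cfg.response_mode == "abundance" else to_presence_absence(filtered)
    Y = ord_mod.hellinger(response)
    candidates = env_transformed.env
    candidates = candidates.loc[:, candidates.std(ddof=1) > 0]  # constant vars carry no signal
    rng_sel = stage_rng(cfg.seed, f"forward_select:{group}")
    if candidates.shape[1]:
        trace = ord_mod.forward_select(Y, candidates, alpha=cfg.alpha,
                                       n_perm=cfg.n_perm, seed=rng_sel)
    else:
        trace = ord_mod.SelectionTrace(stop_reason="exhausted")
    if trace.selected:
        fit = ord_mod.rda(Y, candidates[trace.selected].to_numpy(dtype=float))
        axes = fit.site_scores[:, : max(1, min(2, fit.site_scores.shape[1]))]
        vf = ord_mod.fit_vector(
            axes, alt, name="altitude", n_perm=cfg.n_perm,
            seed=stage_rng(cfg.seed, f"envfit:{group}"),
        )
        vector_fit = pd.DataFrame(
            [("altitude", vf.squared_correlation, vf.perm_p)], columns=["variable", "r2", "perm_p"]
        )
    else:
        vector_fit = pd.DataFrame(columns=["variable", "r2", "perm_p"])

    richness = rich_mod.species_richness(filtered)
    lin = rich_mod.fit_polynomial_richness(richness, alt, 1)
    quad = rich_mod.fit_polynomial_richness(richness, alt, 2)
    pair = rich_mod.compare_models(lin, quad, altitude_range=(alt.min(), alt.max()))

    return GroupReport(
        group=group,
        filtered=filtered,
        summary=summary_df,
        mean_span=mean_span,
        bias_table=bias_table,
        narrow_table=narrow_table,
        selection_trace=trace.to_frame(),
        global_adj_r2=trace.global_adj_r2,
        global_p=trace.global_p,
        vector_fit=vector_fit,
        richness_table=rich_mod.richness_model_table(pair, group),
    )


def run_full_analysis(
    cfg: RunConfig,
    sites: SiteTable | None = None,
    communities: dict[str, CommunityMatrix] | None = None,
) -> ReportBundle:
    """Execute the whole chain; inputs may be passed in memory or by path."""
    if sites is None:
        if cfg.site_csv is None:
            raise ValueError("no site table: set site_csv or pass sites")
        sites = load_site_table(cfg.site_csv, cfg.var_kind)
    if communities is None:
        communities = {
            g: load_community_matrix(p, group=g) for g, p in cfg.community_csvs.items()
        }
    if not communities:
        raise ValueError("no community matrices supplied")

    rules = ord_mod.infer_transform_rules(
        sites, alpha=cfg.alpha, variant=cfg.ks_variant, zero_substitutes=cfg.zero_substitutes
    )
    env_t = ord_mod.transform_env(sites, rules)

    reports = {
        g: analyze_group(g, cm, sites, env_t, cfg) for g, cm in communities.items()
    }

    bias_counts = [
        (g, int(r.bias_table["biased"].sum()), int(len(r.bias_table)))
        for g, r in reports.items()
    ]
    narrow_counts = [
        (g, int(r.narrow_table["narrow"].sum()), int(len(r.narrow_table)))
        for g, r in reports.items()
    ]
    frames = []
    if len(reports) >= 2:
        frames.append(bias_mod.contrasts_to_frame(
            bias_mod.compare_group_proportions(bias_counts), "biased"))
        frames.append(bias_mod.contrasts_to_frame(
            bias_mod.compare_group_proportions(narrow_counts), "narrow"))
    contrasts = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["group_a", "group_b", "metric", "a_hits", "a_total", "b_hits", "b_total", "p"]
    )

    direction = summarize_bias_directions([r.bias_table for r in reports.values()])
    bundle = ReportBundle(
        groups=reports,
        contrasts=contrasts,
        bias_direction_summary={
            "defined": direction.defined,
            "proportion_low": direction.proportion_low,
            "n_low": direction.n_low,
            "n_biased": direction.n_biased,
        },
    )
    if cfg.out_dir:
        write_bundle(bundle, cfg.out_dir)
    return bundle


def write_bundle(bundle: ReportBundle, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for g, r in bundle.groups.items():
        r.bias_table.assign(group=g).to_csv(out / f"bias_{g}.csv", index=False)
        r.narrow_table.assign(group=g).to_csv(out / f"narrow_{g}.csv", index=False)
        r.selection_trace.assign(group=g).to_csv(out / f"selection_{g}.csv", index=False)
        r.vector_fit.to_csv(out / f"vectorfit_{g}.csv", index=False)
        r.richness_table.to_csv(out / f"richness_{g}.csv", index=False)
    bundle.contrasts.to_csv(out / "contrasts.csv", index=False)
    pd.DataFrame([bundle.bias_direction_summary]).to_csv(out / "bias_directions.csv", index=False)
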