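"""End-to-end orchestration: simulate -> build-index -> rates -> associate -> model.

The analysis is a fixed linear chain, so the pipeline is a sequence of stage
functions that read and write delimited text tables under a run directory.
Each stage records a JSON manifest (parameters, SHA-256 of inputs, package
version, seed) so a run is auditable; re-running with the same configuration
and seed reproduces every output byte for byte.  A failing stage leaves a
``FAILED`` marker naming itself and keeps any partial outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .indicators import DOMAINS
from .index import QuintileAssignment, build_index, domain_quintiles, weighted_quintiles
from .models import fit_polynomial, mortality_chi_square, residuals_by_remoteness
from .association import crosstab_shares, gradient_tests, quintile_summary, weighted_pearson
from .rates import StandardPopulation, mean_annual_pph_rate, quintile_death_rates
from .synthetic import SimulationConfig, generate, write_dataset

logger = logging.getLogger(__name__)

STAGES = ("simulate", "build-index", "rates", "associate", "model")

BASES = ("cse_index",) + tuple(DOMAINS)


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    simulate: dict = field(default_factory=dict)
    min_children: int = 30
    max_nonresponse: float = 0.80
    alpha: float = 0.05
    standard_shares: dict = field(
        default_factory=lambda: {"0-4": 0.34, "5-9": 0.33, "10-14": 0.33}
    )
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        raw["outdir"] = Path(raw["outdir"])
        stages = {s: True for s in STAGES}
        stages.update(raw.get("stages", {}))
        raw["stages"] = stages
        return cls(**raw)

    def standard_population(self) -> StandardPopulation:
        return StandardPopulation(shares=self.standard_shares, label="configured standard")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, stage: str, params: dict, inputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "version": __version__,
        "params": params,
        "inputs": {str(p): _sha256(p) for p in inputs},
    }
    (outdir / f"manifest_{stage.replace('-', '_')}.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )


def stage_simulate(cfg: RunConfig) -> None:
    data_dir = cfg.outdir / "data"
    sim = SimulationConfig(**{**cfg.simulate, "seed": cfg.seed})
    ds = generate(sim)
    write_dataset(ds, data_dir)
    _write_manifest(cfg.outdir, "simulate", dataclasses.asdict(sim), [])
    logger.info("simulated %d areas into %s", sim.n_areas, data_dir)


def stage_build_index(cfg: RunConfig) -> None:
    data_dir = cfg.outdir / "data"
    areas_p = data_dir / "areas.csv"
    ind_p = data_dir / "indicators.csv"
    areas = pd.read_csv(areas_p)
    indicators = pd.read_csv(ind_p)
    result = build_index(areas, indicators, cfg.min_children, cfg.max_nonresponse)
    logger.info(
        "index built: %d areas included, %d excluded",
        len(result.table),
        len(result.excluded),
    )
    result.table.reset_index().to_csv(cfg.outdir / "index.csv", index=False)
    result.excluded.to_csv(cfg.outdir / "excluded_areas.csv", index=False)
    _write_manifest(
        cfg.outdir,
        "build-index",
        {"min_children": cfg.min_children, "max_nonresponse": cfg.max_nonresponse},
        [areas_p, ind_p],
    )


def stage_rates(cfg: RunConfig) -> None:
    data_dir = cfg.outdir / "data"
    events_p = data_dir / "pph_counts.csv"
    pops_p = data_dir / "age_populations.csv"
    index_p = cfg.outdir / "index.csv"
    events = pd.read_csv(events_p)
    june_pops = pd.read_csv(pops_p)
    included = pd.read_csv(index_p)["area_id"]
    events = events[events["area_id"].isin(included)]
    june_pops = june_pops[june_pops["area_id"].isin(included)]

    labels = sorted(events["year"].unique())
    year_bounds = {lab: (int(lab.split("-")[0]), int(lab.split("-")[0]) + 1) for lab in labels}
    rate_table = mean_annual_pph_rate(events, june_pops, year_bounds, cfg.standard_population())
    rate_table.to_csv(cfg.outdir / "pph_rates.csv", index=False)
    _write_manifest(
        cfg.outdir,
        "rates",
        {"years": labels, "standard_shares": cfg.standard_shares},
        [events_p, pops_p, index_p],
    )


def _load_quintile_inputs(cfg: RunConfig):
    index = pd.read_csv(cfg.outdir / "index.csv").set_index("area_id")
    rates = pd.read_csv(cfg.outdir / "pph_rates.csv").set_index("area_id")["rate"]
    areas = pd.read_csv(cfg.outdir / "data" / "areas.csv").set_index("area_id")
    weights = areas.loc[index.index, "child_pop_0_15"]
    return index, rates.reindex(index.index), areas, weights


def _basis_quintiles(index: pd.DataFrame, weights: pd.Series) -> dict[str, QuintileAssignment]:
    out = {"cse_index": weighted_quintiles(index["composite"], weights, "cse_index")}
    for domain in DOMAINS:
        out[domain] = weighted_quintiles(index[f"X_{domain}"], weights, domain)
    return out


def stage_associate(cfg: RunConfig) -> None:
    index, rates, areas, weights = _load_quintile_inputs(cfg)
    qas = _basis_quintiles(index, weights)
    pph_q = weighted_quintiles(rates, weights, "pph_rate")

    correlations = {
        name: weighted_pearson(
            index["composite" if name == "cse_index" else f"X_{name}"], rates, weights
        )
        for name in qas
    }
    pd.DataFrame(
        {"basis": list(correlations), "weighted_pearson_r": list(correlations.values())}
    ).to_csv(cfg.outdir / "correlations.csv", index=False)

    rows = []
    for name, qa in qas.items():
        ct = crosstab_shares(pph_q, qa, weights)
        ct.shares.round(6).to_csv(cfg.outdir / f"crosstab_{name.replace(' ', '_')}.csv")
        rows.append(
            {
                "basis": name,
                "diagonal_pct": ct.diagonal_pct,
                "diagonal_adjacent_pct": ct.diagonal_adjacent_pct,
            }
        )
    pd.DataFrame(rows).to_csv(cfg.outdir / "crosstab_diagonals.csv", index=False)

    qs = quintile_summary(rates, qas["cse_index"])
    qs.to_csv(cfg.outdir / "pph_quintile_summary.csv", index=False)
    gt = gradient_tests(rates, qas["cse_index"])
    gradient = {
        "anova_F": gt.anova[0],
        "anova_df_between": gt.anova[1],
        "anova_df_within": gt.anova[2],
        "anova_p": gt.anova[3],
        "kruskal_chi2": gt.kruskal_wallis[0],
        "kruskal_df": gt.kruskal_wallis[1],
        "kruskal_p": gt.kruskal_wallis[2],
        "welch": {f"{a}v{b}": list(v) for (a, b), v in gt.welch_pairs.items()},
    }
    (cfg.outdir / "gradient_tests.json").write_text(json.dumps(gradient, indent=2, sort_keys=True))
    _write_manifest(
        cfg.outdir,
        "associate",
        {},
        [cfg.outdir / "index.csv", cfg.outdir / "pph_rates.csv"],
    )


def stage_model(cfg: RunConfig) -> None:
    index, rates, areas, weights = _load_quintile_inputs(cfg)
    qas = _basis_quintiles(index, weights)

    fit = fit_polynomial(index["composite"], rates, alpha=cfg.alpha)
    fit_summary = {
        "terms": list(fit.terms),
        "coefficients": fit.coefficients,
        "p_values": fit.p_values,
        "r_squared": fit.r_squared,
    }
    (cfg.outdir / "fit_summary.json").write_text(json.dumps(fit_summary, indent=2, sort_keys=True))
    fit.residuals.rename("residual").reset_index().rename(
        columns={"index": "area_id"}
    ).to_csv(cfg.outdir / "residuals.csv", index=False)

    rt = residuals_by_remoteness(fit.residuals, areas.loc[index.index, "remoteness"])
    rt.summary.to_csv(cfg.outdir / "residuals_by_remoteness.csv", index=False)
    rt.tukey.to_csv(cfg.outdir / "tukey_remoteness.csv", index=False)

    deaths_df = pd.read_csv(cfg.outdir / "data" / "death_counts.csv")
    first_year = deaths_df["year"].min()
    deaths = (
        deaths_df[deaths_df["year"] == first_year].set_index("area_id")["count"]
    ).reindex(index.index, fill_value=0)
    june_pops = pd.read_csv(cfg.outdir / "data" / "age_populations.csv")
    pops_0_14 = (
        june_pops[june_pops["june_year"] == first_year]
        .groupby("area_id")["pop"]
        .sum()
        .reindex(index.index)
    )
    pops_0_15 = areas.loc[index.index, "child_pop_0_15"]

    contingency_rows = []
    for name, qa in qas.items():
        qdr = quintile_death_rates(deaths, pops_0_14, qa, pops_0_15)
        res = mortality_chi_square(
            qdr["est_deaths_rounded"].to_numpy(), qdr["pop_0_15"].to_numpy()
        )
        for _, row in qdr.iterrows():
            contingency_rows.append(
                {
                    "basis": name,
                    "quintile": int(row["quintile"]),
                    "est_deaths": int(row["est_deaths_rounded"]),
                    "population_0_15": int(row["pop_0_15"]),
                    "chi2": res.chi2,
                    "df": res.df,
                    "p": res.p,
                }
            )
    pd.DataFrame(contingency_rows).to_csv(cfg.outdir / "mortality_contingency.csv", index=False)
    _write_manifest(
        cfg.outdir,
        "model",
        {"alpha": cfg.alpha, "death_year": int(first_year)},
        [cfg.outdir / "index.csv", cfg.outdir / "pph_rates.csv"],
    )
    _write_report(cfg)


def _write_report(cfg: RunConfig) -> None:
    lines = ["CSE index / child-health association report", "=" * 44, ""]
    diag = pd.read_csv(cfg.outdir / "crosstab_diagonals.csv")
    corr = pd.read_csv(cfg.outdir / "correlations.csv")
    lines += ["Weighted Pearson correlations (index/domain vs PPH rate):"]
    lines += [corr.to_string(index=False), ""]
    for name in diag["basis"]:
        fname = cfg.outdir / f"crosstab_{str(name).replace(' ', '_')}.csv"
        ct = pd.read_csv(fname, index_col=0)
        row = diag[diag["basis"] == name].iloc[0]
        lines += [
            f"Cross-tab: PPH quintile by {name} quintile (% of children)",
            ct.round(1).to_string(),
            f"Diagonal: {row['diagonal_pct']:.1f}%; "
            f"diagonal + adjacent: {row['diagonal_adjacent_pct']:.1f}%",
            "",
        ]
    qs = pd.read_csv(cfg.outdir / "pph_quintile_summary.csv")
    lines += ["PPH rates by composite-index quintile:", qs.round(2).to_string(index=False), ""]
    rr = pd.read_csv(cfg.outdir / "residuals_by_remoteness.csv")
    lines += ["Residual PPH rate by remoteness:", rr.round(2).to_string(index=False), ""]
    mc = pd.read_csv(cfg.outdir / "mortality_contingency.csv")
    for name, grp in mc.groupby("basis", sort=False):
        lines += [
            f"Avoidable-death contingency, {name} quintiles "
            f"(chi2 = {grp['chi2'].iloc[0]:.1f}, df = {int(grp['df'].iloc[0])}, "
            f"p = {grp['p'].iloc[0]:.3g})",
            grp[["quintile", "est_deaths", "population_0_15"]].to_string(index=False),
            "",
        ]
    (cfg.outdir / "report.txt").write_text("\n".join(lines))


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "build-index": stage_build_index,
    "rates": stage_rates,
    "associate": stage_associate,
    "model": stage_model,
}

_STAGE_OUTPUTS = {
    "simulate": ["data/areas.csv"],
    "build-index": ["index.csv"],
    "rates": ["pph_rates.csv"],
    "associate": ["crosstab_diagonals.csv"],
    "model": ["mortality_contingency.csv", "report.txt"],
}


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the enabled stages in dependency order; returns the run directory."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    marker = cfg.outdir / "FAILED"
    if marker.exists():
        marker.unlink()
    for stage in STAGES:
        enabled = cfg.stages.get(stage, True)
        outputs = [cfg.outdir / p for p in _STAGE_OUTPUTS[stage]]
        if not enabled:
            if all(p.exists() for p in outputs):
                logger.info("stage %s disabled; reusing existing outputs", stage)
                continue
            raise RuntimeError(
                f"stage {stage!r} is disabled but its outputs are missing"
            )
        try:
            _STAGE_FUNCS[stage](cfg)
        except Exception as exc:
            marker.write_text(f"stage {stage} failed: {exc}\n")
            raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return cfg.outdir
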