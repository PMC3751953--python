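"""Pipeline orchestration: run the full demographic analysis from one config.

Stages (each writes CSV outputs with a provenance header and can be toggled):
``simulate`` (or load an input table) -> ``validate_ageing`` -> ``growth`` ->
``alk`` -> ``mortality`` -> ``popstats``. Outputs are deterministic given the
configured seeds; a failure in one stage leaves earlier outputs intact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ageing, alk as alk_mod, growth, mortality, popstats
from .records import read_fish_table, write_fish_table
from .simulate import (PopulationConfig, simulate_population,
                       simulate_double_reads, simulate_otc_experiment,
                       simulate_seasonal_otolith_state)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("fishdemog")

# alk precedes growth so key-assigned ages can feed the growth/mortality stages
ALL_STAGES = ("simulate", "validate_ageing", "alk", "growth", "mortality", "popstats")


class PipelineError(RuntimeError):
    """A stage precondition failed; message names the stage and a remedy."""


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    Exactly one of ``input_path`` (a fish-table CSV) or ``simulation`` (a
    :class:`PopulationConfig`) must be given.
    """

    input_path: str | None = None
    input_dialect: str = "mkt"
    simulation: PopulationConfig | None = None
    outdir: str = "fishdemog_out"
    seed: int = 0
    stages: tuple = ALL_STAGES
    bin_cm: float = 1.0
    bootstrap_iterations: int = 200
    group_by: str = "morph"  # growth/mortality grouping: sex | morph
    otc_true_period_days: float = 365.0
    otc_g_days: float = 433.0
    otc_n_fish: int = 8
    otc_noise_cv: float = 0.07
    reader_error_sd: float = 0.3

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("exactly one of input_path or simulation must be set")
        if isinstance(self.simulation, dict):
            self.simulation = PopulationConfig(**self.simulation)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output path excluded)."""
        data = dataclasses.asdict(self)
        data.pop("outdir")
        payload = yaml.safe_dump(data, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, header: str, index: bool = True) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        df.to_csv(fh, index=index)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns a dict of stage -> output paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    provenance = (f"# fishdemog pipeline | config_hash={config.config_hash()} "
                  f"| seed={config.seed}\n")
    outputs: dict = {}
    try:
        records = _stage_input(config, outdir, provenance, outputs)
        aged = [r for r in records if r.age_yr is not None]
        for stage in ALL_STAGES[1:]:
            if stage not in config.stages:
                continue
            t0 = time.perf_counter()
            log.info("stage %s starting", stage)
            fn = globals()[f"_stage_{stage}"]
            try:
                if stage == "alk":
                    records = fn(config, records, outdir, provenance, outputs)
                    aged = [r for r in records if r.age_yr is not None]
                else:
                    if stage in ("growth", "mortality", "popstats") and not aged:
                        raise PipelineError(
                            f"stage {stage}: no aged records available; enable the "
                            "'alk' stage (or supply aged input) first")
                    fn(config, records, outdir, provenance, outputs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {stage} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)
    finally:
        log.removeHandler(handler)
        handler.close()
    return outputs


def _stage_input(config, outdir, provenance, outputs):
    if config.simulation is not None:
        if "simulate" not in config.stages:
            raise PipelineError("no input_path given; enable the 'simulate' stage")
        sim = dataclasses.replace(config.simulation)
        records = simulate_population(sim)
        records = simulate_seasonal_otolith_state(records, seed=config.seed + 1)
        path = outdir / "sample_mkt.csv"
        write_fish_table(records, path)
        outputs["simulate"] = [path]
        log.info("simulated %d records", len(records))
        return records
    records = read_fish_table(config.input_path, dialect=config.input_dialect)
    log.info("loaded %d records from %s", len(records), config.input_path)
    return records


def _stage_validate_ageing(config, records, outdir, provenance, outputs):
    paths = []
    otc = simulate_otc_experiment(config.otc_true_period_days, config.otc_g_days,
                                  config.otc_n_fish, config.otc_noise_cv,
                                  seed=config.seed + 2)
    per_fish = [ageing.compute_periodicity(r) for r in otc]
    summ = ageing.summarize_periodicity(per_fish)
    df = pd.DataFrame({"fish_id": [r.fish_id for r in otc],
                       "periodicity_days": np.round(per_fish, 1)})
    df.loc[len(df)] = ["mean", round(summ.mean_days, 1)]
    p = outdir / "periodicity.csv"
    _write_csv(df, p, provenance, index=False)
    paths.append(p)

    aged = [r for r in records if r.age_yr is not None]
    if aged:
        pairs = simulate_double_reads([r.age_yr for r in aged],
                                      error_sd=config.reader_error_sd,
                                      seed=config.seed + 3)
        prec = pd.DataFrame({
            "metric": ["iape_percent", "percent_agreement_0yr", "percent_agreement_1yr"],
            "value": [round(ageing.iape(pairs), 2),
                      round(ageing.percent_agreement(pairs, 0), 1),
                      round(ageing.percent_agreement(pairs, 1), 1)],
        })
        p = outdir / "reader_precision.csv"
        _write_csv(prec, p, provenance, index=False)
        paths.append(p)

        mi = ageing.monthly_marginal_increment(aged, age_classes={5, 6})
        p = outdir / "monthly_marginal_increment.csv"
        _write_csv(mi, p, provenance)
        paths.append(p)
        edge = ageing.monthly_edge_percent(aged)
        p = outdir / "monthly_edge_percent.csv"
        _write_csv(edge, p, provenance)
        paths.append(p)
        for response in ("oto_weight", "oto_length"):
            try:
                fit = ageing.fit_allometry(aged, response=response)
            except ValueError as exc:
                log.warning("allometry %s skipped: %s", response, exc)
                continue
            tab = pd.DataFrame({"estimate": fit.params, "se": fit.bse,
                                "p": fit.pvalues})
            tab.attrs = {}
            p = outdir / f"allometry_{response}.csv"
            _write_csv(tab, p, provenance + f"# formula: {fit.formula} | "
                       f"r2={fit.r2:.3f} | n={fit.n}\n")
            paths.append(p)
    outputs["validate_ageing"] = paths


def _growth_groups(config, aged):
    groups = {"all": aged}
    if config.group_by in ("sex", "morph"):
        attr = config.group_by
        for val in sorted({getattr(r, attr) for r in aged} - {"unknown"}):
            groups[val] = [r for r in aged if getattr(r, attr) == val]
    return groups


def _stage_growth(config, records, outdir, provenance, outputs):
    aged = [r for r in records if r.age_yr is not None]
    rows = []
    ellipses = {}
    for name, recs in _growth_groups(config, aged).items():
        if len({r.age_yr for r in recs}) < 3:
            log.warning("growth group %s skipped: <3 age classes", name)
            continue
        res = growth.bootstrap_vbgf(recs, mode="constrained",
                                    iterations=config.bootstrap_iterations,
                                    seed=config.seed + 10)
        ci = res.conf_int()
        rows.append({
            "group": name, "n": res.n,
            "l_inf": round(res.params.l_inf, 2),
            "l_inf_lower": round(ci.loc["l_inf", "lower"], 2),
            "l_inf_upper": round(ci.loc["l_inf", "upper"], 2),
            "k": round(res.params.k, 3),
            "k_lower": round(ci.loc["k", "lower"], 3),
            "k_upper": round(ci.loc["k", "upper"], 3),
            "aic": round(res.aic, 1),
        })
        if name != "all":
            ellipses[name] = res.ellipse(0.95)
    p = outdir / "growth_parameters.csv"
    _write_csv(pd.DataFrame(rows), p, provenance, index=False)
    paths = [p]
    if len(ellipses) >= 2:
        names = sorted(ellipses)
        comp = []
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                comp.append({"group_a": a, "group_b": b,
                             "ellipses_overlap": growth.ellipses_overlap(
                                 ellipses[a], ellipses[b])})
        p = outdir / "growth_ellipse_overlap.csv"
        _write_csv(pd.DataFrame(comp), p, provenance, index=False)
        paths.append(p)
    outputs["growth"] = paths


def _stage_alk(config, records, outdir, provenance, outputs):
    aged = [r for r in records if r.age_yr is not None]
    unaged = [r for r in records if r.age_yr is None]
    if not aged:
        raise PipelineError("stage alk: no aged records to build a key from; "
                            "supply aged input or enable the 'simulate' stage")
    keys = alk_mod.build_alk(aged, bin_cm=config.bin_cm, by="pooled")
    p = outdir / "age_length_key.csv"
    _write_csv(keys[alk_mod.POOLED].to_frame(), p, provenance)
    outputs["alk"] = [p]
    if unaged:
        assigned, report = alk_mod.assign_ages(unaged, keys, seed=config.seed + 20)
        log.info("alk: assigned %d, unassigned %d", report.n_assigned,
                 len(report.unassigned))
        p = outdir / "assigned_ages.csv"
        write_fish_table(assigned, p)
        outputs["alk"].append(p)
        aged_map = {r.fish_id: r for r in assigned}
        records = [aged_map.get(r.fish_id, r) for r in records]
    return records


def _stage_mortality(config, records, outdir, provenance, outputs):
    aged = [r for r in records if r.age_yr is not None]
    rows = []
    groups = _growth_groups(config, aged)
    freqs = {}
    for name, recs in groups.items():
        freq = alk_mod.age_frequency(recs)
        try:
            res = mortality.fit_catch_curve(freq)
        except ValueError as exc:
            log.warning("mortality group %s skipped: %s", name, exc)
            continue
        if name != "all":
            freqs[name] = freq
        rows.append({"group": name, "limb_start": res.limb_ages[0],
                     "limb_end": res.limb_ages[1], "z": round(res.z, 3),
                     "z_se": round(res.z_se, 3), "r2": round(res.r2, 3),
                     "a_percent": round(res.a_percent, 1), "n_points": res.n_points})
    df = pd.DataFrame(rows)
    extra = ""
    if len(freqs) >= 2:
        comp = mortality.compare_catch_curves(freqs)
        extra = (f"# slope homogeneity: F={comp.f_stat:.3f}, "
                 f"p={comp.p_value:.4g}\n")
    p = outdir / "mortality.csv"
    _write_csv(df, p, provenance + extra, index=False)
    outputs["mortality"] = [p]


def _stage_popstats(config, records, outdir, provenance, outputs):
    aged = [r for r in records if r.age_yr is not None]
    rows = []
    try:
        lw = popstats.fit_length_weight([r for r in records if r.tw_g is not None])
        for name, est in lw.params.items():
            rows.append({"metric": f"length_weight[{name}]", "group": "all",
                         "value": round(est, 4)})
        rows.append({"metric": "length_weight_r2", "group": "all",
                     "value": round(lw.r2, 3)})
    except ValueError as exc:
        log.warning("length-weight skipped: %s", exc)
    for name, recs in _growth_groups(config, aged).items():
        if len(recs) < 10:
            continue
        old = popstats.oldest_decile_summary(recs)
        rows.append({"metric": "longevity_yr", "group": name,
                     "value": round(old.longevity_yr, 2)})
        rows.append({"metric": "mean_max_size_cm", "group": name,
                     "value": round(old.mean_max_size_cm, 2)})
    p = outdir / "popstats.csv"
    _write_csv(pd.DataFrame(rows), p, provenance, index=False)
    outputs["popstats"] = [p]
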