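"""Config-driven end-to-end orchestration of the longevity analysis.

Stages, in order: read observation and individual tables; split into
site-by-year network periods; permutation-gate each period's network;
assign individuals to groups by weighted clique percolation; compute
the seven network measures; assemble the dead-adult panel with
adult-lifetime averages; run the randomization regressions (unadjusted
and residual-controlled) plus the group-effect and aggression models;
and, when encounter histories are supplied, a Barker survival model
set with QAICc ranking and model-averaged survival.  Everything is
deterministic given the seeds recorded in the report.

:func:`run_pipeline` is the file-based entry point; :func:`analyze`
takes in-memory inputs (as simulation studies do).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import centrality as cen
from . import community as comm
from . import longevity as lon
from . import permtest
from . import survival as surv
from .core_data import NetworkPeriod, read_individuals, read_observations
from .errors import ConfigError, SocnetError

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "analyze"]

logger = logging.getLogger(__name__)

GROUP_METRICS = (
    "sd_strength", "sd_power", "sd_information", "cohesion", "centralization", "size",
)


class PipelineError(SocnetError):
    """A stage failed; the message names the stage and its inputs."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class PipelineConfig:
    observations: str = "observations.csv"
    individuals: str = "individuals.csv"
    encounters: str | None = "encounters.csv"
    output_dir: str = "output"
    # permutation gate
    alpha: float = 0.05
    max_perm: int = 1000
    burn_in: int = 500
    swaps_per_sample: int = 20
    stabilization_tol: float = 0.01
    # community detection
    k: int = 3
    intensity_threshold: float | None = None  # None -> select_threshold scan
    # centrality
    beta: float | None = None
    sd_estimator: str = "population"
    distance_rule: str = "inverse_weight"
    # regressions
    n_perm: int = 2000
    panel_n: int | None = None  # cap on panel size (None = all dead adults)
    controls: tuple[str, ...] = ("mean_group_size",)
    # survival
    c_hat: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        if "controls" in raw:
            raw["controls"] = tuple(raw["controls"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Read the configured input files, analyze, and write the report bundle."""
    try:
        records = read_observations(config.observations)
        read_individuals(config.individuals)  # validates ids/sex/dates
        ind_frame = pd.read_csv(config.individuals, dtype={"id": str})
    except SocnetError as exc:
        raise PipelineError("read", str(exc)) from exc
    histories = None
    if config.encounters and Path(config.encounters).exists():
        histories = surv.read_encounters(config.encounters)
    return analyze(records, ind_frame, config, histories=histories,
                   output_dir=Path(config.output_dir))


def analyze(
    records,
    ind_frame: pd.DataFrame | None,
    config: PipelineConfig,
    histories=None,
    output_dir: Path | None = None,
) -> dict:
    """Run every stage on in-memory inputs; write outputs if a directory is given."""
    rng = np.random.default_rng(config.seed)
    if output_dir is not None:
        (output_dir / "tables").mkdir(parents=True, exist_ok=True)
        (output_dir / "networks").mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "periods": {},
        "provenance": {},
        "status": "ok",
    }
    periods = _split_periods(records)
    report["provenance"]["input_records"] = _digest(
        [(r.date.isoformat(), r.site, r.event_id, r.individual_id,
          r.interaction_type.value, r.marked) for r in records])

    # ---- permutation gate -------------------------------------------------
    perm_results = {}
    for name, (period, recs) in periods.items():
        try:
            structure = permtest.SamplingStructure.from_records(recs, period)
            perm_results[name] = permtest.permutation_test(
                structure,
                max_perm=config.max_perm,
                burn_in=config.burn_in,
                swaps_per_sample=config.swaps_per_sample,
                stabilization_tol=config.stabilization_tol,
                rng=np.random.default_rng(rng.integers(2**31)),
            )
        except SocnetError as exc:
            raise PipelineError("permutation_gate", f"period {name}: {exc}") from exc
    retained = permtest.gate_networks(perm_results, alpha=config.alpha)
    for name, res in perm_results.items():
        report["periods"][name] = {
            "permutation_p": res.p_value,
            "observed_stat": res.observed_stat,
            "n_permutations": res.n_permutations,
            "stabilized": res.stabilized,
            "retained": name in retained,
        }
    report["provenance"]["gate"] = _digest(report["periods"])
    if not retained:
        report["status"] = "stopped_after_gating"
        _write_report(report, output_dir)
        return report

    # ---- communities + the seven measures ---------------------------------
    ind_rows, grp_rows = [], []
    membership: dict[str, dict] = {}
    for name in retained:
        period, recs = periods[name]
        try:
            matrix = assoc.association_matrix_from_records(recs, period)
            graph = matrix.to_graph()
            if config.intensity_threshold is not None:
                threshold = config.intensity_threshold
            else:
                try:
                    threshold = comm.select_threshold(graph, k=config.k)
                except comm.NoCliquesError:
                    threshold = 0.0
            assignment = comm.cpmw_communities(graph, k=config.k,
                                               intensity_threshold=threshold)
            ind_tab, grp_tab = cen.centrality_table(
                graph, assignment, beta=config.beta,
                estimator=config.sd_estimator,
                distance_rule=config.distance_rule, period=name,
            )
            if output_dir is not None:
                matrix.to_graphml(output_dir / "networks" / f"{name}.graphml")
        except SocnetError as exc:
            raise PipelineError("network_measures", f"period {name}: {exc}") from exc
        ind_rows.append(ind_tab)
        grp_rows.append(grp_tab)
        membership[name] = dict(zip(ind_tab["individual"], ind_tab["group"]))
    ind_table = pd.concat(ind_rows, ignore_index=True)
    grp_table = pd.concat(grp_rows, ignore_index=True)
    report["provenance"]["measures"] = _digest(
        [ind_table.to_csv(index=False), grp_table.to_csv(index=False)])
    if output_dir is not None:
        ind_table.to_csv(output_dir / "tables" / "individual_measures.csv", index=False)
        grp_table.to_csv(output_dir / "tables" / "group_measures.csv", index=False)

    # ---- dead-adult panel + regressions -----------------------------------
    panel = pd.DataFrame()
    if ind_frame is not None:
        panel = _build_panel(ind_frame, periods, retained, membership,
                             ind_table, grp_table, records)
    if config.panel_n is not None and len(panel) > config.panel_n:
        panel = panel.sample(n=config.panel_n,
                             random_state=int(rng.integers(2**31))).reset_index(drop=True)
    report["n_panel"] = int(len(panel))
    report["provenance"]["panel"] = _digest(
        panel.to_csv(index=False) if len(panel) else "")
    if len(panel) >= 5:
        if output_dir is not None:
            panel.to_csv(output_dir / "tables" / "panel.csv", index=False)
        regs = []
        predictors = (
            ["mean_group_size", "mean_strength"]
            + [f"mean_{m}" for m in GROUP_METRICS if m != "size"]
            + ["aggression_rate"]
        )
        for pred in predictors:
            if panel[pred].isna().any() or panel[pred].std() == 0:
                continue
            regs.append(_regress(panel, pred, config.n_perm,
                                 np.random.default_rng(rng.integers(2**31))))
            if pred != "mean_group_size":
                regs.append(_regress(panel, pred, config.n_perm,
                                     np.random.default_rng(rng.integers(2**31)),
                                     controls=config.controls))
        report["regressions"] = regs
        report["n_regression_tests"] = len(regs)
        try:
            ge = lon.group_effect_model(
                panel["age_at_death"].to_numpy(float),
                panel["mean_sd_strength"].to_numpy(float),
                panel["group_label"].to_numpy(),
            )
            report["group_effect"] = asdict(ge)
        except SocnetError as exc:
            report["group_effect"] = {"error": str(exc)}
    else:
        report["regressions"] = []
        report["panel_warning"] = "fewer than 5 dead adults; regressions skipped"

    # ---- survival ----------------------------------------------------------
    if histories:
        try:
            fits = [
                surv.fit_model(histories, surv.ModelSpec(), c_hat=config.c_hat),
                surv.fit_model(histories, surv.ModelSpec(S="group"), c_hat=config.c_hat),
                surv.fit_model(histories, surv.ModelSpec(S="group", p="group"),
                               c_hat=config.c_hat),
            ]
            table = surv.model_table(fits)
            if output_dir is not None:
                table.to_csv(output_dir / "tables" / "survival_models.csv", index=False)
            groups = sorted({h.group for h in histories})
            best_group_fit = fits[1]
            averaged = {g: surv.model_average(fits, "S", group=g) for g in groups}
            stat, df, p = surv.likelihood_ratio_test(fits[0], best_group_fit)
            report["survival"] = {
                "model_table": table.to_dict("records"),
                "averaged_S": {g: {"estimate": e, "se": s}
                               for g, (e, s) in averaged.items()},
                "lrt_group_vs_constant": {"chi2": stat, "df": df, "p": p},
                "c_hat": config.c_hat,
            }
            report["provenance"]["survival"] = _digest(report["survival"])
        except SocnetError as exc:
            raise PipelineError("survival", str(exc)) from exc

    _write_report(report, output_dir)
    return report


def _digest(payload) -> str:
    """Stable content hash used for stage-level provenance."""
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_report(report: dict, output_dir: Path | None) -> None:
    if output_dir is not None:
        output_dir.mkdir(parents=True, exist_ok=True)
        (output_dir / "report.json").write_text(
            json.dumps(report, indent=2, default=float)
        )


def _split_periods(records):
    """Group records into (site, calendar-year) network periods."""
    keys = sorted({(r.site, r.date.year) for r in records})
    periods = {}
    for site, year in keys:
        recs = [r for r in records if r.site == site and r.date.year == year]
        periods[f"{site}-{year}"] = (NetworkPeriod(site=site, label=str(year)), recs)
    return periods


def _regress(panel: pd.DataFrame, predictor: str, n_perm: int, rng,
             controls: tuple[str, ...] = ()) -> dict:
    y = panel["age_at_death"].to_numpy(dtype=float)
    x = panel[predictor].to_numpy(dtype=float)
    if controls:
        ctrl = panel[list(controls)].to_numpy(dtype=float)
        y = lon.residual_control(y, ctrl)
        x = lon.residual_control(x, ctrl)
    res = lon.randomization_regression(y, x, n_perm=n_perm, rng=rng)
    return {
        "predictor": predictor,
        "controls": list(controls),
        "slope": res.slope,
        "r_squared": res.r_squared,
        "p_randomization": res.p_randomization,
        "n": res.n,
        "n_permutations": res.n_permutations,
    }


def _build_panel(ind_frame, periods, retained, membership, ind_table, grp_table,
                 records) -> pd.DataFrame:
    """One row per dead adult: adult-lifetime averages of the group metrics.

    Requires ``birth_year`` and ``age_at_death`` columns in the
    individuals table (the synthetic fixture writes both; for field
    data they come from the March-1 convention and the weight model).
    Only years in which the animal was an adult (age >= 2), alive, and
    assigned to a group enter the averages.
    """
    if ind_frame is None or "age_at_death" not in ind_frame.columns \
            or "birth_year" not in ind_frame.columns:
        return pd.DataFrame()
    grp_lookup = {
        (row["period"], row["group"]): row for _, row in grp_table.iterrows()
    }
    ind_lookup = {
        (row["period"], row["individual"]): row for _, row in ind_table.iterrows()
    }
    agonistic_days: dict[str, set] = {}
    obs_days: dict[str, set] = {}
    for r in records:
        if r.interaction_type.value == "agonistic":
            agonistic_days.setdefault(r.individual_id, set()).add(r.date)
        obs_days.setdefault(r.individual_id, set()).add(r.date)

    rows = []
    for _, ind in ind_frame.iterrows():
        if pd.isna(ind.get("age_at_death")) or pd.isna(ind.get("birth_year")):
            continue
        age_death = float(ind["age_at_death"])
        if age_death < 2:
            continue
        birth = int(ind["birth_year"])
        record = lon.LifeRecord(
            individual_id=str(ind["id"]), sex=str(ind.get("sex", "unknown")),
            age_at_death_years=age_death,
        )
        labels = []
        for name in retained:
            period, _ = periods[name]
            year = int(period.label)
            age = year - birth
            gid = membership.get(name, {}).get(str(ind["id"]), -1)
            if age < 2 or age > age_death or gid == -1:
                continue
            grow = grp_lookup.get((name, gid))
            irow = ind_lookup.get((name, str(ind["id"])))
            if grow is None or irow is None:
                continue
            entry = {"group": gid, "group_size": float(grow["size"]),
                     "strength": float(irow["strength"])}
            for m in GROUP_METRICS:
                entry[m] = float(grow[m])
            record.yearly[name] = entry
            record.adult_years.append((name, age))
            labels.append((period.site, gid))
        if not record.adult_years:
            continue
        row = {
            "id": str(ind["id"]), "sex": record.sex, "age_at_death": age_death,
            "mean_group_size": lon.average_adult_metrics(record, "group_size"),
            "mean_strength": lon.average_adult_metrics(record, "strength"),
            "group_label": "/".join(map(str, max(set(labels), key=labels.count))),
            "n_agonistic_days": len(agonistic_days.get(str(ind["id"]), set())),
            "n_observed_days": max(1, len(obs_days.get(str(ind["id"]), set()))),
        }
        for m in GROUP_METRICS:
            if m == "size":
                continue
            try:
                row[f"mean_{m}"] = lon.average_adult_metrics(record, m)
            except SocnetError:
                row[f"mean_{m}"] = np.nan
        rows.append(row)
    panel = pd.DataFrame(rows)
    if len(panel):
        panel["aggression_rate"] = lon.aggression_rate(
            panel["n_agonistic_days"].to_numpy(float),
            panel["mean_group_size"].to_numpy(float),
            panel["n_observed_days"].to_numpy(float),
        )
    return panel
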