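"""End-to-end orchestration: simulate -> metrics -> group stats -> mediation.

A run is configured by :class:`RunConfig` (YAML round-trippable), driven by
one master seed from which every stochastic stage derives its own
substream, and writes a directory of TSV/CSV tables mirroring the study's
reporting structure: per-subject network metrics, global and nodal group
comparisons, standardized regression tables (lesion volume x cognition,
lesion volume x network metrics, network metrics x cognition), and the
mediation results. Every stage table carries the hash of the configuration
that produced it; re-running with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as wio
from .connectome import threshold_and_weight
from .group_stats import GroupAncova, nodal_group_comparison
from .mediation import MediationModel, standardized_regression
from .metrics import network_summary
from .neuropsych import log_wmh, zscore_composites
from .synthetic import (CohortConfig, MediationParams, cohort_to_dataframe,
                        generate_cohort)

_ALL_STAGES = ("simulate", "metrics", "group_stats", "regression", "mediation")
COVARIATES = ("age", "sex_male", "education")


@dataclass
class RunConfig:
    out_dir: str = "wmhnet_run"
    stages: tuple[str, ...] = _ALL_STAGES
    seed: int = 0
    # cohort
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"HC": 52, "WMH-no-CI": 42, "WMH-CI": 41})
    n_nodes: int = 90
    base_density: float = 0.3
    edge_attenuation: float = 0.6
    lesioned_edge_fraction: float = 0.25
    # implanted mediation (signs follow the lesion direction; see synthetic)
    a: float = -0.4
    b: float = 0.4
    c_prime: float = -0.1
    noise_sd: float = 0.5
    x_variable: str = "lg_twmh"
    mediator_node: int | None = None
    # analysis parameters
    fn_threshold: int = 3
    q: float = 0.01
    alpha: float = 0.05
    k_bootstrap: int = 5000
    mediation_outcome: str = "memory"
    mediator_metric: str = "eg"       # nodal metric used as mediator: eg | nlp
    regression_group: str = "WMH-CI"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.stages = tuple(self.stages)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def cohort_config(self) -> CohortConfig:
        sub = np.random.SeedSequence(self.seed).generate_state(2) % (2**31)
        return CohortConfig(
            n_per_group=dict(self.n_per_group), n_nodes=self.n_nodes,
            base_density=self.base_density,
            edge_attenuation=self.edge_attenuation,
            lesioned_edge_fraction=self.lesioned_edge_fraction,
            mediation_params=MediationParams(
                a=self.a, b=self.b, c_prime=self.c_prime,
                noise_sd=self.noise_sd, x_variable=self.x_variable,
                mediator_node=self.mediator_node),
            seed=int(sub[0]))

    def bootstrap_seed(self) -> int:
        return int(np.random.SeedSequence(self.seed).generate_state(2)[1]
                   % (2**31))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if "stages" in payload:
            payload["stages"] = tuple(payload["stages"])
        return cls(**payload)


class StageError(RuntimeError):
    """A stage is missing its upstream inputs."""


def _write_table(df: pd.DataFrame, path: Path, config_hash: str,
                 index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def prepare_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Model-ready cohort: male indicator, log volumes, domain composites.

    Subjects missing any modeling column keep their row but are excluded
    per-model downstream (complete-case analysis).
    """
    df = cohort.copy()
    df["sex_male"] = (df["sex"] == "M").astype(float)
    for col, new in (("twmh", "lg_twmh"), ("pwmh", "lg_pwmh"),
                     ("dwmh", "lg_dwmh")):
        df[new] = log_wmh(df[col].to_numpy())
    comps = zscore_composites(df)
    return pd.concat([df, comps], axis=1)


def _mediator_name(config: RunConfig, node_names: list[str]) -> str:
    idx = config.mediator_node
    if idx is None:
        idx = 10 if config.n_nodes == 90 else 0
    return node_names[idx]


def run_pipeline(config: RunConfig) -> Path:
    out = wio.ensure_dir(config.out_dir)
    chash = config.config_hash()
    import scipy
    import statsmodels

    from . import __version__
    params = dataclasses.asdict(config)
    params.pop("out_dir")  # path choice must not break rerun identity
    log: dict = {"config_hash": chash, "seed": config.seed,
                 "stages": list(config.stages),
                 "parameters": params,
                 "versions": {"wmhnet": __version__,
                              "numpy": np.__version__,
                              "scipy": scipy.__version__,
                              "pandas": pd.__version__,
                              "statsmodels": statsmodels.__version__}}

    # ---- simulate --------------------------------------------------------
    if "simulate" in config.stages:
        records, connectomes = generate_cohort(config.cohort_config())
        cohort = cohort_to_dataframe(records)
        wio.write_cohort_csv(out / "cohort.csv", cohort)
        conn_dir = wio.ensure_dir(out / "connectomes")
        for sid, conn in connectomes.items():
            wio.write_connectome(conn_dir / sid, conn)
        log["n_subjects"] = len(records)

    # ---- metrics ---------------------------------------------------------
    if "metrics" in config.stages:
        conn_dir = out / "connectomes"
        if not conn_dir.is_dir():
            raise StageError("metrics stage requires connectomes/ from "
                             "the simulate (or connectome) stage")
        sids = sorted(p.name[:-len(".fn.tsv")]
                      for p in conn_dir.glob("*.fn.tsv"))
        glob_rows, nlp_rows, neg_rows = [], [], []
        node_names = None
        for sid in sids:
            conn = wio.read_connectome(conn_dir / sid)
            graph = threshold_and_weight(conn, config.fn_threshold)
            node_names = graph.node_names
            g, nm = network_summary(graph)
            glob_rows.append({"subject_id": sid, **g.to_series().to_dict()})
            nlp_rows.append({"subject_id": sid,
                             **dict(zip(node_names, nm.nlp))})
            neg_rows.append({"subject_id": sid,
                             **dict(zip(node_names, nm.eg))})
        _write_table(pd.DataFrame(glob_rows), out / "global_metrics.tsv", chash)
        _write_table(pd.DataFrame(nlp_rows), out / "nodal_nlp.tsv", chash)
        _write_table(pd.DataFrame(neg_rows), out / "nodal_eg.tsv", chash)

    # ---- shared inputs for the statistical stages ------------------------
    needs_stats = {"group_stats", "regression", "mediation"} & set(config.stages)
    if needs_stats:
        for req in ("cohort.csv", "global_metrics.tsv"):
            if not (out / req).exists():
                raise StageError(f"statistics stages require {req}")
        cohort = prepare_cohort(wio.read_cohort_csv(out / "cohort.csv"))
        gm = read_table(out / "global_metrics.tsv")
        nlp = read_table(out / "nodal_nlp.tsv")
        neg = read_table(out / "nodal_eg.tsv")
        data = cohort.merge(gm, on="subject_id", validate="1:1")
        node_names = [c for c in nlp.columns if c != "subject_id"]
        mediator = _mediator_name(config, node_names)
        covs = data[list(COVARIATES)]
        incomplete = int(covs.isna().any(axis=1).sum())
        log["incomplete_covariate_rows"] = incomplete

    # ---- group stats -----------------------------------------------------
    if "group_stats" in config.stages:
        desc = data.groupby("group")[
            ["age", "education", "twmh", "pwmh", "dwmh"]].agg(["mean", "std"])
        desc.columns = ["_".join(c) for c in desc.columns]
        _write_table(desc.reset_index(), out / "group_descriptives.tsv", chash)

        rows = []
        for metric in ("density", "strength", "cp", "lp", "eg", "eloc"):
            res = GroupAncova(data[metric], data["group"], covs).fit()
            row = {"metric": metric, "F": res.f_stat, "p": res.p_value}
            for g, m in res.adjusted_means.items():
                row[f"adj_mean[{g}]"] = m
            for c in res.pairwise(alpha=config.alpha):
                tag = f"{c.pair[0]}_vs_{c.pair[1]}"
                row[f"p_raw[{tag}]"] = c.p_raw
                row[f"p_bonf[{tag}]"] = c.p_bonferroni
            rows.append(row)
        _write_table(pd.DataFrame(rows), out / "global_comparison.tsv", chash)

        for name, table in (("nlp", nlp), ("eg", neg)):
            merged = cohort[["subject_id", "group", *COVARIATES]].merge(
                table, on="subject_id", validate="1:1")
            finite = merged[node_names].replace([np.inf, -np.inf], np.nan)
            result = nodal_group_comparison(
                finite, merged["group"], merged[list(COVARIATES)],
                q=config.q, alpha=config.alpha, metric_name=name)
            _write_table(result, out / f"nodal_comparison_{name}.tsv", chash)

    # ---- regression ------------------------------------------------------
    if "regression" in config.stages:
        sub = data[data["group"] == config.regression_group]
        sub_nlp = sub[["subject_id"]].merge(nlp, on="subject_id")
        sub_neg = sub[["subject_id"]].merge(neg, on="subject_id")
        domains = ["executive", "processing_speed", "memory", "visuospatial",
                   "language"]
        wmh_vars = ["lg_twmh", "lg_pwmh", "lg_dwmh"]
        covsub = sub[list(COVARIATES)]

        rows = []
        for dom in domains:                       # lesion volume -> cognition
            for wv in wmh_vars:
                r = standardized_regression(sub[dom], sub[wv], covsub)
                rows.append({"outcome": dom, "predictor": wv,
                             "beta": r.beta, "p": r.p_value, "n": r.n})
        _write_table(pd.DataFrame(rows), out / "regression_wmh_cognition.tsv",
                     chash)

        rows = []
        metric_cols = {"eg": sub["eg"], "lp": sub["lp"],
                       f"{mediator}_nlp": sub_nlp[mediator],
                       f"{mediator}_eg": sub_neg[mediator]}
        for mname, mvals in metric_cols.items():  # lesion volume -> network
            for wv in wmh_vars:
                r = standardized_regression(mvals.to_numpy(), sub[wv], covsub)
                rows.append({"outcome": mname, "predictor": wv,
                             "beta": r.beta, "p": r.p_value, "n": r.n})
        _write_table(pd.DataFrame(rows), out / "regression_wmh_network.tsv",
                     chash)

        rows = []
        for dom in domains:                       # network -> cognition
            for mname, mvals in metric_cols.items():
                r = standardized_regression(sub[dom], mvals.to_numpy(), covsub)
                rows.append({"outcome": dom, "predictor": mname,
                             "beta": r.beta, "p": r.p_value, "n": r.n})
        _write_table(pd.DataFrame(rows), out / "regression_network_cognition.tsv",
                     chash)

    # ---- mediation -------------------------------------------------------
    if "mediation" in config.stages:
        mtable = nlp if config.mediator_metric == "nlp" else neg
        merged = data.merge(mtable[["subject_id", mediator]].rename(
            columns={mediator: "mediator_value"}), on="subject_id")
        model = MediationModel(
            merged[config.x_variable], merged["mediator_value"],
            merged[config.mediation_outcome], merged[list(COVARIATES)])
        res = model.fit(k=config.k_bootstrap, seed=config.bootstrap_seed())
        row = {"x": config.x_variable,
               "m": f"{mediator}_{config.mediator_metric}",
               "y": config.mediation_outcome,
               "a": res.a, "b": res.b, "c": res.c, "c_prime": res.c_prime,
               "indirect": res.indirect, "ci_low": res.ci_low,
               "ci_high": res.ci_high, "significant": res.significant,
               "k": res.k, "n": res.n}
        _write_table(pd.DataFrame([row]), out / "mediation.tsv", chash)

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=str)
    config.to_yaml(out / "run_config.yaml")
    return out
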