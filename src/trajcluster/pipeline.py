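"""End-to-end orchestration: simulate -> select -> encode -> compress ->
cluster -> profile -> survive, with a JSON run manifest.

Every stage writes documented delimited-text artifacts into the output
directory, so any stage can be inspected, replaced, or re-run standalone.
Reruns with the same configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as clustering
from . import cohort, encoding, medoids, profiling, simulate, survival

__all__ = ["RunConfig", "run_pipeline", "DEFAULT_PROFILE_SPECS"]

log = logging.getLogger("trajcluster")

STAGES = ("simulate", "select", "encode", "compress", "cluster",
          "profile", "survive")


@dataclass(frozen=True)
class RunConfig:
    out_dir: str = "trajcluster_run"
    rng_seed: int = 0
    n_patients: int = 5000
    cluster_weights: tuple = (0.66, 0.12, 0.21, 0.01)
    window_days: int = 365
    k_medoids: int = 100
    kmeans_n_init: int = 10
    n_clusters: int = 4
    min_age: float = 40.0
    incident_lookback: int = 1826
    skip_stages: tuple = ()
    events_file: str | None = None      # used when 'simulate' is skipped
    covariates_file: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("cluster_weights", "skip_stages"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


DEFAULT_PROFILE_SPECS = (
    profiling.ProfileSpec("age", "continuous", ("covariate", "age")),
    profiling.ProfileSpec("male_sex", "categorical", ("covariate", "sex"),
                          levels=("male", "female")),
    profiling.ProfileSpec(
        "exacerbation_hospitalisations", "categorical",
        ("event_count", simulate.EXACERBATION),
        bins=(0, 2, 4), bin_labels=("0", "1-2", "3-4", ">=5")),
    profiling.ProfileSpec(
        "exacerbation_days", "continuous", ("event_days", simulate.EXACERBATION)),
    profiling.ProfileSpec(
        "gp_consultations", "categorical", ("event_count", "gp_consult"),
        bins=(0, 2, 5, 10, 20), bin_labels=("0", "1-2", "3-5", "6-10", "11-20", ">20")),
    *(profiling.ProfileSpec(flag, "categorical", ("covariate", flag), levels=(1, 0))
      for flag in simulate.COMORBIDITY_FLAGS),
)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return (and write) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "rng_seed": config.rng_seed,
        "config": asdict(config),
        "stages": {},
    }

    def record(stage: str, t0: float, **counts) -> None:
        manifest["stages"][stage] = {
            "status": "completed",
            "seconds": round(_time.perf_counter() - t0, 3),
            **counts,
        }
        log.info("stage %s done (%s)", stage, counts)

    # -- simulate ----------------------------------------------------------
    t0 = _time.perf_counter()
    if "simulate" in config.skip_stages:
        if not (config.events_file and config.covariates_file):
            raise ValueError("skipping 'simulate' requires events_file and covariates_file")
        events = pd.read_csv(config.events_file)
        covariates = pd.read_csv(config.covariates_file)
        truth = None
        manifest["stages"]["simulate"] = {"status": "skipped (user input)"}
    else:
        gen_cfg = simulate.GeneratorConfig(
            n_patients=config.n_patients,
            cluster_weights=tuple(config.cluster_weights),
            window_days=config.window_days,
            rng_seed=config.rng_seed,
        )
        events, covariates, truth = simulate.generate_cohort(gen_cfg)
        events.to_csv(out / "events.csv", index=False)
        covariates.to_csv(out / "covariates.csv", index=False)
        truth.to_csv(out / "truth_labels.csv", index=False)
        record("simulate", t0, n_events=len(events), n_patients=len(covariates))

    # -- select ------------------------------------------------------------
    t0 = _time.perf_counter()
    rules = cohort.SelectionRules(min_age=config.min_age,
                                  incident_lookback=config.incident_lookback)
    included, exclusions = cohort.select_cohort(events, covariates, rules)
    cohort.attrition_table(included, exclusions).to_csv(out / "attrition.csv", index=False)
    exclusions.to_csv(out / "exclusions.csv", index=False)
    record("select", t0, n_included=len(included), n_excluded=len(exclusions))

    # -- encode ------------------------------------------------------------
    t0 = _time.perf_counter()
    ids, seqs = encoding.encode_cohort(events[events["patient_id"].isin(included)],
                                       included, window_days=config.window_days)
    encoding.write_sequences(out / "sequences.csv", ids, seqs)
    record("encode", t0, n_sequences=len(ids), window_days=seqs.shape[1])

    # -- compress ----------------------------------------------------------
    t0 = _time.perf_counter()
    n_distinct = len(np.unique(seqs, axis=0))
    k = min(config.k_medoids, n_distinct)
    mset = medoids.compress(seqs, k=k, n_init=config.kmeans_n_init,
                            rng_seed=config.rng_seed)
    encoding.write_sequences(out / "medoids.csv", np.arange(mset.k), mset.medoids)
    pd.DataFrame({"patient_id": ids, "medoid": mset.assignment,
                  "homogeneity": mset.homogeneity}).to_csv(
        out / "assignment.csv", index=False)
    (out / "homogeneity.json").write_text(json.dumps({
        "k": mset.k, "mean": mset.mean_homogeneity, "sd": mset.sd_homogeneity}, indent=2))
    record("compress", t0, k=mset.k, mean_homogeneity=round(mset.mean_homogeneity, 3))

    # -- cluster -----------------------------------------------------------
    t0 = _time.perf_counter()
    D = clustering.hamming_matrix(mset.medoids)
    model = clustering.ward_cluster(D, mset.member_counts, config.n_clusters)
    model = clustering.order_by_severity(model, seqs, mset.assignment)
    labels = pd.DataFrame({"patient_id": ids,
                           "cluster": model.labels[mset.assignment]})
    labels.to_csv(out / "labels.csv", index=False)
    pd.DataFrame(model.merges, columns=["node_a", "node_b", "height", "size"]).to_csv(
        out / "merge_tree.csv", index=False)
    raster, row_clusters = clustering.visualization_matrix(model, mset.medoids)
    pd.DataFrame(raster).assign(cluster=row_clusters).to_csv(
        out / "raster.csv", index=False)
    (out / "silhouette.json").write_text(json.dumps(
        {"n_clusters": model.n_clusters,
         "silhouette": model.silhouette_value,
         "patient_counts": model.patient_counts().tolist()}, indent=2))
    record("cluster", t0, n_clusters=model.n_clusters,
           silhouette=None if model.silhouette_value is None
           else round(model.silhouette_value, 4))

    # -- profile -----------------------------------------------------------
    t0 = _time.perf_counter()
    label_series = labels.set_index("patient_id")["cluster"]
    table = profiling.profile(covariates, events, label_series, DEFAULT_PROFILE_SPECS)
    table.to_csv(out / "profile.csv", index=False)
    record("profile", t0, n_rows=len(table))

    # -- survive -----------------------------------------------------------
    t0 = _time.perf_counter()
    records = survival.build_survival_records(covariates, label_series)
    km_rows = []
    for c in sorted(records["cluster"].unique()):
        sub = records[records["cluster"] == c]
        km = survival.km_fit(sub["time"], sub["event"])
        km_rows.append(pd.DataFrame({
            "cluster": c, "time": km.times, "n_risk": km.n_risk,
            "n_events": km.n_events, "survival": km.survival}))
    pd.concat(km_rows).to_csv(out / "km.csv", index=False)
    stat, df, p = survival.log_rank(records["time"], records["event"],
                                    records["cluster"])
    pw = survival.log_rank(records["time"], records["event"], records["cluster"],
                           pairwise=True)
    pw.to_csv(out / "logrank_pairwise.csv", index=False)
    X = pd.get_dummies(records[["age", "male", "cluster"]].astype({"cluster": str}),
                       columns=["cluster"], drop_first=True).astype(float)
    fit = survival.cox_fit(X, records["time"].to_numpy(), records["event"].to_numpy())
    fit.summary().to_csv(out / "cox.csv", index=False)
    (out / "logrank.json").write_text(json.dumps(
        {"statistic": stat, "df": df, "p_value": p}, indent=2))
    record("survive", t0, n_records=len(records), logrank_p=p)

    manifest["n_completed_stages"] = sum(
        1 for s in manifest["stages"].values() if s["status"] == "completed")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
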