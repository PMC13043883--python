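"""Pipeline orchestration.

``run_pipeline`` executes simulate -> normalize -> fit -> assign ->
associate -> clinical from a single :class:`~substage.config.RunConfig`,
writing an auditable results directory.  Each stage is also callable on its
own (the CLI subcommands map onto them) and communicates only through files
in the output directory, so re-running any stage from the same config and
inputs reproduces its outputs bit for bit.  All randomness derives from
named sub-streams of the root seed.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import pandas as pd

from . import association as assoc
from . import clinical as clin
from . import cohort, io, normalization, sustain
from .config import RunConfig, substream_seed

__all__ = [
    "run_pipeline", "read_inputs",
    "stage_simulate", "stage_normalize", "stage_fit",
    "stage_assign", "stage_associate", "stage_clinical",
]

log = logging.getLogger("substage")

ARTEFACTS = (
    "config.yaml", "truth.yaml", "subjects.csv", "volumes.csv",
    "connectivity.csv", "control_model.yaml", "zscores.csv", "model.yaml",
    "assignments.csv",
)


def _meta(cfg: RunConfig) -> dict:
    return {"config": cfg.digest()}


def read_inputs(subjects_path, volumes_path, connectivity_path=None):
    """Load and cross-validate the three input tables.

    Rows of the volume matrix and connectivity stack must cover the subject
    table's ids; volumes are reindexed to subject order.
    """
    subjects = io.read_subjects(subjects_path)
    cohort.validate_subjects(subjects)
    volumes = io.read_matrix(volumes_path)
    missing = set(subjects["subject_id"]) - set(volumes.index)
    if missing:
        raise ValueError(f"volume matrix missing subjects: {sorted(missing)[:5]}")
    volumes = volumes.loc[subjects["subject_id"]]
    conn = None
    if connectivity_path is not None:
        conn = io.read_connectivity(connectivity_path)
        missing = set(subjects["subject_id"]) - set(conn.subject_ids)
        if missing:
            raise ValueError(f"connectivity missing subjects: {sorted(missing)[:5]}")
    return subjects, volumes, conn


def stage_simulate(cfg: RunConfig, out: Path) -> None:
    c = cfg.cohort
    reg = cohort.default_registry()
    subjects = cohort.generate_demographics(
        c.n_controls, c.n_patients, seed=substream_seed(cfg.seed, "demographics"))
    sequences = None
    if c.opposed_sequences:
        if c.n_subtypes != 2:
            raise ValueError("opposed_sequences requires exactly 2 subtypes")
        sequences = cohort.opposed_pair(len(reg.biomarkers), cfg.sustain.z_thresholds)
    truth = cohort.generate_truth(
        c.n_patients, c.n_subtypes, reg.biomarkers,
        z_thresholds=cfg.sustain.z_thresholds, fractions=c.fractions,
        seed=substream_seed(cfg.seed, "truth"), sequences=sequences)
    truth.planted_edges = [
        cohort.PlantedEdge(e.i, e.j, e.rho, e.subtype) for e in c.planted_edges]
    volumes = cohort.generate_volumes(
        subjects, truth, noise_sd=c.volume_noise_sd, registry=reg,
        split_bilateral=c.split_bilateral, asymmetry_sd=c.asymmetry_sd,
        seed=substream_seed(cfg.seed, "volumes"))
    conn = cohort.generate_connectivity(
        subjects, truth, n_regions=c.n_regions, planted=truth.planted_edges,
        edge_noise_sd=c.edge_noise_sd, seed=substream_seed(cfg.seed, "connectivity"))
    subjects = cohort.generate_clinical(
        subjects, truth, slopes=c.clinical_slopes, score_noise_sd=c.score_noise_sd,
        seed=substream_seed(cfg.seed, "clinical"))
    truth.clinical_slopes = {
        k: list(v) for k, v in (c.clinical_slopes or {}).items()}
    m = _meta(cfg)
    io.write_subjects(subjects, out / "subjects.csv", m)
    io.write_matrix(volumes, out / "volumes.csv", m)
    io.write_connectivity(conn, out / "connectivity.csv", m)
    io.write_yaml(truth.to_dict(), out / "truth.yaml")


def stage_normalize(cfg: RunConfig, out: Path) -> None:
    subjects, volumes, _ = read_inputs(out / "subjects.csv", out / "volumes.csv")
    reg = cohort.default_registry()
    pairs = {b: lr for b, lr in reg.bilateral_pairs.items()
             if lr[0] in volumes.columns and lr[1] in volumes.columns}
    if pairs:
        volumes = normalization.average_bilateral(volumes, pairs)
    model = normalization.fit_control_model(volumes, subjects)
    z = normalization.compute_zscores(volumes, subjects, model)
    m = _meta(cfg)
    io.write_yaml(model.to_dict(), out / "control_model.yaml")
    io.write_matrix(volumes, out / "volumes_bilateral.csv", m)
    io.write_matrix(z, out / "zscores.csv", m)


def stage_fit(cfg: RunConfig, out: Path) -> None:
    subjects = io.read_subjects(out / "subjects.csv")
    z = io.read_matrix(out / "zscores.csv")
    pat = subjects.loc[subjects["group"] == "patient", "subject_id"]
    Z = z.loc[pat].to_numpy()
    s = cfg.sustain
    models = sustain.fit_subtypes(
        Z, max_subtypes=s.max_subtypes, n_restarts=s.n_restarts,
        em_iters=s.em_iters, seed=substream_seed(cfg.seed, "fit"),
        sigma=s.sigma, z_max=s.z_max, thresholds=tuple(s.z_thresholds),
        split_restarts=s.split_restarts)
    chosen = sustain.select_model(models, param_count=s.bic_param_count)
    table = [
        {"n_subtypes": m.n_subtypes,
         "log_likelihood": m.log_likelihood,
         "bic": sustain.bic(m, param_count=s.bic_param_count)}
        for m in models
    ]
    best = models[chosen - 1]
    doc = best.to_dict()
    doc["biomarkers"] = list(z.columns)
    doc["selected_n_subtypes"] = chosen
    doc["bic_table"] = table
    io.write_yaml(doc, out / "model.yaml")
    log.info("selected %d subtype(s); BIC table: %s", chosen, table)


def _load_model(out: Path):
    doc = io.read_yaml(out / "model.yaml")
    model = sustain.SubtypeModel.from_dict(doc, len(doc["biomarkers"]))
    return model, doc


def stage_assign(cfg: RunConfig, out: Path) -> None:
    subjects = io.read_subjects(out / "subjects.csv")
    z = io.read_matrix(out / "zscores.csv")
    model, doc = _load_model(out)
    pat = subjects.loc[subjects["group"] == "patient", "subject_id"]
    Z = z.loc[pat].to_numpy()
    a = sustain.assign_subjects(Z, model)
    df = pd.DataFrame({
        "subject_id": pat.to_numpy(), "subtype": a.subtype, "stage": a.stage,
        "subtype_posterior": a.subtype_posterior, "tied": a.tied,
    })
    io.write_csv(df, out / "assignments.csv", _meta(cfg))
    rows = []
    for c, seq in enumerate(model.sequences):
        E = sustain.expected_z_matrix(seq, model.z_max)
        for k in range(seq.n_events + 1):
            for b, name in enumerate(doc["biomarkers"]):
                rows.append({"subtype": c, "stage": k, "biomarker": name,
                             "expected_z": E[k, b]})
    io.write_csv(pd.DataFrame(rows), out / "expected_z.csv", _meta(cfg))


def stage_associate(cfg: RunConfig, out: Path) -> None:
    subjects, volumes, conn = read_inputs(
        out / "subjects.csv", out / "volumes_bilateral.csv", out / "connectivity.csv")
    assign = io.read_csv(out / "assignments.csv")
    a = cfg.association
    meta = {"B": a.n_permutations, "volume_covariates": a.volume_covariates,
            "edge_covariates": a.edge_covariates, "subtypes": {}}
    sub_order = {sid: k for k, sid in enumerate(subjects["subject_id"])}
    edge_vals, pairs = conn.edge_matrix()
    edge_names = [f"{conn.regions[i]}--{conn.regions[j]}" for i, j in pairs]
    for c in sorted(assign["subtype"].unique()):
        members = assign.loc[assign["subtype"] == c]
        rows = [sub_order[s] for s in members["subject_id"]]
        n_c = len(rows)
        max_cov = max(len(a.volume_covariates), len(a.edge_covariates))
        if n_c < max(a.min_subtype_n, max_cov + 3):
            log.warning("subtype %d has %d patients; association scan skipped", c, n_c)
            continue
        stage = members["stage"].to_numpy(dtype=float)
        sub = subjects.iloc[rows]
        seed_v = substream_seed(cfg.seed, f"assoc-vol-{c}")
        res_v = assoc.permutation_scan(
            stage, volumes.iloc[rows],
            assoc.design_from_subjects(sub, a.volume_covariates),
            B=a.n_permutations, seed=seed_v)
        seed_e = substream_seed(cfg.seed, f"assoc-edge-{c}")
        res_e = assoc.permutation_scan(
            stage, edge_vals[rows], assoc.design_from_subjects(sub, a.edge_covariates),
            B=a.n_permutations, seed=seed_e, unit_names=edge_names)
        m = _meta(cfg)
        for res, tag in ((res_v, "volumes"), (res_e, "edges")):
            ordered = res.reindex(res["rho"].abs().sort_values(ascending=False).index)
            io.write_csv(ordered, out / f"assoc_{tag}_subtype{c}.csv", m)
        meta["subtypes"][int(c)] = {
            "n": n_c, "seed_volumes": seed_v, "seed_edges": seed_e,
            "volume_fdr_hits": int((res_v["q_fdr"] < a.fdr_q).sum()),
            "edge_fdr_hits": int((res_e["q_fdr"] < a.fdr_q).sum()),
            "edge_fwer_hits": int((res_e["p_fwer"] < a.alpha).sum()),
        }
    io.write_yaml(meta, out / "association_meta.yaml")


_DEMOGRAPHIC_VARS = (("age", False), ("sex", True), ("handedness", True),
                     ("scanner", True))


def stage_clinical(cfg: RunConfig, out: Path) -> None:
    subjects = io.read_subjects(out / "subjects.csv")
    assign = io.read_csv(out / "assignments.csv")
    merged = subjects.merge(assign, on="subject_id", how="left")
    scores = [c for c in subjects.columns if c not in cohort.SUBJECT_COLUMNS]
    rows = []

    def add(context, r: clin.ComparisonResult):
        rows.append({"context": context, "variable": r.variable, "test": r.test,
                     "statistic": r.statistic, "p_value": r.p_value, "n": r.n,
                     **{f"extra_{k}": v for k, v in r.extra.items()}})

    for var, cat in _DEMOGRAPHIC_VARS:
        add("patient_vs_control",
            clin.compare_groups(subjects[var], subjects["group"], var, categorical=cat))
    pat = merged[merged["group"] == "patient"]
    subtypes = sorted(pat["subtype"].dropna().unique())
    for score in scores:
        if len(subtypes) >= 2:
            two = pat[pat["subtype"].isin(subtypes[:2])]
            try:
                add("subtype_comparison",
                    clin.compare_groups(two[score], two["subtype"], score))
                add("subtype_comparison_stage_adjusted",
                    clin.ancova_stage_adjusted(two[score], two["subtype"],
                                               two["stage"], score))
            except ValueError as err:
                log.warning("skipping %s subtype comparison: %s", score, err)
        for c in subtypes:
            grp = pat[pat["subtype"] == c]
            try:
                add(f"stage_regression_subtype{int(c)}",
                    clin.stage_clinical_regression(
                        grp[score], grp["stage"], grp["age"], grp["sex"], score))
            except ValueError as err:
                log.warning("skipping %s stage regression (subtype %s): %s",
                            score, c, err)
    io.write_csv(pd.DataFrame(rows), out / "clinical.csv", _meta(cfg))


_STAGES = (
    ("simulate", stage_simulate),
    ("normalize", stage_normalize),
    ("fit", stage_fit),
    ("assign", stage_assign),
    ("associate", stage_associate),
    ("clinical", stage_clinical),
)


def run_pipeline(cfg: RunConfig, overwrite: bool = False) -> Path:
    """Run every stage from one config; returns the results directory."""
    out = Path(cfg.output_dir)
    existing = [a for a in ARTEFACTS if (out / a).exists()]
    if existing and not overwrite:
        raise FileExistsError(
            f"{out} already holds pipeline artefacts ({existing[:3]}...); "
            "pass overwrite=True to redo")
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    timings = {}
    try:
        cfg.to_yaml(out / "config.yaml")
        log.info("run config digest %s, root seed %d", cfg.digest(), cfg.seed)
        for name, fn in _STAGES:
            t0 = time.perf_counter()
            fn(cfg, out)
            timings[name] = round(time.perf_counter() - t0, 3)
            log.info("stage %-9s done in %.2fs", name, timings[name])
        doc = io.read_yaml(out / "model.yaml")
        summary = {
            "config_digest": cfg.digest(),
            "seed": cfg.seed,
            "selected_n_subtypes": doc["selected_n_subtypes"],
            "bic_table": doc["bic_table"],
            "timings_s": timings,
        }
        io.write_yaml(summary, out / "summary.yaml")
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
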