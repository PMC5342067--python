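"""End-to-end orchestration: simulate/load → diversity → stratify →
survival → robustness → validation, with a reproducible run manifest.

The pipeline configuration is a plain dict (or YAML file) with optional
blocks::

    seed: 0
    simulate: { ...CohortConfig fields... }     # or:
    inputs: {cells: cells.tsv, clinical: clinical.tsv, annotations: ann.tsv}
    stratify: {metdiv_method: iterative}        # iterative | median
    robustness: {enabled: true, n_reps: 200, fractions: [0.7, 0.8, 0.9, 1.0]}
    plots: true

All randomness flows from the single root seed (per-stage streams are
spawned from it), and the manifest records a SHA-256 digest of every text
output, so two runs of the same config are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity, io, robustness, stratify, survival
from .exceptions import ConfigError, MetdivError
from .simulate import CohortConfig, generate_annotations, generate_cohort
from .validation import agreement_table, confusion_metrics

log = logging.getLogger("metdiv.pipeline")


@dataclass
class RunManifest:
    config: dict
    seed: int
    package_version: str
    stage_counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)       # filename -> sha256
    excluded_patients: list = field(default_factory=list)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_config(config) -> dict:
    if config is None:
        return {}
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            return yaml.safe_load(fh) or {}
    if isinstance(config, CohortConfig):
        return {"simulate": config.to_dict()}
    return dict(config)


def _grouped_fits(merged: pd.DataFrame, groupings: dict, endpoint: str,
                  dur: str, ev: str) -> pd.DataFrame:
    rows = []
    for name, grp in groupings.items():
        lab = grp.labels.reindex(merged["patient_id"]).to_numpy()
        ok = pd.notna(lab)
        fit = survival.grouped_univariate_fit(
            merged.loc[ok, dur], merged.loc[ok, ev], lab[ok],
            name=name, endpoint=endpoint)
        rows.append({
            "variable": name, "endpoint": endpoint,
            "hr": fit.hr[name], "ci_low": fit.ci_low[name],
            "ci_high": fit.ci_high[name], "p": fit.p[name],
            "logrank_p": fit.logrank_p, "concordance": fit.concordance,
            "threshold": grp.threshold, "method": grp.method,
            "n_low": grp.n_low, "n_high": grp.n_high,
        })
    return pd.DataFrame(rows)


def run_pipeline(config=None, out_dir="metdiv_run", seed: int | None = None) -> RunManifest:
    """Run the full analysis; returns the manifest (also written as JSON).

    ``config`` may be a dict, a YAML path, a :class:`CohortConfig`
    (simulation-only shorthand) or None for the default synthetic cohort.
    ``seed`` overrides the config seed.
    """
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_seed = int(cfg.get("seed", 0) if seed is None else seed)
    manifest = RunManifest(config=cfg, seed=root_seed, package_version=_pkg_version("metdiv"))
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        written.append(path)

    # -- stage 1: data -------------------------------------------------
    ss = np.random.SeedSequence(root_seed)
    s_sim, s_ann, s_rob = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))
    annotations = None
    if "inputs" in cfg:
        inp = cfg["inputs"]
        cells = io.read_cell_table(inp["cells"])
        clinical = io.read_clinical(inp["clinical"])
        if inp.get("annotations"):
            annotations = io.read_annotations(inp["annotations"])
    else:
        sim_cfg = CohortConfig.from_dict({**cfg.get("simulate", {}), "seed": s_sim})
        cohort = generate_cohort(sim_cfg, with_cells=True)
        cells, clinical = cohort.cells, cohort.clinical
        emit(cohort.truth_sections, "truth_sections.tsv")
        emit(cohort.truth_patients, "truth_patients.tsv")
        io.write_cell_table(cells, out / "cells.tsv")
        written.append(out / "cells.tsv")
        io.write_clinical(clinical, out / "clinical.tsv")
        written.append(out / "clinical.tsv")
        annotations = generate_annotations(seed=s_ann)
        io.write_annotations(annotations, out / "annotations.tsv")
        written.append(out / "annotations.tsv")
    manifest.stage_counts["cells"] = len(cells)
    manifest.stage_counts["patients"] = len(clinical)

    # -- stage 2: diversity --------------------------------------------
    sections = diversity.section_table(cells)
    emit(sections, "sections.tsv")
    profiles = diversity.patient_table(sections)
    excluded = profiles.loc[profiles["metdiv"].isna(), "patient_id"].tolist()
    if excluded:
        log.warning("excluding %d patient(s) without a non-ovary section: %s",
                    len(excluded), excluded)
    manifest.excluded_patients = excluded
    profiles = profiles[profiles["metdiv"].notna()].reset_index(drop=True)
    if profiles.empty:
        raise MetdivError("diversity stage: MetDiv undefined for every patient "
                          "(no non-ovary sections)")
    emit(profiles, "profiles.tsv")
    manifest.stage_counts["sections"] = len(sections)
    manifest.stage_counts["profiled"] = len(profiles)

    merged = profiles.merge(clinical, on="patient_id", validate="1:1")

    # -- stage 3: stratification ---------------------------------------
    strat_cfg = cfg.get("stratify", {})
    metdiv_method = strat_cfg.get("metdiv_method", "iterative")
    scores = merged.set_index("patient_id")
    if metdiv_method == "iterative":
        g_metdiv = stratify.iterative_threshold(
            scores["metdiv"], scores["os_months"], scores["os_event"],
            variable="metdiv")
    elif metdiv_method == "median":
        g_metdiv = stratify.median_split(scores["metdiv"], variable="metdiv")
    else:
        raise ConfigError(f"unknown metdiv_method {metdiv_method!r}")
    groupings = {"metdiv_group": g_metdiv}
    if scores["ovary_stromal_ratio"].notna().sum() >= 4:
        groupings["stromal_group"] = stratify.median_split(
            scores["ovary_stromal_ratio"], variable="ovary_stromal_ratio")
    if scores["ovary_lym_ratio"].notna().sum() >= 6:
        groupings["lym_group"] = stratify.tertile_split(
            scores["ovary_lym_ratio"], variable="ovary_lym_ratio")
    groupings["age_group"] = stratify.median_split(scores["age"], variable="age")

    groups_df = pd.DataFrame({"patient_id": scores.index})
    for name, grp in groupings.items():
        groups_df[name] = grp.labels.reindex(scores.index).to_numpy()
    emit(groups_df, "groups.tsv")

    # -- stage 4: survival ---------------------------------------------
    reports = {}
    for endpoint, dur, ev in (("OS", "os_months", "os_event"),
                              ("PFS", "pfs_months", "pfs_event")):
        reports[endpoint] = _grouped_fits(merged, groupings, endpoint, dur, ev)
        emit(reports[endpoint], f"survival_{endpoint.lower()}.tsv")

    # multivariate: OS-eligible factors (univariate p < 0.05) plus forced
    forced = strat_cfg.get("force", ["stromal_group", "lym_group"])
    eligible = survival.select_multivariate_factors(
        list(zip(reports["OS"]["variable"], reports["OS"]["p"])))
    multi_covs = list(dict.fromkeys(eligible + [f for f in forced if f in groupings]))
    multi_rows = []
    if len(multi_covs) >= 2:
        design = pd.DataFrame({
            name: (groups_df.set_index("patient_id")[name]
                   .reindex(merged["patient_id"]) == "high").astype(int).to_numpy()
            for name in multi_covs})
        for endpoint, dur, ev in (("OS", "os_months", "os_event"),
                                  ("PFS", "pfs_months", "pfs_event")):
            d = design.copy()
            d["_t"] = merged[dur].to_numpy()
            d["_e"] = merged[ev].to_numpy()
            fit = survival.cox_fit_robust(d, "_t", "_e", multi_covs, endpoint=endpoint)
            for c in multi_covs:
                multi_rows.append({
                    "endpoint": endpoint, "variable": c, "hr": fit.hr[c],
                    "ci_low": fit.ci_low[c], "ci_high": fit.ci_high[c],
                    "p": fit.p[c], "concordance": fit.concordance,
                    "forced": c not in eligible,
                })
        emit(pd.DataFrame(multi_rows), "survival_multivariate.tsv")

    # landmark 5-year OS by MetDiv group
    lab = g_metdiv.labels.reindex(merged["patient_id"]).to_numpy()
    landmark_rows = []
    for grp_name in ("low", "high"):
        m = lab == grp_name
        km = survival.km_estimate(merged.loc[m, "os_months"], merged.loc[m, "os_event"])
        landmark_rows.append({"metdiv_group": grp_name, "n": int(m.sum()),
                              "os_5yr": survival.landmark_survival(km, 60.0)})
    emit(pd.DataFrame(landmark_rows), "landmark_os.tsv")

    _write_report(out / "report.txt", reports, multi_rows, landmark_rows, g_metdiv)
    written.append(out / "report.txt")

    # -- stage 5: robustness -------------------------------------------
    rob_cfg = cfg.get("robustness", {})
    if rob_cfg.get("enabled", True):
        curve = robustness.resampling_stability(
            merged["os_months"].to_numpy(), merged["os_event"].to_numpy(),
            labels=lab, fractions=tuple(rob_cfg.get("fractions", (0.7, 0.8, 0.9, 1.0))),
            n_reps=int(rob_cfg.get("n_reps", 200)), seed=s_rob, endpoint="OS")
        emit(curve.as_frame().assign(analysis=curve.analysis), "stability_resampling.tsv")
        first_sid = sections["section_id"].iloc[0]
        first = cells[cells["section_id"] == first_sid]
        sub = robustness.cell_subsampling_stability(first, n_reps=int(rob_cfg.get("n_reps", 200)) // 2 or 1,
                                                    seed=s_rob)
        emit(sub.as_frame().assign(section_id=sub.section_id), "stability_subsampling.tsv")
        splits = [robustness.half_split_stability(first, o) for o in ("vertical", "horizontal")]
        emit(pd.DataFrame([vars(s) for s in splits]), "stability_halfsplit.tsv")

    # -- stage 6: validation -------------------------------------------
    if annotations is not None:
        emit(confusion_metrics(annotations, by_site=True), "validation_confusion.tsv")

    # -- stage 7: plots -------------------------------------------------
    if cfg.get("plots", True):
        from . import plots
        groups_km = {
            name: (merged.loc[lab == name, "os_months"], merged.loc[lab == name, "os_event"])
            for name in ("low", "high")
        }
        plots.km_plot(groups_km, out / "km_os.png", title="OS by MetDiv group")
        plots.ternary_plot(sections, out / "ternary.png",
                           title="Section compositions over Shannon field")

    for path in written:
        manifest.outputs[path.name] = _sha256(path)
    manifest.save(out / "manifest.json")
    return manifest


def _write_report(path: Path, reports: dict, multi_rows: list,
                  landmark_rows: list, g_metdiv) -> None:
    lines = ["Prognostic value of MetDiv and other groupings", "=" * 60, ""]
    for endpoint, df in reports.items():
        lines.append(f"Univariate ({endpoint}):")
        for _, r in df.iterrows():
            lines.append(
                f"  {r['variable']:<16s} HR {r['hr']:.2f} "
                f"({r['ci_low']:.2f}-{r['ci_high']:.2f})  p={r['p']:.4g}  "
                f"logrank p={r['logrank_p']:.4g}  Conc {r['concordance']:.2f}")
        lines.append("")
    if multi_rows:
        lines.append("Multivariate:")
        for r in multi_rows:
            tag = " (forced)" if r["forced"] else ""
            lines.append(
                f"  {r['endpoint']:<4s} {r['variable']:<16s} HR {r['hr']:.2f} "
                f"({r['ci_low']:.2f}-{r['ci_high']:.2f})  p={r['p']:.4g}{tag}")
        lines.append("")
    lines.append("5-year OS by MetDiv group "
                 f"(method={g_metdiv.method}, threshold={g_metdiv.threshold:.4f}):")
    for r in landmark_rows:
        val = "undefined" if pd.isna(r["os_5yr"]) else f"{100 * r['os_5yr']:.1f}%"
        lines.append(f"  {r['metdiv_group']:<5s} (n={r['n']}): {val}")
    lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")
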