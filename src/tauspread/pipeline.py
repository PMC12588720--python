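"""End-to-end orchestration: simulate -> harmonize -> connectome -> trajectories
-> epicentres -> association, with a machine-readable summary per run.

A run writes every stage artefact into one immutable run directory, stamped
with the config hash and seed, so reruns with the same config are
reproducible and comparable byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, connectome, epicentres, harmonize, io, synthetic, trajectories
from .errors import InvalidArgumentError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """All tunable parameters of a pipeline run.

    Defaults follow the published analysis conventions: 30% connection
    density, top-5% epicentres, 1000 connectome null models, 0.5 mm
    scrubbing threshold with a 5-minute usable-data minimum, and
    age/sex/site covariate adjustment.
    """

    seed: int = 0
    # synthetic study
    n_roi: int = 200
    n_networks: int = 7
    n_subjects: int = 50
    n_controls: int = 30
    timepoints: tuple[float, ...] = (0.0, 1.0, 2.0)
    n_bold_subjects: int = 42
    n_frames: int = 400
    tr: float = 2.0
    # analysis parameters
    density: float = 0.30
    epicentre_fraction: float = 0.05
    n_nulls: int = 1000
    covariates: tuple[str, ...] = ("age", "sex", "site")
    value_kind: str = "positivity"        # tau scale for covariance/quartiles
    scrub_threshold_mm: float = 0.5
    min_usable_seconds: float = 300.0

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["timepoints"] = list(self.timepoints)
        payload["covariates"] = list(self.covariates)
        with open(path, "w") as fh:
            yaml.safe_dump({"run": payload}, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)["run"]
        payload["timepoints"] = tuple(payload["timepoints"])
        payload["covariates"] = tuple(payload["covariates"])
        return cls(**payload)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload["timepoints"] = list(self.timepoints)
        payload["covariates"] = list(self.covariates)
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage on a synthetic study and write all artefacts.

    Returns the machine-readable summary (also written to ``summary.json``).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": config.config_hash(), "seed": config.seed}

    # -- stage 1: synthetic study ----------------------------------------
    study = synthetic.build_study(config.seed, n_roi=config.n_roi,
                                  n_networks=config.n_networks,
                                  density=config.density)
    study.atlas.to_tsv(out / "atlas.tsv")
    study.scenario.to_yaml(out / "scenario.yaml")
    cohort, truth = synthetic.simulate_tau_cohort(
        study.distance, study.scenario, n_subjects=config.n_subjects,
        timepoints=config.timepoints, n_controls=config.n_controls,
        noise_coupling=study.connectome)
    io.write_cohort(cohort, out / "cohort.tsv")

    # -- stage 2: connectome from control BOLD ---------------------------
    fc_list = []
    for s in range(config.n_bold_subjects):
        series, fd = synthetic.sample_bold(study.connectome, config.n_frames,
                                           tr=config.tr, seed=config.seed + 1000 + s)
        report = connectome.scrub(fd, tr=config.tr,
                                  threshold=config.scrub_threshold_mm,
                                  min_usable_seconds=config.min_usable_seconds)
        if not report.valid:
            logger.warning("BOLD subject %d below usable-duration minimum; excluded", s)
            continue
        fc_list.append(connectome.compute_fc(series, report.kept))
    group = connectome.group_fc(fc_list)
    thresholded = connectome.threshold_density(group, density=config.density)
    dist = connectome.fc_to_distance(thresholded, density=config.density)
    io.write_matrix(dist.matrix, out / "fc_distance.tsv")
    summary["n_disconnected_pairs"] = dist.n_disconnected_pairs

    # -- stage 3: harmonization ------------------------------------------
    model = harmonize.TracerMixtureModel.fit(cohort, seed=config.seed)
    model.to_tsv(out / "mixture_model.tsv")
    harmonized = model.apply(cohort)
    io.write_cohort(harmonized, out / "cohort_harmonized.tsv")

    patients = harmonized[harmonized["group"] == "patient"]
    suvr_wide = io.cohort_to_wide(patients, "suvr")
    value_col = config.value_kind if config.value_kind in harmonized.columns else "suvr"
    value_wide = io.cohort_to_wide(patients, value_col)
    meta = io.subject_metadata(patients)
    covariates = meta[[c for c in config.covariates if c in meta.columns]]

    # -- stage 4: trajectories -------------------------------------------
    change_wide = None
    if len(config.timepoints) > 1:
        change = trajectories.cohort_change_maps(patients)
        change.to_csv(out / "pct_change.tsv", sep="\t", index=False)
        change_wide = change.pivot(index="subject_id", columns="roi_id",
                                   values="pct_change").sort_index(axis=1)

    # -- stage 5: epicentres ---------------------------------------------
    epis = epicentres.cohort_epicentres(suvr_wide, config.epicentre_fraction,
                                        basis="baseline_suvr")
    epicentres.epicentres_to_frame(epis).to_csv(out / "epicentres.tsv",
                                                sep="\t", index=False)
    planted = set(study.scenario.epicentre_rois)
    if planted:
        hits = [len(planted & set(e.roi_set)) for e in epis]
        summary["epicentre_recovery_rate"] = float(
            np.mean([h >= 0.8 * len(planted) for h in hits]))
        summary["mean_epicentre_overlap"] = float(np.mean(hits))
    prob = epicentres.probability_map(epis, config.n_roi, display_threshold=20.0)
    prob.to_csv(out / "epicentre_probability.tsv", sep="\t", index=False)
    if change_wide is not None:
        acc_epis = epicentres.cohort_epicentres(change_wide, config.epicentre_fraction,
                                                basis="pct_change")
        epicentres.probability_map(acc_epis, config.n_roi, display_threshold=10.0
                                   ).to_csv(out / "accumulation_epicentre_probability.tsv",
                                            sep="\t", index=False)

    # -- stage 6: covariance vs distance ---------------------------------
    cov = association.tau_covariance(value_wide, covariates, kind="pearson")
    actual = association.covariance_vs_distance(cov, dist)
    rows = [{"scope": actual.scope, "beta_std": actual.beta_std,
             "p_param": actual.p_param, "n_pairs": actual.n_pairs}]
    for network in study.atlas.networks:
        try:
            res = association.covariance_vs_distance(cov, dist, scope=network,
                                                     atlas=study.atlas)
            rows.append({"scope": network, "beta_std": res.beta_std,
                         "p_param": res.p_param, "n_pairs": res.n_pairs})
        except InvalidArgumentError:
            continue
    summary["beta_std_whole_brain"] = actual.beta_std

    if config.n_nulls > 0:
        null = association.null_distribution(cov, thresholded, actual,
                                             B=config.n_nulls, seed=config.seed + 5000,
                                             density=config.density)
        pd.DataFrame({"replicate": np.arange(null.B), "beta": null.betas}
                     ).to_csv(out / "null_betas.tsv", sep="\t", index=False)
        rows[0]["p_exact"] = null.p_exact
        rows[0]["B"] = null.B
        summary["p_exact_whole_brain"] = null.p_exact
    pd.DataFrame(rows).to_csv(out / "associations.tsv", sep="\t", index=False)

    # -- stage 7: subject gradients and quartiles ------------------------
    epi_dists = {e.subject_id: connectome.epicentre_distance(dist, np.array(e.roi_set))
                 for e in epis}
    gradients = association.cohort_gradients(suvr_wide, epi_dists)
    gradients.to_csv(out / "subject_gradients.tsv", sep="\t", index=False)
    summary["median_subject_beta"] = float(gradients["beta_std"].median())

    quart = association.quartile_gradient(value_wide, epi_dists,
                                          value_kind=value_col)
    quart.quartile_means.to_csv(out / "quartile_means.tsv", sep="\t", index=False)
    quart.pairwise_tests.to_csv(out / "quartile_tests.tsv", sep="\t", index=False)
    group_means = quart.quartile_means.groupby("quartile")["mean_value"].mean()
    summary["quartile_means"] = [float(group_means[q]) for q in range(1, 5)]
    summary["quartile_max_p"] = float(quart.pairwise_tests["p_value"].max())

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    config.to_yaml(out / "config.yaml")
    return summary


def make_report(run_dir: str | Path) -> Path:
    """Render tables and figures from a completed run into ``report.md``.

    Regeneration is idempotent; an incomplete run raises with the missing
    artefacts listed.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run = Path(run_dir)
    required = ["summary.json", "associations.tsv", "epicentre_probability.tsv",
                "quartile_means.tsv", "fc_distance.tsv"]
    missing = [f for f in required if not (run / f).exists()]
    if missing:
        raise InvalidArgumentError(f"incomplete run, missing: {missing}")

    summary = json.loads((run / "summary.json").read_text())
    figures = []

    dist = io.read_matrix(run / "fc_distance.tsv")
    prob = pd.read_csv(run / "epicentre_probability.tsv", sep="\t")
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.bar(prob["roi_id"], prob["probability"], width=1.0)
    ax.set_xlabel("ROI")
    ax.set_ylabel("epicentre probability (%)")
    fig.savefig(run / "fig_epicentre_probability.png", dpi=100)
    plt.close(fig)
    figures.append("fig_epicentre_probability.png")

    quart = pd.read_csv(run / "quartile_means.tsv", sep="\t")
    fig, ax = plt.subplots(figsize=(5, 4))
    quart.boxplot(column="mean_value", by="quartile", ax=ax)
    ax.set_xlabel("distance quartile (1 = closest to epicentre)")
    ax.set_ylabel("mean tau value")
    fig.suptitle("")
    ax.set_title("tau by epicentre-distance quartile")
    fig.savefig(run / "fig_quartile_gradient.png", dpi=100)
    plt.close(fig)
    figures.append("fig_quartile_gradient.png")

    if (run / "null_betas.tsv").exists():
        nulls = pd.read_csv(run / "null_betas.tsv", sep="\t")
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.hist(nulls["beta"], bins=30)
        ax.axvline(summary["beta_std_whole_brain"], color="red",
                   label=f"actual beta = {summary['beta_std_whole_brain']:.2f}")
        ax.set_xlabel("null-model standardized beta")
        ax.legend()
        fig.savefig(run / "fig_null_betas.png", dpi=100)
        plt.close(fig)
        figures.append("fig_null_betas.png")

    # covariance-vs-distance scatter needs the harmonized cohort; rebuild pairs
    if (run / "cohort_harmonized.tsv").exists():
        harmonized = io.read_cohort(run / "cohort_harmonized.tsv")
        patients = harmonized[harmonized["group"] == "patient"]
        value_col = "positivity" if "positivity" in patients.columns else "suvr"
        wide = io.cohort_to_wide(patients, value_col)
        meta = io.subject_metadata(patients)
        cov = association.tau_covariance(
            wide, meta[[c for c in ("age", "sex", "site") if c in meta.columns]])
        iu, ju = np.triu_indices(cov.n_roi, k=1)
        z, d = cov.matrix[iu, ju], dist[iu, ju]
        ok = np.isfinite(z) & np.isfinite(d)
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(d[ok], z[ok], ".", ms=1, alpha=0.3)
        ax.set_xlabel("functional connectivity-based distance")
        ax.set_ylabel("tau covariance (Fisher z)")
        fig.savefig(run / "fig_covariance_vs_distance.png", dpi=100)
        plt.close(fig)
        figures.append("fig_covariance_vs_distance.png")

    assoc = pd.read_csv(run / "associations.tsv", sep="\t")
    lines = ["# tauspread run report", "",
             f"Config hash: `{summary['config_hash']}`, seed {summary['seed']}.", "",
             "## Covariance vs functional distance", "",
             assoc.to_markdown(index=False), ""]
    if "quartile_means" in summary:
        lines += ["## Quartile gradient", "",
                  "Group-mean tau by distance quartile (Q1 closest): "
                  + ", ".join(f"{v:.2f}" for v in summary["quartile_means"]), ""]
    lines += ["## Figures", ""]
    lines += [f"![{f}]({f})" for f in figures]
    report = run / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report
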