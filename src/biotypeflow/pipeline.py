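"""End-to-end orchestration: discovery -> validation -> replication.

The discovery stage fits everything that is fit at all — covariate
residualization, feature screens, the (alpha x dimension) biotyping
grid, and both classifiers — on the training split; the validation
split only ranks candidate solutions and freezes the decision
threshold; the replication split is touched exactly once, with frozen
artifacts.  An audit helper proves no replication subject leaked into
any fitted model's provenance.

The genetic association stage treats the frozen classifier's biotype
scores (and the baseline case score) as quantitative traits, runs
QC + GRM + LMM Wald tests on the discovery subjects of the two large
ancestry groups, applies LD-adjusted Bonferroni, and re-tests the
significant SNPs on the replication subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from biotypeflow import classifier as clf
from biotypeflow import clustering, evaluation, genetics, screening
from biotypeflow.clustering import OMITTED, BiotypeSolution
from biotypeflow.motion import ResidualModel, fit_residual_model
from biotypeflow.synthetic import Cohort

GENETICS_POPULATIONS = ("EA", "AA")  # the two large ancestry groups


@dataclass
class PipelineConfig:
    """Every tunable of a full run, serialized into the run report."""

    alphas: Sequence[float] = (0.05, 0.005, 0.0005)
    dims: Sequence[int] = (2, 3, 4)
    k_candidates: Sequence[int] = (2, 3, 4)
    min_cluster_size: int = 20
    reducer: str = "umap"
    spearman_population: str = "all"
    classifier: clf.TrainConfig = field(default_factory=clf.TrainConfig)
    n_perm: int = 0
    qc_call_rate_min: float = 0.95
    qc_hwe_min: float = 1e-7
    qc_maf_min: float = 0.05
    ld_r2_threshold: float = 0.5
    ld_window: int = 50
    assoc_alpha: float = 0.05
    seed: int = 0


@dataclass
class DiscoveryResult:
    """Frozen artifacts and validation metrics of the discovery stage."""

    residual_model_scan1: ResidualModel
    residual_model_scan2: ResidualModel
    feature_masks: dict[float, np.ndarray]
    solutions: list[BiotypeSolution]
    selected_solution: BiotypeSolution
    baseline_model: clf.ClassifierModel
    aware_model: clf.ClassifierModel
    threshold: clf.DecisionThreshold
    threshold_baseline: clf.DecisionThreshold
    validation_auc_baseline: float
    validation_auc_aware: float
    grid_validation_aucs: list[float]
    adjusted: dict[str, np.ndarray]  # split/scan keyed adjusted FC panels
    train_biotype_labels: np.ndarray
    fitted_subject_ids: set[str]


def _covariates(subjects: pd.DataFrame) -> np.ndarray:
    return subjects[["age", "sex", "censored_frames"]].to_numpy(dtype=float)


def _biotype_label_vector(
    cohort: Cohort, solution: BiotypeSolution, train_mask: np.ndarray
) -> np.ndarray:
    """Per-train-subject labels: 0 control, 1..B biotype, OMITTED dropped cases."""
    am = cohort.am_mask()
    labels = np.zeros(int(train_mask.sum()), dtype=int)
    am_in_train = am[train_mask]
    labels[am_in_train] = solution.labels
    return labels


def run_discovery(cohort: Cohort, cfg: PipelineConfig) -> DiscoveryResult:
    subjects = cohort.subjects
    train = cohort.split_mask("train")
    val = cohort.split_mask("validation")
    rep = cohort.split_mask("replication")
    am = cohort.am_mask()
    cov = _covariates(subjects)

    # covariate residualization, fitted per scan on the training split
    res1 = fit_residual_model(cohort.fc_scan1[train], cov[train])
    res2 = fit_residual_model(cohort.fc_scan2[train], cov[train])
    adjusted = {
        "train_scan1": res1.transform(cohort.fc_scan1[train], cov[train]),
        "val_scan1": res1.transform(cohort.fc_scan1[val], cov[val]),
        "rep_scan1": res1.transform(cohort.fc_scan1[rep], cov[rep]),
        "train_scan2": res2.transform(cohort.fc_scan2[train], cov[train]),
    }

    metrics = subjects.loc[train, list(screening.METRIC_COLUMNS)].to_numpy(dtype=float)
    y_train = am[train].astype(int)
    masks = {
        alpha: screening.screen_features(
            adjusted["train_scan1"], metrics, y_train, alpha,
            spearman_population=cfg.spearman_population,
        ).selected
        for alpha in cfg.alphas
    }

    am_train_fc = adjusted["train_scan1"][am[train]]
    solutions = clustering.solution_grid(
        am_train_fc, masks, dims=cfg.dims, seed=cfg.seed,
        k_candidates=cfg.k_candidates, min_cluster_size=cfg.min_cluster_size,
        reducer=cfg.reducer,
    )
    if not solutions:
        raise ValueError("no biotyping solution could be built (all masks empty?)")

    y_val = am[val].astype(int)
    baseline = clf.train_baseline(
        adjusted["train_scan1"], y_train, adjusted["val_scan1"], y_val,
        seed=cfg.seed, config=cfg.classifier,
    )
    auc_baseline = clf.auc(baseline.predict_combined(adjusted["val_scan1"]), y_val)

    grid_aucs: list[float] = []
    best: tuple[float, BiotypeSolution, clf.ClassifierModel] | None = None
    for sol in solutions:
        blabs = _biotype_label_vector(cohort, sol, train)
        model = clf.train_biotype_aware(
            adjusted["train_scan1"], y_train, blabs,
            adjusted["val_scan1"], y_val, seed=cfg.seed, config=cfg.classifier,
        )
        val_auc = clf.auc(model.predict_combined(adjusted["val_scan1"]), y_val)
        grid_aucs.append(val_auc)
        if best is None or val_auc > best[0]:
            best = (val_auc, sol, model)
    assert best is not None
    auc_aware, selected, aware = best

    threshold = clf.choose_threshold(aware.predict_combined(adjusted["val_scan1"]), y_val)
    threshold_baseline = clf.choose_threshold(
        baseline.predict_combined(adjusted["val_scan1"]), y_val
    )

    fitted_ids = set(subjects.loc[train, "subject_id"]) | set(
        subjects.loc[val, "subject_id"]
    )
    return DiscoveryResult(
        residual_model_scan1=res1,
        residual_model_scan2=res2,
        feature_masks=masks,
        solutions=solutions,
        selected_solution=selected,
        baseline_model=baseline,
        aware_model=aware,
        threshold=threshold,
        threshold_baseline=threshold_baseline,
        validation_auc_baseline=auc_baseline,
        validation_auc_aware=auc_aware,
        grid_validation_aucs=grid_aucs,
        adjusted=adjusted,
        train_biotype_labels=_biotype_label_vector(cohort, selected, train),
        fitted_subject_ids=fitted_ids,
    )


def run_replication(cohort: Cohort, disc: DiscoveryResult) -> dict:
    """Apply every frozen artifact once to the replication split."""
    rep = cohort.split_mask("replication")
    y_rep = cohort.am_mask()[rep].astype(int)
    fc_rep = disc.adjusted["rep_scan1"]
    out: dict = {}
    for name, model, thr in (
        ("baseline", disc.baseline_model, disc.threshold_baseline),
        ("biotype_aware", disc.aware_model, disc.threshold),
    ):
        scores = model.predict_combined(fc_rep)
        sens, spec = clf._sens_spec(scores, y_rep, thr.cutoff)
        out[name] = {
            "auc": clf.auc(scores, y_rep),
            "sensitivity": sens,
            "specificity": spec,
            "gscore": clf.gscore(sens, spec),
        }
    return out


def audit_split_hygiene(cohort: Cohort, disc: DiscoveryResult) -> None:
    """Assert no replication subject took part in any model fit."""
    rep_ids = set(cohort.subjects.loc[cohort.split_mask("replication"), "subject_id"])
    leaked = rep_ids & disc.fitted_subject_ids
    if leaked:
        raise RuntimeError(f"replication subjects leaked into fitting: {sorted(leaked)[:5]}")


def scan2_consistency(cohort: Cohort, disc: DiscoveryResult) -> evaluation.ConsistencyReport:
    """Biotype-score robustness on the training subjects' second scan."""
    train = cohort.split_mask("train")
    am_train = cohort.am_mask()[train]
    fc2_am = disc.adjusted["train_scan2"][am_train]
    return evaluation.scan2_consistency(disc.aware_model, fc2_am, disc.selected_solution)


def replication_auc_metric(cohort: Cohort, disc: DiscoveryResult, cfg: PipelineConfig, mode: str):
    """Metric closure for permutation testing of the replication AUC.

    Clustering stays fixed (the selected assignment solution); the
    classifier is retrained from scratch for each permuted label vector.
    Under permutation, newly-case subjects receive biotype labels drawn
    with the retained clusters' size proportions; originally clustered
    subjects that remain cases keep their assignment.
    """
    train = cohort.split_mask("train")
    val = cohort.split_mask("validation")
    rep = cohort.split_mask("replication")
    orig_blabs = disc.train_biotype_labels
    sizes = disc.selected_solution.cluster_sizes()
    retained = [b for b in sizes if b != OMITTED]
    probs = np.array([sizes[b] for b in retained], dtype=float)
    probs /= probs.sum()

    def metric(labels: np.ndarray, rng: np.random.Generator) -> float:
        y_train = labels[train].astype(int)
        y_val = labels[val].astype(int)
        y_rep = labels[rep].astype(int)
        if mode == "baseline":
            model = clf.train_baseline(
                disc.adjusted["train_scan1"], y_train,
                disc.adjusted["val_scan1"], y_val,
                seed=cfg.seed, config=cfg.classifier,
            )
        else:
            blabs = np.where(y_train == 1, orig_blabs, 0)
            new_cases = (y_train == 1) & (blabs == 0)
            blabs[new_cases] = rng.choice(retained, size=int(new_cases.sum()), p=probs)
            model = clf.train_biotype_aware(
                disc.adjusted["train_scan1"], y_train, blabs,
                disc.adjusted["val_scan1"], y_val,
                seed=cfg.seed, config=cfg.classifier,
            )
        return clf.auc(model.predict_combined(disc.adjusted["rep_scan1"]), y_rep)

    return metric


def run_genetics(cohort: Cohort, disc: DiscoveryResult, cfg: PipelineConfig) -> dict:
    """QC, GRM, LMM association and LD-adjusted significance per trait."""
    subjects = cohort.subjects
    in_pop = subjects["race"].isin(GENETICS_POPULATIONS).to_numpy()
    train = cohort.split_mask("train")
    rep = cohort.split_mask("replication")
    disc_mask = train & in_pop
    rep_mask = rep & in_pop

    panel_disc = cohort.genotypes.subset_subjects(disc_mask)
    panel_disc, qc_flags = genetics.snp_qc(
        panel_disc, cfg.qc_call_rate_min, cfg.qc_hwe_min, cfg.qc_maf_min
    )
    grm = genetics.compute_grm(panel_disc)
    cov, _ = genetics.build_covariates(
        subjects.loc[disc_mask, "age"].to_numpy(float),
        subjects.loc[disc_mask, "sex"].to_numpy(float),
        subjects.loc[disc_mask, "race"].to_numpy(),
    )
    blocks = genetics.ld_blocks(panel_disc, cfg.ld_r2_threshold, cfg.ld_window)

    # quantitative traits: per-biotype scores + the baseline case score
    fc_disc = disc.residual_model_scan1.transform(
        cohort.fc_scan1[disc_mask], _covariates(subjects)[disc_mask]
    )
    aware_scores = disc.aware_model.predict(fc_disc)["biotype_scores"]
    traits = {
        f"biotype{b}": aware_scores[:, j]
        for j, b in enumerate(disc.aware_model.provenance["biotype_ids"])
    }
    traits["am"] = disc.baseline_model.predict_combined(fc_disc)

    fc_rep = disc.residual_model_scan1.transform(
        cohort.fc_scan1[rep_mask], _covariates(subjects)[rep_mask]
    )
    rep_aware = disc.aware_model.predict(fc_rep)["biotype_scores"]
    rep_traits = {
        f"biotype{b}": rep_aware[:, j]
        for j, b in enumerate(disc.aware_model.provenance["biotype_ids"])
    }
    rep_traits["am"] = disc.baseline_model.predict_combined(fc_rep)

    panel_rep = cohort.genotypes.subset_subjects(rep_mask).subset_snps(
        np.isin(cohort.genotypes.snp_ids, panel_disc.snp_ids)
    )
    results: dict[str, dict] = {}
    rep_model: genetics.LinearMixedModel | None = None
    for name, trait in traits.items():
        table = genetics.association_scan(trait, panel_disc, cov, grm)
        table["significant"] = genetics.ld_adjusted_bonferroni(
            table["p"].to_numpy(), blocks, cfg.assoc_alpha
        )
        entry = {"table": table, "n_independent": blocks.n_independent}
        sig = table[table["significant"]]
        if len(sig) and rep_mask.sum() >= 10:
            if rep_model is None:
                grm_rep = genetics.compute_grm(panel_rep)
                cov_rep, _ = genetics.build_covariates(
                    subjects.loc[rep_mask, "age"].to_numpy(float),
                    subjects.loc[rep_mask, "sex"].to_numpy(float),
                    subjects.loc[rep_mask, "race"].to_numpy(),
                )
                rep_model = genetics.LinearMixedModel(cov_rep, grm_rep)
            rep_rows = []
            for snp_id in sig["snp_id"]:
                jj = int(np.flatnonzero(panel_rep.snp_ids == snp_id)[0])
                beta, se, p = rep_model.fit_snp(rep_traits[name], panel_rep.dosages[:, jj])
                rep_rows.append((snp_id, beta, se, p))
            entry["replication"] = pd.DataFrame(
                rep_rows, columns=["snp_id", "beta", "se", "p"]
            )
        results[name] = entry
    results["qc_flags"] = qc_flags
    return results


def run_pipeline(cohort: Cohort, cfg: PipelineConfig, with_genetics: bool = True) -> dict:
    """Full discovery -> replication (-> genetics, -> permutations) run."""
    disc = run_discovery(cohort, cfg)
    audit_split_hygiene(cohort, disc)
    report: dict = {
        "selected_cell": {
            "alpha": disc.selected_solution.provenance.get("alpha"),
            "d": disc.selected_solution.provenance.get("d"),
            "method": disc.selected_solution.method,
            "k": disc.selected_solution.k,
        },
        "validation": {
            "auc_baseline": disc.validation_auc_baseline,
            "auc_biotype_aware": disc.validation_auc_aware,
            "threshold": disc.threshold.cutoff,
        },
        "replication": run_replication(cohort, disc),
        "scan2_consistency": None,
        "discovery": disc,
    }
    try:
        consistency = scan2_consistency(cohort, disc)
        report["scan2_consistency"] = {
            "per_biotype_auc": consistency.biotype_aucs,
            "sizes": consistency.biotype_sizes,
            "weighted_auc": consistency.weighted_auc,
        }
    except ValueError:
        pass
    if with_genetics:
        report["genetics"] = run_genetics(cohort, disc, cfg)
    if cfg.n_perm > 0:
        labels = cohort.am_mask().astype(int)
        split = cohort.subjects["split"].to_numpy()
        perm = evaluation.permutation_test(
            replication_auc_metric(cohort, disc, cfg, "biotype_aware"),
            labels, split=split, n_perm=cfg.n_perm, seed=cfg.seed,
        )
        report["permutation"] = {
            "observed_replication_auc": perm.observed,
            "p_value": perm.p_value,
            "n_perm": perm.n_perm,
        }
    return report
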