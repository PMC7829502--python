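"""End-to-end orchestration: QC -> dynamic graphs -> partition ensembles ->
metrics -> group statistics -> discrimination, with full provenance.

Every run writes its configuration verbatim into the output directory and
fans all randomness out of one master seed through a counter scheme
(``SeedSequence(seed, spawn_key=...)``), so results are reproducible
bit-for-bit and independent of subject-level execution order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import atlas_io, classify, metrics, modularity, stats, synth, windows
from .atlas_io import Atlas, SubjectRecord
from .classify import CvResult, SvmConfig
from .metrics import MetricTable
from .modularity import ModularityParams
from .synth import GroundTruth, PlantedDesign
from .windows import WindowSpec

logger = logging.getLogger("dynbrain")


@dataclass
class RunConfig:
    """Every tunable of one pipeline run; serialized into the output directory."""

    window_length: int = 45
    window_step: int = 1
    tr: float = 2.5
    gamma: float = 1.0
    omega: float = 1.0
    n_runs: int = 100
    seed: int = 0
    selector: str = "fscore"
    kernel: str = "rbf"
    k: int = 23
    n_perm: int = 1000
    atlas_path: str | None = None
    manifest: str | None = None
    synthetic: bool = False

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    @property
    def window_spec(self) -> WindowSpec:
        return WindowSpec(length=self.window_length, step=self.window_step, tr=self.tr)

    def modularity_params(self, seed: int) -> ModularityParams:
        return ModularityParams(gamma=self.gamma, omega=self.omega,
                                n_runs=self.n_runs, seed=seed)


def default_synthetic_config(seed: int = 0, n_runs: int = 20, n_perm: int = 200) -> RunConfig:
    """Configuration matched to the default synthetic design: one analysis
    window per planted epoch (30 TR, step 30), gamma = omega = 1, and the
    10 planted effect nodes as the feature budget k."""
    return RunConfig(
        window_length=30, window_step=30, tr=2.5,
        gamma=1.0, omega=1.0, n_runs=n_runs, seed=seed,
        k=10, n_perm=n_perm, synthetic=True,
    )


def _subject_seed(master_seed: int, index: int) -> int:
    return int(np.random.SeedSequence(master_seed, spawn_key=(100, index)).generate_state(1)[0] % (2**31))


def subject_metrics(
    subject: SubjectRecord,
    spec: WindowSpec,
    params: ModularityParams,
) -> MetricTable:
    """One subject through windows -> multilayer modularity -> nodal metrics."""
    dg = windows.dynamic_graph(subject, spec)
    mg = modularity.build_multilayer(dg, params)
    ens = modularity.ensemble(mg, params)
    return metrics.compute_metrics(ens)


@dataclass
class CohortResult:
    """Everything the pipeline computes for one cohort."""

    qc: pd.DataFrame
    node_metrics: dict[str, pd.DataFrame]      # metric -> subjects x nodes
    network_metrics: dict[str, pd.DataFrame]   # metric -> subjects x networks
    group_tests: dict[str, pd.DataFrame]       # family -> compare_groups table
    correlations: pd.DataFrame
    cv: CvResult | None
    labels: list[str]
    subjects: list[str]


def run_pipeline(
    config: RunConfig,
    subjects: Sequence[SubjectRecord],
    atlas: Atlas,
    outdir: str | Path | None = None,
) -> CohortResult:
    """Execute the full analysis for an already-loaded cohort.

    Stages: motion QC (excluded subjects dropped) -> per-subject dynamic
    graphs and partition ensembles -> nodal/network metrics -> three-group
    Kruskal-Wallis comparisons with BH-FDR -> covariate-adjusted partial
    correlations (patients only) -> MHE-vs-noHE LOOCV SVM on node
    disjointness with permutation significance.
    """
    t0 = time.perf_counter()
    spec = config.window_spec
    reports = [atlas_io.qc_motion(s) for s in subjects]
    kept = [s for s, r in zip(subjects, reports) if not r.excluded]
    for r in reports:
        if r.excluded:
            logger.info("excluding %s: %s", r.subject_id, r.reason)
    qc = atlas_io.qc_table(reports)
    logger.info("stage=qc kept=%d/%d elapsed=%.1fs", len(kept), len(subjects), time.perf_counter() - t0)

    node_cols = [f"node{i}" for i in range(1, atlas.n_nodes + 1)]
    per_metric: dict[str, list[np.ndarray]] = {m: [] for m in
        ("flexibility", "disjointness", "cohesion_strength")}
    net_rows: dict[str, list[pd.Series]] = {m: [] for m in
        ("connection_stability", "flexibility", "disjointness", "cohesion_strength")}
    mean_fd = []
    for idx, subj in enumerate(kept):
        params = config.modularity_params(_subject_seed(config.seed, idx))
        table = subject_metrics(subj, spec, params)
        nets = metrics.network_aggregate(table, atlas)
        for m in per_metric:
            per_metric[m].append(getattr(table, m))
        for m in net_rows:
            net_rows[m].append(nets[m])
        r = atlas_io.qc_motion(subj)
        mean_fd.append(r.mean_fd if r.mean_fd is not None else 0.0)
    subject_ids = [s.subject_id for s in kept]
    node_metrics = {
        m: pd.DataFrame(np.vstack(v), index=subject_ids, columns=node_cols)
        for m, v in per_metric.items()
    }
    network_metrics = {
        m: pd.DataFrame(v, index=subject_ids)
        for m, v in net_rows.items()
    }
    logger.info("stage=metrics subjects=%d elapsed=%.1fs", len(kept), time.perf_counter() - t0)

    labels = [s.group for s in kept]
    group_tests: dict[str, pd.DataFrame] = {}
    have_three = all(g in labels for g in ("HC", "noHE", "MHE"))
    if have_three:
        group_tests["network_stability"] = stats.compare_groups(
            network_metrics["connection_stability"], labels)
        for m in ("disjointness", "flexibility", "cohesion_strength"):
            group_tests[f"node_{m}"] = stats.compare_groups(node_metrics[m], labels)

    # covariate-adjusted correlations, patients only, network-level disjointness
    corr_rows = []
    patients = [i for i, g in enumerate(labels) if g in ("noHE", "MHE")]
    if len(patients) > 6:
        cov = np.column_stack([
            [kept[i].age for i in patients],
            [1.0 if kept[i].sex == "M" else 0.0 for i in patients],
            [kept[i].education for i in patients],
            [mean_fd[i] for i in patients],
        ])
        cov_names = ("age", "sex", "education", "mean_fd")
        for score_name in ("dst", "nct_a", "blood_ammonia"):
            score = np.array([
                np.nan if getattr(kept[i], score_name) is None else float(getattr(kept[i], score_name))
                for i in patients
            ])
            ok = np.isfinite(score)
            if ok.sum() <= 6:
                continue
            for net in network_metrics["disjointness"].columns:
                vals = network_metrics["disjointness"].iloc[patients][net].to_numpy()
                res = stats.partial_corr(vals[ok], score[ok], cov[ok], cov_names)
                corr_rows.append({"unit": net, "score": score_name, "r": res.r, "p": res.p, "n": res.n})
    correlations = pd.DataFrame(corr_rows)
    if len(corr_rows):
        from statsmodels.stats.multitest import multipletests
        correlations["p_fdr"] = np.nan
        for score_name in correlations["score"].unique():
            m = correlations["score"] == score_name
            correlations.loc[m, "p_fdr"] = multipletests(correlations.loc[m, "p"], method="fdr_bh")[1]

    # discrimination: MHE vs noHE on node disjointness
    cv = None
    y = np.array([1 if g == "MHE" else 0 for g in labels])
    mask = np.array([g in ("MHE", "noHE") for g in labels])
    if mask.sum() >= 6 and len(np.unique(y[mask])) == 2 and min(
        (y[mask] == 1).sum(), (y[mask] == 0).sum()) >= 3:
        X = node_metrics["disjointness"].to_numpy()[mask]
        k = min(config.k, X.shape[1])
        svm = SvmConfig(kernel=config.kernel)
        cv = classify.loocv_classify(X, y[mask], k, svm=svm)
        if config.n_perm > 0:
            perm_seed = int(np.random.SeedSequence(config.seed, spawn_key=(200,)).generate_state(1)[0] % (2**31))
            cv.permutation_p, cv.perm_accuracies = classify.permutation_test(
                X, y[mask], k, n_perm=config.n_perm, seed=perm_seed, svm=svm)
    logger.info("stage=discrimination elapsed=%.1fs", time.perf_counter() - t0)

    result = CohortResult(
        qc=qc,
        node_metrics=node_metrics,
        network_metrics=network_metrics,
        group_tests=group_tests,
        correlations=correlations,
        cv=cv,
        labels=labels,
        subjects=subject_ids,
    )
    if outdir is not None:
        _write_result(result, config, Path(outdir))
    return result


def _write_result(result: CohortResult, config: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_json(outdir / "config.json")
    result.qc.to_csv(outdir / "qc.tsv", sep="\t", index=False)
    for m, df in result.node_metrics.items():
        df.to_csv(outdir / f"node_{m}.tsv", sep="\t")
    for m, df in result.network_metrics.items():
        df.to_csv(outdir / f"network_{m}.tsv", sep="\t")
    for fam, df in result.group_tests.items():
        df.to_csv(outdir / f"groups_{fam}.tsv", sep="\t")
    result.correlations.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
    if result.cv is not None:
        cv = result.cv
        payload = {
            "accuracy": cv.accuracy,
            "sensitivity": cv.sensitivity,
            "specificity": cv.specificity,
            "auc": cv.auc,
            "permutation_p": cv.permutation_p,
            "consensus_features": [int(i) + 1 for i in cv.consensus_features],
        }
        (outdir / "cv_result.json").write_text(json.dumps(payload, indent=2))
        np.savetxt(outdir / "roc_points.tsv", cv.roc_points, delimiter="\t",
                   header="fpr\ttpr", comments="")


# ---------------------------------------------------------------------------
# The default synthetic study (used by the acceptance script and tests)
# ---------------------------------------------------------------------------

def run_default_synthetic_study(
    seed: int,
    n_runs: int = 20,
    n_perm: int = 200,
    outdir: str | Path | None = None,
) -> dict[str, object]:
    """Generate the default 103-subject synthetic cohort, run the full
    pipeline, and summarize recovery/discrimination quantities.

    Returns a dict with: the Spearman rank correlation between planted and
    estimated node disjointness (pooled over subjects x nodes), the
    hypergeometric enrichment p of planted effect nodes among FDR-significant
    disjointness units, LOOCV accuracy / sensitivity / specificity (%), AUC,
    and the permutation p of the accuracy.
    """
    design = synth.default_design()
    cohort = synth.generate_cohort({"HC": 41, "noHE": 32, "MHE": 30}, design, seed=seed)
    subjects = [rec for rec, _ in cohort]
    truths = [t for _, t in cohort]
    config = default_synthetic_config(seed=seed, n_runs=n_runs, n_perm=n_perm)
    result = run_pipeline(config, subjects, design.atlas, outdir=outdir)

    n_boundaries = design.n_epochs - 1
    planted = np.vstack([t.disjoint_count / n_boundaries for t in truths])
    estimated = result.node_metrics["disjointness"].to_numpy()
    rank_r = float(sps.spearmanr(planted.ravel(), estimated.ravel()).statistic)

    table = result.group_tests["node_disjointness"]
    sig = table.index[table["p_fdr"] < 0.05]
    sig_idx = {int(u.removeprefix("node")) for u in sig}
    effect = set(truths[0].effect_nodes)
    n_nodes = design.n_nodes
    overlap = len(sig_idx & effect)
    enrichment_p = float(sps.hypergeom.sf(overlap - 1, n_nodes, len(effect), len(sig_idx))) if sig_idx else 1.0

    cv = result.cv
    out: dict[str, object] = {
        "planted_disjointness_rank_corr": rank_r,
        "n_fdr_significant_nodes": len(sig_idx),
        "effect_node_overlap": overlap,
        "enrichment_p": enrichment_p,
        "accuracy": cv.accuracy if cv else np.nan,
        "sensitivity": cv.sensitivity if cv else np.nan,
        "specificity": cv.specificity if cv else np.nan,
        "auc": cv.auc if cv else np.nan,
        "permutation_p": cv.permutation_p if cv else np.nan,
        "perm_accuracy_p95": (
            float(np.percentile(cv.perm_accuracies, 95))
            if cv is not None and cv.perm_accuracies is not None else np.nan
        ),
        "n_subjects": len(subjects),
    }
    return out


def run_grid(
    subjects: Sequence[SubjectRecord],
    atlas: Atlas,
    base_config: RunConfig,
    window_lengths: Sequence[int] = (40, 45, 50, 55),
    gammas: Sequence[float] = (1.0,),
    omegas: Sequence[float] = (1.0,),
    outdir: str | Path | None = None,
) -> pd.DataFrame:
    """Validation grid over window length and (gamma, omega); one accuracy per cell."""
    rows = []
    for wl in window_lengths:
        for g in gammas:
            for om in omegas:
                cfg = dataclasses.replace(base_config, window_length=wl, gamma=g, omega=om)
                sub_out = None
                if outdir is not None:
                    sub_out = Path(outdir) / f"w{wl}_g{g}_o{om}"
                res = run_pipeline(cfg, subjects, atlas, outdir=sub_out)
                rows.append({
                    "window_length": wl, "gamma": g, "omega": om,
                    "accuracy": res.cv.accuracy if res.cv else np.nan,
                    "sensitivity": res.cv.sensitivity if res.cv else np.nan,
                    "specificity": res.cv.specificity if res.cv else np.nan,
                    "auc": res.cv.auc if res.cv else np.nan,
                })
    table = pd.DataFrame(rows)
    if outdir is not None:
        table.to_csv(Path(outdir) / "grid.tsv", sep="\t", index=False)
    return table


def report(result_dir: str | Path) -> str:
    """Human-readable markdown summary of a completed run directory."""
    result_dir = Path(result_dir)
    lines = ["# dynbrain run report", ""]
    cfg = result_dir / "config.json"
    if cfg.exists():
        lines += ["## Configuration", "```json", cfg.read_text().strip(), "```", ""]
    else:
        lines += ["WARNING: no config.json found; incomplete run?", ""]
    for fam in sorted(result_dir.glob("groups_*.tsv")):
        df = pd.read_csv(fam, sep="\t", index_col=0)
        sig = df[df["p_fdr"] < 0.05]
        lines += [f"## {fam.stem}", f"{len(sig)} / {len(df)} units FDR-significant"]
        if len(sig):
            lines += ["", sig.round(4).to_markdown()]
        lines.append("")
    cv_file = result_dir / "cv_result.json"
    if cv_file.exists():
        cv = json.loads(cv_file.read_text())
        lines += [
            "## Discrimination (MHE vs noHE)",
            f"- accuracy: {cv['accuracy']:.2f}%",
            f"- sensitivity: {cv['sensitivity']:.2f}%",
            f"- specificity: {cv['specificity']:.2f}%",
            f"- AUC: {cv['auc']:.3f}",
            f"- permutation p: {cv['permutation_p']}",
            f"- consensus features (1-based nodes): {cv['consensus_features']}",
            "",
        ]
    else:
        lines += ["WARNING: no classification result found", ""]
    return "\n".join(lines)
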