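"""End-to-end orchestration of the study analogue.

``run_all`` drives the full chain on synthetic data: cohort simulation ->
burn-event preprocessing checks -> PCA of the biomechanical/biochemical
table -> Kruskal-Wallis/Dunn comparisons of the PCA-important variables ->
PLS-DA with repeated 80/20 evaluation, VIP refinement and FL-vs-rest ROC ->
Ward + multiscale-bootstrap clustering of the false-lumen spectra ->
histology quantification of the FL sections with Mann-Whitney comparisons
between the recovered clusters.  Every stage receives a seed derived from
the master seed by a fixed offset, and the report records the config and
its hash, so identical configs reproduce identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemometrics, cluster, histology, npstats, reims, synthetic

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one end-to-end run; round-trips losslessly through YAML."""

    seed: int = 0
    out_dir: str = "aadkit_run"
    n_fl: int = 10
    n_fp: int = 10
    n_tl: int = 6
    class_effect: float = 1.0
    n_subclusters: int = 3
    subcluster_effect: float = 2.0
    noise_cv: float = 0.2
    n_bins: int = 1150
    bin_width: float = 1.0
    n_repeats: int = 50
    train_fraction: float = 0.8
    max_components: int = 10
    n_boot: int = 1000
    au_threshold: float = 0.90
    loading_cutoff: float = 0.30
    image_size: int = 160
    fast_mode: bool = False

    def effective(self) -> "RunConfig":
        """Apply fast-mode downscaling (fewer repeats/replicates, same science)."""
        if not self.fast_mode:
            return self
        d = asdict(self)
        d.update(n_repeats=min(self.n_repeats, 10), n_boot=min(self.n_boot, 100))
        return RunConfig(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _stage_seed(master: int, offset: int) -> int:
    return int((master * 1000 + offset) % (2**31 - 1))


def run_all(config: RunConfig) -> dict:
    """Execute the full study analogue; returns the report dict and writes it.

    Any stage failure raises with the stage name in the message.
    """
    cfg = config.effective()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config), "config_hash": config.hash(), "stages": {}}
    stage = "simulate"
    try:
        cohort = synthetic.CohortConfig(
            n_fl=cfg.n_fl,
            n_fp=cfg.n_fp,
            n_tl=cfg.n_tl,
            class_effect=cfg.class_effect,
            n_subclusters=cfg.n_subclusters,
            subcluster_effect=cfg.subcluster_effect,
            noise_cv=cfg.noise_cv,
            seed=_stage_seed(cfg.seed, 1),
        )
        table, _ = synthetic.generate_feature_table(cohort)
        sset, _ = synthetic.generate_spectrum_set(cohort, n_bins=cfg.n_bins)
        table.to_csv(out / "feature_table.csv", index=False)
        sset.intensities.to_csv(out / "spectra.csv")
        sset.labels.to_csv(out / "labels.csv", index=False)
        report["stages"][stage] = {
            "n_samples": int(len(table)),
            "n_bins": int(sset.intensities.shape[1]),
        }

        stage = "reims_preprocess"
        rng = np.random.default_rng(_stage_seed(cfg.seed, 2))
        traces = []
        for k in range(3):
            duration = float(rng.uniform(10.0, 30.0))
            run = synthetic.generate_burn_event(
                duration, seed=_stage_seed(cfg.seed, 10 + k)
            )
            events = reims.detect_burn_events(run)
            for w in events:
                tr = reims.pseudo_gaussianize(run, w)
                traces.append(
                    {
                        "duration_s": duration,
                        "trace_length": int(tr.tic_trace.size),
                        "burn_span": tr.burn_span,
                        "peak_index": tr.peak_index,
                        "tic_conserved": bool(
                            np.isclose(
                                tr.tic_trace.sum(),
                                run.tic[w.start_scan : w.end_scan + 1].sum(),
                            )
                        ),
                    }
                )
        report["stages"][stage] = {"events": traces}

        stage = "pca"
        variables = [c for c in table.columns if c not in ("sample_id", "tissue_type", "patient_id")]
        pca_res = chemometrics.pca(table[variables])
        pd.DataFrame(
            pca_res.scores[:, :2], columns=["PC1", "PC2"], index=table["sample_id"]
        ).to_csv(out / "pca_scores.csv")
        important = [
            variables[j]
            for j in range(len(variables))
            if np.abs(pca_res.loadings[j, :2]).max() > cfg.loading_cutoff
        ]
        report["stages"][stage] = {
            "explained_variance_ratio": pca_res.explained_variance_ratio[:3].tolist(),
            "important_variables": important,
        }

        stage = "group_tests"
        tests = []
        for var in important:
            kw = npstats.kruskal_wallis(table[var], table["tissue_type"])
            tests.append(
                {"variable": var, "test": "kruskal-wallis", "statistic": kw.statistic,
                 "p_adjusted": kw.p_adjusted, "groups": "all"}
            )
            for res in npstats.dunn_posthoc(table[var], table["tissue_type"]):
                tests.append(
                    {"variable": var, "test": res.method, "statistic": res.statistic,
                     "p_adjusted": res.p_adjusted, "groups": "-".join(res.groups)}
                )
        pd.DataFrame(tests).to_csv(out / "group_tests.csv", index=False)
        report["stages"][stage] = {"n_tests": len(tests)}

        stage = "plsda"
        X = sset.X
        labels = sset.tissue_type
        summary, vip = chemometrics.repeated_evaluation(
            X,
            labels,
            n_repeats=cfg.n_repeats,
            train_fraction=cfg.train_fraction,
            seed=_stage_seed(cfg.seed, 3),
            max_components=cfg.max_components,
        )
        selected = chemometrics.refine_by_vip(vip)
        refined_summary, _ = chemometrics.repeated_evaluation(
            X,
            labels,
            n_repeats=cfg.n_repeats,
            train_fraction=cfg.train_fraction,
            seed=_stage_seed(cfg.seed, 4),
            max_components=cfg.max_components,
            feature_mask=selected,
        )
        summary.per_repeat.to_csv(out / "plsda_repeats.csv", index=False)
        pd.DataFrame(
            {"mz": sset.mz_centers, "vip_mean": vip.mean, "vip_median": vip.median,
             "selected": selected}
        ).to_csv(out / "vip_table.csv", index=False)
        # FL-vs-rest ROC from one representative refined-model split
        from sklearn.model_selection import train_test_split

        tr, te = train_test_split(
            np.arange(len(labels)),
            train_size=cfg.train_fraction,
            stratify=labels,
            random_state=_stage_seed(cfg.seed, 5),
        )
        k = chemometrics.select_n_components(
            X[tr][:, selected], labels[tr], cfg.max_components, seed=_stage_seed(cfg.seed, 5)
        )
        model = chemometrics.fit_plsda(X[tr][:, selected], labels[tr], k)
        fl_col = model.class_order.index("FL")
        roc = chemometrics.roc_auc(
            model.decision_scores(X[te][:, selected])[:, fl_col], labels[te] == "FL"
        )
        pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr}).to_csv(out / "roc_points.csv", index=False)
        report["stages"][stage] = {
            "mean_metrics": summary.means(),
            "refined_mean_metrics": refined_summary.means(),
            "n_selected_features": int(selected.sum()),
            "roc_auc_fl_vs_rest": roc.auc,
        }

        stage = "fl_clustering"
        fl_mask = labels == "FL"
        fl_X = X[fl_mask]
        fl_ids = sset.labels.loc[fl_mask, "sample_id"].tolist()
        dend, supports = cluster.multiscale_bootstrap(
            fl_X, n_boot=cfg.n_boot, seed=_stage_seed(cfg.seed, 6)
        )
        dend.leaf_labels = fl_ids
        assignment = cluster.stable_clusters(dend, supports, cfg.au_threshold)
        cluster.support_table(supports, fl_ids).to_csv(out / "fl_cluster_support.csv", index=False)
        (out / "fl_dendrogram.nwk").write_text(cluster.to_newick(dend, supports))
        member_lists = [sorted(fl_ids[i] for i in c) for c in assignment.clusters]
        pd.DataFrame(
            {"sample_id": fl_ids, "cluster": assignment.labels()}
        ).to_csv(out / "fl_cluster_assignment.csv", index=False)
        report["stages"][stage] = {
            "n_stable_clusters": assignment.n_clusters,
            "clusters": member_lists,
            "n_singletons": len(assignment.singletons),
        }

        stage = "histology"
        rng = np.random.default_rng(_stage_seed(cfg.seed, 7))
        cluster_labels = assignment.labels()
        records = []
        for i, sid in enumerate(fl_ids):
            sub = sset.labels.loc[sid, "subcluster"]
            col = float(np.clip(0.25 + 0.12 * sub + rng.normal(0, 0.02), 0.02, 0.8))
            el = float(np.clip(0.45 - 0.10 * sub + rng.normal(0, 0.02), 0.02, 1 - col))
            img_seed = _stage_seed(cfg.seed, 100 + i)
            vvg, truth = synthetic.generate_vvg_image(
                cfg.image_size, cfg.image_size, col, el, seed=img_seed, sample_id=sid
            )
            psr = synthetic.generate_psr_image(truth, cfg.image_size, cfg.image_size, seed=img_seed + 1)
            rep = histology.quantify_section_pair(vvg, psr)
            records.append(
                {
                    "sample_id": sid,
                    "cluster": int(cluster_labels[i]),
                    "collagen_fraction": rep["collagen"]["fraction"],
                    "elastin_fraction": rep["elastin"]["fraction"],
                    "psr_collagen_fraction": rep.get("psr_collagen_fraction", np.nan),
                }
            )
        hist_df = pd.DataFrame(records)
        hist_df.to_csv(out / "fl_histology.csv", index=False)
        comparisons = []
        real = sorted(set(c for c in hist_df["cluster"] if (hist_df["cluster"] == c).sum() >= 2))
        for a_idx in range(len(real)):
            for b_idx in range(a_idx + 1, len(real)):
                for var in ("collagen_fraction", "elastin_fraction"):
                    a = hist_df.loc[hist_df["cluster"] == real[a_idx], var]
                    b = hist_df.loc[hist_df["cluster"] == real[b_idx], var]
                    res = npstats.mann_whitney(a, b)
                    comparisons.append(
                        {"variable": var, "cluster_a": real[a_idx], "cluster_b": real[b_idx],
                         "U": res.statistic, "p_raw": res.p_raw}
                    )
        if comparisons:
            comp_df = pd.DataFrame(comparisons)
            comp_df["p_adjusted"] = npstats.holm_adjust(comp_df["p_raw"].to_numpy())
            comp_df.to_csv(out / "fl_cluster_comparisons.csv", index=False)
            report["stages"][stage] = {
                "n_comparisons": len(comp_df),
                "min_p_adjusted": float(comp_df["p_adjusted"].min()),
            }
        else:
            report["stages"][stage] = {"n_comparisons": 0}
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    logger.info("run complete: %s", out / "report.json")
    return report
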