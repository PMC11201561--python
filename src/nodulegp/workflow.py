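"""End-to-end synthetic experiment orchestration.

Mirrors the evaluation design of the growth-prediction study at synthetic,
CPU-friendly scale: simulate a longitudinal cohort, train the GP-WGAN on
baseline/follow-up pairs, deploy the frozen predictor to held-out baselines,
score baseline / predicted (GP-nodule) / real follow-up patches with a toy
risk model, compare the three AUCs (paired DeLong + Hochberg adjustment),
and quantify risk-group migration (reclassification table, NRI, Z-tests)
when GP-nodule scores replace baseline scores.

Every stage's randomness derives from the single experiment seed via
splitmix hashing, so a rerun with the same config reproduces the report
bit-for-bit; the report carries a manifest (config hash, seeds, library
versions, problem sizes).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import riskstats
from .gpwgan import (LossWeights, TrainConfig, predict_followup, save_predictor,
                     train)
from .simgrowth import SimulatorConfig, derive_seed, generate_dataset
from .riskstats import (RiskScoreSet, builtin_reclassification_counts,
                        escalation_summary, match_subgroup_thresholds, nri,
                        reclassification_table, score_patches, stratify_risk,
                        train_toy_scorer)

__all__ = ["ExperimentConfig", "reclassification_report",
           "run_synthetic_experiment"]


@dataclass(frozen=True)
class ExperimentConfig:
    """All knobs of one synthetic experiment; serializes losslessly.

    Default cohort sizes are a smoke-scale split (64 training pairs, 32 test
    pairs at the cohort's ~21% malignant fraction); ``full_scale()`` returns
    the 776/450-subject profile of the reference cohort.
    """

    seed: int = 0
    n_train_malignant: int = 14
    n_train_benign: int = 50
    n_test_malignant: int = 7
    n_test_benign: int = 25
    interval_months: float = 12.0
    iterations: int = 200
    n_critic: int = 5
    batch_size: int = 8
    learning_rate: float = 2e-4
    lambda1: float = 100.0
    lambda2: float = 10.0
    lambda3: float = 1.0
    lambda4: float = 1.0
    lambda_d: float = 10.0
    sign_convention: str = "standard"
    base_channels: int = 16
    initial_group_fractions: tuple[float, float, float] = (0.4, 0.4, 0.2)
    benign_jitter: bool = False

    @classmethod
    def full_scale(cls, seed: int = 0) -> "ExperimentConfig":
        return cls(seed=seed, n_train_malignant=165, n_train_benign=611,
                   n_test_malignant=53, n_test_benign=397)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["initial_group_fractions"] = list(self.initial_group_fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "initial_group_fractions" in d:
            d["initial_group_fractions"] = tuple(d["initial_group_fractions"])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _group_targets(n: int, fractions) -> tuple[int, int, int]:
    low = int(round(n * fractions[0]))
    med = int(round(n * fractions[1]))
    low, med = min(low, n), min(med, n - min(low, n))
    return low, med, n - low - med


def _auc_entry(score_set: RiskScoreSet) -> dict:
    auc, se = riskstats.roc_auc(score_set)
    return {"auc": auc, "se": se, "n": len(score_set.scores)}


def report_checksum(report: dict) -> str:
    blob = json.dumps(report, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_synthetic_experiment(config: ExperimentConfig | None = None,
                             out_dir: str | Path | None = None) -> dict:
    """Simulate -> train -> predict -> score -> stratify -> reclassify."""
    config = config or ExperimentConfig()
    stage = "simulate"
    try:
        sim_cfg = SimulatorConfig(benign_jitter=config.benign_jitter)
        train_pairs, train_labels = generate_dataset(
            config.n_train_malignant, config.n_train_benign,
            derive_seed(config.seed, 11), sim_cfg, config.interval_months)
        test_pairs, test_labels = generate_dataset(
            config.n_test_malignant, config.n_test_benign,
            derive_seed(config.seed, 12), sim_cfg, config.interval_months)

        stage = "train"
        tconf = TrainConfig(
            iterations=config.iterations, n_critic=config.n_critic,
            batch_size=config.batch_size, learning_rate=config.learning_rate,
            weights=LossWeights(config.lambda1, config.lambda2, config.lambda3,
                                config.lambda4, config.lambda_d),
            seed=derive_seed(config.seed, 13),
            sign_convention=config.sign_convention,
            base_channels=config.base_channels)
        state = train(train_pairs, tconf)

        stage = "predict"
        predictor = state.predictor.freeze()
        gp_nodules = predict_followup(predictor,
                                      [p.baseline for p in test_pairs])

        stage = "score"
        scorer = train_toy_scorer([p.followup for p in train_pairs],
                                  train_labels,
                                  seed=derive_seed(config.seed, 14))
        ids = [p.subject_id for p in test_pairs]
        conditions = {
            "baseline": [p.baseline for p in test_pairs],
            "gp_nodule": gp_nodules,
            "real_followup": [p.followup for p in test_pairs],
        }
        score_sets = {name: score_patches(scorer, patches, ids, test_labels)
                      for name, patches in conditions.items()}
        aucs = {name: _auc_entry(s) for name, s in score_sets.items()}

        comparisons = {}
        raw_p = []
        for a, b in (("gp_nodule", "baseline"), ("gp_nodule", "real_followup"),
                     ("baseline", "real_followup")):
            z, p = riskstats.delong_test(score_sets[a], score_sets[b])
            comparisons[f"{a}_vs_{b}"] = {"z": z, "p": p}
            raw_p.append(p)
        adjusted = riskstats.hochberg_adjust(raw_p)
        for key, adj in zip(comparisons, adjusted):
            comparisons[key]["p_hochberg"] = float(adj)

        stage = "image-similarity"
        mal = test_labels == 1
        mse_all = [riskstats.image_mse(g, p.followup)
                   for g, p in zip(gp_nodules, test_pairs)]
        ssim_gp = np.array([riskstats.image_ssim(g, p.followup)
                            for g, p in zip(gp_nodules, test_pairs)])
        ssim_base = np.array([riskstats.image_ssim(p.baseline, p.followup)
                              for p in test_pairs])
        similarity = {
            "mse_gp_vs_followup": float(np.mean(mse_all)),
            "ssim_gp_vs_followup": float(np.mean(ssim_gp)),
            "ssim_baseline_vs_followup": float(np.mean(ssim_base)),
            "ssim_gp_vs_followup_malignant": float(np.mean(ssim_gp[mal])),
            "ssim_baseline_vs_followup_malignant": float(np.mean(ssim_base[mal])),
        }

        stage = "reclassify"
        targets = _group_targets(len(test_labels),
                                 config.initial_group_fractions)
        init_match = match_subgroup_thresholds(
            score_sets["baseline"].scores, targets)
        initial = stratify_risk(score_sets["baseline"].scores,
                                init_match.thresholds)
        new_match = match_subgroup_thresholds(
            score_sets["gp_nodule"].scores, initial.sizes())
        new = stratify_risk(score_sets["gp_nodule"].scores,
                            new_match.thresholds)
        table = reclassification_table(initial, new, test_labels)
        res = nri(table)
        reclass = {
            "initial_thresholds": list(init_match.thresholds),
            "new_thresholds": list(new_match.thresholds),
            "initial_sizes": list(initial.sizes()),
            "new_sizes": list(new.sizes()),
            "event_counts": table.event_counts.tolist(),
            "nonevent_counts": table.nonevent_counts.tolist(),
            "event_nri": res.event_nri, "nonevent_nri": res.nonevent_nri,
            "overall_nri": res.overall_nri,
            "z": {"event": res.z_event, "nonevent": res.z_nonevent,
                  "overall": res.z_overall},
            "p": {"event": res.p_event, "nonevent": res.p_nonevent,
                  "overall": res.p_overall},
            "escalation": escalation_summary(table),
        }

        stage = "report"
        h = state.history
        k = min(20, max(1, len(h["l1"])))
        training = {
            "iterations": state.iteration,
            "critic_updates_total": int(np.sum(h["critic_updates"])),
            "l1_first20_mean": float(np.mean(h["l1"][:k])) if h["l1"] else None,
            "l1_last20_mean": float(np.mean(h["l1"][-k:])) if h["l1"] else None,
            "final_losses": {key: (h[key][-1] if h[key] else None)
                             for key in ("l1", "ssim", "perceptual",
                                         "adversarial", "critic_total")},
        }
        import skimage
        import sklearn
        report = {
            "config": config.to_dict(),
            "manifest": {
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "n_train": len(train_pairs),
                "n_test": len(test_pairs),
                "versions": {"numpy": np.__version__,
                             "scikit-image": skimage.__version__,
                             "scikit-learn": sklearn.__version__},
            },
            "training": training,
            "auc": aucs,
            "auc_comparisons": comparisons,
            "image_similarity": similarity,
            "reclassification": reclass,
        }
        report["manifest"]["report_checksum"] = report_checksum(report)
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        raise RuntimeError(f"experiment failed at stage '{stage}': {exc}") \
            from exc

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        save_predictor(predictor, out / "predictor.npz",
                       extra={"config_hash": config.config_hash()})
        with open(out / "losses.csv", "w") as fh:
            keys = list(state.history.keys())
            fh.write(",".join(["iteration"] + keys) + "\n")
            for i in range(state.iteration):
                fh.write(",".join([str(i)] + [repr(state.history[key][i])
                                              for key in keys]) + "\n")
    return report


def reclassification_report(tables: dict | None = None) -> dict:
    """NRI report for the packaged (or supplied) reclassification blocks."""
    tables = tables or builtin_reclassification_counts()
    out = {}
    for name, table in tables.items():
        res = nri(table)
        ev, ne, ov = res.rounded(2)
        out[name] = {
            "event_nri": res.event_nri,
            "nonevent_nri": res.nonevent_nri,
            "overall_nri": res.overall_nri,
            "rounded": {"event": ev, "nonevent": ne, "overall": ov},
            "z": {"event": res.z_event, "nonevent": res.z_nonevent,
                  "overall": res.z_overall},
            "p": {"event": res.p_event, "nonevent": res.p_nonevent,
                  "overall": res.p_overall},
            "escalation": escalation_summary(table),
        }
    return out
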