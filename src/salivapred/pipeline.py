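"""End-to-end orchestration of the prediction workflow.

Stages run in a fixed order — training-set construction, featurization,
feature selection, cross-validation, final training, manifold ranking and
(optionally) differential expression plus candidate intersection — each
reading and writing only declared files. A manifest records, per stage, the
input hashes, outputs, parameters and wall time; a single global seed fans
out to per-stage seeds by fixed offsets.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import biomarker, classify, featsel, rank, seqio, trainset
from .descriptors import DescriptorConfig, featurize

log = logging.getLogger(__name__)

STAGE_SEED_OFFSETS = {
    "select": 11,
    "cv": 23,
    "train": 37,
    "rank": 41,
}


@dataclass
class PipelineConfig:
    fasta: Path
    annotations: Path
    seeds_file: Path  # accessions of the seed positives, one per line
    out_dir: Path
    expression: Path | None = None
    secretory_ids: Path | None = None
    seed: int = 0
    q_cutoff: float = 0.005
    n_perm: int = 10000
    cv_folds: int = 10
    cv_repeats: int = 100
    alpha: float = 0.99
    fc_threshold: float = 1.5
    p_threshold: float = 0.05

    def __post_init__(self) -> None:
        for attr in ("fasta", "annotations", "seeds_file", "out_dir"):
            setattr(self, attr, Path(getattr(self, attr)))
        if self.expression is not None:
            self.expression = Path(self.expression)
        if self.secretory_ids is not None:
            self.secretory_ids = Path(self.secretory_ids)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute the whole workflow; returns the manifest (also written to
    ``manifest.json`` in the output directory)."""
    cfg = config
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": []}

    def stage(name: str, inputs: list[Path], params: dict):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                outputs = fn()
            except Exception as exc:
                manifest["stages"].append(
                    {"stage": name, "status": "failed", "error": str(exc)}
                )
                _write_manifest(cfg.out_dir, manifest)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            manifest["stages"].append(
                {
                    "stage": name,
                    "status": "ok",
                    "inputs": {str(p): _sha256(p) for p in inputs},
                    "outputs": {str(p): _sha256(p) for p in outputs},
                    "params": params,
                    "wall_time_s": round(time.perf_counter() - t0, 3),
                }
            )
            return outputs

        return wrap

    records = seqio.read_fasta(cfg.fasta)
    ann = seqio.read_annotations(cfg.annotations)
    records = seqio.attach_annotations(records, ann)
    by_id = {r.id: r for r in records}
    seed_ids = [s for s in cfg.seeds_file.read_text().split() if s]
    missing = [s for s in seed_ids if s not in by_id]
    if missing:
        raise ValueError(f"seed accessions not in FASTA: {missing}")

    # 1. training set
    pos_path = cfg.out_dir / "positives.txt"
    neg_path = cfg.out_dir / "negatives.txt"

    def _trainset():
        seeds = [by_id[s] for s in seed_ids]
        saliva_ids = {r.id for r in records
                      if r.annotations is not None and r.annotations.saliva_evidence}
        positives = trainset.expand_positives(seeds, records)
        negatives = trainset.select_negatives(
            [r for r in records if r.id not in {p.id for p in positives}],
            saliva_ids=saliva_ids,
        )
        pos_path.write_text("".join(f"{r.id}\n" for r in positives))
        neg_path.write_text("".join(f"{r.id}\n" for r in negatives))
        return [pos_path, neg_path]

    stage("trainset", [cfg.fasta, cfg.annotations, cfg.seeds_file], {})(_trainset)

    # 2. featurization (whole pool; training rows are a view)
    feat_path = cfg.out_dir / "features.tsv"

    def _featurize():
        X = featurize(records, DescriptorConfig())
        X.to_csv(feat_path, sep="\t", float_format="%.8g")
        return [feat_path]

    stage("featurize", [cfg.fasta], {"dimension": DescriptorConfig().dimension})(_featurize)

    X_all = pd.read_csv(feat_path, sep="\t", index_col="id")
    pos_ids = pos_path.read_text().split()
    neg_ids = neg_path.read_text().split()
    train_ids = pos_ids + neg_ids
    X_train = X_all.loc[train_ids]
    y = np.array([1] * len(pos_ids) + [-1] * len(neg_ids))

    # 3. feature selection
    sel_path = cfg.out_dir / "selection.tsv"

    def _select():
        res = featsel.select(
            X_train, y, q_cutoff=cfg.q_cutoff, n_perm=cfg.n_perm,
            cv_folds=cfg.cv_folds, seed=cfg.seed + STAGE_SEED_OFFSETS["select"],
        )
        res.to_frame().to_csv(sel_path, sep="\t", index=False, float_format="%.8g")
        return [sel_path]

    stage("select", [feat_path, pos_path, neg_path],
          {"q_cutoff": cfg.q_cutoff, "n_perm": cfg.n_perm})(_select)

    sel = pd.read_csv(sel_path, sep="\t")
    kept = sel.loc[sel["selected"] == 1, "feature"].tolist()
    X_sel = X_train[kept]

    # 4. cross-validation
    cv_path = cfg.out_dir / "cv_metrics.tsv"

    def _cv():
        metrics = classify.cross_validate(
            X_sel, y, folds=cfg.cv_folds, repeats=cfg.cv_repeats,
            seed=cfg.seed + STAGE_SEED_OFFSETS["cv"],
        )
        seqio.write_table(
            [
                ["metric", "value"],
                ["recall", metrics.recall],
                ["precision", metrics.precision],
                ["pr_auc", metrics.pr_auc],
            ],
            cv_path,
        )
        return [cv_path]

    stage("cv", [feat_path, sel_path],
          {"folds": cfg.cv_folds, "repeats": cfg.cv_repeats})(_cv)

    # 5. final model
    model_path = cfg.out_dir / "model.tsv"

    def _train():
        mu = X_sel.to_numpy().mean(axis=0)
        sd = X_sel.to_numpy().std(axis=0)
        sd[sd == 0] = 1.0
        model = classify.train((X_sel - mu) / sd, y)
        rows = [["feature", "weight"]]
        rows += [[n, w] for n, w in zip(kept, model.weights)]
        rows.append(["__bias__", model.bias])
        seqio.write_table(rows, model_path)
        return [model_path]

    stage("train", [feat_path, sel_path], {"C": 1.0})(_train)

    # 6. manifold ranking over the full pool
    rank_path = cfg.out_dir / "ranking.tsv"

    def _rank():
        Xr = X_all[kept]
        Z = (Xr - Xr.mean()) / Xr.std().replace(0, 1.0)
        W = rank.build_affinity(Z, rank.RankingConfig(alpha=cfg.alpha))
        res = rank.manifold_rank(
            W, pos_ids, list(X_all.index), rank.RankingConfig(alpha=cfg.alpha)
        )
        res.to_frame().to_csv(rank_path, sep="\t", index=False, float_format="%.8g")
        return [rank_path]

    stage("rank", [feat_path, pos_path], {"alpha": cfg.alpha})(_rank)

    # 7./8. optional expression branch
    if cfg.expression is not None:
        deg_path = cfg.out_dir / "deg.tsv"

        def _deg():
            df = pd.read_csv(cfg.expression, sep="\t", index_col=0)
            expr = biomarker.ExpressionMatrix.from_frame(df)
            fc = biomarker.fold_change(expr)
            pv = biomarker.paired_ttest(expr)
            deg = biomarker.select_deg(
                fc, pv, expr.gene_ids,
                fc_threshold=cfg.fc_threshold, p_threshold=cfg.p_threshold,
            )
            rows = [["gene", "fold_change", "pvalue", "deg"]]
            deg_set = set(deg)
            rows += [
                [g, f, p, int(g in deg_set)]
                for g, f, p in zip(expr.gene_ids, fc, pv)
            ]
            seqio.write_table(rows, deg_path)
            return [deg_path]

        stage("deg", [cfg.expression],
              {"fc_threshold": cfg.fc_threshold, "p_threshold": cfg.p_threshold})(_deg)

        cand_path = cfg.out_dir / "candidates.tsv"

        def _candidates():
            deg_df = pd.read_csv(deg_path, sep="\t")
            deg_ids = deg_df.loc[deg_df["deg"] == 1, "gene"].astype(str).tolist()
            secretory = (
                cfg.secretory_ids.read_text().split()
                if cfg.secretory_ids is not None
                else deg_ids
            )
            rank_df = pd.read_csv(rank_path, sep="\t")
            ranking = dict(zip(rank_df["id"].astype(str), rank_df["rank"]))
            saliva_pred = rank_df["id"].astype(str).tolist()
            cands = biomarker.intersect_candidates(
                deg_ids, secretory, saliva_pred, ranking
            )
            rows = [["candidate"]] + [[c] for c in cands]
            seqio.write_table(rows, cand_path)
            return [cand_path]

        stage("candidates", [deg_path, rank_path], {})(_candidates)

    _write_manifest(cfg.out_dir, manifest)
    return manifest


def _write_manifest(out_dir: Path, manifest: dict) -> None:
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
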