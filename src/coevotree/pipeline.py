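"""End-to-end pipeline: prep -> scores -> APC -> (prior) -> posterior -> chains/eval."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np

from coevotree import (
    DirichletParams, PreprocessConfig, apc_correct, build_beta, column_counts,
    column_entropy, edge_posteriors, preprocess_alignment, read_alignment,
    rescale_beta, score_matrix, write_fasta, z_transform,
)
from coevotree.chain_analysis import explain_distal_pairs, write_chains_tsv
from coevotree.config import RunConfig, config_hash
from coevotree.pair_stats import write_score_tsv
from coevotree.prior_model import PriorModel, edge_prior_matrix
from coevotree.structure_contacts import ContactMap, read_contact_tsv
from coevotree.tree_model import write_posterior_tsv

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def run_pipeline(cfg: RunConfig, aln_path, out_dir,
                 contacts_path=None, prior: PriorModel | None = None,
                 preprocess: bool = True) -> dict:
    """Run the full analysis on one alignment, writing artifacts to out_dir.

    Returns the manifest dict (also written as ``manifest.json``): config
    hash, seed, per-stage timings and output paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config_hash(cfg), "seed": cfg.seed,
                      "config": dataclasses.asdict(cfg),
                      "stages": {}, "outputs": {}}

    def stage(name: str):
        start = time.perf_counter()

        def done():
            manifest["stages"][name] = round(time.perf_counter() - start, 4)
            logger.info("stage %s: %.2fs", name, manifest["stages"][name])
        return done

    try:
        fin = stage("prep")
        aln = read_alignment(aln_path)
        if preprocess:
            pcfg = PreprocessConfig(
                max_col_gap_frac=cfg.max_col_gap_frac,
                max_seq_gap_frac=cfg.max_seq_gap_frac,
                min_seqs=cfg.min_seqs, min_cols=cfg.min_cols,
                max_cols=cfg.max_cols)
            aln = preprocess_alignment(aln, pcfg)
        clean_path = out / "aln.clean.fa"
        write_fasta(aln, clean_path)
        manifest["outputs"]["alignment"] = str(clean_path)
        fin()
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise StageError("prep", exc) from exc

    try:
        fin = stage("scores")
        params = DirichletParams(lambda_single=cfg.lambda_single)
        scores = score_matrix(aln, params, kind="logR")
        write_score_tsv(scores, out / "logR.tsv")
        manifest["outputs"]["logR"] = str(out / "logR.tsv")
        zed = z_transform(scores)
        write_score_tsv(zed, out / "z.tsv")
        manifest["outputs"]["z"] = str(out / "z.tsv")
        fin()
    except Exception as exc:
        raise StageError("scores", exc) from exc

    corrected = scores
    if cfg.apc:
        try:
            fin = stage("apc")
            corrected = apc_correct(scores)
            write_score_tsv(corrected, out / "logR_apc.tsv")
            manifest["outputs"]["logR_apc"] = str(out / "logR_apc.tsv")
            fin()
        except Exception as exc:
            raise StageError("apc", exc) from exc

    try:
        fin = stage("posterior")
        prior_w = None
        alpha = 1.0
        if prior is not None:
            entropies = np.array([column_entropy(column_counts(aln, i))
                                  for i in range(aln.n_cols)])
            sep = np.abs(aln.col_origin[:, None] - aln.col_origin[None, :])
            prior_w = edge_prior_matrix(sep, entropies, prior).w
            alpha = prior.alpha
        beta = build_beta(corrected, prior_weights=prior_w, alpha=alpha)
        beta = rescale_beta(beta, lambda_min=cfg.lambda_min)
        post = edge_posteriors(beta)
        write_posterior_tsv(post, out / "posterior.tsv")
        manifest["outputs"]["posterior"] = str(out / "posterior.tsv")
        manifest["posterior_sum"] = post.total()
        fin()
    except Exception as exc:
        raise StageError("posterior", exc) from exc

    if contacts_path is not None:
        try:
            fin = stage("chains")
            cm: ContactMap = read_contact_tsv(contacts_path)
            results = explain_distal_pairs(zed, cm, z_threshold=cfg.z_threshold)
            write_chains_tsv(results, out / "chains.tsv")
            manifest["outputs"]["chains"] = str(out / "chains.tsv")
            manifest["n_explained_pairs"] = len(results)
            fin()
        except Exception as exc:
            raise StageError("chains", exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
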