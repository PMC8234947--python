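"""End-to-end orchestration: harmonize → z-matrix → cluster → GRS → MR.

Each stage writes its outputs to flat files in the run directory, so every
number in the final report is traceable to a stage output and stages can be
rerun independently.  A machine-readable manifest (inputs, seeds, versions)
is written at the end; on failure a FAILED marker names the stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import kmeans, pca_project, select_k
from .config import RunConfig, stage_seed
from .exceptions import ClustmrError, PipelineError
from .meta import bonferroni_threshold, cluster_grs_associations, grs_table
from .mr import mr_table, run_mr_suite
from .sumstats import (
    actions_to_frame,
    harmonize_to_panel,
    read_association_table,
    read_variant_panel,
    substitute_proxies,
    write_association_table,
)
from .zmatrix import build_zscore_matrix, filter_complete, missingness_report

__all__ = ["run_pipeline"]

log = logging.getLogger("clustmr")


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _stage_harmonize(cfg: RunConfig, outdir: Path):
    panel = read_variant_panel(cfg.panel)
    harmonized = {}
    all_actions = []
    hdir = outdir / "harmonized"
    hdir.mkdir(exist_ok=True)
    for name, path in {**cfg.traits, **cfg.outcomes}.items():
        if not Path(path).exists():
            raise PipelineError(f"harmonize: table for trait {name!r} not found at {path}")
        records = read_association_table(path, cfg.column_map or None)
        records, proxy_actions = substitute_proxies(records, panel, cfg.r2_min)
        recs, actions = harmonize_to_panel(
            records, panel, cfg.palindrome_policy, cfg.eaf_window
        )
        # one action per panel variant: the proxy action (if any) is the
        # informative one and supersedes the post-substitution harmonize action
        merged = {a.variant_id: a for a in actions}
        merged.update({a.variant_id: a for a in proxy_actions})
        all_actions.extend((name, a) for a in merged.values())
        harmonized[name] = recs
        write_association_table(recs, hdir / f"{name}.tsv")
    frames = []
    for name, a in all_actions:
        frames.append({"trait": name, "variant_id": a.variant_id, "action": a.action,
                       "detail": a.detail})
    pd.DataFrame(frames).to_csv(outdir / "harmonization_actions.tsv", sep="\t", index=False)
    return panel, harmonized


def _stage_zmatrix(cfg: RunConfig, outdir: Path, panel, harmonized):
    trait_tables = {t: harmonized[t] for t in cfg.traits}
    matrix = build_zscore_matrix(trait_tables, panel, trait_order=list(cfg.traits))
    matrix = filter_complete(matrix, cfg.max_missing)
    if cfg.clustering.standardize:
        matrix = matrix.standardized()
    matrix.z.to_csv(outdir / "zmatrix.tsv", sep="\t", index_label="variant_id")
    missingness_report(matrix).to_csv(outdir / "missingness.tsv", sep="\t", index=False)
    return matrix


def _stage_cluster(cfg: RunConfig, outdir: Path, matrix):
    cs = cfg.clustering
    sel = select_k(
        matrix,
        k_range=cs.k_range,
        seed=stage_seed(cfg.seed, "select_k"),
        n_restarts=cs.n_restarts,
        gap_b=cs.gap_b,
        gap_restarts=cs.gap_restarts,
        max_iter=cs.max_iter,
        tol=cs.tol,
    )
    (outdir / "k_selection.json").write_text(json.dumps(sel.to_dict(), indent=2) + "\n")
    if sel.chosen_k is None:
        raise PipelineError("cluster: no defensible cluster count (degenerate matrix)")
    sol = kmeans(
        matrix,
        sel.chosen_k,
        n_restarts=cs.n_restarts,
        seed=stage_seed(cfg.seed, "kmeans"),
        max_iter=cs.max_iter,
        tol=cs.tol,
    )
    sol.labels_frame().to_csv(outdir / "cluster_labels.tsv", sep="\t", index=False)
    proj = pca_project(matrix, m=2)
    pd.DataFrame(
        proj.scores, index=proj.variant_ids, columns=["PC1", "PC2"]
    ).to_csv(outdir / "pca_scores.tsv", sep="\t", index_label="variant_id")
    pd.DataFrame(
        proj.loadings, index=proj.trait_ids, columns=["PC1", "PC2"]
    ).to_csv(outdir / "pca_loadings.tsv", sep="\t", index_label="trait")
    return sel, sol


def _stage_grs(cfg: RunConfig, outdir: Path, sol, harmonized):
    n_tests = len(cfg.traits) + len(cfg.outcomes)
    threshold = bonferroni_threshold(cfg.alpha, n_tests)
    labels = dict(zip(sol.variant_ids, (int(x) for x in sol.labels)))
    rows = cluster_grs_associations(labels, harmonized, threshold)
    table = grs_table(rows)
    table.to_csv(outdir / "grs_associations.tsv", sep="\t", index=False)
    report = {
        "alpha": cfg.alpha,
        "n_tests": n_tests,
        "bonferroni_threshold": threshold,
        "n_significant": int(table["significant"].sum()),
        "not_estimable": table.loc[~table["estimable"], ["cluster", "trait"]].to_dict(
            "records"
        ),
    }
    (outdir / "grs_report.json").write_text(json.dumps(report, indent=2) + "\n")
    return table, report


def _stage_mr(cfg: RunConfig, outdir: Path):
    if not cfg.mr_pairs:
        return None
    estimates = {}
    diagnostics = {}
    for pair in cfg.mr_pairs:
        exposure = read_association_table(pair.exposure, cfg.column_map or None)
        outcome = read_association_table(pair.outcome, cfg.column_map or None)
        ests = run_mr_suite(
            exposure,
            outcome,
            se_mode=cfg.mr.se_mode,
            n_boot=cfg.mr.n_boot,
            seed=stage_seed(cfg.seed, f"mr:{pair.label}"),
            level=cfg.mr.level,
            palindrome_policy=cfg.palindrome_policy,
            eaf_window=cfg.eaf_window,
        )
        estimates[pair.label] = ests
        diagnostics[pair.label] = {
            e.method: {k: v for k, v in e.extras.items()} for e in ests
        }
    table = mr_table(estimates)
    table.to_csv(outdir / "mr_estimates.tsv", sep="\t", index=False)
    (outdir / "mr_diagnostics.json").write_text(json.dumps(diagnostics, indent=2) + "\n")
    return table


def run_pipeline(cfg: RunConfig, outdir, seed: int | None = None) -> Path:
    """Run all stages into ``outdir``; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        cfg = cfg.model_copy(update={"seed": seed})
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(name)s: %(message)s")
    stage = "setup"
    try:
        stage = "harmonize"
        log.info("stage %s", stage)
        panel, harmonized = _stage_harmonize(cfg, outdir)
        stage = "zmatrix"
        log.info("stage %s", stage)
        matrix = _stage_zmatrix(cfg, outdir, panel, harmonized)
        stage = "cluster"
        log.info("stage %s", stage)
        sel, sol = _stage_cluster(cfg, outdir, matrix)
        stage = "grs"
        log.info("stage %s", stage)
        _stage_grs(cfg, outdir, sol, harmonized)
        stage = "mr"
        log.info("stage %s", stage)
        _stage_mr(cfg, outdir)
    except ClustmrError as exc:
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise PipelineError(f"stage {stage} failed: {exc}") from exc
    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "stage_seeds": {
            s: stage_seed(cfg.seed, s) for s in ("select_k", "kmeans")
        },
        "inputs": {
            "panel": {"path": str(cfg.panel), "sha256_16": _file_hash(Path(cfg.panel))},
            **{
                name: {"path": str(p), "sha256_16": _file_hash(Path(p))}
                for name, p in {**cfg.traits, **cfg.outcomes}.items()
            },
        },
        "config": json.loads(cfg.model_dump_json()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir
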