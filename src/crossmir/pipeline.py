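"""End-to-end pipeline: config validation, stage orchestration, report bundle.

Stage order: preprocess (threshold -> filter -> center -> NRQ), differential
expression, optional homology + cross-species concordance/overlap, and
multivariate structure (clustering, branch enrichment, PCA).  Outputs are
delimited text, Newick and JSON under one output directory, together with a
manifest recording parameters, seed, package version and input checksums.
A stage failure aborts with the stage name and an error code; the manifest
is still written, marked incomplete.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .crossspecies import (
    build_concordance_table,
    compare_de_lists,
    concordance_frame,
    concordance_summary,
    load_table1,
    read_direction_calls,
    restrict_to_conserved,
    strip_species_prefix,
    DirectionCall,
)
from .diffexp import call_differential, de_results_frame
from .homology import find_homologs, read_mature_fasta, write_homology_tsv
from .multivariate import (
    cut_two_branches,
    enrichment_chi2,
    expression_matrix,
    hierarchical_cluster,
    linkage_to_newick,
    pca,
    rank_loadings,
    spearman_distance_matrix,
)
from .preprocess import preprocess, read_ct_matrix

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "run_table1_check"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure carrying the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class RunConfig:
    """Validated run parameters; every field maps to a CLI flag or config key."""

    ct_matrix: str
    metadata: str
    outdir: str
    mouse_fasta: str | None = None
    human_fasta: str | None = None
    human_calls: str | None = None  # direction-call TSV for cross-species stage
    threshold: float = 35.0
    min_samples: int = 10
    alpha: float = 0.05
    fc_min: float = 2.0
    n_tests: int | None = None
    group_by: str = "tissue_class"
    group1: str = "tumor"
    group2: str = "adrenal"
    transform: str = "log2_nrq"
    overlap_universe: str | None = None  # {"conserved_measured", "conserved_all"}
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate(self) -> None:
        for key in ("ct_matrix", "metadata", "mouse_fasta", "human_fasta", "human_calls"):
            value = getattr(self, key)
            if value is not None and not Path(value).exists():
                raise PipelineError("config", "missing_input", f"{key}: {value} not found")
        if not 0.0 <= self.alpha <= 1.0:
            raise PipelineError("config", "bad_param", f"alpha={self.alpha} outside [0, 1]")
        if self.fc_min < 1.0:
            raise PipelineError("config", "bad_param", f"fc_min={self.fc_min} must be >= 1")
        if self.min_samples < 0:
            raise PipelineError("config", "bad_param", "min_samples must be >= 0")
        if self.transform not in ("log2_nrq", "nrq", "centered_ct"):
            raise PipelineError("config", "bad_param", f"unknown transform {self.transform!r}")
        want_cross = self.human_calls is not None and self.mouse_fasta and self.human_fasta
        if want_cross and self.overlap_universe not in ("conserved_measured", "conserved_all"):
            raise PipelineError(
                "config", "bad_param",
                "overlap_universe must be set explicitly to 'conserved_measured' or "
                "'conserved_all' when the cross-species stage is requested",
            )


def _sha256(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages and write the report bundle.

    Returns the manifest (also written to ``<outdir>/manifest.json``).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": asdict(config),
        "seed": config.seed,
        "inputs": {
            k: {"path": v, "sha256": _sha256(v)}
            for k, v in (
                ("ct_matrix", config.ct_matrix),
                ("metadata", config.metadata),
                ("mouse_fasta", config.mouse_fasta),
                ("human_fasta", config.human_fasta),
                ("human_calls", config.human_calls),
            )
            if v is not None
        },
        "stages": [],
        "status": "incomplete",
    }

    def _write_manifest() -> None:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    def _stage(name: str):
        class _Ctx:
            def __enter__(self):
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    manifest["stages"].append({"name": name, "status": "failed"})
                    _write_manifest()
                    if not isinstance(exc, PipelineError):
                        raise PipelineError(name, "stage_error", str(exc)) from exc
                    return False
                manifest["stages"].append({"name": name, "status": "ok"})
                return False

        return _Ctx()

    with _stage("preprocess"):
        m = read_ct_matrix(config.ct_matrix, config.metadata)
        norm = preprocess(m, threshold=config.threshold, min_samples=config.min_samples)
        norm.centered_ct.to_csv(outdir / "centered_ct.tsv", sep="\t")
        norm.nrq.to_csv(outdir / "nrq.tsv", sep="\t")

    with _stage("diffexp"):
        grouping = norm.samples[config.group_by]
        results = call_differential(
            norm, grouping, group1=config.group1, group2=config.group2,
            alpha=config.alpha, fc_min=config.fc_min, n_tests=config.n_tests,
        )
        de_frame = de_results_frame(results)
        de_frame.to_csv(outdir / "de_results.tsv", sep="\t")

    hmap = None
    if config.mouse_fasta and config.human_fasta:
        with _stage("homology"):
            mouse_rec = read_mature_fasta(config.mouse_fasta)
            human_rec = read_mature_fasta(config.human_fasta)
            hmap = find_homologs(mouse_rec, human_rec)
            write_homology_tsv(hmap, outdir / "homology.tsv")

    if hmap is not None and config.human_calls is not None:
        with _stage("crossspecies"):
            mouse_calls = [
                DirectionCall(r.Index, "mouse", r.direction)
                for r in de_frame.itertuples()
                if r.direction != "NS"
            ]
            _, human_by_study = read_direction_calls(config.human_calls)
            mouse_kept, _ = restrict_to_conserved(mouse_calls, hmap)
            human_kept_by_study = {
                s: restrict_to_conserved(calls, hmap)[0]
                for s, calls in human_by_study.items()
            }
            rows = build_concordance_table(mouse_kept, human_kept_by_study)
            concordance_frame(rows).to_csv(outdir / "concordance.tsv", sep="\t")

            conserved_keys = {strip_species_prefix(a) for a, _ in hmap.pairs}
            if config.overlap_universe == "conserved_measured":
                measured = {strip_species_prefix(x) for x in de_frame.index}
                universe = sorted(conserved_keys & measured)
            else:
                universe = sorted(conserved_keys)
            mouse_de = sorted({c.mirna for c in mouse_kept} & set(universe))
            human_de = sorted(
                {c.mirna for calls in human_kept_by_study.values() for c in calls}
                & set(universe)
            )
            test, membership = compare_de_lists(mouse_de, human_de, universe)
            (outdir / "overlap.json").write_text(test.to_json() + "\n")
            membership.to_csv(outdir / "overlap_membership.tsv", sep="\t")

    with _stage("multivariate"):
        expr = expression_matrix(norm, config.transform)
        dist = spearman_distance_matrix(expr)
        part = cut_two_branches(hierarchical_cluster(dist))
        (outdir / "dendrogram.nwk").write_text(linkage_to_newick(part) + "\n")
        pd.Series(part.branch_of, name="branch").rename_axis("sample_id").to_csv(
            outdir / "branches.tsv", sep="\t"
        )
        labels = norm.samples[config.group_by]
        if labels.nunique() == 2:
            enr = enrichment_chi2(part, labels)
            (outdir / "enrichment.json").write_text(
                json.dumps(
                    {
                        "chi2": enr.chi2,
                        "p_value": enr.p_value,
                        "enriched_branch": enr.enriched_branch,
                        "class_fraction": enr.class_fraction,
                        "table": enr.table.to_dict(),
                    },
                    indent=2,
                )
                + "\n"
            )
        p = pca(expr)
        p.scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
        p.loadings.to_csv(outdir / "pca_loadings.tsv", sep="\t")
        pd.Series(
            p.explained_var, index=p.scores.columns, name="explained_var"
        ).rename_axis("component").to_csv(outdir / "pca_explained_var.tsv", sep="\t")
        top = rank_loadings(p, "PC1", min(20, p.loadings.shape[0]))
        (outdir / "pc1_top_loadings.txt").write_text("\n".join(top) + "\n")

    manifest["status"] = "complete"
    _write_manifest()
    return manifest


def run_table1_check(fixture: str | Path | None = None) -> dict:
    """Classify the packaged (or a user-supplied) mouse/human direction table.

    Prints and returns concordant/discordant counts plus per-row labels.
    """
    if fixture is None:
        mouse, human = load_table1()
    else:
        mouse, human = read_direction_calls(fixture)
    rows = build_concordance_table(mouse, human)
    n_con, n_dis = concordance_summary(rows)
    return {
        "n_rows": len(rows),
        "concordant": n_con,
        "discordant": n_dis,
        "labels": {r.mirna: r.label for r in rows},
    }
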