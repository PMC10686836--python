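"""End-to-end orchestration: counts + annotations in, patterns out.

The stage order is fixed: gene filter -> sample filter -> TMM -> log2 ->
boundary/domain fit -> per-replicate spectral design -> stacked fit ->
rescaling -> scores -> weighted-median selection -> cosine similarity ->
k-medoids -> MDS.  Every intermediate is persisted to the output
directory so a run can be inspected or resumed stage by stage, and a
rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import basis as _basis
from . import counts as _counts
from . import domain as _domain
from . import io as _io
from . import patterns as _patterns


@dataclass
class PipelineConfig:
    """Paths and parameters for a pipeline run."""

    counts_path: str = ""
    annotations_path: str = ""
    boundary_path: str = ""
    output_dir: str = "out"
    M: int = 5
    n_nodes: tuple[int, int] = (64, 64)
    min_reads: int = 10
    min_samples: int = 2
    min_total: int = 1_000_000
    pseudocount: float = 0.5
    n_clusters: int = 6
    elbow_range: tuple[int, int] = (2, 12)
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("n_nodes", "elbow_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TranscriptomeResult:
    """In-memory bundle of everything the transcriptome pipeline computes."""

    expression: _counts.ExpressionMatrix
    fit: _domain.DomainFit
    basis: _basis.BasisSet
    coords: list
    in_domain: np.ndarray
    coefficients: np.ndarray
    rescaled: _patterns.RescaledCoefficients
    scores: _patterns.PatternScores
    clustering: _patterns.PatternClustering | None
    mds_coords: np.ndarray | None
    report: dict = field(default_factory=dict)


def analyze_transcriptome(cm: _counts.CountMatrix,
                          annotations: list[_domain.SampleAnnotation],
                          boundary_obs: list[_domain.BoundaryObservations],
                          config: PipelineConfig | None = None
                          ) -> TranscriptomeResult:
    """Run the full spatiotemporal analysis in memory.

    Annotations must cover every sample id in the count matrix; samples
    falling outside the common dimensionless domain are excluded from
    the spectral fit, as are samples removed by the library-size filter.
    """
    cfg = config or PipelineConfig()
    cm = _counts.filter_genes(cm, cfg.min_reads, cfg.min_samples)
    cm = _counts.filter_samples(cm, cfg.min_total)
    factors = _counts.tmm_factors(cm)
    expr = _counts.to_log2(cm, factors, cfg.pseudocount)

    fit = _domain.fit_boundary(boundary_obs)
    ann_by_id = {a.sample_id: a for a in annotations}
    kept_ann = [ann_by_id[s] for s in expr.sample_ids]
    coords = _domain.nondimensionalize(kept_ann, fit)
    in_domain = np.array([c.in_domain for c in coords])
    if not in_domain.any():
        raise ValueError("no samples inside the common domain")

    inner = _basis.build_inner_product(fit.T, cfg.n_nodes)
    bset = _basis.gram_schmidt_basis(inner, cfg.M)

    # per-replicate stacked least squares
    reps = sorted({a.replicate_id for a in kept_ann})
    rep_cols = {
        r: [j for j, a in enumerate(kept_ann) if a.replicate_id == r and in_domain[j]]
        for r in reps
    }
    designs = {r: _basis.evaluate_design(bset, [coords[j] for j in cols])
               for r, cols in rep_cols.items() if cols}
    values = expr.values
    gs = [values[:, rep_cols[r]] for r in designs]
    X = np.vstack([designs[r] for r in designs])
    G = np.concatenate(gs, axis=1)          # genes x pooled in-domain samples
    coef = np.linalg.lstsq(X, G.T, rcond=None)[0].T

    resc = _patterns.rescale(coef, G, bset.p0, expr.gene_ids)
    sc = _patterns.scores(G, resc, X)
    selected = _patterns.select(sc)

    clustering = None
    mds_coords = None
    sel_idx = np.flatnonzero(selected)
    if sel_idx.size >= cfg.n_clusters:
        sim = _patterns.cosine_similarity(resc.k[sel_idx])
        ok = ~np.isnan(sim).all(axis=1)
        sim = sim[np.ix_(ok, ok)]
        ids = [expr.gene_ids[i] for i in sel_idx[ok]]
        clustering = _patterns.cluster(sim, cfg.n_clusters, cfg.seed, ids)
        mds_coords, _stress = _patterns.mds_embed(sim, cfg.seed)

    report = build_report(cm, expr, fit, sc, clustering, cfg)
    return TranscriptomeResult(expression=expr, fit=fit, basis=bset,
                               coords=coords, in_domain=in_domain,
                               coefficients=coef, rescaled=resc, scores=sc,
                               clustering=clustering, mds_coords=mds_coords,
                               report=report)


def build_report(cm, expr, fit, sc, clustering, cfg: PipelineConfig) -> dict:
    """Human-readable run summary (counts surviving filters, selection, clusters)."""
    selected = sc.selected if sc.selected is not None else np.zeros(len(sc.gene_ids), bool)
    rep = {
        "n_genes_after_filter": len(cm.gene_ids),
        "n_samples_after_filter": len(cm.sample_ids),
        "tau_h": fit.tau,
        "T": fit.T,
        "n_selected": int(selected.sum()),
        "cluster_sizes": (np.bincount(clustering.labels).tolist()
                          if clustering is not None else []),
        "seed": cfg.seed,
        "M": cfg.M,
        "n_clusters": cfg.n_clusters,
        "config_hash": cfg.config_hash(),
    }
    if not selected.any():
        rep["note"] = "no genes selected as spatiotemporally patterned"
    return rep


def run_transcriptome(cfg: PipelineConfig) -> TranscriptomeResult:
    """File-based pipeline run with persisted intermediates."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cm = (_io.read_counts_tsv(cfg.counts_path) if str(cfg.counts_path).endswith(".tsv")
          else _io.read_counts_mtx(cfg.counts_path))
    annotations = _io.read_annotations(cfg.annotations_path)
    boundary = _io.read_boundary_observations(cfg.boundary_path)
    res = analyze_transcriptome(cm, annotations, boundary, cfg)

    res.expression.to_frame().to_csv(out / "expression_log2.tsv", sep="\t")
    (out / "domain_fit.json").write_text(res.fit.to_json())
    (out / "basis.json").write_text(res.basis.to_json())
    scores_df = pd.DataFrame({
        "gene_id": res.scores.gene_ids,
        "E": res.scores.E, "P": res.scores.P, "R": res.scores.R,
        "selected": res.scores.selected,
    })
    scores_df.to_csv(out / "scores.tsv", sep="\t", index=False)
    if res.clustering is not None:
        pd.DataFrame({"gene_id": res.clustering.gene_ids,
                      "cluster": res.clustering.labels}).to_csv(
            out / "clusters.tsv", sep="\t", index=False)
        pd.DataFrame(res.mds_coords, columns=["mds1", "mds2"]).assign(
            gene_id=res.clustering.gene_ids).to_csv(
            out / "mds_coords.tsv", sep="\t", index=False)
    (out / "report.json").write_text(json.dumps(res.report, indent=2))
    return res
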