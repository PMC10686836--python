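"""Count-matrix processing: filtering, TMM normalization, log2 expression.

Implements the standard bulk RNA-seq preprocessing chain for the swarm
samples: gene detection filter, per-sample library-size filter, trimmed
mean of M-values (TMM) between-sample normalization, and log2
counts-per-million on effective library sizes.  Also provides the
kymograph tiling used for spatiotemporal heat maps and the dynamic-range
summary statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Gene-by-sample matrix of nonnegative integer read counts."""

    counts: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (genes x samples)")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match id lists")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ExpressionMatrix:
    """Gene-by-sample log2-scale expression with normalization factors."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    normalization_factors: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")
        if self.normalization_factors is not None:
            f = np.asarray(self.normalization_factors, float)
            if np.any(f <= 0):
                raise ValueError("normalization factors must be positive")
            self.normalization_factors = f

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def filter_genes(cm: CountMatrix, min_reads: int = 10, min_samples: int = 2) -> CountMatrix:
    """Keep genes detected (count >= min_reads) in at least min_samples samples."""
    if min_reads < 0 or min_samples < 0:
        raise ValueError("thresholds must be nonnegative")
    if cm.counts.size == 0:
        raise ValueError("empty count matrix")
    keep = (cm.counts >= min_reads).sum(axis=1) >= min_samples
    return CountMatrix(cm.counts[keep],
                       [g for g, k in zip(cm.gene_ids, keep) if k],
                       list(cm.sample_ids))


def filter_samples(cm: CountMatrix, min_total: int = 1_000_000) -> CountMatrix:
    """Drop samples whose total count over the retained genes is < min_total."""
    totals = cm.counts.sum(axis=0)
    keep = totals >= min_total
    if not keep.any():
        raise ValueError("all samples fall below the library-size threshold")
    return CountMatrix(cm.counts[:, keep], list(cm.gene_ids),
                       [s for s, k in zip(cm.sample_ids, keep) if k])


def _tmm_pair(obs: np.ndarray, ref: np.ndarray,
              trim_logratio: float, trim_abs: float) -> float:
    """log2 TMM factor of one library against the reference library.

    Trimmed, precision-weighted mean of per-gene log-ratios (M-values),
    trimming the most extreme M and A (absolute expression) values.
    """
    n_obs, n_ref = obs.sum(), ref.sum()
    mask = (obs > 0) & (ref > 0)
    o, r = obs[mask].astype(float), ref[mask].astype(float)
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # delta-method variance of M
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if m.size == 0:
        return 0.0
    if np.max(np.abs(m)) < 1e-6:  # identical compositions
        return 0.0
    n = m.size
    lo_m, hi_m = np.floor(n * trim_logratio) + 1, n + 1 - (np.floor(n * trim_logratio) + 1)
    lo_a, hi_a = np.floor(n * trim_abs) + 1, n + 1 - (np.floor(n * trim_abs) + 1)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(f) if np.isfinite(f) else 0.0


def tmm_factors(cm: CountMatrix, ref_column: int | None = None,
                trim_logratio: float = 0.30, trim_abs: float = 0.05) -> np.ndarray:
    """Per-sample TMM normalization factors, geometric mean 1.

    The reference library is the one whose upper-quartile count fraction
    is closest to the mean upper quartile, unless ``ref_column`` is given.
    """
    counts = cm.counts.astype(float)
    totals = counts.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("zero-count column")
    if ref_column is None:
        uq = np.array([np.percentile(counts[:, j] / totals[j], 75)
                       for j in range(counts.shape[1])])
        ref_column = int(np.argmin(np.abs(uq - uq.mean())))
    ref = counts[:, ref_column]
    logf = np.array([_tmm_pair(counts[:, j], ref, trim_logratio, trim_abs)
                     for j in range(counts.shape[1])])
    factors = 2.0 ** logf
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def to_log2(cm: CountMatrix, factors: np.ndarray,
            pseudocount: float = 0.5) -> ExpressionMatrix:
    """log2 counts-per-million on effective library sizes.

    Effective library size = column sum x TMM factor; a pseudocount keeps
    zero counts finite.
    """
    eff = cm.counts.sum(axis=0) * np.asarray(factors, float)
    cpm = (cm.counts + pseudocount) / eff[None, :] * 1e6
    return ExpressionMatrix(np.log2(cpm), list(cm.gene_ids), list(cm.sample_ids),
                            normalization_factors=np.asarray(factors, float))


def dynamic_range(gene_values: np.ndarray) -> float:
    """Fold-change between the 95th and 5th percentile expression values.

    ``gene_values`` are log2 expression values for one gene pooled over all
    replicates; the ratio is reported on the linear scale, 2^(q95 - q5),
    using linear-interpolation percentiles.
    """
    v = np.asarray(gene_values, float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    q5, q95 = np.percentile(v, [5, 95])
    return float(2.0 ** (q95 - q5))


def assemble_kymograph(values: np.ndarray, annotations,
                       sample_ids: list[str]) -> pd.DataFrame:
    """Long-format tile grid keyed by (time, position) per sample.

    One tile per sample; duplicate (replicate, time, position) keys are an
    error listing the collisions.  The grid is naturally ragged (later
    times reach more radial positions); missing tiles are simply absent
    rows, never zero-filled.
    """
    ann = {a.sample_id: a for a in annotations}
    rows = []
    for j, sid in enumerate(sample_ids):
        a = ann[sid]
        rows.append({"sample_id": sid, "replicate_id": a.replicate_id,
                     "time": a.time, "position": a.position,
                     "value": float(values[j])})
    df = pd.DataFrame(rows)
    dup = df.duplicated(subset=["replicate_id", "time", "position"], keep=False)
    if dup.any():
        coll = df.loc[dup, ["replicate_id", "time", "position"]].drop_duplicates()
        raise ValueError(f"duplicate kymograph tiles:\n{coll.to_string(index=False)}")
    return df
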