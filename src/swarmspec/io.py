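"""Reading and writing the pipeline's on-disk formats.

Count matrices travel as TSV (genes x samples, labelled) or MatrixMarket
with gene/sample sidecar files; annotations, cell tables, kymographs and
metabolite tables as TSV; domain fits and basis sets as JSON.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .counts import CountMatrix
from .domain import BoundaryObservations, SampleAnnotation


def write_counts_tsv(cm: CountMatrix, path: str | Path) -> None:
    cm.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(df.to_numpy(), [str(g) for g in df.index],
                       [str(s) for s in df.columns])


def write_counts_mtx(cm: CountMatrix, prefix: str | Path) -> None:
    """Write <prefix>.mtx plus <prefix>.genes.txt / <prefix>.samples.txt."""
    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), csr_matrix(cm.counts))
    prefix.with_suffix(".genes.txt").write_text("\n".join(cm.gene_ids) + "\n")
    prefix.with_suffix(".samples.txt").write_text("\n".join(cm.sample_ids) + "\n")


def read_counts_mtx(prefix: str | Path) -> CountMatrix:
    prefix = Path(prefix)
    mat = np.asarray(mmread(str(prefix.with_suffix(".mtx"))).todense())
    genes = prefix.with_suffix(".genes.txt").read_text().splitlines()
    samples = prefix.with_suffix(".samples.txt").read_text().splitlines()
    return CountMatrix(mat.astype(np.int64), genes, samples)


def write_annotations(annotations: list[SampleAnnotation], path: str | Path) -> None:
    pd.DataFrame([a.__dict__ for a in annotations]).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def read_annotations(path: str | Path) -> list[SampleAnnotation]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [SampleAnnotation(str(r.sample_id), str(r.replicate_id),
                             float(r.time), float(r.position),
                             float(r.boundary_radius))
            for r in df.itertuples()]


def write_boundary_observations(obs: list[BoundaryObservations],
                                path: str | Path) -> None:
    rows = [{"replicate_id": o.replicate_id, "time": t, "radius": r}
            for o in obs for t, r in zip(o.times, o.radii)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_boundary_observations(path: str | Path) -> list[BoundaryObservations]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [BoundaryObservations(str(rep), grp["time"].to_numpy(float),
                                 grp["radius"].to_numpy(float))
            for rep, grp in df.groupby("replicate_id", sort=True)]
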