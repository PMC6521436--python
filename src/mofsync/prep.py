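"""Expression-matrix preparation.

Operates on already RMA-normalized, log-scale intensity matrices
(rows = probes or genes, columns = samples): detection-p filtering,
probe-to-gene collapsing by averaging, restriction to autosomal genes,
and per-gene z-scaling, z = (x - mu) / sigma across all samples
("scaled expression").
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AUTOSOMES = {str(i) for i in range(1, 23)}


def filter_detection(
    probe_matrix: pd.DataFrame,
    detection_p: pd.DataFrame,
    alpha: float = 0.05,
    min_fraction: float = 0.0,
) -> pd.DataFrame:
    """Keep probes detected (p <= alpha) in enough samples.

    By default a probe is retained when detected in at least one sample;
    ``min_fraction`` raises that to a fraction of samples.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if probe_matrix.shape != detection_p.shape or not probe_matrix.index.equals(
        detection_p.index
    ):
        raise ValueError("probe matrix and detection-p matrix must share shape and ids")
    detected = (detection_p.to_numpy() <= alpha).mean(axis=1)
    threshold = max(min_fraction, 1.0 / probe_matrix.shape[1])
    keep = detected >= threshold
    return probe_matrix.loc[keep]


def collapse_probes(
    probe_matrix: pd.DataFrame, probe_to_gene: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse probe rows to gene rows by per-sample arithmetic mean.

    Probes without a gene mapping are dropped.
    """
    genes = probe_matrix.index.map(lambda p: probe_to_gene.get(str(p)))
    mapped = probe_matrix.loc[genes.notna()]
    if mapped.empty:
        return mapped.set_index(pd.Index([], name="gene"))
    out = mapped.groupby(genes[genes.notna()], sort=True).mean()
    out.index.name = "gene"
    return out


def filter_autosomal(
    gene_matrix: pd.DataFrame, annotation: Mapping[str, str]
) -> pd.DataFrame:
    """Restrict to genes annotated on chromosomes 1-22.

    Sex chromosomes carry trivial sex differences, so the differential
    analysis regards autosomal genes only. Unannotated genes are dropped
    with a logged count.
    """
    chroms = gene_matrix.index.map(lambda g: annotation.get(str(g)))
    n_unannotated = int(chroms.isna().sum())
    if n_unannotated:
        logger.info("filter_autosomal: dropped %d unannotated genes", n_unannotated)
    keep = chroms.map(lambda c: c is not None and str(c) in AUTOSOMES)
    return gene_matrix.loc[np.asarray(keep, dtype=bool)]


def z_transform(gene_matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scaling across all samples: z = (x - mu) / sigma.

    sigma is the sample standard deviation (n-1 denominator). Rows with
    zero variance are set to 0 with a warning rather than NaN.
    """
    if gene_matrix.shape[1] < 2:
        raise ValueError("z_transform requires at least 2 samples")
    values = gene_matrix.to_numpy(dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sigma = values.std(axis=1, ddof=1, keepdims=True)
    degenerate = sigma[:, 0] == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance rows set to z = 0", stacklevel=2
        )
    sigma[degenerate] = 1.0
    z = (values - mu) / sigma
    z[degenerate] = 0.0
    return pd.DataFrame(z, index=gene_matrix.index, columns=gene_matrix.columns)
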