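"""Cross-platform / cross-species integration of choroid plexus transcriptomes.

Heterogeneous platforms (different microarrays, RNA-seq) are made
comparable with a per-sample cumulative-proportion transform: within each
sample, genes are ranked by expression and each gene receives one minus
the cumulative share of the sample's total signal captured by all genes
at least as expressed.  The result lives in [0, 1), depends only on
within-sample ranks and relative magnitudes, and is exactly invariant to
per-sample positive scaling — which is what makes values from different
experiments and platforms comparable.

Workflow: transform each dataset separately, intersect shared genes
within species, pair orthologs across species into a combined cohort,
then summarize with a transcriptome-wide Spearman correlogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cluster_partition import sample_correlation_matrix
from .matrix_io import ExpressionMatrix, OrthologMap

logger = logging.getLogger(__name__)

__all__ = [
    "CombinedCohort",
    "cumulative_proportion_transform",
    "intersect_shared_genes",
    "pair_orthologs",
    "correlogram",
    "extract_gene_levels",
]


@dataclass
class CombinedCohort:
    """Orthologous genes x all samples, with species/dataset labels per sample.

    Row identifiers carry both symbols as "HUMAN|Mouse"; values are
    cumulative-proportion transformed, hence within [0, 1].
    """

    matrix: ExpressionMatrix
    species: list[str]
    dataset: list[str]
    symbol_pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.species) != self.matrix.n_samples:
            raise ValueError("one species label per sample required")
        if len(self.dataset) != self.matrix.n_samples:
            raise ValueError("one dataset label per sample required")
        v = self.matrix.values
        if v.size and (v.min() < 0.0 or v.max() > 1.0):
            raise ValueError("combined cohort values must lie in [0, 1]")


def cumulative_proportion_transform(
    m: ExpressionMatrix, delog: bool = False, log_base: float = 2.0
) -> ExpressionMatrix:
    """Per-sample cumulative-proportion normalization onto [0, 1).

    For each sample, with values sorted descending, the gene at sorted
    position i maps to ``1 - cumsum_through_i / sample_total``; values
    are returned in the original gene order.  Tied input values all
    receive the value computed at the END of their tie block, so the
    output is deterministic and independent of input order.  The most
    expressed gene gets the largest output; a constant sample maps to
    all zeros.

    The transform is only meaningful on a linear intensity scale.
    Log-scale matrices are refused unless ``delog=True`` explicitly
    exponentiates them first (``log_base ** x``); there is no silent
    auto-detection.
    """
    values = m.values
    if m.scale_tag == "log":
        if not delog:
            raise ValueError(
                "cumulative_proportion_transform requires linear-scale values; "
                "pass delog=True to exponentiate log-scale input first"
            )
        values = np.power(log_base, values)
    if values.min() < 0.0:
        raise ValueError(
            "negative expression values: the transform needs a linear, non-negative "
            "scale (de-log the matrix first)"
        )
    totals = values.sum(axis=0)
    if np.any(totals <= 0.0):
        bad = m.sample_ids[int(np.argmin(totals))]
        raise ValueError(f"sample {bad!r} has zero total signal")

    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(-col, kind="stable")
        sorted_vals = col[order]
        cum = np.cumsum(sorted_vals) / totals[j]
        # ties: every member of a tie block takes the block-end cumulative value
        boundary = np.empty(col.size, dtype=bool)
        boundary[:-1] = sorted_vals[:-1] != sorted_vals[1:]
        boundary[-1] = True
        # nearest block-end index at or after each position
        idx = np.where(boundary, np.arange(col.size), col.size)
        block_end = np.minimum.accumulate(idx[::-1])[::-1]
        transformed_sorted = 1.0 - cum[block_end]
        out[order, j] = transformed_sorted
    out = np.clip(out, 0.0, None)
    return ExpressionMatrix.from_arrays(
        m.feature_ids, m.sample_ids, out, scale_tag="linear", platform_tag=m.platform_tag
    )


def intersect_shared_genes(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict two gene-level matrices to their shared symbols, identically ordered."""
    shared = sorted(set(a.feature_ids) & set(b.feature_ids))
    if not shared:
        raise ValueError("no shared genes between the two matrices")
    logger.info("shared genes: %d", len(shared))
    return a.subset_features(shared), b.subset_features(shared)


def pair_orthologs(
    h: ExpressionMatrix, m: ExpressionMatrix, omap: OrthologMap
) -> CombinedCohort:
    """Concatenate human and mouse samples over orthologous gene pairs.

    Inputs are expected already transformed and within-species
    intersected.  Rows are restricted to map pairs present in both
    matrices; pairing is independent of input row order.
    """
    h_set = set(h.feature_ids)
    m_set = set(m.feature_ids)
    pairs = sorted((a, b) for a, b in omap.pairs if a in h_set and b in m_set)
    if not pairs:
        raise ValueError("no ortholog pair present in both matrices")
    h_sub = h.subset_features([a for a, _ in pairs])
    m_sub = m.subset_features([b for _, b in pairs])
    row_ids = [f"{a}|{b}" for a, b in pairs]
    values = np.hstack([h_sub.values, m_sub.values])
    sample_ids = h.sample_ids + m.sample_ids
    matrix = ExpressionMatrix.from_arrays(
        row_ids, sample_ids, values, scale_tag="linear", platform_tag="combined"
    )
    species = [omap.species_a] * h.n_samples + [omap.species_b] * m.n_samples
    dataset = (
        [h.platform_tag or omap.species_a] * h.n_samples
        + [m.platform_tag or omap.species_b] * m.n_samples
    )
    logger.info("paired %d orthologous genes across %d samples", len(pairs), len(sample_ids))
    return CombinedCohort(matrix, species, dataset, pairs)


def correlogram(c: CombinedCohort) -> tuple[np.ndarray, dict[str, float]]:
    """Transcriptome-wide Spearman sample x sample matrix plus summary means.

    The summary reports the mean off-diagonal correlation within each
    species and between species.
    """
    corr = sample_correlation_matrix(c.matrix, method="spearman")
    sp = np.asarray(c.species)
    summary: dict[str, float] = {}
    for s in dict.fromkeys(c.species):
        mask = sp == s
        block = corr[np.ix_(mask, mask)]
        off = block[~np.eye(block.shape[0], dtype=bool)]
        summary[f"within_{s}"] = float(np.nanmean(off)) if off.size else float("nan")
    species_unique = list(dict.fromkeys(c.species))
    if len(species_unique) >= 2:
        a, b = species_unique[:2]
        block = corr[np.ix_(sp == a, sp == b)]
        summary["between_species"] = float(np.nanmean(block))
    return corr, summary


def extract_gene_levels(
    c: CombinedCohort, gene_pair: tuple[str, str] | str
) -> pd.DataFrame:
    """Per-sample transformed levels of one orthologous gene pair.

    Returns a tidy table (sample, species, dataset, value) with
    per-species median and IQR attached as ``df.attrs["summary"]``;
    a single-sample species reports IQR 0 with a degenerate flag.
    """
    if isinstance(gene_pair, str):
        row_id = gene_pair
    else:
        row_id = f"{gene_pair[0]}|{gene_pair[1]}"
    if row_id not in c.matrix.data.index:
        raise KeyError(f"gene pair {row_id!r} absent from combined cohort")
    vals = c.matrix.row(row_id)
    df = pd.DataFrame(
        {
            "sample": c.matrix.sample_ids,
            "species": c.species,
            "dataset": c.dataset,
            "value": vals,
        }
    )
    summary = {}
    for s, grp in df.groupby("species", sort=False):
        v = grp["value"].to_numpy()
        q1, q3 = np.percentile(v, [25, 75], method="linear")
        summary[s] = {
            "median": float(np.median(v)),
            "iqr": float(q3 - q1),
            "n": int(v.size),
            "degenerate": bool(v.size < 2),
        }
    df.attrs["summary"] = summary
    return df
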