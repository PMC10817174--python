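"""Gene-level preprocessing of omics panels.

Covers the steps needed to turn platform-specific matrices into
comparable gene-symbol-indexed layers:

* transcript-to-symbol collapsing by arithmetic mean,
* retention of the highest-variance genes (noise reduction),
* ploidy-relative binarization of integer copy numbers,
* silent-variant filtering into a binary mutation matrix,
* gene alignment of two panels to their shared symbols.

The variance filter and copy-number binarizer are scikit-learn style
transformers; the module-level functions wrap them for one-shot use.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .panel import NON_SILENT, OmicsPanel

logger = logging.getLogger(__name__)

#: pseudo-count substituted for zero copies before the log ratio
CN_FLOOR = 0.25

#: |log2 ratio| below this is copy-neutral; integer copies equal to the
#: ploidy are the only neutral case, so the tolerance is essentially zero
CN_NEUTRAL_TOL = 1e-9


def collapse_transcripts(
    matrix: pd.DataFrame, mapping: dict[str, str]
) -> pd.DataFrame:
    """Collapse a cell-line x transcript matrix to gene symbols.

    Multiple transcripts mapping to one symbol are averaged
    (arithmetic mean). Transcripts absent from ``mapping`` are dropped
    and their count logged.
    """
    if not mapping:
        raise ValueError("transcript-to-symbol mapping is empty")
    mapped = [t for t in matrix.columns if t in mapping]
    n_dropped = matrix.shape[1] - len(mapped)
    if not mapped:
        raise ValueError("no transcript in the matrix has a mapping entry")
    if n_dropped:
        logger.info("collapse_transcripts: dropped %d unmapped transcripts", n_dropped)
    sub = matrix[mapped]
    symbols = [mapping[t] for t in mapped]
    collapsed = sub.T.groupby(pd.Index(symbols, name="gene"), sort=False).mean().T
    return collapsed


class TopVarianceFilter(TransformerMixin, BaseEstimator):
    """Keep the ``keep_fraction`` of genes with highest sample variance.

    Retains ``ceil(keep_fraction * n_genes)`` genes. Their original
    input order is preserved; variance ties at the cutoff are broken in
    favour of the gene earlier in input order.
    """

    def __init__(self, keep_fraction: float = 0.2):
        self.keep_fraction = keep_fraction

    def fit(self, X: pd.DataFrame, y=None) -> "TopVarianceFilter":
        if not 0.0 < self.keep_fraction <= 1.0:
            raise ValueError("keep_fraction must lie in (0, 1]")
        if len(X) < 2:
            raise ValueError("variance filtering needs at least 2 cell lines")
        variances = X.var(axis=0, ddof=1).to_numpy()
        k = math.ceil(self.keep_fraction * X.shape[1])
        # stable argsort on -variance: earlier input position wins ties
        order = np.argsort(-variances, kind="stable")[:k]
        keep = np.zeros(X.shape[1], dtype=bool)
        keep[order] = True
        self.support_ = keep
        self.selected_genes_ = list(X.columns[keep])
        self.variances_ = variances
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.selected_genes_]


def variance_filter(matrix: pd.DataFrame, keep_fraction: float) -> pd.DataFrame:
    """One-shot top-variance gene filter (fit and transform on ``matrix``)."""
    return TopVarianceFilter(keep_fraction).fit_transform(matrix)


@dataclass(frozen=True)
class CopyNumberRecord:
    """Gene-level copy-number call relative to the copy-neutral state."""

    cn_min: int
    cn_max: int
    ploidy: float
    log_ratio: float
    binary_call: int


def binarize_copy_number(
    cn_min: int,
    cn_max: int,
    ploidy: float,
    tol: float = CN_NEUTRAL_TOL,
    floor: float = CN_FLOOR,
) -> CopyNumberRecord:
    """Binarize one gene's copy number against the cell-line ploidy.

    Both min and max copies are divided by the ploidy and log2
    transformed; the ratio with the larger absolute value is kept
    (magnitude ties resolve to the max-derived ratio). The gene is
    called altered (1) when ``|log_ratio| > tol``, copy-neutral (0)
    otherwise. Zero copies are floored at ``floor`` before the ratio.
    """
    if cn_min < 0 or cn_max < 0:
        raise ValueError("copy numbers must be non-negative")
    if cn_min > cn_max:
        raise ValueError("cn_min cannot exceed cn_max")
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    lo = math.log2(max(cn_min, floor) / ploidy)
    hi = math.log2(max(cn_max, floor) / ploidy)
    log_ratio = hi if abs(hi) >= abs(lo) else lo
    call = int(abs(log_ratio) > tol)
    return CopyNumberRecord(cn_min, cn_max, ploidy, log_ratio, call)


class CopyNumberBinarizer(TransformerMixin, BaseEstimator):
    """Vectorized ploidy-relative binarization of a panel's CN layers."""

    def __init__(self, tol: float = CN_NEUTRAL_TOL, floor: float = CN_FLOOR):
        self.tol = tol
        self.floor = floor

    def fit(self, X=None, y=None):
        return self

    def transform(self, panel: OmicsPanel) -> pd.DataFrame:
        cn_min = panel.cn_min.to_numpy()
        cn_max = panel.cn_max.to_numpy()
        if (cn_min < 0).any() or (cn_max < 0).any():
            raise ValueError("copy numbers must be non-negative")
        ploidy = panel.ploidy.to_numpy()[:, None]
        lo = np.log2(np.maximum(cn_min, self.floor) / ploidy)
        hi = np.log2(np.maximum(cn_max, self.floor) / ploidy)
        log_ratio = np.where(np.abs(hi) >= np.abs(lo), hi, lo)
        calls = (np.abs(log_ratio) > self.tol).astype(int)
        return pd.DataFrame(
            calls, index=panel.cn_min.index, columns=panel.cn_min.columns
        )


def build_mutation_matrix(
    variants: pd.DataFrame,
    cell_ids: list[str] | None = None,
    gene_ids: list[str] | None = None,
    strict: bool = False,
) -> pd.DataFrame:
    """Binary cell-line x gene matrix from variant records.

    An entry is 1 iff the cell line carries at least one protein-
    affecting (non-silent) variant of the gene. Unknown consequence
    classes raise when ``strict`` and are otherwise kept with a
    warning (treated as protein-affecting).
    """
    known = NON_SILENT | {"silent"}
    unknown = set(variants["consequence"]) - known
    if unknown:
        if strict:
            raise ValueError(f"unknown consequence classes: {sorted(unknown)}")
        logger.warning(
            "build_mutation_matrix: keeping unknown consequence classes %s",
            sorted(unknown),
        )
    damaging = variants[variants["consequence"] != "silent"]
    cells = cell_ids if cell_ids is not None else sorted(variants["cell_line"].unique())
    genes = gene_ids if gene_ids is not None else sorted(variants["gene"].unique())
    matrix = pd.DataFrame(0, index=pd.Index(cells, name="cell_line"), columns=genes)
    hit = damaging[damaging["cell_line"].isin(matrix.index) & damaging["gene"].isin(genes)]
    for c, g in zip(hit["cell_line"], hit["gene"]):
        matrix.loc[c, g] = 1
    return matrix


def align_panels(train: OmicsPanel, test: OmicsPanel) -> tuple[OmicsPanel, OmicsPanel]:
    """Restrict both panels to their shared genes, in the train panel's order."""
    shared = [g for g in train.expression.columns if g in set(test.expression.columns)]
    if not shared:
        raise ValueError("panels share no genes")
    logger.info("align_panels: %d shared genes", len(shared))

    def restrict(p: OmicsPanel) -> OmicsPanel:
        out = OmicsPanel(
            expression=p.expression[shared],
            cn_min=p.cn_min[shared],
            cn_max=p.cn_max[shared],
            ploidy=p.ploidy,
            variants=p.variants[p.variants["gene"].isin(shared)].reset_index(drop=True),
        )
        if p.cn_binary is not None:
            out.cn_binary = p.cn_binary[shared]
        if p.mutation is not None:
            out.mutation = p.mutation[shared]
        return out

    return restrict(train), restrict(test)


def preprocess_panel(
    panel: OmicsPanel,
    keep_fraction: float | None = 0.2,
    tol: float = CN_NEUTRAL_TOL,
) -> OmicsPanel:
    """Derive the binary layers and (optionally) variance-filter expression."""
    out = panel.copy()
    if keep_fraction is not None:
        out.expression = variance_filter(out.expression, keep_fraction)
    out.cn_binary = CopyNumberBinarizer(tol=tol).transform(panel)
    out.mutation = build_mutation_matrix(
        panel.variants, cell_ids=panel.cell_ids, gene_ids=list(panel.cn_min.columns)
    )
    return out
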