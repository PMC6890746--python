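"""Tissue specificity, gene-set enrichment and qPCR validation statistics.

Three independent downstream summaries of the network results: (i) TPM
normalisation and per-gene z-scores across a multi-tissue panel, used to ask
whether disease-regulated lncRNAs are depleted or enriched in normal brain;
(ii) one-sided hypergeometric enrichment of hub partner sets against GMT
gene-set collections (raw p < 0.05 marks significance, mirroring the
screening convention; a BH column is reported but does not drive the flag);
(iii) relative qPCR quantification by the 2^-ddCt method with a Welch
two-tailed t-test on per-sample dCt values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .differential_expression import bh_adjust
from .io import GeneSet

logger = logging.getLogger(__name__)

TPM_SCALE = 1e6


def tpm_normalize(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: length-normalised counts scaled per column.

    ``rate = count / length_kb``; ``TPM = rate / sum(rate) * 1e6`` per
    column, so every column sums to 1e6.  Raises for missing/non-positive
    lengths and for all-zero columns (undefined normalisation).
    """
    missing = [g for g in counts.index if g not in lengths.index]
    if missing:
        raise AnalysisError(f"missing transcript lengths for: {missing[:5]}")
    lens = lengths.loc[counts.index].to_numpy(dtype=float)
    if (lens <= 0).any():
        raise AnalysisError("transcript lengths must be positive")
    rate = counts.to_numpy(dtype=float) / (lens[:, None] / 1e3)
    colsum = rate.sum(axis=0)
    if (colsum == 0).any():
        bad = counts.columns[np.nonzero(colsum == 0)[0][0]]
        raise AnalysisError(f"column {bad!r} is all zero; TPM undefined")
    return pd.DataFrame(
        rate / colsum * TPM_SCALE, index=counts.index, columns=counts.columns
    )


def zscore_by_gene(panel: pd.DataFrame) -> pd.DataFrame:
    """Standard score per gene across all panel columns (sample sd, ddof=1).

    Constant genes become all-zero rows, with a logged warning.
    """
    values = panel.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        logger.warning("zscore_by_gene: %d constant gene(s) set to zero", constant.sum())
    sd[sd == 0] = 1.0
    return pd.DataFrame((values - mean) / sd, index=panel.index, columns=panel.columns)


def brain_contrast(
    z: pd.DataFrame,
    up_set: Iterable[str],
    down_set: Iterable[str],
    brain_label: str = "brain",
) -> tuple[float, float]:
    """Mean brain z-score of the up- and down-regulated gene sets.

    ``z`` has MultiIndex (tissue, replicate) columns; the mean is taken over
    all brain replicate columns and over the genes of each set.  An empty
    set yields NaN (undefined, reported as such).
    """
    if isinstance(z.columns, pd.MultiIndex):
        brain_cols = [c for c in z.columns if c[0] == brain_label]
    else:
        brain_cols = [c for c in z.columns if str(c).split(".")[0] == brain_label]
    if not brain_cols:
        raise AnalysisError(f"no {brain_label!r} columns in the panel")

    def _mean(gene_set: Iterable[str]) -> float:
        genes = [g for g in gene_set if g in z.index]
        if not genes:
            return float("nan")
        return float(z.loc[genes, brain_cols].to_numpy().mean())

    return _mean(up_set), _mean(down_set)


def hypergeometric_enrichment(
    query: Iterable[str],
    sets: Sequence[GeneSet],
    universe: Iterable[str],
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """One-sided upper-tail hypergeometric enrichment of a query gene set.

    Query genes outside the universe are dropped (logged); each term is
    intersected with the universe too.  ``significant`` is a strict raw
    p < p_cut; the ``padj`` column is informational only.
    """
    universe = set(universe)
    if not universe:
        raise AnalysisError("empty universe")
    query = set(query)
    outside = query - universe
    if outside:
        logger.info(
            "hypergeometric_enrichment: %d query gene(s) outside universe dropped",
            len(outside),
        )
    query &= universe
    big_n = len(universe)
    rows = []
    for gs in sets:
        members = gs.members & universe
        if not members:
            continue
        overlap = len(query & members)
        # P(X >= overlap), X ~ Hypergeom(N=universe, K=set, n=query)
        p = float(stats.hypergeom.sf(overlap - 1, big_n, len(members), len(query)))
        rows.append(
            dict(
                term=gs.term_id,
                name=gs.name,
                source=gs.source,
                overlap_count=overlap,
                query_size=len(query),
                set_size=len(members),
                universe_size=big_n,
                p=p,
            )
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "term",
            "name",
            "source",
            "overlap_count",
            "query_size",
            "set_size",
            "universe_size",
            "p",
        ],
    )
    if len(result):
        result["padj"] = bh_adjust(result["p"].to_numpy())
        result["significant"] = result["p"] < p_cut
        result = result.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    else:
        result["padj"] = []
        result["significant"] = []
    return result


@dataclass(frozen=True)
class DdctResult:
    """Relative-quantification summary for one target gene."""

    fold_change: float
    ddct: float
    p: float  # NaN when a group has < 2 samples
    n_case: int
    n_control: int


def ddct_fold_change(
    ct: pd.DataFrame, equal_var: bool = False
) -> DdctResult:
    """2^-ddCt fold change of case vs control with a two-tailed t-test.

    ``ct`` needs columns sample, group, ct_target, ct_reference.  Per sample
    dCt = ct_target - ct_reference; ddCt = mean dCt(case) - mean
    dCt(control); fold change = 2^-ddCt.  The default test is Welch
    (unequal variances), fitting unbalanced group sizes; ``equal_var=True``
    gives the pooled-variance variant.  With fewer than 2 samples in a
    group the fold change is still computed but p is undefined.
    """
    required = {"sample", "group", "ct_target", "ct_reference"}
    if not required.issubset(ct.columns):
        raise AnalysisError(f"Ct table needs columns {sorted(required)}")
    values = ct[["ct_target", "ct_reference"]].to_numpy(dtype=float)
    if not np.isfinite(values).all() or (values <= 0).any():
        raise AnalysisError("Ct values must be positive and finite")
    dct = ct["ct_target"].astype(float) - ct["ct_reference"].astype(float)
    case = dct[ct["group"] == "case"]
    control = dct[ct["group"] == "control"]
    if case.empty or control.empty:
        raise AnalysisError("both case and control samples are required")
    ddct = float(case.mean() - control.mean())
    fold = 2.0 ** (-ddct)
    if len(case) < 2 or len(control) < 2:
        p = float("nan")
    elif case.std(ddof=1) == 0 and control.std(ddof=1) == 0:
        p = 1.0 if ddct == 0 else 0.0
    else:
        p = float(stats.ttest_ind(case, control, equal_var=equal_var).pvalue)
    return DdctResult(
        fold_change=fold, ddct=ddct, p=p, n_case=len(case), n_control=len(control)
    )
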