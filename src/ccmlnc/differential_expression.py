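"""Two-group negative-binomial differential expression.

The model follows the normalisation-plus-NB-Wald scheme used by count-based
DE packages: per-sample size factors by the median-of-ratios rule, per-gene
dispersion by method of moments on normalised counts (variance
``mu + alpha * mu**2``), and a Wald statistic on the log2 fold change with a
delta-method standard error.  Two deliberate simplifications, documented in
the methods note: no dispersion shrinkage across genes and no independent
filtering; externally produced DE tables can be imported instead via
:func:`ccmlnc.io.read_de_table`.

P-values use a Student-t reference with ``n1 + n2 - 2`` degrees of freedom.
With cohorts this small (10 vs 4) a normal reference is anti-conservative in
exactly the tail that matters for FDR control at padj < 0.01; the t
reference keeps the all-null false-discovery proportion at its nominal
level.  Statuses follow the strict thresholds padj < 0.01 and
|log2 fold change| > 1.5.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError
from .io import CountMatrix, DE_COLUMNS

logger = logging.getLogger(__name__)

#: floor for the method-of-moments dispersion estimate
MIN_DISPERSION = 1e-8

#: pseudocount (normalised-count scale) stabilising log2 fold changes at zero
PSEUDOCOUNT = 0.5


def size_factors(cm: CountMatrix, allow_pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    Each sample's factor is the median, over reference genes, of its count
    divided by that gene's geometric mean across samples.  Genes with a zero
    in any sample are excluded from the reference set; if none remain, an
    error advises the ``allow_pseudo_reference`` fallback, which instead
    takes geometric means over positive counts only.
    """
    counts = cm.data.to_numpy(dtype=float)
    all_nonzero = (counts > 0).all(axis=1)
    if all_nonzero.any():
        ref = counts[all_nonzero]
        log_geo = np.log(ref).mean(axis=1)
        log_ratios = np.log(ref) - log_geo[:, None]
    elif allow_pseudo_reference:
        pos = counts > 0
        usable = pos.any(axis=1)
        with np.errstate(divide="ignore"):
            logs = np.where(pos, np.log(np.maximum(counts, 1e-300)), np.nan)
        log_geo = np.nanmean(logs[usable], axis=1)
        log_ratios = np.where(
            pos[usable], np.log(np.maximum(counts[usable], 1e-300)) - log_geo[:, None], np.nan
        )
    else:
        raise AnalysisError(
            "no gene has nonzero counts in every sample; rerun with "
            "allow_pseudo_reference=True to use a positive-count pseudo-reference"
        )
    with np.errstate(invalid="ignore"):
        factors = np.exp(np.nanmedian(log_ratios, axis=0))
    if not np.all(np.isfinite(factors)) or (factors <= 0).any():
        raise AnalysisError("size factor estimation failed (non-positive factor)")
    return pd.Series(factors, index=cm.samples, name="size_factor")


def nb_wald_test(
    cm: CountMatrix,
    factors: pd.Series | None = None,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene NB Wald test of case vs control.

    Returns a DE table indexed by gene id with columns ``base_mean, log2fc,
    se_log2fc, p, padj, status``.  ``padj`` is BH-adjusted over the tested
    genes; genes with all-zero counts are ``untested`` with undefined p.
    Statuses other than ``untested`` are left ``ns`` until
    :func:`filter_de` applies thresholds.
    """
    case = cm.samples_in_group("case")
    ctrl = cm.samples_in_group("control")
    if len(case) < 2 or len(ctrl) < 2:
        raise AnalysisError(
            f"each group needs >=2 samples (case={len(case)}, control={len(ctrl)})"
        )
    if factors is None:
        factors = size_factors(cm)
    norm = cm.data.to_numpy(dtype=float) / factors.loc[cm.samples].to_numpy()
    idx_case = [cm.samples.index(s) for s in case]
    idx_ctrl = [cm.samples.index(s) for s in ctrl]
    n1, n0 = len(idx_case), len(idx_ctrl)

    x1, x0 = norm[:, idx_case], norm[:, idx_ctrl]
    mu1, mu0 = x1.mean(axis=1), x0.mean(axis=1)
    base_mean = norm.mean(axis=1)

    s2_pool = ((n1 - 1) * x1.var(axis=1, ddof=1) + (n0 - 1) * x0.var(axis=1, ddof=1)) / (
        n1 + n0 - 2
    )
    mu_bar = (n1 * mu1 + n0 * mu0) / (n1 + n0)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.maximum(
            (s2_pool - mu_bar) / np.maximum(mu_bar, 1e-300) ** 2, MIN_DISPERSION
        )
    var_mean1 = (mu1 + alpha * mu1**2) / n1
    var_mean0 = (mu0 + alpha * mu0**2) / n0

    c = pseudocount
    log2fc = np.log2((mu1 + c) / (mu0 + c))
    se = np.sqrt(var_mean1 / (mu1 + c) ** 2 + var_mean0 / (mu0 + c) ** 2) / np.log(2)

    tested = base_mean > 0
    p = np.full(len(base_mean), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = log2fc[tested] / se[tested]
    p[tested] = 2.0 * stats.t.sf(np.abs(wald), df=n1 + n0 - 2)

    det = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se_log2fc": se,
            "p": p,
            "padj": bh_adjust(p),
            "status": np.where(tested, "ns", "untested"),
        },
        index=pd.Index(cm.genes, name="gene_id"),
    )
    return det


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with NaN passthrough.

    ``m`` is the number of defined p-values; undefined entries stay NaN.
    """
    p = np.asarray(p, dtype=float)
    defined = ~np.isnan(p)
    if ((p[defined] < 0) | (p[defined] > 1)).any():
        bad = p[defined][(p[defined] < 0) | (p[defined] > 1)][0]
        raise AnalysisError(f"p-value {bad} outside [0, 1]")
    out = np.full(p.shape, np.nan)
    if defined.any():
        out[defined] = multipletests(p[defined], method="fdr_bh")[1]
    return out


def filter_de(
    det: pd.DataFrame, padj_cut: float = 0.01, lfc_cut: float = 1.5
) -> pd.DataFrame:
    """Set up/down/ns status using strict threshold inequalities.

    ``up`` iff padj < padj_cut and log2fc > lfc_cut; ``down`` iff padj <
    padj_cut and log2fc < -lfc_cut ("greater than" in both directions);
    untested genes keep their status.
    """
    det = det.copy()
    padj = det["padj"].to_numpy(dtype=float)
    lfc = det["log2fc"].to_numpy(dtype=float)
    tested = det["status"].to_numpy() != "untested"
    sig = tested & ~np.isnan(padj) & (padj < padj_cut)
    status = np.where(tested, "ns", "untested").astype(object)
    status[sig & (lfc > lfc_cut)] = "up"
    status[sig & (lfc < -lfc_cut)] = "down"
    det["status"] = status
    return det


def merge_cohorts(a: CountMatrix, b: CountMatrix) -> CountMatrix:
    """Merge two cohorts on the intersection of their gene sets.

    Sample ids must be disjoint; group labels and per-sample cohort tags are
    preserved.  Gene order follows cohort ``a``.
    """
    overlap = set(a.samples) & set(b.samples)
    if overlap:
        raise AnalysisError(f"overlapping sample ids between cohorts: {sorted(overlap)}")
    shared = [g for g in a.genes if g in set(b.genes)]
    if not shared:
        raise AnalysisError("cohorts share no gene ids; nothing to merge")
    dropped = (len(a.genes) - len(shared)) + (len(b.genes) - len(shared))
    if dropped:
        logger.info("merge_cohorts: dropped %d non-shared gene rows", dropped)
    data = pd.concat([a.data.loc[shared], b.data.loc[shared]], axis=1)
    groups = {**dict(a.groups), **dict(b.groups)}
    cohorts = {**dict(a.cohorts), **dict(b.cohorts)}
    return CountMatrix(data, groups, cohorts)


def overlap_fraction(
    combined_sig: Iterable[str], reference_sig: Iterable[str]
) -> tuple[int, float | None]:
    """Overlap of a combined-analysis gene set with a reference set.

    Returns ``(count, fraction)`` where fraction = count / |combined|;
    fraction is None (undefined) when the combined set is empty.
    """
    combined = set(combined_sig)
    count = len(combined & set(reference_sig))
    if not combined:
        return 0, None
    return count, count / len(combined)
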