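"""All-pairs lncRNA-mRNA Spearman co-expression and hub selection.

Every differentially expressed lncRNA is correlated against every
differentially expressed protein-coding gene across the pooled samples.
Pairs are retained when the Spearman coefficient is strictly above the
cut-off (0.9, signed by default -- co-expression means similar expression
patterns) with p strictly below 0.05.  A lncRNA becomes a *hub* when it
retains strictly more than ``min_partners`` (100) partners.  P-values are
exact for n <= 9 samples (full enumeration of rank permutations, valid
under ties) and use the classical t approximation above that.

Correlations are computed on log2(normalised count + 1); raw p-values are
reported without multiple-testing correction by default (a BH column can be
requested), matching the screening character of the analysis.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .differential_expression import bh_adjust

logger = logging.getLogger(__name__)

RHO_CUT = 0.9
P_CUT = 0.05
MIN_PARTNERS = 100
EXACT_P_MAX_N = 9  # full permutation enumeration up to this sample count


@dataclass(frozen=True)
class HubRecord:
    """A hub lncRNA with its co-expressed protein-coding partner set."""

    lnc_id: str
    partners: frozenset[str]

    @property
    def degree(self) -> int:
        return len(self.partners)


def spearman_rho(x, y) -> float:
    """Spearman correlation: Pearson correlation of average ranks.

    Returns NaN (undefined) when either series is constant.  Requires
    equal-length series of n >= 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AnalysisError("series must be 1-D and of equal length")
    if len(x) < 3:
        raise AnalysisError("need n >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


@lru_cache(maxsize=8)
def _perm_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _exact_pvalue(x: np.ndarray, y: np.ndarray, observed_rho: float) -> float:
    """Two-sided exact p by enumerating all n! rank permutations.

    Counts permutations whose |rho| is at least the observed |rho| (within
    1e-12 to absorb float noise).  Average ranks make this valid for tied
    data.
    """
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt((rx_c @ rx_c) * (ry_c @ ry_c))
    perms = _perm_matrix(n)
    rhos = (ry_c[perms] @ rx_c) / denom
    return float(np.mean(np.abs(rhos) >= abs(observed_rho) - 1e-12))


def spearman_pvalue(rho: float, n: int, x=None, y=None) -> float:
    """Significance of a Spearman coefficient.

    For n <= 9 (``x`` and ``y`` required) the p-value is exact by full
    permutation enumeration; beyond that the t approximation
    ``t = rho * sqrt((n-2) / (1-rho^2))`` with n-2 degrees of freedom is
    used.  Undefined rho gives undefined p.
    """
    if isinstance(rho, float) and math.isnan(rho):
        return float("nan")
    if n <= EXACT_P_MAX_N:
        if x is None or y is None:
            raise AnalysisError("exact p-value (n <= 9) needs the data series x and y")
        return _exact_pvalue(np.asarray(x, float), np.asarray(y, float), rho)
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def correlate_pairs(
    lnc_expr: pd.DataFrame,
    pcg_expr: pd.DataFrame,
    rho_cut: float = RHO_CUT,
    p_cut: float = P_CUT,
    mode: str = "positive",
    adjust: bool = False,
) -> pd.DataFrame:
    """Score all lncRNA x PCG pairs; keep significant co-expressed ones.

    Inputs are normalised expression matrices (genes x samples) sharing the
    same sample columns.  A pair is retained iff rho > rho_cut
    (``mode="positive"``) or |rho| > rho_cut (``mode="absolute"``) -- both
    strict -- and p < p_cut.  Constant genes are dropped with a logged
    count.  Returns a pair table (lnc_id, pcg_id, rho, p, n); with
    ``adjust=True`` a BH-adjusted column ``padj`` over the retained pairs'
    raw tests is appended (off by default).
    """
    if mode not in ("positive", "absolute"):
        raise AnalysisError(f"mode must be 'positive' or 'absolute', got {mode!r}")
    if list(lnc_expr.columns) != list(pcg_expr.columns):
        raise AnalysisError("lncRNA and PCG matrices must share identical sample columns")
    n = lnc_expr.shape[1]
    if n < 3:
        raise AnalysisError("need at least 3 samples")

    def _prep(df: pd.DataFrame, label: str) -> pd.DataFrame:
        values = df.to_numpy(dtype=float)
        keep = np.ptp(values, axis=1) > 0
        if (~keep).any():
            logger.info("correlate_pairs: dropped %d constant %s gene(s)", (~keep).sum(), label)
        return df.loc[keep]

    lnc_expr = _prep(lnc_expr, "lncRNA")
    pcg_expr = _prep(pcg_expr, "PCG")
    if lnc_expr.empty or pcg_expr.empty:
        return pd.DataFrame(columns=["lnc_id", "pcg_id", "rho", "p", "n"])

    rl = stats.rankdata(lnc_expr.to_numpy(dtype=float), axis=1)
    rp = stats.rankdata(pcg_expr.to_numpy(dtype=float), axis=1)
    rl = rl - rl.mean(axis=1, keepdims=True)
    rp = rp - rp.mean(axis=1, keepdims=True)
    rl /= np.sqrt((rl**2).sum(axis=1, keepdims=True))
    rp /= np.sqrt((rp**2).sum(axis=1, keepdims=True))
    rho = rl @ rp.T  # lnc x pcg

    passed = rho > rho_cut if mode == "positive" else np.abs(rho) > rho_cut
    li, pi = np.nonzero(passed)
    rhos = rho[li, pi]
    if n > EXACT_P_MAX_N:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rhos * np.sqrt((n - 2) / np.maximum(1.0 - rhos**2, 1e-300))
        pvals = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        pvals[np.abs(rhos) >= 1.0] = 0.0
    else:
        lvals = lnc_expr.to_numpy(dtype=float)
        pvals_list = []
        pcg_vals = pcg_expr.to_numpy(dtype=float)
        for i, j, r in zip(li, pi, rhos):
            pvals_list.append(_exact_pvalue(lvals[i], pcg_vals[j], r))
        pvals = np.array(pvals_list)

    keep = pvals < p_cut
    pairs = pd.DataFrame(
        {
            "lnc_id": lnc_expr.index.to_numpy()[li[keep]],
            "pcg_id": pcg_expr.index.to_numpy()[pi[keep]],
            "rho": rhos[keep],
            "p": pvals[keep],
            "n": n,
        }
    ).reset_index(drop=True)
    if adjust:
        pairs["padj"] = bh_adjust(pairs["p"].to_numpy())
    return pairs


def select_hubs(pairs: pd.DataFrame, min_partners: int = MIN_PARTNERS) -> list[HubRecord]:
    """Hub lncRNAs: strictly more than ``min_partners`` retained partners."""
    if pairs.empty:
        return []
    hubs = []
    for lnc, sub in pairs.groupby("lnc_id", sort=True):
        partners = frozenset(sub["pcg_id"])
        if len(partners) > min_partners:
            hubs.append(HubRecord(lnc_id=str(lnc), partners=partners))
    hubs.sort(key=lambda h: (-h.degree, h.lnc_id))
    return hubs


def common_partners(a: HubRecord, b: HubRecord) -> frozenset[str]:
    """PCGs co-expressed with both hubs (partner-set intersection)."""
    return a.partners & b.partners


def build_network(pairs: pd.DataFrame) -> nx.Graph:
    """Bipartite co-expression graph; nodes typed lncRNA/PCG, edges carry rho/p."""
    g = nx.Graph()
    for row in pairs.itertuples(index=False):
        if g.has_edge(row.lnc_id, row.pcg_id):
            raise AnalysisError(f"duplicate edge {row.lnc_id} -- {row.pcg_id}")
        g.add_node(row.lnc_id, kind="lncRNA")
        g.add_node(row.pcg_id, kind="PCG")
        g.add_edge(row.lnc_id, row.pcg_id, rho=float(row.rho), p=float(row.p))
    return g


def hub_table(hubs: list[HubRecord]) -> pd.DataFrame:
    """Flatten hub records for TSV export."""
    return pd.DataFrame(
        {
            "lnc_id": [h.lnc_id for h in hubs],
            "degree": [h.degree for h in hubs],
            "partners": [",".join(sorted(h.partners)) for h in hubs],
        }
    )
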