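"""Synthetic transcriptome cohorts with planted, recoverable ground truth.

The generator emulates the statistical shape of a two-group patient study
(10 cases vs 4 controls by default): negative-binomial gene counts with
per-sample library-size factors, planted up/down differential expression,
hub lncRNAs whose partner PCGs share a latent per-sample co-expression
factor, genes placed on three susceptibility loci, a 16-tissue expression
panel in which disease-up lncRNAs are brain-low, and qPCR Ct tables with a
known ddCt.  Every planted effect is recorded in a
:class:`SyntheticTruth` ledger so downstream tests can score recovery.

Parameterisation and conventions
--------------------------------
* Counts are NB with mean ``mu`` and dispersion ``alpha`` (variance
  ``mu + alpha * mu**2``), the convention the DE module assumes.
* Planted DE multiplies the case-group mean by ``2**log2fc``.
* Co-expression is induced on the log2 scale before rounding back to
  integer counts: the hub lncRNA carries a per-sample latent factor
  (standardised to spread ``module_factor_sd`` log2 units) and each partner
  follows it with gene-level noise (``module_noise_sd``).  The factor is
  centred within each group so module structure never aliases the disease
  contrast, and module genes are generated with their own low NB dispersion
  (``module_dispersion``), modelling tight co-regulation.
* Planted effects are deliberately strong so that planted structure is
  unambiguous at n = 14 and recovery failures indicate pipeline defects,
  not sampling noise: module genes (hub + partners) carry |log2FC| in
  (7, 9) and sit in the 500-2000 count range; background DE genes carry
  moderate effects (|log2FC| in (2.5, 4)) that keep their counts nonzero
  in both groups, which keeps the median-of-ratios reference set balanced.
* A single top-level seed deterministically spawns one substream per stage,
  so adding a later stage never perturbs earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigError
from .io import CountMatrix, GeneSet
from . import genomic_context

_STAGES = ("genes", "de", "counts", "modules", "tissue", "qpcr", "gene_sets", "transcripts")

#: tissue labels of the normal-tissue panel (first entry is brain)
TISSUES = (
    "brain", "heart", "liver", "kidney", "lung", "spleen", "colon", "ovary",
    "testis", "prostate", "thyroid", "adrenal", "adipose", "muscle",
    "lymphnode", "breast", "skin", "stomach", "pancreas", "placenta",
)

_LNC_CLASS_PROBS = {"lincRNA": 0.55, "antisense": 0.35, "sense_overlapping": 0.10}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort."""

    n_lncRNA: int = 220
    n_PCG: int = 1000
    n_case: int = 10
    n_control: int = 4
    baseline_mean_log_range: tuple[float, float] = (math.log(50.0), math.log(2000.0))
    dispersion: float = 0.02
    de_fraction_lnc: float = 0.25
    de_fraction_pcg: float = 0.25
    planted_log2fc_range: tuple[float, float] = (2.5, 4.0)
    module_log2fc_range: tuple[float, float] = (7.0, 9.0)  # hubs + partners
    n_hubs: int = 0
    partners_per_hub: int = 120
    module_factor_sd: float = 1.2  # log2 spread of the shared latent factor
    module_noise_sd: float = 0.05  # log2 sd of partner-level noise on module shifts
    module_dispersion: float = 0.002  # NB dispersion of module genes (tight regulation)
    hub_direction: str = "up"  # planted hubs (and their partners) are disease-up
    library_size_sd: float = 0.15  # log-normal sd of true per-sample depth factors
    locus_fraction: float = 0.06  # fraction of genes placed on the three loci
    qpcr_ddct: float = -2.0
    qpcr_noise_sd: float = 0.2
    n_gene_sets: int = 30
    rng_seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        for name in ("n_lncRNA", "n_PCG", "n_case", "n_control", "n_hubs",
                     "partners_per_hub", "n_gene_sets"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if self.partners_per_hub > self.n_PCG:
            problems.append("partners_per_hub exceeds n_PCG")
        for name in ("de_fraction_lnc", "de_fraction_pcg", "locus_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                problems.append(f"{name} must lie in [0, 1]")
        if not isinstance(self.dispersion, Mapping) and self.dispersion <= 0:
            problems.append("dispersion must be > 0")
        if self.module_dispersion <= 0:
            problems.append("module_dispersion must be > 0")
        if self.module_noise_sd < 0 or self.module_factor_sd < 0:
            problems.append("module noise/factor sd must be >= 0")
        if self.qpcr_noise_sd < 0:
            problems.append("qpcr_noise_sd must be >= 0")
        for name in ("planted_log2fc_range", "module_log2fc_range"):
            lo, hi = getattr(self, name)
            if not (2.0 <= abs(lo) <= abs(hi)):
                problems.append(f"{name} magnitudes must be >= 2 and ordered")
        if self.hub_direction not in ("up", "down"):
            problems.append("hub_direction must be 'up' or 'down'")
        if self.n_hubs > self.n_lncRNA:
            problems.append("n_hubs exceeds n_lncRNA")
        if problems:
            raise ConfigError("; ".join(problems))


@dataclass
class SyntheticTruth:
    """Ledger of every planted effect, keyed by generated gene ids."""

    de_genes: dict[str, float] = field(default_factory=dict)
    hub_modules: dict[str, frozenset[str]] = field(default_factory=dict)
    locus_placements: dict[str, str] = field(default_factory=dict)
    tissue_profile: dict[str, str] = field(default_factory=dict)
    ddct_truth: float = 0.0


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return np.random.default_rng(children[_STAGES.index(stage)])


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha) -> np.ndarray:
    """Gamma-Poisson mixture: NB(mean mu, variance mu + alpha mu^2).

    ``alpha`` may be scalar or a per-gene vector broadcast over rows.
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim == 1:
        alpha = alpha[:, None]
    lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# counts + annotation + truth
# ---------------------------------------------------------------------------

def generate_counts(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate a two-group NB count matrix, gene annotation, and truth ledger.

    Planted DE genes have case/control group-mean ratio ``2**log2fc``.  Hub
    lncRNAs are drawn from (and forced into) the DE set with the configured
    direction; their partner PCGs are sampled from same-direction DE PCGs.
    Co-expression itself is planted separately by
    :func:`plant_coexpression_modules`.
    """
    cfg = config
    rng_genes = _stage_rng(cfg.rng_seed, "genes")
    rng_de = _stage_rng(cfg.rng_seed, "de")
    rng_counts = _stage_rng(cfg.rng_seed, "counts")

    lnc_ids = [f"LNC{i:05d}" for i in range(1, cfg.n_lncRNA + 1)]
    pcg_ids = [f"PCG{i:05d}" for i in range(1, cfg.n_PCG + 1)]
    gene_ids = lnc_ids + pcg_ids
    n_genes = len(gene_ids)

    classes = list(_LNC_CLASS_PROBS)
    probs = np.array(list(_LNC_CLASS_PROBS.values()))
    lnc_classes = rng_genes.choice(classes, size=cfg.n_lncRNA, p=probs)
    biotypes = list(lnc_classes) + ["protein_coding"] * cfg.n_PCG

    lo, hi = cfg.baseline_mean_log_range
    baselines = np.exp(rng_genes.uniform(lo, hi, size=n_genes))
    lengths = rng_genes.integers(500, 5001, size=n_genes)

    # genomic placement: a slice of genes on the three susceptibility loci
    loci = genomic_context.resolve_ccm_loci()
    n_on_loci = int(round(cfg.locus_fraction * n_genes))
    placed = rng_genes.choice(n_genes, size=n_on_loci, replace=False) if n_on_loci else np.array([], int)
    locus_of = {}
    chroms = np.empty(n_genes, dtype=object)
    starts = np.empty(n_genes, dtype=np.int64)
    for rank, gi in enumerate(placed):
        locus = loci[rank % len(loci)]
        span = locus.end - locus.start - int(lengths[gi])
        starts[gi] = locus.start + int(rng_genes.integers(0, max(span, 1)))
        chroms[gi] = locus.chrom
        locus_of[gene_ids[gi]] = locus.name
    unplaced = np.setdiff1d(np.arange(n_genes), placed)
    chroms[unplaced] = rng_genes.choice(["1", "2", "5", "11", "17"], size=len(unplaced))
    starts[unplaced] = rng_genes.integers(1_000_000, 200_000_000, size=len(unplaced))
    strands = rng_genes.choice(["+", "-"], size=n_genes)

    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "symbol": gene_ids,
            "biotype": biotypes,
            "chrom": chroms,
            "start": starts,
            "end": starts + lengths,
            "strand": strands,
            "length": lengths,
        }
    )

    # --- planted differential expression -----------------------------------
    truth = SyntheticTruth(ddct_truth=cfg.qpcr_ddct)
    hub_sign = 1.0 if cfg.hub_direction == "up" else -1.0
    n_de_lnc = int(round(cfg.de_fraction_lnc * cfg.n_lncRNA))
    n_de_pcg = int(round(cfg.de_fraction_pcg * cfg.n_PCG))

    hubs = [lnc_ids[i] for i in rng_de.choice(cfg.n_lncRNA, size=cfg.n_hubs, replace=False)] \
        if cfg.n_hubs else []
    non_hub_lnc = [g for g in lnc_ids if g not in set(hubs)]
    extra = max(n_de_lnc - cfg.n_hubs, 0)
    de_lnc = list(hubs) + [
        non_hub_lnc[i] for i in rng_de.choice(len(non_hub_lnc), size=extra, replace=False)
    ]
    de_pcg = [pcg_ids[i] for i in rng_de.choice(cfg.n_PCG, size=n_de_pcg, replace=False)]

    # Partner sets are disjoint across hubs: a PCG driven by two independent
    # latent factors could not reach rho > 0.9 with either hub, so shared
    # membership would contradict the planted-pair contract.  Enough DE PCGs
    # are therefore assigned the hub direction to supply all partner sets.
    required = cfg.n_hubs * cfg.partners_per_hub
    if cfg.n_hubs and required > n_de_pcg:
        raise ConfigError(
            f"{cfg.n_hubs} hubs x {cfg.partners_per_hub} disjoint partners need "
            f"{required} DE PCGs but de_fraction_pcg yields only {n_de_pcg}"
        )
    forced = set(
        rng_de.choice(de_pcg, size=required, replace=False)
    ) if cfg.n_hubs else set()

    # Keep planted up/down counts as balanced as the partner requirement
    # allows: a direction imbalance shifts median-of-ratios size factors by
    # a different amount per group, which would leak a spurious contrast
    # into every null gene.
    counter_set: set[str] = set()
    if cfg.n_hubs:
        remaining = [g for g in de_pcg if g not in forced]
        rng_de.shuffle(remaining)
        n_counter = min(len(remaining), int(round(n_de_pcg / 2)))
        counter_set = set(remaining[:n_counter])

    # Module genes (hub + partners) carry the strong effects from
    # module_log2fc_range; other DE genes use the moderate
    # planted_log2fc_range.  Extreme down-effects would zero out case counts
    # and silently drop those genes from the median-of-ratios reference set,
    # unbalancing normalisation -- hence the split.
    flo, fhi = cfg.planted_log2fc_range
    mlo, mhi = cfg.module_log2fc_range
    hub_set = set(hubs)
    for g in de_lnc + de_pcg:
        if g in hub_set or g in forced:
            sign, lo_, hi_ = hub_sign, abs(mlo), abs(mhi)
        elif g in counter_set:
            sign, lo_, hi_ = -hub_sign, abs(flo), abs(fhi)
        elif cfg.n_hubs:
            # Remaining DE genes -- decoy lncRNAs and background PCGs --
            # take the counter direction.  At n = 14 a same-direction DE
            # lncRNA shares the disease contrast with every module partner
            # (rank rho ~ 0.6 from group separation alone) and can ride a
            # module's latent factor past 0.9 by chance; opposite-direction
            # decoys are true negatives by construction.
            sign, lo_, hi_ = -hub_sign, abs(flo), abs(fhi)
        else:
            sign = 1.0 if rng_de.random() < 0.5 else -1.0
            lo_, hi_ = abs(flo), abs(fhi)
        truth.de_genes[g] = sign * rng_de.uniform(lo_, hi_)

    if cfg.n_hubs:
        shuffled = sorted(forced)
        rng_de.shuffle(shuffled)
        for k, hub in enumerate(hubs):
            chunk = shuffled[k * cfg.partners_per_hub : (k + 1) * cfg.partners_per_hub]
            truth.hub_modules[hub] = frozenset(chunk)

    # module genes are re-based into the well-measured count range so the
    # shared factor dominates counting noise
    module_members = set(truth.hub_modules) | {
        p for ps in truth.hub_modules.values() for p in ps
    }
    if module_members:
        idx = [gene_ids.index(g) for g in sorted(module_members)]
        baselines[idx] = np.exp(
            rng_de.uniform(math.log(500.0), math.log(2000.0), size=len(idx))
        )
        # other DE genes move off the lowest baselines so that down-regulated
        # case counts stay nonzero and remain in the normalisation reference
        other_de = sorted(g for g in truth.de_genes if g not in module_members)
        if other_de:
            idx2 = [gene_ids.index(g) for g in other_de]
            baselines[idx2] = np.exp(
                rng_de.uniform(math.log(200.0), math.log(2000.0), size=len(idx2))
            )

    truth.locus_placements = locus_of
    for g, lfc in truth.de_genes.items():
        truth.tissue_profile[g] = "brain_low" if lfc > 0 else "brain_high"

    # --- counts -------------------------------------------------------------
    samples = [f"case{i:02d}" for i in range(1, cfg.n_case + 1)] + [
        f"ctrl{i:02d}" for i in range(1, cfg.n_control + 1)
    ]
    groups = {s: ("case" if s.startswith("case") else "control") for s in samples}
    depth = np.exp(rng_counts.normal(0.0, cfg.library_size_sd, size=len(samples)))
    lfc_vec = np.array([truth.de_genes.get(g, 0.0) for g in gene_ids])
    case_mask = np.array([groups[s] == "case" for s in samples], dtype=float)
    mu = baselines[:, None] * depth[None, :] * np.power(2.0, lfc_vec[:, None] * case_mask[None, :])
    if isinstance(cfg.dispersion, Mapping):
        missing = [g for g in gene_ids if g not in cfg.dispersion]
        if missing:
            raise ConfigError(f"per-gene dispersion missing entries, e.g. {missing[:3]}")
        alpha_vec = np.array([float(cfg.dispersion[g]) for g in gene_ids])
    else:
        alpha_vec = np.full(n_genes, float(cfg.dispersion))
    if module_members:
        alpha_vec[[gene_ids.index(g) for g in sorted(module_members)]] = cfg.module_dispersion
    counts = _nb_draw(rng_counts, mu, alpha_vec).astype(np.int64)

    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=samples),
        groups,
        "synthetic",
    )
    return cm, genes, truth


def plant_coexpression_modules(
    counts: CountMatrix, truth: SyntheticTruth, config: SimConfig
) -> CountMatrix:
    """Impose the shared latent factor on every hub module.

    Hub and partners get a common per-sample log2 shift (sd
    ``module_factor_sd``, centred within each group) plus independent
    Gaussian noise of sd ``module_noise_sd``; counts are rescaled on the
    log scale and rounded back to integers.  Genes outside modules are
    untouched; with no hubs the matrix is returned unchanged.
    """
    if not truth.hub_modules:
        return counts
    unknown = [h for h in truth.hub_modules if h not in set(counts.genes)]
    if unknown:
        raise AnalysisError(f"hub id(s) not in count matrix: {unknown}")
    rng = _stage_rng(config.rng_seed, "modules")
    data = counts.data.copy()
    case = [s for s in counts.samples if counts.groups[s] == "case"]
    ctrl = [s for s in counts.samples if counts.groups[s] == "control"]
    prev_factor: pd.Series | None = None
    for i, hub in enumerate(sorted(truth.hub_modules)):
        # Gaussian draw, centred within each group (so the module never
        # aliases the disease contrast) and standardised to a fixed realised
        # spread: every module carries the same signal strength instead of
        # inheriting the chi-square tail of a raw variance realisation.
        # Consecutive modules get antithetic (negated) factors: summed over
        # modules the per-sample shifts cancel, so planted co-expression
        # does not leak into median-of-ratios size-factor estimation as a
        # spurious sample-wide factor.
        if i % 2 == 1 and prev_factor is not None:
            factor = -prev_factor
        else:
            factor = pd.Series(
                rng.normal(0.0, 1.0, size=len(counts.samples)), index=counts.samples
            )
            factor[case] -= factor[case].mean()
            factor[ctrl] -= factor[ctrl].mean()
            spread = float(np.std(factor.to_numpy()))
            factor = factor * (config.module_factor_sd / max(spread, 1e-12))
        prev_factor = factor
        members = [hub] + sorted(truth.hub_modules[hub])
        for gene in members:
            # the hub lncRNA *is* the module driver: it carries the factor
            # itself; partners follow it with gene-level noise
            shift = factor.to_numpy().copy()
            if gene != hub:
                shift += rng.normal(0.0, config.module_noise_sd, size=len(counts.samples))
            data.loc[gene] = np.rint(
                data.loc[gene].to_numpy(dtype=float) * np.power(2.0, shift)
            ).astype(np.int64)
    return CountMatrix(data, dict(counts.groups), dict(counts.cohorts))


def simulate_dataset(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Counts with planted DE *and* planted co-expression modules."""
    cm, genes, truth = generate_counts(config)
    return plant_coexpression_modules(cm, truth, config), genes, truth


# ---------------------------------------------------------------------------
# tissue panel
# ---------------------------------------------------------------------------

def generate_tissue_panel(
    genes: pd.DataFrame,
    truth: SyntheticTruth,
    n_tissues: int = 16,
    replicates: int = 2,
    seed: int = 0,
    brain_shift_log2: float = 2.5,
) -> pd.DataFrame:
    """TPM panel over ``n_tissues`` x ``replicates`` columns including brain.

    Disease-up genes (planted positive log2FC) are drawn brain-low and
    disease-down genes brain-high, by ``brain_shift_log2`` log2 units.
    Columns are a (tissue, replicate) MultiIndex; each column sums to 1e6.
    """
    from .downstream_stats import tpm_normalize

    if n_tissues < 2:
        raise AnalysisError("need at least 2 tissues (one of them brain)")
    if n_tissues > len(TISSUES):
        raise AnalysisError(f"at most {len(TISSUES)} tissue labels available")
    rng = _stage_rng(seed, "tissue")
    tissues = TISSUES[:n_tissues]
    gene_ids = list(genes["gene_id"])
    base = rng.normal(5.0, 1.5, size=len(gene_ids))  # log2 abundance
    tissue_effect = rng.normal(0.0, 0.5, size=(len(gene_ids), n_tissues))
    shift = np.zeros(len(gene_ids))
    profile = [truth.tissue_profile.get(g, "neutral") for g in gene_ids]
    shift[np.array(profile) == "brain_low"] = -brain_shift_log2
    shift[np.array(profile) == "brain_high"] = brain_shift_log2

    lengths = genes.set_index("gene_id")["length"]
    cols = pd.MultiIndex.from_product(
        [tissues, [str(r) for r in range(1, replicates + 1)]],
        names=("tissue", "replicate"),
    )
    counts = np.empty((len(gene_ids), len(cols)), dtype=np.int64)
    for j, (tissue, _rep) in enumerate(cols):
        t = tissues.index(tissue)
        log2_expr = base + tissue_effect[:, t] + (shift if tissue == "brain" else 0.0)
        lam = np.power(2.0, log2_expr) * lengths.to_numpy() / 1e3
        counts[:, j] = rng.poisson(lam)
    panel_counts = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=cols)
    # guard against an (astronomically unlikely) all-zero column
    zero = panel_counts.sum(axis=0) == 0
    if zero.any():
        first = panel_counts.index[0]
        panel_counts.loc[first, zero[zero].index] = 1
    return tpm_normalize(panel_counts, lengths)


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def generate_qpcr(
    n_case: int,
    n_control: int,
    ddct_truth: float,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample target/reference Ct table with a planted ddCt.

    Control dCt is centred at 6 cycles; case dCt at ``6 + ddct_truth``, so
    the expected downstream fold change is ``2**(-ddct_truth)``.  Gaussian
    noise of sd ``noise_sd`` applies to the per-sample dCt; with zero noise
    all dCt values are exactly equal within groups.
    """
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    rng = _stage_rng(seed, "qpcr")
    rows = []
    for group, n, offset in (("case", n_case, ddct_truth), ("control", n_control, 0.0)):
        for i in range(1, n + 1):
            ct_ref = 20.0 + rng.normal(0.0, 0.3)
            dct = 6.0 + offset + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append(
                dict(
                    sample=f"{group}{i:02d}",
                    group=group,
                    ct_target=ct_ref + dct,
                    ct_reference=ct_ref,
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene sets and transcript sequences
# ---------------------------------------------------------------------------

_SOURCES = ("GO_BP", "GO_CC", "GO_MF", "KEGG", "Reactome", "HPO")


def generate_gene_sets(
    genes: pd.DataFrame,
    truth: SyntheticTruth,
    n_sets: int = 30,
    seed: int = 0,
    planted_size: int = 30,
    planted_background: int = 10,
) -> list[GeneSet]:
    """GMT-style collection with one planted term per hub plus random terms.

    Each planted term contains ``planted_size`` of that hub's partners plus
    ``planted_background`` random genes, so enrichment of the partner set
    should flag it; the remaining terms are random draws.
    """
    rng = _stage_rng(seed, "gene_sets")
    symbols = list(genes["symbol"])
    sets: list[GeneSet] = []
    for k, hub in enumerate(sorted(truth.hub_modules)):
        partners = sorted(truth.hub_modules[hub])
        take = min(planted_size, len(partners))
        members = set(rng.choice(partners, size=take, replace=False))
        members |= set(rng.choice(symbols, size=planted_background, replace=False))
        sets.append(
            GeneSet(
                term_id=f"PLANTED:{hub}",
                name=f"planted partner set of {hub}",
                source=_SOURCES[k % len(_SOURCES)],
                members=frozenset(members),
            )
        )
    for k in range(max(n_sets - len(sets), 0)):
        size = int(rng.integers(20, 81))
        members = frozenset(rng.choice(symbols, size=min(size, len(symbols)), replace=False))
        sets.append(
            GeneSet(
                term_id=f"RAND:{k:04d}",
                name=f"random term {k}",
                source=_SOURCES[k % len(_SOURCES)],
                members=members,
            )
        )
    return sets


_CODING_POS_PROBS = (
    {"A": 0.28, "C": 0.20, "G": 0.34, "T": 0.18},
    {"A": 0.30, "C": 0.22, "G": 0.19, "T": 0.29},
    {"A": 0.14, "C": 0.33, "G": 0.33, "T": 0.20},
)
_STOPS = ("TAA", "TAG", "TGA")


def generate_transcripts(
    genes: pd.DataFrame, seed: int = 0, orf_fraction: float = 0.7
) -> dict[str, str]:
    """Transcript sequences: codon-structured ORFs for PCGs, random lncRNAs.

    Protein-coding transcripts get an ATG..stop ORF covering about
    ``orf_fraction`` of their length, built from codon-position-biased
    nucleotide frequencies (so the TESTCODE statistic is high).  lncRNA
    transcripts are uniform random sequence with chance ORFs disrupted down
    to min(0.25 x length, 400 nt): unconstrained random sequence of a few
    kb typically carries a 500-700 nt open reading frame (longest-run
    statistics), whereas real lncRNAs are ORF-poor -- without the cap a
    coding-potential screen would rightly flag such transcripts.
    """
    rng = _stage_rng(seed, "transcripts")
    bases = np.array(list("ACGT"))
    # sense codons with probability proportional to the per-position base
    # frequencies (stop codons excluded, renormalised)
    codon_list = []
    codon_p = []
    for b1 in "ACGT":
        for b2 in "ACGT":
            for b3 in "ACGT":
                codon = b1 + b2 + b3
                if codon in _STOPS:
                    continue
                codon_list.append(codon)
                codon_p.append(
                    _CODING_POS_PROBS[0][b1] * _CODING_POS_PROBS[1][b2] * _CODING_POS_PROBS[2][b3]
                )
    codon_arr = np.array(codon_list)
    codon_p = np.array(codon_p) / np.sum(codon_p)

    out: dict[str, str] = {}
    for row in genes.itertuples(index=False):
        length = int(row.length)
        if row.biotype == "protein_coding":
            n_codons = max(int(orf_fraction * length) // 3 - 2, 2)
            codons = codon_arr[rng.choice(len(codon_arr), size=n_codons, p=codon_p)]
            orf = "ATG" + "".join(codons) + _STOPS[int(rng.integers(0, 3))]
            utr_total = max(length - len(orf), 0)
            utr5 = int(rng.integers(0, utr_total + 1))
            head = "".join(rng.choice(bases, size=utr5))
            tail = "".join(rng.choice(bases, size=utr_total - utr5))
            out[row.gene_id] = head + orf + tail
        else:
            seq = "".join(rng.choice(bases, size=length))
            out[row.gene_id] = _disrupt_long_orfs(seq)
    return out


def _disrupt_long_orfs(seq: str, max_fraction: float = 0.25, max_nt: int = 400) -> str:
    """Break chance ORFs until the longest is below the lncRNA-like cap."""
    from .coding_potential import longest_orf

    cap = min(int(max_fraction * len(seq)) // 3 * 3, max_nt)
    cap = max(cap, 30)  # never chase ORFs below a codon handful
    for _ in range(200):  # generous bound; each pass at least halves one ORF
        start, end, length = longest_orf(seq)
        if length <= cap:
            return seq
        # place a stop mid-ORF, on the ORF's own frame
        mid_codon = start + (((end - start) // 3) // 2) * 3
        seq = seq[:mid_codon] + "TAA" + seq[mid_codon + 3 :]
    return seq


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# truth ledger export
# ---------------------------------------------------------------------------

def write_truth(truth: SyntheticTruth, outdir: str | Path) -> None:
    """Write the truth ledger as plain TSV files under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        sorted(truth.de_genes.items()), columns=["gene_id", "log2fc"]
    ).to_csv(outdir / "truth_de.tsv", sep="\t", index=False, float_format="%.10g")
    pd.DataFrame(
        [(h, ",".join(sorted(ps))) for h, ps in sorted(truth.hub_modules.items())],
        columns=["hub", "partners"],
    ).to_csv(outdir / "truth_hubs.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.locus_placements.items()), columns=["gene_id", "locus"]
    ).to_csv(outdir / "truth_loci.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.tissue_profile.items()), columns=["gene_id", "profile"]
    ).to_csv(outdir / "truth_tissue.tsv", sep="\t", index=False)
    (outdir / "truth_ddct.tsv").write_text(f"ddct_truth\t{truth.ddct_truth:.10g}\n")
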