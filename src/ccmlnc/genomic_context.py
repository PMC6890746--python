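"""Mapping transcripts onto susceptibility loci expressed as cytoband ranges.

The three loci classically linked to cerebral cavernous malformations are
given as band ranges (CCM1: 7q11-q22, CCM2: 7p15-13, CCM3: 3q25.2-q27).
Resolving such a range to genomic coordinates requires a band-to-coordinate
table (UCSC cytoBand format).  The table that ships with the package covers
chr3 and chr7 only and is *synthetic*: a constructed, internally consistent
band layout, not real genome-build coordinates.  Supply a real cytoBand file
for work on actual annotation.

All interval arithmetic here is 0-based half-open; a gene hits a locus iff
the overlap is at least ``min_overlap_bp`` (default 1 bp).  Strand is
ignored.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError, FormatError
from .io import LNC_BIOTYPES

logger = logging.getLogger(__name__)

#: the paper-era locus definitions, usable directly with :func:`resolve_locus`
CCM_LOCI = {"CCM1": "7q11-q22", "CCM2": "7p15-13", "CCM3": "3q25.2-q27"}


@dataclass(frozen=True)
class LocusInterval:
    """A named genomic interval (0-based half-open)."""

    name: str
    chrom: str
    start: int
    end: int
    band_range: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"locus {self.name!r}: start ({self.start}) must be < end ({self.end})"
            )


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def load_cytobands(path: str | Path | None = None) -> pd.DataFrame:
    """Load a cytoband table (chrom, start, end, band, stain).

    With no ``path`` the packaged synthetic chr3/chr7 table is used.  Bands
    within a chromosome must be non-overlapping and ordered.
    """
    if path is None:
        ref = resources.files("ccmlnc").joinpath("data/cytobands_synthetic.tsv")
        with resources.as_file(ref) as p:
            bands = pd.read_csv(p, sep="\t", names=["chrom", "start", "end", "band", "stain"])
    else:
        bands = pd.read_csv(path, sep="\t", names=["chrom", "start", "end", "band", "stain"])
    bands["chrom"] = bands["chrom"].map(_norm_chrom)
    for chrom, sub in bands.groupby("chrom"):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if not (np.diff(starts) > 0).all() or not (ends[:-1] <= starts[1:]).all():
            raise FormatError(f"cytoband table: bands on chr{chrom} overlap or are unordered")
        if not (starts < ends).all():
            raise FormatError(f"cytoband table: empty band on chr{chrom}")
    return bands


_BAND_RANGE_RE = re.compile(
    r"^(?:chr)?(\d{1,2}|X|Y)([pq])(\d+(?:\.\d+)?)(?:-([pq])?(\d+(?:\.\d+)?))?$"
)


def _matching_bands(bands: pd.DataFrame, chrom: str, token: str) -> pd.DataFrame:
    sub = bands[bands["chrom"] == chrom]
    hit = sub[(sub["band"] == token) | sub["band"].str.startswith(token + ".")]
    if hit.empty:
        raise AnalysisError(f"band {chrom}{token} not present in the cytoband table")
    return hit


def resolve_locus(
    band_range: str, bands: pd.DataFrame, name: str | None = None
) -> LocusInterval:
    """Resolve a band range like ``7q11-q22`` to a genomic interval.

    The interval spans from the minimum start to the maximum end over both
    endpoint band groups (so every band lying between the endpoints is
    covered).  Sub-bands match by prefix: ``q25.2`` matches ``q25.2`` and any
    ``q25.2x`` subdivision, ``q11`` matches every ``q11.*``.  In a range like
    ``7p15-13`` the second token inherits the arm of the first.
    """
    m = _BAND_RANGE_RE.match(band_range.strip())
    if not m:
        raise FormatError(f"cannot parse band range {band_range!r}")
    chrom, arm1, b1, arm2, b2 = m.groups()
    first = _matching_bands(bands, chrom, arm1 + b1)
    if b2 is None:
        last = first
    else:
        last = _matching_bands(bands, chrom, (arm2 or arm1) + b2)
    start = int(min(first["start"].min(), last["start"].min()))
    end = int(max(first["end"].max(), last["end"].max()))
    return LocusInterval(
        name=name or band_range, chrom=chrom, start=start, end=end, band_range=band_range
    )


def resolve_ccm_loci(bands: pd.DataFrame | None = None) -> list[LocusInterval]:
    """Resolve the three canonical susceptibility loci against a band table."""
    if bands is None:
        bands = load_cytobands()
    return [resolve_locus(rng, bands, name=nm) for nm, rng in CCM_LOCI.items()]


def assign_to_loci(
    genes: pd.DataFrame,
    loci: Sequence[LocusInterval],
    min_overlap_bp: int = 1,
) -> dict[str, list[str]]:
    """Assign each gene to every locus it overlaps by >= ``min_overlap_bp``.

    Chromosome names are normalised (``chr7`` == ``7``); a mismatch in style
    is logged, not an error.  Returns gene_id -> list of locus names (empty
    list for unplaced genes).
    """
    if min_overlap_bp < 1:
        raise AnalysisError("min_overlap_bp must be >= 1")
    gchrom = genes["chrom"].map(_norm_chrom).to_numpy()
    if (genes["chrom"].to_numpy() != gchrom).any():
        logger.info("assign_to_loci: normalised 'chr' prefixes on gene chromosomes")
    gstart = genes["start"].to_numpy()
    gend = genes["end"].to_numpy()
    out: dict[str, list[str]] = {g: [] for g in genes["gene_id"]}
    gene_ids = genes["gene_id"].to_numpy()
    for locus in loci:
        lchrom = _norm_chrom(locus.chrom)
        overlap = np.minimum(gend, locus.end) - np.maximum(gstart, locus.start)
        hit = (gchrom == lchrom) & (overlap >= min_overlap_bp)
        for g in gene_ids[hit]:
            out[g].append(locus.name)
    return out


def locus_summary(
    assignments: Mapping[str, Sequence[str]],
    de_table: pd.DataFrame,
    genes: pd.DataFrame,
) -> pd.DataFrame:
    """Per-locus counts of differentially expressed lncRNAs and PCGs.

    Genes on several loci are counted once per locus.  Rows are loci in
    first-seen order; columns split lncRNA/PCG by up/down status.
    """
    biotype = dict(zip(genes["gene_id"], genes["biotype"]))
    locus_names: list[str] = []
    for names in assignments.values():
        for n in names:
            if n not in locus_names:
                locus_names.append(n)
    rows = []
    for locus in locus_names:
        members = [g for g, names in assignments.items() if locus in names]
        rec = dict(
            locus=locus,
            de_lncRNA_up=0,
            de_lncRNA_down=0,
            de_PCG_up=0,
            de_PCG_down=0,
        )
        for g in members:
            if g not in de_table.index:
                continue
            status = de_table.loc[g, "status"]
            if status not in ("up", "down"):
                continue
            cls = "lncRNA" if biotype.get(g) in LNC_BIOTYPES else "PCG"
            rec[f"de_{cls}_{status}"] += 1
        rec["de_lncRNA"] = rec["de_lncRNA_up"] + rec["de_lncRNA_down"]
        rec["de_PCG"] = rec["de_PCG_up"] + rec["de_PCG_down"]
        rows.append(rec)
    cols = ["locus", "de_lncRNA", "de_lncRNA_up", "de_lncRNA_down", "de_PCG", "de_PCG_up", "de_PCG_down"]
    return pd.DataFrame(rows, columns=cols)
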