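"""Readers and writers for every on-disk format the pipeline touches.

All tabular interchange is plain TSV.  Internal genomic coordinates are
0-based half-open everywhere; GTF (1-based inclusive) and BED (0-based
half-open) are converted at this boundary and nowhere else.  Readers reject
malformed input with a :class:`~ccmlnc.errors.FormatError` naming the
offending record instead of silently repairing it, and every writer/reader
pair is the identity on valid data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

GROUP_LABELS = ("case", "control")

#: closed biotype vocabulary; anything else read from a GTF maps to other_lnc
BIOTYPES = ("protein_coding", "lincRNA", "antisense", "sense_overlapping", "other_lnc")
LNC_BIOTYPES = ("lincRNA", "antisense", "sense_overlapping", "other_lnc")

#: columns of a gene-annotation table (one row per GeneRecord)
GENE_COLUMNS = ("gene_id", "symbol", "biotype", "chrom", "start", "end", "strand", "length")

_GTF_BIOTYPE_ALIASES = {
    "protein_coding": "protein_coding",
    "lincRNA": "lincRNA",
    "lncRNA": "other_lnc",
    "antisense": "antisense",
    "antisense_RNA": "antisense",
    "sense_overlapping": "sense_overlapping",
}


@dataclass
class CountMatrix:
    """Genes x samples integer count matrix with sample metadata.

    Parameters
    ----------
    data
        Non-negative integer counts, index = gene ids, columns = sample ids.
    groups
        Mapping sample id -> ``"case"`` or ``"control"``; must cover every
        sample column.
    cohorts
        Mapping sample id -> cohort label.  A plain string is broadcast to
        all samples.
    """

    data: pd.DataFrame
    groups: Mapping[str, str]
    cohorts: Mapping[str, str] | str = "cohort1"

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r} in count matrix")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r} in count matrix")
        if isinstance(self.cohorts, str):
            self.cohorts = {s: self.cohorts for s in self.data.columns}
        missing = [s for s in self.data.columns if s not in self.groups]
        if missing:
            raise FormatError(f"samples without a group label: {missing}")
        bad = [s for s in self.data.columns if self.groups[s] not in GROUP_LABELS]
        if bad:
            raise FormatError(
                f"group labels must be one of {GROUP_LABELS}; offending samples: {bad}"
            )
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            raise FormatError("counts must be integers")
        if (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count at gene {self.data.index[g]!r}, sample {self.data.columns[s]!r}"
            )

    # -- convenience views -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.data.columns if self.groups[s] == group]

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.data.loc[list(gene_ids)], dict(self.groups), dict(self.cohorts))


@dataclass(frozen=True)
class GeneSet:
    """A named gene set from a GMT collection."""

    term_id: str
    name: str
    source: str  # GO_BP, GO_CC, GO_MF, KEGG, Reactome, HPO or custom
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"gene set {self.term_id!r} has no members")


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def read_counts(
    path: str | Path,
    groups: Mapping[str, str],
    cohort: Mapping[str, str] | str = "cohort1",
) -> CountMatrix:
    """Read a genes-in-rows TSV count matrix.

    Raises :class:`FormatError` for duplicate ids and for any entry that is
    negative or not an integer, naming the offending cell.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    parsed = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            gene = df.index[numeric.isna()][0]
            raise FormatError(
                f"non-numeric count {df.loc[gene, col]!r} at gene {gene!r}, sample {col!r}"
            )
        parsed[col] = numeric
    values = parsed.to_numpy()
    frac = np.modf(values)[0]
    if (frac != 0).any():
        g, s = np.argwhere(frac != 0)[0]
        raise FormatError(
            f"non-integer count {values[g, s]} at gene {parsed.index[g]!r}, "
            f"sample {parsed.columns[s]!r} (counts must be integers)"
        )
    if (values < 0).any():
        g, s = np.argwhere(values < 0)[0]
        raise FormatError(
            f"negative count {values[g, s]} at gene {parsed.index[g]!r}, "
            f"sample {parsed.columns[s]!r}"
        )
    return CountMatrix(parsed.astype(np.int64), dict(groups), cohort)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.data.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """Read a sample sheet TSV with columns sample, group[, cohort]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns or "group" not in df.columns:
        raise FormatError("sample sheet needs 'sample' and 'group' columns")
    groups = dict(zip(df["sample"], df["group"]))
    if "cohort" in df.columns:
        cohorts = dict(zip(df["sample"], df["cohort"]))
    else:
        cohorts = {s: "cohort1" for s in df["sample"]}
    return groups, cohorts


def write_sample_sheet(cm: CountMatrix, path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample": cm.samples,
            "group": [cm.groups[s] for s in cm.samples],
            "cohort": [cm.cohorts[s] for s in cm.samples],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene annotation (GTF)
# ---------------------------------------------------------------------------

def read_gtf_genes(path: str | Path) -> pd.DataFrame:
    """Read gene features from a GTF into a gene table.

    Returns a DataFrame with :data:`GENE_COLUMNS`.  GTF 1-based inclusive
    coordinates become internal 0-based half-open.  Unrecognised lncRNA-like
    biotypes map to ``other_lnc``.  Non-gene features are skipped; their
    count is logged as a warning.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted types for bad input
        raise FormatError(f"failed to parse GTF {path}: {exc}") from exc

    skipped = sum(
        db.count_features_of_type(ft) for ft in db.featuretypes() if ft != "gene"
    )
    if skipped:
        logger.warning("read_gtf_genes: skipped %d non-gene feature(s)", skipped)

    rows = []
    for feat in db.features_of_type("gene"):
        if "gene_id" not in feat.attributes:
            raise FormatError(f"GTF gene feature without gene_id at {feat.seqid}:{feat.start}")
        gene_id = feat.attributes["gene_id"][0]
        symbol = feat.attributes.get("gene_name", [gene_id])[0]
        raw_biotype = feat.attributes.get("gene_biotype", ["other_lnc"])[0]
        biotype = _GTF_BIOTYPE_ALIASES.get(raw_biotype, "other_lnc")
        start0 = feat.start - 1  # 1-based inclusive -> 0-based half-open
        end0 = feat.end
        rows.append(
            dict(
                gene_id=gene_id,
                symbol=symbol,
                biotype=biotype,
                chrom=str(feat.seqid),
                start=start0,
                end=end0,
                strand=feat.strand if feat.strand in "+-" else "+",
                length=end0 - start0,
            )
        )
    table = pd.DataFrame(rows, columns=list(GENE_COLUMNS))
    if len(table) and table["gene_id"].duplicated().any():
        dup = table.loc[table["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"duplicate gene_id {dup!r} in GTF")
    return table


def write_gtf_genes(genes: pd.DataFrame, path: str | Path, source: str = "ccmlnc") -> None:
    """Write a gene table as GTF gene features (1-based inclusive coords)."""
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            attrs = (
                f'gene_id "{row.gene_id}"; gene_name "{row.symbol}"; '
                f'gene_biotype "{row.biotype}";'
            )
            fh.write(
                f"{row.chrom}\t{source}\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# BED loci, GMT gene sets
# ---------------------------------------------------------------------------

def read_bed_loci(path: str | Path):
    """Read locus intervals from a BED file (chrom, start, end, name)."""
    from .genomic_context import LocusInterval  # local import; no cycle at module load

    loci = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"BED line {ln}: fewer than 3 fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise FormatError(f"BED line {ln}: end ({end}) <= start ({start})")
            name = parts[3] if len(parts) > 3 else f"locus{ln}"
            loci.append(LocusInterval(name=name, chrom=chrom, start=start, end=end))
    return loci


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT collection: term <tab> description <tab> member genes.

    The description field carries ``source|name`` when written by
    :func:`write_gmt`; a bare description yields source ``custom``.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line {ln}: fewer than 3 fields")
            term, desc = parts[0], parts[1]
            members = frozenset(m for m in parts[2:] if m)
            if not members:
                raise FormatError(f"GMT line {ln}: term {term!r} has no members")
            if "|" in desc:
                source, name = desc.split("|", 1)
            else:
                source, name = "custom", desc
            sets.append(GeneSet(term_id=term, name=name, source=source, members=members))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.term_id}\t{gs.source}|{gs.name}\t{members}\n")


# ---------------------------------------------------------------------------
# co-expression network exports
# ---------------------------------------------------------------------------

def write_network_sif(network: nx.Graph, path: str | Path) -> None:
    """Write one ``lncRNA\tcoexpressed_with\tPCG`` line per edge."""
    with open(path, "w") as fh:
        for u, v in sorted(network.edges()):
            lnc, pcg = (u, v) if network.nodes[u].get("kind") == "lncRNA" else (v, u)
            fh.write(f"{lnc}\tcoexpressed_with\t{pcg}\n")


def write_network_graphml(network: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(network, str(path))


def read_network_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


# ---------------------------------------------------------------------------
# DE tables
# ---------------------------------------------------------------------------

DE_COLUMNS = ("base_mean", "log2fc", "se_log2fc", "p", "padj", "status")


def write_de_table(det: pd.DataFrame, path: str | Path) -> None:
    det.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_de_table(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a DE table; ``columns`` maps standard names to file columns.

    This is the importer that lets externally produced DE results (any DE
    engine) be substituted for the built-in NB Wald test.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if columns:
        rename = {src: std for std, src in columns.items()}
        df = df.rename(columns=rename)
    missing = [c for c in ("log2fc", "p") if c not in df.columns]
    if missing:
        raise FormatError(f"DE table {path} missing required columns: {missing}")
    for col in DE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan if col != "status" else "ns"
    return df[list(DE_COLUMNS)]


# ---------------------------------------------------------------------------
# tissue panels
# ---------------------------------------------------------------------------

def write_tissue_panel(panel: pd.DataFrame, path: str | Path) -> None:
    """Write a TPM panel; MultiIndex (tissue, replicate) columns flatten to tissue.rep."""
    flat = panel.copy()
    flat.columns = [f"{t}.{r}" for t, r in panel.columns]
    flat.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_tissue_panel(path: str | Path) -> pd.DataFrame:
    flat = pd.read_csv(path, sep="\t", index_col=0)
    tuples = []
    for col in flat.columns:
        if "." not in col:
            raise FormatError(f"tissue panel column {col!r} is not tissue.replicate")
        tissue, rep = col.rsplit(".", 1)
        tuples.append((tissue, rep))
    flat.columns = pd.MultiIndex.from_tuples(tuples, names=("tissue", "replicate"))
    return flat
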