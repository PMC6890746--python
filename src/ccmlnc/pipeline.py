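"""End-to-end orchestration: one config in, a reproducible output bundle out.

Stages run in a fixed order -- load/simulate, differential expression,
threshold filtering, coding screen (lncRNAs only), co-expression, hub
selection, partner intersection, locus summary, tissue specificity,
enrichment per hub partner set, optional qPCR -- and every stage writes its
table before the next starts.  A failure aborts with the stage name and
leaves partial outputs plus a ``FAILED`` marker.  The run manifest (written
last) echoes the config, the package version, the seed and per-stage record
counts.

All randomness flows from the single config seed through the generator's
per-stage substreams, and all writers use fixed float formatting, so one
config produces a byte-identical bundle on every run (the manifest's wall
time is the one necessarily volatile field).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import coding_potential as cp
from . import coexpression as cx
from . import differential_expression as de
from . import downstream_stats as ds
from . import genomic_context as gc
from . import io as cio
from . import synthetic_data as sim
from .errors import CcmlncError, ConfigError

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    """Every stage cut-off, defaulting to the study's reported values."""

    padj_cut: float = 0.01
    lfc_cut: float = 1.5
    rho_cut: float = 0.9
    p_cut: float = 0.05
    min_partners: int = 100
    coding_threshold: float = 0.37
    min_overlap_bp: int = 1
    enrichment_p_cut: float = 0.05
    top_hubs: int = 2  # hubs taken forward to intersection + enrichment

    def problems(self) -> list[str]:
        out = []
        for name, lo, hi in (
            ("padj_cut", 0, 1), ("lfc_cut", 0, np.inf), ("rho_cut", 0, 1),
            ("p_cut", 0, 1), ("coding_threshold", 0, 1), ("enrichment_p_cut", 0, 1),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                out.append(f"{name}={v} outside [{lo}, {hi}]")
        if self.min_partners < 0:
            out.append("min_partners must be >= 0")
        if self.min_overlap_bp < 1:
            out.append("min_overlap_bp must be >= 1")
        if self.top_hubs < 2:
            out.append("top_hubs must be >= 2")
        return out


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (simulate-mode or file-input mode)."""

    outdir: Path
    seed: int = 0
    simulate: sim.SimConfig | None = None
    inputs: dict[str, Any] | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    loci: Mapping[str, str] = field(default_factory=lambda: dict(gc.CCM_LOCI))

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigError("exactly one of 'simulate' and 'inputs' must be present")


def load_config(path: str | Path) -> PipelineConfig:
    """Parse + validate a YAML config; raises ConfigError listing all problems."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg, errors = config_from_dict(raw)
    if errors:
        raise ConfigError("; ".join(errors))
    return cfg


def config_from_dict(raw: Mapping[str, Any]) -> tuple[PipelineConfig | None, list[str]]:
    """Build a config, collecting every validation error (not first-failure)."""
    errors: list[str] = []
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append("seed must be an integer")
        seed = 0
    outdir = raw.get("outdir")
    if not outdir:
        errors.append("outdir is required")

    thresholds = Thresholds()
    for key, value in (raw.get("thresholds") or {}).items():
        if not hasattr(thresholds, key):
            errors.append(f"unknown threshold {key!r}")
        else:
            setattr(thresholds, key, value)
    errors.extend(thresholds.problems())

    sim_block = raw.get("simulate")
    inputs = raw.get("inputs")
    if (sim_block is None) == (inputs is None):
        errors.append("exactly one of 'simulate' and 'inputs' must be present")
    sim_cfg = None
    if sim_block is not None:
        known = {f.name for f in dataclasses.fields(sim.SimConfig)}
        unknown = set(sim_block) - known
        if unknown:
            errors.append(f"unknown simulate key(s): {sorted(unknown)}")
        try:
            params = {k: v for k, v in sim_block.items() if k in known}
            for tup in ("baseline_mean_log_range", "planted_log2fc_range"):
                if tup in params:
                    params[tup] = tuple(params[tup])
            params.setdefault("rng_seed", seed)
            sim_cfg = sim.SimConfig(**params)
        except (ConfigError, TypeError) as exc:
            errors.append(str(exc))
    if inputs is not None:
        for required in ("counts", "samples"):
            if required not in inputs:
                errors.append(f"inputs mode requires {required!r} path")
        for key, value in inputs.items():
            if key in ("counts", "samples", "gtf", "fasta", "gmt", "ct",
                       "tissue_panel", "cytobands", "loci_bed"):
                if not Path(value).exists():
                    errors.append(f"inputs.{key}: file not found: {value}")
            elif key != "loci":
                errors.append(f"unknown inputs key {key!r}")

    loci = raw.get("loci") or ((inputs or {}).get("loci")) or dict(gc.CCM_LOCI)
    if errors:
        return None, errors
    return (
        PipelineConfig(
            outdir=Path(outdir),
            seed=seed,
            simulate=sim_cfg,
            inputs=dict(inputs) if inputs is not None else None,
            thresholds=thresholds,
            loci=loci,
        ),
        [],
    )


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to manifest.json)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    t0 = time.perf_counter()
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "seed": config.seed,
        "config": _config_echo(config),
        "stages": {},
    }
    stage = "setup"
    try:
        # ---- stage: load or simulate ------------------------------------
        stage = "input"
        bundle = _load_inputs(config, out)
        cm, genes, truth = bundle["counts"], bundle["genes"], bundle.get("truth")
        manifest["stages"]["input"] = {
            "genes": len(cm.genes),
            "samples": len(cm.samples),
            "case": len(cm.samples_in_group("case")),
            "control": len(cm.samples_in_group("control")),
        }

        # ---- stage: differential expression -----------------------------
        stage = "differential_expression"
        factors = de.size_factors(cm)
        det = de.nb_wald_test(cm, factors)
        det = de.filter_de(det, config.thresholds.padj_cut, config.thresholds.lfc_cut)
        _write(det, out / "de_table.tsv", index_label="gene_id")
        biotype = dict(zip(genes["gene_id"], genes["biotype"])) if genes is not None else {}
        is_lnc = det.index.map(lambda g: biotype.get(g) in cio.LNC_BIOTYPES)
        de_status = det["status"].isin(["up", "down"])
        de_lnc = list(det.index[de_status & is_lnc])
        de_pcg = list(det.index[de_status & ~is_lnc])
        manifest["stages"]["differential_expression"] = {
            "tested": int((det["status"] != "untested").sum()),
            "de_lncRNA": len(de_lnc),
            "de_PCG": len(de_pcg),
            "up": int((det["status"] == "up").sum()),
            "down": int((det["status"] == "down").sum()),
        }

        # ---- stage: coding screen (lncRNAs only) ------------------------
        stage = "coding_screen"
        if bundle.get("fasta"):
            coding = cp.screen_fasta(
                bundle["fasta"], de_lnc, config.thresholds.coding_threshold
            )
            _write(coding, out / "coding.tsv")
            noncoding = set(coding.index[coding["label"] == "noncoding"])
            de_lnc_screened = [g for g in de_lnc if g in noncoding]
            manifest["stages"]["coding_screen"] = {
                "screened": len(coding),
                "noncoding": len(noncoding),
            }
        else:
            de_lnc_screened = de_lnc
            manifest["stages"]["coding_screen"] = {"screened": 0, "noncoding": None}

        # ---- stage: co-expression ---------------------------------------
        stage = "coexpression"
        norm = cm.data.to_numpy(float) / factors.to_numpy()
        log_norm = pd.DataFrame(
            np.log2(norm + 1.0), index=cm.data.index, columns=cm.data.columns
        )
        pairs = cx.correlate_pairs(
            log_norm.loc[de_lnc_screened],
            log_norm.loc[de_pcg],
            rho_cut=config.thresholds.rho_cut,
            p_cut=config.thresholds.p_cut,
        )
        _write(pairs, out / "pairs.tsv", index=False)
        manifest["stages"]["coexpression"] = {"pairs_retained": len(pairs)}

        # ---- stage: hubs + network --------------------------------------
        stage = "hubs"
        hubs = cx.select_hubs(pairs, config.thresholds.min_partners)
        _write(cx.hub_table(hubs), out / "hubs.tsv", index=False)
        network = cx.build_network(pairs)
        cio.write_network_sif(network, out / "network.sif")
        cio.write_network_graphml(network, out / "network.graphml")
        manifest["stages"]["hubs"] = {
            "hubs": len(hubs),
            "hub_ids": [h.lnc_id for h in hubs],
        }

        # ---- stage: partner intersection --------------------------------
        stage = "partner_intersection"
        top = hubs[: config.thresholds.top_hubs]
        if len(top) >= 2:
            shared = cx.common_partners(top[0], top[1])
            pd.DataFrame({"pcg_id": sorted(shared)}).to_csv(
                out / "common_partners.tsv", sep="\t", index=False
            )
            manifest["stages"]["partner_intersection"] = {
                "hub_a": top[0].lnc_id,
                "hub_b": top[1].lnc_id,
                "common": len(shared),
            }
        else:
            manifest["stages"]["partner_intersection"] = {"common": None}

        # ---- stage: locus summary ---------------------------------------
        stage = "locus_summary"
        if genes is not None:
            bands = gc.load_cytobands(bundle.get("cytobands"))
            if bundle.get("loci_bed"):
                loci = cio.read_bed_loci(bundle["loci_bed"])
            else:
                loci = [gc.resolve_locus(rng, bands, name=nm) for nm, rng in config.loci.items()]
            assignments = gc.assign_to_loci(genes, loci, config.thresholds.min_overlap_bp)
            summary = gc.locus_summary(assignments, det, genes)
            _write(summary, out / "locus_summary.tsv", index=False)
            manifest["stages"]["locus_summary"] = {
                row["locus"]: {"de_lncRNA": int(row["de_lncRNA"]), "de_PCG": int(row["de_PCG"])}
                for _, row in summary.iterrows()
            }

        # ---- stage: tissue specificity ----------------------------------
        stage = "tissue_specificity"
        panel = bundle.get("tissue_panel")
        if panel is not None:
            z = ds.zscore_by_gene(panel)
            cio.write_tissue_panel(z, out / "tissue_z.tsv")
            up_set = [g for g in de_lnc_screened if det.loc[g, "status"] == "up"]
            down_set = [g for g in de_lnc_screened if det.loc[g, "status"] == "down"]
            up_z, down_z = ds.brain_contrast(z, up_set, down_set)
            pd.DataFrame(
                [
                    {"set": "de_up_lncRNA", "mean_brain_z": up_z, "n": len(up_set)},
                    {"set": "de_down_lncRNA", "mean_brain_z": down_z, "n": len(down_set)},
                ]
            ).to_csv(out / "brain_contrast.tsv", sep="\t", index=False, float_format="%.10g")
            manifest["stages"]["tissue_specificity"] = {
                "mean_brain_z_up": None if np.isnan(up_z) else round(up_z, 6),
                "mean_brain_z_down": None if np.isnan(down_z) else round(down_z, 6),
            }

        # ---- stage: enrichment (per hub partner set) --------------------
        stage = "enrichment"
        gene_sets = bundle.get("gene_sets")
        if gene_sets:
            universe = set(cm.genes)
            frames = []
            queries = [(h.lnc_id, h.partners) for h in top]
            if len(top) >= 2:
                queries.append(("common", cx.common_partners(top[0], top[1])))
            for label, query in queries:
                res = ds.hypergeometric_enrichment(
                    query, gene_sets, universe, config.thresholds.enrichment_p_cut
                )
                res.insert(0, "query", label)
                frames.append(res)
            enrichment = (
                pd.concat(frames, ignore_index=True)
                if frames
                else pd.DataFrame(columns=["query", "term", "p", "significant"])
            )
            _write(enrichment, out / "enrichment.tsv", index=False)
            manifest["stages"]["enrichment"] = {
                "queries": len(frames),
                "significant_terms": int(enrichment["significant"].sum())
                if len(enrichment)
                else 0,
            }

        # ---- stage: qPCR -------------------------------------------------
        stage = "qpcr"
        ct = bundle.get("ct")
        if ct is not None:
            result = ds.ddct_fold_change(ct)
            pd.DataFrame(
                [
                    {
                        "fold_change": result.fold_change,
                        "ddct": result.ddct,
                        "p": result.p,
                        "n_case": result.n_case,
                        "n_control": result.n_control,
                    }
                ]
            ).to_csv(out / "qpcr_result.tsv", sep="\t", index=False, float_format="%.10g")
            manifest["stages"]["qpcr"] = {
                "fold_change": round(result.fold_change, 6),
                "p": None if np.isnan(result.p) else round(result.p, 6),
            }

    except Exception as exc:
        failed_marker.write_text(f"stage: {stage}\nerror: {exc}\n")
        raise CcmlncError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["wall_time_s"] = round(time.perf_counter() - t0, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _config_echo(config: PipelineConfig) -> dict:
    echo: dict[str, Any] = {
        "outdir": str(config.outdir),
        "seed": config.seed,
        "thresholds": dataclasses.asdict(config.thresholds),
        "loci": dict(config.loci),
    }
    if config.simulate is not None:
        echo["simulate"] = dataclasses.asdict(config.simulate)
    if config.inputs is not None:
        echo["inputs"] = {k: str(v) for k, v in config.inputs.items()}
    return echo


def _load_inputs(config: PipelineConfig, out: Path) -> dict[str, Any]:
    """Simulate (writing all synthetic inputs) or read the configured files."""
    if config.simulate is not None:
        cfg = dataclasses.replace(config.simulate, rng_seed=config.seed)
        cm, genes, truth = sim.simulate_dataset(cfg)
        indir = out / "inputs"
        indir.mkdir(parents=True, exist_ok=True)
        cio.write_counts(cm, indir / "counts.tsv")
        cio.write_sample_sheet(cm, indir / "samples.tsv")
        cio.write_gtf_genes(genes, indir / "genes.gtf")
        transcripts = sim.generate_transcripts(genes, seed=cfg.rng_seed)
        sim.write_fasta(transcripts, indir / "transcripts.fasta")
        gene_sets = sim.generate_gene_sets(genes, truth, cfg.n_gene_sets, seed=cfg.rng_seed)
        cio.write_gmt(gene_sets, indir / "gene_sets.gmt")
        panel = sim.generate_tissue_panel(genes, truth, seed=cfg.rng_seed)
        cio.write_tissue_panel(panel, indir / "tissue_tpm.tsv")
        ct = sim.generate_qpcr(
            cfg.n_case, cfg.n_control, cfg.qpcr_ddct, cfg.qpcr_noise_sd, seed=cfg.rng_seed
        )
        ct.to_csv(indir / "qpcr_ct.tsv", sep="\t", index=False, float_format="%.10g")
        sim.write_truth(truth, indir)
        return {
            "counts": cm,
            "genes": genes,
            "truth": truth,
            "fasta": indir / "transcripts.fasta",
            "gene_sets": gene_sets,
            "tissue_panel": panel,
            "ct": ct,
        }

    inputs = config.inputs or {}
    groups, cohorts = cio.read_sample_sheet(inputs["samples"])
    cm = cio.read_counts(inputs["counts"], groups, cohorts)
    bundle: dict[str, Any] = {"counts": cm, "genes": None, "truth": None}
    if "gtf" in inputs:
        bundle["genes"] = cio.read_gtf_genes(inputs["gtf"])
    if "fasta" in inputs:
        bundle["fasta"] = inputs["fasta"]
    if "gmt" in inputs:
        bundle["gene_sets"] = cio.read_gmt(inputs["gmt"])
    if "tissue_panel" in inputs:
        bundle["tissue_panel"] = cio.read_tissue_panel(inputs["tissue_panel"])
    if "ct" in inputs:
        bundle["ct"] = pd.read_csv(inputs["ct"], sep="\t")
    if "cytobands" in inputs:
        bundle["cytobands"] = inputs["cytobands"]
    if "loci_bed" in inputs:
        bundle["loci_bed"] = inputs["loci_bed"]
    return bundle
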