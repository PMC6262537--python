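"""End-to-end orchestration of the discovery and validation flows.

``run_discovery`` executes the full funnel — block aggregation,
differential-CNA testing against recurrence and synchronous status,
chromosome hotspot enrichment, signature derivation, risk stratification —
from either on-disk inputs or a simulated cohort, writing machine-readable
artifacts (TSV tables, JSON signature/risk/funnel reports) to an output
directory.  ``run_validation`` applies a saved signature to an external
cohort.  Runs are reproducible from config + seed alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as cio
from .association import test_blocks
from .blocks import aggregate, blocks_to_bed, build_blocks
from .enrichment import enrich_by_chromosome
from .signature import Signature, derive_signature, map_blocks_to_genes
from .simulate import SimConfig, generate_cohort
from .survival import apply_signature_external, stratify

log = logging.getLogger("cnasig")

__all__ = ["PipelineConfig", "run_discovery", "run_validation"]


@dataclass
class PipelineConfig:
    """Discovery-run configuration: real inputs XOR a simulation config."""

    matrix_path: Optional[str] = None
    clinical_path: Optional[str] = None
    genes_path: Optional[str] = None
    sim: Optional[SimConfig] = None
    k: int = 10
    alpha_ttest: float = 0.05
    alpha_enrich: float = 0.05
    keep_partial: bool = True
    bh_correct: bool = False
    tie_policy: str = "high"
    time_col: str = "rfs_time"
    event_col: str = "rfs_event"
    out_dir: str = "results/discovery"
    seed: int = 0
    overwrite: bool = True

    def __post_init__(self) -> None:
        have_paths = self.matrix_path is not None
        if have_paths == (self.sim is not None):
            raise ValueError("config needs exactly one of: input paths, simulation config")
        if not 0 <= self.alpha_ttest <= 1 or not 0 < self.alpha_enrich <= 1:
            raise ValueError("alphas must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        cfg = cls(sim=SimConfig(**sim) if sim is not None else None, **raw)
        return cfg


def _prepare_outdir(out_dir: str, overwrite: bool) -> Path:
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {out} is not empty (overwrite disabled)")
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_json(payload: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def run_discovery(config: PipelineConfig) -> dict:
    """Run the full discovery funnel; returns the in-memory results.

    Artifacts written to ``config.out_dir``: the simulated inputs (when
    simulating), association tables, enrichment table, signature JSON/BED,
    funnel audit JSON, and the risk-stratification report (when survival
    columns are available).
    """
    out = _prepare_outdir(config.out_dir, config.overwrite)
    log.info("discovery run: k=%d alpha_ttest=%g alpha_enrich=%g tie_policy=%s seed=%d",
             config.k, config.alpha_ttest, config.alpha_enrich, config.tie_policy, config.seed)

    truth = None
    if config.sim is not None:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        matrix, probes, clinical, genes, truth = generate_cohort(sim)
        cio.write_cna_matrix(matrix, probes, out / "matrix.tsv")
        cio.write_clinical(clinical, out / "clinical.csv")
        cio.write_gene_bed(genes, out / "genes.bed")
        truth.to_json(out / "truth.json")
        log.info("simulated cohort: %d probes x %d patients", len(matrix), matrix.shape[1])
    else:
        matrix, probes = cio.read_cna_matrix(config.matrix_path)
        clinical = cio.read_clinical(config.clinical_path)
        genes = cio.read_gene_bed(config.genes_path)

    blocks = build_blocks(probes, k=config.k, keep_partial=config.keep_partial)
    bm = aggregate(matrix, blocks)
    blocks_to_bed(blocks, out / "blocks.bed")
    log.info("aggregated %d probes into %d blocks (k=%d)", len(matrix), len(bm), config.k)

    labels = clinical.set_index("patient_id")
    assoc_rec = test_blocks(bm, labels["relapse"], "relapse",
                            alpha=config.alpha_ttest, bh_correct=config.bh_correct)
    assoc_syn = test_blocks(bm, labels["synchronous"], "synchronous",
                            alpha=config.alpha_ttest, bh_correct=config.bh_correct)
    assoc_rec.table.to_csv(out / "association_recurrence.tsv", sep="\t", index=False)
    assoc_syn.table.to_csv(out / "association_synchronous.tsv", sep="\t", index=False)

    enrich = enrich_by_chromosome(assoc_rec.table, blocks, alpha_enrich=config.alpha_enrich)
    enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    hotspots = list(enrich.loc[enrich["hotspot"], "chromosome"])
    log.info("recurrence-significant blocks: %d; hotspot chromosomes: %s",
             int(assoc_rec.table["significant"].sum()), hotspots)

    gene_map = map_blocks_to_genes(blocks, genes)
    sig = derive_signature(assoc_rec.table, assoc_syn.table, hotspots, gene_map, blocks, genes)
    sig.to_json(out / "signature.json")
    if len(sig.genes):
        sig.to_bed(out / "signature.bed")
    _write_json(sig.funnel, out / "funnel.json")
    log.info("funnel: %s", sig.funnel)

    risk = None
    has_survival = (
        config.time_col in clinical.columns
        and clinical[config.time_col].notna().all()
        and clinical[config.event_col].notna().all()
    )
    if len(sig.genes) == 0:
        log.warning("empty signature: risk stratification skipped")
    elif not has_survival:
        log.warning("survival columns unavailable: risk stratification skipped")
    else:
        risk = stratify(bm, sig, clinical, time_col=config.time_col,
                        event_col=config.event_col, tie_policy=config.tie_policy)
        risk.to_json(out / "risk_result.json")
        log.info("log-rank chi2=%.3f p=%.4g", risk.logrank_chi2, risk.logrank_p)

    return {
        "blocks": blocks, "block_matrix": bm, "clinical": clinical, "genes": genes,
        "assoc_recurrence": assoc_rec, "assoc_synchronous": assoc_syn,
        "enrichment": enrich, "hotspots": hotspots, "signature": sig,
        "risk": risk, "truth": truth,
    }


def run_validation(
    signature_path,
    matrix_path,
    clinical_path,
    out_dir: str = "results/validation",
    time_col: str = "rfs_time",
    event_col: str = "rfs_event",
    tie_policy: str = "high",
    overwrite: bool = True,
) -> dict:
    """Apply a saved signature to an external cohort and write the report.

    The external matrix may be probe-level (annotated TSV as written by
    :func:`cnasig.io.write_cna_matrix`) or gene-level (TSV with a leading
    ``symbol`` column).
    """
    sig_path = Path(signature_path)
    if not sig_path.exists():
        raise FileNotFoundError(f"signature file not found: {sig_path}")
    out = _prepare_outdir(out_dir, overwrite)
    sig = Signature.from_json(sig_path)
    clinical = cio.read_clinical(clinical_path)

    probes = None
    head = pd.read_csv(matrix_path, sep="\t", nrows=1)
    if set(["probe_id", "chromosome", "start", "end"]).issubset(head.columns):
        matrix, probes = cio.read_cna_matrix(matrix_path)
    else:
        matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)

    risk = apply_signature_external(
        matrix, sig, clinical, probes=probes,
        time_col=time_col, event_col=event_col, tie_policy=tie_policy,
    )
    risk.to_json(out / "risk_result.json")
    log.info("validation: %d patients, log-rank chi2=%.3f p=%.4g",
             len(risk.scores), risk.logrank_chi2, risk.logrank_p)
    return {"signature": sig, "risk": risk}
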