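"""Gene-signature derivation by the recurrence/hotspot/synchronous funnel.

The selection funnel proceeds:

1. blocks with a significant recurrence association,
2. of those, blocks on hotspot chromosomes,
3. of those, blocks overlapping annotated gene regions (>= 1 bp, half-open),
4. of those, blocks also significantly associated with synchronous
   metastasis.

Genes supported by at least one surviving block form the signature; a
gene's direction (loss vs gain) is the sign of its supporting blocks' mean
copy-number difference in the recurrence contrast.  All four intermediate
sets are recorded for auditability, in both block and probe counts.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = ["Signature", "map_blocks_to_genes", "derive_signature"]


@dataclass
class Signature:
    """Selected genes with direction, support, and the funnel audit trail."""

    genes: pd.DataFrame  # symbol, chromosome, start, end, direction, supporting_blocks
    funnel: dict

    @property
    def symbols(self) -> list:
        return list(self.genes["symbol"])

    def to_json(self, path) -> None:
        payload = {
            "genes": [
                {**row, "supporting_blocks": list(row["supporting_blocks"])}
                for row in self.genes.to_dict("records")
            ],
            "funnel": self.funnel,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "Signature":
        with open(path) as fh:
            payload = json.load(fh)
        genes = pd.DataFrame(
            payload["genes"],
            columns=["symbol", "chromosome", "start", "end", "direction", "supporting_blocks"],
        )
        genes["supporting_blocks"] = genes["supporting_blocks"].map(tuple)
        return cls(genes=genes, funnel=payload["funnel"])

    def to_bed(self, path) -> None:
        self.genes[["chromosome", "start", "end", "symbol"]].to_csv(
            path, sep="\t", header=False, index=False
        )


def map_blocks_to_genes(blocks: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Overlap blocks with gene intervals (half-open, >= 1 bp).

    Returns a long-form frame with columns ``block_id, symbol``; a block
    overlapping several genes appears once per gene.  Gene chromosomes
    absent from the block annotation indicate a naming-scheme mismatch and
    raise an error listing the offenders.
    """
    block_chroms = set(blocks["chromosome"])
    offenders = sorted(set(genes["chromosome"]) - block_chroms)
    if offenders:
        raise ValueError(f"gene chromosomes absent from block annotation: {offenders}")
    pairs = []
    for chrom, gg in genes.groupby("chromosome", sort=False):
        bb = blocks[blocks["chromosome"] == chrom]
        for sym, gs, ge in zip(gg["symbol"], gg["start"], gg["end"]):
            hit = bb[(bb["start"] < ge) & (bb["end"] > gs)]
            pairs.extend((bid, sym) for bid in hit["block_id"])
    return pd.DataFrame(pairs, columns=["block_id", "symbol"])


def derive_signature(
    assoc_recurrence: pd.DataFrame,
    assoc_synchronous: pd.DataFrame,
    hotspots,
    gene_map: pd.DataFrame,
    blocks: pd.DataFrame,
    genes: pd.DataFrame,
) -> Signature:
    """Intersect the funnel stages and assemble the gene signature.

    Parameters
    ----------
    assoc_recurrence, assoc_synchronous : association tables over the same
        blocks (``test_blocks`` output with ``significant`` column).
    hotspots : iterable of hotspot chromosome names.
    gene_map : block-to-gene overlap (``map_blocks_to_genes`` output).
    blocks, genes : block and gene annotations (for coordinates and probe
        counts in the audit trail).

    An empty hotspot list, or alpha = 0 upstream, yields an empty signature
    with a warning — an admissible outcome, not an error.
    """
    rec = assoc_recurrence.set_index("block_id")
    syn = assoc_synchronous.set_index("block_id")
    if not rec.index.equals(syn.index):
        common = rec.index.intersection(syn.index)
        if len(common) == 0:
            raise ValueError("association tables share no blocks")
        rec, syn = rec.loc[common], syn.loc[common]

    hotspots = list(hotspots)
    if not hotspots:
        warnings.warn("empty hotspot list: signature will be empty")

    chrom_of = blocks.set_index("block_id")["chromosome"]
    nprobes_of = blocks.set_index("block_id")["n_probes"]

    s1 = set(rec.index[rec["significant"]])
    s2 = {b for b in s1 if chrom_of.get(b) in set(hotspots)}
    mapped = set(gene_map["block_id"])
    s3 = s2 & mapped
    s4 = {b for b in s3 if bool(syn.loc[b, "significant"])}

    def _count(blockset):
        return {"blocks": len(blockset), "probes": int(sum(nprobes_of.get(b, 0) for b in blockset))}

    funnel = {
        "recurrence_significant": _count(s1),
        "on_hotspot_chromosomes": _count(s2),
        "in_gene_regions": _count(s3),
        "synchronous_significant": _count(s4),
        "hotspot_chromosomes": sorted(hotspots),
    }

    gene_coords = genes.set_index("symbol")
    rows = []
    for sym, grp in gene_map[gene_map["block_id"].isin(s4)].groupby("symbol"):
        support = tuple(sorted(grp["block_id"]))
        mean_diff = rec.loc[list(support), "mean_diff"].mean()
        coords = gene_coords.loc[sym]
        rows.append(
            (sym, coords["chromosome"], int(coords["start"]), int(coords["end"]),
             "loss" if mean_diff < 0 else "gain", support)
        )
    genes_df = pd.DataFrame(
        rows, columns=["symbol", "chromosome", "start", "end", "direction", "supporting_blocks"]
    ).sort_values("symbol", kind="stable").reset_index(drop=True)
    funnel["signature_genes"] = list(genes_df["symbol"])
    return Signature(genes=genes_df, funnel=funnel)
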