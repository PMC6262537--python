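"""Elementary-block formation and per-block signal aggregation.

Array-CGH log2 ratios are noisy at single-probe resolution; grouping k
consecutively located probes (k=10 by default) into "elementary blocks" and
averaging within each block enhances signal while preserving the expected
log2 ratio.  Blocks never span chromosomes; a trailing run of fewer than k
probes is retained as one final partial block (switchable).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["build_blocks", "aggregate", "blocks_to_bed"]


def build_blocks(probes: pd.DataFrame, k: int = 10, keep_partial: bool = True) -> pd.DataFrame:
    """Group consecutive probes into blocks of ``k`` per chromosome.

    Parameters
    ----------
    probes : DataFrame with columns probe_id, chromosome, start, end,
        sorted by (chromosome, start).
    k : probes per block (default 10).
    keep_partial : retain a trailing block of < k probes instead of
        dropping those probes.

    Returns a block annotation with columns ``block_id, chromosome, start,
    end, n_probes, probe_ids`` (probe_ids an ordered tuple); each block's
    interval spans exactly its member probes and blocks partition the
    retained probe set.
    """
    if k <= 0:
        raise ValueError("block size k must be >= 1")
    rows = []
    for chrom, grp in probes.groupby("chromosome", sort=False):
        grp = grp.sort_values("start", kind="stable")
        ids = grp["probe_id"].to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        n_blocks = int(np.ceil(len(grp) / k))
        for b in range(n_blocks):
            members = ids[b * k : (b + 1) * k]
            if len(members) < k and not keep_partial:
                continue
            rows.append(
                (
                    f"{chrom}_B{b:05d}",
                    chrom,
                    int(starts[b * k]),
                    int(ends[min((b + 1) * k, len(grp)) - 1]),
                    len(members),
                    tuple(members),
                )
            )
    return pd.DataFrame(
        rows, columns=["block_id", "chromosome", "start", "end", "n_probes", "probe_ids"]
    )


def aggregate(matrix: pd.DataFrame, blocks: pd.DataFrame) -> pd.DataFrame:
    """Mean log2 ratio per (block, patient), ignoring missing probe values.

    A block whose member values are all missing for a patient yields NaN for
    that patient.  Referencing a probe absent from the matrix is an error.
    """
    probe_to_block: dict = {}
    for block_id, members in zip(blocks["block_id"], blocks["probe_ids"]):
        for pid in members:
            probe_to_block[pid] = block_id
    unknown = set(probe_to_block) - set(matrix.index)
    if unknown:
        raise ValueError(f"blocks reference probes absent from matrix: {sorted(unknown)[:5]}")
    sub = matrix.loc[list(probe_to_block)]
    grouped = sub.groupby(sub.index.map(probe_to_block.get)).mean()  # skipna by default
    grouped.index.name = "block_id"
    return grouped.loc[blocks["block_id"]]


def blocks_to_bed(blocks: pd.DataFrame, path) -> None:
    """Export block definitions as BED4 (block_id in the name column)."""
    blocks[["chromosome", "start", "end", "block_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )
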