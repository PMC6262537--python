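"""Chromosome-level hotspot enrichment of differential-CNA blocks.

For each chromosome a 2x2 table (significant vs not x on-chromosome vs rest
of genome) is tested with the two-sided Fisher's exact test.  A chromosome
is called a hotspot when its Bonferroni-corrected p-value is below
``alpha_enrich`` AND its significant-block density exceeds the genome-wide
density — enrichment calls hotspots, depletion does not.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["fisher_exact_two_sided", "enrich_by_chromosome"]


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    The two-sided p sums, over all tables with the observed margins, the
    hypergeometric probabilities no larger than that of the observed table.
    A zero row or column margin is degenerate and returns p = 1.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if (a + b + c + d) == 0:
        raise ValueError("at least one margin must be positive")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return 1.0
    return float(min(1.0, stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]))


def enrich_by_chromosome(
    assoc: pd.DataFrame,
    blocks: pd.DataFrame,
    alpha_enrich: float = 0.05,
) -> pd.DataFrame:
    """Per-chromosome Fisher enrichment of significant blocks.

    Parameters
    ----------
    assoc : association table (``test_blocks`` output) with block_id and
        significant columns.
    blocks : block annotation assigning every block to one chromosome.
    alpha_enrich : family-wise level; Bonferroni-corrected across the
        chromosomes tested.

    Returns the enrichment table with one row per chromosome: counts of the
    2x2 construction, density, odds ratio, raw and Bonferroni p, hotspot
    flag.  Chromosomes with zero blocks are excluded with a warning.
    """
    chrom_of = blocks.set_index("block_id")["chromosome"]
    tab = assoc.merge(chrom_of.rename("chromosome"), left_on="block_id", right_index=True)
    all_chroms = blocks["chromosome"].unique()
    empty = [c for c in all_chroms if c not in set(tab["chromosome"])]
    if empty:
        warnings.warn(f"chromosomes with no testable blocks excluded: {empty}")

    n_total = len(tab)
    n_sig = int(tab["significant"].sum())
    genome_density = n_sig / n_total if n_total else 0.0

    rows = []
    for chrom, grp in tab.groupby("chromosome", sort=False):
        n_on = len(grp)
        sig_on = int(grp["significant"].sum())
        n_off = n_total - n_on
        sig_off = n_sig - sig_on
        a, b = sig_on, n_on - sig_on
        c, d = sig_off, n_off - sig_off
        p = fisher_exact_two_sided(a, b, c, d)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
        rows.append((chrom, sig_on, n_on, sig_off, n_off, sig_on / n_on, odds, p))
    out = pd.DataFrame(
        rows,
        columns=["chromosome", "n_sig_on", "n_total_on", "n_sig_off", "n_total_off", "density", "odds_ratio", "p_value"],
    )
    m = len(out)
    out["p_bonferroni"] = np.minimum(out["p_value"] * m, 1.0)
    out["hotspot"] = (out["p_bonferroni"] < alpha_enrich) & (out["density"] > genome_density)
    return out.sort_values("chromosome", kind="stable").reset_index(drop=True)
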