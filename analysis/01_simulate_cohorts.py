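"""Simulate the discovery and external validation cohorts.

Writes a 21-patient discovery cohort and a 45-patient external cohort
(mirroring the two study cohort sizes) with planted chr1/chr5 losses and
signature-linked relapse-free survival, under results/data/.
"""

import argparse
from pathlib import Path

from cnasig import SimConfig, generate_cohort
from cnasig.io import write_clinical, write_cna_matrix, write_gene_bed


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    cohorts = {
        "discovery": SimConfig(seed=args.seed),
        "external": SimConfig(n_patients=45, n_relapse=28, n_synchronous=28,
                              seed=args.seed + 1),
    }
    for name, cfg in cohorts.items():
        out = args.out / name
        out.mkdir(parents=True, exist_ok=True)
        matrix, probes, clinical, genes, truth = generate_cohort(cfg)
        write_cna_matrix(matrix, probes, out / "matrix.tsv")
        write_clinical(clinical, out / "clinical.csv")
        write_gene_bed(genes, out / "genes.bed")
        truth.to_json(out / "truth.json")
        print(f"{name}: {len(matrix)} probes x {matrix.shape[1]} patients, "
              f"{len(truth.affected_patients)} signature-lesion carriers -> {out}")


if __name__ == "__main__":
    main()
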