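"""Summarize the packaged CRCLM discovery-cohort clinical table.

Recomputes the cohort demographics (age distribution, sex, relapse,
synchronous status, primary-site split) from the packaged 21-patient table
and writes them to results/tables/clinical_summary.json.
"""

import argparse
import json
from pathlib import Path

from cnasig.io import load_crclm_clinical, summarize_clinical


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/tables/clinical_summary.json"))
    args = ap.parse_args()

    summary = summarize_clinical(load_crclm_clinical())
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(summary, indent=2, sort_keys=True))
    print(f"n={summary['n']} patients; mean age {summary['age_mean']} "
          f"(range {summary['age_min']:.0f}-{summary['age_max']:.0f}); "
          f"{summary['n_relapse']} relapsed / {summary['n_non_relapse']} not; "
          f"{summary['n_male']}M/{summary['n_female']}F; "
          f"{summary['n_synchronous']} synchronous; "
          f"{summary['n_colon']} colon / {summary['n_rectum']} rectal primaries")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
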