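"""Multi-caller consensus and somatic filtering for every tumor sample.

For each sample the three callers' VCFs are merged (2-of-3 consensus,
10% read support), annotated, MAF-tiered, and classified somatic
(zero-alt-in-normal where a matched normal exists, population-frequency +
COSMIC/impact rescue otherwise). Writes the consensus variant table and a
per-sample filtering census.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import require_run, results_dir  # noqa: E402

from gliomapairs import io as gio  # noqa: E402
from gliomapairs.cohort import read_clinical_table  # noqa: E402
from gliomapairs.pipeline import filter_sample  # noqa: E402
from gliomapairs.variants import FilterPolicy, consensus_to_frame  # noqa: E402


def main() -> None:
    run_dir = require_run()
    pairs = read_clinical_table(run_dir / "clinical.tsv")
    annotation = gio.read_annotation(run_dir / "annotation.tsv")
    policy = FilterPolicy()

    frames = []
    census = []
    for pair in pairs:
        for sample_id in (pair.primary_sample_id, pair.recurrence_sample_id):
            variants = filter_sample(run_dir, sample_id, pair.patient_id,
                                     policy, annotation)
            frame = consensus_to_frame(variants)
            frames.append(frame)
            census.append(
                {
                    "sample_id": sample_id,
                    "n_consensus": len(frame),
                    "n_kept": int((frame["status"] != "filtered").sum()),
                    "n_somatic": int((frame["status"] == "somatic").sum()),
                    "n_putative": int((frame["status"] == "putative_somatic").sum()),
                    "n_filtered": int((frame["status"] == "filtered").sum()),
                }
            )
    out_dir = results_dir()
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(out_dir / "consensus_variants.tsv", sep="\t", index=False)
    census_df = pd.DataFrame(census)
    census_df.to_csv(out_dir / "filtering_census.tsv", sep="\t", index=False)

    print(f"{len(table)} consensus variants across {len(census)} tumor samples")
    print(f"kept per sample: median {census_df['n_kept'].median():.0f}, "
          f"max {census_df['n_kept'].max()} (hypermutator recurrence)")
    print(f"tables -> {out_dir / 'consensus_variants.tsv'}, "
          f"{out_dir / 'filtering_census.tsv'}")


if __name__ == "__main__":
    main()
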