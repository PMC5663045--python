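"""Shared vs private mutations per pair, molecular grouping, and the
gene-by-pair conservation matrix.

Reproduces the temporal-comparison layer: clonal drivers are expected to be
shared (conserved at recurrence), passengers split between timepoints, and
the cohort stratifies into H3/IDH1 mutant / wildtype / NF1 germline.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import require_run, results_dir  # noqa: E402

from gliomapairs import io as gio  # noqa: E402
from gliomapairs.cohort import read_clinical_table  # noqa: E402
from gliomapairs.pipeline import filter_sample, germline_consensus  # noqa: E402
from gliomapairs.resources import load_pathway_map  # noqa: E402
from gliomapairs.temporal import (  # noqa: E402
    assign_group,
    conservation_matrix,
    partition_pair,
)
from gliomapairs.variants import FilterPolicy  # noqa: E402


def main() -> None:
    run_dir = require_run()
    pairs = read_clinical_table(run_dir / "clinical.tsv")
    annotation = gio.read_annotation(run_dir / "annotation.tsv")
    policy = FilterPolicy()

    rows = []
    partitions = {}
    gene_of = {}
    for pair in pairs:
        kept = {}
        for sample_id in (pair.primary_sample_id, pair.recurrence_sample_id):
            variants = filter_sample(run_dir, sample_id, pair.patient_id,
                                     policy, annotation)
            kept[sample_id] = [v for v in variants if v.status != "filtered"]
            for v in kept[sample_id]:
                if v.gene:
                    gene_of[v.key] = v.gene
        part = partition_pair(kept[pair.primary_sample_id],
                              kept[pair.recurrence_sample_id])
        partitions[pair.patient_id] = part
        germ = germline_consensus(run_dir, pair.patient_id, policy, annotation)
        group = assign_group(
            kept[pair.primary_sample_id] + kept[pair.recurrence_sample_id], germ
        )
        rows.append(
            {
                "pair_id": pair.patient_id,
                "group": group,
                "shared": part.n_shared,
                "primary_only": part.n_primary_only,
                "recurrence_only": part.n_recurrence_only,
            }
        )
    out_dir = results_dir()
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "temporal_partitions.tsv", sep="\t", index=False)
    matrix = conservation_matrix(partitions, gene_of, load_pathway_map())
    matrix.to_csv(out_dir / "conservation_matrix.tsv", sep="\t")

    counts = table["group"].value_counts()
    print("group counts:", dict(counts))
    print(f"median shared per pair: {table['shared'].median():.0f}; "
          f"private (P/R): {table['primary_only'].median():.0f}/"
          f"{table['recurrence_only'].median():.0f}")
    print(f"tables -> {out_dir / 'temporal_partitions.tsv'}, "
          f"{out_dir / 'conservation_matrix.tsv'}")


if __name__ == "__main__":
    main()
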