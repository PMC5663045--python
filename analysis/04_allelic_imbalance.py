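"""Allelic-imbalance regions per tumor and shared/private region counts
per pair (counted regardless of region size).

The pair whose recurrence underwent genome-wide copy-neutral LOH shows the
expected surge of recurrence-specific AI regions.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import require_run, results_dir  # noqa: E402

from gliomapairs import io as gio  # noqa: E402
from gliomapairs.allelic_imbalance import (  # noqa: E402
    compare_ai_regions,
    detect_ai,
    normal_folded_baseline,
    segments_to_frame,
    select_het_sites,
)
from gliomapairs.cohort import read_clinical_table  # noqa: E402


def main() -> None:
    run_dir = require_run()
    pairs = read_clinical_table(run_dir / "clinical.tsv")

    seg_frames = []
    comparison_rows = []
    for pair in pairs:
        segments = {}
        for sample_id in (pair.primary_sample_id, pair.recurrence_sample_id):
            track = gio.read_track(run_dir / "tracks" / f"{sample_id}.tsv")
            sites = select_het_sites(track)
            segments[sample_id] = detect_ai(
                sites, baseline=normal_folded_baseline(track)
            )
            frame = segments_to_frame(segments[sample_id])
            if not frame.empty:
                frame.insert(0, "sample_id", sample_id)
                seg_frames.append(frame)
        cmp = compare_ai_regions(
            segments[pair.primary_sample_id], segments[pair.recurrence_sample_id]
        )
        comparison_rows.append(
            {
                "pair_id": pair.patient_id,
                "shared_primary": cmp.shared_primary,
                "shared_recurrence": cmp.shared_recurrence,
                "primary_only": cmp.primary_only,
                "recurrence_only": cmp.recurrence_only,
            }
        )
    out_dir = results_dir()
    pd.concat(seg_frames, ignore_index=True).to_csv(
        out_dir / "ai_segments.tsv", sep="\t", index=False
    )
    comparisons = pd.DataFrame(comparison_rows)
    comparisons.to_csv(out_dir / "ai_comparisons.tsv", sep="\t", index=False)

    worst = comparisons.loc[comparisons["recurrence_only"].idxmax()]
    print(f"AI regions per tumor: median "
          f"{np.median(comparisons[['shared_primary', 'primary_only']].sum(axis=1)):.0f}")
    print(f"largest recurrence-specific burden: pair {worst['pair_id']} "
          f"({worst['recurrence_only']} recurrence-only regions - the "
          f"genome-wide cnLOH recurrence)")
    print(f"tables -> {out_dir / 'ai_segments.tsv'}, {out_dir / 'ai_comparisons.tsv'}")


if __name__ == "__main__":
    main()
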