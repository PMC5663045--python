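"""Joint coverage+BAF CNV calling for the pairs with matched normals:
segment-level events at the union of the two features' breakpoints and
arm-level rollups.

Checks the two planted flavor events: 17q copy-neutral LOH in the NF1
germline recurrences and the genome-wide copy-neutral recurrence.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import require_run, results_dir  # noqa: E402

from gliomapairs import io as gio  # noqa: E402
from gliomapairs.allelic_imbalance import (  # noqa: E402
    detect_ai,
    normal_folded_baseline,
    select_het_sites,
)
from gliomapairs.cnv import call_cnv, events_to_frame  # noqa: E402
from gliomapairs.cohort import read_clinical_table  # noqa: E402


def main() -> None:
    run_dir = require_run()
    pairs = [p for p in read_clinical_table(run_dir / "clinical.tsv")
             if p.germline_available]

    frames = []
    for pair in pairs:
        for sample_id in (pair.primary_sample_id, pair.recurrence_sample_id):
            track = gio.read_track(run_dir / "tracks" / f"{sample_id}.tsv")
            normal = track[["chrom", "pos"]].assign(
                tumor_depth=track["normal_depth"]
            )
            ai_segs = detect_ai(
                select_het_sites(track),
                baseline=normal_folded_baseline(track),
            )
            seg_events, arm_events = call_cnv(track, normal, ai_segs)
            frame = events_to_frame(seg_events + arm_events)
            frame.insert(0, "sample_id", sample_id)
            frame.insert(1, "pair_id", pair.patient_id)
            frames.append(frame)
    out_dir = results_dir()
    events = pd.concat(frames, ignore_index=True)
    events.to_csv(out_dir / "cnv_events.tsv", sep="\t", index=False)

    arm = events[(events["level"] == "arm") & (events["event_class"] != "none")]
    nf1_recs = [p.recurrence_sample_id for p in pairs
                if p.molecular_group == "NF1 germline"]
    nf1_17q = arm[
        arm["sample_id"].isin(nf1_recs)
        & (arm["chrom"] == "chr17") & (arm["arm"] == "q")
        & (arm["event_class"] == "cnLOH")
    ]
    print(f"{len(events)} CNV events ({len(arm)} non-neutral arm-level calls) "
          f"across {2 * len(pairs)} tumors with matched normals")
    print(f"17q cnLOH called in {len(nf1_17q)}/{len(nf1_recs)} "
          f"NF1-germline recurrences")
    per_sample_arms = arm.groupby("sample_id").size()
    if not per_sample_arms.empty:
        top = per_sample_arms.idxmax()
        print(f"most altered genome: {top} with {per_sample_arms.max()} "
              f"arm-level events")
    print(f"table -> {out_dir / 'cnv_events.tsv'}")


if __name__ == "__main__":
    main()
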