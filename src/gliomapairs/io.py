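"""Shared readers and writers binding the pipeline together.

Coordinate conventions: VCF and track TSVs are 1-based; BED output and
internal segment intervals are 0-based half-open. All writers are
deterministic (fixed column order, fixed float formats) so identical inputs
produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from gliomapairs.resources import chromosome_lengths

_EXTRA_CONTIGS = {"chrX": 155270560, "chrY": 59373566}

_NATURAL_CHROM_ORDER = {
    f"chr{i}": i for i in range(1, 23)
} | {"chrX": 23, "chrY": 24}


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    return (_NATURAL_CHROM_ORDER.get(chrom, 99), chrom)


def write_vcf(
    path: str | Path,
    sample_id: str,
    records: Sequence[tuple[str, int, str, str, int, int]],
) -> None:
    """Write a minimal single-sample VCF 4.2 with GT:AD:DP.

    ``records`` are (chrom, pos, ref, alt, depth, alt_reads) tuples; they are
    sorted by (chrom, pos, ref, alt) before writing.
    """
    contigs = dict(chromosome_lengths()) | _EXTRA_CONTIGS
    lines = [
        "##fileformat=VCFv4.2",
        "##source=gliomapairs-synthetic",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    for chrom in sorted(contigs, key=chrom_sort_key):
        lines.append(f"##contig=<ID={chrom},length={contigs[chrom]}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id
    )
    for chrom, pos, ref, alt, depth, alt_reads in sorted(
        records, key=lambda r: (chrom_sort_key(r[0]), r[1], r[2], r[3])
    ):
        ad = f"{depth - alt_reads},{alt_reads}"
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:AD:DP\t0/1:{ad}:{depth}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_track(path: str | Path, track: pd.DataFrame) -> None:
    """Write a per-site coverage/BAF track TSV (1-based positions)."""
    cols = [
        "chrom", "pos", "ref_reads", "alt_reads", "tumor_depth",
        "normal_depth", "normal_ref_reads", "normal_alt_reads",
    ]
    track[[c for c in cols if c in track.columns]].to_csv(
        path, sep="\t", index=False
    )


def read_track(path: str | Path) -> pd.DataFrame:
    track = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref_reads", "alt_reads"}
    missing = required - set(track.columns)
    if missing:
        raise ValueError(f"track {path} missing columns: {sorted(missing)}")
    return track


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    ann["in_cosmic"] = ann["in_cosmic"].astype(bool)
    return ann


def write_annotation(path: str | Path, annotation: pd.DataFrame) -> None:
    cols = [
        "chrom", "pos", "ref", "alt", "gene", "protein_change", "effect",
        "functional_impact", "in_cosmic",
        "pop_af_1000g", "pop_af_evs", "pop_af_exac",
    ]
    annotation[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_normal_counts(path: str | Path) -> dict[tuple[str, int, str, str], int]:
    """Normal-sample alt read counts keyed by variant."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        (r.chrom, int(r.pos), r.ref, r.alt): int(r.normal_alt_reads)
        for r in df.itertuples()
    }


def write_bed(path: str | Path, segments: pd.DataFrame, score_col: str | None = None) -> None:
    """Segments as BED (0-based half-open); score defaults to -log10(q)."""
    out = segments.copy()
    if score_col is None and "q_value" in out.columns:
        out["score"] = -np.log10(np.maximum(out["q_value"], 1e-300))
        score_col = "score"
    name = out["event_class"] if "event_class" in out.columns else out.get("arm", ".")
    bed = pd.DataFrame(
        {
            "chrom": out["chrom"],
            "start": out["start"],
            "end": out["end"],
            "name": name,
            "score": out[score_col].round(3) if score_col in out.columns else 0,
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def config_hash(config: Any) -> str:
    """Stable hash of a configuration object (dataclass or mapping)."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        payload = dataclasses.asdict(config)
    else:
        payload = dict(config)
    blob = json.dumps(payload, sort_keys=True, default=repr).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    run_dir: str | Path,
    config: Any,
    seed: int,
    files: Sequence[str | Path],
    extra: Mapping[str, Any] | None = None,
) -> Path:
    """Write a JSON run manifest: inputs, config hash, versions, seed."""
    import gliomapairs

    run_dir = Path(run_dir)
    manifest = {
        "config_hash": config_hash(config),
        "seed": seed,
        "versions": {
            "gliomapairs": gliomapairs.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "files": {
            str(Path(f).relative_to(run_dir)): file_sha256(f)
            for f in sorted(map(str, files))
        },
    }
    if extra:
        manifest.update(extra)
    path = run_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
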