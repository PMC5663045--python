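"""Shared paths and helpers for the numbered analysis drivers."""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
RUN_DIR = ROOT / "scratch" / "cohort_run"
RESULTS = ROOT / "results"
SEED = 1


def require_run() -> Path:
    if not (RUN_DIR / "manifest.json").exists():
        raise SystemExit(
            "no simulated cohort found - run `python analysis/01_simulate_cohort.py` first"
        )
    return RUN_DIR


def results_dir() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
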