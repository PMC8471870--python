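"""Shared plumbing for the numbered analysis drivers.

Each driver operates on the synthetic multi-cohort study written under
``results/data`` (created by 01_simulate.py, or on demand); tables produced
by the drivers land under ``results/analysis``.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from xspecies_nash.pipeline import (
    CohortConfig,
    RunConfig,
    load_config,
    preprocess_cohort,
    simulate_to_dir,
)

ROOT = Path(__file__).resolve().parent.parent
DATA_DIR = ROOT / "results" / "study"
OUT_DIR = ROOT / "results" / "analysis"


def parse_seed(description: str) -> int:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=1)
    return parser.parse_args().seed


def ensure_study(seed: int) -> RunConfig:
    """Simulate the study on first use; reuse the written files afterwards."""
    config_path = DATA_DIR / "config.yaml"
    if config_path.exists():
        config = load_config(config_path)
        if config.seed == seed:
            return config
    return simulate_to_dir(seed, DATA_DIR)


def load_processed(config: RunConfig, cohort_id: str):
    cfg = next(c for c in config.cohorts if c.cohort_id == cohort_id)
    return preprocess_cohort(cfg, config.thresholds)


def out_path(name: str) -> Path:
    OUT_DIR.mkdir(parents=True, exist_ok=True)
    return OUT_DIR / name
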