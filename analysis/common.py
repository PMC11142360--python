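"""Shared driver plumbing: run the study pipeline up to a given stage."""

from __future__ import annotations

import copy
from pathlib import Path

from statefate.pipeline import DEFAULT_CONFIG, run_pipeline

STAGE_ORDER = ["synthetic", "assign", "activity", "boolnet", "koscreen", "predict"]
STUDY_DIR = Path(__file__).resolve().parents[1] / "results" / "study"


def run_study(up_to: str) -> dict:
    """Run the deterministic synthetic study through stage ``up_to``.

    Every driver replays the pipeline from the start (seconds of work);
    fixed per-stage seeds make all reruns byte-identical, so the stages
    compose across scripts.
    """
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    cut = STAGE_ORDER.index(up_to)
    cfg["stages"] = {s: i <= cut for i, s in enumerate(STAGE_ORDER)}
    return run_pipeline(cfg, STUDY_DIR)
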