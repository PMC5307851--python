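"""Deterministic synthetic fixtures: interim count tables and config files.

These are small text artifacts for testing and demonstration: a two-row
interim counts CSV produced by simulating a burn-in cohort under a chosen
truth, plus design/scenario config files with the package defaults.
"""

from __future__ import annotations

import csv
import hashlib
from pathlib import Path

import numpy as np
import yaml

from .config import design_to_dict, scenario_to_dict
from .decisions import DesignSpec
from .simulate import Scenario, scenario_presets, simulate_subject

__all__ = ["make_fixtures", "write_counts_csv", "read_counts_csv", "fixture_digest"]


def write_counts_csv(path: str | Path, rows: list[tuple[str, int, int]]) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["arm_id", "births", "events"])
        writer.writerows(rows)
    return path


def read_counts_csv(path: str | Path) -> list[tuple[str, int, int]]:
    path = Path(path)
    rows: list[tuple[str, int, int]] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(reader.fieldnames) < {"arm_id", "births", "events"}:
            raise ValueError(f"{path} must have header arm_id,births,events")
        for rec in reader:
            rows.append((rec["arm_id"], int(rec["births"]), int(rec["events"])))
    if len(rows) < 2:
        raise ValueError(f"{path} must contain at least two arm rows")
    return rows


def make_fixtures(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a synthetic interim-counts CSV plus default config files.

    The counts come from simulating a 150-per-arm burn-in cohort under the
    most-likely truth scenario (4% vs 1% ePTB); identical seeds give
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    scenario = scenario_presets()["#1"]
    rows = []
    for arm, label in enumerate(scenario.arm_labels):
        events = sum(
            simulate_subject(arm, scenario, rng, subject_id=i).eptb for i in range(150)
        )
        rows.append((label, 150, int(events)))
    paths = {
        "counts": write_counts_csv(out_dir / "interim_counts.csv", rows),
        "design": out_dir / "design.yaml",
        "scenario": out_dir / "scenario.yaml",
    }
    paths["design"].write_text(
        yaml.safe_dump({**design_to_dict(DesignSpec()), "seed": seed}, sort_keys=True)
    )
    paths["scenario"].write_text(
        yaml.safe_dump({**scenario_to_dict(scenario), "seed": seed}, sort_keys=True)
    )
    return paths


def fixture_digest(paths: dict[str, Path]) -> str:
    """Joint content digest of a fixture set (order-independent)."""
    h = hashlib.sha256()
    for key in sorted(paths):
        h.update(key.encode())
        h.update(Path(paths[key]).read_bytes())
    return h.hexdigest()[:16]
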