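"""File I/O: tidy choice tables, truth side-cars, results, run config.

All tabular exchange is comma-separated UTF-8 text with a mandatory
header; nested results go to JSON.  Every written file embeds the seed
and a hash of the settings that produced it (as a ``# key: value``
comment header in CSVs, or top-level fields in JSON).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd
import yaml

from .cohort import ParticipantDataset
from .models import MODEL_ORDER

REQUIRED_COLUMNS = ("participant_id", "trial_index", "block", "scenario",
                    "x1", "x2", "x3", "cost", "ratio", "choice")
_SPLITS = (50, 60, 70, 80, 90)
_CHOICE_MAP = {"0": 0, "1": 1, "no": 0, "yes": 1}


@dataclass
class RunConfig:
    """Top-level pipeline settings."""

    seed: int = 0
    models: List[str] = field(default_factory=lambda: list(MODEL_ORDER))
    n_starts: int = 50
    n_participants: int = 20
    k_range: List[int] = field(default_factory=lambda: list(range(2, 11)))
    n_restarts: int = 100
    bms_mc_samples: int = 100_000

    def __post_init__(self) -> None:
        unknown = [m for m in self.models if m not in MODEL_ORDER]
        if unknown:
            raise ValueError(f"unknown models in config: {unknown}")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def config_header(config: Optional[RunConfig], seed: Optional[int]) -> str:
    parts = []
    if seed is not None:
        parts.append(f"# seed: {seed}")
    if config is not None:
        parts.append(f"# config_hash: {config.hash()}")
    return "\n".join(parts)


def write_cohort(datasets: Sequence[ParticipantDataset],
                 path: Union[str, Path],
                 truth_path: Optional[Union[str, Path]] = None,
                 config: Optional[RunConfig] = None,
                 seed: Optional[int] = None) -> None:
    """One tidy table (one row per trial per participant); optional JSON
    side-car with the generating truth."""
    frames = []
    for ds in datasets:
        cols = [c for c in REQUIRED_COLUMNS if c in ds.trials.columns]
        extra = [c for c in ("split", "decision_time")
                 if c in ds.trials.columns]
        frames.append(ds.trials[cols + extra])
    table = pd.concat(frames, ignore_index=True)
    path = Path(path)
    header = config_header(config, seed)
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(header + "\n")
        table.to_csv(fh, index=False)
    if truth_path is not None:
        truth = {
            ds.participant_id: {
                "model": ds.true_model,
                "params": ds.true_params,
                "archetype": ds.archetype,
                "attention_correct": ds.attention_correct,
            }
            for ds in datasets
        }
        obj = {"seed": seed, "truth": truth}
        if config is not None:
            obj["config_hash"] = config.hash()
        Path(truth_path).write_text(json.dumps(obj, indent=2), encoding="utf-8")


def _parse_choice(value, row: int) -> int:
    key = str(value).strip().lower()
    if key in _CHOICE_MAP:
        return _CHOICE_MAP[key]
    raise ValueError(f"row {row}: unparseable choice {value!r}")


def read_choice_table(path: Union[str, Path]) -> List[ParticipantDataset]:
    """Read and validate a tidy choice table into per-participant datasets.

    Validation failures (missing columns, non-numeric payoffs,
    x1 + x2 != 100, unknown scenario, bad choice coding) raise with the
    offending row number (1-based data rows).
    """
    table = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    table["scenario"] = table["scenario"].astype(str).str.strip().str.lower()
    for i, row in enumerate(table.itertuples(), start=1):
        if row.scenario not in ("punishment", "helping"):
            raise ValueError(f"row {i}: unknown scenario {row.scenario!r}")
        try:
            x1, x2 = float(row.x1), float(row.x2)
        except (TypeError, ValueError):
            raise ValueError(f"row {i}: non-numeric payoff") from None
        if x1 + x2 != 100:
            raise ValueError(f"row {i}: x1 + x2 = {x1 + x2}, expected 100")
    table["choice"] = [_parse_choice(v, i) for i, v in
                       enumerate(table["choice"], start=1)]
    if "split" not in table.columns:
        # nominal split bin from the jittered transgressor share (+/-2)
        nearest = (table["x1"] / 10).round() * 10
        table["split"] = nearest.clip(min(_SPLITS), max(_SPLITS)).astype(int)
    datasets = []
    for pid, grp in table.groupby("participant_id", sort=False):
        grp = grp.sort_values("trial_index").reset_index(drop=True)
        datasets.append(ParticipantDataset(participant_id=str(pid), trials=grp))
    return datasets


def read_truth_sidecar(path: Union[str, Path]) -> Dict[str, Dict]:
    obj = json.loads(Path(path).read_text(encoding="utf-8"))
    return obj["truth"]


def write_json(obj: Dict, path: Union[str, Path],
               seed: Optional[int] = None,
               config: Optional[RunConfig] = None) -> None:
    out = dict(obj)
    if seed is not None:
        out.setdefault("seed", seed)
    if config is not None:
        out.setdefault("config_hash", config.hash())
    Path(path).write_text(json.dumps(out, indent=2, default=float),
                          encoding="utf-8")


def write_table(table: pd.DataFrame, path: Union[str, Path],
                seed: Optional[int] = None,
                config: Optional[RunConfig] = None) -> None:
    header = config_header(config, seed)
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(header + "\n")
        table.to_csv(fh, index=False)
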