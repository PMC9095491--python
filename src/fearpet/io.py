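"""File formats and run configuration.

Two TSV dialects are shared across the package (UTF-8, tab-separated, one
header line):

- TAC tables: ``frame_start_min  frame_end_min  activity_kBq_per_mL``
- SCR trial tables: ``trial_index  cs_type  reinforced  amplitude_uS``

Run configuration is a flat YAML mapping; a run's resolved configuration is
always echoed next to its outputs so any result can be reproduced from
(inputs, config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import FrameSchedule, InputModel, NoiseModel, DEFAULT_KINETICS

logger = logging.getLogger("fearpet")

__all__ = ["RunConfig", "read_tac_tsv", "write_tac_tsv",
           "read_scr_tsv", "write_scr_tsv", "TAC_COLUMNS", "SCR_COLUMNS"]

TAC_COLUMNS = ["frame_start_min", "frame_end_min", "activity_kBq_per_mL"]
SCR_COLUMNS = ["trial_index", "cs_type", "reinforced", "amplitude_uS"]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def write_tac_tsv(path, tac: np.ndarray, frames: FrameSchedule) -> None:
    df = pd.DataFrame({TAC_COLUMNS[0]: frames.starts,
                       TAC_COLUMNS[1]: frames.ends,
                       TAC_COLUMNS[2]: np.asarray(tac, dtype=float)})
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_tac_tsv(path) -> tuple[np.ndarray, FrameSchedule]:
    """Read a TAC table, validating the header and frame monotonicity."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TAC_COLUMNS:
            raise ParseError(f"{path}:1: expected header "
                             f"{chr(9).join(TAC_COLUMNS)!r}")
        starts, ends, vals = [], [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            try:
                s, e, v = (float(c) for c in cells)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cell") from exc
            starts.append(s)
            ends.append(e)
            vals.append(v)
    try:
        frames = FrameSchedule(np.array(starts), np.array(ends))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return np.array(vals), frames


def write_scr_tsv(path, table: pd.DataFrame) -> None:
    table[SCR_COLUMNS].to_csv(path, sep="\t", index=False,
                              float_format="%.17g")


def read_scr_tsv(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != SCR_COLUMNS:
        raise ParseError(f"{path}:1: expected header "
                         f"{chr(9).join(SCR_COLUMNS)!r}")
    if not set(df["cs_type"].unique()) <= {"+", "-"}:
        raise ParseError(f"{path}: cs_type must be '+' or '-'")
    if (df["amplitude_uS"] < 0).any():
        raise ParseError(f"{path}: negative amplitude")
    return df


@dataclass
class RunConfig:
    """Resolved settings of one run, fully serialisable to YAML."""

    kinetics: dict = field(default_factory=lambda: dict(DEFAULT_KINETICS))
    n_frames: int = 18
    frame_min: float = 5.0
    noise_alpha: float = NoiseModel().alpha
    baseline_window: tuple[float, float] = (0.0, 50.0)
    post_window: tuple[float, float] = (70.0, 90.0)
    t_on: float = 50.0
    t_off: float = 70.0
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    def frames(self) -> FrameSchedule:
        return FrameSchedule.default(self.n_frames, self.frame_min)

    def noise(self) -> NoiseModel:
        return NoiseModel(alpha=self.noise_alpha)

    def input_model(self) -> InputModel:
        return InputModel()

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["baseline_window"] = list(self.baseline_window)
        d["post_window"] = list(self.post_window)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        for key in ("baseline_window", "post_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def echo(self, out_dir=None) -> None:
        """Write the resolved config next to the outputs and log it."""
        out = Path(out_dir or self.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_yaml(out / "run_config.yaml")
        logger.info("resolved config: %s", asdict(self))
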