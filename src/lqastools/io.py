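"""Survey-table I/O, bundled example data, and run configuration.

Survey tables travel as CSV with the header ``sa_id,successes,sampled``.
The two rounds of the Nepal oral-rehydration-solution (ORS) survey — seven
supervision areas, nineteen mothers sampled per area — ship with the
package both as module constants and as CSV files, so every worked example
runs without downloads.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .priors import BetaPrior, SurveyTable, beta_from_mean_sd

__all__ = [
    "read_survey_csv",
    "write_survey_csv",
    "nepal_survey",
    "parse_prior_spec",
    "RunConfig",
    "NEPAL_ROUNDS",
]

log = logging.getLogger("lqastools")

REQUIRED_COLUMNS = ("sa_id", "successes", "sampled")

#: Nepal ORS correct-preparation counts per SA (n = 19 sampled per SA).
NEPAL_ROUNDS = {
    "jan1999": (7, 7, 12, 9, 11, 16, 8),
    "jan2000": (7, 9, 14, 13, 17, 19, 12),
}
NEPAL_N = 19


def nepal_survey(survey_round: str = "jan2000") -> SurveyTable:
    """The bundled Nepal ORS survey for one round ("jan1999" or "jan2000")."""
    if survey_round not in NEPAL_ROUNDS:
        raise ValueError(
            f"unknown round {survey_round!r}; choose from {sorted(NEPAL_ROUNDS)}"
        )
    return SurveyTable.from_counts(NEPAL_ROUNDS[survey_round], NEPAL_N)


def nepal_csv_path(survey_round: str = "jan2000") -> Path:
    """Path of the packaged CSV fixture for one Nepal round."""
    if survey_round not in NEPAL_ROUNDS:
        raise ValueError(
            f"unknown round {survey_round!r}; choose from {sorted(NEPAL_ROUNDS)}"
        )
    return Path(str(resources.files("lqastools") / "data" / f"nepal_{survey_round}.csv"))


def read_survey_csv(path) -> SurveyTable:
    """Read and validate a survey table from CSV.

    The file must carry the header ``sa_id,successes,sampled``; rows with
    ``successes > sampled`` (or negative counts) are rejected with a
    row-indexed message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"survey file not found: {path}")
    frame = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; "
            f"expected header {','.join(REQUIRED_COLUMNS)}"
        )
    if frame.empty:
        raise ValueError(f"{path}: survey file has no data rows")
    for col in ("successes", "sampled"):
        if frame[col].isna().any() or not pd.api.types.is_numeric_dtype(frame[col]):
            bad = int(frame.index[frame[col].isna()][0]) if frame[col].isna().any() else 0
            raise ValueError(f"{path}: row {bad}: column {col!r} must be an integer")
    try:
        return SurveyTable.from_frame(frame)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


def write_survey_csv(survey: SurveyTable, path) -> None:
    survey.to_frame().to_csv(path, index=False)


def parse_prior_spec(text: str) -> BetaPrior:
    """Parse a prior given as shapes "a,b" or as moments "mean=0.68,sd=0.09"."""
    text = text.strip()
    if "=" in text:
        fields: dict[str, float] = {}
        for part in text.split(","):
            key, _, value = part.partition("=")
            try:
                fields[key.strip()] = float(value)
            except ValueError as err:
                raise ValueError(f"bad prior spec {text!r}: {part!r}") from err
        if set(fields) != {"mean", "sd"}:
            raise ValueError(
                f"bad prior spec {text!r}: moment form needs exactly mean=...,sd=..."
            )
        return beta_from_mean_sd(fields["mean"], fields["sd"])
    parts = text.split(",")
    if len(parts) != 2:
        raise ValueError(
            f"bad prior spec {text!r}: expected 'a,b' or 'mean=...,sd=...'"
        )
    try:
        a, b = (float(p) for p in parts)
    except ValueError as err:
        raise ValueError(f"bad prior spec {text!r}: shapes must be numbers") from err
    return BetaPrior(a, b)


def _require(mapping: dict, key: str, context: str) -> Any:
    if key not in mapping:
        raise ValueError(f"config {context}: missing required field {key!r}")
    return mapping[key]


@dataclass(frozen=True)
class RunConfig:
    """A validated end-to-end run configuration.

    ``design`` holds the risk parameters (and optionally a fixed ``n``/``d``),
    ``priors`` a list of labelled Beta priors for the accuracy report, and
    ``posthoc`` the survey path, interval and bootstrap settings.
    """

    design: dict = field(default_factory=dict)
    priors: list = field(default_factory=list)
    posthoc: dict = field(default_factory=dict)
    output_dir: Path | None = None

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path) as fh:
            if path.suffix.lower() == ".json":
                raw = json.load(fh)
            else:
                raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"config {path}: top level must be a mapping")
        return cls.from_mapping(raw, context=str(path))

    @classmethod
    def from_mapping(cls, raw: dict, context: str = "<config>") -> "RunConfig":
        design = dict(raw.get("design", {}))
        if design:
            for key in ("p_l", "p_u", "alpha_max", "beta_max"):
                value = _require(design, key, context)
                if not isinstance(value, (int, float)) or not 0 < float(value) < 1:
                    raise ValueError(
                        f"config {context}: design.{key} must be a number in (0, 1); "
                        f"got {value!r}"
                    )
        priors = []
        for i, entry in enumerate(raw.get("priors", [])):
            if isinstance(entry, str):
                label, spec = entry, entry
            elif isinstance(entry, dict) and {"label", "spec"} <= set(entry):
                label, spec = str(entry["label"]), str(entry["spec"])
            else:
                raise ValueError(
                    f"config {context}: priors[{i}] must be a spec string or a "
                    "mapping with 'label' and 'spec'"
                )
            try:
                priors.append((label, parse_prior_spec(spec)))
            except ValueError as err:
                raise ValueError(f"config {context}: priors[{i}]: {err}") from err
        posthoc = dict(raw.get("posthoc", {}))
        if posthoc:
            survey = _require(posthoc, "survey", context)
            if not Path(survey).exists():
                raise ValueError(
                    f"config {context}: posthoc.survey file does not exist: {survey}"
                )
        out = raw.get("output_dir")
        return cls(
            design=design,
            priors=priors,
            posthoc=posthoc,
            output_dir=Path(out) if out else None,
        )
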