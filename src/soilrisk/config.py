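"""YAML configuration loading for standards, grading, toxicity and exposure.

Package-shipped defaults live under ``soilrisk/data``; every loader takes
an optional path to override them with a user file of the same schema.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .distributions import DistributionSpec
from .health_risk import ExposureParameters, ToxicityTable
from .pollution import GradeScheme, ScreeningStandard

__all__ = [
    "load_screening_standard",
    "load_grade_scheme",
    "load_toxicity_table",
    "load_exposure_parameters",
    "parse_spec",
]


def _load_yaml(path: Optional[str | Path], default_name: str) -> dict:
    if path is not None:
        return yaml.safe_load(Path(path).read_text())
    ref = resources.files("soilrisk.data").joinpath(default_name)
    return yaml.safe_load(ref.read_text())


def parse_spec(value):
    """A scalar stays fixed; {family, params} becomes a DistributionSpec."""
    if isinstance(value, dict):
        return DistributionSpec(value["family"], tuple(value["params"]))
    return float(value)


def load_screening_standard(path: Optional[str | Path] = None) -> ScreeningStandard:
    return ScreeningStandard.from_dict(_load_yaml(path, "screening.yaml"))


def load_grade_scheme(path: Optional[str | Path] = None) -> GradeScheme:
    d = _load_yaml(path, "grades.yaml")
    return GradeScheme(breaks=tuple(d["breaks"]), labels=tuple(d["labels"]))


def load_toxicity_table(path: Optional[str | Path] = None) -> ToxicityTable:
    d = _load_yaml(path, "toxicity.yaml")
    return ToxicityTable(rfd=d["rfd"], sf=d["sf"])


def load_exposure_parameters(
    cohort: str, path: Optional[str | Path] = None
) -> ExposureParameters:
    d = _load_yaml(path, "exposure.yaml")
    if cohort not in d:
        raise KeyError(f"cohort {cohort!r} not in exposure config")
    c = d[cohort]
    return ExposureParameters(
        cohort=cohort,
        IRing=parse_spec(c["IRing"]),
        EF=parse_spec(c["EF"]),
        ED=parse_spec(c["ED"]),
        BW=parse_spec(c["BW"]),
        AF=parse_spec(c["AF"]),
        SA=parse_spec(c["SA"]),
        ABS=parse_spec(c["ABS"]),
    )
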