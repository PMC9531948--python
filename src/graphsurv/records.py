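"""Patient-level clinical record and the controlled vocabularies it uses.

One record corresponds to one node of the population graph: demographics,
tumour location, histology, pathological TNM sub-stage, and the two survival
endpoints (overall survival and recurrence-free survival), each as an
observed time in months plus an event indicator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

SEXES = ("male", "female")
HISTOLOGIES = ("adenocarcinoma", "squamous", "other")
LOBES = ("LUL", "LLL", "RUL", "RML", "RLL")
STAGES = ("IA", "IB", "IIA", "IIB")
SPLITS = ("train", "val", "test")

#: Ordinal coding of the pTNM sub-stage, used both by the synthetic-cohort
#: generator's hazard model and by the stage-only baseline risk score.
STAGE_ORDINAL = {s: i for i, s in enumerate(STAGES)}


class RecordValidationError(ValueError):
    """A patient record violates the schema (vocabulary, sign, missing field)."""


@dataclass(frozen=True)
class PatientRecord:
    """Clinical covariates and survival endpoints for one patient.

    Times are in months from surgery; events are 1 if the endpoint was
    observed and 0 if follow-up was censored.
    """

    id: str
    age: float
    sex: str
    histology: str
    lobe: str
    stage: str
    os_time: float
    os_event: int
    rfs_time: float
    rfs_event: int
    split: Optional[str] = None

    def validate(self) -> list:
        """Return a list of human-readable schema violations (empty if valid)."""
        errs = []
        if not self.id:
            errs.append("empty id")
        if not (0 <= self.age <= 130):
            errs.append(f"age {self.age!r} outside [0, 130]")
        if self.sex not in SEXES:
            errs.append(f"sex {self.sex!r} not in {SEXES}")
        if self.histology not in HISTOLOGIES:
            errs.append(f"histology {self.histology!r} not in {HISTOLOGIES}")
        if self.lobe not in LOBES:
            errs.append(f"lobe {self.lobe!r} not in {LOBES}")
        if self.stage not in STAGES:
            errs.append(f"stage {self.stage!r} not in {STAGES} (cohort is stage I-II)")
        for name, t in (("os_time", self.os_time), ("rfs_time", self.rfs_time)):
            if not t >= 0:
                errs.append(f"{name} {t!r} is negative")
        for name, e in (("os_event", self.os_event), ("rfs_event", self.rfs_event)):
            if e not in (0, 1):
                errs.append(f"{name} {e!r} not in {{0, 1}}")
        if self.split is not None and self.split not in SPLITS:
            errs.append(f"split {self.split!r} not in {SPLITS}")
        # RFS after OS with both events observed is suspicious but occurs in
        # real registries; warn rather than reject.
        if not errs and self.os_event == 1 and self.rfs_event == 1 and self.rfs_time > self.os_time:
            warnings.warn(
                f"record {self.id}: rfs_time {self.rfs_time} > os_time {self.os_time} "
                "with both events observed",
                stacklevel=2,
            )
        return errs

    def validated(self) -> "PatientRecord":
        errs = self.validate()
        if errs:
            raise RecordValidationError(f"record {self.id!r}: " + "; ".join(errs))
        return self

    def with_split(self, split: str) -> "PatientRecord":
        return replace(self, split=split)

    @property
    def stage_ordinal(self) -> int:
        return STAGE_ORDINAL[self.stage]
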