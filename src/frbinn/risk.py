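"""Cancer-propensity classification of chronic inflammatory diseases.

A disease is *cancer-prone* (CP-CID) when any of its reported epidemiological
effect sizes exceeds its threshold:

    prone  ⇔  (RR > 2) ∨ (HR > 2) ∨ (SIR > 1.4)

with RR the relative risk, HR the hazard ratio and SIR the standardized
incidence ratio; all comparisons are strict, absent statistics contribute
nothing, and diseases documented only through an inverse association with
cancer carry a ``protective`` flag that forces *not prone*.  The shipped
reference registry encodes nine diseases with published effect sizes and
splits them 5 NCP / 4 CP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

RR_THRESHOLD = 2.0
HR_THRESHOLD = 2.0
SIR_THRESHOLD = 1.4

PRONE = "prone"
NOT_PRONE = "not_prone"


class InsufficientEvidenceError(ValueError):
    """No statistic and no protective flag: the rule cannot decide."""


@dataclass(frozen=True)
class DiseaseStats:
    """One disease's epidemiological evidence; absent values are ``None``."""

    name: str
    rr: Optional[float] = None
    hr: Optional[float] = None
    sir: Optional[float] = None
    protective: bool = False
    group: str = "inflammatory"

    def __post_init__(self) -> None:
        for label, value in (("RR", self.rr), ("HR", self.hr), ("SIR", self.sir)):
            if value is not None and value <= 0:
                raise ValueError(f"{self.name}: {label} must be positive, got {value}")


@dataclass(frozen=True)
class DiseaseRegistry:
    diseases: tuple[DiseaseStats, ...]

    def __post_init__(self) -> None:
        names = [d.name for d in self.diseases]
        if len(set(names)) != len(names):
            raise ValueError("disease names must be unique")

    def inflammatory(self) -> list[DiseaseStats]:
        return [d for d in self.diseases if d.group == "inflammatory"]


def classify_propensity(stats: DiseaseStats) -> str:
    """Apply the prone/not-prone rule to one disease.

    Strict thresholds: RR > 2, HR > 2, SIR > 1.4.  The protective flag wins
    regardless of any value.  Raises :class:`InsufficientEvidenceError` when
    every statistic is absent and the flag is unset.
    """
    if stats.protective:
        return NOT_PRONE
    if stats.rr is None and stats.hr is None and stats.sir is None:
        raise InsufficientEvidenceError(
            f"{stats.name}: insufficient evidence (no RR/HR/SIR and no protective flag)"
        )
    if (
        (stats.rr is not None and stats.rr > RR_THRESHOLD)
        or (stats.hr is not None and stats.hr > HR_THRESHOLD)
        or (stats.sir is not None and stats.sir > SIR_THRESHOLD)
    ):
        return PRONE
    return NOT_PRONE


def classify_registry(registry: DiseaseRegistry) -> tuple[dict[str, str], dict[str, int]]:
    """Classify every inflammatory disease; return per-disease category and counts.

    Per-disease errors propagate with the disease name (it is already in the
    message raised by :func:`classify_propensity`).
    """
    categories = {d.name: classify_propensity(d) for d in registry.inflammatory()}
    counts = {
        "CP-CID": sum(1 for v in categories.values() if v == PRONE),
        "NCP-CID": sum(1 for v in categories.values() if v == NOT_PRONE),
    }
    return categories, counts


def reference_registry() -> DiseaseRegistry:
    """The nine-disease registry with published effect sizes.

    Asthma HR 1.36; Alzheimer's disease inverse association; Psoriasis RR
    1.21; irritable bowel syndrome reduced colorectal-cancer risk; rheumatoid
    arthritis SIR 1.20; ulcerative colitis SIR 2.4 and RR 2.4; Crohn's
    disease RR 2.5; non-alcoholic steatohepatitis HR 7.62; hepatitis B HR
    15.77.
    """
    return DiseaseRegistry(
        diseases=(
            DiseaseStats("Asthma", hr=1.36),
            DiseaseStats("Alzheimer's disease", protective=True),
            DiseaseStats("Psoriasis", rr=1.21),
            DiseaseStats("Irritable bowel syndrome", protective=True),
            DiseaseStats("Rheumatoid arthritis", sir=1.20),
            DiseaseStats("Ulcerative colitis", sir=2.4, rr=2.4),
            DiseaseStats("Crohn's disease", rr=2.5),
            DiseaseStats("Non-alcoholic steatohepatitis", hr=7.62),
            DiseaseStats("Hepatitis B virus", hr=15.77),
        )
    )
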