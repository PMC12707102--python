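"""The nine key shared-decision-making concepts for localized prostate cancer.

AUA guidelines recommend that treatment consultations cover five content
areas; coded at sentence level these decompose into nine binary concepts:
cancer severity (tumor risk, pathology results), life expectancy, cancer
prognosis, baseline function (urinary, erectile), and treatment side
effects (erectile dysfunction, urinary incontinence, irritative lower
urinary tract symptoms).
"""

from __future__ import annotations

from enum import Enum


class Concept(str, Enum):
    """Key SDM concept codes, in canonical reporting order."""

    TR = "TR"  # tumor risk
    PR = "PR"  # pathology results
    LE = "LE"  # life expectancy
    CP = "CP"  # cancer prognosis
    UF = "UF"  # baseline urinary function
    EF = "EF"  # baseline erectile function
    ED = "ED"  # erectile dysfunction (side effect)
    UI = "UI"  # urinary incontinence (side effect)
    LUTS = "LUTS"  # irritative lower urinary tract symptoms (side effect)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical ordering used everywhere (reports, files, rankings).
CONCEPTS: tuple[Concept, ...] = tuple(Concept)

CONCEPT_NAMES: dict[Concept, str] = {
    Concept.TR: "Tumor Risk",
    Concept.PR: "Pathology Results",
    Concept.LE: "Life Expectancy",
    Concept.CP: "Cancer Prognosis",
    Concept.UF: "Urinary Function",
    Concept.EF: "Erectile Function",
    Concept.ED: "Erectile Dysfunction",
    Concept.UI: "Urinary Incontinence",
    Concept.LUTS: "Irritative Lower Urinary Tract Symptoms",
}
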