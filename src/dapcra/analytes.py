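"""Dialkylphosphate (DAP) metabolite definitions.

Urinary DAPs are the non-specific metabolites of organophosphate
pesticides.  Six are routinely measured: the dimethyl series (DMP,
DMTP, DMDTP) and the diethyl series (DEP, DETP, DEDTP).  Molecular
weights are those of the free acids, since the urinary analyte is the
acid/anion rather than the potassium salt used as a calibration
standard.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

AlkylClass = Literal["dimethyl", "diethyl"]

#: Canonical column order for the six DAP metabolites.
ANALYTE_ORDER = ("DMP", "DMTP", "DMDTP", "DEP", "DETP", "DEDTP")

#: The five analytes that enter molar sums; DEDTP is excluded when its
#: detected count falls at or below the exclusion threshold.
DOSE_ANALYTES = ("DMP", "DMTP", "DMDTP", "DEP", "DETP")


@dataclass(frozen=True)
class AnalyteDefinition:
    """Identity and physical constants of one DAP metabolite.

    Parameters
    ----------
    code : str
        One of ``DMP, DMTP, DMDTP, DEP, DETP, DEDTP``.
    molecular_weight : float
        Free-acid molecular weight in g/mol.
    mrl : float
        Minimum reporting level in ng/mL; measurements below it are
        reported as nondetects.
    alkyl_class : {"dimethyl", "diethyl"}
        Which molar sum (DMs or DEs) the analyte contributes to.
    """

    code: str
    molecular_weight: float
    mrl: float
    alkyl_class: AlkylClass

    def __post_init__(self) -> None:
        if self.code not in ANALYTE_ORDER:
            raise ValueError(f"unknown analyte code {self.code!r}")
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be positive")
        if self.mrl <= 0:
            raise ValueError("mrl must be positive")
        expected = "dimethyl" if self.code.startswith("DM") else "diethyl"
        if self.alkyl_class != expected:
            raise ValueError(
                f"{self.code} must have alkyl_class {expected!r}, "
                f"got {self.alkyl_class!r}"
            )


def default_analytes() -> dict[str, AnalyteDefinition]:
    """The six DAP metabolites with free-acid molecular weights and
    default minimum reporting levels (0.997 ng/mL, except DETP at
    1.2 ng/mL whose per-batch limit may also be 1.3 ng/mL)."""
    defs = [
        AnalyteDefinition("DMP", 126.05, 0.997, "dimethyl"),
        AnalyteDefinition("DMTP", 142.11, 0.997, "dimethyl"),
        AnalyteDefinition("DMDTP", 158.18, 0.997, "dimethyl"),
        AnalyteDefinition("DEP", 154.10, 0.997, "diethyl"),
        AnalyteDefinition("DETP", 170.17, 1.2, "diethyl"),
        AnalyteDefinition("DEDTP", 186.24, 0.997, "diethyl"),
    ]
    return {a.code: a for a in defs}


def default_mrls() -> dict[str, float]:
    """Per-analyte default minimum reporting levels (ng/mL)."""
    return {code: a.mrl for code, a in default_analytes().items()}
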