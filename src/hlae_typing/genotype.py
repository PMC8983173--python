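"""Shared genotype-call vocabulary for the three detection methods."""

from __future__ import annotations

from dataclasses import dataclass

GG = "G/G"
GT = "G/T"
TT = "T/T"
UNKNOWN = "UNKNOWN"

GENOTYPES = (GG, GT, TT)
CALL_VALUES = frozenset((*GENOTYPES, UNKNOWN))

SBT = "SBT"
TAQMAN = "TAQMAN"
HRM = "HRM"
METHODS = frozenset((SBT, TAQMAN, HRM))

#: Raised by the HRM caller when no catalogued reference curve is close enough;
#: the well likely carries a mutation elsewhere in the amplicon.
VARIANT_SUSPECTED = "VARIANT_SUSPECTED"


def het_label(ref_base: str, alt_base: str) -> str:
    """Single unordered representation of the heterozygote, ref base first."""
    return f"{ref_base}/{alt_base}"


@dataclass(frozen=True)
class GenotypeCall:
    """One genotype call at a named site, with its method of provenance."""

    sample_id: str
    site_label: str
    genotype: str
    method: str
    flag: str | None = None

    def __post_init__(self) -> None:
        if self.genotype not in CALL_VALUES:
            raise ValueError(f"invalid genotype {self.genotype!r}")
        if self.method not in METHODS:
            raise ValueError(f"invalid method {self.method!r}")
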