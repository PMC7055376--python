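"""The three condensin-complex gene classes surveyed by the pipeline."""

from __future__ import annotations

import enum


class TargetClass(enum.Enum):
    """Gene classes of the prokaryotic condensin-like Smc-ScpAB complex.

    SMC is the ATPase subunit, SCPA the kleisin bridging the two SMC head
    domains, and SCPB the kite subunit that in bacteria binds the kleisin
    middle region.
    """

    SMC = "smc"
    SCPA = "scpA"
    SCPB = "scpB"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


ALL_TARGETS: tuple[TargetClass, ...] = (
    TargetClass.SMC,
    TargetClass.SCPA,
    TargetClass.SCPB,
)
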