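"""Spin-echo signal model linking relaxation parameters to weighted signals.

An optional forward layer for deriving plausible agent effect fractions
from physical parameters.  The idealized spin-echo equation

    S = PD * (1 - exp(-TR/T1)) * exp(-TE/T2)

is used for both weightings; RARE echo-train and MESE multi-echo effects,
flip angles and B0/B1 inhomogeneity are deliberately ignored.  An agent at
concentration C adds to the relaxation rates:

    1/T1' = 1/T1 + r1*C,    1/T2' = 1/T2 + r2*C

where r1, r2 are the relaxivities (rate-increase slopes per unit
concentration — distinct from the bare rates 1/T1, 1/T2).  Relaxivities of
the dual-action NaDyF4/NaGdF4 core/shell nanoparticles are given per
nanoparticle-molar concentration, so concentrations here are expressed in
those same units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError
from .phantom import AgentEffect


@dataclass(frozen=True)
class SequenceParams:
    """Echo time and repetition time of a spin-echo acquisition (seconds)."""

    te: float
    tr: float
    label: str = "custom"

    def __post_init__(self) -> None:
        if not 0 < self.te < self.tr:
            raise ValidationError("sequence requires 0 < TE < TR")


#: T1w RARE preset: TE 7 ms, TR 750 ms.
T1W_RARE = SequenceParams(te=0.007, tr=0.750, label="t1w_rare")
#: T2w MESE preset: TE 35 ms, TR 5000 ms.
T2W_MESE = SequenceParams(te=0.035, tr=5.000, label="t2w_mese")


@dataclass(frozen=True)
class TissueRelaxation:
    """Proton density (au) and relaxation times (seconds) of a tissue."""

    pd: float
    t1: float
    t2: float

    def __post_init__(self) -> None:
        if self.t2 <= 0 or self.t1 < self.t2:
            raise ValidationError("relaxation times must satisfy t1 >= t2 > 0")
        if self.pd < 0:
            raise ValidationError("proton density must be >= 0")


@dataclass(frozen=True)
class Relaxivity:
    """Agent relaxivities r1, r2 (mM^-1 s^-1) and concentration (mM).

    For the dual-action nanoparticle class modeled here r2 >= r1.
    Measured values for NaDyF4/NaGdF4 core/shell particles in water:
    r1 = 9.0e5, r2 = 147.0e5 mM^-1 s^-1 (per nanoparticle concentration).
    """

    r1: float
    r2: float
    concentration: float

    def __post_init__(self) -> None:
        if self.r1 < 0 or self.r2 < 0 or self.concentration < 0:
            raise ValidationError("relaxivities and concentration must be >= 0")
        if self.r2 < self.r1:
            raise ValidationError("expected r2 >= r1 for this agent class")


#: Measured relaxivities of the NaDyF4/NaGdF4 core/shell agent (zero dose).
NADYF4_NAGDF4 = Relaxivity(r1=9.0e5, r2=147.0e5, concentration=0.0)


def shorten_relaxation(base: TissueRelaxation, agent: Relaxivity) -> TissueRelaxation:
    """Relaxation times after adding the agent's rate contributions.

    1/T1' = 1/T1 + r1*C and 1/T2' = 1/T2 + r2*C; proton density unchanged.
    """
    if agent.concentration == 0:
        return base
    t1 = 1.0 / (1.0 / base.t1 + agent.r1 * agent.concentration)
    t2 = 1.0 / (1.0 / base.t2 + agent.r2 * agent.concentration)
    return TissueRelaxation(pd=base.pd, t1=t1, t2=t2)


def se_signal(tissue: TissueRelaxation, seq: SequenceParams) -> float:
    """Idealized spin-echo signal PD * (1 - exp(-TR/T1)) * exp(-TE/T2)."""
    return (tissue.pd
            * (1.0 - math.exp(-seq.tr / tissue.t1))
            * math.exp(-seq.te / tissue.t2))


def predicted_fraction(tissue: TissueRelaxation, agent: Relaxivity,
                       seq: SequenceParams) -> float:
    """Fractional signal change the agent produces under a sequence.

    Returns f such that the post-agent signal equals (1 + f) times the
    baseline — the bridge from physics to the phantom's agent-effect
    abstraction.
    """
    s0 = se_signal(tissue, seq)
    if s0 == 0:
        raise ValidationError("baseline signal is zero; fraction undefined")
    return se_signal(shorten_relaxation(tissue, agent), seq) / s0 - 1.0


def predicted_effect(tumor: TissueRelaxation, agent: Relaxivity,
                     seq_t1w: SequenceParams = T1W_RARE,
                     seq_t2w: SequenceParams = T2W_MESE,
                     name: str = "physics") -> AgentEffect:
    """AgentEffect for a tumor-targeted agent from the spin-echo model."""
    return AgentEffect(
        name=name,
        f_t1w_tumor=predicted_fraction(tumor, agent, seq_t1w),
        f_t2w_tumor=predicted_fraction(tumor, agent, seq_t2w),
    )
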