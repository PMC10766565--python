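"""Restraint free-energy corrections.

An always-on harmonic restraint 1/2 k ζ² applied during the umbrella runs is
removed afterwards with the correction

    ΔU = -RT ln [ <e^{-kζ²/2RT}>_bulk / <e^{-kζ²/2RT}>_pocket ]

where each average is taken under the 1-D PMF of ζ measured (or known
analytically) in the bulk and in the binding pocket.  Nested restraints are
removed one at a time, innermost last: each term's PMFs must be measured
with exactly the outer restraints still applied, which is why conditioning
metadata is carried explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import rt
from .orientation import OrientationPMF, restraint_average_from_pmf
from .pmf import PMFProfile

PMFLike = OrientationPMF | PMFProfile


@dataclass
class RestraintCorrection:
    cv: str
    k: float
    du: float                       # kcal/mol
    du_err: float = 0.0
    conditioned_on: list[str] = field(default_factory=list)


@dataclass
class ChainedRestraint:
    """One link of a restraint chain: the restrained CV, its force constant,
    and the pocket/bulk PMFs measured with ``conditioned_on`` still applied."""

    cv: str
    k: float
    pocket_pmf: PMFLike
    bulk_pmf: PMFLike
    conditioned_on: list[str] = field(default_factory=list)


@dataclass
class RestraintChain:
    """Ordered restraints, first element removed first; element i's PMFs must
    be conditioned on the CVs of all later elements (still restrained)."""

    restraints: list[ChainedRestraint]

    def validate(self) -> None:
        for i, link in enumerate(self.restraints):
            expected = sorted(r.cv for r in self.restraints[i + 1 :])
            if sorted(link.conditioned_on) != expected:
                raise ValueError(
                    f"restraint {link.cv!r}: conditioned_on {link.conditioned_on} "
                    f"inconsistent with chain order (expected {expected})"
                )


def restraint_correction(
    pocket_pmf: PMFLike,
    bulk_pmf: PMFLike,
    k: float,
    temperature: float,
    cv: str = "cv",
    conditioned_on: list[str] | None = None,
) -> RestraintCorrection:
    """ΔU for a single always-on restraint from its pocket and bulk PMFs.

    Positive when the restraint penalizes the bulk more than the pocket
    (the usual case: the pocket already confines ζ).  Swapping the two PMFs
    flips the sign exactly; identical PMFs give 0.
    """
    avg_bulk = restraint_average_from_pmf(bulk_pmf, k, temperature)
    avg_pocket = restraint_average_from_pmf(pocket_pmf, k, temperature)
    du = float(-rt(temperature) * np.log(avg_bulk / avg_pocket))
    return RestraintCorrection(
        cv=cv, k=k, du=du, conditioned_on=list(conditioned_on or [])
    )


def chain_corrections(
    chain: RestraintChain, temperature: float
) -> list[RestraintCorrection]:
    """Corrections for a chain of nested restraints, in removal order.

    A single-element chain reduces to the single-restraint correction; a
    chain (γ, β, α) yields [ΔU_γ, ΔU_β^γ, ΔU_α^{β,γ}].
    """
    chain.validate()
    out = []
    for link in chain.restraints:
        out.append(
            restraint_correction(
                link.pocket_pmf,
                link.bulk_pmf,
                link.k,
                temperature,
                cv=link.cv,
                conditioned_on=link.conditioned_on,
            )
        )
    return out
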