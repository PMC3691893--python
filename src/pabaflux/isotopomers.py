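"""Acetyl ¹³C-isotopomer enrichments from N-acetyl-PABA multiplet areas.

The methyl (carbon 2) resonance is quantified against the natural-abundance
aromatic reference carbons of the PABA moiety:

    total C2 enrichment (%) = (C2 area / per-carbon aromatic area) × CF × 1.11

where CF is the empirical correction factor from a nonenriched standard
(see :func:`pabaflux.nmr.correction_factor`).  The singlet/doublet split of
the C2 resonance then resolves the [2-¹³C] and [1,2-¹³C₂] species, natural
abundance (1.11%) is subtracted from the singly labeled totals, and the
carbon-1 quantities are anchored to carbon 2 through the shared [1,2-¹³C₂]
doublet:

    total C1 enrichment (%) = total [1,2-¹³C₂] enrichment × C1/C1D.

The doubly labeled species needs no background correction: the probability
of two adjacent natural-abundance ¹³C nuclei (~0.012%) is negligible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

from .nmr import MultipletAreas, NATURAL_ABUNDANCE_PCT, QuantificationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AcetylIsotopomerProfile:
    """Total and excess acetyl ¹³C enrichments, in percent.

    Invariants: ``total_c2 = total_2_13c + total_12_13c2``,
    ``total_c1 = total_1_13c + total_12_13c2``; excesses of the singly
    labeled species are totals minus natural abundance (floored at 0);
    ``excess_12_13c2 = total_12_13c2``.
    """

    total_c1: float
    total_c2: float
    total_1_13c: float
    total_2_13c: float
    total_12_13c2: float
    excess_1_13c: float
    excess_2_13c: float
    excess_12_13c2: float
    natural_abundance: float = NATURAL_ABUNDANCE_PCT

    def __post_init__(self) -> None:
        for name in ("total_c1", "total_c2", "total_1_13c", "total_2_13c",
                     "total_12_13c2", "excess_1_13c", "excess_2_13c",
                     "excess_12_13c2"):
            if getattr(self, name) < 0:
                raise QuantificationError(f"{name} must be >= 0")

    @property
    def excesses(self) -> tuple[float, float, float]:
        """(excess [1-¹³C], excess [2-¹³C], excess [1,2-¹³C₂]), percent."""
        return (self.excess_1_13c, self.excess_2_13c, self.excess_12_13c2)

    def to_json(self, path: str | Path) -> None:
        payload = {"units": "% enrichment", **asdict(self)}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AcetylIsotopomerProfile":
        data = json.loads(Path(path).read_text())
        data.pop("units", None)
        return cls(**data)


def total_c2_enrichment(areas: MultipletAreas) -> float:
    """Total carbon-2 ¹³C enrichment, percent.

    The published form of this relation carries an extra ×100 that would
    make a nonenriched sample read 111%; it is implemented as
    ratio × CF × 1.11 with the natural abundance already expressed in
    percent, the only reading under which the nonenriched standard returns
    1.11% by construction of CF.
    """
    if areas.aromatic_per_carbon <= 0:
        raise QuantificationError("aromatic reference areas must be positive")
    return (areas.c2_total / areas.aromatic_per_carbon
            * areas.correction_factor * NATURAL_ABUNDANCE_PCT)


def split_c2(areas: MultipletAreas, total_c2: float) -> tuple[float, float]:
    """Resolve total C2 enrichment into ([2-¹³C], [1,2-¹³C₂]) totals via
    the singlet/doublet area fractions."""
    if areas.c2_total <= 0:
        raise QuantificationError("cannot split a zero C2 resonance")
    s = areas.c2_singlet / areas.c2_total
    d = areas.c2_doublet / areas.c2_total
    return (s * total_c2, d * total_c2)


def excess_singly_labeled(total: float,
                          natural_abundance: float = NATURAL_ABUNDANCE_PCT) -> float:
    """Excess enrichment of a singly labeled species: total − 1.11, floored.

    Totals below natural abundance (noise at low enrichment) are floored to
    zero with a logged warning, never silently returned negative.
    """
    if total < 0:
        raise QuantificationError("total enrichment must be >= 0")
    excess = total - natural_abundance
    if excess < 0:
        logger.warning(
            "total enrichment %.3f%% is below natural abundance %.2f%%; "
            "flooring excess at 0", total, natural_abundance)
        return 0.0
    return excess


def carbon1_from_doublet(areas: MultipletAreas,
                         total_12_13c2: float) -> tuple[float, float]:
    """Anchor the carbon-1 enrichments to the shared [1,2-¹³C₂] doublet.

    Returns ``(total_c1, total_1_13c)``.  The C1 and C2 doublets report the
    same doubly labeled pool, so total C1 = total [1,2-¹³C₂] × C1/C1D and
    the singlet fraction of C1 gives the [1-¹³C] total.  When both the
    doublet area and the doubly labeled enrichment vanish the anchor is
    undefined; the carbon-1 totals are then taken as natural abundance
    (zero excess), which is the correct reading for a nonenriched sample.
    """
    if areas.c1_doublet <= 0:
        if total_12_13c2 > 0:
            raise QuantificationError(
                "inconsistent multiplet data: [1,2-13C2] enrichment is "
                "positive but the C1 doublet area is zero")
        return (NATURAL_ABUNDANCE_PCT, NATURAL_ABUNDANCE_PCT)
    total_c1 = total_12_13c2 * areas.c1_total / areas.c1_doublet
    total_1_13c = total_12_13c2 * areas.c1_singlet / areas.c1_doublet
    return (total_c1, total_1_13c)


def quantify_profile(areas: MultipletAreas) -> AcetylIsotopomerProfile:
    """Full isotopomer profile from multiplet areas (composition of the
    enrichment, splitting, background-subtraction and C1-anchoring steps)."""
    total_c2 = total_c2_enrichment(areas)
    total_2, total_12 = split_c2(areas, total_c2)
    total_c1, total_1 = carbon1_from_doublet(areas, total_12)
    return AcetylIsotopomerProfile(
        total_c1=total_c1,
        total_c2=total_c2,
        total_1_13c=total_1,
        total_2_13c=total_2,
        total_12_13c2=total_12,
        excess_1_13c=excess_singly_labeled(total_1),
        excess_2_13c=excess_singly_labeled(total_2),
        excess_12_13c2=total_12,
    )
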