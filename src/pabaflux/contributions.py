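"""Substrate contributions to cytosolic acetyl-CoA from excess enrichments.

Under the drinking-water tracer design, [U-¹³C]fructose (half of the
fructose load) is catabolized to [U-¹³C]pyruvate and hence [1,2-¹³C₂]
acetyl-CoA, while [1-¹³C]glucose yields one [3-¹³C]pyruvate per molecule,
i.e. [2-¹³C]acetyl-CoA from half of the glucose-derived acetyl units.

Pyruvate cycling (PC–PEPCK/malic enzyme exchange with the symmetric
fumarate pool) scrambles the glucose label between the two acetyl carbons,
producing the observed [1-¹³C]acetyl.  The fructose estimate is immune to
this (cycled [U-¹³C]pyruvate still yields [1,2-¹³C₂]acetyl), but the
glucose contribution is only bracketed:

    upper = (e2 + e1) / g      # all [1-¹³C]acetyl from cycled glucose label
    lower = (e2 − e1) / g      # all [1-¹³C]acetyl from TCA-randomized label

with e1, e2 the excess [1-¹³C]/[2-¹³C] enrichments and g the labeled
fraction of glucose-derived acetyl (0.5).  If a fraction ``f`` of the
[1-¹³C]acetyl stems from cycled glucose label, the point estimate is the
affine interpolation (e2 + (2f−1)·e1)/g; TCA-cycle simulations put f near
0.5, the midpoint of the bounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from .isotopomers import AcetylIsotopomerProfile
from .nmr import QuantificationError


@dataclass(frozen=True)
class TracerScheme:
    """Probabilities that an acetyl unit derived from each drinking-water
    sugar carries its diagnostic isotopomer.

    With a 50/50 [U-¹³C]/unlabeled fructose mix, ``fructose_labeled_fraction``
    is 0.5; with [1-¹³C]glucose, half of the triose units carry the label, so
    ``glucose_labeled_fraction`` is 0.5 absent cycling.  ``tracer_purity``
    (0.99 for the commercial tracers) is applied only where explicitly
    requested; the default estimates match the uncorrected convention.
    """

    fructose_labeled_fraction: float = 0.5
    glucose_labeled_fraction: float = 0.5
    tracer_purity: float = 0.99

    def __post_init__(self) -> None:
        for name in ("fructose_labeled_fraction", "glucose_labeled_fraction",
                     "tracer_purity"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise QuantificationError(f"{name} must be in (0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TracerScheme":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))


@dataclass(frozen=True)
class ContributionEstimate:
    """Fractional substrate contributions to acetyl-CoA appearance (%).

    Endogenous (unlabeled dietary + endogenous substrates) is reported per
    glucose bound, since each bound implies its own balance to 100%.
    """

    fructose_pct: float
    glucose_upper_pct: float
    glucose_lower_pct: float
    glucose_mid_pct: float
    endogenous_upper_pct: float   # paired with the glucose *upper* bound
    endogenous_lower_pct: float   # paired with the glucose *lower* bound
    cycling_fraction_f: float

    def __post_init__(self) -> None:
        if not (self.glucose_lower_pct <= self.glucose_mid_pct + 1e-9
                and self.glucose_mid_pct <= self.glucose_upper_pct + 1e-9):
            raise QuantificationError("glucose bounds must satisfy lower <= mid <= upper")
        for name, v in asdict(self).items():
            if name == "cycling_fraction_f":
                continue
            if not -1e-9 <= v <= 100 + 1e-9:
                raise QuantificationError(f"{name}={v} outside [0, 100]")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"units": "% of acetyl-CoA appearance",
                                          **asdict(self)}, indent=2))


def fructose_contribution(excess_12_13c2: float, scheme: TracerScheme,
                          purity_correction: bool = False) -> float:
    """Fructose contribution (%): excess [1,2-¹³C₂] ÷ labeled fraction.

    Valid regardless of pyruvate cycling: no other substrate in the scheme
    can generate the doubly labeled acetyl species, and cycled [U-¹³C]
    pyruvate still returns it.
    """
    if excess_12_13c2 < 0:
        raise QuantificationError("excess enrichment must be >= 0")
    denom = scheme.fructose_labeled_fraction
    if purity_correction:
        denom *= scheme.tracer_purity
    if denom <= 0:
        raise QuantificationError("labeled fraction must be positive")
    return excess_12_13c2 / denom


def glucose_limits(excess_2_13c: float, excess_1_13c: float,
                   scheme: TracerScheme,
                   purity_correction: bool = False) -> tuple[float, float]:
    """(upper, lower) bounds on the glucose contribution (%).

    Upper: all observed [1-¹³C]acetyl is cycled glucose label (sum of the
    excesses).  Lower: all of it is TCA-randomized label from either
    substrate (difference of the excesses, floored at 0).
    """
    if excess_2_13c < 0 or excess_1_13c < 0:
        raise QuantificationError("excess enrichments must be >= 0")
    denom = scheme.glucose_labeled_fraction
    if purity_correction:
        denom *= scheme.tracer_purity
    upper = (excess_2_13c + excess_1_13c) / denom
    lower = max(0.0, excess_2_13c - excess_1_13c) / denom
    return (upper, lower)


def glucose_estimate(excess_2_13c: float, excess_1_13c: float, f: float,
                     scheme: TracerScheme,
                     purity_correction: bool = False) -> float:
    """Glucose contribution (%) at cycling fraction ``f``.

    ``f`` is the fraction of observed [1-¹³C]acetyl attributed to cycling
    of glucose-derived [3-¹³C]pyruvate: (e2 + (2f−1)·e1)/g, which equals the
    lower bound at f=0, the upper bound at f=1 and the midpoint at f=0.5.
    """
    if not 0.0 <= f <= 1.0:
        raise QuantificationError("cycling fraction f must be in [0, 1]")
    upper, lower = glucose_limits(excess_2_13c, excess_1_13c, scheme,
                                  purity_correction)
    denom = scheme.glucose_labeled_fraction
    if purity_correction:
        denom *= scheme.tracer_purity
    est = (excess_2_13c + (2.0 * f - 1.0) * excess_1_13c) / denom
    # the affine form can dip below the floored lower bound when e1 > e2
    return min(upper, max(lower, est))


def endogenous_contribution(fructose_pct: float, glucose_pct: float) -> float:
    """Endogenous contribution (%): 100 − fructose − glucose, floored at 0."""
    if not (0 <= fructose_pct <= 100 and 0 <= glucose_pct <= 100):
        raise QuantificationError("contributions must be in [0, 100]")
    return max(0.0, 100.0 - fructose_pct - glucose_pct)


def estimate_all(profile: AcetylIsotopomerProfile, scheme: TracerScheme,
                 f: float = 0.5,
                 purity_correction: bool = False) -> ContributionEstimate:
    """Full contribution report from an isotopomer profile."""
    e1, e2, e12 = profile.excesses
    fru = fructose_contribution(e12, scheme, purity_correction)
    upper, lower = glucose_limits(e2, e1, scheme, purity_correction)
    mid = glucose_estimate(e2, e1, f, scheme, purity_correction)
    return ContributionEstimate(
        fructose_pct=fru,
        glucose_upper_pct=upper,
        glucose_lower_pct=lower,
        glucose_mid_pct=mid,
        endogenous_upper_pct=endogenous_contribution(fru, upper),
        endogenous_lower_pct=endogenous_contribution(fru, lower),
        cycling_fraction_f=f,
    )
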