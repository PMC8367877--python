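"""pH-dependent octanol-water distribution coefficients.

log D at a given pH combines the neutral-species partition coefficient
log P with the aqueous ionization state populations:

    log D = log P + log10 f_neutral,

where ``f_neutral`` is the aqueous mole fraction of the neutral species.
Charged species are assumed absent from the organic phase by construction
(the standard conversion formula), so log D <= log P always, with equality
only for a fully neutral solution.

For the SAMPL7 compound set the relevant ionization is a single neutral
acid -> anion transition, so the monoprotic-acid form

    f_neutral = 1 / (1 + 10**(pH - pKa))

is the default; the general multiprotic acid/base expression is available
through :class:`IonizationProfile`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "IonizationProfile",
    "ConventionFlag",
    "DistributionResult",
    "neutral_fraction",
    "log_d",
    "log_d_no_pka",
    "invert_log_d",
    "reconstruct_indirect_logd",
    "direct_indirect_discrepancy",
]

DEFAULT_PH = 7.4


class ConventionFlag(str, enum.Enum):
    """How a log D value was obtained."""

    COMPUTED = "computed"
    EQUALS_LOGP_NO_PKA = "equals_logp_no_pka"


@dataclass(frozen=True)
class IonizationProfile:
    """Acid/base pKa ladder of a compound at a working pH.

    ``acid_pkas`` are successive deprotonations in the neutral -> anion
    direction (the first entry is the transition adjacent to the neutral
    species); ``base_pkas`` are successive protonations listed in the
    cation -> neutral direction (the last entry adjacent to neutral).
    Either list may be empty.
    """

    acid_pkas: tuple[float, ...] = ()
    base_pkas: tuple[float, ...] = ()
    ph: float = DEFAULT_PH

    def __post_init__(self) -> None:
        object.__setattr__(self, "acid_pkas", tuple(self.acid_pkas))
        object.__setattr__(self, "base_pkas", tuple(self.base_pkas))
        for v in (*self.acid_pkas, *self.base_pkas, self.ph):
            if not math.isfinite(v):
                raise ValueError(f"non-finite pKa/pH value: {v}")

    @classmethod
    def monoprotic_acid(cls, pka: float, ph: float = DEFAULT_PH) -> "IonizationProfile":
        return cls(acid_pkas=(pka,), ph=ph)


@dataclass(frozen=True)
class DistributionResult:
    log_p: float
    log_d: float
    neutral_fraction_aq: float
    convention_flag: ConventionFlag = ConventionFlag.COMPUTED


def neutral_fraction(profile: IonizationProfile) -> float:
    """Aqueous mole fraction of the neutral species, in (0, 1].

    f = 1 / (1 + sum_k 10**(k*pH - sum_{i<=k} pKa_a,i)
            + sum_k 10**(sum_{i<=k} pKa_b,i - k*pH)),

    with the cumulative sums taken outward from the neutral species on each
    side of the ladder.  Reduces to 1/(1 + 10**(pH - pKa)) for a monoprotic
    acid and to 1 when no pKa applies.
    """
    ph = profile.ph
    denom = 1.0
    cum = 0.0
    for k, pka in enumerate(profile.acid_pkas, start=1):
        cum += pka
        denom += 10.0 ** (k * ph - cum)
    cum = 0.0
    # base list is cation -> neutral; walk outward from the neutral species
    for k, pka in enumerate(reversed(profile.base_pkas), start=1):
        cum += pka
        denom += 10.0 ** (cum - k * ph)
    return 1.0 / denom


def log_d(logp: float, profile: IonizationProfile) -> DistributionResult:
    """Distribution coefficient from log P and an ionization profile."""
    if not math.isfinite(logp):
        raise ValueError(f"non-finite log P: {logp}")
    f = neutral_fraction(profile)
    return DistributionResult(
        log_p=logp,
        log_d=logp + math.log10(f),
        neutral_fraction_aq=f,
        convention_flag=ConventionFlag.COMPUTED,
    )


def log_d_no_pka(logp: float) -> DistributionResult:
    """log D convention for compounds without an assigned experimental pKa.

    When no pKa is assigned (SAMPL7's SM28 and SM33), the hypothetically
    predicted log D is taken equal to the predicted log P.
    """
    if not math.isfinite(logp):
        raise ValueError(f"non-finite log P: {logp}")
    return DistributionResult(
        log_p=logp,
        log_d=logp,
        neutral_fraction_aq=1.0,
        convention_flag=ConventionFlag.EQUALS_LOGP_NO_PKA,
    )


def invert_log_d(logd: float, profile: IonizationProfile) -> float:
    """Recover log P from a log D and the same ionization profile."""
    return logd - math.log10(neutral_fraction(profile))


def reconstruct_indirect_logd(
    exp_log_p: float, exp_pka: float, ph: float = DEFAULT_PH
) -> float:
    """Reconstruct an 'indirect' experimental log D from experimental
    log P and (single acid) pKa — same math as :func:`log_d`, kept as a
    named operation for the direct-vs-indirect comparison report."""
    for v in (exp_log_p, exp_pka, ph):
        if not math.isfinite(v):
            raise ValueError(f"non-finite input: {v}")
    return log_d(exp_log_p, IonizationProfile.monoprotic_acid(exp_pka, ph)).log_d


def direct_indirect_discrepancy(
    direct: Mapping[str, float],
    indirect: Mapping[str, float],
    threshold: float = 0.1,
) -> pd.DataFrame:
    """Per-compound difference between directly measured log D and the
    value reconstructed from experimental pKa and log P.

    Returns a DataFrame (index: compound_id) with columns ``direct``,
    ``indirect``, ``difference`` (direct - indirect) and ``flagged``
    (|difference| > threshold).  Mismatched compound sets raise.
    """
    missing = sorted(set(direct) ^ set(indirect))
    if missing:
        raise ValueError(f"unmatched compound ids: {missing}")
    ids = list(direct)
    df = pd.DataFrame(
        {
            "direct": [direct[c] for c in ids],
            "indirect": [indirect[c] for c in ids],
        },
        index=pd.Index(ids, name="compound_id"),
    )
    df["difference"] = df["direct"] - df["indirect"]
    df["flagged"] = df["difference"].abs() > threshold
    return df
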