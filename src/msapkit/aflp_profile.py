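"""AFLP fragment-change classification between two genotypes.

Each AFLP locus is a dominant PstI–MseI band.  Comparing the consensus
call of a reference genotype (here the diploid) with a derived genotype
(here the autotetraploid) puts every observed band into one of three
types: A, bands specific to the derived genotype (gained fragments); B,
bands specific to the reference (lost fragments); C, bands shared by
both.  A band present in neither consensus is unobservable for a dominant
marker and is excluded from every denominator.  The fraction (A+B)/(A+B+C)
summarizes how much of the banding pattern changed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from ._util import pct
from .band_io import Digest
from .consensus import ConsensusProfile

__all__ = ["AFLPClass", "AFLPSummary", "LocusAlignmentError", "classify_aflp_locus", "summarize_aflp"]


class AFLPClass(Enum):
    A_DERIVED_SPECIFIC = "A"
    B_REFERENCE_SPECIFIC = "B"
    C_SHARED = "C"
    EXCLUDED = "excluded"


class LocusAlignmentError(ValueError):
    """Reference and derived profiles disagree on the locus list."""


_LOOKUP = {
    (0, 1): AFLPClass.A_DERIVED_SPECIFIC,
    (1, 0): AFLPClass.B_REFERENCE_SPECIFIC,
    (1, 1): AFLPClass.C_SHARED,
    (0, 0): AFLPClass.EXCLUDED,
}


def classify_aflp_locus(reference_call: int, derived_call: int) -> AFLPClass:
    """Map a (reference, derived) consensus pair to its fragment type."""
    key = (reference_call, derived_call)
    if key not in _LOOKUP:
        raise ValueError(f"calls must be 0/1, got {key}")
    return _LOOKUP[key]


@dataclass(frozen=True)
class AFLPSummary:
    """Tally of fragment types with report-ready percentages.

    Percentages are of the observed total A+B+C, rounded to ``ndigits``
    half-away-from-zero at report time; counts stay exact.
    ``changed_fraction`` is 100*(A+B)/(A+B+C).
    """

    reference_group: str
    derived_group: str
    a_count: int
    b_count: int
    c_count: int
    excluded_count: int
    per_locus: pd.DataFrame
    ndigits: int = 2

    @property
    def total_scored(self) -> int:
        return self.a_count + self.b_count + self.c_count

    @property
    def a_pct(self) -> float:
        return pct(self.a_count, self.total_scored, self.ndigits)

    @property
    def b_pct(self) -> float:
        return pct(self.b_count, self.total_scored, self.ndigits)

    @property
    def c_pct(self) -> float:
        return pct(self.c_count, self.total_scored, self.ndigits)

    @property
    def changed_fraction(self) -> float:
        return pct(self.a_count + self.b_count, self.total_scored, self.ndigits)

    def to_dict(self) -> dict:
        return {
            "reference_group": self.reference_group,
            "derived_group": self.derived_group,
            "counts": {
                "A_derived_specific": self.a_count,
                "B_reference_specific": self.b_count,
                "C_shared": self.c_count,
                "excluded": self.excluded_count,
            },
            "total_scored": self.total_scored,
            "percentages": {"A": self.a_pct, "B": self.b_pct, "C": self.c_pct},
            "changed_fraction": self.changed_fraction,
        }


def _aligned_calls(reference: ConsensusProfile, derived: ConsensusProfile) -> pd.DataFrame:
    ref = reference.calls_for_digest(Digest.PSTI_MSEI)
    der = derived.calls_for_digest(Digest.PSTI_MSEI)
    if set(ref.index) != set(der.index):
        diff = sorted(set(ref.index) ^ set(der.index))
        raise LocusAlignmentError(
            f"profiles disagree on {len(diff)} loci (symmetric difference): {diff[:10]}"
        )
    return pd.DataFrame({"reference": ref, "derived": der.reindex(ref.index)})


def summarize_aflp(reference: ConsensusProfile, derived: ConsensusProfile) -> AFLPSummary:
    """Classify every locus and tally fragment types A/B/C.

    Swap-symmetric: exchanging the profiles exchanges A and B and fixes C.
    """
    calls = _aligned_calls(reference, derived)
    classes = [
        classify_aflp_locus(int(r), int(d))
        for r, d in zip(calls["reference"], calls["derived"])
    ]
    per_locus = pd.DataFrame(
        {
            "locus": calls.index,
            "reference_call": calls["reference"].to_numpy(),
            "derived_call": calls["derived"].to_numpy(),
            "aflp_class": [c.value for c in classes],
        }
    ).reset_index(drop=True)
    counts = {cls: classes.count(cls) for cls in AFLPClass}
    return AFLPSummary(
        reference_group=reference.group,
        derived_group=derived.group,
        a_count=counts[AFLPClass.A_DERIVED_SPECIFIC],
        b_count=counts[AFLPClass.B_REFERENCE_SPECIFIC],
        c_count=counts[AFLPClass.C_SHARED],
        excluded_count=counts[AFLPClass.EXCLUDED],
        per_locus=per_locus,
    )
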