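"""MSAP methylation-state and methylation-pattern-change classification.

MSAP scores each CCGG locus twice, once per isoschizomer digest.  HpaII is
blocked by full (double-strand, internal-cytosine) methylation but cuts
hemimethylated sites; MspI cuts internal-cytosine-methylated sites but is
blocked by hemimethylation of the external cytosine.  The (HpaII, MspI)
consensus band pair of a genotype therefore encodes the site's state:

=========  =====  =====
state      HpaII  MspI
=========  =====  =====
HEMI         1      0
FULL         0      1
NON          1      1
ABSENT       0      0
=========  =====  =====

Methylation-level summaries count HEMI/FULL/NON per genotype over its
informative (non-ABSENT) loci; total methylation is (HEMI+FULL) over the
same denominator.

Comparing the digest pair of a derived genotype with that of a reference
classifies each locus' pattern change.  The quadruple
(derived HpaII, derived MspI, reference HpaII, reference MspI) maps to:
A (unchanged, 3 quadruples), B (demethylation, 5), C (hypermethylation,
5), two quadruples that swap hemi- and full methylation and belong to
neither direction (UNCLASSIFIED, outside the A/B/C denominator), and the
all-zero quadruple (EXCLUDED).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, NamedTuple

import pandas as pd
from scipy.stats import chi2_contingency

from ._util import pct
from .band_io import Digest
from .consensus import ConsensusProfile

__all__ = [
    "DigestProfile",
    "MethylationState",
    "MethylationLevelSummary",
    "PatternChangeClass",
    "PatternChangeSummary",
    "TwoProportionResult",
    "classify_methylation_state",
    "digest_profiles",
    "summarize_methylation_levels",
    "classify_pattern_change",
    "summarize_pattern_changes",
    "compare_methylation_levels",
]


class DigestProfile(NamedTuple):
    """Consensus band pair of one locus in one genotype."""

    hpaii: int
    mspi: int


class MethylationState(Enum):
    HEMI = "hemi"
    FULL = "full"
    NON = "non"
    ABSENT = "absent"


_STATE_LOOKUP = {
    (1, 0): MethylationState.HEMI,
    (0, 1): MethylationState.FULL,
    (1, 1): MethylationState.NON,
    (0, 0): MethylationState.ABSENT,
}


class PatternChangeClass(Enum):
    A_UNCHANGED = "A"
    B_DEMETHYLATION = "B"
    C_HYPERMETHYLATION = "C"
    UNCLASSIFIED = "unclassified"
    EXCLUDED = "excluded"


# Quadruple (derived HpaII, derived MspI, reference HpaII, reference MspI).
_PATTERN_LOOKUP: dict[tuple[int, int, int, int], PatternChangeClass] = {
    # unchanged
    (0, 1, 0, 1): PatternChangeClass.A_UNCHANGED,
    (1, 0, 1, 0): PatternChangeClass.A_UNCHANGED,
    (1, 1, 1, 1): PatternChangeClass.A_UNCHANGED,
    # demethylation (less methylated in the derived genotype)
    (1, 1, 1, 0): PatternChangeClass.B_DEMETHYLATION,
    (1, 1, 0, 1): PatternChangeClass.B_DEMETHYLATION,
    (1, 1, 0, 0): PatternChangeClass.B_DEMETHYLATION,
    (1, 0, 0, 0): PatternChangeClass.B_DEMETHYLATION,
    (0, 1, 0, 0): PatternChangeClass.B_DEMETHYLATION,
    # hypermethylation (more methylated in the derived genotype)
    (1, 0, 1, 1): PatternChangeClass.C_HYPERMETHYLATION,
    (0, 1, 1, 1): PatternChangeClass.C_HYPERMETHYLATION,
    (0, 0, 1, 1): PatternChangeClass.C_HYPERMETHYLATION,
    (0, 0, 1, 0): PatternChangeClass.C_HYPERMETHYLATION,
    (0, 0, 0, 1): PatternChangeClass.C_HYPERMETHYLATION,
    # hemi<->full swaps change the pattern but neither direction applies
    (1, 0, 0, 1): PatternChangeClass.UNCLASSIFIED,
    (0, 1, 1, 0): PatternChangeClass.UNCLASSIFIED,
    # band in neither genotype nor digest: unobservable
    (0, 0, 0, 0): PatternChangeClass.EXCLUDED,
}


def classify_methylation_state(profile: DigestProfile) -> MethylationState:
    """Map a (HpaII, MspI) consensus pair to its methylation state."""
    key = (profile.hpaii, profile.mspi)
    if key not in _STATE_LOOKUP:
        raise ValueError(f"digest flags must be 0/1, got {key}")
    return _STATE_LOOKUP[key]


def classify_pattern_change(
    derived: DigestProfile, reference: DigestProfile
) -> PatternChangeClass:
    """Classify the between-genotype change of one locus' digest pattern."""
    key = (derived.hpaii, derived.mspi, reference.hpaii, reference.mspi)
    if any(v not in (0, 1) for v in key):
        raise ValueError(f"digest flags must be 0/1, got {key}")
    return _PATTERN_LOOKUP[key]


def digest_profiles(profile: ConsensusProfile) -> pd.DataFrame:
    """Pivot an MSAP consensus into a per-locus (hpaii, mspi) flag table."""
    hpaii = profile.calls_for_digest(Digest.ECORI_HPAII)
    mspi = profile.calls_for_digest(Digest.ECORI_MSPI)
    if set(hpaii.index) != set(mspi.index):
        raise ValueError("HpaII and MspI calls cover different loci")
    return pd.DataFrame(
        {"hpaii": hpaii, "mspi": mspi.reindex(hpaii.index)}, index=hpaii.index
    ).rename_axis("locus")


@dataclass(frozen=True)
class MethylationLevelSummary:
    """Per-genotype methylation-level tally.

    ``informative_total`` excludes ABSENT loci; all percentages use it as
    denominator and are rounded half-away-from-zero at report time.
    """

    group: str
    hemi_count: int
    full_count: int
    non_count: int
    absent_count: int
    ndigits: int = 2

    @property
    def informative_total(self) -> int:
        return self.hemi_count + self.full_count + self.non_count

    @property
    def methylated_count(self) -> int:
        return self.hemi_count + self.full_count

    @property
    def hemi_pct(self) -> float:
        return pct(self.hemi_count, self.informative_total, self.ndigits)

    @property
    def full_pct(self) -> float:
        return pct(self.full_count, self.informative_total, self.ndigits)

    @property
    def non_pct(self) -> float:
        return pct(self.non_count, self.informative_total, self.ndigits)

    @property
    def total_methylation_pct(self) -> float:
        return pct(self.methylated_count, self.informative_total, self.ndigits)

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "counts": {
                "hemi": self.hemi_count,
                "full": self.full_count,
                "non": self.non_count,
                "absent": self.absent_count,
            },
            "informative_total": self.informative_total,
            "percentages": {
                "hemi": self.hemi_pct,
                "full": self.full_pct,
                "non": self.non_pct,
                "total_methylation": self.total_methylation_pct,
            },
        }


def summarize_methylation_levels(
    profiles: pd.DataFrame | Iterable[DigestProfile], group: str = ""
) -> MethylationLevelSummary:
    """Tally methylation states for one genotype's digest-profile set.

    Accepts the frame from :func:`digest_profiles` or an iterable of
    :class:`DigestProfile`.  Raises on zero informative loci.
    """
    if isinstance(profiles, pd.DataFrame):
        pairs = [DigestProfile(int(h), int(m)) for h, m in zip(profiles["hpaii"], profiles["mspi"])]
    else:
        pairs = [DigestProfile(*p) for p in profiles]
    if not pairs:
        raise ValueError("empty digest-profile set")
    states = [classify_methylation_state(p) for p in pairs]
    counts = {s: states.count(s) for s in MethylationState}
    summary = MethylationLevelSummary(
        group=group,
        hemi_count=counts[MethylationState.HEMI],
        full_count=counts[MethylationState.FULL],
        non_count=counts[MethylationState.NON],
        absent_count=counts[MethylationState.ABSENT],
    )
    if summary.informative_total == 0:
        raise ValueError(f"group {group!r}: no informative (non-absent) loci")
    return summary


@dataclass(frozen=True)
class PatternChangeSummary:
    """Tally of pattern-change classes with report-ready percentages.

    Percentages are of the classified total A+B+C; UNCLASSIFIED and
    EXCLUDED loci are reported but kept outside the denominator.
    ``altered_fraction`` is 100*(B+C)/(A+B+C).
    """

    derived_group: str
    reference_group: str
    a_count: int
    b_count: int
    c_count: int
    unclassified_count: int
    excluded_count: int
    per_locus: pd.DataFrame
    ndigits: int = 2

    @property
    def classified_total(self) -> int:
        return self.a_count + self.b_count + self.c_count

    @property
    def a_pct(self) -> float:
        return pct(self.a_count, self.classified_total, self.ndigits)

    @property
    def b_pct(self) -> float:
        return pct(self.b_count, self.classified_total, self.ndigits)

    @property
    def c_pct(self) -> float:
        return pct(self.c_count, self.classified_total, self.ndigits)

    @property
    def altered_fraction(self) -> float:
        return pct(self.b_count + self.c_count, self.classified_total, self.ndigits)

    def to_dict(self) -> dict:
        return {
            "derived_group": self.derived_group,
            "reference_group": self.reference_group,
            "counts": {
                "A_unchanged": self.a_count,
                "B_demethylation": self.b_count,
                "C_hypermethylation": self.c_count,
                "unclassified": self.unclassified_count,
                "excluded": self.excluded_count,
            },
            "classified_total": self.classified_total,
            "percentages": {"A": self.a_pct, "B": self.b_pct, "C": self.c_pct},
            "altered_fraction": self.altered_fraction,
        }


def summarize_pattern_changes(
    derived: pd.DataFrame, reference: pd.DataFrame, *, derived_group: str = "", reference_group: str = ""
) -> PatternChangeSummary:
    """Classify every shared locus' pattern change and tally the classes.

    Both arguments are per-locus (hpaii, mspi) frames as returned by
    :func:`digest_profiles`; they must cover the same loci.
    """
    if set(derived.index) != set(reference.index):
        diff = sorted(set(derived.index) ^ set(reference.index))
        raise ValueError(
            f"profile sets disagree on {len(diff)} loci (symmetric difference): {diff[:10]}"
        )
    reference = reference.reindex(derived.index)
    rows = []
    counts = {cls: 0 for cls in PatternChangeClass}
    for locus, dh, dm, rh, rm in zip(
        derived.index, derived["hpaii"], derived["mspi"], reference["hpaii"], reference["mspi"]
    ):
        cls = classify_pattern_change(DigestProfile(int(dh), int(dm)), DigestProfile(int(rh), int(rm)))
        counts[cls] += 1
        rows.append((locus, int(dh), int(dm), int(rh), int(rm), cls.value))
    per_locus = pd.DataFrame(
        rows,
        columns=["locus", "derived_hpaii", "derived_mspi", "reference_hpaii", "reference_mspi", "pattern_class"],
    )
    return PatternChangeSummary(
        derived_group=derived_group,
        reference_group=reference_group,
        a_count=counts[PatternChangeClass.A_UNCHANGED],
        b_count=counts[PatternChangeClass.B_DEMETHYLATION],
        c_count=counts[PatternChangeClass.C_HYPERMETHYLATION],
        unclassified_count=counts[PatternChangeClass.UNCLASSIFIED],
        excluded_count=counts[PatternChangeClass.EXCLUDED],
        per_locus=per_locus,
    )


@dataclass(frozen=True)
class TwoProportionResult:
    """Yates-corrected chi-square comparison of two total-methylation rates."""

    statistic: float
    p_value: float
    proportion_a: float
    proportion_b: float
    table: tuple[tuple[int, int], tuple[int, int]]

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "proportion_a": self.proportion_a,
            "proportion_b": self.proportion_b,
            "table": [list(self.table[0]), list(self.table[1])],
        }


def compare_methylation_levels(
    summary_a: MethylationLevelSummary, summary_b: MethylationLevelSummary
) -> TwoProportionResult:
    """Two-proportion chi-square test (continuity-corrected) on total methylation.

    The 2x2 table rows are the genotypes, columns (methylated, non-methylated)
    counts over each genotype's informative loci.
    """
    if summary_a.informative_total == 0 or summary_b.informative_total == 0:
        raise ValueError("both groups need informative loci")
    table = (
        (summary_a.methylated_count, summary_a.non_count),
        (summary_b.methylated_count, summary_b.non_count),
    )
    stat, p, _, _ = chi2_contingency(table, correction=True)
    return TwoProportionResult(
        statistic=float(stat),
        p_value=float(p),
        proportion_a=summary_a.methylated_count / summary_a.informative_total,
        proportion_b=summary_b.methylated_count / summary_b.informative_total,
        table=table,
    )
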