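"""Simulation of AFLP/MSAP band matrices and exact tabulated fixtures.

Two generators emulate the experimental design the classifiers assume:

* :func:`simulate_msap` draws a true methylation state per CCGG locus for
  a reference genotype, transforms it through a state-transition change
  process into the derived genotype's state (modelling
  polyploidization-induced demethylation/hypermethylation), maps states to
  their canonical (HpaII, MspI) band pairs, and scores replicate
  individual lanes with independent dropout/spurious-band noise.
* :func:`simulate_aflp` does the two-state analogue for dominant PstI–MseI
  bands: reference bands are lost in the derived genotype at a loss rate,
  and a pool of derived-specific bands is gained at a gain rate (new
  fragments, not re-appearances of scored reference bands).

Both return the true per-locus states alongside the matrices so that
parameter-recovery tests can close the loop.  :func:`build_paper_fixture`
builds unanimous-individual matrices that reproduce published per-type
site counts exactly, and :func:`estimate_change_rates` turns a summary
back into class-rate estimates with Wilson confidence intervals.

Defaults mirror the study conditions: 10 individuals per genotype for
MSAP (5 for AFLP), a few hundred loci, reference state frequencies taken
from the diploid's observed level tally, and change rates that give
expected class fractions near the observed pattern-change split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .aflp_profile import AFLPSummary
from .band_io import BandMatrix, Digest, Lane, MarkerSystem
from .msap_profile import (
    DigestProfile,
    MethylationState,
    PatternChangeSummary,
    classify_pattern_change,
)

__all__ = [
    "STATE_ORDER",
    "STATE_TO_BANDS",
    "SimulationParams",
    "AFLPSimulationParams",
    "SimulationTruth",
    "SimulationResult",
    "RateEstimate",
    "simulate_msap",
    "simulate_aflp",
    "build_paper_fixture",
    "estimate_change_rates",
]

# Canonical state order used for probability vectors and transition rows.
STATE_ORDER = (
    MethylationState.HEMI,
    MethylationState.FULL,
    MethylationState.NON,
    MethylationState.ABSENT,
)

# Canonical MSAP reading: state -> (HpaII band, MspI band).
STATE_TO_BANDS = {
    MethylationState.HEMI: (1, 0),
    MethylationState.FULL: (0, 1),
    MethylationState.NON: (1, 1),
    MethylationState.ABSENT: (0, 0),
}


@dataclass
class SimulationParams:
    """Parameters of the MSAP generator.

    ``ref_state_probs`` orders probabilities as (HEMI, FULL, NON, ABSENT).
    The change process is either an explicit 4x4 row-stochastic
    ``transition`` matrix (reference state in rows, derived state in
    columns, same order) or the shorthand rates: with probability
    ``p_demethylation`` a methylated (HEMI/FULL) site becomes NON; with
    probability ``p_hypermethylation`` a NON site becomes FULL and a
    HEMI/FULL site loses both bands (ABSENT — methylation blocking both
    digests).  ``dropout_rate``/``spurious_rate`` are per-lane scoring
    error probabilities for truly present / truly absent bands.
    """

    n_loci: int = 400
    n_individuals_ref: int = 10
    n_individuals_derived: int = 10
    ref_state_probs: tuple[float, float, float, float] = (0.40, 0.1433, 0.4567, 0.0)
    transition: np.ndarray | None = None
    p_demethylation: float = 0.45
    p_hypermethylation: float = 0.36
    dropout_rate: float = 0.02
    spurious_rate: float = 0.02
    seed: int = 0
    ref_group: str = "RCC"
    derived_group: str = "4nRR"

    def validate(self) -> None:
        if self.n_loci <= 0:
            raise ValueError("n_loci must be positive")
        if self.n_individuals_ref <= 0 or self.n_individuals_derived <= 0:
            raise ValueError("individual counts must be positive")
        probs = np.asarray(self.ref_state_probs, dtype=float)
        if probs.shape != (4,) or (probs < 0).any() or (probs > 1).any():
            raise ValueError("ref_state_probs must be four probabilities")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"ref_state_probs sums to {probs.sum()}, not 1")
        for name in ("p_demethylation", "p_hypermethylation", "dropout_rate", "spurious_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.transition is not None:
            t = np.asarray(self.transition, dtype=float)
            if t.shape != (4, 4) or (t < 0).any() or (t > 1).any():
                raise ValueError("transition must be a 4x4 probability matrix")
            if not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"transition rows must sum to 1, got {t.sum(axis=1)}")
        elif self.p_demethylation + self.p_hypermethylation > 1.0:
            raise ValueError("p_demethylation + p_hypermethylation exceeds 1")

    def resolve_transition(self) -> np.ndarray:
        """The 4x4 change matrix, built from shorthand rates if not given."""
        self.validate()
        if self.transition is not None:
            return np.asarray(self.transition, dtype=float)
        pd_, ph = self.p_demethylation, self.p_hypermethylation
        stay = 1.0 - pd_ - ph
        # rows/cols: HEMI, FULL, NON, ABSENT
        return np.array(
            [
                [stay, 0.0, pd_, ph],  # HEMI -> NON (demeth) or ABSENT (hypermeth)
                [0.0, stay, pd_, ph],  # FULL -> NON or ABSENT
                [0.0, ph, 1.0 - ph, 0.0],  # NON -> FULL (hypermeth)
                [0.0, 0.0, 0.0, 1.0],  # ABSENT stays unobservable
            ]
        )


@dataclass
class AFLPSimulationParams:
    """Parameters of the AFLP generator (two-state presence/absence model)."""

    n_loci: int = 371
    n_individuals_ref: int = 5
    n_individuals_derived: int = 5
    p_loss: float = 0.485
    p_gain: float = 0.488
    dropout_rate: float = 0.02
    spurious_rate: float = 0.02
    seed: int = 0
    ref_group: str = "RCC"
    derived_group: str = "4nRR"

    def validate(self) -> None:
        if self.n_loci <= 0:
            raise ValueError("n_loci must be positive")
        if self.n_individuals_ref <= 0 or self.n_individuals_derived <= 0:
            raise ValueError("individual counts must be positive")
        for name in ("p_loss", "p_gain", "dropout_rate", "spurious_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class SimulationTruth:
    """True per-locus states and the change class they imply."""

    table: pd.DataFrame  # columns: locus, reference_state, derived_state, change_class

    def class_counts(self) -> dict[str, int]:
        return self.table["change_class"].value_counts().to_dict()

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


class SimulationResult(NamedTuple):
    reference: BandMatrix
    derived: BandMatrix
    truth: SimulationTruth


def _noisy_lane(truth: np.ndarray, rng: np.random.Generator, dropout: float, spurious: float) -> np.ndarray:
    u = rng.random(truth.shape[0])
    present = truth == 1
    out = np.where(present, (u >= dropout), (u < spurious))
    return out.astype(np.uint8)


def simulate_msap(params: SimulationParams) -> SimulationResult:
    """Simulate paired-digest band matrices for a reference and a derived genotype.

    Deterministic for a fixed seed; lanes are generated group by group,
    individual by individual, HpaII before MspI.
    """
    transition = params.resolve_transition()  # validates
    rng = np.random.default_rng(params.seed)
    probs = np.asarray(params.ref_state_probs, dtype=float)

    ref_idx = rng.choice(4, size=params.n_loci, p=probs)
    cum = transition.cumsum(axis=1)
    u = rng.random(params.n_loci)
    der_idx = (u[:, None] >= cum[ref_idx]).sum(axis=1)

    loci = [f"L{i + 1:05d}" for i in range(params.n_loci)]
    bands = np.array([STATE_TO_BANDS[s] for s in STATE_ORDER], dtype=np.uint8)
    ref_bands = bands[ref_idx]  # (n_loci, 2): HpaII, MspI
    der_bands = bands[der_idx]

    truth_rows = []
    for i in range(params.n_loci):
        cls = classify_pattern_change(
            DigestProfile(int(der_bands[i, 0]), int(der_bands[i, 1])),
            DigestProfile(int(ref_bands[i, 0]), int(ref_bands[i, 1])),
        )
        truth_rows.append(
            (loci[i], STATE_ORDER[ref_idx[i]].value, STATE_ORDER[der_idx[i]].value, cls.value)
        )
    truth = SimulationTruth(
        pd.DataFrame(truth_rows, columns=["locus", "reference_state", "derived_state", "change_class"])
    )

    def build(group: str, n_ind: int, true_bands: np.ndarray) -> BandMatrix:
        lanes: list[Lane] = []
        cols: list[np.ndarray] = []
        for k in range(n_ind):
            sample = f"{group}_{k + 1:02d}"
            for digest, col in ((Digest.ECORI_HPAII, 0), (Digest.ECORI_MSPI, 1)):
                lanes.append(Lane(sample_id=sample, group=group, digest=digest))
                cols.append(
                    _noisy_lane(true_bands[:, col], rng, params.dropout_rate, params.spurious_rate)
                )
        return BandMatrix(
            system=MarkerSystem.MSAP,
            loci=list(loci),
            lanes=lanes,
            presence=np.column_stack(cols),
        )

    reference = build(params.ref_group, params.n_individuals_ref, ref_bands)
    derived = build(params.derived_group, params.n_individuals_derived, der_bands)
    return SimulationResult(reference=reference, derived=derived, truth=truth)


def simulate_aflp(params: AFLPSimulationParams) -> SimulationResult:
    """Simulate dominant-band matrices with loss and gain between genotypes.

    The locus list is the reference band pool plus a gained pool of
    derived-specific bands (``Binomial(n_loci, p_gain)`` new fragments);
    both matrices share that list so downstream summaries align.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    lost = rng.random(params.n_loci) < params.p_loss
    n_gain = int(rng.binomial(params.n_loci, params.p_gain))

    loci = [f"R{i + 1:05d}" for i in range(params.n_loci)] + [
        f"G{i + 1:05d}" for i in range(n_gain)
    ]
    ref_true = np.concatenate(
        [np.ones(params.n_loci, dtype=np.uint8), np.zeros(n_gain, dtype=np.uint8)]
    )
    der_true = np.concatenate(
        [(~lost).astype(np.uint8), np.ones(n_gain, dtype=np.uint8)]
    )

    classes = np.where(ref_true == 1, np.where(der_true == 1, "C", "B"), "A")
    truth = SimulationTruth(
        pd.DataFrame(
            {
                "locus": loci,
                "reference_state": np.where(ref_true == 1, "present", "absent"),
                "derived_state": np.where(der_true == 1, "present", "absent"),
                "change_class": classes,
            }
        )
    )

    def build(group: str, n_ind: int, true_bands: np.ndarray) -> BandMatrix:
        lanes: list[Lane] = []
        cols: list[np.ndarray] = []
        for k in range(n_ind):
            lanes.append(Lane(sample_id=f"{group}_{k + 1:02d}", group=group, digest=Digest.PSTI_MSEI))
            cols.append(_noisy_lane(true_bands, rng, params.dropout_rate, params.spurious_rate))
        return BandMatrix(
            system=MarkerSystem.AFLP,
            loci=list(loci),
            lanes=lanes,
            presence=np.column_stack(cols),
        )

    reference = build(params.ref_group, params.n_individuals_ref, ref_true)
    derived = build(params.derived_group, params.n_individuals_derived, der_true)
    return SimulationResult(reference=reference, derived=derived, truth=truth)


# Published per-type site counts the exact fixtures reconstruct.
_TABLE1_COUNTS = (  # (reference call, derived call, count, label)
    (0, 1, 181, "A"),
    (1, 0, 180, "B"),
    (1, 1, 191, "C"),
)
_TABLE2_COUNTS = {  # group -> counts per state
    "reference": {"hemi": 120, "full": 43, "non": 137},
    "derived": {"hemi": 117, "full": 87, "non": 205},
}
_TABLE3_ROWS = (  # (derived HpaII, derived MspI, reference HpaII, reference MspI, count)
    (0, 1, 0, 1, 7),
    (1, 0, 1, 0, 15),
    (1, 1, 1, 1, 132),
    (1, 1, 1, 0, 22),
    (1, 1, 0, 1, 17),
    (1, 1, 0, 0, 17),
    (1, 0, 0, 0, 25),
    (0, 1, 0, 0, 13),
    (1, 0, 1, 1, 38),
    (0, 1, 1, 1, 24),
    (0, 0, 1, 1, 35),
    (0, 0, 1, 0, 23),
    (0, 0, 0, 1, 20),
)

_STATE_BANDS_BY_NAME = {
    "hemi": (1, 0),
    "full": (0, 1),
    "non": (1, 1),
}


def _unanimous_aflp(loci, ref_calls, der_calls, ref_group, derived_group, n_ind) -> BandMatrix:
    lanes = []
    cols = []
    for group, calls in ((ref_group, ref_calls), (derived_group, der_calls)):
        for k in range(n_ind):
            lanes.append(Lane(sample_id=f"{group}_{k + 1:02d}", group=group, digest=Digest.PSTI_MSEI))
            cols.append(np.asarray(calls, dtype=np.uint8))
    return BandMatrix(MarkerSystem.AFLP, list(loci), lanes, np.column_stack(cols))


def _unanimous_msap(loci, band_pairs, group, n_ind) -> BandMatrix:
    """One group's matrix: every individual shows the locus' canonical bands."""
    pairs = np.asarray(band_pairs, dtype=np.uint8)  # (n_loci, 2)
    lanes = []
    cols = []
    for k in range(n_ind):
        sample = f"{group}_{k + 1:02d}"
        lanes.append(Lane(sample_id=sample, group=group, digest=Digest.ECORI_HPAII))
        cols.append(pairs[:, 0])
        lanes.append(Lane(sample_id=sample, group=group, digest=Digest.ECORI_MSPI))
        cols.append(pairs[:, 1])
    return BandMatrix(MarkerSystem.MSAP, list(loci), lanes, np.column_stack(cols))


def build_paper_fixture(
    table: str,
    *,
    ref_group: str = "RCC",
    derived_group: str = "4nRR",
    n_individuals: int | None = None,
):
    """Reconstruct the published per-type site counts as unanimous matrices.

    ``table`` selects the fixture:

    * ``"TABLE1"`` — one AFLP matrix with both groups (5 individuals each
      by default): 181 derived-specific, 180 reference-specific and 191
      shared loci (552 total).
    * ``"TABLE2"`` — dict mapping each group name to its own single-group
      MSAP matrix (10 individuals each): 120/43/137 hemi/full/non loci for
      the reference and 117/87/205 for the derived genotype.  The two
      matrices are separate because the published per-genotype level
      tallies are not locus-aligned across genotypes.
    * ``"TABLE3"`` — one MSAP matrix with both groups (10 individuals
      each): one locus per counted digest quadruple, 388 in total
      (154 unchanged, 94 demethylated, 140 hypermethylated).

    All individuals are unanimous, so every consensus threshold reproduces
    the printed patterns exactly.
    """
    table = table.upper()
    if table == "TABLE1":
        n_ind = n_individuals or 5
        loci, ref_calls, der_calls = [], [], []
        for ref, der, count, label in _TABLE1_COUNTS:
            for i in range(count):
                loci.append(f"T1_{label}_{i + 1:03d}")
                ref_calls.append(ref)
                der_calls.append(der)
        return _unanimous_aflp(loci, ref_calls, der_calls, ref_group, derived_group, n_ind)

    if table == "TABLE2":
        n_ind = n_individuals or 10
        out = {}
        for role, group in (("reference", ref_group), ("derived", derived_group)):
            loci, pairs = [], []
            for state, count in _TABLE2_COUNTS[role].items():
                for i in range(count):
                    loci.append(f"T2_{group}_{state}_{i + 1:03d}")
                    pairs.append(_STATE_BANDS_BY_NAME[state])
            out[group] = _unanimous_msap(loci, pairs, group, n_ind)
        return out

    if table == "TABLE3":
        n_ind = n_individuals or 10
        loci, ref_pairs, der_pairs = [], [], []
        for row_idx, (dh, dm, rh, rm, count) in enumerate(_TABLE3_ROWS, start=1):
            for i in range(count):
                loci.append(f"T3_p{row_idx:02d}_{i + 1:03d}")
                der_pairs.append((dh, dm))
                ref_pairs.append((rh, rm))
        ref_matrix = _unanimous_msap(loci, ref_pairs, ref_group, n_ind)
        der_matrix = _unanimous_msap(loci, der_pairs, derived_group, n_ind)
        from .band_io import concat_band_matrices

        return concat_band_matrices([ref_matrix, der_matrix])

    raise ValueError(f"unknown fixture table {table!r} (expected TABLE1/TABLE2/TABLE3)")


@dataclass(frozen=True)
class RateEstimate:
    """A class fraction with its Wilson score interval."""

    count: int
    total: int
    estimate: float
    ci_low: float
    ci_high: float
    level: float

    def to_dict(self) -> dict:
        return {
            "count": self.count,
            "total": self.total,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
        }


def estimate_change_rates(
    summary: PatternChangeSummary | AFLPSummary, level: float = 0.95
) -> dict[str, RateEstimate]:
    """Class-rate point estimates with Wilson intervals from a summary tally.

    For a pattern-change summary the keys are ``A``/``B``/``C`` plus
    ``altered`` (B+C); for an AFLP summary ``A``/``B``/``C`` plus
    ``changed`` (A+B).  Denominator is the classified total.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    if isinstance(summary, PatternChangeSummary):
        total = summary.classified_total
        named = {
            "A": summary.a_count,
            "B": summary.b_count,
            "C": summary.c_count,
            "altered": summary.b_count + summary.c_count,
        }
    elif isinstance(summary, AFLPSummary):
        total = summary.total_scored
        named = {
            "A": summary.a_count,
            "B": summary.b_count,
            "C": summary.c_count,
            "changed": summary.a_count + summary.b_count,
        }
    else:
        raise TypeError(f"unsupported summary type {type(summary).__name__}")
    if total == 0:
        raise ValueError("summary has no classified loci")

    out = {}
    for name, count in named.items():
        low, high = proportion_confint(count, total, alpha=1.0 - level, method="wilson")
        # the Wilson bound is exactly 0/1 at empty/full counts; pin the
        # boundary against floating-point round-off
        if count == 0:
            low = 0.0
        if count == total:
            high = 1.0
        out[name] = RateEstimate(
            count=count,
            total=total,
            estimate=count / total,
            ci_low=float(low),
            ci_high=float(high),
            level=level,
        )
    return out
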