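"""Shared builders for band matrices and consensus profiles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from msapkit import BandMatrix, ConsensusProfile, Digest, Lane, MarkerSystem


def make_aflp_matrix(
    calls_by_group: dict[str, np.ndarray | list],
    loci: list[str] | None = None,
    n_individuals: int = 3,
) -> BandMatrix:
    """Unanimous AFLP matrix: each group's individuals all show its call vector."""
    first = np.asarray(next(iter(calls_by_group.values())))
    loci = loci or [f"L{i + 1:03d}" for i in range(len(first))]
    lanes, cols = [], []
    for group, calls in calls_by_group.items():
        calls = np.asarray(calls, dtype=np.uint8)
        for k in range(n_individuals):
            lanes.append(Lane(f"{group}_{k + 1}", group, Digest.PSTI_MSEI))
            cols.append(calls)
    return BandMatrix(MarkerSystem.AFLP, loci, lanes, np.column_stack(cols))


def make_msap_matrix(
    pairs_by_group: dict[str, list[tuple[int, int]]],
    loci: list[str] | None = None,
    n_individuals: int = 3,
) -> BandMatrix:
    """Unanimous MSAP matrix from per-group (HpaII, MspI) band pairs."""
    first = next(iter(pairs_by_group.values()))
    loci = loci or [f"L{i + 1:03d}" for i in range(len(first))]
    lanes, cols = [], []
    for group, pairs in pairs_by_group.items():
        arr = np.asarray(pairs, dtype=np.uint8)
        for k in range(n_individuals):
            sample = f"{group}_{k + 1}"
            lanes.append(Lane(sample, group, Digest.ECORI_HPAII))
            cols.append(arr[:, 0])
            lanes.append(Lane(sample, group, Digest.ECORI_MSPI))
            cols.append(arr[:, 1])
    return BandMatrix(MarkerSystem.MSAP, loci, lanes, np.column_stack(cols))


def make_profile(group: str, calls: dict[str, int], threshold: float = 0.5) -> ConsensusProfile:
    """A single-individual AFLP consensus profile straight from a call dict."""
    frame = pd.DataFrame(
        {
            "locus": list(calls),
            "digest": Digest.PSTI_MSEI.value,
            "call": np.array(list(calls.values()), dtype=np.uint8),
            "support": [float(v) for v in calls.values()],
            "n": 1,
        }
    )
    return ConsensusProfile(group=group, threshold=threshold, calls=frame)


def make_digest_frame(pairs: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """Per-locus (hpaii, mspi) frame as digest_profiles() would return."""
    return pd.DataFrame(
        {
            "hpaii": [p[0] for p in pairs.values()],
            "mspi": [p[1] for p in pairs.values()],
        },
        index=pd.Index(list(pairs), name="locus"),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)
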