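"""Collapse replicate individuals of a genotype group into consensus calls.

Downstream classification (fragment types, methylation states, pattern
changes) is written in terms of one presence/absence state per genotype
group per locus (per digest for MSAP), while the gels score several
replicate individuals per group.  The collapse rule is a support
threshold: a band is called present for the group iff the fraction of the
group's individuals presenting it is at least ``threshold``.  The default
0.5 is majority rule; 1.0 requires within-group monomorphism (logical
AND); any positive threshold with one individual reproduces that
individual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .band_io import BandMatrix, Digest

__all__ = ["ConsensusProfile", "UnknownGroupError", "consensus_call", "consensus_discordance"]


class UnknownGroupError(KeyError):
    pass


@dataclass
class ConsensusProfile:
    """Per-locus (and per-digest) consensus calls for one genotype group.

    ``calls`` has columns ``locus``, ``digest`` (header code), ``call``
    (0/1), ``support`` (attained fraction of individuals presenting the
    band) and ``n`` (individuals scored).
    """

    group: str
    threshold: float
    calls: pd.DataFrame

    @property
    def digests(self) -> list[str]:
        return list(dict.fromkeys(self.calls["digest"]))

    def calls_for_digest(self, digest: Digest) -> pd.Series:
        sub = self.calls[self.calls["digest"] == digest.value]
        return pd.Series(sub["call"].to_numpy(), index=sub["locus"].to_numpy(), name="call")

    def to_frame(self) -> pd.DataFrame:
        return self.calls.copy()


def _group_digests(matrix: BandMatrix, group: str) -> list[Digest]:
    digests = [d for d in Digest if matrix.lane_indices(group, d)]
    if not digests:
        known = ", ".join(matrix.groups) or "<none>"
        raise UnknownGroupError(f"group {group!r} has no lanes (groups present: {known})")
    return digests


def consensus_call(matrix: BandMatrix, group: str, threshold: float = 0.5) -> ConsensusProfile:
    """Consensus presence/absence per locus (per digest) for ``group``.

    ``call == 1`` iff support >= threshold; ties at the threshold count as
    present.  Deterministic and invariant under individual reordering.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    frames = []
    for digest in _group_digests(matrix, group):
        idx = matrix.lane_indices(group, digest)
        sub = matrix.presence[:, idx]
        n = sub.shape[1]
        support = sub.sum(axis=1) / n
        frames.append(
            pd.DataFrame(
                {
                    "locus": matrix.loci,
                    "digest": digest.value,
                    "call": (support >= threshold).astype(np.uint8),
                    "support": support,
                    "n": n,
                }
            )
        )
    calls = pd.concat(frames, ignore_index=True)
    return ConsensusProfile(group=group, threshold=threshold, calls=calls)


def consensus_discordance(
    matrix: BandMatrix, group: str, threshold: float = 0.5
) -> pd.DataFrame:
    """Per-locus fraction of individuals disagreeing with the consensus call.

    A QC view of within-group scoring noise; rows sorted by descending
    discordance.  Columns: ``locus``, ``digest``, ``call``, ``discordance``.
    """
    profile = consensus_call(matrix, group, threshold)
    rows = []
    for digest_code, sub in profile.calls.groupby("digest", sort=False):
        idx = matrix.lane_indices(group, Digest(digest_code))
        lanes = matrix.presence[:, idx]
        calls = sub["call"].to_numpy()[:, None]
        discord = (lanes != calls).mean(axis=1)
        rows.append(
            pd.DataFrame(
                {
                    "locus": sub["locus"].to_numpy(),
                    "digest": digest_code,
                    "call": sub["call"].to_numpy(),
                    "discordance": discord,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values("discordance", ascending=False, kind="stable").reset_index(drop=True)
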