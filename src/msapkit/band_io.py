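"""Reading, writing and validating scored gel band matrices.

AFLP and MSAP gels are scored as dominant presence/absence markers: each
locus (a band of a given mobility under a given selective primer
combination) is recorded as 1 if the band is visible in a lane and 0
otherwise.  A :class:`BandMatrix` holds one such scored matrix, loci in
rows and lanes in columns, together with per-lane metadata: the sample
(individual), its genotype group, and the restriction digest the lane was
run with.  AFLP lanes come from a PstI–MseI digest; MSAP lanes come in
pairs per sample, EcoRI–HpaII and EcoRI–MspI, whose joint presence pattern
encodes the methylation state of the CCGG site.

On-disk format (one format, bit-exact round trip): delimited text, comma
for ``.csv`` and tab for ``.tsv``/anything else.  The first column is the
locus label; every other column header encodes its lane as
``sample|group|digest`` (optionally ``sample|group|digest|primer``), with
digest codes ``PM`` (PstI–MseI), ``H`` (EcoRI–HpaII), ``M`` (EcoRI–MspI).
Cells are ``0``/``1`` plus an optional missing token handled by a parse
policy.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Digest",
    "MarkerSystem",
    "Lane",
    "BandMatrix",
    "Violation",
    "BandMatrixError",
    "BandParseError",
    "BandValidationError",
    "LanePairingError",
    "read_band_matrix",
    "write_band_matrix",
    "validate_band_matrix",
    "concat_band_matrices",
]


class Digest(Enum):
    """Restriction digest a lane was amplified from (header code in value)."""

    PSTI_MSEI = "PM"
    ECORI_HPAII = "H"
    ECORI_MSPI = "M"


class MarkerSystem(Enum):
    AFLP = "AFLP"
    MSAP = "MSAP"

    @property
    def allowed_digests(self) -> frozenset[Digest]:
        if self is MarkerSystem.AFLP:
            return frozenset({Digest.PSTI_MSEI})
        return frozenset({Digest.ECORI_HPAII, Digest.ECORI_MSPI})


class BandMatrixError(ValueError):
    """Base class for band-matrix I/O and validation failures."""


class BandParseError(BandMatrixError):
    """Malformed file structure (header, delimiter, ragged rows)."""


class BandValidationError(BandMatrixError):
    """An invariant violation, with the offending coordinates in the message."""

    def __init__(self, violations: Sequence["Violation"]):
        self.violations = list(violations)
        super().__init__("; ".join(v.message for v in self.violations))


class LanePairingError(BandValidationError):
    """An MSAP sample missing one of its two digest lanes."""


@dataclass(frozen=True)
class Lane:
    """Metadata for one gel lane: one individual in one digest."""

    sample_id: str
    group: str
    digest: Digest
    primer_combo: str = ""

    def encode(self) -> str:
        parts = [self.sample_id, self.group, self.digest.value]
        if self.primer_combo:
            parts.append(self.primer_combo)
        return "|".join(parts)

    @classmethod
    def decode(cls, header: str) -> "Lane":
        parts = header.split("|")
        if len(parts) not in (3, 4):
            raise BandParseError(
                f"lane header {header!r} is not 'sample|group|digest[|primer]'"
            )
        try:
            digest = Digest(parts[2])
        except ValueError:
            codes = ", ".join(d.value for d in Digest)
            raise BandParseError(
                f"lane header {header!r}: unknown digest code {parts[2]!r} "
                f"(expected one of {codes})"
            ) from None
        primer = parts[3] if len(parts) == 4 else ""
        return cls(sample_id=parts[0], group=parts[1], digest=digest, primer_combo=primer)


@dataclass(frozen=True)
class Violation:
    """One invariant violation: the rule broken and where."""

    rule: str
    message: str
    locus: str | None = None
    lane: str | None = None


@dataclass
class BandMatrix:
    """A loci x lanes binary presence table with lane metadata.

    ``presence`` is a ``uint8`` array of shape ``(len(loci), len(lanes))``
    whose cells are strictly 0 or 1 after validation.
    """

    system: MarkerSystem
    loci: list[str]
    lanes: list[Lane]
    presence: np.ndarray

    def __post_init__(self) -> None:
        self.loci = [str(x) for x in self.loci]
        arr = np.asarray(self.presence)
        if arr.ndim != 2 or arr.shape != (len(self.loci), len(self.lanes)):
            raise BandMatrixError(
                f"presence shape {arr.shape} does not match "
                f"{len(self.loci)} loci x {len(self.lanes)} lanes"
            )
        self.presence = arr.astype(np.uint8, copy=False)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_lanes(self) -> int:
        return len(self.lanes)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for lane in self.lanes:
            seen.setdefault(lane.group, None)
        return list(seen)

    def lane_indices(self, group: str, digest: Digest | None = None) -> list[int]:
        return [
            i
            for i, lane in enumerate(self.lanes)
            if lane.group == group and (digest is None or lane.digest == digest)
        ]

    def to_frame(self) -> pd.DataFrame:
        """Presence table as a DataFrame, loci in the index, encoded lane headers."""
        return pd.DataFrame(
            self.presence,
            index=pd.Index(self.loci, name="locus"),
            columns=[lane.encode() for lane in self.lanes],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BandMatrix):
            return NotImplemented
        return (
            self.system == other.system
            and self.loci == other.loci
            and self.lanes == other.lanes
            and np.array_equal(self.presence, other.presence)
        )


def _delimiter_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def validate_band_matrix(matrix: BandMatrix) -> list[Violation]:
    """Check every structural invariant; return all violations (never raises).

    Rules: cells binary; locus labels unique; (sample, digest) unique;
    digests consistent with the marker system; every MSAP sample carries
    both an HpaII and an MspI lane.
    """
    violations: list[Violation] = []

    bad = np.argwhere(matrix.presence > 1)
    for i, j in bad:
        violations.append(
            Violation(
                rule="binary-cells",
                message=f"cell at locus {matrix.loci[i]!r}, lane "
                f"{matrix.lanes[j].encode()!r} is not 0/1",
                locus=matrix.loci[i],
                lane=matrix.lanes[j].encode(),
            )
        )

    seen_loci: set[str] = set()
    for locus in matrix.loci:
        if locus in seen_loci:
            violations.append(
                Violation(
                    rule="unique-loci",
                    message=f"duplicated locus label {locus!r}",
                    locus=locus,
                )
            )
        seen_loci.add(locus)

    seen_lanes: set[tuple[str, Digest]] = set()
    for lane in matrix.lanes:
        key = (lane.sample_id, lane.digest)
        if key in seen_lanes:
            violations.append(
                Violation(
                    rule="unique-lanes",
                    message=f"duplicated lane for sample {lane.sample_id!r}, "
                    f"digest {lane.digest.value}",
                    lane=lane.encode(),
                )
            )
        seen_lanes.add(key)
        if lane.digest not in matrix.system.allowed_digests:
            violations.append(
                Violation(
                    rule="digest-schema",
                    message=f"lane {lane.encode()!r} has digest {lane.digest.value} "
                    f"not allowed in a {matrix.system.value} matrix",
                    lane=lane.encode(),
                )
            )

    if matrix.system is MarkerSystem.MSAP:
        by_sample: dict[str, set[Digest]] = {}
        for lane in matrix.lanes:
            if lane.digest in matrix.system.allowed_digests:
                by_sample.setdefault(lane.sample_id, set()).add(lane.digest)
        for sample, digests in sorted(by_sample.items()):
            missing = {Digest.ECORI_HPAII, Digest.ECORI_MSPI} - digests
            for d in sorted(missing, key=lambda d: d.value):
                violations.append(
                    Violation(
                        rule="msap-pairing",
                        message=f"sample {sample!r} has no {d.value} "
                        "(paired-digest) lane",
                        lane=sample,
                    )
                )

    return violations


def _raise_on_violations(violations: list[Violation]) -> None:
    if not violations:
        return
    if any(v.rule == "msap-pairing" for v in violations):
        pairing = [v for v in violations if v.rule == "msap-pairing"]
        raise LanePairingError(pairing)
    raise BandValidationError(violations)


def read_band_matrix(
    path: str | Path,
    system: MarkerSystem | str,
    *,
    missing_token: str = "NA",
    missing_policy: Literal["error", "absent"] = "error",
    delimiter: str | None = None,
) -> BandMatrix:
    """Parse a delimited band-matrix file and return a validated matrix.

    ``missing_policy`` controls cells equal to ``missing_token``:
    ``"error"`` (default, the strict binary convention) rejects them;
    ``"absent"`` scores them 0.
    """
    path = Path(path)
    system = MarkerSystem(system) if not isinstance(system, MarkerSystem) else system
    sep = delimiter or _delimiter_for(path)

    with path.open(newline="") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    if not rows:
        raise BandParseError(f"{path}: empty file")
    header = rows[0]
    if not header or header[0] != "locus":
        raise BandParseError(
            f"{path}: first header column must be 'locus', got "
            f"{header[0]!r}" if header else f"{path}: empty header"
        )
    lanes = [Lane.decode(h) for h in header[1:]]

    loci: list[str] = []
    cells = np.zeros((len(rows) - 1, len(lanes)), dtype=np.uint8)
    violations: list[Violation] = []
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise BandParseError(
                f"{path}:{r}: expected {len(header)} fields, got {len(row)}"
            )
        locus = row[0]
        loci.append(locus)
        for c, value in enumerate(row[1:]):
            if value == missing_token:
                if missing_policy == "absent":
                    continue  # scored 0
                violations.append(
                    Violation(
                        rule="binary-cells",
                        message=f"missing value at locus {locus!r}, lane "
                        f"{lanes[c].encode()!r} under policy 'error'",
                        locus=locus,
                        lane=lanes[c].encode(),
                    )
                )
            elif value in ("0", "1"):
                cells[r - 2, c] = int(value)
            else:
                violations.append(
                    Violation(
                        rule="binary-cells",
                        message=f"non-binary cell {value!r} at locus {locus!r}, "
                        f"lane {lanes[c].encode()!r}",
                        locus=locus,
                        lane=lanes[c].encode(),
                    )
                )
    _raise_on_violations(violations)

    matrix = BandMatrix(system=system, loci=loci, lanes=lanes, presence=cells)
    _raise_on_violations(validate_band_matrix(matrix))
    return matrix


def write_band_matrix(matrix: BandMatrix, path: str | Path) -> None:
    """Serialize a valid matrix; the written file round-trips bit-exactly."""
    _raise_on_violations(validate_band_matrix(matrix))
    path = Path(path)
    sep = _delimiter_for(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep, lineterminator="\n")
        writer.writerow(["locus"] + [lane.encode() for lane in matrix.lanes])
        for i, locus in enumerate(matrix.loci):
            writer.writerow([locus] + [str(int(x)) for x in matrix.presence[i]])


def concat_band_matrices(
    matrices: Iterable[BandMatrix], join: Literal["exact", "outer"] = "exact"
) -> BandMatrix:
    """Join matrices lane-wise (e.g. one file per genotype group).

    ``join="exact"`` (default) requires identical locus lists.
    ``join="outer"`` takes the union of loci in first-seen order and scores
    a locus 0 in lanes of any matrix that did not carry it — a band never
    recorded in one gel set is absent there under the dominant-marker
    convention.
    """
    matrices = list(matrices)
    if not matrices:
        raise BandMatrixError("nothing to concatenate")
    first = matrices[0]
    for m in matrices[1:]:
        if m.system is not first.system:
            raise BandMatrixError("cannot mix AFLP and MSAP matrices")
        if join == "exact" and m.loci != first.loci:
            raise BandMatrixError("matrices disagree on the locus list")
    if join == "exact":
        loci = list(first.loci)
        blocks = [m.presence for m in matrices]
    else:
        loci = list(dict.fromkeys(locus for m in matrices for locus in m.loci))
        pos = {locus: i for i, locus in enumerate(loci)}
        blocks = []
        for m in matrices:
            block = np.zeros((len(loci), m.n_lanes), dtype=np.uint8)
            rows = [pos[locus] for locus in m.loci]
            block[rows, :] = m.presence
            blocks.append(block)
    joined = BandMatrix(
        system=first.system,
        loci=loci,
        lanes=[lane for m in matrices for lane in m.lanes],
        presence=np.concatenate(blocks, axis=1),
    )
    _raise_on_violations(validate_band_matrix(joined))
    return joined
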