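"""Categorical coding of cranial bone contacts.

A contact between two skull bones is described by two independent aspects:

* a **spatial relation** — how the two bones meet in cross section:
  parallel (``p``), overlapping (``o``) / underlying (``u``), clasping
  (``c``) / clasped-by (``cb``), or vertically transverse (``t``);
* a **suture depth** — an ordinal four-level interdigitation scale:
  smooth (``s``), faintly (``if``), moderately (``im``) or strongly
  (``is``) interfingering.  Fossil material sometimes allows the spatial
  relation to be determined while the suture type remains unknown, so the
  depth may also be ``?``.

A contact may change character along its course; it is then stored as an
ordered list of segments, listed from anterior to posterior.

The relations ``o``/``u`` and ``c``/``cb`` are directional complements:
"A overlaps B" is the same observation as "B underlies A".  Records are
therefore canonicalized so that the lexicographically smaller bone name
comes first and the relation codes are expressed from its point of view.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

__all__ = [
    "SPATIAL_CODES",
    "SPATIAL_COMPLEMENT",
    "DEPTH_CODES",
    "UNKNOWN_DEPTH",
    "BONE_VOCABULARY",
    "NON_UNIVERSAL_BONES",
    "SutureDepth",
    "ContactSegment",
    "ContactRecord",
    "ContactTable",
    "ContactError",
    "VocabularyError",
    "SelfContactError",
    "ParseError",
    "IntegrityError",
    "canonicalize_contact",
    "read_contact_table",
    "write_contact_table",
    "validate_table",
]

#: The six spatial-relation codes.
SPATIAL_CODES = ("p", "o", "u", "c", "cb", "t")

#: Directional complements under reversal of the bone pair.  ``p`` and
#: ``t`` are self-symmetric.
SPATIAL_COMPLEMENT = {"p": "p", "o": "u", "u": "o", "c": "cb", "cb": "c", "t": "t"}

#: Ordinal depth codes, indexed by level 0..3.
DEPTH_CODES = ("s", "if", "im", "is")
_DEPTH_LEVEL = {code: i for i, code in enumerate(DEPTH_CODES)}

#: Controlled vocabulary of skull bones.
BONE_VOCABULARY = (
    "prefrontal", "frontal", "parietal", "postorbital", "jugal",
    "quadratojugal", "squamosal", "premaxilla", "maxilla", "vomer",
    "palatine", "pterygoid", "epipterygoid", "basisphenoid", "parasphenoid",
    "prootic", "opisthotic", "quadrate", "basioccipital", "exoccipital",
    "supraoccipital", "nasal", "columella",
)

#: Bones that do not occur in every taxon; flagged so that downstream
#: analyses can exclude their contacts in a data-driven way.
NON_UNIVERSAL_BONES = frozenset({"nasal", "columella", "epipterygoid", "parasphenoid"})

_BONE_SET = frozenset(BONE_VOCABULARY)


class ContactError(ValueError):
    """Base class for contact-coding errors."""


class VocabularyError(ContactError):
    """A bone name is outside the controlled vocabulary."""


class SelfContactError(ContactError):
    """A bone was paired with itself."""


class ParseError(ContactError):
    """A contact file row could not be interpreted."""


class IntegrityError(ContactError):
    """Duplicate or mutually inconsistent rows for the same contact."""


@dataclass(frozen=True, order=False)
class SutureDepth:
    """Ordinal suture depth; ``level`` is 0..3 or ``None`` for unknown.

    The four named levels are totally ordered.  An unknown depth takes part
    in no numeric comparison: ordering against it raises ``TypeError``.
    """

    level: Optional[int]

    def __post_init__(self) -> None:
        if self.level is not None and self.level not in (0, 1, 2, 3):
            raise ContactError(f"depth level out of range: {self.level!r}")

    @property
    def known(self) -> bool:
        return self.level is not None

    @property
    def code(self) -> str:
        return "?" if self.level is None else DEPTH_CODES[self.level]

    @classmethod
    def from_code(cls, code: str) -> "SutureDepth":
        if code == "?":
            return UNKNOWN_DEPTH
        if code not in _DEPTH_LEVEL:
            raise ParseError(f"unknown suture depth code: {code!r}")
        return cls(_DEPTH_LEVEL[code])

    def _check_comparable(self, other: "SutureDepth") -> None:
        if self.level is None or other.level is None:
            raise TypeError("unknown suture depth is not ordered")

    def __lt__(self, other: "SutureDepth") -> bool:
        self._check_comparable(other)
        return self.level < other.level

    def __le__(self, other: "SutureDepth") -> bool:
        self._check_comparable(other)
        return self.level <= other.level

    def __gt__(self, other: "SutureDepth") -> bool:
        return other < self

    def __ge__(self, other: "SutureDepth") -> bool:
        return other <= self

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"SutureDepth({self.code!r})"


UNKNOWN_DEPTH = SutureDepth(None)


@dataclass(frozen=True)
class ContactSegment:
    """One stretch of a contact: a spatial relation plus a suture depth."""

    spatial: str
    depth: SutureDepth = UNKNOWN_DEPTH

    def __post_init__(self) -> None:
        if self.spatial not in SPATIAL_CODES:
            raise ParseError(f"unknown spatial relation code: {self.spatial!r}")
        if not isinstance(self.depth, SutureDepth):
            object.__setattr__(self, "depth", SutureDepth.from_code(self.depth))

    def flipped(self) -> "ContactSegment":
        """The same observation expressed from the other bone's viewpoint."""
        return ContactSegment(SPATIAL_COMPLEMENT[self.spatial], self.depth)


def _check_bone(name: str) -> str:
    if name not in _BONE_SET:
        raise VocabularyError(f"bone not in vocabulary: {name!r}")
    return name


@dataclass(frozen=True)
class ContactRecord:
    """A single bone-pair contact in one taxon.

    ``status`` is ``present`` (with at least one segment), ``absent`` (the
    bones demonstrably do not meet) or ``unknown`` (the region cannot be
    assessed).  ``bone_a < bone_b`` under the canonical lexicographic
    ordering and relations are expressed as ``bone_a`` acting on ``bone_b``.
    """

    bone_a: str
    bone_b: str
    status: str
    segments: tuple = ()

    def __post_init__(self) -> None:
        _check_bone(self.bone_a)
        _check_bone(self.bone_b)
        if self.bone_a == self.bone_b:
            raise SelfContactError(f"self-contact: {self.bone_a!r}")
        if self.bone_a > self.bone_b:
            raise ContactError(
                f"record not canonical: {self.bone_a!r} > {self.bone_b!r}"
            )
        if self.status not in ("present", "absent", "unknown"):
            raise ContactError(f"invalid status: {self.status!r}")
        object.__setattr__(self, "segments", tuple(self.segments))
        if self.status == "present" and not self.segments:
            raise ContactError("present contact requires at least one segment")
        if self.status != "present" and self.segments:
            raise ContactError(f"{self.status} contact must carry no segments")

    @property
    def pair(self) -> tuple:
        return (self.bone_a, self.bone_b)


def canonicalize_contact(
    bone_x: str,
    bone_y: str,
    segments: Iterable[Union[ContactSegment, tuple]],
    status: str = "present",
) -> ContactRecord:
    """Build a canonical :class:`ContactRecord` from a directed observation.

    ``segments`` describe ``bone_x`` acting on ``bone_y``; if the canonical
    ordering swaps the bones, every ``o``/``u`` and ``c``/``cb`` code is
    replaced by its complement so the stored record is direction-free.
    """
    _check_bone(bone_x)
    _check_bone(bone_y)
    if bone_x == bone_y:
        raise SelfContactError(f"self-contact: {bone_x!r}")
    segs = tuple(
        s if isinstance(s, ContactSegment) else ContactSegment(*s) for s in segments
    )
    if bone_x < bone_y:
        return ContactRecord(bone_x, bone_y, status, segs)
    return ContactRecord(bone_y, bone_x, status, tuple(s.flipped() for s in segs))


@dataclass
class ContactTable:
    """Per-taxon map of canonical bone pairs to contact records."""

    taxa: list = field(default_factory=list)
    records: dict = field(default_factory=dict)
    bone_vocabulary: tuple = BONE_VOCABULARY

    def add(self, taxon: str, record: ContactRecord) -> None:
        key = (taxon, record.pair)
        if key in self.records:
            raise IntegrityError(f"duplicate record for {key}")
        if taxon not in self.taxa:
            self.taxa.append(taxon)
        self.records[key] = record

    def get(self, taxon: str, pair: tuple) -> Optional[ContactRecord]:
        return self.records.get((taxon, tuple(sorted(pair))))

    def pairs_for(self, taxon: str) -> dict:
        return {
            pair: rec for (tx, pair), rec in self.records.items() if tx == taxon
        }

    def __eq__(self, other) -> bool:
        if not isinstance(other, ContactTable):
            return NotImplemented
        return (
            sorted(self.taxa) == sorted(other.taxa)
            and self.records == other.records
        )


_COLUMNS = ["taxon", "bone_a", "bone_b", "status", "segment_index", "spatial", "depth"]


def read_contact_table(path, dialect: str = "long_tsv") -> ContactTable:
    """Read a contact table from the long tab-separated format.

    One row per segment; ``absent``/``unknown`` contacts occupy a single row
    with blank segment fields.  Records are canonicalized on input, so the
    file may state either bone first.
    """
    if dialect != "long_tsv":
        raise ValueError(f"unsupported dialect: {dialect!r}")
    path = Path(path)
    grouped: dict = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != _COLUMNS:
            raise ParseError(
                f"{path}: expected header {_COLUMNS}, got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            taxon = row["taxon"].strip()
            a, b = row["bone_a"].strip(), row["bone_b"].strip()
            status = row["status"].strip()
            if not taxon or not a or not b:
                raise ParseError(f"{path}:{lineno}: missing taxon or bone name")
            if status not in ("present", "absent", "unknown"):
                raise ParseError(f"{path}:{lineno}: bad status {status!r}")
            key = (taxon, a, b)
            entry = grouped.setdefault(key, {"status": status, "segments": {}, "line": lineno})
            if entry["status"] != status:
                raise IntegrityError(
                    f"{path}:{lineno}: conflicting status for {key}"
                )
            if status == "present":
                idx_raw = row["segment_index"].strip()
                if not idx_raw:
                    raise ParseError(
                        f"{path}:{lineno}: present row requires segment_index"
                    )
                try:
                    idx = int(idx_raw)
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: bad segment_index {idx_raw!r}"
                    ) from exc
                if idx in entry["segments"]:
                    raise IntegrityError(
                        f"{path}:{lineno}: duplicate segment {idx} for {key}"
                    )
                spatial = row["spatial"].strip()
                depth = row["depth"].strip()
                if spatial not in SPATIAL_CODES:
                    raise ParseError(
                        f"{path}:{lineno}: bad spatial code {spatial!r}"
                    )
                try:
                    seg = ContactSegment(spatial, SutureDepth.from_code(depth))
                except ParseError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
                entry["segments"][idx] = seg
            else:
                if len(entry["segments"]) or row["segment_index"].strip():
                    raise IntegrityError(
                        f"{path}:{lineno}: segment data on {status} contact {key}"
                    )
                if key in grouped and entry["line"] != lineno:
                    raise IntegrityError(f"{path}:{lineno}: duplicate row for {key}")

    table = ContactTable()
    for (taxon, a, b), entry in grouped.items():
        if entry["status"] == "present":
            idxs = sorted(entry["segments"])
            if idxs != list(range(1, len(idxs) + 1)):
                raise IntegrityError(
                    f"{path}: non-contiguous segment indices for {(taxon, a, b)}"
                )
            segs = [entry["segments"][i] for i in idxs]
            record = canonicalize_contact(a, b, segs)
        else:
            record = canonicalize_contact(a, b, (), status=entry["status"])
        table.add(taxon, record)
    return table


def write_contact_table(table: ContactTable, path) -> None:
    """Write ``table`` in the long tab-separated format (round-trip safe)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_COLUMNS)
        for taxon in table.taxa:
            for pair in sorted(table.pairs_for(taxon)):
                rec = table.records[(taxon, pair)]
                if rec.status == "present":
                    for i, seg in enumerate(rec.segments, start=1):
                        writer.writerow(
                            [taxon, rec.bone_a, rec.bone_b, rec.status,
                             i, seg.spatial, seg.depth.code]
                        )
                else:
                    writer.writerow(
                        [taxon, rec.bone_a, rec.bone_b, rec.status, "", "", ""]
                    )


def validate_table(table: ContactTable) -> list:
    """Return a list of human-readable integrity issues (empty = valid)."""
    issues = []
    vocab = frozenset(table.bone_vocabulary)
    seen_taxa = set()
    for (taxon, pair), rec in table.records.items():
        seen_taxa.add(taxon)
        for bone in pair:
            if bone not in vocab:
                issues.append(f"{taxon}: bone {bone!r} not in vocabulary")
        if rec.status == "present" and not rec.segments:
            issues.append(f"{taxon}: present contact {pair} has no segments")
    for taxon in table.taxa:
        if taxon not in seen_taxa:
            issues.append(f"taxon {taxon!r} has no contact records")
    return issues
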