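"""Discrete morphological character matrices and their assembly.

Supports the workflow of updating a published matrix for a re-study of a
fossil: reading/writing NEXUS and TNT dialects, inserting newly defined
characters at stated positions (which renumbers all later characters),
applying a recoding patch guarded by the expected previous states,
flagging ordered (morphocline) characters, and deactivating taxa without
deleting them from the file.

Cells are frozensets of integer states (singletons or polymorphisms) or
the sentinels :data:`MISSING` (``?``) and :data:`GAP` (``-``).  The gap
symbol is preserved on round trips but treated exactly like missing data
in all counting, the usual convention for morphology.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "MISSING",
    "GAP",
    "CharacterMatrix",
    "CharacterDef",
    "RecodingEntry",
    "RecodingError",
    "read_matrix",
    "write_matrix",
    "new_characters_table3",
    "insert_characters",
    "apply_recoding_patch",
    "builtin_dlowii_patch",
    "set_ordered",
    "ORDERED_CHARACTERS",
    "deactivate_taxa",
    "synthetic_base_matrix",
    "STUDY_TAXA",
]

#: Missing-data cell (``?``).
MISSING = "?"
#: Inapplicable/gap cell (``-``); counted as missing everywhere.
GAP = "-"

SYMBOLS = "0123456789"

#: The four skulls scored for the newly defined characters.
STUDY_TAXA = (
    "Desmatochelys_lowii",
    "Eretmochelys_imbricata",
    "Dermochelys_coriacea",
    "Chelydra_serpentina",
)

#: 1-based indices (final numbering) of the morphocline characters run
#: ordered; 37 in total.
ORDERED_CHARACTERS = (
    7, 17, 22, 44, 49, 52, 55, 57, 59, 66, 70, 71, 76, 79, 89, 101, 106,
    118, 122, 128, 135, 138, 144, 148, 171, 174, 189, 191, 211, 223, 225,
    229, 244, 256, 257, 258, 262,
)


class RecodingError(ValueError):
    """A recoding patch did not match the matrix it was applied to."""


@dataclass
class CharacterMatrix:
    """Taxa-by-characters matrix of discrete state sets.

    ``rows`` maps each taxon label to its list of cells; ``characters``
    holds per-column names (base columns keep their original number as
    name, inserted columns carry their definition's name).
    """

    taxa: List[str] = field(default_factory=list)
    characters: List[str] = field(default_factory=list)
    rows: Dict[str, list] = field(default_factory=dict)
    ordered: List[bool] = field(default_factory=list)
    active: Dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ordered:
            self.ordered = [False] * len(self.characters)
        if not self.active:
            self.active = {t: True for t in self.taxa}
        self._validate()

    def _validate(self) -> None:
        n = len(self.characters)
        if len(self.ordered) != n:
            raise ValueError("ordered flags do not match character count")
        for taxon in self.taxa:
            if taxon not in self.rows or len(self.rows[taxon]) != n:
                raise ValueError(f"ragged or missing row for taxon {taxon!r}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    @property
    def n_active(self) -> int:
        return sum(1 for t in self.taxa if self.active[t])

    def cell(self, taxon: str, index: int):
        """Cell for ``taxon`` at 1-based character ``index``."""
        return self.rows[taxon][index - 1]

    def set_cell(self, taxon: str, index: int, value) -> None:
        self.rows[taxon][index - 1] = value

    def copy(self) -> "CharacterMatrix":
        return CharacterMatrix(
            taxa=list(self.taxa),
            characters=list(self.characters),
            rows={t: list(r) for t, r in self.rows.items()},
            ordered=list(self.ordered),
            active=dict(self.active),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.characters == other.characters
            and self.rows == other.rows
            and self.ordered == other.ordered
            and self.active == other.active
        )


# ---------------------------------------------------------------------------
# cell <-> text

def _cell_to_text(cell, dialect: str) -> str:
    if cell == MISSING:
        return "?"
    if cell == GAP:
        return "-"
    states = sorted(cell)
    if len(states) == 1:
        return SYMBOLS[states[0]]
    body = "".join(SYMBOLS[s] for s in states)
    return f"[{body}]" if dialect == "tnt" else "{" + body + "}"


def _parse_row_text(text: str, where: str) -> list:
    cells = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch in " \t":
            i += 1
            continue
        if ch == "?":
            cells.append(MISSING)
            i += 1
        elif ch == "-":
            cells.append(GAP)
            i += 1
        elif ch in "{([":
            close = {"{": "}", "(": ")", "[": "]"}[ch]
            j = text.find(close, i)
            if j < 0:
                raise ValueError(f"{where}: unterminated state set")
            states = frozenset(
                SYMBOLS.index(c) for c in text[i + 1:j] if c in SYMBOLS
            )
            if not states:
                raise ValueError(f"{where}: empty state set")
            cells.append(states)
            i = j + 1
        elif ch in SYMBOLS:
            cells.append(frozenset({SYMBOLS.index(ch)}))
            i += 1
        else:
            raise ValueError(f"{where}: unexpected symbol {ch!r}")
    return cells


# ---------------------------------------------------------------------------
# I/O

def _detect_format(path: Path) -> str:
    head = path.read_text(encoding="utf-8", errors="replace")[:4096].lower()
    if head.lstrip().startswith("#nexus"):
        return "nexus"
    if "xread" in head:
        return "tnt"
    suffix = path.suffix.lower()
    if suffix in (".nex", ".nexus"):
        return "nexus"
    if suffix in (".tnt", ".ss"):
        return "tnt"
    raise ValueError(f"cannot detect matrix format of {path}")


def read_matrix(path, format: Optional[str] = None) -> CharacterMatrix:
    """Read a character matrix from a NEXUS or TNT (xread) file."""
    path = Path(path)
    fmt = format or _detect_format(path)
    if fmt == "nexus":
        return _read_nexus(path)
    if fmt == "tnt":
        return _read_tnt(path)
    raise ValueError(f"unsupported format: {fmt!r}")


def _read_nexus(path: Path) -> CharacterMatrix:
    import dendropy

    dmat = dendropy.StandardCharacterMatrix.get(path=path, schema="nexus")
    taxa, rows = [], {}
    for taxon in dmat:
        label = taxon.label.replace(" ", "_")
        taxa.append(label)
        cells = []
        for state in dmat[taxon]:
            if state.symbol == "?":
                cells.append(MISSING)
            elif state.symbol == "-":
                cells.append(GAP)
            elif state.symbol is not None:
                cells.append(frozenset({SYMBOLS.index(state.symbol)}))
            else:
                members = frozenset(
                    SYMBOLS.index(s.symbol)
                    for s in state.member_states
                    if s.symbol in SYMBOLS
                )
                cells.append(members)
        rows[label] = cells
    n = len(rows[taxa[0]]) if taxa else 0
    matrix = CharacterMatrix(
        taxa=taxa,
        characters=[str(i + 1) for i in range(n)],
        rows=rows,
    )
    # ordered characters recorded in an ASSUMPTIONS TYPESET line
    text = path.read_text(encoding="utf-8")
    m = re.search(r"typeset[^=]*=\s*ord\s*:\s*([0-9\s]+)[;,]", text, re.I)
    if m:
        indices = [int(tok) for tok in m.group(1).split()]
        matrix = set_ordered(matrix, indices)
    return matrix


def _read_tnt(path: Path) -> CharacterMatrix:
    text = path.read_text(encoding="utf-8")
    text = re.sub(r"'[^']*'", " ", text)  # strip quoted comments
    m = re.search(r"xread\s+(\d+)\s+(\d+)(.*?);", text, re.S | re.I)
    if not m:
        raise ValueError(f"{path}: no xread block found")
    nchar, ntax = int(m.group(1)), int(m.group(2))
    body = m.group(3).strip()
    taxa, rows = [], {}
    for lineno, line in enumerate(body.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        name, _, row_text = line.partition(" ")
        cells = _parse_row_text(row_text.strip(), f"{path}:{name}")
        if len(cells) != nchar:
            raise ValueError(
                f"{path}: taxon {name!r} has {len(cells)} cells, expected {nchar}"
            )
        taxa.append(name)
        rows[name] = cells
    if len(taxa) != ntax:
        raise ValueError(f"{path}: {len(taxa)} taxa found, header says {ntax}")
    matrix = CharacterMatrix(
        taxa=taxa, characters=[str(i + 1) for i in range(nchar)], rows=rows
    )
    m = re.search(r"ccode\s+([^;]*);", text, re.I)
    if m:
        ordered = [
            int(tok.lstrip("+")) + 1
            for tok in m.group(1).split()
            if tok.startswith("+")
        ]
        if ordered:
            matrix = set_ordered(matrix, ordered)
    return matrix


def write_matrix(matrix: CharacterMatrix, path, format: str = "nexus") -> None:
    """Write ``matrix`` to NEXUS or TNT; ordered flags are preserved."""
    path = Path(path)
    pad = max((len(t) for t in matrix.taxa), default=0) + 2
    ordered_idx = [i + 1 for i, o in enumerate(matrix.ordered) if o]
    if format == "nexus":
        lines = [
            "#NEXUS",
            "BEGIN DATA;",
            f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};",
            'FORMAT DATATYPE=STANDARD SYMBOLS="0123456789" MISSING=? GAP=-;',
            "MATRIX",
        ]
        for taxon in matrix.taxa:
            row = "".join(_cell_to_text(c, "nexus") for c in matrix.rows[taxon])
            lines.append(f"{taxon.ljust(pad)}{row}")
        lines += [";", "END;"]
        if ordered_idx:
            lines += [
                "BEGIN ASSUMPTIONS;",
                "TYPESET * default = ord: " + " ".join(map(str, ordered_idx)) + ";",
                "END;",
            ]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "tnt":
        lines = [
            "xread",
            f"{matrix.n_characters} {matrix.n_taxa}",
        ]
        for taxon in matrix.taxa:
            row = "".join(_cell_to_text(c, "tnt") for c in matrix.rows[taxon])
            lines.append(f"{taxon.ljust(pad)}{row}")
        lines.append(";")
        if ordered_idx:
            lines.append(
                "ccode " + " ".join(f"+{i - 1}" for i in ordered_idx) + ";"
            )
        lines.append("proc /;")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unsupported format: {format!r}")


# ---------------------------------------------------------------------------
# the seven added characters

@dataclass(frozen=True)
class CharacterDef:
    """A character to insert: its slot in the base numbering, a name, and
    codings for the taxa it was scored for (all others become MISSING)."""

    slot: int
    name: str
    description: str
    codings: dict


def _c(state) -> object:
    if state == "-":
        return GAP
    return frozenset({int(state)})


def new_characters_table3() -> List[CharacterDef]:
    """The seven characters added to the base matrix, scored only for the
    four study skulls (dashes = inapplicable, treated as missing)."""
    rows = [
        (32, "Recess on the ventral side of the dorsal part of the postorbital:"
             " 0 = absent; 1 = present", ("1", "0", "0", "1")),
        (33, "Position of notch in the posterior margin of the orbit:"
             " 0 = at the top of the orbit; 1 = at the mid level", ("1", "0", "0", "1")),
        (62, "Participation of the epipterygoid to the foramen nervi trigemini:"
             " 0 = absent; 1 = present", ("0", "-", "-", "1")),
        (64, "Extent of the prootic-parietal suture:"
             " 0 = very short or absent; 1 = long", ("1", "0", "0", "1")),
        (87, "Dorsomedial process of the prootic in medial view:"
             " 0 = absent; 1 = present", ("-", "0", "0", "1")),
        (88, "Participation of the opisthotic to the foramen stapedio-temporale:"
             " 0 = absent; 1 = present", ("1", "0", "1", "0")),
        (92, "Processus epipterygoideus of the quadrate:"
             " 0 = absent; 1 = present", ("0", "1", "1", "1")),
    ]
    return [
        CharacterDef(
            slot=slot,
            name=f"add{slot}",
            description=desc,
            codings={t: _c(s) for t, s in zip(STUDY_TAXA, states)},
        )
        for slot, desc, states in rows
    ]


def insert_characters(
    matrix: CharacterMatrix, defs: Sequence[CharacterDef]
) -> Tuple[CharacterMatrix, Dict[int, int]]:
    """Insert ``defs`` at their slots in the base numbering.

    A definition with slot *p* is placed immediately before the base
    matrix's character *p*; every base character keeps its relative order
    and is renumbered accordingly.  Returns the new matrix and the mapping
    from old (base) to new 1-based indices.  Re-inserting a definition
    whose name already exists is refused.
    """
    existing = set(matrix.characters)
    for d in defs:
        if d.name in existing:
            raise ValueError(f"character {d.name!r} already inserted")
    slots = [d.slot for d in defs]
    if len(set(slots)) != len(slots):
        raise ValueError("duplicate insertion slots")
    by_slot = {d.slot: d for d in defs}
    unknown = set().union(*(d.codings.keys() for d in defs)) - set(matrix.taxa)
    if unknown:
        raise KeyError(f"codings for taxa not in matrix: {sorted(unknown)}")

    n = matrix.n_characters
    new_chars: List[str] = []
    new_ordered: List[bool] = []
    plan: List[Tuple[str, object]] = []  # ("base", old_idx) or ("def", def)
    for old in range(1, n + 1):
        if old in by_slot:
            plan.append(("def", by_slot[old]))
        plan.append(("base", old))
    for slot in sorted(by_slot):
        if slot > n:
            plan.append(("def", by_slot[slot]))

    mapping: Dict[int, int] = {}
    for kind, payload in plan:
        if kind == "base":
            mapping[payload] = len(new_chars) + 1
            new_chars.append(matrix.characters[payload - 1])
            new_ordered.append(matrix.ordered[payload - 1])
        else:
            new_chars.append(payload.name)
            new_ordered.append(False)

    new_rows: Dict[str, list] = {}
    for taxon in matrix.taxa:
        row = []
        for kind, payload in plan:
            if kind == "base":
                row.append(matrix.rows[taxon][payload - 1])
            else:
                row.append(payload.codings.get(taxon, MISSING))
        new_rows[taxon] = row

    out = CharacterMatrix(
        taxa=list(matrix.taxa),
        characters=new_chars,
        rows=new_rows,
        ordered=new_ordered,
        active=dict(matrix.active),
    )
    return out, mapping


# ---------------------------------------------------------------------------
# recoding patch

@dataclass(frozen=True)
class RecodingEntry:
    taxon: str
    char_index: int  # 1-based, in the matrix the patch targets
    old: object
    new: object
    note: str = ""


def builtin_dlowii_patch() -> List[RecodingEntry]:
    """The ten re-scorings of *Desmatochelys lowii* (final numbering)."""
    dl = "Desmatochelys_lowii"
    entries = [
        (8, "0", "?", "prefrontal scutes cannot be observed"),
        (18, "1", "0", "the median hole is damage, not a pineal foramen"),
        (21, "1", "0", "jugal separated from quadrate by the quadratojugal"),
        (78, "1", "0", "no median pterygoid ridge; area is flat"),
        (84, "1", "0", "basioccipital tubercles present in referred material"),
        (90, "0", "1", "rostrum basisphenoidale rod-like"),
        (96, "0", "1", "dorsum sellae notably high"),
        (105, "0", "2", "foramen nervi hypoglossi covered by basioccipital"),
        (107, "1", "?", "carotid foramen not visible"),
        (109, "0", "?", "fenestra perilymphatica cannot be identified"),
    ]
    def cell(tok):
        return MISSING if tok == "?" else frozenset({int(tok)})
    return [
        RecodingEntry(dl, idx, cell(old), cell(new), note)
        for idx, old, new, note in entries
    ]


def apply_recoding_patch(
    matrix: CharacterMatrix, patch: Sequence[RecodingEntry]
) -> Tuple[CharacterMatrix, List[str]]:
    """Apply ``patch`` after verifying every expected previous state.

    If any cell does not hold its expected old state (for example because
    the patch was already applied, or the matrix was renumbered), nothing
    is changed and :class:`RecodingError` reports every mismatch.
    """
    mismatches = []
    for entry in patch:
        if entry.taxon not in matrix.rows:
            mismatches.append(f"unknown taxon {entry.taxon!r}")
            continue
        if not 1 <= entry.char_index <= matrix.n_characters:
            mismatches.append(f"character {entry.char_index} out of bounds")
            continue
        current = matrix.cell(entry.taxon, entry.char_index)
        if current != entry.old:
            mismatches.append(
                f"character {entry.char_index} of {entry.taxon}: expected "
                f"{entry.old!r}, found {current!r}"
            )
    if mismatches:
        raise RecodingError("; ".join(mismatches))
    out = matrix.copy()
    audit = []
    for entry in patch:
        out.set_cell(entry.taxon, entry.char_index, entry.new)
        audit.append(
            f"{entry.taxon} char {entry.char_index}: {entry.old!r} -> "
            f"{entry.new!r} ({entry.note})"
        )
    return out, audit


# ---------------------------------------------------------------------------
# flags

def set_ordered(matrix: CharacterMatrix, indices: Iterable[int]) -> CharacterMatrix:
    """Return a copy with the 1-based ``indices`` flagged as ordered."""
    out = matrix.copy()
    for idx in indices:
        if not 1 <= idx <= out.n_characters:
            raise IndexError(f"character index out of range: {idx}")
        out.ordered[idx - 1] = True
    return out


def deactivate_taxa(matrix: CharacterMatrix, labels: Iterable[str]) -> CharacterMatrix:
    """Return a copy with ``labels`` excluded from analysis but kept in
    the matrix."""
    out = matrix.copy()
    for label in labels:
        if label not in out.active:
            raise KeyError(f"unknown taxon: {label!r}")
        out.active[label] = False
    return out


# ---------------------------------------------------------------------------
# synthetic stand-in for the published base matrix

def synthetic_base_matrix(
    seed: int, n_taxa: int = 154, n_chars: int = 256
) -> CharacterMatrix:
    """Random base matrix with the published study's shape (synthetic).

    A stand-in with the dimensions and cell vocabulary of the published
    154-taxon global turtle matrix: mostly binary characters with some
    multistate columns, about 30 % missing data, occasional gaps and
    polymorphisms.  The four study taxa, the outgroup and filler taxa are
    included, and *Desmatochelys lowii* carries the previous codings that
    the built-in recoding patch expects, so the full assembly pipeline can
    run end to end on it.
    """
    if n_taxa < 6:
        raise ValueError("need at least the five named taxa plus one filler")
    rng = np.random.default_rng(seed)
    taxa = ["Odontochelys_semitestacea", *STUDY_TAXA]
    taxa += [f"Synthtax_{i:03d}" for i in range(len(taxa) + 1, n_taxa + 1)]
    n_states = rng.choice([2, 2, 2, 3, 4], size=n_chars)
    rows: Dict[str, list] = {}
    for taxon in taxa:
        cells = []
        for j in range(n_chars):
            r = rng.random()
            if r < 0.30:
                cells.append(MISSING)
            elif r < 0.32:
                cells.append(GAP)
            elif r < 0.34 and n_states[j] > 1:
                pair = rng.choice(n_states[j], size=2, replace=False)
                cells.append(frozenset(int(s) for s in pair))
            else:
                cells.append(frozenset({int(rng.integers(n_states[j]))}))
        rows[taxon] = cells
    matrix = CharacterMatrix(
        taxa=taxa, characters=[str(i + 1) for i in range(n_chars)], rows=rows
    )
    # previous D. lowii codings, in the base numbering
    previous = {8: "0", 18: "1", 21: "1", 74: "1", 80: "1", 86: "0",
                90: "0", 98: "0", 100: "1", 102: "0"}
    for base_idx, tok in previous.items():
        if base_idx <= n_chars:
            matrix.set_cell("Desmatochelys_lowii", base_idx, frozenset({int(tok)}))
    return matrix
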