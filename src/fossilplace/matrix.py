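"""Discrete morphological character matrices.

Cells distinguish three kinds of entry, following standard NEXUS usage:

* **observed** — one or more integer state codes; more than one code records
  polymorphism or scoring ambiguity (``{01}`` / ``(01)`` groups),
* **missing** (``?``) — the character could not be scored (e.g. the structure
  is hidden in the fossil),
* **inapplicable** (``-``) — the character logically cannot be scored (a
  feature of a structure the taxon lacks).

The distinction between missing and inapplicable is preserved through
parse/write round-trips even though the default parsimony scoring treats both
as full ambiguity; downstream code that wants to treat them differently can.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

__all__ = [
    "CellState",
    "CharacterMatrix",
    "MatrixParseError",
    "DimensionMismatchError",
    "DuplicateTaxonError",
    "UnknownSymbolError",
    "UnknownTaxonError",
    "parse_matrix",
    "write_matrix",
    "count_applicable",
    "normalize_label",
]


class MatrixParseError(ValueError):
    """Base class for character-matrix parse failures."""


class DimensionMismatchError(MatrixParseError):
    """Declared and parsed matrix dimensions disagree, or rows have unequal length."""


class DuplicateTaxonError(MatrixParseError):
    """The same taxon label occurs more than once."""


class UnknownSymbolError(MatrixParseError):
    """A cell symbol outside digits, '?', '-' and polymorphism groups."""


class UnknownTaxonError(KeyError):
    """A taxon label absent from the matrix."""


def normalize_label(label: str) -> str:
    """Canonicalize a taxon label: strip surrounding quotes, underscores -> spaces.

    Newick and NEXUS files routinely disagree on quoting and on
    underscore-vs-space; matching between matrix and tree is exact after this
    normalization.
    """
    label = label.strip()
    if len(label) >= 2 and label[0] == label[-1] and label[0] in "'\"":
        label = label[1:-1]
    return label.replace("_", " ").strip()


@dataclass(frozen=True)
class CellState:
    """One cell of the matrix: a kind plus a (possibly empty) state set."""

    kind: str  # "observed" | "missing" | "inapplicable"
    states: frozenset[int] = frozenset()

    _KINDS = ("observed", "missing", "inapplicable")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown cell kind {self.kind!r}")
        if self.kind == "observed":
            if not self.states:
                raise ValueError("observed cell requires at least one state")
            if any(s < 0 for s in self.states):
                raise ValueError("state codes must be non-negative")
        elif self.states:
            raise ValueError(f"{self.kind} cell must have an empty state set")

    @classmethod
    def observed(cls, states: Iterable[int] | int) -> "CellState":
        if isinstance(states, int):
            states = (states,)
        return cls("observed", frozenset(states))

    @classmethod
    def missing(cls) -> "CellState":
        return cls("missing")

    @classmethod
    def inapplicable(cls) -> "CellState":
        return cls("inapplicable")

    @property
    def is_observed(self) -> bool:
        return self.kind == "observed"

    def symbol(self) -> str:
        """The NEXUS token for this cell (``?``, ``-``, ``3`` or ``{03}``)."""
        if self.kind == "missing":
            return "?"
        if self.kind == "inapplicable":
            return "-"
        codes = sorted(self.states)
        if any(s > 9 for s in codes):
            raise ValueError("state codes above 9 cannot be written as single symbols")
        if len(codes) == 1:
            return str(codes[0])
        return "{" + "".join(str(s) for s in codes) + "}"


@dataclass
class CharacterMatrix:
    """An ordered taxa × characters grid of :class:`CellState`.

    Taxon labels are unique (checked) and stored in input order; rows are
    addressed by label.
    """

    taxa: list[str]
    rows: dict[str, list[CellState]]
    state_labels: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.taxa:
            raise ValueError("matrix needs at least one taxon")
        if len(set(self.taxa)) != len(self.taxa):
            raise DuplicateTaxonError("duplicate taxon label in matrix")
        lengths = {len(self.rows[t]) for t in self.taxa}
        if len(lengths) > 1:
            raise DimensionMismatchError(f"rows of unequal length: {sorted(lengths)}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return len(self.rows[self.taxa[0]])

    def row(self, taxon: str) -> list[CellState]:
        try:
            return self.rows[taxon]
        except KeyError:
            raise UnknownTaxonError(taxon) from None

    def column(self, index: int) -> dict[str, CellState]:
        return {t: self.rows[t][index] for t in self.taxa}

    def max_state(self) -> int:
        mx = -1
        for t in self.taxa:
            for c in self.rows[t]:
                if c.is_observed:
                    mx = max(mx, max(c.states))
        return mx

    def with_row(self, taxon: str, cells: Sequence[CellState]) -> "CharacterMatrix":
        """A copy with one row replaced (used by the fossilizer)."""
        if taxon not in self.rows:
            raise UnknownTaxonError(taxon)
        if len(cells) != self.n_chars:
            raise DimensionMismatchError("replacement row has the wrong length")
        rows = {t: list(r) for t, r in self.rows.items()}
        rows[taxon] = list(cells)
        return CharacterMatrix(list(self.taxa), rows, self.state_labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return self.taxa == other.taxa and all(
            self.rows[t] == other.rows[t] for t in self.taxa
        )


# ---------------------------------------------------------------------------
# parsing

_CELL_TOKEN = re.compile(r"\{[^{}()]*\}|\([^{}()]*\)|\S")


def _token_to_cell(token: str) -> CellState:
    if token == "?":
        return CellState.missing()
    if token == "-":
        return CellState.inapplicable()
    if token[0] in "{(":
        inner = token[1:-1].replace(",", "").replace(" ", "")
        if not inner:
            raise UnknownSymbolError(f"empty polymorphism group {token!r}")
        if "-" in inner and not inner.replace("-", ""):
            return CellState.inapplicable()
        digits = [c for c in inner if c.isdigit()]
        if len(digits) != len(inner.replace("-", "")):
            raise UnknownSymbolError(f"bad symbol inside group {token!r}")
        return CellState.observed(int(d) for d in digits)
    if token.isdigit() and len(token) == 1:
        return CellState.observed(int(token))
    raise UnknownSymbolError(f"unknown cell symbol {token!r}")


def _parse_bare(text: str) -> CharacterMatrix:
    """Whitespace-delimited fallback dialect: one ``taxon cells...`` row per line."""
    taxa: list[str] = []
    rows: dict[str, list[CellState]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        label = normalize_label(parts[0])
        body = parts[1] if len(parts) > 1 else ""
        cells = [_token_to_cell(tok) for tok in _CELL_TOKEN.findall(body)]
        if label in rows:
            raise DuplicateTaxonError(f"duplicate taxon label {label!r}")
        taxa.append(label)
        rows[label] = cells
    if not taxa:
        raise MatrixParseError("no matrix rows found")
    lengths = {len(rows[t]) for t in taxa}
    if len(lengths) > 1:
        raise DimensionMismatchError(
            f"rows have unequal numbers of characters: {sorted(lengths)}"
        )
    return CharacterMatrix(taxa, rows)


_DIM_RE = re.compile(
    r"DIMENSIONS[^;]*?NTAX\s*=\s*(\d+)[^;]*?NCHAR\s*=\s*(\d+)", re.I | re.S
)


def _parse_nexus(text: str) -> CharacterMatrix:
    dims = _DIM_RE.search(text)
    declared = (int(dims.group(1)), int(dims.group(2))) if dims else None

    if declared and declared[1] == 0:
        # dendropy rejects zero-character blocks; taxa rows are bare labels
        m = re.search(r"MATRIX(.*?);", text, re.I | re.S)
        if m is None:
            raise MatrixParseError("no MATRIX block found")
        labels = [normalize_label(tok) for tok in m.group(1).split()]
        if len(labels) != declared[0]:
            raise DimensionMismatchError(
                f"declared NTAX={declared[0]} but found {len(labels)} labels"
            )
        if len(set(labels)) != len(labels):
            raise DuplicateTaxonError("duplicate taxon label")
        return CharacterMatrix(labels, {t: [] for t in labels})

    try:
        dmat = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except dendropy.utility.error.DataParseError as exc:  # classify if possible
        msg = str(exc)
        low = msg.lower()
        if declared is not None and "interleave" not in text.lower():
            # dendropy reports a row/NCHAR disagreement as a symbol error
            # (it consumes the next label as a state), so recheck row lengths
            block = re.search(r"MATRIX(.*?);", text, re.I | re.S)
            if block:
                for line in block.group(1).splitlines():
                    parts = line.strip().split(None, 1)
                    if len(parts) == 2:
                        n = len(_CELL_TOKEN.findall(parts[1]))
                        if n != declared[1]:
                            raise DimensionMismatchError(
                                f"row {parts[0]!r} has {n} characters, "
                                f"declared NCHAR={declared[1]}"
                            ) from exc
        if "expecting" in low and "characters" in low or "nchar" in low:
            raise DimensionMismatchError(msg) from exc
        if "duplicate" in low or "multiple" in low:
            raise DuplicateTaxonError(msg) from exc
        if "symbol" in low or "unrecognized" in low:
            raise UnknownSymbolError(msg) from exc
        raise MatrixParseError(msg) from exc

    taxa: list[str] = []
    rows: dict[str, list[CellState]] = {}
    for taxon in dmat.taxon_namespace:
        label = normalize_label(taxon.label)
        if label in rows:
            raise DuplicateTaxonError(f"duplicate taxon label {label!r}")
        cells: list[CellState] = []
        for st in dmat[taxon]:
            sym = st.symbol
            if sym == "?":
                cells.append(CellState.missing())
            elif sym == "-":
                cells.append(CellState.inapplicable())
            elif sym is not None and sym.isdigit():
                cells.append(CellState.observed(int(sym)))
            else:  # polymorphic / ambiguous group
                members = [s.symbol for s in st.fundamental_states]
                digits = [int(s) for s in members if s.isdigit()]
                if not digits:
                    cells.append(CellState.inapplicable())
                else:
                    cells.append(CellState.observed(digits))
        taxa.append(label)
        rows[label] = cells

    mat = CharacterMatrix(taxa, rows)
    if declared is not None:
        if mat.n_taxa != declared[0] or mat.n_chars != declared[1]:
            raise DimensionMismatchError(
                f"declared {declared[0]}x{declared[1]} but parsed "
                f"{mat.n_taxa}x{mat.n_chars}"
            )
    return mat


def parse_matrix(text: str) -> CharacterMatrix:
    """Parse a discrete character matrix.

    Accepts a NEXUS ``DATA``/``CHARACTERS`` block (interleaved or not; parsed
    with dendropy) or, failing the ``#NEXUS`` header, a bare whitespace-
    delimited block with one ``taxon  symbols`` row per line.  Both ``{..}``
    and ``(..)`` polymorphism groups are accepted and stored identically.

    Raises
    ------
    DimensionMismatchError, DuplicateTaxonError, UnknownSymbolError
        for the respective malformations; all subclass
        :class:`MatrixParseError`.
    """
    if text.lstrip().upper().startswith("#NEXUS"):
        return _parse_nexus(text)
    return _parse_bare(text)


def write_matrix(m: CharacterMatrix) -> str:
    """Serialize to a NEXUS DATA block that :func:`parse_matrix` reads back losslessly."""
    mx = max(m.max_state(), 1)
    symbols = "".join(str(s) for s in range(mx + 1))
    width = max(len(t.replace(" ", "_")) for t in m.taxa) + 2
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"DIMENSIONS NTAX={m.n_taxa} NCHAR={m.n_chars};",
        f'FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;',
        "MATRIX",
    ]
    for t in m.taxa:
        label = t.replace(" ", "_")
        body = "".join(c.symbol() for c in m.rows[t])
        lines.append(f"{label:<{width}}{body}")
    lines += [";", "END;", ""]
    return "\n".join(lines)


def count_applicable(m: CharacterMatrix, taxon: str) -> int:
    """Number of cells in *taxon*'s row scored with an actual state.

    Missing (``?``) and inapplicable (``-``) cells do not count; this is the
    per-taxon codability figure used as a matrix quality check (a largely
    complete extant taxon scores near ``n_chars``, a fragmentary fossil far
    less).
    """
    return sum(1 for c in m.row(taxon) if c.is_observed)
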