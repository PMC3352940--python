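"""Character matrices for morphological parsimony analysis.

A cell holds a *state set*: a singleton for an ordinary observation, a
multi-member set for polymorphism/uncertainty, or one of two markers —
``MISSING`` (``?``, no information) and ``INAPPLICABLE`` (``-``, the
character cannot be scored, e.g. a feature of a bone the taxon lacks).
By default both markers are scored as full ambiguity, the common default
of parsimony programs for morphology; ``gap_as_state`` turns ``-`` into an
extra state instead.

Character indices are 1-based in every file, report and error message, as
is conventional for published character lists; all internal arrays are
0-based and that convention never leaks past this module's API.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy

__all__ = [
    "MISSING",
    "INAPPLICABLE",
    "CharacterDefinition",
    "CharacterMatrix",
    "MatrixDialect",
    "MatrixError",
    "parse_matrix",
    "write_matrix",
    "prune_taxa",
]


class MatrixError(ValueError):
    pass


class _Marker:
    """Singleton cell marker."""

    __slots__ = ("name",)

    def __init__(self, name: str) -> None:
        self.name = name

    def __repr__(self) -> str:
        return self.name


MISSING = _Marker("MISSING")
INAPPLICABLE = _Marker("INAPPLICABLE")

Cell = "frozenset[int] | _Marker"


@dataclass(frozen=True)
class CharacterDefinition:
    """One character of the character list (1-based index)."""

    index: int
    description: str = ""
    states: tuple[int, ...] = (0, 1)
    ordered: bool = False

    def __post_init__(self) -> None:
        if self.index < 1:
            raise MatrixError(f"character index must be >= 1, got {self.index}")
        if len(self.states) < 1:
            raise MatrixError(f"character {self.index}: needs >= 1 state")


@dataclass(frozen=True)
class MatrixDialect:
    """How a matrix is written on disk."""

    format: str = "nexus"  # nexus | tsv
    missing_symbol: str = "?"
    gap_symbol: str = "-"
    poly_open: str = "{"
    poly_close: str = "}"

    def __post_init__(self) -> None:
        if self.missing_symbol == self.gap_symbol:
            raise MatrixError("missing and gap symbols must differ")
        if self.format not in ("nexus", "tsv"):
            raise MatrixError(f"unknown matrix format {self.format!r}")


NEXUS = MatrixDialect(format="nexus")
TSV = MatrixDialect(format="tsv")


class CharacterMatrix:
    """Taxa x characters table of state sets."""

    def __init__(
        self,
        taxa: Sequence[str],
        cells: Sequence[Sequence[object]],
        states: Sequence[tuple[int, ...]] | None = None,
        ordered: Sequence[bool] | None = None,
        definitions: Sequence[CharacterDefinition] | None = None,
    ) -> None:
        self.taxa: list[str] = list(taxa)
        self.cells: list[list[object]] = [list(row) for row in cells]
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise MatrixError(f"duplicate taxon names: {dupes}")
        if any(not t for t in self.taxa):
            raise MatrixError("empty taxon name")
        if len(self.cells) != len(self.taxa):
            raise MatrixError("one cell row required per taxon")
        ncols = {len(r) for r in self.cells}
        if len(ncols) > 1:
            for t, r in zip(self.taxa, self.cells):
                if len(r) != len(self.cells[0]):
                    raise MatrixError(
                        f"ragged matrix: taxon {t!r} has {len(r)} cells, "
                        f"expected {len(self.cells[0])}"
                    )
        self.n_char: int = len(self.cells[0]) if self.cells else 0

        if definitions is not None:
            if [d.index for d in definitions] != list(range(1, self.n_char + 1)):
                raise MatrixError("definition indices must be contiguous from 1")
            states = [d.states for d in definitions]
            ordered = [d.ordered for d in definitions]
        if states is None:
            states = [self._observed_states(j) or (0,) for j in range(self.n_char)]
        self.states: list[tuple[int, ...]] = [tuple(sorted(s)) for s in states]
        self.ordered: list[bool] = list(ordered) if ordered is not None else [False] * self.n_char
        self.definitions = list(definitions) if definitions is not None else None
        self.meta: dict = {}
        self._check_cells()

    # ------------------------------------------------------------------ #

    def _observed_states(self, j: int) -> tuple[int, ...]:
        s: set[int] = set()
        for row in self.cells:
            c = row[j]
            if isinstance(c, frozenset):
                s |= c
        return tuple(sorted(s))

    def _check_cells(self) -> None:
        for i, row in enumerate(self.cells):
            for j, c in enumerate(row):
                if c is MISSING or c is INAPPLICABLE:
                    continue
                if not isinstance(c, frozenset) or not c:
                    raise MatrixError(
                        f"cell ({self.taxa[i]!r}, char {j + 1}) is not a "
                        "non-empty state set or marker"
                    )
                extra = c - set(self.states[j])
                if extra:
                    raise MatrixError(
                        f"cell ({self.taxa[i]!r}, char {j + 1}) uses undeclared "
                        f"state(s) {sorted(extra)}"
                    )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> list[object]:
        try:
            return self.cells[self.taxa.index(taxon)]
        except ValueError:
            raise MatrixError(f"unknown taxon {taxon!r}") from None

    def column(self, j: int, gap_as_state: bool = False) -> dict[str, frozenset[int]]:
        """Scoring view of 0-based column ``j``: every cell a state set.

        MISSING becomes the full declared state set; INAPPLICABLE likewise
        unless ``gap_as_state``, in which case it becomes a dedicated extra
        state one past the declared maximum.
        """
        declared = frozenset(self.states[j])
        gap_state = max(self.states[j]) + 1
        out: dict[str, frozenset[int]] = {}
        for taxon, row in zip(self.taxa, self.cells):
            c = row[j]
            if c is MISSING:
                out[taxon] = declared | ({gap_state} if gap_as_state else frozenset())
            elif c is INAPPLICABLE:
                out[taxon] = frozenset([gap_state]) if gap_as_state else declared
            else:
                out[taxon] = c
        return out

    def column_informative(self, j: int) -> bool:
        """Parsimony-informative: >= 2 states each fixed in >= 2 taxa."""
        from collections import Counter

        counts: Counter[int] = Counter()
        for row in self.cells:
            c = row[j]
            if isinstance(c, frozenset) and len(c) == 1:
                counts[next(iter(c))] += 1
        return sum(1 for v in counts.values() if v >= 2) >= 2

    def equal_cells(self, other: "CharacterMatrix") -> bool:
        return (
            self.taxa == other.taxa
            and self.n_char == other.n_char
            and all(
                a is b if isinstance(a, _Marker) or isinstance(b, _Marker) else a == b
                for ra, rb in zip(self.cells, other.cells)
                for a, b in zip(ra, rb)
            )
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"CharacterMatrix({self.n_taxa} taxa x {self.n_char} characters)"


# ---------------------------------------------------------------------- #
# parsing


def _symbol_to_state(sym: str, j: int, taxon: str) -> int:
    if sym.isdigit():
        return int(sym)
    if sym.isalpha():  # A=10, B=11, ... (PAUP-style extended symbols)
        return 10 + ord(sym.upper()) - ord("A")
    raise MatrixError(f"taxon {taxon!r}, char {j + 1}: bad state symbol {sym!r}")


def _parse_nexus(text: str) -> CharacterMatrix:
    try:
        dm = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:
        raise MatrixError(f"NEXUS parse failure: {exc}") from exc
    taxa: list[str] = []
    cells: list[list[object]] = []
    declared: set[int] = set()
    for sym in dm.default_state_alphabet.symbols:
        if sym not in ("?", "-"):
            try:
                declared.add(_symbol_to_state(sym, 0, "<alphabet>"))
            except MatrixError:
                continue
    for tax in dm:
        taxa.append(tax.label)
        row: list[object] = []
        for st in dm[tax]:
            syms = {str(f) for f in st.fundamental_states}
            if st.symbol == "?":
                row.append(MISSING)
            elif syms == {"-"}:
                row.append(INAPPLICABLE)
            else:
                row.append(
                    frozenset(
                        _symbol_to_state(s, len(row), tax.label)
                        for s in syms
                        if s != "-"
                    )
                )
        cells.append(row)
    states = [tuple(sorted(declared))] * (len(cells[0]) if cells else 0)
    m = CharacterMatrix(taxa, cells, states=states)
    # ASSUMPTIONS/TYPESET ordering is not parsed by dendropy's standard
    # reader; ordered characters are declared via `CharacterDefinition`s or
    # the `ordered` argument instead.
    return m


_TOKEN_RE = re.compile(r"\{([^}]*)\}|\(([^)]*)\)|(\S)")


def _parse_cell_token(tok: str, dialect: MatrixDialect, j: int, taxon: str) -> object:
    tok = tok.strip()
    if tok == dialect.missing_symbol:
        return MISSING
    if tok == dialect.gap_symbol:
        return INAPPLICABLE
    inner = tok
    if tok.startswith(dialect.poly_open) and tok.endswith(dialect.poly_close):
        inner = tok[1:-1]
    states = frozenset(
        _symbol_to_state(ch, j, taxon) for ch in inner if not ch.isspace() and ch != ","
    )
    if not states:
        raise MatrixError(f"taxon {taxon!r}, char {j + 1}: empty cell token {tok!r}")
    return states


def _parse_tsv(text: str, dialect: MatrixDialect) -> CharacterMatrix:
    taxa: list[str] = []
    cells: list[list[object]] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise MatrixError(f"line {lineno}: expected taxon<TAB>cells")
        taxon = parts[0].strip()
        row = [
            _parse_cell_token(tok, dialect, j, taxon)
            for j, tok in enumerate(parts[1:])
        ]
        taxa.append(taxon)
        cells.append(row)
    if not taxa:
        raise MatrixError("empty TSV matrix")
    return CharacterMatrix(taxa, cells)


def parse_matrix(
    text: str,
    dialect: MatrixDialect = NEXUS,
    definitions: Sequence[CharacterDefinition] | None = None,
    ordered: Sequence[bool] | None = None,
) -> CharacterMatrix:
    """Parse matrix ``text`` in the given dialect.

    ``?`` cells become MISSING (scored as full ambiguity), ``-`` cells
    INAPPLICABLE, ``{jk}``/``(jk)`` cells the state set {j, k}.
    """
    if dialect.format == "nexus":
        m = _parse_nexus(text)
    else:
        m = _parse_tsv(text, dialect)
    if definitions is not None:
        m = CharacterMatrix(m.taxa, m.cells, definitions=definitions)
    elif ordered is not None:
        if len(ordered) != m.n_char:
            raise MatrixError("ordered flags must match n_char")
        m.ordered = list(ordered)
    return m


# ---------------------------------------------------------------------- #
# writing


def _state_symbol(s: int, j: int) -> str:
    if 0 <= s <= 9:
        return str(s)
    if 10 <= s <= 35:
        return chr(ord("A") + s - 10)
    raise MatrixError(f"char {j + 1}: state {s} not representable as one symbol")


def _cell_token(c: object, dialect: MatrixDialect, j: int) -> str:
    if c is MISSING:
        return dialect.missing_symbol
    if c is INAPPLICABLE:
        return dialect.gap_symbol
    syms = [_state_symbol(s, j) for s in sorted(c)]
    if len(syms) == 1:
        return syms[0]
    return dialect.poly_open + "".join(syms) + dialect.poly_close


def write_matrix(matrix: CharacterMatrix, dialect: MatrixDialect = NEXUS) -> str:
    """Serialize; the output re-parses to a cell-identical matrix."""
    if not matrix.taxa:
        raise MatrixError("refusing to write a matrix with no taxa")
    if dialect.format == "tsv":
        lines = []
        for taxon, row in zip(matrix.taxa, matrix.cells):
            toks = [_cell_token(c, dialect, j) for j, c in enumerate(row)]
            lines.append(taxon + "\t" + "\t".join(toks))
        return "\n".join(lines) + "\n"

    symbols = sorted({s for st in matrix.states for s in st})
    symstr = "".join(_state_symbol(s, 0) for s in symbols)
    name_w = max(len(t) for t in matrix.taxa)
    buf = io.StringIO()
    buf.write("#NEXUS\n\nBEGIN DATA;\n")
    buf.write(f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_char};\n")
    buf.write(
        f'FORMAT DATATYPE=STANDARD SYMBOLS="{symstr}" '
        f"MISSING={dialect.missing_symbol} GAP={dialect.gap_symbol};\n"
    )
    buf.write("MATRIX\n")
    for taxon, row in zip(matrix.taxa, matrix.cells):
        body = "".join(
            _cell_token(c, MatrixDialect(poly_open="{", poly_close="}"), j)
            for j, c in enumerate(row)
        )
        safe = f"'{taxon}'" if re.search(r"[\s(){};,\[\]]", taxon) else taxon
        buf.write(f"{safe:<{name_w + 2}} {body}\n")
    buf.write(";\nEND;\n")
    if any(matrix.ordered):
        idx = [str(j + 1) for j, o in enumerate(matrix.ordered) if o]
        buf.write(
            "\nBEGIN ASSUMPTIONS;\nTYPESET * default = ord: "
            + " ".join(idx)
            + ";\nEND;\n"
        )
    return buf.getvalue()


def prune_taxa(matrix: CharacterMatrix, drop: Iterable[str]) -> CharacterMatrix:
    """Remove taxa; characters are untouched (constants retained, flagged).

    Mirrors the reduced reanalysis in which fragmentary taxa are deleted
    from the matrix while the character set stays fixed.
    """
    drop = list(drop)
    unknown = [t for t in drop if t not in matrix.taxa]
    if unknown:
        raise MatrixError(f"cannot drop unknown taxa: {unknown}")
    keep = [i for i, t in enumerate(matrix.taxa) if t not in set(drop)]
    out = CharacterMatrix(
        [matrix.taxa[i] for i in keep],
        [matrix.cells[i] for i in keep],
        states=matrix.states,
        ordered=matrix.ordered,
        definitions=matrix.definitions,
    )
    out.meta["uninformative_after_prune"] = [
        j + 1 for j in range(out.n_char) if not out.column_informative(j)
    ]
    return out
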