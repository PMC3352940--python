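"""The dromaeosaurid tail-evolution scenario.

This module turns the comparative caudal-skeleton table (caudal counts,
transverse-process extent, centrum elongation, and the extent of the
caudotheca — the sheath of elongated prezygapophyseal and chevron
processes that stiffens the distal tail) into discrete characters, maps
them onto the coelurosaurian phylogeny by parsimony, classifies isolated
tail specimens by sheath pattern, and reproduces the positional bound for
a caudotheca on a tail missing its proximal vertebrae.

Numeric table entries may be exact ("24"), ranges ("24-26"), lower bounds
(">10"), or carry estimated extras ("36 (+4)"); all are held as closed
integer intervals and binning uses interval containment, returning an
ambiguity set (or a fully missing cell) when an interval straddles bin
edges rather than guessing.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

from .mapping import Change, optimize_states
from .matrix import INAPPLICABLE, MISSING, CharacterDefinition, CharacterMatrix
from .parsimony import character_length
from .trees import Tree, TreeError

__all__ = [
    "Bound",
    "TailRecord",
    "TailError",
    "parse_tail_table",
    "load_tail_table",
    "load_hemicaudotheca_taxa",
    "load_reference_tree",
    "encode_tail_characters",
    "map_tail_changes",
    "classify_tail_condition",
    "infer_caudotheca_position",
    "restrict_tree",
]


class TailError(ValueError):
    pass


@dataclass(frozen=True)
class Bound:
    """Closed integer interval; ``hi`` may be infinite (lower bounds)."""

    lo: float
    hi: float
    approx: bool = False

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise TailError(f"empty interval [{self.lo}, {self.hi}]")

    @property
    def exact(self) -> bool:
        return self.lo == self.hi and not self.approx

    def entirely_at_least(self, v: float) -> bool:
        return self.lo >= v

    def entirely_at_most(self, v: float) -> bool:
        return self.hi <= v

    def entirely_within(self, lo: float, hi: float) -> bool:
        return self.lo >= lo and self.hi <= hi


@dataclass(frozen=True)
class TailRecord:
    """One taxon row of the caudal data table."""

    taxon: str
    group: str
    nc: object = None  # Bound | None (unknown) | INAPPLICABLE
    tp: object = None
    e: object = None
    pz: object = None
    c: object = None
    twofold: bool | None = None
    trpt: bool | None = None

    def __post_init__(self) -> None:
        pz, c = self.pz, self.c
        if isinstance(pz, Bound) and isinstance(c, Bound) and pz.exact and c.exact:
            if c.lo > pz.lo:
                raise TailError(
                    f"{self.taxon}: caudotheca contact (C={c.lo:g}) cannot lie "
                    f"caudal to its first contributor (PZ={pz.lo:g})"
                )


# ---------------------------------------------------------------------- #
# token parsing

_RANGE_RE = re.compile(r"^(\d+)\s*[-–]\s*(\d+)$")
_EXTRA_RE = re.compile(r"^(\d+)\s*\(\+(\d+)(\?)?\)$")
_EXTRA_RANGE_RE = re.compile(r"^(\d+)\s*\(\+(\d+)\s*to\s*(\d+)\)$")


def parse_value(token: str) -> object:
    """Parse one numeric table token into a Bound / None / INAPPLICABLE."""
    tok = token.strip()
    if tok in ("-", "−", "–"):
        return INAPPLICABLE
    if tok == "?":
        return None
    if tok.endswith("*"):  # footnoted value; the qualifier lives in the text
        tok = tok[:-1].strip()
    approx = False
    if tok.lower().startswith("approx."):
        approx = True
        tok = tok[len("approx."):].strip()
    if tok.startswith(">"):
        base = int(tok[1:])
        return Bound(base + 1, math.inf)
    m = _RANGE_RE.match(tok)
    if m:
        a, b = sorted((int(m.group(1)), int(m.group(2))))
        return Bound(a, b)
    m = _EXTRA_RANGE_RE.match(tok)
    if m:
        base, lo, hi = (int(m.group(i)) for i in (1, 2, 3))
        return Bound(base + lo, base + hi)
    m = _EXTRA_RE.match(tok)
    if m:
        base, extra = int(m.group(1)), int(m.group(2))
        if m.group(3):  # uncertain extras: "(+5?)"
            return Bound(base, base + extra)
        return Bound(base + extra, base + extra)
    if tok.isdigit():
        v = int(tok)
        return Bound(v, v, approx=approx)
    raise TailError(f"cannot parse value token {token!r}")


def _parse_flag(token: str) -> bool | None:
    tok = token.strip().lower()
    if tok in ("yes", "y"):
        return True
    if tok in ("no", "n"):
        return False
    if tok == "?":
        return None
    raise TailError(f"cannot parse yes/no token {token!r}")


_COLUMNS = ("taxon", "group", "NC", "TP", "E", "PZ", "C", "2x", "TrPt")


def parse_tail_table(text: str) -> list[TailRecord]:
    """Parse the tab-separated caudal data table."""
    lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    if not lines:
        return []
    header = tuple(h.strip() for h in lines[0].split("\t"))
    if header != _COLUMNS:
        raise TailError(f"unexpected header {header}; want {_COLUMNS}")
    records = []
    for lineno, line in enumerate(lines[1:], 2):
        parts = line.split("\t")
        if len(parts) != len(_COLUMNS):
            raise TailError(f"row {lineno}: {len(parts)} fields, want {len(_COLUMNS)}")
        try:
            records.append(
                TailRecord(
                    taxon=parts[0].strip(),
                    group=parts[1].strip(),
                    nc=parse_value(parts[2]),
                    tp=parse_value(parts[3]),
                    e=parse_value(parts[4]),
                    pz=parse_value(parts[5]),
                    c=parse_value(parts[6]),
                    twofold=_parse_flag(parts[7]),
                    trpt=_parse_flag(parts[8]),
                )
            )
        except TailError as exc:
            raise TailError(f"row {lineno} ({parts[0].strip()!r}): {exc}") from exc
    return records


# ---------------------------------------------------------------------- #
# packaged study data


def _data_text(name: str) -> str:
    return resources.files("morphpars.data").joinpath(name).read_text()


def load_tail_table() -> list[TailRecord]:
    return parse_tail_table(_data_text("table1_tails.tsv"))


def load_hemicaudotheca_taxa() -> list[str]:
    return [
        l.strip()
        for l in _data_text("hemicaudotheca_taxa.tsv").splitlines()
        if l.strip() and not l.startswith("#") and l.strip() != "taxon"
    ]


def load_reference_tree() -> Tree:
    """Rooted reference topology for the tail scenario.

    Assembled from the published topology statements (clade ladder of the
    dromaeosaurid synapomorphy table, the successive caudothecate sister
    groups of the hemicaudothecate clade, and the placement discussion),
    restricted to taxa with caudal data; unresolved groups are polytomies.
    """
    return Tree.from_newick(_data_text("reference_phylogeny.nwk"), rooted=True)


# ---------------------------------------------------------------------- #
# character encoding

# bin edges (inclusive ranges); the NC bins follow the documented choice
# <=24 / 25-30 / >30 so that the early caudal-count decrease and the
# eudromaeosaurian increase are both expressible
_NC_BINS = ((1, 24), (25, 30), (31, math.inf))
_TP_BINS = ((1, 6), (7, 10), (11, math.inf))
_PZ_BINS = ((1, 6), (7, math.inf))
_C_BINS = ((1, 4), (5, math.inf))

TAIL_CHARACTERS = (
    "caudotheca",  # 0 absent, 1 caudotheca, 2 hemicaudotheca
    "transition_point",  # 0 none, 1 type 1 (prezygapophyseal), 2 type 2 (centrum)
    "elongation_2x",  # mid-caudals >= 2x proximal centra
    "nc_class",  # caudal count bin
    "tp_class",  # last transverse-process caudal bin
    "pz_class",  # first caudotheca-contributing caudal bin
    "c_class",  # first caudotheca-contacted caudal bin
)


def _bin_cell(value: object, bins: Sequence[tuple[float, float]]) -> object:
    if value is None or value is INAPPLICABLE:
        return MISSING
    assert isinstance(value, Bound)
    hits = frozenset(
        i for i, (lo, hi) in enumerate(bins) if value.lo <= hi and value.hi >= lo
    )
    if not hits:
        raise TailError(f"value {value} fits no bin")
    if len(hits) == len(bins):
        return MISSING
    return hits


def encode_tail_characters(
    records: Iterable[TailRecord],
    extra_states: Iterable[str] = (),
    keep_taxa: Iterable[str] | None = None,
) -> CharacterMatrix:
    """Discretize tail records into a character matrix.

    ``extra_states`` lists hemicaudotheca-bearing taxa absent from the
    table; they enter with the sheath character set to hemicaudothecate and
    everything else missing.  If ``keep_taxa`` is given, records whose
    taxon is not in it are dropped (logged in ``meta['dropped_taxa']``),
    matching the leaves of the mapping tree.
    """
    records = list(records)
    extra = [t for t in extra_states if t not in {r.taxon for r in records}]
    keep = set(keep_taxa) if keep_taxa is not None else None
    hemi = set(extra_states)

    taxa: list[str] = []
    cells: list[list[object]] = []
    dropped: list[str] = []

    def caudotheca_cell(r: TailRecord) -> object:
        if r.taxon in hemi:
            return frozenset([2])
        if r.pz is INAPPLICABLE and r.c is INAPPLICABLE:
            return frozenset([0])
        if isinstance(r.pz, Bound) or isinstance(r.c, Bound):
            return frozenset([1])
        return MISSING

    def transition_cell(r: TailRecord) -> object:
        if r.trpt is False:
            return frozenset([0])
        if r.trpt is None:
            return MISSING
        if isinstance(r.e, Bound):
            return frozenset([2])
        if r.e is INAPPLICABLE:
            return frozenset([1])
        return frozenset([1, 2])

    for r in records:
        if keep is not None and r.taxon not in keep:
            dropped.append(r.taxon)
            continue
        taxa.append(r.taxon)
        cells.append(
            [
                caudotheca_cell(r),
                transition_cell(r),
                MISSING if r.twofold is None else frozenset([int(r.twofold)]),
                _bin_cell(r.nc, _NC_BINS),
                _bin_cell(r.tp, _TP_BINS),
                _bin_cell(r.pz, _PZ_BINS),
                _bin_cell(r.c, _C_BINS),
            ]
        )
    for t in extra:
        if keep is not None and t not in keep:
            dropped.append(t)
            continue
        taxa.append(t)
        cells.append([frozenset([2])] + [MISSING] * 6)

    defs = [
        CharacterDefinition(i + 1, name, states=(0, 1, 2) if i in (0, 1, 3, 4) else (0, 1))
        for i, name in enumerate(TAIL_CHARACTERS)
    ]
    m = CharacterMatrix(taxa, cells, definitions=defs)
    m.meta["dropped_taxa"] = dropped
    return m


# ---------------------------------------------------------------------- #
# mapping onto the phylogeny


def restrict_tree(tree: Tree, taxa: Iterable[str]) -> Tree:
    """Rooted copy with only the given leaves; degree-2 nodes suppressed."""
    keep = set(taxa)
    missing = keep - set(tree.labels.values())
    if missing:
        raise TreeError(f"taxa not in tree: {sorted(missing)}")
    t = tree.copy()
    if t.root is None:
        raise TreeError("restrict_tree expects a rooted tree")
    pruned = True
    while pruned:
        pruned = False
        for node, lab in list(t.labels.items()):
            if lab not in keep:
                (nbr,) = t.adj[node]
                t.remove_edge(node, nbr)
                del t.adj[node]
                del t.labels[node]
                pruned = True
        for node in list(t.adj):
            if node in t.labels:
                continue
            deg = len(t.adj[node])
            if deg == 0:
                del t.adj[node]
            elif deg == 1 and node != t.root:
                (nbr,) = t.adj[node]
                t.remove_edge(node, nbr)
                del t.adj[node]
                pruned = True
            elif deg == 2 and node != t.root:
                a, b = t.adj[node]
                t.remove_edge(node, a)
                t.remove_edge(node, b)
                del t.adj[node]
                t.add_edge(a, b)
                pruned = True
        if t.root not in t.adj:
            raise TreeError("root lost during restriction")
        while t.root in t.adj and len(t.adj[t.root]) == 1 and t.root not in t.labels:
            child = t.adj[t.root][0]
            t.remove_edge(t.root, child)
            del t.adj[t.root]
            t.root = child
    return t


@dataclass(frozen=True)
class TailChange:
    """One inferred tail-character change on a branch of the phylogeny."""

    character: str
    clade: frozenset[str]
    from_state: int
    to_state: int


def map_tail_changes(
    tree: Tree, tail_matrix: CharacterMatrix, mode: str = "DELTRAN"
) -> list[TailChange]:
    """Parsimony-optimize every tail character on the rooted phylogeny.

    The tree is restricted to taxa present in the matrix (and vice versa);
    each character is optimized independently and the branch-wise changes
    pooled.  Change counts per character equal the character's parsimony
    length on the same tree.
    """
    shared = sorted(set(tree.labels.values()) & set(tail_matrix.taxa))
    if len(shared) < 3:
        raise TailError("fewer than 3 taxa shared between tree and tail matrix")
    t = restrict_tree(tree, shared)
    keep_idx = [i for i, tx in enumerate(tail_matrix.taxa) if tx in set(shared)]
    sub = CharacterMatrix(
        [tail_matrix.taxa[i] for i in keep_idx],
        [tail_matrix.cells[i] for i in keep_idx],
        states=tail_matrix.states,
        ordered=tail_matrix.ordered,
        definitions=tail_matrix.definitions,
    )
    names = (
        [d.description for d in sub.definitions]
        if sub.definitions
        else [f"char{j+1}" for j in range(sub.n_char)]
    )
    out: list[TailChange] = []
    for j in range(sub.n_char):
        col = sub.column(j)
        rec = optimize_states(t, col, mode, sub.ordered[j])
        for ch in rec.changes:
            out.append(TailChange(names[j], ch.clade, ch.from_state, ch.to_state))
    return out


# ---------------------------------------------------------------------- #
# specimen classification


def classify_tail_condition(record: TailRecord) -> str:
    """Classify a tail by its caudotheca/transverse-process pattern.

    * ``microraptorian-pattern`` — transverse processes end by caudal 6,
      the sheath's first contributor lies at or before caudal 6, and the
      sheath reaches caudal 3-4.
    * ``eudromaeosaurian-pattern`` — the sheath starts farther back
      (first contributor at caudal 7 or beyond) and reaches no farther
      forward than caudal 6.  Transverse-process extent is not decisive
      here: known eudromaeosaurian tails range to caudal 11.
    * ``acaudothecate`` — the sheath fields are inapplicable (no
      caudotheca at all).

    Interval values participate by containment; a value straddling a rule
    boundary yields ``indeterminate`` rather than a guess.
    """
    if record.pz is INAPPLICABLE and record.c is INAPPLICABLE:
        return "acaudothecate"
    tp, pz, c = record.tp, record.pz, record.c
    if (
        isinstance(tp, Bound)
        and isinstance(pz, Bound)
        and isinstance(c, Bound)
        and tp.entirely_at_most(6)
        and pz.entirely_at_most(6)
        and c.entirely_within(3, 4)
    ):
        return "microraptorian-pattern"
    if (
        isinstance(pz, Bound)
        and isinstance(c, Bound)
        and pz.entirely_at_least(7)
        and c.entirely_at_least(6)
    ):
        return "eudromaeosaurian-pattern"
    return "indeterminate"


# ---------------------------------------------------------------------- #
# caudotheca position bound


def infer_caudotheca_position(
    missing_proximal: int, surround_index: int
) -> tuple[int, int]:
    """Upper bounds on where a partly preserved caudotheca begins.

    Given ``missing_proximal`` proximal caudals absent from the specimen
    and the 1-based position within the preserved series of the first
    vertebra the sheath surrounds, returns
    ``(first_contributing_caudal, cranial_extent_caudal)``: the sheath's
    first contributing vertebra lies no farther cranial than the former
    and the sheath itself extends no farther forward than the latter.
    """
    if missing_proximal < 0:
        raise ValueError("missing_proximal must be >= 0")
    if surround_index < 1:
        raise ValueError("surround_index is 1-based and must be >= 1")
    cranial_extent = missing_proximal + surround_index
    return cranial_extent + 1, cranial_extent
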