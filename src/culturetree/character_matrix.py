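"""Cultural character matrices with multi-state, absence and missing coding.

The data model follows the primary-homology coding used for musical
patrimonies: a taxon (a patrimony) is scored for hundreds of characters in
labeled categories (repertoire, instrument, rhythmic cell, metric, scale,
polyphonic process, vocal form, vocal technique).  A cell holds the set of
states observed for that taxon — for an intrinsic character each state names
the repertoire in which the trait occurs, so a cell like ``{a,b}`` means the
trait is present in repertoires *a* and *b*.  Absence is coded ``0`` and is
treated as an ordinary, optimizable state (this is what makes rooting on an
all-zero hypothetical ancestor meaningful); missing data is ``?``.

Supported dialects: a spreadsheet/CSV layout (header row of character names,
first column of taxon names, cells ``0`` / ``?`` / ``a`` / ``{a,b}``) and
NEXUS (DATA/CHARACTERS plus a SETS block with one CHARSET per category).
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import dendropy

__all__ = [
    "ABSENT_SYMBOL",
    "MISSING",
    "ABSENT",
    "StateSet",
    "CharacterDef",
    "TaxonRecord",
    "CharacterMatrix",
    "MatrixParseError",
    "MatrixValidationError",
    "CATEGORY_CLASS",
    "S1_CATEGORY_RANGES",
    "read_matrix",
    "write_matrix",
    "write_nexus",
    "write_csv",
    "write_category_map",
    "binarize",
    "informative_mask",
    "parse_category_map",
]

ABSENT_SYMBOL = "0"

CATEGORY_CLASS = {
    "repertoire": "repertoire",
    "instrument": "performative",
    "polyphonic_process": "performative",
    "vocal_form": "performative",
    "vocal_technique": "performative",
    "rhythmic_cell": "intrinsic",
    "metric": "intrinsic",
    "scale": "intrinsic",
}

#: 1-based inclusive column ranges of the published 58x322 patrimony matrix.
S1_CATEGORY_RANGES = {
    "repertoire": (1, 161),
    "instrument": (162, 224),
    "rhythmic_cell": (225, 288),
    "metric": (289, 302),
    "scale": (303, 315),
    "polyphonic_process": (316, 318),
    "vocal_form": (319, 320),
    "vocal_technique": (321, 322),
}


class MatrixParseError(ValueError):
    pass


class MatrixValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# cells


@dataclass(frozen=True)
class StateSet:
    """States coded in one cell.

    ``states`` is a frozenset of tokens.  The two special cells are absence
    (exactly ``{"0"}``) and missing (empty set with ``missing=True``); listed
    states are mutually exclusive with both.
    """

    states: frozenset = frozenset()
    missing: bool = False

    def __post_init__(self):
        if self.missing and self.states:
            raise MatrixValidationError("a cell cannot be both missing and coded")
        if not self.missing and not self.states:
            raise MatrixValidationError("a coded cell needs at least one state")
        if ABSENT_SYMBOL in self.states and len(self.states) > 1:
            raise MatrixValidationError(
                "absence ('0') cannot be combined with other states"
            )

    @property
    def is_missing(self) -> bool:
        return self.missing

    @property
    def is_absent(self) -> bool:
        return self.states == frozenset((ABSENT_SYMBOL,))

    def tokens(self) -> frozenset:
        return self.states

    def __iter__(self):
        return iter(self.states)

    def __repr__(self) -> str:
        return f"StateSet({format_cell(self)!r})"


MISSING = StateSet(missing=True)
ABSENT = StateSet(frozenset((ABSENT_SYMBOL,)))


_TOKEN_RE = re.compile(r"^[0-9a-z_]+$")


def parse_cell(text: str) -> StateSet:
    """Parse ``0`` / ``?`` / ``a`` / ``a,b`` / ``{a,b}`` (whitespace ignored,
    case-insensitive)."""
    t = str(text).strip().lower()
    if t in ("?", ""):
        return MISSING
    if t in ("0", "0.0"):
        return ABSENT
    t = t.strip("{}")
    toks = [x.strip() for x in re.split(r"[,\s]+", t) if x.strip()]
    if not toks:
        return MISSING
    for tok in toks:
        if not _TOKEN_RE.match(tok):
            raise MatrixParseError(f"unknown state symbol {tok!r} in cell {text!r}")
    return StateSet(frozenset(toks))


def format_cell(cell: StateSet) -> str:
    if cell.is_missing:
        return "?"
    if cell.is_absent:
        return ABSENT_SYMBOL
    toks = sorted(cell.states)
    if len(toks) == 1:
        return toks[0]
    return "{" + ",".join(toks) + "}"


# ---------------------------------------------------------------------------
# characters and taxa


@dataclass(frozen=True)
class CharacterDef:
    """One column: 1-based index, name, category and its (non-absent) state
    alphabet.  ``source_index`` tracks the origin column after binarization."""

    index: int
    name: str
    category: str = "repertoire"
    alphabet: tuple = ()
    source_index: Optional[int] = None

    def __post_init__(self):
        if self.category not in CATEGORY_CLASS:
            raise MatrixValidationError(
                f"unknown category {self.category!r} for character {self.name!r}"
            )
        if ABSENT_SYMBOL in self.alphabet:
            raise MatrixValidationError("alphabet lists non-absent states only")
        if len(set(self.alphabet)) != len(self.alphabet):
            raise MatrixValidationError(f"duplicate states in alphabet of {self.name!r}")

    @property
    def category_class(self) -> str:
        return CATEGORY_CLASS[self.category]

    @property
    def full_alphabet(self) -> tuple:
        """States available to parsimony: absence first, then the alphabet."""
        return (ABSENT_SYMBOL,) + tuple(self.alphabet)


_DESCENT_BY_LETTER = {"P": "Pa", "M": "Ma", "A": "A"}


@dataclass(frozen=True)
class TaxonRecord:
    """A musical patrimony: the operational taxonomic unit."""

    name: str
    code: Optional[str] = None
    descent: Optional[str] = None
    province: Optional[str] = None
    river_side: Optional[str] = None

    def __post_init__(self):
        if self.descent is not None and self.descent not in ("Pa", "Ma", "A"):
            raise MatrixValidationError(f"bad descent {self.descent!r} for {self.name}")
        if self.code and self.descent:
            want = _DESCENT_BY_LETTER.get(self.code[0].upper())
            if want is not None and want != self.descent:
                raise MatrixValidationError(
                    f"code {self.code!r} does not match descent {self.descent!r}"
                )


# ---------------------------------------------------------------------------
# the matrix


class CharacterMatrix:
    """Rectangular taxa x characters grid of :class:`StateSet` cells."""

    def __init__(
        self,
        taxa: Sequence[TaxonRecord],
        characters: Sequence[CharacterDef],
        cells: Sequence[Sequence[StateSet]],
    ):
        self.taxa = list(taxa)
        self.characters = list(characters)
        self.cells = [list(row) for row in cells]
        self.validate()

    # -- basics ------------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    @property
    def shape(self) -> tuple:
        return (self.n_taxa, self.n_characters)

    def taxon_names(self) -> list[str]:
        return [t.name for t in self.taxa]

    def cell(self, taxon: int, char: int) -> StateSet:
        return self.cells[taxon][char]

    def column(self, char: int) -> list[StateSet]:
        return [row[char] for row in self.cells]

    def taxon_index(self, name: str) -> int:
        for i, t in enumerate(self.taxa):
            if t.name == name:
                return i
        raise KeyError(name)

    def category_counts(self) -> dict:
        out: dict = {}
        for c in self.characters:
            out[c.category] = out.get(c.category, 0) + 1
        return out

    def validate(self) -> None:
        names = self.taxon_names()
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise MatrixValidationError(f"duplicate taxon name(s): {sorted(dupes)}")
        if len(self.cells) != self.n_taxa:
            raise MatrixValidationError("row count does not match taxa")
        for i, row in enumerate(self.cells):
            if len(row) != self.n_characters:
                raise MatrixValidationError(
                    f"ragged row for taxon {names[i]!r}: "
                    f"{len(row)} cells, expected {self.n_characters}"
                )
        for j, cdef in enumerate(self.characters):
            allowed = set(cdef.alphabet)
            for i, row in enumerate(self.cells):
                cell = row[j]
                if cell.is_missing or cell.is_absent:
                    continue
                extra = cell.states - allowed
                if extra:
                    raise MatrixValidationError(
                        f"taxon {names[i]!r}, character {cdef.name!r} "
                        f"(column {cdef.index}): state(s) {sorted(extra)} "
                        f"not in declared alphabet"
                    )

    def __eq__(self, other) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxon_names() == other.taxon_names()
            and [(c.name, c.category) for c in self.characters]
            == [(c.name, c.category) for c in other.characters]
            and self.cells == other.cells
        )

    def __repr__(self) -> str:
        return f"<CharacterMatrix {self.n_taxa} taxa x {self.n_characters} characters>"


# ---------------------------------------------------------------------------
# category maps


def _categories_from_ranges(ranges: dict, n_char: int) -> list[str]:
    cats = [None] * n_char
    for cat, (lo, hi) in ranges.items():
        if cat not in CATEGORY_CLASS:
            raise MatrixParseError(f"unknown category {cat!r} in category map")
        for idx in range(lo, hi + 1):
            if not 1 <= idx <= n_char:
                raise MatrixParseError(
                    f"category range {cat} = {lo}-{hi} exceeds {n_char} characters"
                )
            cats[idx - 1] = cat
    missing = [i + 1 for i, c in enumerate(cats) if c is None]
    if missing:
        raise MatrixParseError(f"characters without category: {missing[:10]}...")
    return cats


def parse_category_map(path) -> dict:
    """Sidecar key-value file: one ``category lo-hi`` (or ``category idx``)
    per line; '#' comments allowed."""
    ranges = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace("=", " ").split()
        if len(parts) != 2:
            raise MatrixParseError(f"bad category map line: {line!r}")
        cat, span = parts
        if "-" in span:
            lo, hi = span.split("-")
        else:
            lo = hi = span
        ranges[cat] = (int(lo), int(hi))
    return ranges


def _resolve_categories(n_char: int, categories) -> list[str]:
    if categories is None:
        if n_char == 322:
            return _categories_from_ranges(S1_CATEGORY_RANGES, n_char)
        return ["repertoire"] * n_char
    if isinstance(categories, (str, Path)):
        return _categories_from_ranges(parse_category_map(categories), n_char)
    if isinstance(categories, dict):
        return _categories_from_ranges(categories, n_char)
    cats = list(categories)
    if len(cats) != n_char:
        raise MatrixParseError("per-character category list has wrong length")
    return cats


# ---------------------------------------------------------------------------
# readers


def _matrix_from_grid(
    taxon_names: list[str],
    char_names: list[str],
    grid: list[list[StateSet]],
    categories,
) -> CharacterMatrix:
    cats = _resolve_categories(len(char_names), categories)
    chars = []
    for j, (name, cat) in enumerate(zip(char_names, cats)):
        observed = set()
        for row in grid:
            cell = row[j]
            if not (cell.is_missing or cell.is_absent):
                observed |= cell.states
        chars.append(
            CharacterDef(index=j + 1, name=name, category=cat, alphabet=tuple(sorted(observed)))
        )
    taxa = [TaxonRecord(name=n) for n in taxon_names]
    return CharacterMatrix(taxa, chars, grid)


def _read_delimited(rows: list[list[str]], categories, where: str) -> CharacterMatrix:
    if len(rows) < 2:
        raise MatrixParseError(f"{where}: need a header row and at least one taxon")
    header = rows[0]
    char_names = [str(h).strip() for h in header[1:]]
    taxon_names, grid = [], []
    width = len(char_names)
    for r, row in enumerate(rows[1:], start=2):
        vals = [str(v) for v in row]
        if all(not v.strip() for v in vals):
            continue
        if len(vals) - 1 != width:
            raise MatrixParseError(
                f"{where}: ragged row {r}: {len(vals) - 1} cells, expected {width}"
            )
        taxon_names.append(vals[0].strip())
        cells = []
        for c, v in enumerate(vals[1:], start=1):
            try:
                cells.append(parse_cell(v))
            except MatrixParseError as e:
                raise MatrixParseError(f"{where}: row {r}, column {c}: {e}") from None
        grid.append(cells)
    return _matrix_from_grid(taxon_names, char_names, grid, categories)


def _read_csv(path, categories) -> CharacterMatrix:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    return _read_delimited(rows, categories, str(path))


def _read_spreadsheet(path, categories) -> CharacterMatrix:
    import openpyxl

    wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    ws = wb.worksheets[0]
    rows = [["" if v is None else v for v in row] for row in ws.iter_rows(values_only=True)]
    wb.close()
    return _read_delimited(rows, categories, str(path))


def _read_nexus(path, categories) -> CharacterMatrix:
    try:
        dm = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    except Exception as e:
        raise MatrixParseError(f"{path}: {e}") from None
    taxon_names = [t.label for t in dm.taxon_namespace]
    grid = []
    for t in dm.taxon_namespace:
        row = []
        for s in dm[t]:
            if s.symbol == "?":
                row.append(MISSING)
            elif s.symbol is not None:
                sym = s.symbol.lower()
                row.append(ABSENT if sym == ABSENT_SYMBOL else StateSet(frozenset((sym,))))
            else:
                toks = frozenset(m.symbol.lower() for m in s.member_states)
                row.append(StateSet(toks - {"-"}))
        grid.append(row)
    n_char = len(grid[0]) if grid else 0
    char_names = [f"char{j + 1}" for j in range(n_char)]
    if categories is None and dm.character_subsets:
        cats = [None] * n_char
        for label, subset in dm.character_subsets.items():
            if label in CATEGORY_CLASS:
                for idx in subset.character_indices:
                    cats[idx] = label
        if all(c is not None for c in cats):
            categories = cats
    return _matrix_from_grid(taxon_names, char_names, grid, categories)


_DIALECTS = {
    "csv": _read_csv,
    "spreadsheet": _read_spreadsheet,
    "nexus": _read_nexus,
}

_EXT_DIALECT = {".csv": "csv", ".tsv": "csv", ".xlsx": "spreadsheet",
                ".nex": "nexus", ".nexus": "nexus"}


def read_matrix(path, dialect: Optional[str] = None, categories=None) -> CharacterMatrix:
    """Read and validate a character matrix.

    ``dialect`` is one of ``csv``, ``spreadsheet``, ``nexus``; inferred from
    the extension when omitted.  ``categories`` may be a sidecar map path, a
    ``{category: (lo, hi)}`` dict, or a per-character list; with 322 columns
    the published category column ranges are assumed by default.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = _EXT_DIALECT.get(path.suffix.lower())
        if dialect is None:
            raise MatrixParseError(f"cannot infer dialect from {path.suffix!r}")
    if dialect not in _DIALECTS:
        raise MatrixParseError(f"unknown dialect {dialect!r}")
    return _DIALECTS[dialect](path, categories)


# ---------------------------------------------------------------------------
# writers


def write_csv(matrix: CharacterMatrix, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["taxon"] + [c.name for c in matrix.characters])
        for t, row in zip(matrix.taxa, matrix.cells):
            w.writerow([t.name] + [format_cell(cell) for cell in row])


def _category_spans(matrix: CharacterMatrix) -> list[tuple]:
    """(category, lo, hi) runs of consecutive same-category columns, 1-based."""
    spans = []
    for j, c in enumerate(matrix.characters, start=1):
        if spans and spans[-1][0] == c.category and spans[-1][2] == j - 1:
            spans[-1] = (c.category, spans[-1][1], j)
        else:
            spans.append((c.category, j, j))
    return spans


def write_nexus(matrix: CharacterMatrix, path) -> None:
    """Emit a standard NEXUS CHARACTERS block plus a SETS block with one
    CHARSET per category run.

    NEXUS standard data uses single-character state symbols, so state tokens
    must be single characters (the usual ``a``-``z`` coding); matrices with
    longer minted tokens should be serialized as CSV instead.
    """
    symbols = set()
    for c in matrix.characters:
        symbols |= set(c.alphabet)
    for row in matrix.cells:
        for cell in row:
            if not (cell.is_missing or cell.is_absent):
                symbols |= cell.states
    bad = sorted(s for s in symbols if len(s) != 1)
    if bad:
        raise MatrixValidationError(
            f"NEXUS needs single-character state symbols; offending tokens: {bad[:5]}"
        )
    sym_list = [ABSENT_SYMBOL] + sorted(symbols)
    buf = io.StringIO()
    buf.write("#NEXUS\n\nBEGIN TAXA;\n")
    buf.write(f"    DIMENSIONS NTAX={matrix.n_taxa};\n")
    buf.write("    TAXLABELS\n")
    for t in matrix.taxa:
        buf.write(f"        {_nexus_label(t.name)}\n")
    buf.write("    ;\nEND;\n\nBEGIN CHARACTERS;\n")
    buf.write(f"    DIMENSIONS NCHAR={matrix.n_characters};\n")
    buf.write(
        '    FORMAT DATATYPE=STANDARD SYMBOLS="%s" MISSING=? GAP=-;\n'
        % "".join(sym_list)
    )
    buf.write("    MATRIX\n")
    pad = max(len(t.name) for t in matrix.taxa) + 2
    for t, row in zip(matrix.taxa, matrix.cells):
        cells = []
        for cell in row:
            if cell.is_missing:
                cells.append("?")
            elif cell.is_absent:
                cells.append(ABSENT_SYMBOL)
            elif len(cell.states) == 1:
                cells.append(next(iter(cell.states)))
            else:
                cells.append("{" + "".join(sorted(cell.states)) + "}")
        buf.write(f"        {_nexus_label(t.name):<{pad}}{''.join(cells)}\n")
    buf.write("    ;\nEND;\n\nBEGIN SETS;\n")
    for cat, lo, hi in _category_spans(matrix):
        span = str(lo) if lo == hi else f"{lo}-{hi}"
        buf.write(f"    CHARSET {cat} = {span};\n")
    buf.write("END;\n")
    Path(path).write_text(buf.getvalue())


def _nexus_label(label: str) -> str:
    if re.search(r"[\s(){}\[\]/\\,;:=*'\"`+<>-]", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_category_map(matrix: CharacterMatrix, path) -> None:
    """Sidecar category map (one ``category lo-hi`` run per line), the
    companion of :func:`write_csv` for dialects without a SETS block."""
    lines = []
    for cat, lo, hi in _category_spans(matrix):
        span = str(lo) if lo == hi else f"{lo}-{hi}"
        lines.append(f"{cat} {span}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_matrix(matrix: CharacterMatrix, path, dialect: Optional[str] = None) -> None:
    path = Path(path)
    if dialect is None:
        dialect = _EXT_DIALECT.get(path.suffix.lower())
    if dialect == "csv":
        write_csv(matrix, path)
    elif dialect == "nexus":
        write_nexus(matrix, path)
    else:
        raise MatrixParseError(f"unsupported output dialect {dialect!r}")


# ---------------------------------------------------------------------------
# recoding


def binarize(matrix: CharacterMatrix) -> CharacterMatrix:
    """Expand every multi-state character into one presence/absence column per
    state (state present in the cell -> ``1``, absent -> ``0``; missing
    propagates to all expansion columns).  Characters that are already
    presence/absence (a single non-absent state) pass through unchanged.
    ``source_index`` on each output column maps back to the origin character.
    """
    one = StateSet(frozenset(("1",)))
    chars: list[CharacterDef] = []
    cols: list[list[StateSet]] = []
    for j, cdef in enumerate(matrix.characters):
        src = matrix.column(j)
        if len(cdef.alphabet) <= 1:
            # already presence/absence: pass through unchanged
            chars.append(
                CharacterDef(
                    index=len(chars) + 1,
                    name=cdef.name,
                    category=cdef.category,
                    alphabet=cdef.alphabet,
                    source_index=cdef.index,
                )
            )
            cols.append(list(src))
            continue
        for state in cdef.alphabet:
            col = []
            for cell in src:
                if cell.is_missing:
                    col.append(MISSING)
                elif state in cell.states:
                    col.append(one)
                else:
                    col.append(ABSENT)
            chars.append(
                CharacterDef(
                    index=len(chars) + 1,
                    name=f"{cdef.name}[{state}]",
                    category=cdef.category,
                    alphabet=("1",),
                    source_index=cdef.index,
                )
            )
            cols.append(col)
    cells = [[cols[j][i] for j in range(len(cols))] for i in range(matrix.n_taxa)]
    return CharacterMatrix(matrix.taxa, chars, cells)


# ---------------------------------------------------------------------------
# parsimony informativeness


def _resolved_state_counts(column: Sequence[StateSet]) -> dict:
    """State -> number of taxa bearing it after greedy resolution of
    ambiguous cells toward the commonest states (absence counts as a state,
    missing cells never contribute)."""
    freq: dict = {}
    for cell in column:
        if cell.is_missing:
            continue
        for s in cell.states:
            freq[s] = freq.get(s, 0) + 1
    counts: dict = {}
    for cell in column:
        if cell.is_missing:
            continue
        best = max(sorted(cell.states), key=lambda s: freq[s])
        counts[best] = counts.get(best, 0) + 1
    return counts


def is_informative(column: Sequence[StateSet]) -> bool:
    counts = _resolved_state_counts(column)
    return sum(1 for v in counts.values() if v >= 2) >= 2


def informative_mask(matrix: CharacterMatrix) -> list[bool]:
    """Flag parsimony-informative characters: at least two states each borne
    by at least two taxa (ambiguity resolved greedily, see
    :func:`is_informative`)."""
    return [is_informative(matrix.column(j)) for j in range(matrix.n_characters)]
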