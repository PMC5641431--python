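"""Core data model: trees, character matrices, partitions, constraints, and I/O.

Trees are stored rooted internally; unrooted trees carry ``rooted=False`` and
are interpreted via their bipartition set. Character matrices hold DNA (with
IUPAC ambiguity) or standard multistate data with per-character metadata
(partition id, anatomical region) used by the morphology pipeline.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import dendropy

__all__ = [
    "PhylogeoError",
    "FormatError",
    "TreeNode",
    "Tree",
    "CharacterMatrix",
    "PartitionScheme",
    "ConstraintSet",
    "read_matrix",
    "write_matrix",
    "read_tree",
    "bipartitions",
    "satisfies",
    "load_constraint_sets",
    "GAP",
    "MISSING",
    "IUPAC_DNA",
]


class PhylogeoError(Exception):
    """Base error for this package."""


class FormatError(PhylogeoError):
    """Raised when an input file violates its declared format."""


# Sentinels for cells. For likelihood purposes both integrate over all states;
# they are kept distinct so round-trips preserve the original symbol.
GAP = "-"
MISSING = "?"

IUPAC_DNA = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"), "X": frozenset("ACGT"),
}

_DNA_STATES = ("A", "C", "G", "T")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class TreeNode:
    __slots__ = ("children", "parent", "length", "label", "support")

    def __init__(self, label=None, length=0.0):
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.length: float = length
        self.label: str | None = label
        self.support: float | None = None  # posterior probability annotation

    def add_child(self, node: "TreeNode") -> "TreeNode":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    """Rooted container; ``rooted=False`` marks the root as an arbitrary anchor."""

    def __init__(self, root: TreeNode, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise FormatError(f"duplicate leaf label(s): {dup}")
        for n in self.postorder():
            if n.length < 0:
                raise FormatError(f"negative branch length {n.length} at {n.label!r}")

    # -- traversal ---------------------------------------------------------
    def postorder(self):
        stack, out = [self.root], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return reversed(out)

    def preorder(self):
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self):
        return [n.label for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n is not self.root)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, rooted: bool | None = None) -> "Tree":
        newick = newick.strip()
        if newick.count("(") != newick.count(")"):
            # locate the first unmatched parenthesis for the error offset
            depth = 0
            off = len(newick)
            for i, ch in enumerate(newick):
                if ch == "(":
                    depth += 1
                elif ch == ")":
                    depth -= 1
                if depth < 0:
                    off = i
                    break
            raise FormatError(f"unbalanced parentheses in newick (offset {off})")
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises various parse errors
            raise FormatError(f"newick parse error: {exc}") from exc
        root = _from_dendropy(dtree.seed_node)
        if rooted is None:
            rooted = len(dtree.seed_node.child_nodes()) == 2
        return cls(root, rooted=rooted)

    def copy(self) -> "Tree":
        def rec(n):
            m = TreeNode(n.label, n.length)
            m.support = n.support
            for c in n.children:
                m.add_child(rec(c))
            return m
        # invariants hold by construction; skip re-validation
        t = object.__new__(Tree)
        t.root = rec(self.root)
        t.rooted = self.rooted
        return t

    # -- serialization -----------------------------------------------------
    def newick(self, lengths: bool = True, support: bool = False) -> str:
        def fmt_label(lbl):
            if lbl is None:
                return ""
            if re.fullmatch(r"[A-Za-z0-9_.\-]+", lbl):
                return lbl
            return "'" + lbl.replace("'", "''") + "'"

        def rec(n):
            if n.is_leaf:
                s = fmt_label(n.label)
            else:
                s = "(" + ",".join(rec(c) for c in n.children) + ")"
                if support and n.support is not None:
                    s += format(n.support, "g")
                elif n.label:
                    s += fmt_label(n.label)
            if lengths and n is not self.root:
                s += f":{n.length:.10g}"
            return s

        return rec(self.root) + ";"

    # -- splits ------------------------------------------------------------
    def edge_leafsets(self):
        """Leaf-label set below every non-root node (pendant edges included)."""
        below: dict[int, frozenset] = {}
        out = []
        for n in self.postorder():
            if n.is_leaf:
                below[id(n)] = frozenset([n.label])
            else:
                below[id(n)] = frozenset().union(*(below[id(c)] for c in n.children))
            if n is not self.root:
                out.append(below[id(n)])
        return out

    def bipartitions(self) -> frozenset:
        return bipartitions(self)


def _from_dendropy(dnode) -> TreeNode:
    label = dnode.taxon.label if dnode.taxon is not None else dnode.label
    n = TreeNode(label, dnode.edge.length if dnode.edge.length is not None else 0.0)
    if not dnode.is_leaf() and dnode.label is not None:
        try:
            n.support = float(dnode.label)
        except ValueError:
            pass
    for c in dnode.child_nodes():
        n.add_child(_from_dendropy(c))
    return n


def read_tree(path, format: str = "newick") -> Tree:
    """Read a Newick tree file. Missing branch lengths default to 0."""
    if format != "newick":
        raise ValueError(f"unsupported tree format: {format}")
    with open(path) as fh:
        text = fh.read()
    return Tree.from_newick(text)


def normalize_split(side: frozenset, all_taxa: frozenset) -> frozenset:
    """Orient a bipartition to the side NOT containing the lexicographic first taxon."""
    first = min(all_taxa)
    return all_taxa - side if first in side else side


def bipartitions(tree: Tree) -> frozenset:
    """Non-trivial bipartitions induced by internal edges, orientation-normalized."""
    taxa = frozenset(tree.leaf_labels())
    out = set()
    for side in tree.edge_leafsets():
        if 1 < len(side) < len(taxa) - 1:
            out.add(normalize_split(side, taxa))
    # For a rooted tree the two root children induce the same split; set dedups.
    return frozenset(out)


# ---------------------------------------------------------------------------
# Character matrices
# ---------------------------------------------------------------------------

class CharacterMatrix:
    """Taxa x characters over a declared alphabet.

    Cells are frozensets of state symbols (singleton for a plain state, larger
    for ambiguity), or the sentinels ``GAP`` / ``MISSING``.
    """

    def __init__(self, taxa, cells, alphabet: str, states=None, char_meta=None):
        self.taxa = list(taxa)
        if len(set(self.taxa)) != len(self.taxa):
            raise FormatError("duplicate taxon labels in matrix")
        self.cells = [list(row) for row in cells]
        ncols = {len(r) for r in self.cells}
        if len(ncols) > 1:
            bad = self.taxa[[len(r) for r in self.cells].index(max(ncols))]
            raise FormatError(f"ragged matrix: row length differs at taxon {bad!r}")
        if alphabet not in ("dna", "standard"):
            raise ValueError(f"unknown alphabet {alphabet!r}")
        self.alphabet = alphabet
        if states is None:
            if alphabet == "dna":
                states = _DNA_STATES
            else:
                seen = set()
                for row in self.cells:
                    for c in row:
                        if isinstance(c, frozenset):
                            seen |= c
                states = tuple(sorted(seen))
        self.states = tuple(states)
        sset = set(self.states)
        for ti, row in enumerate(self.cells):
            for j, c in enumerate(row):
                if c in (GAP, MISSING):
                    continue
                if not isinstance(c, frozenset) or not c or not c <= sset:
                    raise FormatError(
                        f"unknown symbol {c!r} at taxon {self.taxa[ti]!r}, site {j + 1}")
        n = self.n_chars
        if char_meta is None:
            char_meta = [{"partition": None, "region": "other"} for _ in range(n)]
        self.char_meta = char_meta

    @property
    def n_taxa(self):
        return len(self.taxa)

    @property
    def n_chars(self):
        return len(self.cells[0]) if self.cells else 0

    def row(self, taxon):
        return self.cells[self.taxa.index(taxon)]

    def column(self, j):
        return [row[j] for row in self.cells]

    def subset_sites(self, indices) -> "CharacterMatrix":
        return CharacterMatrix(
            self.taxa,
            [[row[j] for j in indices] for row in self.cells],
            self.alphabet, self.states,
            [self.char_meta[j] for j in indices],
        )

    def __eq__(self, other):
        return (isinstance(other, CharacterMatrix)
                and self.taxa == other.taxa
                and self.alphabet == other.alphabet
                and self.cells == other.cells)

    # -- symbol round-trip -------------------------------------------------
    def cell_symbol(self, cell) -> str:
        if cell in (GAP, MISSING):
            return cell
        if len(cell) == 1:
            return next(iter(cell))
        if self.alphabet == "dna":
            for sym, ss in IUPAC_DNA.items():
                if ss == cell and sym not in "UX":
                    return sym
        return "{" + "".join(sorted(cell)) + "}"  # NEXUS-style multistate ambiguity

    def write_fasta(self, path):
        with open(path, "w") as fh:
            for t, row in zip(self.taxa, self.cells):
                fh.write(f">{t}\n")
                fh.write("".join(self.cell_symbol(c) for c in row) + "\n")

    def write_nexus(self, path):
        dtype = "dna" if self.alphabet == "dna" else "standard"
        symbols = "" if self.alphabet == "dna" else \
            f' symbols="{" ".join(self.states)}"'
        with open(path, "w") as fh:
            fh.write("#NEXUS\nBEGIN DATA;\n")
            fh.write(f"  DIMENSIONS NTAX={self.n_taxa} NCHAR={self.n_chars};\n")
            fh.write(f"  FORMAT DATATYPE={dtype}{symbols} GAP=- MISSING=?;\n")
            fh.write("  MATRIX\n")
            w = max(len(t) for t in self.taxa) + 2
            for t, row in zip(self.taxa, self.cells):
                name = f"'{t}'" if not re.fullmatch(r"[A-Za-z0-9_.\-]+", t) else t
                fh.write(f"    {name:<{w}}"
                         + "".join(self.cell_symbol(c) for c in row) + "\n")
            fh.write("  ;\nEND;\n")


def _parse_symbol(sym: str, alphabet: str, states, taxon, pos):
    if sym == GAP:
        return GAP
    if sym in (MISSING, "N") and alphabet == "standard":
        return MISSING
    if sym == MISSING:
        return MISSING
    if alphabet == "dna":
        up = sym.upper()
        if up in IUPAC_DNA:
            return IUPAC_DNA[up]
        raise FormatError(f"unknown symbol {sym!r} at taxon {taxon!r}, site {pos}")
    if sym in states:
        return frozenset([sym])
    raise FormatError(f"unknown symbol {sym!r} at taxon {taxon!r}, site {pos}")


def read_matrix(path, format: str) -> CharacterMatrix:
    """Read a FASTA (DNA) or NEXUS (dna / standard datatype) character matrix."""
    if format == "fasta":
        from Bio import SeqIO
        taxa, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in taxa:
                raise FormatError(f"duplicate taxon {rec.id!r}")
            taxa.append(rec.id)
            rows.append([_parse_symbol(s, "dna", _DNA_STATES, rec.id, i + 1)
                         for i, s in enumerate(str(rec.seq))])
        if not taxa:
            raise FormatError(f"no records in {path}")
        return CharacterMatrix(taxa, rows, "dna")
    if format == "nexus":
        try:
            ds = dendropy.DataSet.get(path=str(path), schema="nexus",
                                      preserve_underscores=True)
        except Exception as exc:
            raise FormatError(f"NEXUS parse error: {exc}") from exc
        if not ds.char_matrices:
            raise FormatError("NEXUS file contains no character matrix")
        cm = ds.char_matrices[0]
        is_dna = isinstance(cm, dendropy.DnaCharacterMatrix)
        alphabet = "dna" if is_dna else "standard"
        taxa, rows = [], []
        raw_rows = []
        for taxon in cm:
            taxa.append(taxon.label)
            raw_rows.append([str(ch) for ch in cm[taxon].symbols_as_list()])
        states = None
        if alphabet == "standard":
            states = tuple(sorted({s for row in raw_rows for s in row
                                   if s not in (GAP, MISSING)}))
        for t, raw in zip(taxa, raw_rows):
            rows.append([_parse_symbol(s, alphabet, states or (), t, i + 1)
                         for i, s in enumerate(raw)])
        return CharacterMatrix(taxa, rows, alphabet, states)
    raise ValueError(f"unsupported matrix format: {format}")


def write_matrix(matrix: CharacterMatrix, path, format: str) -> None:
    if format == "fasta":
        matrix.write_fasta(path)
    elif format == "nexus":
        matrix.write_nexus(path)
    else:
        raise ValueError(f"unsupported matrix format: {format}")


# ---------------------------------------------------------------------------
# Partition schemes
# ---------------------------------------------------------------------------

@dataclass
class PartitionScheme:
    """Named disjoint site-index sets covering an alignment (0-based internally)."""

    parts: dict  # name -> (tuple of 0-based indices, model spec string or None)

    def __post_init__(self):
        seen = set()
        for name, (idx, _model) in self.parts.items():
            s = set(idx)
            if s & seen:
                raise FormatError(f"partition {name!r} overlaps another partition")
            seen |= s
        self._covered = seen

    def validate_covers(self, n_sites: int):
        if self._covered != set(range(n_sites)):
            missing = sorted(set(range(n_sites)) - self._covered)
            raise FormatError(
                f"partition scheme does not cover all {n_sites} sites "
                f"(first missing 1-based site: {missing[0] + 1})")

    @property
    def names(self):
        return list(self.parts)

    def indices(self, name):
        return self.parts[name][0]

    def model(self, name):
        return self.parts[name][1]

    @classmethod
    def single(cls, n_sites: int, model: str | None = None,
               name: str = "all") -> "PartitionScheme":
        return cls({name: (tuple(range(n_sites)), model)})

    @classmethod
    def from_text(cls, text: str) -> "PartitionScheme":
        """Parse INI-style lines ``name = 1-600, 1201-1800 [; model=GTR+I+G]``.

        Ranges are 1-based inclusive, matching the conventional "COI (1-600)"
        style of published partition tables.
        """
        parts = {}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line or line.startswith("["):
                continue
            if "=" not in line:
                raise FormatError(f"cannot parse partition line: {raw!r}")
            name, rhs = line.split("=", 1)
            name = name.strip()
            model = None
            if ";" in rhs:
                rhs, opts = rhs.split(";", 1)
                m = re.search(r"model\s*=\s*([A-Za-z0-9+]+)", opts)
                if m:
                    model = m.group(1)
            idx = []
            for token in rhs.split(","):
                token = token.strip()
                if not token:
                    continue
                m = re.fullmatch(r"(\d+)\s*-\s*(\d+)(?:\\(\d+))?", token)
                if m:
                    a, b = int(m.group(1)), int(m.group(2))
                    step = int(m.group(3)) if m.group(3) else 1
                    if b < a:
                        raise FormatError(f"bad range {token!r} in {name!r}")
                    idx.extend(range(a - 1, b, step))
                elif token.isdigit():
                    idx.append(int(token) - 1)
                else:
                    raise FormatError(f"bad range token {token!r} in {name!r}")
            parts[name] = (tuple(idx), model)
        if not parts:
            raise FormatError("empty partition scheme")
        return cls(parts)


# ---------------------------------------------------------------------------
# Constraint sets
# ---------------------------------------------------------------------------

@dataclass
class ConstraintSet:
    """Named collection of taxon subsets each required to be monophyletic."""

    name: str
    subsets: list = field(default_factory=list)  # list[frozenset[str]]

    def __post_init__(self):
        self.subsets = [frozenset(s) for s in self.subsets]
        for s in self.subsets:
            if len(s) < 2:
                raise FormatError(
                    f"constraint in {self.name!r} has fewer than 2 taxa: {sorted(s)}")
        for i, a in enumerate(self.subsets):
            for b in self.subsets[i + 1:]:
                inter = a & b
                if inter and not (a <= b or b <= a):
                    raise FormatError(
                        f"incompatible constraints in {self.name!r}: "
                        f"{sorted(a)[:3]}... vs {sorted(b)[:3]}... overlap without nesting")

    def __len__(self):
        return len(self.subsets)

    def validate_taxa(self, taxa):
        taxa = frozenset(taxa)
        for s in self.subsets:
            missing = s - taxa
            if missing:
                raise PhylogeoError(
                    f"constraint taxa not in data: {sorted(missing)}")
            if s >= taxa:
                raise FormatError(
                    f"constraint in {self.name!r} is not a proper subset of all taxa")

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump({self.name: [sorted(s) for s in self.subsets]}, fh, indent=1)

    @classmethod
    def from_tree(cls, tree: Tree, name: str = "tree") -> "ConstraintSet":
        """Fully resolved constraint set: one subset per internal edge clade."""
        taxa = frozenset(tree.leaf_labels())
        subs = []
        for side in tree.edge_leafsets():
            side = normalize_split(side, taxa)
            if 1 < len(side) < len(taxa):
                subs.append(side)
        return cls(name, sorted(set(subs), key=lambda s: (len(s), sorted(s))))


def load_constraint_sets(path) -> dict:
    """Load ``{name: [[taxon, ...], ...]}`` JSON into ConstraintSet objects."""
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise FormatError("constraint JSON must map name -> list of taxon lists")
    return {name: ConstraintSet(name, [frozenset(x) for x in lists])
            for name, lists in data.items()}


def satisfies(tree: Tree, constraints: ConstraintSet) -> bool:
    """True iff every constrained subset is a clade of the unrooted tree."""
    constraints.validate_taxa(tree.leaf_labels())
    taxa = frozenset(tree.leaf_labels())
    sides = set()
    for side in tree.edge_leafsets():
        sides.add(side)
        sides.add(taxa - side)
    return all(s in sides for s in constraints.subsets)
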