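"""Molecules as abstract undirected graphs, one-hot atom features, label tables.

A molecule is reduced to its topology: atoms are typed vertices (element
symbol only), bonds are plain undirected edges. Bond order, aromaticity,
charges, isotopes and stereochemistry are deliberately discarded — the
downstream convolutional model only consumes topological connectivity.
Hydrogens are materialized as explicit vertices by default so that e.g.
water is a 3-vertex star, not a single oxygen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MolecularGraph",
    "AtomAlphabet",
    "AtomFeatureMatrix",
    "LabelMatrix",
    "SmilesParseError",
    "UnknownAtomError",
    "LabelTableError",
    "parse_smiles",
    "read_smiles_file",
    "read_sdf",
    "one_hot_encode",
    "infer_alphabet",
    "read_label_table",
    "write_label_table",
]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed.

    Carries ``line_number`` (1-based, or None for free-standing strings)
    so file-level callers can point at the offending record.
    """

    def __init__(self, smiles: str, line_number: int | None = None):
        self.smiles = smiles
        self.line_number = line_number
        where = f" (line {line_number})" if line_number is not None else ""
        super().__init__(f"unparseable SMILES{where}: {smiles!r}")


class UnknownAtomError(KeyError):
    """An atom symbol is absent from the model's frozen alphabet."""

    def __init__(self, symbol: str, compound_id: str):
        self.symbol = symbol
        self.compound_id = compound_id
        super().__init__(
            f"atom symbol {symbol!r} of compound {compound_id!r} is not in the alphabet"
        )


class LabelTableError(ValueError):
    """Malformed label table (non-binary cell, duplicate id, bad header)."""


@dataclass(frozen=True)
class MolecularGraph:
    """Undirected graph of one compound: element-typed vertices, bond edges."""

    compound_id: str
    atoms: tuple[str, ...]
    edges: frozenset[frozenset[int]] = field(default_factory=frozenset)

    def __post_init__(self):
        if len(self.atoms) < 1:
            raise ValueError(f"compound {self.compound_id!r} has no atoms")
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"self-loop or malformed edge {set(e)} in {self.compound_id!r}")
            for i in e:
                if not (0 <= i < len(self.atoms)):
                    raise ValueError(f"edge {set(e)} references invalid atom index in {self.compound_id!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def edge_list(self) -> list[tuple[int, int]]:
        """Edges as sorted (i, j) pairs with i < j, in deterministic order."""
        return sorted(tuple(sorted(e)) for e in self.edges)

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix (no self-connections)."""
        a = np.zeros((self.n_atoms, self.n_atoms), dtype=np.float64)
        for i, j in self.edge_list():
            a[i, j] = a[j, i] = 1.0
        return a

    def neighbors(self, i: int) -> list[int]:
        return sorted(j for e in self.edges if i in e for j in e if j != i)

    @staticmethod
    def from_edge_pairs(compound_id, atoms, pairs) -> "MolecularGraph":
        edges = frozenset(frozenset(p) for p in pairs)
        return MolecularGraph(compound_id, tuple(atoms), edges)


@dataclass(frozen=True)
class AtomAlphabet:
    """Ordered, duplicate-free element symbols; position fixes the one-hot index."""

    symbols: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet contains duplicate symbols")
        if len(self.symbols) == 0:
            raise ValueError("alphabet is empty")

    def __len__(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        try:
            return self.symbols.index(symbol)
        except ValueError:
            raise KeyError(symbol) from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols


@dataclass
class AtomFeatureMatrix:
    """Per-atom feature vectors of one molecule at convolution layer ``layer_index``.

    Row i is the feature vector of atom i. Layer 0 holds the one-hot input;
    layers >= 1 are post-ReLU and therefore non-negative.
    """

    values: np.ndarray
    layer_index: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D (atoms x features)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_atoms(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass
class LabelMatrix:
    """Binary multilabel membership of compounds over K named categories."""

    compound_ids: list[str]
    categories: list[str]
    membership: np.ndarray

    def __post_init__(self):
        self.membership = np.asarray(self.membership)
        if self.membership.shape != (len(self.compound_ids), len(self.categories)):
            raise ValueError("membership shape does not match ids x categories")
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise LabelTableError("duplicate compound_id in label matrix")
        if self.membership.size and not np.isin(self.membership, (0, 1)).all():
            raise LabelTableError("membership entries must be 0 or 1")
        self.membership = self.membership.astype(np.int8)

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def row(self, compound_id: str) -> np.ndarray:
        return self.membership[self.compound_ids.index(compound_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.membership, index=pd.Index(self.compound_ids, name="compound_id"),
            columns=self.categories,
        )


def _rdkit():
    # imported lazily so the pure-graph paths need no chemistry toolkit
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.*")
    return Chem


def _mol_to_graph(mol, compound_id: str, explicit_h: bool) -> MolecularGraph:
    Chem = _rdkit()
    if explicit_h:
        mol = Chem.AddHs(mol)
    atoms = tuple(a.GetSymbol() for a in mol.GetAtoms())
    pairs = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    return MolecularGraph.from_edge_pairs(compound_id, atoms, pairs)


def parse_smiles(
    line: str, explicit_h: bool = True, line_number: int | None = None
) -> MolecularGraph | None:
    """Parse one SMILES record (``SMILES`` or ``SMILES<tab/space>id``) into a graph.

    Returns None for blank lines (a skip signal for file readers). Raises
    :class:`SmilesParseError` on syntactically invalid SMILES. With
    ``explicit_h`` (the default) hydrogens become vertices of the graph.
    """
    stripped = line.strip()
    if not stripped:
        return None
    parts = stripped.split(None, 1)
    smiles = parts[0]
    compound_id = parts[1].strip() if len(parts) > 1 else smiles
    Chem = _rdkit()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles, line_number)
    return _mol_to_graph(mol, compound_id, explicit_h)


def read_smiles_file(path, explicit_h: bool = True) -> list[MolecularGraph]:
    """Read a SMILES line file (one ``SMILES<tab>compound_id`` record per line)."""
    graphs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            g = parse_smiles(line, explicit_h=explicit_h, line_number=lineno)
            if g is not None:
                graphs.append(g)
    return graphs


def read_sdf(path, explicit_h: bool = True, id_property: str | None = None) -> list[MolecularGraph]:
    """Read an MDL SDF; compound ids from the title line or ``id_property``."""
    Chem = _rdkit()
    graphs = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise SmilesParseError(f"<SDF record {idx}>", idx + 1)
        if id_property and mol.HasProp(id_property):
            cid = mol.GetProp(id_property)
        else:
            cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{idx}"
        graphs.append(_mol_to_graph(mol, cid, explicit_h))
    return graphs


def one_hot_encode(g: MolecularGraph, alphabet: AtomAlphabet) -> AtomFeatureMatrix:
    """One-hot atom-type features: row i has a single 1 at atom i's alphabet index."""
    x = np.zeros((g.n_atoms, len(alphabet)), dtype=np.float64)
    for i, sym in enumerate(g.atoms):
        if sym not in alphabet:
            raise UnknownAtomError(sym, g.compound_id)
        x[i, alphabet.index(sym)] = 1.0
    return AtomFeatureMatrix(x, layer_index=0)


def infer_alphabet(graphs: list[MolecularGraph]) -> AtomAlphabet:
    """Sorted distinct element symbols over a training set (deterministic)."""
    if not graphs:
        raise ValueError("cannot infer an alphabet from an empty graph list")
    return AtomAlphabet(tuple(sorted({s for g in graphs for s in g.atoms})))


def read_label_table(path) -> LabelMatrix:
    """Read a delimited label table: ``compound_id`` column then one 0/1 column per category.

    The delimiter is taken from the extension (.csv -> comma, otherwise tab).
    """
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2 or df.columns[0] != "compound_id":
        raise LabelTableError(
            f"{path}: header must start with 'compound_id' followed by category columns"
        )
    ids = df["compound_id"].tolist()
    dupes = df["compound_id"][df["compound_id"].duplicated()].tolist()
    if dupes:
        raise LabelTableError(f"{path}: duplicate compound_id {dupes[0]!r}")
    cats = list(df.columns[1:])
    raw = df[cats].to_numpy()
    membership = np.zeros(raw.shape, dtype=np.int8)
    for r in range(raw.shape[0]):
        for c in range(raw.shape[1]):
            cell = str(raw[r, c]).strip()
            if cell not in ("0", "1"):
                raise LabelTableError(
                    f"{path}: non-binary cell {cell!r} at row {r + 2}, column {cats[c]!r}"
                )
            membership[r, c] = int(cell)
    return LabelMatrix(ids, cats, membership)


def write_label_table(labels: LabelMatrix, path) -> None:
    """Write a label table in the format accepted by :func:`read_label_table`."""
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    labels.to_frame().to_csv(path, sep=sep)
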