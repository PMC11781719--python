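"""Reading, writing and validation of heterogeneous-network inputs.

The package works on a four-class node universe (drugs, proteins, diseases,
side effects) connected by six binary relations.  All matrices in the
pipeline share one canonical coordinate system: node indices are dense,
0-based, and fixed by the order of the registry files.  This module owns
that registry plus the plain-text formats everything else reads and writes:
TSV edge lists, TSV similarity matrices with identifier headers, FASTA
sequences and fingerprint bit-strings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping

import numpy as np
from Bio import SeqIO

NODE_CLASSES = ("drug", "protein", "disease", "side_effect")

#: relation name -> (row node class, column node class)
RELATIONS: Dict[str, tuple] = {
    "drug_drug": ("drug", "drug"),
    "drug_disease": ("drug", "disease"),
    "drug_sideeffect": ("drug", "side_effect"),
    "drug_protein": ("drug", "protein"),
    "protein_protein": ("protein", "protein"),
    "protein_disease": ("protein", "disease"),
}

WITHIN_CLASS_RELATIONS = ("drug_drug", "protein_protein")


class ParseError(ValueError):
    """Malformed input file (reported with the offending line number)."""


@dataclass
class NodeRegistry:
    """Ordered node identifiers per class; the canonical index space.

    Indices are dense ``0..N-1`` within each class, in file order.
    Identifiers must be unique within a class.
    """

    drugs: List[str] = field(default_factory=list)
    proteins: List[str] = field(default_factory=list)
    diseases: List[str] = field(default_factory=list)
    side_effects: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for cls in NODE_CLASSES:
            ids = self.ids(cls)
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate identifiers in class {cls!r}")

    def ids(self, node_class: str) -> List[str]:
        return {
            "drug": self.drugs,
            "protein": self.proteins,
            "disease": self.diseases,
            "side_effect": self.side_effects,
        }[node_class]

    def size(self, node_class: str) -> int:
        return len(self.ids(node_class))

    def index(self, node_class: str) -> Dict[str, int]:
        return {name: i for i, name in enumerate(self.ids(node_class))}

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    def relation_shape(self, relation: str) -> tuple:
        row_cls, col_cls = RELATIONS[relation]
        return (self.size(row_cls), self.size(col_cls))


@dataclass
class HeteroNetwork:
    """The raw input universe: a registry plus six 0/1 relation tables.

    Within-class tables (drug_drug, protein_protein) are undirected:
    symmetric with a zero diagonal.  The drug_protein table is the
    gold-standard interaction matrix, i.e. the prediction target.
    """

    registry: NodeRegistry
    relations: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in RELATIONS:
            if name not in self.relations:
                raise ValueError(f"missing relation table {name!r}")
            table = np.asarray(self.relations[name])
            expected = self.registry.relation_shape(name)
            if table.shape != expected:
                raise ValueError(
                    f"relation {name!r} has shape {table.shape}, expected {expected}"
                )
            if not np.isin(table, (0, 1)).all():
                raise ValueError(f"relation {name!r} has non-binary entries")
            if name in WITHIN_CLASS_RELATIONS:
                if not np.array_equal(table, table.T):
                    raise ValueError(f"within-class relation {name!r} not symmetric")
                if np.any(np.diag(table) != 0):
                    raise ValueError(f"within-class relation {name!r} has self-edges")

    @property
    def interactions(self) -> np.ndarray:
        """The N_d x N_p drug-protein interaction matrix."""
        return self.relations["drug_protein"]


# ---------------------------------------------------------------------------
# registry files: one identifier per line, one file per class

_REGISTRY_FILES = {
    "drug": "drugs.txt",
    "protein": "proteins.txt",
    "disease": "diseases.txt",
    "side_effect": "side_effects.txt",
}


def _read_id_file(path: Path) -> List[str]:
    ids: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    return ids


def read_registry(directory: str | Path) -> NodeRegistry:
    """Load a registry from ``drugs.txt``/``proteins.txt``/... in *directory*."""
    directory = Path(directory)
    kw = {}
    for cls, fname in _REGISTRY_FILES.items():
        key = {"drug": "drugs", "protein": "proteins",
               "disease": "diseases", "side_effect": "side_effects"}[cls]
        kw[key] = _read_id_file(directory / fname)
    return NodeRegistry(**kw)


def write_registry(registry: NodeRegistry, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for cls, fname in _REGISTRY_FILES.items():
        with open(directory / fname, "w") as fh:
            for name in registry.ids(cls):
                fh.write(name + "\n")


# ---------------------------------------------------------------------------
# edge lists


def read_edge_list(
    path: str | Path,
    relation: str,
    registry: NodeRegistry,
    *,
    delimiter: str = "\t",
    on_unknown: str = "warn",
) -> np.ndarray:
    """Parse a two-column edge list into a 0/1 relation table.

    Lines are ``node_a<delim>node_b`` (an optional third weight column is
    ignored); ``#`` starts a comment.  Duplicate edges collapse to a single
    1.  Within-class relations are symmetrized and self-edges are dropped
    with a warning.  Unknown identifiers are skipped with a warning
    (``on_unknown="warn"``) or abort the parse (``on_unknown="error"``).
    """
    if relation not in RELATIONS:
        raise ValueError(f"unknown relation {relation!r}")
    if on_unknown not in ("warn", "error"):
        raise ValueError("on_unknown must be 'warn' or 'error'")
    row_cls, col_cls = RELATIONS[relation]
    row_index = registry.index(row_cls)
    col_index = registry.index(col_cls)
    table = np.zeros(registry.relation_shape(relation), dtype=np.uint8)
    within = relation in WITHIN_CLASS_RELATIONS

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected at least 2 columns")
            a, b = parts[0].strip(), parts[1].strip()
            if a not in row_index or b not in col_index:
                msg = f"{path}:{lineno}: identifier not in registry: " \
                      f"{a if a not in row_index else b!r}"
                if on_unknown == "error":
                    raise ParseError(msg)
                warnings.warn(msg)
                continue
            i, j = row_index[a], col_index[b]
            if within and i == j:
                warnings.warn(f"{path}:{lineno}: self-edge {a!r} dropped")
                continue
            table[i, j] = 1
            if within:
                table[j, i] = 1
    return table


def write_edge_list(
    table: np.ndarray,
    relation: str,
    registry: NodeRegistry,
    path: str | Path,
    *,
    delimiter: str = "\t",
) -> None:
    """Write the nonzero entries of a relation table as an edge list.

    For within-class relations only the upper triangle is written (the
    reader re-symmetrizes), so write-then-read round-trips exactly.
    """
    row_cls, col_cls = RELATIONS[relation]
    row_ids = registry.ids(row_cls)
    col_ids = registry.ids(col_cls)
    within = relation in WITHIN_CLASS_RELATIONS
    with open(path, "w") as fh:
        rows, cols = np.nonzero(table)
        for i, j in zip(rows, cols):
            if within and j <= i:
                continue
            fh.write(f"{row_ids[i]}{delimiter}{col_ids[j]}\n")


# ---------------------------------------------------------------------------
# similarity matrices


def read_similarity_matrix(
    path: str | Path,
    *,
    delimiter: str = "\t",
    asymmetry_tolerance: float = 1e-6,
) -> tuple:
    """Read a square similarity matrix with identifier header row/column.

    Returns ``(ids, matrix)``.  Small asymmetry (max ``|M - M.T|`` at or
    below *asymmetry_tolerance*) is repaired by averaging with the
    transpose; larger asymmetry is an error.  Entries outside [0, 1] are
    clipped with a warning.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delimiter)
        col_ids = [c for c in header[1:] if c != ""]
        rows = []
        row_ids = []
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split(delimiter)
            row_ids.append(parts[0])
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric entry") from exc
    matrix = np.asarray(rows, dtype=float)
    if matrix.shape[0] != matrix.shape[1] or len(col_ids) != matrix.shape[1]:
        raise ParseError(f"{path}: similarity matrix is not square")
    if row_ids != col_ids:
        raise ParseError(f"{path}: header row and column identifiers differ")
    asym = np.abs(matrix - matrix.T).max() if matrix.size else 0.0
    if asym > asymmetry_tolerance:
        raise ValueError(
            f"{path}: asymmetry {asym:.3g} exceeds tolerance {asymmetry_tolerance:g}"
        )
    matrix = (matrix + matrix.T) / 2.0
    if matrix.size and (matrix.min() < 0.0 or matrix.max() > 1.0):
        warnings.warn(f"{path}: entries outside [0, 1] clipped")
        matrix = np.clip(matrix, 0.0, 1.0)
    return row_ids, matrix


def write_similarity_matrix(
    ids: List[str],
    matrix: np.ndarray,
    path: str | Path,
    *,
    delimiter: str = "\t",
) -> None:
    matrix = np.asarray(matrix, dtype=float)
    with open(path, "w") as fh:
        fh.write(delimiter + delimiter.join(ids) + "\n")
        for name, row in zip(ids, matrix):
            fh.write(name + delimiter
                     + delimiter.join(repr(float(x)) for x in row) + "\n")


# ---------------------------------------------------------------------------
# sequences and fingerprints


def read_sequences(path: str | Path) -> Dict[str, str]:
    """Read protein sequences from FASTA into an identifier -> string map.

    Identifiers are the first whitespace-delimited token of each header;
    sequences are uppercased.  Duplicate identifiers and empty records are
    errors; unusual residue characters are kept verbatim with a warning.
    """
    sequences: Dict[str, str] = {}
    standard = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*")
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        seq = str(record.seq).upper()
        if not seq:
            raise ParseError(f"{path}: empty record {name!r}")
        if name in sequences:
            raise ParseError(f"{path}: duplicate header {name!r}")
        if set(seq) - standard:
            warnings.warn(
                f"{path}: record {name!r} has non-amino-acid characters (kept)"
            )
        sequences[name] = seq
    return sequences


def read_fingerprints(
    path: str | Path,
    *,
    delimiter: str = "\t",
    fmt: str = "bits",
    n_bits: int | None = None,
) -> Dict[str, np.ndarray]:
    """Read fingerprint bit-vectors: one ``identifier<delim>bits`` per line.

    ``fmt="bits"`` expects a 0/1 string; ``fmt="hex"`` expects hexadecimal
    with *n_bits* giving the vector length.  All vectors must have the same
    length.
    """
    if fmt not in ("bits", "hex"):
        raise ValueError("fmt must be 'bits' or 'hex'")
    if fmt == "hex" and n_bits is None:
        raise ValueError("hex fingerprints require n_bits")
    fingerprints: Dict[str, np.ndarray] = {}
    length = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            name, bits = parts[0], parts[1]
            if fmt == "hex":
                value = int(bits, 16)
                vec = np.array(
                    [(value >> (n_bits - 1 - k)) & 1 for k in range(n_bits)],
                    dtype=np.uint8,
                )
            else:
                if set(bits) - {"0", "1"}:
                    raise ParseError(f"{path}:{lineno}: non-binary fingerprint")
                vec = np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0")
            if length is None:
                length = len(vec)
            elif len(vec) != length:
                raise ParseError(
                    f"{path}:{lineno}: fingerprint length {len(vec)} != {length}"
                )
            fingerprints[name] = vec
    return fingerprints


def load_network(
    directory: str | Path,
    *,
    delimiter: str = "\t",
    on_unknown: str = "warn",
) -> HeteroNetwork:
    """Load a registry plus the six relation edge lists from one directory."""
    directory = Path(directory)
    registry = read_registry(directory)
    relations = {
        name: read_edge_list(
            directory / f"{name}.tsv", name, registry,
            delimiter=delimiter, on_unknown=on_unknown,
        )
        for name in RELATIONS
    }
    return HeteroNetwork(registry=registry, relations=relations)


def write_network(net: HeteroNetwork, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_registry(net.registry, directory)
    for name, table in net.relations.items():
        write_edge_list(table, name, net.registry, directory / f"{name}.tsv")
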