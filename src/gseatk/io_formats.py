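"""Readers and writers for the community enrichment-analysis file formats.

Supported dialects
------------------
GMT   tab-separated: set name, description, then one gene symbol per field.
RNK   two tab-separated columns: gene symbol, real-valued ranking score.
CLS   three-line two-class phenotype file: ``N 2 1`` / ``# nameA nameB`` /
      N space-separated class labels (either the class names or 0/1 tokens,
      mapped to the names on line 2 by first-appearance order).
GCT   version 1.2: ``#1.2`` / ``n_genes n_samples`` / header row
      (Name, Description, samples...) / one row per gene.
TSV   plain matrix: header row of sample ids, first column gene ids.

All gene symbols are case-folded to upper case on load so that symbol
matching across libraries, ranked lists and expression matrices is
case-insensitive (Enrichr-style libraries are upper-case).  Files are read
as UTF-8; Unix and Windows newlines are both accepted.
"""

from __future__ import annotations

import io
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GeneSet",
    "GeneSetLibrary",
    "RankedList",
    "ExpressionDataset",
    "read_gmt",
    "write_gmt",
    "read_rnk",
    "write_rnk",
    "read_cls",
    "write_cls",
    "read_expression",
    "write_expression",
    "read_gene_list",
]

NA_TOKENS = {"", "NA", "NAN", "NaN", "nan", "na"}


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


def _norm_symbol(symbol: str) -> str:
    return symbol.strip().upper()


# ---------------------------------------------------------------------------
# Gene set libraries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols with a free-text description."""

    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.members)


class GeneSetLibrary:
    """An ordered, name-unique collection of :class:`GeneSet` objects."""

    def __init__(self, sets: Iterable[GeneSet] = ()) -> None:
        self._sets: dict[str, GeneSet] = {}
        for gs in sets:
            self.add(gs)

    def add(self, gs: GeneSet) -> None:
        if gs.name in self._sets:
            raise ValueError(f"duplicate gene set name {gs.name!r}")
        self._sets[gs.name] = gs

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Sequence[str]]) -> "GeneSetLibrary":
        """Build a library from ``{name: [genes...]}``; descriptions left blank."""
        lib = cls()
        for name, genes in mapping.items():
            seen: dict[str, None] = {}
            for g in genes:
                seen.setdefault(_norm_symbol(g), None)
            lib.add(GeneSet(name=name, description="", members=tuple(seen)))
        return lib

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def all_genes(self) -> set[str]:
        """Union of all member symbols across the library."""
        out: set[str] = set()
        for gs in self._sets.values():
            out.update(gs.members)
        return out

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetLibrary):
            return NotImplemented
        return list(self) == list(other)

    def __repr__(self) -> str:
        return f"GeneSetLibrary({len(self)} sets)"


def read_gmt(path: str | Path) -> GeneSetLibrary:
    """Read a GMT gene set library.

    Each non-blank line must have at least three tab-separated fields
    (name, description, one or more genes).  Duplicate genes within a line
    are removed keeping the first occurrence; a duplicate set name is an
    error.  File order of sets and members is preserved.
    """
    lib = GeneSetLibrary()
    with open(path, encoding="utf-8", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT line needs >= 3 tab-separated "
                    f"fields (name, description, genes...), got {len(fields)}"
                )
            name, description = fields[0].strip(), fields[1]
            members: dict[str, None] = {}
            for tok in fields[2:]:
                sym = _norm_symbol(tok)
                if sym:
                    members.setdefault(sym, None)
            if not members:
                raise FormatError(f"{path}: line {lineno}: set {name!r} has no genes")
            try:
                lib.add(GeneSet(name=name, description=description, members=tuple(members)))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return lib


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    """Write a library as GMT; an empty description is emitted as ``na``."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gs in library:
            desc = gs.description if gs.description else "na"
            fh.write("\t".join([gs.name, desc, *gs.members]) + "\n")


# ---------------------------------------------------------------------------
# Ranked lists
# ---------------------------------------------------------------------------

class RankedList:
    """Gene symbols with real-valued ranking scores, ordered descending.

    Ties in score are broken by ascending lexicographic gene symbol so that
    the total order is unique for any input.  Symbols are case-folded to
    upper case and must be unique; scores must be finite.
    """

    __slots__ = ("genes", "scores", "_positions")

    def __init__(self, genes: Sequence[str], scores: Sequence[float]) -> None:
        genes_arr = np.asarray([_norm_symbol(g) for g in genes], dtype=object)
        scores_arr = np.asarray(scores, dtype=float)
        if genes_arr.shape != scores_arr.shape or genes_arr.ndim != 1:
            raise ValueError("genes and scores must be 1-D and the same length")
        if genes_arr.size == 0:
            raise ValueError("ranked list is empty")
        if not np.all(np.isfinite(scores_arr)):
            bad = genes_arr[~np.isfinite(scores_arr)]
            raise ValueError(f"non-finite score(s) for: {', '.join(map(str, bad[:5]))}")
        uniq, counts = np.unique(genes_arr.astype(str), return_counts=True)
        if np.any(counts > 1):
            dups = uniq[counts > 1]
            raise ValueError(f"duplicate gene symbol(s): {', '.join(dups[:5])}")
        order = np.lexsort((genes_arr.astype(str), -scores_arr))
        self.genes: np.ndarray = genes_arr[order].astype(str)
        self.scores: np.ndarray = scores_arr[order]
        self._positions: dict[str, int] | None = None

    @classmethod
    def from_series(cls, series: pd.Series) -> "RankedList":
        return cls(series.index.astype(str).tolist(), series.to_numpy(dtype=float))

    def position_of(self, gene: str) -> int:
        """1-based rank position of *gene* (case-insensitive)."""
        if self._positions is None:
            self._positions = {g: i + 1 for i, g in enumerate(self.genes)}
        return self._positions[_norm_symbol(gene)]

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, index=pd.Index(self.genes, name="gene"), name="score")

    def __len__(self) -> int:
        return len(self.genes)

    def __repr__(self) -> str:
        return f"RankedList({len(self)} genes, top={self.genes[0]!r})"


def read_rnk(path: str | Path) -> RankedList:
    """Read a RNK file (gene<TAB>score); sorted descending regardless of file order."""
    genes: list[str] = []
    scores: list[float] = []
    with open(path, encoding="utf-8", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: RNK line needs exactly 2 tab-separated fields"
                )
            gene = _norm_symbol(fields[0])
            try:
                score = float(fields[1].replace("−", "-"))  # tolerate unicode minus
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: cannot parse score {fields[1]!r}"
                ) from exc
            genes.append(gene)
            scores.append(score)
    try:
        return RankedList(genes, scores)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_rnk(ranked: RankedList, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g, s in zip(ranked.genes, ranked.scores):
            fh.write(f"{g}\t{float(s)!r}\n")


# ---------------------------------------------------------------------------
# Phenotype labels (CLS)
# ---------------------------------------------------------------------------

def read_cls(path: str | Path) -> tuple[list[str], tuple[str, str]]:
    """Read a two-class CLS file.

    Returns ``(labels, class_names)`` where *labels* is one class name per
    sample in file order and *class_names* are the two names from the header
    line in header order (the first is treated downstream as class A).
    Labels given as 0/1 (or other non-name) tokens are mapped to the header
    names by first-appearance order.
    """
    with open(path, encoding="utf-8", newline=None) as fh:
        lines = [ln.rstrip("\r\n") for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise FormatError(f"{path}: CLS needs 3 non-blank lines, got {len(lines)}")
    head = lines[0].split()
    if len(head) != 3:
        raise FormatError(f"{path}: line 1 must be 'N n_classes 1'")
    n_samples, n_classes = int(head[0]), int(head[1])
    if n_classes != 2:
        raise FormatError(f"{path}: only two-class CLS supported, declared {n_classes}")
    name_line = lines[1].split()
    if name_line[0] != "#" and not name_line[0].startswith("#"):
        raise FormatError(f"{path}: line 2 must start with '#'")
    names = name_line[1:] if name_line[0] == "#" else [name_line[0][1:], *name_line[1:]]
    names = [n for n in names if n]
    if len(names) != 2 or names[0] == names[1]:
        raise FormatError(f"{path}: line 2 must name exactly 2 distinct classes")
    tokens = lines[2].split()
    if len(tokens) != n_samples:
        raise FormatError(
            f"{path}: line 1 declares {n_samples} samples but line 3 has {len(tokens)}"
        )
    distinct = list(dict.fromkeys(tokens))
    if len(distinct) != 2:
        raise FormatError(
            f"{path}: expected exactly 2 distinct labels on line 3, got {len(distinct)}"
        )
    if set(distinct) == set(names):
        mapping = {t: t for t in distinct}
    else:
        # numeric or otherwise renamed tokens: first-appearance order maps to
        # the header names in header order
        mapping = {distinct[0]: names[0], distinct[1]: names[1]}
    labels = [mapping[t] for t in tokens]
    for name in names:
        if labels.count(name) < 2:
            raise FormatError(f"{path}: class {name!r} has fewer than 2 samples")
    return labels, (names[0], names[1])


def write_cls(labels: Sequence[str], class_names: tuple[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"{len(labels)} 2 1\n")
        fh.write(f"# {class_names[0]} {class_names[1]}\n")
        fh.write(" ".join(labels) + "\n")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """A genes x samples real matrix with optional two-class phenotypes.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with one column per sample.
    phenotypes
        Optional class label per sample (in sample order).
    class_order
        The two class names; the first is class A for ranking metrics.
        Defaults to first-appearance order of *phenotypes*.
    """

    values: pd.DataFrame
    phenotypes: list[str] | None = None
    class_order: tuple[str, str] | None = None
    description: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = self.values.copy()
        self.values.index = [_norm_symbol(g) for g in self.values.index]
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene id(s): {', '.join(dups[:5])}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        mat = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(mat)):
            raise ValueError("expression matrix contains missing/non-finite values")
        if self.phenotypes is not None:
            if len(self.phenotypes) != self.values.shape[1]:
                raise ValueError("one phenotype label per sample required")
            classes = list(dict.fromkeys(self.phenotypes))
            if len(classes) != 2:
                raise ValueError(f"exactly 2 phenotype classes required, got {len(classes)}")
            if self.class_order is None:
                self.class_order = (classes[0], classes[1])
            elif set(self.class_order) != set(classes):
                raise ValueError("class_order does not match phenotype labels")
            for c in classes:
                if self.phenotypes.count(c) < 2:
                    raise ValueError(f"phenotype class {c!r} has fewer than 2 samples")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(map(str, self.values.columns))

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def class_mask(self) -> np.ndarray:
        """Boolean mask over samples: True where the sample is in class A."""
        if self.phenotypes is None or self.class_order is None:
            raise ValueError("dataset has no phenotypes")
        return np.asarray([p == self.class_order[0] for p in self.phenotypes])

    def with_phenotypes(
        self, labels: Sequence[str], class_order: tuple[str, str] | None = None
    ) -> "ExpressionDataset":
        return ExpressionDataset(
            self.values, phenotypes=list(labels), class_order=class_order,
            description=self.description,
        )


def _collapse_duplicate_genes(frame: pd.DataFrame) -> pd.DataFrame:
    """Keep, per duplicated gene id, the row with the highest mean value."""
    if not frame.index.has_duplicates:
        return frame
    means = frame.mean(axis=1).to_numpy()
    keep = np.zeros(len(frame), dtype=bool)
    best: dict[str, int] = {}
    for i, g in enumerate(frame.index):
        j = best.get(g)
        if j is None or means[i] > means[j]:
            best[g] = i
    for i in best.values():
        keep[i] = True
    return frame.iloc[keep]


def _check_numeric(frame: pd.DataFrame, path: str | Path, drop_na_genes: bool) -> pd.DataFrame:
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad_cells = numeric.isna() & ~frame.astype(str).apply(
        lambda col: col.str.strip().isin(NA_TOKENS)
    )
    if bad_cells.to_numpy().any():
        gene = bad_cells.any(axis=1).idxmax()
        raise FormatError(f"{path}: non-numeric value in row {gene!r}")
    if numeric.isna().to_numpy().any():
        if drop_na_genes:
            numeric = numeric.dropna(axis=0, how="any")
        else:
            gene = numeric.isna().any(axis=1).idxmax()
            raise FormatError(
                f"{path}: missing value in row {gene!r} "
                "(pass drop_na_genes=True to drop such genes)"
            )
    return numeric.astype(float)


def read_expression(
    path: str | Path, format: str = "tsv", drop_na_genes: bool = False
) -> ExpressionDataset:
    """Read an expression matrix from GCT v1.2 or plain TSV.

    NA tokens ("", "NA", "NaN") are rejected unless ``drop_na_genes`` is
    set, in which case any gene row containing an NA is dropped.  Duplicate
    gene rows are collapsed keeping the row with the highest mean value.
    """
    path = Path(path)
    if format not in {"gct", "tsv"}:
        raise ValueError(f"unknown expression format {format!r}")
    if format == "gct":
        with open(path, encoding="utf-8", newline=None) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise FormatError(f"{path}: expected GCT version line '#1.2', got {version!r}")
            dims = fh.readline().split()
            if len(dims) != 2:
                raise FormatError(f"{path}: GCT dimension line must have 2 fields")
            n_genes, n_samples = int(dims[0]), int(dims[1])
            body = pd.read_csv(io.StringIO(fh.read()), sep="\t", dtype=str)
        if body.shape[1] != n_samples + 2:
            raise FormatError(
                f"{path}: GCT declares {n_samples} samples but header has "
                f"{body.shape[1] - 2} sample columns"
            )
        if body.shape[0] != n_genes:
            raise FormatError(
                f"{path}: GCT declares {n_genes} genes but body has {body.shape[0]} rows"
            )
        description = pd.Series(
            body.iloc[:, 1].to_numpy(), index=body.iloc[:, 0].str.upper().to_numpy()
        )
        frame = body.set_index(body.columns[0]).drop(columns=body.columns[1])
    else:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        description = None
    frame.index = [_norm_symbol(str(g)) for g in frame.index]
    frame = _check_numeric(frame, path, drop_na_genes)
    frame = _collapse_duplicate_genes(frame)
    return ExpressionDataset(frame, description=description)


def write_expression(dataset: ExpressionDataset, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        dataset.values.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")
    elif format == "gct":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("#1.2\n")
            fh.write(f"{dataset.n_genes}\t{dataset.n_samples}\n")
            fh.write("Name\tDescription\t" + "\t".join(dataset.sample_ids) + "\n")
            desc = dataset.description
            for gene, row in dataset.values.iterrows():
                d = str(desc[gene]) if desc is not None and gene in desc.index else "na"
                fh.write(gene + "\t" + d + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
    else:
        raise ValueError(f"unknown expression format {format!r}")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text query gene list, one symbol per line, case-folded,
    de-duplicated keeping first occurrence."""
    seen: dict[str, None] = {}
    with open(path, encoding="utf-8", newline=None) as fh:
        for raw in fh:
            sym = _norm_symbol(raw)
            if sym and not sym.startswith("#"):
                seen.setdefault(sym, None)
    return list(seen)
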