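"""Gene set collections and the binary annotation matrix.

Reads GMT files (the MSigDB interchange format: one set per line,
tab-separated name, description, then gene identifiers) and aligns a
collection against the genes of an expression matrix to build the m x p
binary membership matrix used by the scoring algorithms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = ["GeneSetCollection", "AnnotationMatrix", "read_gmt", "build_annotation"]


@dataclass
class GeneSetCollection:
    """Ordered, named gene sets. Within-set duplicates are removed."""

    sets: dict[str, list[str]]
    source_path: str = ""

    def __len__(self) -> int:
        return len(self.sets)

    def sizes(self) -> dict[str, int]:
        return {name: len(genes) for name, genes in self.sets.items()}


@dataclass
class AnnotationMatrix:
    """Binary m x p membership matrix A over the genes of an expression matrix.

    ``membership[i, j] = 1`` iff gene ``j`` belongs to set ``i``. Row sums
    are the matched set sizes ``l_i``; ``mean_size`` is their arithmetic
    mean over the retained sets. Columns may sum to zero (genes outside
    every set), rows may not (empty sets are dropped on construction).
    """

    membership: np.ndarray
    set_names: list[str]
    gene_ids: list[str] = field(repr=False)

    @property
    def n_sets(self) -> int:
        return self.membership.shape[0]

    @property
    def set_sizes(self) -> np.ndarray:
        return self.membership.sum(axis=1).astype(int)

    @property
    def mean_size(self) -> float:
        return float(self.set_sizes.mean())

    def indices(self, i: int) -> np.ndarray:
        """Column indices of the genes in set ``i``."""
        return np.flatnonzero(self.membership[i])

    def to_mtx(self, path: str | Path) -> None:
        """Export the membership matrix as sparse MatrixMarket (debugging aid)."""
        spio.mmwrite(str(path), sparse.coo_matrix(self.membership))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file into an ordered collection.

    Each line must have at least three tab-separated fields: set name,
    description (ignored) and one or more gene identifiers. Blank gene
    fields are skipped, duplicate genes within a line are removed
    (first occurrence kept). Malformed lines raise with the line number.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                g = g.strip()
                if g and g not in seen:
                    genes.append(g)
                    seen.add(g)
            sets[name] = genes
    return GeneSetCollection(sets=sets, source_path=str(path))


def build_annotation(
    collection: GeneSetCollection,
    gene_ids: list[str],
    min_size: int = 5,
    max_size: int | None = None,
) -> AnnotationMatrix:
    """Align a collection to ``gene_ids`` and build the membership matrix.

    Genes absent from ``gene_ids`` are dropped from each set (exact,
    case-sensitive string match). Sets whose matched size falls outside
    ``[min_size, max_size]`` are dropped with a logged count. Raises if no
    set survives.
    """
    col_of = {g: j for j, g in enumerate(gene_ids)}
    rows: list[np.ndarray] = []
    names: list[str] = []
    n_dropped = 0
    upper = np.inf if max_size is None else max_size
    for name, genes in collection.sets.items():
        idx = [col_of[g] for g in genes if g in col_of]
        if not (min_size <= len(idx) <= upper):
            n_dropped += 1
            continue
        row = np.zeros(len(gene_ids), dtype=np.int8)
        row[idx] = 1
        rows.append(row)
        names.append(name)
    if n_dropped:
        logger.warning(
            "dropped %d of %d gene sets with matched size outside [%s, %s]",
            n_dropped, len(collection.sets), min_size, upper,
        )
    if not rows:
        raise ValueError(
            f"no gene set has matched size within [{min_size}, {upper}] "
            f"against the {len(gene_ids)} provided genes"
        )
    return AnnotationMatrix(
        membership=np.vstack(rows), set_names=names, gene_ids=list(gene_ids)
    )
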