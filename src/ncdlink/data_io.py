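"""Association-table I/O, cleaning rules, and synthetic data generation.

The central container is :class:`AssociationDataset`: an indexed set of
verified (ncRNA, drug) pairs with entity vocabularies. ncRNAs play the role
of users and drugs the role of items in a bipartite interaction graph; the
dense view ``R`` is the m x n binary correlation matrix.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np


class ParseError(ValueError):
    """Raised when an association table cannot be parsed."""


@dataclass(frozen=True)
class AssociationRecord:
    """One verified (ncRNA, drug-resistance) pair."""

    ncrna_id: str
    drug_id: str

    def __post_init__(self) -> None:
        if not self.ncrna_id or not self.drug_id:
            raise ValueError("ncRNA and drug labels must be non-empty")


@dataclass
class AssociationDataset:
    """Indexed set of verified ncRNA-drug pairs.

    Parameters
    ----------
    ncrnas : list of str
        Ordered unique ncRNA labels (first-appearance order). Size ``m``.
    drugs : list of str
        Ordered unique drug labels. Size ``n``.
    pairs : set of (int, int)
        Index pairs ``(i, j)`` meaning ncRNA ``i`` is associated with drug
        ``j`` (entry ``R[i, j] = 1``).
    """

    ncrnas: list[str]
    drugs: list[str]
    pairs: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(set(self.ncrnas)) != len(self.ncrnas):
            raise ValueError("duplicate ncRNA labels")
        if len(set(self.drugs)) != len(self.drugs):
            raise ValueError("duplicate drug labels")
        if self.m < 1 or self.n < 1:
            raise ValueError("dataset must have at least one ncRNA and one drug")
        for i, j in self.pairs:
            if not (0 <= i < self.m and 0 <= j < self.n):
                raise ValueError(f"pair index ({i}, {j}) out of range for "
                                 f"{self.m} ncRNAs x {self.n} drugs")

    @property
    def m(self) -> int:
        return len(self.ncrnas)

    @property
    def n(self) -> int:
        return len(self.drugs)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def to_dense(self) -> np.ndarray:
        """Dense m x n binary correlation matrix R."""
        R = np.zeros((self.m, self.n), dtype=np.float64)
        for i, j in self.pairs:
            R[i, j] = 1.0
        return R

    def drugs_of(self, i: int) -> set[int]:
        """Indices of drugs linked to ncRNA ``i`` (the positive set V_i+)."""
        return {j for a, j in self.pairs if a == i}

    def ncrnas_of(self, j: int) -> set[int]:
        """Indices of ncRNAs linked to drug ``j``."""
        return {i for i, b in self.pairs if b == j}

    def ncrna_degrees(self) -> np.ndarray:
        deg = np.zeros(self.m, dtype=np.int64)
        for i, _ in self.pairs:
            deg[i] += 1
        return deg

    def records(self) -> list[AssociationRecord]:
        """Pairs as labelled records, sorted by index for reproducibility."""
        return [AssociationRecord(self.ncrnas[i], self.drugs[j])
                for i, j in sorted(self.pairs)]

    def subset(self, pairs: Iterable[tuple[int, int]]) -> "AssociationDataset":
        """Same vocabularies, restricted pair set (used for CV folds)."""
        return AssociationDataset(list(self.ncrnas), list(self.drugs), set(pairs))


def _detect_delimiter(sample: str) -> str:
    # prefer tab when both appear: canonical format is TSV
    if "\t" in sample:
        return "\t"
    if "," in sample:
        return ","
    return "\t"


def read_associations(
    path: str | Path,
    columns: tuple[int, int] | tuple[str, str] = (0, 1),
    delimiter: str | None = None,
) -> AssociationDataset:
    """Read an association table into an :class:`AssociationDataset`.

    Parameters
    ----------
    path : path
        TSV or CSV file. Delimiter is auto-detected from {tab, comma}
        unless ``delimiter`` is given.
    columns : pair of int or pair of str
        ncRNA and drug columns, by zero-based position (headerless file)
        or by header name (first row is then consumed as the header).

    Entity order is first-appearance order; duplicate rows collapse to a
    single pair, so re-reading the same file always yields the same indexing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"association table not found: {path}")
    text = path.read_text()
    lines = [ln for ln in text.splitlines()]
    if not any(ln.strip() for ln in lines):
        raise ParseError(f"no associations in {path}")
    delim = delimiter or _detect_delimiter(lines[0])

    by_name = isinstance(columns[0], str)
    reader = csv.reader(io.StringIO(text), delimiter=delim)
    rows = list(reader)
    start = 0
    if by_name:
        header = [h.strip() for h in rows[0]]
        try:
            ci, cj = header.index(columns[0]), header.index(columns[1])
        except ValueError as exc:
            raise ParseError(f"column not found in header {header}: {exc}") from exc
        start = 1
    else:
        ci, cj = int(columns[0]), int(columns[1])

    ncrnas: list[str] = []
    drugs: list[str] = []
    nc_idx: dict[str, int] = {}
    dr_idx: dict[str, int] = {}
    pairs: set[tuple[int, int]] = set()
    for lineno, row in enumerate(rows[start:], start=start + 1):
        if not row or not any(f.strip() for f in row):
            continue
        if len(row) <= max(ci, cj):
            raise ParseError(f"line {lineno}: expected at least "
                             f"{max(ci, cj) + 1} fields, got {len(row)}")
        u, v = row[ci].strip(), row[cj].strip()
        if not u or not v:
            raise ParseError(f"line {lineno}: empty label")
        if u not in nc_idx:
            nc_idx[u] = len(ncrnas)
            ncrnas.append(u)
        if v not in dr_idx:
            dr_idx[v] = len(drugs)
            drugs.append(v)
        pairs.add((nc_idx[u], dr_idx[v]))
    if not pairs:
        raise ParseError(f"no associations in {path}")
    return AssociationDataset(ncrnas, drugs, pairs)


def write_associations(ds: AssociationDataset, path: str | Path) -> None:
    """Write the canonical two-column TSV ``ncrna_id<TAB>drug_id``."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in ds.records():
            fh.write(f"{rec.ncrna_id}\t{rec.drug_id}\n")


def write_vocabularies(ds: AssociationDataset, outdir: str | Path) -> None:
    """Write ``ncrnas.txt`` and ``drugs.txt``, one label per line in index order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "ncrnas.txt").write_text("".join(f"{u}\n" for u in ds.ncrnas))
    (outdir / "drugs.txt").write_text("".join(f"{v}\n" for v in ds.drugs))


def clean_dataset(
    ds: AssociationDataset,
    min_degree: int = 2,
    iterate: bool = False,
) -> AssociationDataset:
    """Drop ncRNAs with fewer than ``min_degree`` associated drugs.

    A single pass: ncRNA degrees are computed once, sub-threshold ncRNAs are
    removed together with their pairs, and drugs left with no pairs are
    dropped. With ``iterate=True`` the pass repeats until no ncRNA falls
    below the threshold (removing drugs never lowers an ncRNA degree, so
    this converges; it matters only when ``min_degree`` interacts with a
    prior drug-side filter).

    The default ``min_degree=2`` removes ncRNAs bound to a single drug
    resistance, the cleaning rule used to assemble the reference dataset.
    """
    if min_degree < 1:
        raise ValueError("min_degree must be >= 1")

    def one_pass(d: AssociationDataset) -> AssociationDataset:
        deg = d.ncrna_degrees()
        keep_nc = [i for i in range(d.m) if deg[i] >= min_degree]
        kept_pairs = [(i, j) for i, j in d.pairs if deg[i] >= min_degree]
        keep_dr = sorted({j for _, j in kept_pairs})
        if not kept_pairs:
            raise ValueError("cleaning removed all associations")
        nc_map = {old: new for new, old in enumerate(keep_nc)}
        dr_map = {old: new for new, old in enumerate(keep_dr)}
        return AssociationDataset(
            [d.ncrnas[i] for i in keep_nc],
            [d.drugs[j] for j in keep_dr],
            {(nc_map[i], dr_map[j]) for i, j in kept_pairs},
        )

    out = one_pass(ds)
    if iterate:
        while True:
            nxt = one_pass(out)
            if nxt.n_pairs == out.n_pairs and nxt.m == out.m and nxt.n == out.n:
                break
            out = nxt
    return out


class SyntheticData(NamedTuple):
    """A planted-structure dataset plus held-out evaluation pairs."""

    dataset: AssociationDataset
    heldout_pos: list[tuple[int, int]]
    heldout_neg: list[tuple[int, int]]
    ncrna_blocks: np.ndarray
    drug_blocks: np.ndarray


def generate_synthetic(
    m: int = 100,
    n: int = 30,
    k_blocks: int = 2,
    density_in: float = 0.5,
    density_out: float = 0.02,
    seed: int = 0,
    holdout_fraction: float = 0.1,
) -> SyntheticData:
    """Generate a bipartite association table with planted block structure.

    ncRNAs and drugs are each partitioned into ``k_blocks`` contiguous
    groups; a pair is sampled as positive with probability ``density_in``
    when the groups match and ``density_out`` otherwise. A fraction of the
    positives is held out, together with an equal number of sampled
    non-positive pairs, for link-prediction evaluation.

    The planted low-rank structure mimics the community organization of
    curated ncRNA-drug resistance networks (groups of ncRNAs co-associated
    with groups of drugs) while leaving cross-group noise edges.
    """
    if k_blocks > min(m, n):
        raise ValueError("k_blocks must be <= min(m, n)")
    if not (0.0 <= density_out < density_in <= 1.0):
        raise ValueError("require 0 <= density_out < density_in <= 1")
    rng = np.random.default_rng(seed)
    nc_blocks = np.array([i * k_blocks // m for i in range(m)])
    dr_blocks = np.array([j * k_blocks // n for j in range(n)])

    prob = np.where(nc_blocks[:, None] == dr_blocks[None, :], density_in, density_out)
    R = rng.random((m, n)) < prob
    pos = [(i, j) for i in range(m) for j in range(n) if R[i, j]]
    if not pos:
        raise ValueError("parameters produced an empty positive set")

    n_hold = int(round(holdout_fraction * len(pos)))
    order = rng.permutation(len(pos))
    heldout_pos = [pos[t] for t in order[:n_hold]]
    train_pos = {pos[t] for t in order[n_hold:]}
    if not train_pos:
        raise ValueError("holdout_fraction left no training positives")

    all_pos = set(pos)
    negatives = [(i, j) for i in range(m) for j in range(n) if (i, j) not in all_pos]
    if len(negatives) < n_hold:
        raise ValueError("not enough unverified pairs for held-out negatives")
    neg_order = rng.permutation(len(negatives))
    heldout_neg = [negatives[t] for t in neg_order[:n_hold]]

    ncrnas = [f"ncRNA_{i:04d}" for i in range(m)]
    drugs = [f"drug_{j:03d}" for j in range(n)]
    ds = AssociationDataset(ncrnas, drugs, train_pos)
    return SyntheticData(ds, heldout_pos, heldout_neg, nc_blocks, dr_blocks)
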