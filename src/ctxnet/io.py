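"""Domain containers and readers/writers for the formats the pipeline touches.

Expression comes in as a tab-separated table, genes (or gene sets) in rows and
samples in columns, either continuous or already quantized to the three-state
alphabet UP / DOWN / NOCHANGE. Gene sets use the GMT format, sample condition
labels a two-column TSV, and networks go out as edge-list TSV or GraphML.

Internally the three states are coded as signed integers: UP = +1, DOWN = -1,
NOCHANGE = 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "UP",
    "DOWN",
    "NOCHANGE",
    "TrinaryMatrix",
    "GeneSetCollection",
    "ConditionTable",
    "read_expression",
    "read_gmt",
    "read_conditions",
    "quantize_log_ratio",
    "quantize_zscore",
]

UP: int = 1
DOWN: int = -1
NOCHANGE: int = 0

STATE_TO_TOKEN = {UP: "UP", DOWN: "DOWN", NOCHANGE: "NOCHANGE"}
TOKEN_TO_STATE = {v: k for k, v in STATE_TO_TOKEN.items()}


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


class TrinaryMatrix:
    """A genes-or-gene-sets × samples matrix over {UP, DOWN, NOCHANGE}.

    Parameters
    ----------
    values
        Integer array of shape ``(len(row_ids), len(sample_ids))`` with
        entries in {-1, 0, +1}.
    row_ids, sample_ids
        Unique identifiers for rows and columns, order preserved.
    """

    def __init__(
        self,
        values: np.ndarray,
        row_ids: Sequence[str],
        sample_ids: Sequence[str],
    ) -> None:
        values = np.asarray(values, dtype=np.int8)
        if values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        if values.shape != (len(row_ids), len(sample_ids)):
            raise ValueError(
                f"shape {values.shape} does not match "
                f"{len(row_ids)} rows x {len(sample_ids)} samples"
            )
        bad = ~np.isin(values, (-1, 0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"entry ({row_ids[r]!r}, {sample_ids[c]!r}) is not one of "
                "UP/DOWN/NOCHANGE"
            )
        _check_unique(row_ids, "row")
        _check_unique(sample_ids, "sample")
        self.values = values
        self.row_ids = list(row_ids)
        self.sample_ids = list(sample_ids)
        self._row_index = {r: i for i, r in enumerate(self.row_ids)}
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row_index(self, row_id: str) -> int:
        try:
            return self._row_index[row_id]
        except KeyError:
            raise KeyError(f"unknown row identifier: {row_id!r}") from None

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sample_index[sample_id]
        except KeyError:
            raise KeyError(f"unknown sample identifier: {sample_id!r}") from None

    def __getitem__(self, key: tuple[str, str]) -> int:
        row, sample = key
        return int(self.values[self.row_index(row), self.sample_index(sample)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrinaryMatrix):
            return NotImplemented
        return (
            self.row_ids == other.row_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"TrinaryMatrix({len(self.row_ids)} rows x {len(self.sample_ids)} samples)"

    # -- subsetting ----------------------------------------------------------
    def select_rows(self, row_ids: Sequence[str]) -> "TrinaryMatrix":
        idx = [self.row_index(r) for r in row_ids]
        return TrinaryMatrix(self.values[idx, :], list(row_ids), self.sample_ids)

    def select_samples(self, sample_ids: Sequence[str]) -> "TrinaryMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return TrinaryMatrix(self.values[:, idx], self.row_ids, list(sample_ids))

    def drop_samples(self, sample_ids: Iterable[str]) -> "TrinaryMatrix":
        drop = set(sample_ids)
        keep = [s for s in self.sample_ids if s not in drop]
        return self.select_samples(keep)

    # -- conversion and serialization ----------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Token (string) representation as a DataFrame."""
        tokens = np.vectorize(STATE_TO_TOKEN.__getitem__)(self.values)
        return pd.DataFrame(tokens, index=self.row_ids, columns=self.sample_ids)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrinaryMatrix":
        """Build from a DataFrame of state tokens (case-insensitive)."""
        values = np.empty(df.shape, dtype=np.int8)
        raw = df.to_numpy()
        for i in range(df.shape[0]):
            for j in range(df.shape[1]):
                tok = str(raw[i, j]).strip().upper()
                if tok not in TOKEN_TO_STATE:
                    raise ValueError(
                        f"unknown state token {raw[i, j]!r} at row "
                        f"{df.index[i]!r}, column {df.columns[j]!r}"
                    )
                values[i, j] = TOKEN_TO_STATE[tok]
        return cls(values, [str(r) for r in df.index], [str(c) for c in df.columns])


@dataclass
class GeneSetCollection:
    """Named, non-empty sets of gene identifiers.

    A gene may belong to several sets; set names are unique. ``directions``
    optionally tags a set as over- ("UP") or under-expressed ("DOWN") in its
    defining context.
    """

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)
    directions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(members)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def add(self, name: str, members: Iterable[str], description: str = "") -> None:
        if name in self.sets:
            raise ValueError(f"duplicate gene set name: {name!r}")
        members = list(members)
        if len(set(members)) < len(members):
            logger.warning("gene set %r contains duplicated members; storing unique", name)
        if not members:
            raise ValueError(f"gene set {name!r} has no members")
        self.sets[name] = frozenset(members)
        self.descriptions[name] = description

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                desc = self.descriptions.get(name, "")
                fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


@dataclass
class ConditionTable:
    """Sample condition assignments over a sample universe.

    Each condition label maps to a proper, non-empty subset of the universe;
    conditions may overlap (the same sample can carry a subtype label and a
    mutation label at once).
    """

    assignments: dict[str, list[str]]
    universe: list[str]

    def __post_init__(self) -> None:
        _check_unique(self.universe, "universe sample")
        uni = set(self.universe)
        for label, samples in self.assignments.items():
            if len(set(samples)) < len(samples):
                raise ValueError(f"condition {label!r} lists a sample twice")
            extra = set(samples) - uni
            if extra:
                raise ValueError(
                    f"condition {label!r} references samples outside the "
                    f"universe: {sorted(extra)}"
                )
            if not samples:
                raise ValueError(f"condition {label!r} has no samples")
            if len(samples) >= len(self.universe):
                raise ValueError(
                    f"condition {label!r} covers every sample; the leave-out "
                    "set would be empty"
                )

    @property
    def labels(self) -> list[str]:
        return list(self.assignments)

    def samples_of(self, label: str) -> list[str]:
        return list(self.assignments[label])

    def complement_of(self, label: str) -> list[str]:
        inside = set(self.assignments[label])
        return [s for s in self.universe if s not in inside]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tcondition\n")
            for label, samples in self.assignments.items():
                for s in samples:
                    fh.write(f"{s}\t{label}\n")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    # pandas mangles duplicate column names on read; detect from the raw header
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split("\t")[1:]
                break
        else:  # pragma: no cover
            raise ValueError(f"{path}: empty file")
    _check_unique(header, "sample")
    _check_unique([str(r) for r in df.index], "row")
    df.columns = header
    return df


def read_expression(path: str | Path, dialect: str = "continuous"):
    """Read an expression table.

    ``dialect="trinary"`` validates the three-state alphabet and returns a
    :class:`TrinaryMatrix`; ``dialect="continuous"`` returns a float
    DataFrame for the quantization functions.
    """
    if dialect not in ("continuous", "trinary"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    df = _read_table(path)
    if dialect == "trinary":
        return TrinaryMatrix.from_frame(df)
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    values = df.to_numpy()
    numeric = np.empty(df.shape, dtype=float)
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            try:
                numeric[i, j] = float(values[i, j])
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric value {values[i, j]!r} at row "
                    f"{df.index[i]!r}, column {df.columns[j]!r}"
                ) from None
            if not np.isfinite(numeric[i, j]):
                raise ValueError(
                    f"non-finite value {values[i, j]!r} at row "
                    f"{df.index[i]!r}, column {df.columns[j]!r}"
                )
    out.loc[:, :] = numeric
    return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name, description, then tab-separated members."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    "at least one member"
                )
            name, desc, *members = fields
            members = [m for m in members if m.strip()]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            try:
                coll.add(name, members, desc)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return coll


def read_conditions(path: str | Path, universe: Sequence[str] | None = None) -> ConditionTable:
    """Read a sample→condition TSV (columns ``sample`` and ``condition``).

    One row per sample-condition pair. If ``universe`` is omitted it defaults
    to the unique samples appearing in the file, in file order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = [c.lower() for c in df.columns]
    if cols[:2] != ["sample", "condition"]:
        raise ValueError(
            f"{path}: expected header columns 'sample' and 'condition', "
            f"got {list(df.columns)!r}"
        )
    assignments: dict[str, list[str]] = {}
    order: list[str] = []
    seen_samples: list[str] = []
    for sample, condition in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if condition not in assignments:
            assignments[condition] = []
            order.append(condition)
        assignments[condition].append(sample)
        if sample not in seen_samples:
            seen_samples.append(sample)
    if universe is None:
        universe = seen_samples
    return ConditionTable({k: assignments[k] for k in order}, list(universe))


# ---------------------------------------------------------------------------
# Quantization
# ---------------------------------------------------------------------------

def quantize_log_ratio(expr: pd.DataFrame, fold: float = 2.0) -> TrinaryMatrix:
    """Quantize tumor/baseline expression ratios with a fold-change threshold.

    Ratios at or above ``fold`` become UP, at or below ``1/fold`` DOWN, and
    NOCHANGE otherwise (the boundary is inclusive). Default two-fold.
    """
    if fold <= 1:
        raise ValueError("fold threshold must exceed 1")
    values = expr.to_numpy(dtype=float)
    if (values <= 0).any():
        i, j = np.argwhere(values <= 0)[0]
        raise ValueError(
            f"non-positive ratio at row {expr.index[i]!r}, "
            f"column {expr.columns[j]!r}; ratios must be > 0"
        )
    out = np.zeros(values.shape, dtype=np.int8)
    out[values >= fold] = UP
    out[values <= 1.0 / fold] = DOWN
    return TrinaryMatrix(out, [str(r) for r in expr.index], [str(c) for c in expr.columns])


def quantize_zscore(
    expr: pd.DataFrame,
    reference_samples: Sequence[str],
    sd_threshold: float = 1.0,
) -> TrinaryMatrix:
    """Quantize expression by z-score against reference samples, per gene.

    z strictly above ``sd_threshold`` is UP, strictly below the negative
    threshold DOWN, otherwise NOCHANGE (the boundary is exclusive). A gene
    with zero reference standard deviation is set to NOCHANGE everywhere,
    with a warning.
    """
    if sd_threshold <= 0:
        raise ValueError("sd_threshold must be positive")
    missing = [s for s in reference_samples if s not in expr.columns]
    if missing:
        raise ValueError(f"reference samples not in matrix: {missing}")
    if len(reference_samples) < 2:
        raise ValueError("need at least 2 reference samples")
    ref = expr.loc[:, list(reference_samples)].to_numpy(dtype=float)
    mean = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    values = expr.to_numpy(dtype=float)
    out = np.zeros(values.shape, dtype=np.int8)
    zero_sd = sd == 0
    if zero_sd.any():
        names = [str(expr.index[i]) for i in np.flatnonzero(zero_sd)]
        warnings.warn(
            f"zero reference SD for {len(names)} gene(s) "
            f"({', '.join(names[:5])}{'...' if len(names) > 5 else ''}); "
            "set to NOCHANGE",
            stacklevel=2,
        )
    ok = ~zero_sd
    z = np.zeros_like(values)
    z[ok, :] = (values[ok, :] - mean[ok, None]) / sd[ok, None]
    out[z > sd_threshold] = UP
    out[z < -sd_threshold] = DOWN
    out[zero_sd, :] = NOCHANGE
    return TrinaryMatrix(out, [str(r) for r in expr.index], [str(c) for c in expr.columns])
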