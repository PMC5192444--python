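"""Declarative Y-block coding for designed experiments.

A :class:`CodingScheme` translates per-sample factor levels into a structured
target matrix ``Y`` for multi-response PLS.  Each experimental factor occupies
one *block* of contiguous Y columns:

* a **categorical** block is a one-of-k sub-matrix whose "off"/"on" values are
  configurable (classical PLS-DA uses 0/1, but any pair works and can be used
  to balance block variances);
* an **ordinal** block is a single column holding one coded real value per
  level (e.g. dosages 0, 0.2, 0.4, 0.6 mg/mL coded as 0, 2, 4, 6).

The inverse operation, *crisping*, maps a raw real-valued predicted Y row back
to one level per block: arg-max within a categorical block, nearest coded
value for an ordinal block.  The per-sample prediction error is the number of
misassigned blocks (Hamming distance on label tuples), giving the error set
{0, 1, ..., B} for B blocks.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

CATEGORICAL = "categorical"
ORDINAL = "ordinal"

__all__ = [
    "FactorBlock",
    "CodingScheme",
    "block_errors",
    "VarianceBalance",
    "variance_balance",
    "load_scheme",
    "packaged_scheme",
]


@dataclass(frozen=True)
class FactorBlock:
    """One experimental factor and how its levels are coded in Y.

    Parameters
    ----------
    name
        Factor label (e.g. ``"strain"``).
    kind
        ``"categorical"`` or ``"ordinal"``.
    levels
        Ordered level labels; order fixes the column order (categorical) or
        the code order (ordinal).
    codes
        For a categorical block, the ``(off, on)`` pair written into its
        one-of-k sub-matrix.  For an ordinal block, one real coded value per
        level, strictly monotone in level order.
    """

    name: str
    kind: str
    levels: tuple[str, ...]
    codes: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(str(v) for v in self.levels))
        object.__setattr__(self, "codes", tuple(float(c) for c in self.codes))
        if not self.levels:
            raise ValueError(f"block {self.name!r}: levels must be non-empty")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"block {self.name!r}: levels must be unique")
        if self.kind == CATEGORICAL:
            if len(self.codes) != 2:
                raise ValueError(
                    f"block {self.name!r}: categorical codes must be an (off, on) pair"
                )
            if self.codes[0] == self.codes[1]:
                raise ValueError(f"block {self.name!r}: off and on codes must differ")
        elif self.kind == ORDINAL:
            if len(self.codes) != len(self.levels):
                raise ValueError(
                    f"block {self.name!r}: ordinal needs one code per level"
                )
            diffs = np.diff(self.codes)
            if not (np.all(diffs > 0) or np.all(diffs < 0)):
                raise ValueError(
                    f"block {self.name!r}: ordinal codes must be strictly monotone"
                )
        else:
            raise ValueError(f"block {self.name!r}: unknown kind {self.kind!r}")

    @property
    def width(self) -> int:
        """Number of Y columns this block occupies."""
        return len(self.levels) if self.kind == CATEGORICAL else 1

    def level_index(self, level: str) -> int:
        try:
            return self.levels.index(str(level))
        except ValueError:
            raise KeyError(
                f"unknown level {level!r} for block {self.name!r}; "
                f"expected one of {list(self.levels)}"
            ) from None

    def encode(self, level: str) -> np.ndarray:
        """Code one level as this block's Y sub-row."""
        i = self.level_index(level)
        if self.kind == CATEGORICAL:
            off, on = self.codes
            row = np.full(self.width, off, dtype=float)
            row[i] = on
            return row
        return np.array([self.codes[i]], dtype=float)

    def crisp(self, values: np.ndarray) -> str:
        """Assign a level to a raw predicted sub-row.

        Categorical: the level of the largest column (ties -> lowest level
        index).  Ordinal: the level whose code is nearest in absolute
        difference (exact midpoint ties -> the lower coded level).
        """
        values = np.asarray(values, dtype=float)
        if values.shape != (self.width,):
            raise ValueError(
                f"block {self.name!r}: expected {self.width} values, got {values.shape}"
            )
        if self.kind == CATEGORICAL:
            return self.levels[int(np.argmax(values))]
        dist = np.abs(np.asarray(self.codes) - values[0])
        tied = np.flatnonzero(dist == dist.min())
        # among exact ties, take the smaller coded value
        best = tied[int(np.argmin(np.asarray(self.codes)[tied]))]
        return self.levels[int(best)]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "type": self.kind,
            "levels": list(self.levels),
            "codes": list(self.codes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FactorBlock":
        return cls(
            name=d["name"],
            kind=d.get("type", d.get("kind")),
            levels=tuple(d["levels"]),
            codes=tuple(d["codes"]),
        )


@dataclass(frozen=True)
class CodingScheme:
    """Ordered collection of factor blocks defining the Y matrix layout."""

    blocks: tuple[FactorBlock, ...]
    _ranges: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if not self.blocks:
            raise ValueError("scheme needs at least one block")
        names = [b.name for b in self.blocks]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate block names in {names}")
        ranges: dict[str, tuple[int, int]] = {}
        start = 0
        for b in self.blocks:
            ranges[b.name] = (start, start + b.width)
            start += b.width
        object.__setattr__(self, "_ranges", ranges)

    @property
    def width(self) -> int:
        return sum(b.width for b in self.blocks)

    @property
    def block_names(self) -> list[str]:
        return [b.name for b in self.blocks]

    def block(self, name: str) -> FactorBlock:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(f"no block named {name!r}; have {self.block_names}")

    def column_range(self, name: str) -> tuple[int, int]:
        """Half-open column interval of one block within Y."""
        if name not in self._ranges:
            raise KeyError(f"no block named {name!r}; have {self.block_names}")
        return self._ranges[name]

    # -- encoding ---------------------------------------------------------

    def encode_sample(self, labels: Sequence[str]) -> np.ndarray:
        """Code one label tuple (one level per block, in block order)."""
        labels = tuple(labels)
        if len(labels) != len(self.blocks):
            raise ValueError(
                f"expected {len(self.blocks)} labels (one per block), got {len(labels)}"
            )
        return np.concatenate(
            [b.encode(lab) for b, lab in zip(self.blocks, labels)]
        )

    def encode_dataset(self, design) -> np.ndarray:
        """Row-wise encoding of a design.

        ``design`` may be a DataFrame holding one column per block (extra
        columns ignored) or any iterable of label tuples.  Row order is
        preserved.
        """
        rows = self._label_rows(design)
        if not rows:
            return np.empty((0, self.width), dtype=float)
        out = np.empty((len(rows), self.width), dtype=float)
        for i, labels in enumerate(rows):
            try:
                out[i] = self.encode_sample(labels)
            except (KeyError, ValueError) as e:
                raise type(e)(f"design row {i}: {e}") from None
        return out

    def _label_rows(self, design) -> list[tuple[str, ...]]:
        if isinstance(design, pd.DataFrame):
            missing = [n for n in self.block_names if n not in design.columns]
            if missing:
                raise ValueError(f"design table lacks factor columns {missing}")
            sub = design[self.block_names].astype(str)
            return [tuple(r) for r in sub.itertuples(index=False, name=None)]
        return [tuple(str(x) for x in row) for row in design]

    # -- crisping ---------------------------------------------------------

    def crisp(self, y_raw: np.ndarray) -> tuple[str, ...]:
        """Decode one raw predicted Y row to a label tuple."""
        y_raw = np.asarray(y_raw, dtype=float).ravel()
        if y_raw.shape != (self.width,):
            raise ValueError(
                f"expected a length-{self.width} prediction, got {y_raw.shape}"
            )
        out = []
        for b in self.blocks:
            lo, hi = self._ranges[b.name]
            out.append(b.crisp(y_raw[lo:hi]))
        return tuple(out)

    def crisp_matrix(self, Y: np.ndarray) -> list[tuple[str, ...]]:
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        return [self.crisp(row) for row in Y]

    def label_space(self) -> Iterable[tuple[str, ...]]:
        """All label tuples expressible under this scheme (full product)."""
        import itertools

        return itertools.product(*(b.levels for b in self.blocks))

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {"blocks": [b.to_dict() for b in self.blocks]}

    @classmethod
    def from_dict(cls, d: dict) -> "CodingScheme":
        return cls(blocks=tuple(FactorBlock.from_dict(b) for b in d["blocks"]))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CodingScheme":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def block_errors(predicted: Sequence[str], truth: Sequence[str]) -> int:
    """Number of misassigned blocks between two label tuples (0..B)."""
    predicted = tuple(predicted)
    truth = tuple(truth)
    if len(predicted) != len(truth):
        raise ValueError(
            f"label tuples differ in length: {len(predicted)} vs {len(truth)}"
        )
    return sum(p != t for p, t in zip(predicted, truth))


@dataclass(frozen=True)
class VarianceBalance:
    """Per-block variance diagnostics of an encoded design."""

    total_variance: dict[str, float]  # sum of column variances per block
    mean_variance: dict[str, float]  # total / block width
    ratio: float  # max/min of mean column variance
    warn: bool
    threshold: float


def variance_balance(
    scheme: CodingScheme, design, threshold: float = 4.0
) -> VarianceBalance:
    """Check that blocks contribute comparable variance to Y.

    PLS minimises squared error over all Y columns jointly, so a block whose
    coded columns carry much more variance than the others dominates the fit.
    The diagnostic reports, per block, the total and the per-column mean of
    the column variances of the encoded design, and flags the scheme when the
    max/min ratio of per-column mean variances exceeds ``threshold``.  The
    per-column mean is used for the ratio so that a wide one-of-k block is not
    penalised merely for having more columns than a one-column ordinal block.
    """
    Y = scheme.encode_dataset(design)
    if Y.shape[0] < 2:
        raise ValueError("variance undefined for designs with fewer than 2 samples")
    col_var = Y.var(axis=0, ddof=1)
    total: dict[str, float] = {}
    mean: dict[str, float] = {}
    for b in scheme.blocks:
        lo, hi = scheme.column_range(b.name)
        total[b.name] = float(col_var[lo:hi].sum())
        mean[b.name] = float(col_var[lo:hi].mean())
    vals = np.array(list(mean.values()))
    if vals.min() <= 0:
        ratio = float("inf")
    else:
        ratio = float(vals.max() / vals.min())
    return VarianceBalance(
        total_variance=total,
        mean_variance=mean,
        ratio=ratio,
        warn=bool(ratio > threshold),
        threshold=float(threshold),
    )


def load_scheme(path) -> CodingScheme:
    """Read a coding scheme from a YAML file."""
    return CodingScheme.from_yaml(path)


def packaged_scheme(name: str) -> CodingScheme:
    """Load one of the shipped coding schemes.

    Available: ``riboswitch`` (two 0/1 one-of-k blocks: 5 strains x 4 inducer
    conditions), ``propranolol`` (0/6 strain block, dosage codes 0/2/4/6,
    time codes 0/1/6), ``propranolol_even_time`` (time codes 0/3/6).
    """
    ref = importlib.resources.files("structpls") / "schemes" / f"{name}.yaml"
    if not ref.is_file():
        raise KeyError(f"no packaged scheme named {name!r}")
    with importlib.resources.as_file(ref) as p:
        return CodingScheme.from_yaml(p)
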