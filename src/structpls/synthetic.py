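"""Synthetic factorial-design feature tables with known ground truth.

Emulates an omics peak table (samples x features) produced under a factorial
design: each factor shifts a random subset of "affected" features, either by
level-specific offsets (categorical factors) or linearly in a standardised
ordinal code (dose-response style), optionally with a pairwise interaction,
plus i.i.d. Gaussian noise.  The generator records which features each factor
touched, so recovery of effects, classification rates and VIP rankings can be
checked against ground truth.

Two presets mirror the shapes of typical designed metabolomics studies: a
complete 5x4 two-factor layout with three biological replicates (60 samples),
and an incomplete 3 strains x 4 dosages x 3 time-points layout in which the
pre-exposure time point exists only for control dosage.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FactorEffect",
    "Interaction",
    "EffectSpec",
    "SyntheticDataset",
    "generate",
    "riboswitch_like",
    "propranolol_like",
    "knn_impute",
]

CATEGORICAL_SHIFT = "categorical-shift"
LINEAR_IN_CODE = "linear-in-code"


@dataclass(frozen=True)
class FactorEffect:
    """One design factor and the effect it plants in the feature table.

    ``effect_size`` is in units of the noise standard deviation: for a
    categorical-shift factor each affected feature gets an independent
    N(0, effect_size^2) offset per level; for a linear-in-code factor each
    affected feature gets slope ~ N(0, effect_size^2) per standardised code
    unit (codes are centred and scaled to unit variance across levels before
    multiplying).
    """

    name: str
    levels: tuple[str, ...]
    effect_type: str = CATEGORICAL_SHIFT
    effect_size: float = 1.0
    affected_fraction: float = 0.2
    codes: tuple[float, ...] | None = None  # required for linear-in-code

    def __post_init__(self):
        object.__setattr__(self, "levels", tuple(str(v) for v in self.levels))
        if not self.levels or len(set(self.levels)) != len(self.levels):
            raise ValueError(f"factor {self.name!r}: levels must be non-empty, unique")
        if self.effect_type not in (CATEGORICAL_SHIFT, LINEAR_IN_CODE):
            raise ValueError(f"factor {self.name!r}: bad effect_type {self.effect_type!r}")
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ValueError(f"factor {self.name!r}: affected_fraction outside [0, 1]")
        if self.effect_size < 0:
            raise ValueError(f"factor {self.name!r}: effect_size must be >= 0")
        if self.effect_type == LINEAR_IN_CODE:
            if self.codes is None or len(self.codes) != len(self.levels):
                raise ValueError(
                    f"factor {self.name!r}: linear-in-code needs one code per level"
                )
            object.__setattr__(self, "codes", tuple(float(c) for c in self.codes))


@dataclass(frozen=True)
class Interaction:
    """Pairwise interaction: an extra cell-specific shift for a factor pair."""

    factors: tuple[str, str]
    effect_size: float
    affected_fraction: float = 0.1

    def __post_init__(self):
        if len(self.factors) != 2 or self.factors[0] == self.factors[1]:
            raise ValueError("interaction needs two distinct factor names")
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ValueError("interaction affected_fraction outside [0, 1]")


@dataclass(frozen=True)
class EffectSpec:
    """Full description of a synthetic designed experiment."""

    factors: tuple[FactorEffect, ...]
    n_features: int = 200
    replicates: int = 3
    noise_sd: float = 1.0
    interaction: Interaction | None = None
    cells: tuple[tuple[str, ...], ...] | None = None  # explicit incomplete layout

    def __post_init__(self):
        object.__setattr__(self, "factors", tuple(self.factors))
        if not self.factors:
            raise ValueError("need at least one factor")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_features < 1 or self.replicates < 1:
            raise ValueError("n_features and replicates must be >= 1")
        if self.interaction is not None:
            names = {f.name for f in self.factors}
            if not set(self.interaction.factors) <= names:
                raise ValueError("interaction references unknown factors")
        if self.cells is not None:
            cells = tuple(tuple(str(x) for x in c) for c in self.cells)
            if len(set(cells)) != len(cells):
                raise ValueError("explicit cell list contains duplicates")
            for c in cells:
                if len(c) != len(self.factors):
                    raise ValueError(f"cell {c} does not match the factor count")
                for lev, f in zip(c, self.factors):
                    if lev not in f.levels:
                        raise ValueError(
                            f"cell {c}: {lev!r} is not a level of factor {f.name!r}"
                        )
            object.__setattr__(self, "cells", cells)

    def layout(self) -> tuple[tuple[str, ...], ...]:
        if self.cells is not None:
            return self.cells
        return tuple(itertools.product(*(f.levels for f in self.factors)))

    def to_dict(self) -> dict:
        d = {
            "factors": [
                {
                    "name": f.name,
                    "levels": list(f.levels),
                    "effect_type": f.effect_type,
                    "effect_size": f.effect_size,
                    "affected_fraction": f.affected_fraction,
                    "codes": list(f.codes) if f.codes else None,
                }
                for f in self.factors
            ],
            "n_features": self.n_features,
            "replicates": self.replicates,
            "noise_sd": self.noise_sd,
            "cells": [list(c) for c in self.cells] if self.cells else None,
        }
        if self.interaction is not None:
            d["interaction"] = {
                "factors": list(self.interaction.factors),
                "effect_size": self.interaction.effect_size,
                "affected_fraction": self.interaction.affected_fraction,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EffectSpec":
        factors = tuple(
            FactorEffect(
                name=f["name"],
                levels=tuple(f["levels"]),
                effect_type=f.get("effect_type", CATEGORICAL_SHIFT),
                effect_size=f.get("effect_size", 1.0),
                affected_fraction=f.get("affected_fraction", 0.2),
                codes=tuple(f["codes"]) if f.get("codes") else None,
            )
            for f in d["factors"]
        )
        inter = None
        if d.get("interaction"):
            di = d["interaction"]
            inter = Interaction(
                factors=tuple(di["factors"]),
                effect_size=di["effect_size"],
                affected_fraction=di.get("affected_fraction", 0.1),
            )
        return cls(
            factors=factors,
            n_features=d.get("n_features", 200),
            replicates=d.get("replicates", 3),
            noise_sd=d.get("noise_sd", 1.0),
            interaction=inter,
            cells=tuple(tuple(c) for c in d["cells"]) if d.get("cells") else None,
        )


@dataclass
class SyntheticDataset:
    """Feature table + design table + planted ground truth."""

    features: pd.DataFrame  # samples x features
    design: pd.DataFrame  # sample_id, replicate_id, one column per factor
    truth: dict[str, np.ndarray]  # factor (or "a:b") -> boolean affected mask
    spec: EffectSpec
    seed: int

    def write(self, outdir) -> None:
        """Write features.csv, design.csv and truth.json into a directory."""
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.features.to_csv(outdir / "features.csv", index_label="sample_id")
        self.design.to_csv(outdir / "design.csv", index=False)
        payload = {
            "seed": self.seed,
            "spec": self.spec.to_dict(),
            "affected_features": {
                k: [self.features.columns[j] for j in np.flatnonzero(m)]
                for k, m in self.truth.items()
            },
        }
        with open(outdir / "truth.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def generate(spec: EffectSpec, seed: int) -> SyntheticDataset:
    """Draw one dataset under ``spec``; bit-reproducible from ``seed``."""
    rng = np.random.default_rng(seed)
    cells = spec.layout()
    rows = []
    for ci, cell in enumerate(cells):
        for r in range(1, spec.replicates + 1):
            rows.append((*cell, f"r{r}"))
    n = len(rows)
    m = spec.n_features
    factor_names = [f.name for f in spec.factors]
    design = pd.DataFrame(rows, columns=factor_names + ["replicate_id"])
    design.insert(0, "sample_id", [f"s{i + 1:03d}" for i in range(n)])

    X = np.zeros((n, m))
    truth: dict[str, np.ndarray] = {}
    level_idx = {
        f.name: design[f.name].map({lev: i for i, lev in enumerate(f.levels)}).to_numpy()
        for f in spec.factors
    }
    for f in spec.factors:
        mask = np.zeros(m, dtype=bool)
        n_aff = int(round(f.affected_fraction * m))
        if f.effect_size > 0 and n_aff > 0:
            aff = np.sort(rng.choice(m, size=n_aff, replace=False))
            mask[aff] = True
            if f.effect_type == CATEGORICAL_SHIFT:
                shifts = f.effect_size * rng.standard_normal((len(f.levels), n_aff))
                X[:, aff] += shifts[level_idx[f.name]]
            else:
                codes = np.asarray(f.codes, dtype=float)
                z = (codes - codes.mean()) / codes.std()
                slopes = f.effect_size * rng.standard_normal(n_aff)
                X[:, aff] += np.outer(z[level_idx[f.name]], slopes)
        truth[f.name] = mask

    if spec.interaction is not None and spec.interaction.effect_size > 0:
        ia = spec.interaction
        mask = np.zeros(m, dtype=bool)
        n_aff = int(round(ia.affected_fraction * m))
        if n_aff > 0:
            aff = np.sort(rng.choice(m, size=n_aff, replace=False))
            mask[aff] = True
            fa = next(f for f in spec.factors if f.name == ia.factors[0])
            fb = next(f for f in spec.factors if f.name == ia.factors[1])
            combo = level_idx[fa.name] * len(fb.levels) + level_idx[fb.name]
            shifts = ia.effect_size * rng.standard_normal(
                (len(fa.levels) * len(fb.levels), n_aff)
            )
            X[:, aff] += shifts[combo]
        truth[f"{ia.factors[0]}:{ia.factors[1]}"] = mask

    X += spec.noise_sd * rng.standard_normal((n, m))
    features = pd.DataFrame(
        X,
        index=pd.Index(design["sample_id"], name="sample_id"),
        columns=[f"var_{j + 1:03d}" for j in range(m)],
    )
    return SyntheticDataset(
        features=features, design=design, truth=truth, spec=spec, seed=int(seed)
    )


def riboswitch_like(seed: int) -> SyntheticDataset:
    """Complete 5x4 factorial, 3 replicates per cell (60 samples), 200 features.

    One strong 5-level factor (strain, 2.5 sd shifts) and one weak 4-level
    factor (inducer, 0.8 sd shifts), each touching 20% of the features, with
    unit noise.  A third design column ``batch`` aliases the biological
    replicate index (b1..b3) and carries no effect at all — a built-in
    negative control for classification-rate and permutation-test checks.
    """
    spec = EffectSpec(
        factors=(
            FactorEffect(
                name="strain",
                levels=("wild-type", "PET", "EGFP", "iL3EGFP", "iL3PET"),
                effect_type=CATEGORICAL_SHIFT,
                effect_size=2.5,
                affected_fraction=0.2,
            ),
            FactorEffect(
                name="inducer",
                levels=("no_inducer", "IPTG", "IPTG+PPDA", "PPDA"),
                effect_type=CATEGORICAL_SHIFT,
                effect_size=0.8,
                affected_fraction=0.2,
            ),
        ),
        n_features=200,
        replicates=3,
        noise_sd=1.0,
    )
    ds = generate(spec, seed)
    ds.design["batch"] = "b" + ds.design["replicate_id"].str.lstrip("r")
    ds.truth["batch"] = np.zeros(spec.n_features, dtype=bool)
    return ds


def propranolol_like(seed: int) -> SyntheticDataset:
    """Incomplete 3 strains x 4 dosages x 3 times design, 4 replicates.

    The pre-exposure time point T0 exists only at control dosage D0, giving
    27 populated cells (108 samples).  Dosage and time act linearly in their
    coded values (dose-response gradients); the strain factor shifts
    categorically.  Effect sizes are moderate so the factors are clearly but
    not perfectly recoverable under unit noise.
    """
    strains = ("S1", "S2", "S3")
    dosages = ("D0", "D1", "D2", "D3")
    times = ("T0", "T1", "T2")
    cells = [(s, "D0", "T0") for s in strains]
    cells += [
        (s, d, t) for s in strains for d in dosages for t in ("T1", "T2")
    ]
    spec = EffectSpec(
        factors=(
            FactorEffect(
                name="strain",
                levels=strains,
                effect_type=CATEGORICAL_SHIFT,
                effect_size=2.0,
                affected_fraction=0.2,
            ),
            FactorEffect(
                name="dosage",
                levels=dosages,
                effect_type=LINEAR_IN_CODE,
                effect_size=1.2,
                affected_fraction=0.2,
                codes=(0.0, 2.0, 4.0, 6.0),
            ),
            FactorEffect(
                name="time",
                levels=times,
                effect_type=LINEAR_IN_CODE,
                effect_size=1.0,
                affected_fraction=0.2,
                codes=(0.0, 1.0, 6.0),
            ),
        ),
        n_features=200,
        replicates=4,
        noise_sd=1.0,
        cells=tuple(cells),
    )
    return generate(spec, seed)


def knn_impute(table, k: int):
    """K-nearest-neighbour imputation of missing feature values.

    Each missing cell is replaced by the mean of that feature over the k
    nearest samples (Euclidean distance on mutually observed features,
    rescaled by the fraction observed).  Observed cells are untouched.
    Features with no observed value at all are rejected by name.
    """
    from sklearn.impute import KNNImputer

    if k < 1:
        raise ValueError("k must be >= 1")
    is_df = isinstance(table, pd.DataFrame)
    values = table.to_numpy(dtype=float) if is_df else np.asarray(table, dtype=float)
    if values.ndim != 2:
        raise ValueError("table must be 2-D (samples x features)")
    all_missing = np.flatnonzero(np.isnan(values).all(axis=0))
    if all_missing.size:
        names = (
            [table.columns[j] for j in all_missing]
            if is_df
            else all_missing.tolist()
        )
        raise ValueError(f"feature(s) entirely missing, cannot impute: {names}")
    if not np.isnan(values).any():
        return table.copy() if is_df else values.copy()
    imputer = KNNImputer(n_neighbors=min(k, values.shape[0] - 1), weights="uniform")
    filled = imputer.fit_transform(values)
    if is_df:
        return pd.DataFrame(filled, index=table.index, columns=table.columns)
    return filled
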