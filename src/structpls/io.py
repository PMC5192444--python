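"""Table formats, run configuration and the end-to-end validation pipeline.

Feature tables are CSV/TSV with sample IDs in the first column and variable
names in the header; empty cells are missing values.  Design tables carry
``sample_id``, ``replicate_id`` and one column per experimental factor.  A
run configuration (YAML) points at the three inputs and fixes the iteration
count, LV cap, seed and comparison mode; every output directory contains a
config echo sufficient to reproduce the run exactly.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .coding import CodingScheme, load_scheme, packaged_scheme
from .pls import fit_pls
from .synthetic import knn_impute
from .validation import (
    ValidationReport,
    all_cells_binary,
    double_cv,
    permutation_test,
)
from .vip import vip_table

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_design_table",
    "align_tables",
    "RunConfig",
    "load_run_config",
    "run_validate",
    "run_vip",
]

MODES = ("structured", "all-cells-binary", "per-factor-binary")


def _read_table(path) -> pd.DataFrame:
    path = pathlib.Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_feature_table(path) -> pd.DataFrame:
    """Read a samples x variables numeric table; empty cells become NaN."""
    raw = _read_table(path)
    if raw.shape[1] < 2:
        raise ValueError(f"{path}: expected sample IDs plus at least one variable")
    ids = raw.iloc[:, 0]
    dup = ids[ids.duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate sample IDs {sorted(set(dup))}")
    body = raw.iloc[:, 1:].replace("", np.nan)
    numeric = body.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & body.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {body.iat[r, c]!r} at sample "
            f"{ids.iloc[r]!r}, variable {body.columns[c]!r}"
        )
    numeric.index = pd.Index(ids, name="sample_id")
    return numeric


def write_feature_table(features: pd.DataFrame, path) -> None:
    features.to_csv(path, index_label="sample_id")


def read_design_table(path) -> pd.DataFrame:
    """Read a design table; requires sample_id, keeps all columns as text."""
    df = _read_table(path)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: design table needs a 'sample_id' column")
    dup = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate sample IDs {sorted(set(dup))}")
    return df


def align_tables(
    features: pd.DataFrame, design: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reindex the feature table to the design's sample order (1-1 match)."""
    feat_ids = set(features.index)
    des_ids = set(design["sample_id"])
    only_feat = sorted(feat_ids - des_ids)
    only_des = sorted(des_ids - feat_ids)
    if only_feat or only_des:
        raise ValueError(
            "sample IDs do not match 1-1: "
            f"only in features {only_feat[:10]}, only in design {only_des[:10]}"
        )
    return features.loc[design["sample_id"]], design.reset_index(drop=True)


@dataclass
class RunConfig:
    """Everything needed to reproduce one validation run."""

    features: str
    design: str
    scheme: str  # path to a YAML scheme or the name of a packaged one
    outdir: str
    n_iterations: int = 1000
    max_lv: int | None = None
    seed: int = 0
    permutation: bool = False
    mode: str = "structured"
    impute_k: int = 5
    split_factors: Sequence[str] | None = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    def echo(self) -> dict:
        return {
            "features": str(self.features),
            "design": str(self.design),
            "scheme": str(self.scheme),
            "outdir": str(self.outdir),
            "n_iterations": self.n_iterations,
            "max_lv": self.max_lv,
            "seed": self.seed,
            "permutation": self.permutation,
            "mode": self.mode,
            "impute_k": self.impute_k,
            "split_factors": list(self.split_factors) if self.split_factors else None,
        }


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return RunConfig(**d)


def _load_scheme(ref: str) -> CodingScheme:
    p = pathlib.Path(ref)
    if p.exists():
        return load_scheme(p)
    return packaged_scheme(ref)


def _prepare(config: RunConfig):
    features = read_feature_table(config.features)
    design = read_design_table(config.design)
    features, design = align_tables(features, design)
    if features.isna().to_numpy().any():
        features = knn_impute(features, k=config.impute_k)
    scheme = _load_scheme(config.scheme)
    return features, design, scheme


def run_validate(config: RunConfig) -> ValidationReport:
    """Impute -> encode -> double CV (-> permutation) -> reports on disk."""
    features, design, scheme = _prepare(config)
    X = features.to_numpy(dtype=float)
    split_factors = list(config.split_factors or scheme.block_names)
    outdir = pathlib.Path(config.outdir)

    if config.mode == "per-factor-binary":
        report = _run_per_factor_binary(X, design, scheme, config, split_factors)
    else:
        if config.mode == "all-cells-binary":
            run_scheme, run_design, report_factors = all_cells_binary(scheme, design)
        else:
            run_scheme, run_design, report_factors = scheme, design, None
        report = double_cv(
            X,
            run_design,
            run_scheme,
            n_iterations=config.n_iterations,
            max_lv=config.max_lv,
            rng_seed=config.seed,
            split_factors=split_factors,
            report_factors=report_factors,
            config_echo=config.echo(),
        )
        if config.permutation:
            report.p_values = permutation_test(
                X,
                run_design,
                run_scheme,
                n_iterations=config.n_iterations,
                max_lv=config.max_lv,
                rng_seed=config.seed + 1,
                split_factors=split_factors,
            )
    report.write(outdir)
    return report


def _run_per_factor_binary(X, design, scheme, config, split_factors):
    """One single-block 0/1 PLS-DA run per factor; reports merged."""
    from .coding import CATEGORICAL, FactorBlock

    confusion = {}
    ccr = {}
    p_values = {} if config.permutation else None
    lv_counts: list[int] = []
    for b in scheme.blocks:
        sub = CodingScheme(
            blocks=(
                FactorBlock(
                    name=b.name, kind=CATEGORICAL, levels=b.levels, codes=(0.0, 1.0)
                ),
            )
        )
        rep = double_cv(
            X,
            design,
            sub,
            n_iterations=config.n_iterations,
            max_lv=config.max_lv,
            rng_seed=config.seed,
            split_factors=split_factors,
            config_echo=config.echo(),
        )
        confusion[b.name] = rep.confusion[b.name]
        ccr[b.name] = rep.ccr[b.name]
        lv_counts.extend(rep.lv_counts)
        if config.permutation:
            p_values[b.name] = permutation_test(
                X,
                design,
                sub,
                n_iterations=config.n_iterations,
                max_lv=config.max_lv,
                rng_seed=config.seed + 1,
                split_factors=split_factors,
            )[b.name]
    return ValidationReport(
        confusion=confusion,
        ccr=ccr,
        conditional={},
        p_values=p_values,
        lv_counts=lv_counts,
        n_iterations=config.n_iterations,
        max_lv=max(lv_counts) if lv_counts else 0,
        seed=config.seed,
        config_echo=config.echo(),
    )


def run_vip(
    config: RunConfig, n_components: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Block-summarised VIP scores, written as CSV.

    The model is fitted on all samples.  If ``n_components`` is not given, a
    double-CV pass selects the LV count most frequently chosen across
    iterations.
    """
    features, design, scheme = _prepare(config)
    X = features.to_numpy(dtype=float)
    Y = scheme.encode_dataset(design)
    if n_components is None:
        report = double_cv(
            X,
            design,
            scheme,
            n_iterations=config.n_iterations,
            max_lv=config.max_lv,
            rng_seed=config.seed,
            split_factors=config.split_factors,
        )
        n_components = report.modal_lv()
    model = fit_pls(X, Y, n_components)
    per_col, per_block = vip_table(model, scheme, variable_names=list(features.columns))
    outdir = pathlib.Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    combined = per_col.join(per_block.add_prefix("block:"))
    combined.to_csv(outdir / "vip.csv", index_label="variable")
    with open(outdir / "vip_meta.json", "w") as fh:
        json.dump(
            {"n_components": int(n_components), "config": config.echo()},
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return per_col, per_block
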