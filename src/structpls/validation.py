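"""Replicate-aware double cross-validation for structured-output PLS.

The outer loop repeatedly splits samples into a training set and a blind test
set by holding out one biological replicate from every populated design cell.
On each training set an inner leave-one-out pass picks the number of latent
variables minimising the mean block-misassignment error; the model refitted
on the whole training set then predicts the test set, predictions are crisped
back to factor levels, and per-block confusion matrices are tallied.  Row
percentages are averaged over iterations to give the final confusion
matrices; correct-classification rates (CCRs) and conditional CCRs come from
the pooled tallies.  An accompanying permutation test reruns the identical
pipeline with label tuples permuted across samples and reports, per block,
the fraction of iterations in which the observed test error strictly
exceeded the permuted-label ("null") error — an empirical p-value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .coding import CodingScheme, block_errors
from .pls import fit_pls

__all__ = [
    "SplitPlan",
    "make_split",
    "loocv_error_curve",
    "select_n_components",
    "ReportFactor",
    "ValidationReport",
    "double_cv",
    "permutation_test",
    "conditional_ccr",
    "all_cells_binary",
]


@dataclass(frozen=True)
class SplitPlan:
    """One outer train/test split (indices into the design row order)."""

    test: tuple[int, ...]
    train: tuple[int, ...]

    def __post_init__(self):
        if set(self.test) & set(self.train):
            raise ValueError("test and train indices overlap")


def _cells(design: pd.DataFrame, factors: Sequence[str]):
    """Group sample indices by design cell, then by replicate within cell."""
    missing = [f for f in factors if f not in design.columns]
    if missing:
        raise ValueError(f"design table lacks factor columns {missing}")
    rep_col = "replicate_id" if "replicate_id" in design.columns else None
    cells: dict[tuple, dict] = {}
    for i in range(len(design)):
        key = tuple(str(design.iloc[i][f]) for f in factors)
        rep = str(design.iloc[i][rep_col]) if rep_col else str(i)
        cells.setdefault(key, {}).setdefault(rep, []).append(i)
    return cells


def make_split(
    design: pd.DataFrame, factors: Sequence[str], rng: np.random.Generator
) -> SplitPlan:
    """Hold out one biological replicate per populated design cell.

    Every cell must contain at least two replicates, otherwise the held-out
    replicate could not be matched by any training sample from its own cell.
    Cells are visited in sorted order so the plan depends only on the rng
    state, not on dictionary insertion order.
    """
    cells = _cells(design, factors)
    test: list[int] = []
    for key in sorted(cells):
        reps = cells[key]
        if len(reps) < 2:
            raise ValueError(
                f"design cell {dict(zip(factors, key))} has only {len(reps)} "
                "replicate(s); need >= 2 to split"
            )
        rep_names = sorted(reps)
        chosen = rep_names[int(rng.integers(len(rep_names)))]
        test.extend(reps[chosen])
    test_set = set(test)
    train = [i for i in range(len(design)) if i not in test_set]
    return SplitPlan(test=tuple(sorted(test)), train=tuple(train))


def loocv_error_curve(
    X_train: np.ndarray,
    labels_train: Sequence[tuple],
    scheme: CodingScheme,
    max_lv: int,
) -> np.ndarray:
    """Mean block-misassignment error for 1..max_lv latent variables.

    Leave-one-out over the training samples: fit on n-1, predict the held-out
    sample at every candidate component count (components are nested, so one
    fit per left-out sample suffices), crisp and count misassigned blocks.
    """
    X_train = np.asarray(X_train, dtype=float)
    n = X_train.shape[0]
    if n < 3:
        raise ValueError(f"training set too small for LOOCV selection (n={n})")
    labels_train = [tuple(t) for t in labels_train]
    Y = scheme.encode_dataset(labels_train)
    a_cap = min(int(max_lv), n - 2, X_train.shape[1])
    if a_cap < 1:
        raise ValueError("no admissible number of components")
    errs = np.zeros(a_cap)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        model = fit_pls(X_train[keep], Y[keep], a_cap)
        for a in range(1, a_cap + 1):
            a_eff = min(a, model.n_components)
            pred = scheme.crisp(model.predict(X_train[i], n_components=a_eff))
            errs[a - 1] += block_errors(pred, labels_train[i])
    return errs / n


def select_n_components(
    X_train: np.ndarray,
    labels_train: Sequence[tuple],
    scheme: CodingScheme,
    max_lv: int,
) -> int:
    """Smallest component count achieving the minimal LOOCV error."""
    curve = loocv_error_curve(X_train, labels_train, scheme, max_lv)
    return int(np.argmin(curve)) + 1


@dataclass(frozen=True)
class ReportFactor:
    """One factor to tally confusion for, decoded from predicted tuples.

    Normally one per scheme block (identity decode).  For an all-cells binary
    run the single predicted combination label is decoded back into the
    original factors so the confusion matrices stay comparable.
    """

    name: str
    levels: tuple[str, ...]
    truth_column: str
    decode: Callable[[tuple], str]


def _default_report_factors(scheme: CodingScheme) -> list[ReportFactor]:
    out = []
    for i, b in enumerate(scheme.blocks):
        out.append(
            ReportFactor(
                name=b.name,
                levels=b.levels,
                truth_column=b.name,
                decode=(lambda tup, i=i: tup[i]),
            )
        )
    return out


@dataclass
class ValidationReport:
    """Averaged confusion matrices, CCRs, conditional CCRs and p-values."""

    confusion: dict[str, pd.DataFrame]  # factor -> k x k row-percentages
    ccr: dict[str, float]  # factor -> overall CCR, percent
    conditional: dict[str, dict[str, dict[str, float | None]]]
    # conditional[a][b][level_of_b] = CCR of a within that true level of b
    p_values: dict[str, float] | None
    lv_counts: list[int]  # selected LV count per iteration
    n_iterations: int
    max_lv: int
    seed: int
    config_echo: dict = field(default_factory=dict)

    def lv_histogram(self) -> dict[int, int]:
        vals, counts = np.unique(self.lv_counts, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}

    def modal_lv(self) -> int:
        """Most frequently selected LV count (smallest on ties)."""
        hist = self.lv_histogram()
        best = max(hist.values())
        return min(a for a, c in hist.items() if c == best)

    def to_json_dict(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "max_lv": self.max_lv,
            "seed": self.seed,
            "ccr_percent": {k: float(v) for k, v in sorted(self.ccr.items())},
            "conditional_ccr_percent": {
                a: {
                    b: {
                        lev: (None if v is None else float(v))
                        for lev, v in levs.items()
                    }
                    for b, levs in sorted(bs.items())
                }
                for a, bs in sorted(self.conditional.items())
            },
            "p_values": (
                None
                if self.p_values is None
                else {k: float(v) for k, v in sorted(self.p_values.items())}
            ),
            "lv_histogram": {str(k): v for k, v in sorted(self.lv_histogram().items())},
            "confusion_percent": {
                name: {
                    "levels": list(df.index),
                    "rows": [[float(x) for x in row] for row in df.to_numpy()],
                }
                for name, df in sorted(self.confusion.items())
            },
            "config": self.config_echo,
        }

    def write(self, outdir) -> None:
        """One CSV per confusion matrix (2 d.p.) plus a full-precision JSON."""
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in sorted(self.confusion.items()):
            df.round(2).to_csv(outdir / f"confusion_{name}.csv", float_format="%.2f")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


class _Tally:
    """Accumulates confusion and conditional tallies across iterations."""

    def __init__(self, report_factors: list[ReportFactor]):
        self.factors = report_factors
        k = {rf.name: len(rf.levels) for rf in report_factors}
        self.percent_sum = {rf.name: np.zeros((k[rf.name], k[rf.name])) for rf in report_factors}
        self.row_iters = {rf.name: np.zeros(k[rf.name]) for rf in report_factors}
        self.pooled = {rf.name: np.zeros((k[rf.name], k[rf.name])) for rf in report_factors}
        self.cond = {
            a.name: {
                b.name: {lev: [0, 0] for lev in b.levels}
                for b in report_factors
                if b.name != a.name
            }
            for a in report_factors
        }

    def add_iteration(self, truths: list[dict], preds: list[dict]) -> None:
        """truths/preds: per test sample, factor name -> level."""
        for rf in self.factors:
            k = len(rf.levels)
            lev_idx = {lev: i for i, lev in enumerate(rf.levels)}
            counts = np.zeros((k, k))
            for t, p in zip(truths, preds):
                counts[lev_idx[t[rf.name]], lev_idx[p[rf.name]]] += 1
            self.pooled[rf.name] += counts
            row_tot = counts.sum(axis=1)
            present = row_tot > 0
            self.percent_sum[rf.name][present] += (
                100.0 * counts[present] / row_tot[present, None]
            )
            self.row_iters[rf.name] += present
        for a in self.factors:
            for b in self.factors:
                if a.name == b.name:
                    continue
                for t, p in zip(truths, preds):
                    cell = self.cond[a.name][b.name][t[b.name]]
                    cell[1] += 1
                    if p[a.name] == t[a.name]:
                        cell[0] += 1

    def confusion(self) -> dict[str, pd.DataFrame]:
        out = {}
        for rf in self.factors:
            k = len(rf.levels)
            mat = np.full((k, k), np.nan)
            iters = self.row_iters[rf.name]
            present = iters > 0
            mat[present] = self.percent_sum[rf.name][present] / iters[present, None]
            out[rf.name] = pd.DataFrame(
                mat, index=list(rf.levels), columns=list(rf.levels)
            )
        return out

    def ccr(self) -> dict[str, float]:
        out = {}
        for rf in self.factors:
            counts = self.pooled[rf.name]
            total = counts.sum()
            out[rf.name] = float(100.0 * np.trace(counts) / total) if total else float("nan")
        return out

    def conditional(self) -> dict:
        out: dict = {}
        for a_name, bs in self.cond.items():
            out[a_name] = {}
            for b_name, levs in bs.items():
                out[a_name][b_name] = {
                    lev: (100.0 * c / t if t else None) for lev, (c, t) in levs.items()
                }
        return out


def _run_iteration(
    X: np.ndarray,
    design: pd.DataFrame,
    scheme: CodingScheme,
    split_factors: Sequence[str],
    max_lv: int,
    rng: np.random.Generator,
):
    """One outer split: select LVs, fit, predict, crisp."""
    plan = make_split(design, split_factors, rng)
    train = list(plan.train)
    test = list(plan.test)
    labels = [
        tuple(str(design.iloc[i][b]) for b in scheme.block_names)
        for i in range(len(design))
    ]
    labels_train = [labels[i] for i in train]
    a_star = select_n_components(X[train], labels_train, scheme, max_lv)
    model = fit_pls(X[train], scheme.encode_dataset(labels_train), a_star)
    a_eff = min(a_star, model.n_components)
    Yp = model.predict(X[test], n_components=a_eff)
    preds = [scheme.crisp(row) for row in Yp]
    truths = [labels[i] for i in test]
    return plan, a_star, preds, truths


def _default_max_lv(n_train: int, p: int, max_lv: int | None) -> int:
    cap = min(15, n_train - 2, p)
    return cap if max_lv is None else min(int(max_lv), n_train - 2, p)


def double_cv(
    X: np.ndarray,
    design: pd.DataFrame,
    scheme: CodingScheme,
    n_iterations: int = 1000,
    max_lv: int | None = None,
    rng_seed: int = 0,
    split_factors: Sequence[str] | None = None,
    report_factors: list[ReportFactor] | None = None,
    config_echo: dict | None = None,
) -> ValidationReport:
    """Replicate-stratified double cross-validation.

    Parameters
    ----------
    X
        Feature matrix, rows aligned with ``design``.
    design
        Design table with one column per scheme block (plus optional
        ``replicate_id``).
    scheme
        Y-block coding scheme used for encoding, crisping and error counting.
    n_iterations
        Number of outer random splits (1000 reproduces a full run; tests use
        far fewer).
    max_lv
        Cap on candidate latent variables; defaults to min(15, n_train-2, p).
    rng_seed
        Seeds the whole procedure; identical inputs give identical reports.
    split_factors
        Design columns defining the cells for replicate-stratified splitting;
        defaults to the scheme's block names.
    report_factors
        Which factors to tally (defaults to one per scheme block).
    """
    X = np.asarray(X, dtype=float)
    if len(design) != X.shape[0]:
        raise ValueError("X and design have different numbers of samples")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    split_factors = list(split_factors or scheme.block_names)
    report_factors = report_factors or _default_report_factors(scheme)
    # size the LV cap from a representative split
    probe = make_split(design, split_factors, np.random.default_rng(0))
    lv_cap = _default_max_lv(len(probe.train), X.shape[1], max_lv)

    tally = _Tally(report_factors)
    lv_counts: list[int] = []
    children = np.random.SeedSequence(rng_seed).spawn(n_iterations)
    for it in range(n_iterations):
        rng = np.random.default_rng(children[it])
        try:
            plan, a_star, preds, truths = _run_iteration(
                X, design, scheme, split_factors, lv_cap, rng
            )
        except Exception as e:
            raise RuntimeError(
                f"double CV failed at iteration {it} (seed {rng_seed}): {e}"
            ) from e
        lv_counts.append(a_star)
        test = list(plan.test)
        truth_dicts = [
            {
                rf.name: str(design.iloc[i][rf.truth_column])
                for rf in report_factors
            }
            for i in test
        ]
        pred_dicts = [
            {rf.name: rf.decode(p) for rf in report_factors} for p in preds
        ]
        tally.add_iteration(truth_dicts, pred_dicts)

    return ValidationReport(
        confusion=tally.confusion(),
        ccr=tally.ccr(),
        conditional=tally.conditional(),
        p_values=None,
        lv_counts=lv_counts,
        n_iterations=n_iterations,
        max_lv=lv_cap,
        seed=int(rng_seed),
        config_echo=config_echo or {},
    )


def _block_error_counts(
    preds: list[tuple], truths: list[tuple], scheme: CodingScheme
) -> dict[str, int]:
    out = {b: 0 for b in scheme.block_names}
    for p, t in zip(preds, truths):
        for b, pi, ti in zip(scheme.block_names, p, t):
            if pi != ti:
                out[b] += 1
    return out


def permutation_test(
    X: np.ndarray,
    design: pd.DataFrame,
    scheme: CodingScheme,
    n_iterations: int = 1000,
    max_lv: int | None = None,
    rng_seed: int = 0,
    split_factors: Sequence[str] | None = None,
) -> dict[str, float]:
    """Empirical per-block p-values from permuted-label refits.

    Per iteration, the pipeline runs once with the true labels (observed
    errors) and once with the label tuples permuted jointly across samples
    before splitting (null errors).  The p-value of a block is the fraction
    of iterations in which the observed block error strictly exceeded the
    null block error; ties count as non-exceedances, which makes the test
    slightly anti-conservative.
    """
    X = np.asarray(X, dtype=float)
    split_factors = list(split_factors or scheme.block_names)
    # permute whole design rows (label tuple + replicate id) so the null run
    # keeps the same cell/replicate structure, merely reassigned to samples
    perm_cols = [c for c in design.columns if c != "sample_id"]
    probe = make_split(design, split_factors, np.random.default_rng(0))
    lv_cap = _default_max_lv(len(probe.train), X.shape[1], max_lv)

    exceed = {b: 0 for b in scheme.block_names}
    children = np.random.SeedSequence(rng_seed).spawn(n_iterations)
    for it in range(n_iterations):
        perm_rng, obs_rng, null_rng = (
            np.random.default_rng(s) for s in children[it].spawn(3)
        )
        try:
            _, _, preds, truths = _run_iteration(
                X, design, scheme, split_factors, lv_cap, obs_rng
            )
            obs_err = _block_error_counts(preds, truths, scheme)
            perm = perm_rng.permutation(len(design))
            design_null = design.copy()
            design_null[perm_cols] = design[perm_cols].to_numpy()[perm]
            _, _, preds_n, truths_n = _run_iteration(
                X, design_null, scheme, split_factors, lv_cap, null_rng
            )
            null_err = _block_error_counts(preds_n, truths_n, scheme)
        except Exception as e:
            raise RuntimeError(
                f"permutation test failed at iteration {it} (seed {rng_seed}): {e}"
            ) from e
        for b in scheme.block_names:
            if obs_err[b] > null_err[b]:
                exceed[b] += 1
    return {b: exceed[b] / n_iterations for b in scheme.block_names}


def conditional_ccr(
    report: ValidationReport, block_a: str, block_b: str
) -> dict[str, float | None]:
    """CCR of ``block_a`` within each true level of ``block_b``.

    Computed from the pooled test-set tallies of the report; empty strata are
    reported as ``None``.
    """
    try:
        return dict(report.conditional[block_a][block_b])
    except KeyError:
        raise KeyError(
            f"no conditional table for ({block_a!r} | {block_b!r}); "
            f"have factors {sorted(report.conditional)}"
        ) from None


def all_cells_binary(
    scheme: CodingScheme, design: pd.DataFrame, sep: str = "|"
) -> tuple[CodingScheme, pd.DataFrame, list[ReportFactor]]:
    """Re-express a structured scheme as a single one-of-k "all cells" block.

    Every populated combination of factor levels becomes one class of a
    single 0/1 categorical block (classical PLS-DA coding).  The returned
    report factors decode the predicted combination label back into the
    original factors, so confusion matrices remain directly comparable with
    the structured run.
    """
    from .coding import CATEGORICAL, FactorBlock

    factor_cols = scheme.block_names
    for col in factor_cols:
        bad = design[col].astype(str).str.contains(sep, regex=False)
        if bad.any():
            raise ValueError(
                f"factor levels in {col!r} contain the separator {sep!r}"
            )
    populated = {
        tuple(str(design.iloc[i][c]) for c in factor_cols)
        for i in range(len(design))
    }
    combo_levels = [
        sep.join(levels) for levels in scheme.label_space() if tuple(levels) in populated
    ]
    combo_scheme = CodingScheme(
        blocks=(
            FactorBlock(
                name="cell",
                kind=CATEGORICAL,
                levels=tuple(combo_levels),
                codes=(0.0, 1.0),
            ),
        )
    )
    design2 = design.copy()
    design2["cell"] = design[factor_cols].astype(str).agg(sep.join, axis=1)
    report_factors = [
        ReportFactor(
            name="cell",
            levels=tuple(combo_levels),
            truth_column="cell",
            decode=(lambda tup: tup[0]),
        )
    ]
    report_factors += [
        ReportFactor(
            name=b.name,
            levels=b.levels,
            truth_column=b.name,
            decode=(lambda tup, i=i, sep=sep: tup[0].split(sep)[i]),
        )
        for i, b in enumerate(scheme.blocks)
    ]
    return combo_scheme, design2, report_factors
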