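"""Delimited-text I/O and the surrogate-guided model-trimming workflow.

The workflow mirrors how an analyst prunes a probit model with a
continuous-response mindset:

* step 0 — fit the full model, generate the common surrogate (M draws),
  report its R-squared alongside McKelvey–Zavoina and McFadden;
* step 1 — drop covariates whose Wald p-value exceeds a threshold, refit,
  re-evaluate with the *same* surrogate;
* step 2 — compare alternative collinearity-motivated reductions and keep
  the one that costs the least R-squared;
* step 3 — rank the remaining covariates by the percent R-squared drop
  when each is removed alone.

Every R-squared in steps 1–3 reuses the single surrogate bundle generated
at step 0 (the common-surrogate rule).  Percent reductions are always
relative to the *current working model's* R-squared, not the step-0 value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .probit import OrdinalDataset, ProbitFit, fit_probit
from .rsq import CommonSurrogate, mcfadden_r2, mz_r2
from .uncertainty import bootstrap_interval

__all__ = [
    "read_dataset",
    "write_table",
    "ContributionTable",
    "contribution_table",
    "TrimConfig",
    "TrimReport",
    "trim_workflow",
]

logger = logging.getLogger(__name__)

_DELIMITERS = (",", ";", "\t")


def _sniff_delimiter(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    counts = {d: header.count(d) for d in _DELIMITERS}
    best = max(counts, key=counts.get)
    if counts[best] == 0:
        raise ValueError(f"{path}: header contains none of the supported delimiters , ; tab")
    return best


def read_dataset(path, response, covariates=None, levels=None, name=None,
                 delimiter=None) -> OrdinalDataset:
    """Read an :class:`OrdinalDataset` from a delimited text file.

    Parameters
    ----------
    response : str
        Name of the ordinal response column.
    covariates : sequence of str, optional
        Covariate columns (default: every other numeric column, in file
        order).
    levels : sequence, optional
        Explicit response levels in increasing order; otherwise observed
        values are mapped to ``1..J`` by sorted order.
    delimiter : str, optional
        Comma, semicolon or tab; auto-detected from the header if omitted.

    Missing values anywhere in the used columns are an error (no
    imputation), reported with their row numbers.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter)
    if response not in df.columns:
        raise ValueError(f"response column {response!r} not in {list(df.columns)}")
    if covariates is None:
        covariates = [c for c in df.columns
                      if c != response and pd.api.types.is_numeric_dtype(df[c])]
    else:
        missing_cols = [c for c in covariates if c not in df.columns]
        if missing_cols:
            raise ValueError(f"covariate columns not found: {missing_cols}")
    used = df[list(covariates) + [response]]
    na_rows = used.index[used.isna().any(axis=1)]
    if len(na_rows):
        raise ValueError(f"missing values in rows {list(na_rows[:20])}"
                         + (" ..." if len(na_rows) > 20 else ""))
    raw = df[response].to_numpy()
    if levels is None:
        levels = np.unique(raw)
    else:
        levels = np.asarray(levels)
        unknown = np.setdiff1d(np.unique(raw), levels)
        if unknown.size:
            raise ValueError(f"response values {unknown.tolist()} not in declared levels")
    y = np.searchsorted(levels, raw) + 1
    return OrdinalDataset.from_arrays(
        df[list(covariates)].to_numpy(dtype=float), y,
        var_names=covariates, name=name or path.stem, J=len(levels))


def write_table(obj, path, delimiter=","):
    """Write a results object (DataFrame or anything with ``.table`` /
    ``.to_frame``) as delimited text."""
    if isinstance(obj, pd.DataFrame):
        df = obj
    elif hasattr(obj, "table"):
        df = obj.table
    elif hasattr(obj, "to_frame"):
        df = obj.to_frame()
    else:
        raise TypeError(f"don't know how to write {type(obj).__name__}")
    df.to_csv(path, sep=delimiter)


@dataclass
class ContributionTable:
    """Per-variable (or variable-group) contribution to the working model's
    surrogate R-squared, sorted by percent reduction."""

    working_model_r2: float
    rows: pd.DataFrame  # columns: dropped, r2, delta_pct [, ci_lower, ci_upper]

    @property
    def table(self) -> pd.DataFrame:
        return self.rows


def contribution_table(full_fit, data: OrdinalDataset, working_subset=None,
                       drop_sets=None, M: int = 30, seed: int = 0,
                       with_intervals: bool = False, B: int = 2000,
                       level: float = 0.95,
                       common: CommonSurrogate | None = None) -> ContributionTable:
    """Reduction in surrogate R-squared when each drop set is removed from
    the working model.

    ``delta_pct = (working_r2 - reduced_r2) / working_r2 * 100``, computed
    against the working model's own R-squared under the same common
    surrogate.  Rows are sorted by ``delta_pct`` descending.
    """
    if common is None:
        common = CommonSurrogate(full_fit, data, M=M, seed=seed)
    if working_subset is None:
        working_subset = list(common.full_subset)
    working_subset = list(working_subset)
    if drop_sets is None:
        drop_sets = [[v] for v in working_subset]
    ref = common.r2(working_subset).value

    records = []
    for group in drop_sets:
        group = [group] if isinstance(group, str) else list(group)
        if not group:
            raise ValueError("empty drop set")
        unknown = set(group) - set(working_subset)
        if unknown:
            raise ValueError(f"drop set {group} not within working model: {sorted(unknown)}")
        reduced = [v for v in working_subset if v not in group]
        r2 = common.r2(reduced).value
        rec = {
            "dropped": "+".join(group),
            "r2": r2,
            "delta_pct": (ref - r2) / ref * 100.0,
        }
        if with_intervals:
            ci = bootstrap_interval(data, full_subset=list(common.full_subset),
                                    eval_subset=reduced, B=B, level=level,
                                    seed=seed)
            rec["ci_lower"], rec["ci_upper"] = ci.lower, ci.upper
        records.append(rec)
    rows = pd.DataFrame.from_records(records).sort_values(
        "delta_pct", ascending=False, kind="mergesort").reset_index(drop=True)
    return ContributionTable(working_model_r2=ref, rows=rows)


@dataclass
class TrimConfig:
    """Configuration of the trimming workflow.

    ``collinearity_groups`` lists alternative drop sets for step 2 (e.g.
    ``[["density"], ["residual.sugar", "alcohol"]]``); the candidate with
    the smallest R-squared loss is applied.  An empty list skips step 2.
    """

    full_model: list[str]
    alpha: float = 0.05
    collinearity_groups: list[list[str]] = field(default_factory=list)
    M: int = 30
    B: int = 2000
    level: float = 0.95
    with_intervals: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "TrimConfig":
        if "full_model" not in d:
            raise ValueError("config must name the full model covariates ('full_model')")
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class TrimReport:
    """Ordered record of steps 0-3 of the trimming workflow."""

    steps: pd.DataFrame
    contributions: ContributionTable
    working_subset: list[str]
    full_fit: ProbitFit
    seed: int

    @property
    def table(self) -> pd.DataFrame:
        return self.steps


def _step_row(step, label, subset, common, data, interval=None, ref_r2=None):
    fit = fit_probit(data, subset)
    r2 = common.r2(subset).value
    row = {
        "step": step,
        "model": label,
        "n_vars": len(subset),
        "surrogate_r2": r2,
        "delta_pct": np.nan if ref_r2 is None else (ref_r2 - r2) / ref_r2 * 100.0,
        "mz_r2": mz_r2(fit, data).value,
        "mcfadden_r2": mcfadden_r2(fit).value,
    }
    if interval is not None:
        row["ci_lower"], row["ci_upper"] = interval.lower, interval.upper
    return row, fit, r2


def trim_workflow(data: OrdinalDataset, config, seed: int = 0) -> TrimReport:
    """Run the full surrogate-guided trimming workflow (steps 0-3).

    A single common surrogate bundle is generated from the step-0 full fit
    and reused for every R-squared in the report, so nested reductions are
    monotone by construction.  Reproducible bit-for-bit given
    ``(data, config, seed)``.
    """
    if isinstance(config, dict):
        config = TrimConfig.from_dict(config)
    full_subset = list(config.full_model)
    full_fit = fit_probit(data, full_subset)
    if not full_fit.converged:
        raise RuntimeError("full model fit did not converge")
    common = CommonSurrogate(full_fit, data, M=config.M, seed=seed)

    def ci(subset):
        if not config.with_intervals:
            return None
        return bootstrap_interval(data, full_subset=full_subset, eval_subset=subset,
                                  B=config.B, level=config.level, seed=seed)

    rows = []
    row, _, r2_full = _step_row(0, "full", full_subset, common, data, ci(full_subset))
    rows.append(row)
    working = full_subset
    r2_working = r2_full

    # step 1: drop Wald-insignificant covariates from the full fit
    pvals = dict(zip(full_fit.var_subset, full_fit.wald_pvalues()))
    kept = [v for v in full_subset if pvals[v] < config.alpha]
    dropped = sorted(set(full_subset) - set(kept))
    logger.info("step 1 drops %s at alpha=%.3g", dropped or "nothing", config.alpha)
    if kept:
        row, _, r2_kept = _step_row(1, f"-{'+'.join(dropped)}" if dropped else "full",
                                    kept, common, data, ci(kept), ref_r2=r2_working)
        rows.append(row)
        working, r2_working = kept, r2_kept

    # step 2: alternative collinearity reductions; keep the cheapest
    best = None
    for group in config.collinearity_groups:
        group = [group] if isinstance(group, str) else list(group)
        reduced = [v for v in working if v not in group]
        row, _, r2_red = _step_row(2, f"-{'+'.join(group)}", reduced, common, data,
                                   ci(reduced), ref_r2=r2_working)
        rows.append(row)
        if best is None or r2_red > best[1]:
            best = (reduced, r2_red)
    if best is not None:
        working, r2_working = best

    # step 3: rank remaining variables by their individual contribution
    contrib = contribution_table(full_fit, data, working_subset=working,
                                 M=config.M, seed=seed, common=common,
                                 with_intervals=config.with_intervals,
                                 B=config.B, level=config.level)

    return TrimReport(steps=pd.DataFrame(rows), contributions=contrib,
                      working_subset=list(working), full_fit=full_fit, seed=int(seed))
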