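"""Survival labelling, fold-wise standardization, and stratified folds.

Samples are labelled long-term survivors (LTS, the positive class) when
they survived at least ``cutoff_months`` months regardless of vital
status; deceased earlier than the cutoff is non-LTS; alive earlier than
the cutoff is censored and excluded.  Expression is z-scored per gene with
training-fold statistics only, so test samples never leak into scaling.
"""

from __future__ import annotations

from os import PathLike

import numpy as np
import pandas as pd

__all__ = [
    "LabelingError",
    "derive_labels",
    "standardize_fold",
    "stratified_folds",
    "load_expression",
    "load_clinical",
    "align_samples",
]

#: accepted vital-status spellings (case-insensitive) in clinical tables
DECEASED_TOKENS = {"deceased", "dead", "1", "true"}
ALIVE_TOKENS = {"alive", "living", "0", "false"}


class LabelingError(ValueError):
    """Raised when labelling excludes everything or yields one class."""


def _status_to_bool(v) -> bool:
    s = str(v).strip().lower()
    if s in DECEASED_TOKENS:
        return True
    if s in ALIVE_TOKENS:
        return False
    raise ValueError(f"unrecognised vital status {v!r}")


def derive_labels(
    clinical: pd.DataFrame, cutoff_months: float = 24.0
) -> tuple[pd.Series, set[str]]:
    """Derive binary survival labels with censoring exclusion.

    Parameters
    ----------
    clinical
        Columns ``sample_id`` (unique), ``survival_months`` (finite,
        non-negative), and either ``deceased`` (bool) or ``status``
        (deceased/dead/1 vs alive/living/0, case-insensitive).
    cutoff_months
        Class boundary in months; survival exactly at the cutoff counts
        as long-term (the boundary belongs to the >= side).

    Returns
    -------
    labels
        ``pd.Series`` of {0, 1} indexed by sample id, input order, for
        retained samples only (1 = LTS).
    excluded
        Ids of censored samples (alive, below the cutoff).
    """
    if cutoff_months <= 0:
        raise ValueError("cutoff_months must be positive")
    if clinical["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in clinical table")
    t = clinical["survival_months"].to_numpy(dtype=float)
    if not np.all(np.isfinite(t)) or np.any(t < 0):
        raise ValueError("survival_months must be finite and non-negative")
    if "deceased" in clinical.columns:
        dead = clinical["deceased"].to_numpy(dtype=bool)
    elif "status" in clinical.columns:
        dead = clinical["status"].map(_status_to_bool).to_numpy(dtype=bool)
    else:
        raise ValueError("clinical table needs a 'deceased' or 'status' column")

    lts = t >= cutoff_months
    censored = (~dead) & (~lts)
    keep = ~censored
    labels = pd.Series(
        lts[keep].astype(int),
        index=pd.Index(clinical.loc[keep, "sample_id"], name="sample_id"),
    )
    excluded = set(clinical.loc[censored, "sample_id"])
    if labels.empty:
        raise LabelingError("all samples were censored/excluded")
    if labels.nunique() < 2:
        raise LabelingError("labelling produced a single class")
    return labels, excluded


def standardize_fold(
    train_X: np.ndarray, test_X: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-gene z-scores using training mean and population std.

    The same training statistics scale both matrices; a zero-variance
    training gene maps to 0 everywhere (kept, not dropped, so gene
    columns stay aligned with the biadjacency matrix).
    """
    train_X = np.asarray(train_X, dtype=float)
    if train_X.ndim != 2 or train_X.shape[0] < 2:
        raise ValueError("train_X must be 2-D with >= 2 samples")
    mu = train_X.mean(axis=0)
    sd = train_X.std(axis=0)  # population form (ddof=0)
    safe = np.where(sd > 0, sd, 1.0)
    train_Z = (train_X - mu) / safe
    train_Z[:, sd == 0] = 0.0
    if test_X is None:
        return train_Z, None
    test_X = np.asarray(test_X, dtype=float)
    if test_X.shape[1] != train_X.shape[1]:
        raise ValueError("train and test gene columns differ")
    test_Z = (test_X - mu) / safe
    test_Z[:, sd == 0] = 0.0
    return train_Z, test_Z


def stratified_folds(
    y: np.ndarray, k: int, seed: int | np.random.Generator
) -> list[np.ndarray]:
    """Split indices into ``k`` disjoint stratified folds.

    Within each class, indices are shuffled with the given seed and dealt
    round-robin, so per-class fold counts differ by at most one.
    """
    y = np.asarray(y)
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            raise ValueError(
                f"class {cls!r} has {len(idx)} members, fewer than k={k}"
            )
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[pos % k].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _sniff_sep(path: str | PathLike) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def load_expression(path: str | PathLike) -> pd.DataFrame:
    """Load a samples × genes expression table.

    First column is the sample id; remaining columns are gene symbols.
    Tab- or comma-separated, sniffed from the header line.
    """
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    if df.columns.duplicated().any():
        raise ValueError("duplicate gene columns in expression table")
    return df.astype(float)


def load_clinical(path: str | PathLike) -> pd.DataFrame:
    """Load a clinical table with sample_id, survival_months, status.

    Status accepts deceased/dead/1/true vs alive/living/0/false,
    case-insensitively.
    """
    df = pd.read_csv(path, sep=_sniff_sep(path))
    cols = {c.lower(): c for c in df.columns}
    for need in ("sample_id", "survival_months"):
        if need not in cols:
            raise ValueError(f"clinical table lacks column {need!r}")
    status_col = cols.get("status") or cols.get("deceased") or cols.get("vital_status")
    if status_col is None:
        raise ValueError("clinical table lacks a status column")

    out = pd.DataFrame(
        {
            "sample_id": df[cols["sample_id"]].astype(str),
            "survival_months": df[cols["survival_months"]].astype(float),
            "deceased": df[status_col].map(_status_to_bool),
        }
    )
    return out


def align_samples(
    expression: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Intersect expression rows with labelled samples (expression order).

    Returns the aligned expression, aligned labels, and the ids dropped
    from either side; mismatches are reported, not fatal.
    """
    common = [s for s in expression.index if s in labels.index]
    dropped = sorted(
        (set(expression.index) | set(labels.index)) - set(common)
    )
    if not common:
        raise ValueError("no samples shared between expression and labels")
    return expression.loc[common], labels.loc[common], dropped
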