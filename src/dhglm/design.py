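"""Design-matrix construction from phenotype table columns.

Fixed terms: numeric columns enter as-is; categorical/object columns are
expanded to full-rank treatment coding (first level is the reference).
An intercept is always included.  Trailing collinear columns are dropped
with a warning, matching common mixed-model software.

Random terms: a grouping column becomes a one-hot incidence matrix; a
pedigree-linked term builds the incidence over the pedigree ids so that
relationship folding and BLUPs cover non-phenotyped ancestors too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)


@dataclass
class FixedDesign:
    matrix: np.ndarray
    names: list[str]
    #: per-term encoding used to rebuild the design for new data
    encoders: dict[str, list | None] = field(default_factory=dict)
    dropped: list[str] = field(default_factory=list)


@dataclass
class RandomDesign:
    Z: sp.csr_matrix
    levels: list
    term: str
    folded: bool = False


def _is_numeric(s: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(s) and not isinstance(
        s.dtype, pd.CategoricalDtype
    )


def drop_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Drop later columns that are linear combinations of earlier ones."""
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    R = np.linalg.qr(X / norms, mode="r")
    diag = np.abs(np.diag(R))
    keep = diag > 1e-8 * max(diag.max(), 1.0)
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        logger.warning("dropping collinear fixed-effect column(s): %s", dropped)
        X = X[:, keep]
        names = [n for n, k in zip(names, keep) if k]
    return X, names, dropped


def build_fixed_design(data: pd.DataFrame, terms) -> FixedDesign:
    n = len(data)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    encoders: dict[str, list | None] = {}
    for t in terms:
        if t in ("1", ""):
            continue
        if t not in data.columns:
            raise KeyError(f"fixed-effect column {t!r} not in data")
        s = data[t]
        if _is_numeric(s):
            v = s.to_numpy(dtype=float)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite values in fixed-effect column {t!r}")
            cols.append(v)
            names.append(t)
            encoders[t] = None
        else:
            levels = list(pd.Categorical(s).categories)
            encoders[t] = levels
            for lev in levels[1:]:  # first level is the reference
                cols.append((s == lev).to_numpy(dtype=float))
                names.append(f"{t}[{lev}]")
    X = np.column_stack(cols)
    X, names, dropped = drop_collinear(X, names)
    return FixedDesign(matrix=X, names=names, encoders=encoders, dropped=dropped)


def rebuild_fixed_design(data: pd.DataFrame, fd: FixedDesign) -> np.ndarray:
    """Apply a fitted encoding to new data (prediction path)."""
    n = len(data)
    out = {"(Intercept)": np.ones(n)}
    for t, levels in fd.encoders.items():
        s = data[t]
        if levels is None:
            out[t] = s.to_numpy(dtype=float)
        else:
            unseen = set(s.unique()) - set(levels)
            if unseen:
                logger.warning("unseen level(s) %s in %r mapped to reference",
                               sorted(unseen)[:5], t)
            for lev in levels[1:]:
                out[f"{t}[{lev}]"] = (s == lev).to_numpy(dtype=float)
    return np.column_stack([out[n_] for n_ in fd.names])


def build_random_design(data: pd.DataFrame, term: str,
                        level_order: list | None = None) -> RandomDesign:
    """One-hot incidence for a grouping column.

    ``level_order`` pins the column order (e.g. pedigree order); levels
    absent from it are an error for the caller to resolve beforehand.
    """
    if term not in data.columns:
        raise KeyError(f"random-effect grouping column {term!r} not in data")
    s = data[term]
    if s.isna().any():
        raise ValueError(f"missing values in grouping column {term!r}")
    if level_order is None:
        codes, levels = pd.factorize(s, sort=True)
        levels = list(levels)
    else:
        levels = list(level_order)
        index = {l: i for i, l in enumerate(levels)}
        missing = [v for v in s.unique() if v not in index]
        if missing:
            raise KeyError(f"levels {missing[:5]} of {term!r} not in level order")
        codes = s.map(index).to_numpy()
    n = len(data)
    Z = sp.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, len(levels))
    )
    return RandomDesign(Z=Z, levels=levels, term=term)
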