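"""Phenotype-table reading and result writing.

Phenotype files are delimited text with a header; the delimiter is
sniffed (comma, tab or whitespace) and logged.  Rows with a missing
response are rejected with a logged count.  Results are written as a
deterministic set of TSV files enumerable from the output prefix alone.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .model import DHGLM, leverage_report

logger = logging.getLogger(__name__)

RESULT_SUFFIXES = (
    "estimates.tsv", "variances.tsv", "leverages.tsv", "blups.tsv",
    "trajectory.tsv",
)


def read_phenotypes(
    path, response: str | None = None, columns=None
) -> pd.DataFrame:
    """Read a delimited phenotype table into a typed DataFrame.

    ``response`` (if given) must exist, be numeric and finite; rows with
    a missing response are dropped with a logged count.  ``columns``
    lists further required columns.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    logger.info("read %d records, %d columns from %s", len(df), df.shape[1], path)
    required = list(columns or [])
    if response is not None:
        required = [response] + required
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise KeyError(f"column(s) {missing} not found in {path}")
    if response is not None:
        bad = pd.to_numeric(df[response], errors="coerce").isna()
        if bad.any():
            logger.warning("dropping %d record(s) with missing/non-numeric "
                           "response %r", int(bad.sum()), response)
            df = df.loc[~bad].reset_index(drop=True)
        df[response] = df[response].astype(float)
        if not np.all(np.isfinite(df[response])):
            raise ValueError(f"non-finite values in response column {response!r}")
        if df.empty:
            raise ValueError("no usable records after dropping missing responses")
    return df


def result_files(prefix) -> dict[str, Path]:
    """The file set a :func:`write_results` call produces for a prefix."""
    prefix = Path(prefix)
    return {s.split(".")[0]: prefix.with_name(prefix.name + "." + s)
            for s in RESULT_SUFFIXES}


def write_results(model: DHGLM, prefix) -> dict[str, Path]:
    """Write estimates, variances, leverages, BLUPs and trajectory TSVs."""
    model._check_fitted()
    files = result_files(prefix)
    files["estimates"].parent.mkdir(parents=True, exist_ok=True)

    est = pd.concat([
        pd.DataFrame({"part": "mean", "term": model.coef_.index,
                      "estimate": model.coef_.to_numpy()}),
        pd.DataFrame({"part": "dispersion", "term": model.disp_coef_.index,
                      "estimate": model.disp_coef_.to_numpy()}),
    ])
    est.to_csv(files["estimates"], sep="\t", index=False)

    rows = [{"component": "converged", "value": float(model.converged_)},
            {"component": "n_iter", "value": model.n_iter_}]
    rows += [{"component": f"sigma_u2[{t}]", "value": v}
             for t, v in model.sigma_u2_.items()]
    rows += [{"component": f"sigma_d2[{t}]", "value": v}
             for t, v in model.sigma_d2_.items()]
    pd.DataFrame(rows).to_csv(files["variances"], sep="\t", index=False)

    rep = leverage_report(model)
    rep.records.to_csv(files["leverages"], sep="\t", index=False)
    rep.levels.to_csv(files["blups"], sep="\t", index=False)
    model.trajectory_.to_csv(files["trajectory"], sep="\t", index=False)
    logger.info("wrote %d result files with prefix %s", len(files), prefix)
    return files
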