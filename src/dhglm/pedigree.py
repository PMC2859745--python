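"""Pedigrees and additive relationship factors.

An animal model places one random effect per animal with covariance
``A * sigma_u2``, where ``A`` is the additive (numerator) relationship
matrix implied by the pedigree.  Rather than carrying the correlation
through the mixed-model equations, we fold it into the incidence matrix:
with ``A = L L'`` (L lower triangular) and ``Z* = Z L``, the model
``Z* u*`` with i.i.d. ``u* ~ N(0, I sigma_u2)`` has exactly the
covariance ``Z A Z' sigma_u2`` of the original correlated effects.

``L`` is built directly from the pedigree with Henderson's recursive
construction (parent rows averaged, diagonal completed from the
individual's own relationship 1 + F), which is exact and never asks a
numerical factorization to cope with a semi-definite ``A``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: sentinel token for an unknown parent
UNKNOWN = "0"


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, self-ancestry, duplicates)."""


@dataclass
class Pedigree:
    """Ordered (animal, sire, dam) records; ``"0"`` marks an unknown parent.

    IDs are opaque tokens.  Parents that never appear in the animal column
    are added as founders.  A topological order (parents before offspring)
    must exist; cycles raise :class:`PedigreeError`.
    """

    records: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        animals = [a for a, _, _ in self.records]
        if len(set(animals)) != len(animals):
            dupes = sorted({a for a in animals if animals.count(a) > 1})
            raise PedigreeError(f"duplicate animal ids in pedigree: {dupes[:5]}")
        known = set(animals)
        implicit = []
        for _, s, d in self.records:
            for p in (s, d):
                if p != UNKNOWN and p not in known:
                    known.add(p)
                    implicit.append(p)
        if implicit:
            logger.warning(
                "%d parent(s) not listed as animals; added as founders", len(implicit)
            )
            self.records = [(p, UNKNOWN, UNKNOWN) for p in implicit] + self.records
        for a, s, d in self.records:
            if a == s or a == d:
                raise PedigreeError(f"animal {a!r} listed as its own parent")

    @property
    def animal_ids(self) -> list[str]:
        return [a for a, _, _ in self.records]

    def topological_order(self) -> list[str]:
        """Animal ids with every parent preceding its offspring.

        Keeps the supplied record order whenever it is already topological.
        """
        parents = {a: [p for p in (s, d) if p != UNKNOWN] for a, s, d in self.records}
        # fast path: supplied order already valid
        seen: set[str] = set()
        ok = True
        for a in parents:
            if any(p not in seen for p in parents[a]):
                ok = False
                break
            seen.add(a)
        if ok:
            return list(parents)
        ts = TopologicalSorter(parents)
        try:
            order = list(ts.static_order())
        except CycleError as exc:
            raise PedigreeError(f"cycle in pedigree: {exc.args[1]}") from exc
        logger.info("pedigree records reordered topologically")
        return order


@dataclass
class RelationshipFactor:
    """Lower-triangular ``L`` with ``A = L L'`` and the id -> row map."""

    L: np.ndarray
    id_index: dict[str, int] = field(repr=False)

    @property
    def ids(self) -> list[str]:
        return sorted(self.id_index, key=self.id_index.get)

    def a_matrix(self) -> np.ndarray:
        """Reconstruct the additive relationship matrix ``A = L L'``."""
        return self.L @ self.L.T

    def extended(self, extra_ids: list[str]) -> "RelationshipFactor":
        """Append unrelated founders (identity block) for ``extra_ids``."""
        clash = [i for i in extra_ids if i in self.id_index]
        if clash:
            raise PedigreeError(f"ids already in pedigree: {clash[:5]}")
        q = self.L.shape[0]
        m = len(extra_ids)
        L = np.zeros((q + m, q + m))
        L[:q, :q] = self.L
        L[q:, q:] = np.eye(m)
        idx = dict(self.id_index)
        for k, i in enumerate(extra_ids):
            idx[i] = q + k
        return RelationshipFactor(L=L, id_index=idx)


def build_relationship_factor(ped: Pedigree) -> RelationshipFactor:
    """Henderson's recursive Cholesky factor of the relationship matrix.

    Row ``i`` of ``L`` is the average of its parents' rows below the
    diagonal; the diagonal entry completes ``a_ii = 1 + 0.5 A(sire, dam)``
    (> 1 only under inbreeding).  Founders contribute identity rows.
    """
    order = ped.topological_order()
    pos = {a: i for i, a in enumerate(order)}
    par = {a: (s, d) for a, s, d in ped.records}
    q = len(order)
    L = np.zeros((q, q))
    for i, a in enumerate(order):
        s, d = par[a]
        si = pos[s] if s != UNKNOWN else None
        di = pos[d] if d != UNKNOWN else None
        if si is not None:
            L[i, : si + 1] += 0.5 * L[si, : si + 1]
        if di is not None:
            L[i, : di + 1] += 0.5 * L[di, : di + 1]
        if si is not None and di is not None:
            a_sd = float(L[si] @ L[di])
            a_ii = 1.0 + 0.5 * a_sd
        else:
            a_ii = 1.0
        diag2 = a_ii - float(L[i, :i] @ L[i, :i])
        if diag2 <= 0:
            raise PedigreeError(f"non-positive diagonal for {a!r}; invalid pedigree")
        L[i, i] = np.sqrt(diag2)
    return RelationshipFactor(L=L, id_index=pos)


def fold_relationship(Z, rf: RelationshipFactor):
    """Return ``Z @ L`` so i.i.d. effects carry the pedigree covariance.

    ``Z`` columns must follow ``rf.id_index`` order.  Accepts dense or
    sparse ``Z``; the folded matrix is returned dense if either input is
    (folding generally destroys sparsity, which we accept).
    """
    q = rf.L.shape[0]
    if Z.shape[1] != q:
        raise ValueError(f"Z has {Z.shape[1]} columns but factor is {q} x {q}")
    out = Z @ rf.L
    return np.asarray(out) if not sp.issparse(out) else out


def read_pedigree(path) -> Pedigree:
    """Read a 3-column (animal, sire, dam) delimited text file.

    Whitespace or comma delimited; ``"0"`` (or an empty field) marks an
    unknown parent.  A header row is auto-detected from conventional
    column names.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    if df.shape[1] < 3:
        raise PedigreeError(f"pedigree file needs 3 columns, found {df.shape[1]}")
    df = df.iloc[:, :3].fillna(UNKNOWN)
    first = [str(v).strip().lower() for v in df.iloc[0]]
    header_words = {"animal", "id", "indiv", "individual", "sire", "dam",
                    "father", "mother", "offspring", "progeny"}
    if header_words & set(first):
        df = df.iloc[1:]
    recs = [
        (str(a).strip(), str(s).strip() or UNKNOWN, str(d).strip() or UNKNOWN)
        for a, s, d in df.itertuples(index=False)
    ]
    return Pedigree(records=recs)
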