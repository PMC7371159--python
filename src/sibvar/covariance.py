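"""Pairwise relatedness (K) and home-sharing (H) matrices.

The random-effect correlation structure of the sibling-adoption model is
carried by two symmetric matrices indexed by child id: the expected
genome-sharing coefficient K (monozygotic twins 1.0, full siblings or
dizygotic twins 0.5, half siblings 0.25, unrelated 0.0) and the co-rearing
indicator H (same household 1, different households 0).  Coefficients are
assigned from reported pedigree classes; no transitive pedigree inference is
performed, so an inconsistent triad is surfaced as a warning rather than
auto-resolved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PAIR_CLASS_RELATEDNESS",
    "LabeledMatrix",
    "PsdReport",
    "build_relatedness_matrix",
    "build_home_matrix",
    "subset_matrix",
    "validate_psd",
    "read_matrix_csv",
    "write_matrix_csv",
]

#: Pedigree-class -> expected genome-sharing coefficient.
PAIR_CLASS_RELATEDNESS: dict[str, float] = {
    "MZ": 1.0,
    "full_or_DZ": 0.5,
    "half": 0.25,
    "unrelated": 0.0,
}

#: Inverse lookup used when classifying an existing coefficient.
RELATEDNESS_PAIR_CLASS: dict[float, str] = {
    v: k for k, v in PAIR_CLASS_RELATEDNESS.items()
}


@dataclass(frozen=True)
class LabeledMatrix:
    """Symmetric pairwise matrix indexed by child ids.

    Parameters
    ----------
    ids : ordered child identifiers, one per row/column.
    values : symmetric square float array, unit diagonal.
    kind : ``"relatedness"`` or ``"home_sharing"``.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        n = len(self.ids)
        if vals.shape != (n, n):
            raise ValueError(
                f"matrix shape {vals.shape} does not match {n} ids"
            )
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in LabeledMatrix")
        if not np.array_equal(vals, vals.T):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(vals), 1.0):
            raise ValueError("diagonal entries must all be 1.0")
        if self.kind not in ("relatedness", "home_sharing"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, child_id: str) -> int:
        try:
            return self.ids.index(str(child_id))
        except ValueError:
            raise KeyError(f"id {child_id!r} not in matrix") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


@dataclass(frozen=True)
class PsdReport:
    """Positive-semidefiniteness diagnostic for a component matrix."""

    min_eigenvalue: float
    tolerance: float
    passed: bool
    flagged_kind: str = field(default="")


def build_relatedness_matrix(
    pair_relationships: Iterable[tuple[str, str, str]],
    cohort_ids: Sequence[str],
) -> LabeledMatrix:
    """Assemble K from per-pair pedigree classes.

    Unlisted pairs default to unrelated (coefficient 0.0).  Conflicting
    labels for the same unordered pair raise; self-pairs raise.  Triads in
    which two biological links meet at a child but the closing pair is
    labelled unrelated are reported as warnings (labels are trusted
    verbatim, never transitively completed).
    """
    ids = [str(i) for i in cohort_ids]
    index = {cid: k for k, cid in enumerate(ids)}
    n = len(ids)
    K = np.eye(n)
    seen: dict[frozenset[str], str] = {}
    for id_a, id_b, pair_class in pair_relationships:
        a, b = str(id_a), str(id_b)
        if a == b:
            raise ValueError(f"self-pair ({a}, {b}) in relationship list")
        if pair_class not in PAIR_CLASS_RELATEDNESS:
            raise ValueError(
                f"unknown pair class {pair_class!r} for pair ({a}, {b}); "
                f"expected one of {sorted(PAIR_CLASS_RELATEDNESS)}"
            )
        for cid in (a, b):
            if cid not in index:
                raise KeyError(f"id {cid!r} not in cohort")
        key = frozenset((a, b))
        if key in seen and seen[key] != pair_class:
            raise ValueError(
                f"conflicting labels for pair ({a}, {b}): "
                f"{seen[key]!r} vs {pair_class!r}"
            )
        seen[key] = pair_class
        r = PAIR_CLASS_RELATEDNESS[pair_class]
        ia, ib = index[a], index[b]
        K[ia, ib] = K[ib, ia] = r
    _warn_inconsistent_triads(ids, K)
    return LabeledMatrix(ids=tuple(ids), values=K, kind="relatedness")


def _warn_inconsistent_triads(ids: Sequence[str], K: np.ndarray) -> None:
    # Related through a shared sibling but labelled unrelated to each other:
    # plausible (half-sibs through different parents) yet worth surfacing.
    n = len(ids)
    if n > 400:  # diagnostic only; skip on large cohorts
        return
    related = K > 0
    np.fill_diagonal(related, False)
    for j in range(n):
        partners = np.flatnonzero(related[j])
        for x in range(len(partners)):
            for y in range(x + 1, len(partners)):
                i, k = partners[x], partners[y]
                if K[i, j] >= 0.5 and K[j, k] >= 0.5 and K[i, k] == 0.0:
                    warnings.warn(
                        f"triad ({ids[i]}, {ids[j]}, {ids[k]}): two full-sib "
                        "links meet at a child but the closing pair is "
                        "labelled unrelated; labels kept verbatim",
                        stacklevel=3,
                    )


def build_home_matrix(
    household_assignment: Mapping[str, str],
    cohort_ids: Sequence[str] | None = None,
) -> LabeledMatrix:
    """Assemble H with H[i, j] = 1 iff i and j share a household."""
    if cohort_ids is None:
        ids = [str(i) for i in household_assignment]
    else:
        ids = [str(i) for i in cohort_ids]
        missing = [i for i in ids if i not in household_assignment]
        if missing:
            raise KeyError(f"ids missing from household assignment: {missing}")
    hh = np.array([str(household_assignment[i]) for i in ids], dtype=object)
    H = (hh[:, None] == hh[None, :]).astype(float)
    return LabeledMatrix(ids=tuple(ids), values=H, kind="home_sharing")


def subset_matrix(m: LabeledMatrix, keep_ids: Sequence[str]) -> LabeledMatrix:
    """Principal submatrix in ``keep_ids`` order."""
    keep = [str(i) for i in keep_ids]
    idx = np.array([m.index_of(i) for i in keep], dtype=int)
    return LabeledMatrix(
        ids=tuple(keep), values=m.values[np.ix_(idx, idx)], kind=m.kind
    )


def validate_psd(m: LabeledMatrix, tolerance: float = 1e-8) -> PsdReport:
    """Report the smallest eigenvalue; flag if below ``-tolerance``.

    K with MZ pairs and H with any shared home are singular by design
    (duplicate rows); that is a pass here — the fitted covariance always
    adds sigma2_E * I.
    """
    w = np.linalg.eigvalsh((m.values + m.values.T) / 2.0)
    lam = float(w[0])
    return PsdReport(
        min_eigenvalue=lam,
        tolerance=float(tolerance),
        passed=lam >= -tolerance,
        flagged_kind=m.kind if lam < -tolerance else "",
    )


def read_matrix_csv(path, kind: str) -> LabeledMatrix:
    """Read a square matrix CSV (header row + index column of child ids)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        # allow same id set in a different order
        if set(df.index) != set(df.columns):
            raise ValueError("matrix CSV row and column ids differ")
        df = df.loc[:, list(df.index)]
    return LabeledMatrix(
        ids=tuple(df.index), values=df.to_numpy(dtype=float), kind=kind
    )


def write_matrix_csv(m: LabeledMatrix, path) -> None:
    m.to_frame().to_csv(path, index_label="id")
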