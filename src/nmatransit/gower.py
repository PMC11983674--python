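"""Weighted Gower dissimilarity over mixed-type study characteristics.

The dissimilarity between two studies x and y over Z characteristics is the
weighted average of per-characteristic dissimilarities, restricted to
characteristics observed in both studies:

    d(x, y) = sum_i w_i * delta_xy,i * d(x, y)_i  /  sum_i w_i * delta_xy,i

where ``delta_xy,i`` is 1 when characteristic i is observed in both studies and
0 otherwise, and

* quantitative: ``d_i = |x_i - y_i| / R_i`` with ``R_i`` the characteristic's
  range (observed min-max over studies, or a user-supplied override),
* nominal/binary: ``d_i = 1`` if the categories differ, else 0,
* ordinal: ``d_i = |rank(x_i) - rank(y_i)| / RR_i`` with ranks taken from the
  declared level order and ``RR_i`` the range of observed ranks.

All values fall in [0, 1]; a pair sharing no observed characteristic has an
undefined dissimilarity, which is flagged rather than silently set to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import ComparisonTable, StudyDataset
from .specs import CharacteristicSpec


@dataclass
class DistMatrix:
    """Symmetric pairwise dissimilarity matrix with an undefined-pair mask.

    ``values[i, j]`` is the weighted Gower dissimilarity between observations
    i and j (NaN where undefined); ``defined[i, j]`` is False only for pairs
    with no co-observed characteristic.  The diagonal is exactly zero.
    """

    labels: list
    values: np.ndarray
    defined: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.defined = np.asarray(self.defined, dtype=bool)
        n = len(self.labels)
        if self.values.shape != (n, n) or self.defined.shape != (n, n):
            raise ValueError("matrix shape does not match the label count")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_undefined_pairs(self) -> int:
        iu = np.triu_indices(self.n, k=1)
        return int((~self.defined[iu]).sum())

    def is_fully_defined(self) -> bool:
        return self.n_undefined_pairs == 0

    def condensed(self) -> np.ndarray:
        """Condensed upper-triangle vector (requires a fully defined matrix)."""
        if not self.is_fully_defined():
            raise ValueError(
                f"{self.n_undefined_pairs} pair(s) share no observed "
                "characteristic; resolve them (drop rows or supply data) "
                "before clustering"
            )
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def characteristic_dissimilarity(
    x,
    y,
    spec: CharacteristicSpec,
    range_i: Optional[float] = None,
) -> tuple[float, int]:
    """Per-characteristic dissimilarity ``(d_i, delta)`` between two values.

    Returns ``(nan, 0)`` when either value is missing.  ``range_i`` is the
    normalising range for quantitative (R_i) or ordinal (RR_i, rank range)
    characteristics; a zero range with unequal values is degenerate.
    """
    if x is None or y is None:
        return (float("nan"), 0)
    if spec.ctype in ("nominal", "binary"):
        if str(x) not in spec.levels or str(y) not in spec.levels:
            raise ValueError(
                f"characteristic {spec.name!r}: value outside declared levels"
            )
        return (0.0 if str(x) == str(y) else 1.0, 1)
    if spec.is_ordinal:
        rx, ry = spec.rank(x), spec.rank(y)
        if rx == ry:
            return (0.0, 1)
        if range_i is None or range_i <= 0:
            raise ValueError(
                f"characteristic {spec.name!r}: degenerate range for unequal values"
            )
        return (abs(rx - ry) / range_i, 1)
    # quantitative
    fx, fy = float(x), float(y)
    if fx == fy:
        return (0.0, 1)
    if range_i is None or range_i <= 0:
        raise ValueError(
            f"characteristic {spec.name!r}: degenerate range for unequal values"
        )
    return (abs(fx - fy) / range_i, 1)


def gower_distance(
    row_x: dict,
    row_y: dict,
    specs: Sequence[CharacteristicSpec],
    ranges: dict,
) -> float:
    """Weighted Gower dissimilarity between two observations.

    ``ranges`` maps characteristic name to its normalising range (may omit
    purely categorical characteristics).  Returns NaN when the pair shares no
    co-observed characteristic with positive weight.
    """
    num = 0.0
    den = 0.0
    for spec in specs:
        d_i, delta = characteristic_dissimilarity(
            row_x.get(spec.name), row_y.get(spec.name), spec, ranges.get(spec.name)
        )
        if delta:
            num += spec.weight * d_i
            den += spec.weight * delta
    if den == 0:
        return float("nan")
    return num / den


def compute_ranges(ds: StudyDataset) -> dict:
    """Normalising ranges per characteristic, from study-level values.

    Quantitative: observed min-max over studies (a multi-arm study counts
    once), unless the spec carries a range override.  Ordinal: range of the
    observed integer level codes.  A constant quantitative characteristic gets
    range 0 with a warning; it then contributes ``d_i = 0`` for every pair
    (all studies agree, so it carries no dissimilarity signal).
    """
    ranges: dict = {}
    for spec in ds.specs:
        if spec.is_quantitative:
            if spec.range_override is not None:
                ranges[spec.name] = float(spec.range_override)
                continue
            vals = [float(st.values[spec.name]) for st in ds.studies
                    if st.values.get(spec.name) is not None]
            r = (max(vals) - min(vals)) if vals else 0.0
            if r == 0.0:
                warnings.warn(
                    f"quantitative characteristic {spec.name!r} is constant "
                    "across studies; it contributes zero dissimilarity",
                    UserWarning,
                    stacklevel=2,
                )
            ranges[spec.name] = r
        elif spec.is_ordinal:
            codes = [spec.rank(st.values[spec.name]) for st in ds.studies
                     if st.values.get(spec.name) is not None]
            ranges[spec.name] = float(max(codes) - min(codes)) if codes else 0.0
    return ranges


def gower_matrix(ct: ComparisonTable, ranges: dict) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised pairwise weighted Gower over all rows of ``ct``.

    Returns ``(values, defined)`` square arrays.  Same-study row pairs (the
    expanded comparisons of one multi-arm study) are exactly 0 by construction
    since they share identical values.
    """
    n = ct.n_rows
    specs = ct.specs
    w = np.array([s.weight for s in specs], dtype=float)

    # per-characteristic encodings
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for j, spec in enumerate(specs):
        col = [r.values.get(spec.name) for r in ct.rows]
        observed = np.array([v is not None for v in col])
        if spec.is_quantitative or spec.is_ordinal:
            r_j = float(ranges.get(spec.name) or 0.0)
            vals = np.array(
                [
                    (float(v) if spec.is_quantitative else spec.rank(v))
                    if o else 0.0
                    for v, o in zip(col, observed)
                ]
            )
            diff = np.abs(vals[:, None] - vals[None, :])
            if r_j > 0:
                d = diff / r_j
            else:
                if np.any(diff[np.ix_(observed, observed)] > 0):
                    raise ValueError(
                        f"characteristic {spec.name!r}: degenerate range for "
                        "unequal values"
                    )
                d = np.zeros_like(diff)
        else:
            codes = np.array([spec.levels.index(str(v)) if o else -1
                              for v, o in zip(col, observed)])
            d = (codes[:, None] != codes[None, :]).astype(float)
        delta = observed[:, None] & observed[None, :]
        num += np.where(delta, d, 0.0) * w[j]
        den += delta * w[j]

    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(den > 0, num / den, np.nan)
    defined = den > 0
    np.fill_diagonal(values, 0.0)
    np.fill_diagonal(defined, True)
    # rows expanded from one multi-arm study carry identical values -> force
    # exact zeros (guards against float noise and all-missing studies)
    sids = ct.row_study_ids()
    same = np.array([[a == b for b in sids] for a in sids])
    values[same] = 0.0
    defined |= same
    # symmetry to the last bit
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return values, defined


def build_dissimilarity_matrix(
    ct: ComparisonTable, ds: Optional[StudyDataset] = None, ranges: Optional[dict] = None
) -> DistMatrix:
    """Assemble the expanded pairwise dissimilarity matrix ``{d}``.

    Ranges default to the study-level observed ranges of ``ds`` (pass the
    parent dataset so multi-arm studies are not double-counted); when ``ds``
    is omitted they are computed from the expanded rows, which gives the same
    min-max because expansion only duplicates values.
    """
    if ranges is None:
        if ds is not None:
            ranges = compute_ranges(ds)
        else:
            ranges = _ranges_from_rows(ct)
    values, defined = gower_matrix(ct, ranges)
    dm = DistMatrix(ct.labels, values, defined)
    if dm.n_undefined_pairs:
        warnings.warn(
            f"{dm.n_undefined_pairs} observation pair(s) share no observed "
            "characteristic; their dissimilarity is undefined and excluded "
            "from downstream aggregation",
            UserWarning,
            stacklevel=2,
        )
    return dm


def _ranges_from_rows(ct: ComparisonTable) -> dict:
    ranges: dict = {}
    for spec in ct.specs:
        if spec.is_quantitative:
            if spec.range_override is not None:
                ranges[spec.name] = float(spec.range_override)
                continue
            vals = [float(r.values[spec.name]) for r in ct.rows
                    if r.values.get(spec.name) is not None]
            ranges[spec.name] = (max(vals) - min(vals)) if vals else 0.0
        elif spec.is_ordinal:
            codes = [spec.rank(r.values[spec.name]) for r in ct.rows
                     if r.values.get(spec.name) is not None]
            ranges[spec.name] = float(max(codes) - min(codes)) if codes else 0.0
    return ranges


class GowerDissimilarity(BaseEstimator, TransformerMixin):
    """Pairwise weighted Gower dissimilarity as an sklearn transformer.

    ``fit`` learns the normalising ranges from a :class:`StudyDataset` (or a
    :class:`ComparisonTable`); ``transform`` expands the input (if needed) and
    returns the square dissimilarity matrix, suitable for any downstream
    estimator accepting ``metric="precomputed"``.

    Attributes
    ----------
    ranges_ : dict
        Learned normalising range per quantitative/ordinal characteristic.
    labels_ : list of str
        Row labels ("study_id: comparison") of the last transformed matrix.
    """

    def __init__(self, ranges: Optional[dict] = None):
        self.ranges = ranges

    def fit(self, X, y=None):
        from .dataset import expand_comparisons  # local to avoid cycle noise

        if isinstance(X, StudyDataset):
            self.ranges_ = dict(self.ranges) if self.ranges else compute_ranges(X)
        elif isinstance(X, ComparisonTable):
            self.ranges_ = dict(self.ranges) if self.ranges else _ranges_from_rows(X)
        else:
            raise TypeError("X must be a StudyDataset or ComparisonTable")
        return self

    def transform(self, X) -> np.ndarray:
        from .dataset import expand_comparisons

        if not hasattr(self, "ranges_"):
            raise RuntimeError("GowerDissimilarity is not fitted; call fit first")
        ct = expand_comparisons(X) if isinstance(X, StudyDataset) else X
        dm = build_dissimilarity_matrix(ct, ranges=self.ranges_)
        self.labels_ = dm.labels
        self.dist_matrix_ = dm
        return dm.values

    def fit_transform(self, X, y=None, **kwargs) -> np.ndarray:
        return self.fit(X).transform(X)
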