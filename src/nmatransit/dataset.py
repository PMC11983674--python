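"""Study extraction tables and their expansion to comparison-level rows.

A :class:`StudyDataset` holds one row per study of a connected treatment
network: a study id, the treatment arms, and the values of Z study-level
aggregate characteristics (missing entries allowed).  Because a study with
``T`` arms informs ``C(T, 2)`` treatment comparisons, the dataset is expanded
into a :class:`ComparisonTable` with one row per within-study treatment pair;
rows originating from the same multi-arm study carry identical characteristic
values.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .specs import CharacteristicSpec, dump_config, load_config, normalize_summary_weights

#: tokens parsed as a missing cell (case-insensitive), besides the empty string
DEFAULT_MISSING_TOKENS = ("", "na", "nan", "n/a", "none", ".")


def comparison_label(a: str, b: str) -> str:
    """Canonical label for an unordered treatment pair: sorted, ``"A vs B"``."""
    x, y = sorted((str(a), str(b)))
    return f"{x} vs {y}"


@dataclass(frozen=True)
class Study:
    study_id: str
    arms: tuple
    values: dict  # characteristic name -> value (str/float) or None if missing

    @property
    def n_arms(self) -> int:
        return len(self.arms)

    def comparisons(self) -> list[str]:
        """The ``C(T,2)`` canonical comparison labels of this study."""
        return [comparison_label(a, b) for a, b in itertools.combinations(sorted(self.arms), 2)]


class StudyDataset:
    """Validated study-level extraction table for one treatment network."""

    def __init__(self, studies: Sequence[Study], specs: Sequence[CharacteristicSpec]):
        self.specs = list(specs)
        self.studies = list(studies)
        self._validate()

    # -- basic shape ------------------------------------------------------
    @property
    def n_studies(self) -> int:
        return len(self.studies)

    @property
    def n_characteristics(self) -> int:
        return len(self.specs)

    @property
    def characteristic_names(self) -> list[str]:
        return [s.name for s in self.specs]

    @property
    def treatments(self) -> list[str]:
        return sorted({t for s in self.studies for t in s.arms})

    def spec(self, name: str) -> CharacteristicSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    # -- validation -------------------------------------------------------
    def _validate(self) -> None:
        if not self.specs:
            raise ValueError("at least one characteristic is required")
        ids = [s.study_id for s in self.studies]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValueError(f"duplicate study_id(s): {sorted(dup)}")
        for st in self.studies:
            if len(st.arms) < 2:
                raise ValueError(f"study {st.study_id!r}: fewer than two arms")
            if len(set(st.arms)) != len(st.arms):
                raise ValueError(f"study {st.study_id!r}: duplicate arms")
            for spec in self.specs:
                v = st.values.get(spec.name)
                if v is None:
                    continue
                if spec.is_quantitative:
                    try:
                        float(v)
                    except (TypeError, ValueError):
                        raise ValueError(
                            f"study {st.study_id!r}, column {spec.name!r}: "
                            f"non-numeric value {v!r} in quantitative column"
                        ) from None
                else:
                    if str(v) not in spec.levels:
                        raise ValueError(
                            f"study {st.study_id!r}, column {spec.name!r}: value "
                            f"{v!r} outside declared levels {list(spec.levels)}"
                        )
        if self.studies and not self.is_connected():
            warnings.warn(
                "the treatment network implied by the study arms is not "
                "connected; dissimilarities remain computable but indirect "
                "comparisons across components are not meaningful",
                UserWarning,
                stacklevel=3,
            )

    def network(self) -> nx.Graph:
        """Treatment network: nodes are treatments, edges observed comparisons."""
        g = nx.Graph()
        for st in self.studies:
            g.add_nodes_from(st.arms)
            g.add_edges_from(itertools.combinations(st.arms, 2))
        return g

    def is_connected(self) -> bool:
        g = self.network()
        return g.number_of_nodes() > 0 and nx.is_connected(g)

    # -- frames and IO ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: study_id, arms (semicolon-joined), characteristics."""
        rows = []
        for st in self.studies:
            row = {"study_id": st.study_id, "arms": ";".join(st.arms)}
            for spec in self.specs:
                v = st.values.get(spec.name)
                if v is None:
                    row[spec.name] = np.nan
                elif spec.is_quantitative:
                    row[spec.name] = float(v)
                else:
                    row[spec.name] = str(v)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write(self, table_path, config_path) -> None:
        """Write the CSV + YAML pair consumed by :func:`load_dataset`."""
        self.to_csv(table_path)
        dump_config(self.specs, config_path)

    def missing_fraction(self, expanded: bool = True) -> float:
        """Fraction of missing characteristic cells.

        With ``expanded=True`` the fraction is computed over the
        comparison-level table (multi-arm studies counted once per within-study
        treatment pair), matching how the framework summarises data
        availability alongside the expanded dissimilarity matrix.
        """
        total = 0
        missing = 0
        for st in self.studies:
            mult = math.comb(st.n_arms, 2) if expanded else 1
            for spec in self.specs:
                total += mult
                if st.values.get(spec.name) is None:
                    missing += mult
        return missing / total if total else 0.0

    def __eq__(self, other) -> bool:
        if not isinstance(other, StudyDataset):
            return NotImplemented
        return self.specs == other.specs and self.studies == other.studies

    def __repr__(self) -> str:
        return (
            f"StudyDataset(N={self.n_studies}, Z={self.n_characteristics}, "
            f"T={len(self.treatments)})"
        )


@dataclass(frozen=True)
class ComparisonRow:
    study_id: str
    comparison: str
    values: dict


class ComparisonTable:
    """One row per within-study treatment pair (the expanded observations)."""

    def __init__(self, rows: Sequence[ComparisonRow], specs: Sequence[CharacteristicSpec]):
        self.rows = list(rows)
        self.specs = list(specs)
        if len(self.comparisons) < 2:
            raise ValueError(
                "fewer than two distinct treatment comparisons; the framework "
                "needs P >= 2 to compare comparisons"
            )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def labels(self) -> list[str]:
        """Row identifiers, ``"study_id: comparison"``."""
        return [f"{r.study_id}: {r.comparison}" for r in self.rows]

    @property
    def comparisons(self) -> list[str]:
        """The P distinct observed comparisons, in order of first appearance."""
        seen: dict[str, None] = {}
        for r in self.rows:
            seen.setdefault(r.comparison, None)
        return list(seen)

    @property
    def n_comparisons(self) -> int:
        return len(self.comparisons)

    def study_counts(self) -> dict[str, int]:
        """Per-comparison number of informing rows ``h``."""
        out = {c: 0 for c in self.comparisons}
        for r in self.rows:
            out[r.comparison] += 1
        return out

    def indices_of(self, comparison: str) -> np.ndarray:
        idx = [i for i, r in enumerate(self.rows) if r.comparison == comparison]
        if not idx:
            raise KeyError(f"comparison {comparison!r} not observed in the network")
        return np.asarray(idx, dtype=int)

    def row_study_ids(self) -> list[str]:
        return [r.study_id for r in self.rows]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.rows:
            d = {"study_id": r.study_id, "comparison": r.comparison}
            for spec in self.specs:
                v = r.values.get(spec.name)
                d[spec.name] = np.nan if v is None else v
            rows.append(d)
        return pd.DataFrame(rows)


def expand_comparisons(ds: StudyDataset) -> ComparisonTable:
    """Expand multi-arm studies into comparison-level observations.

    A study with ``T`` arms yields ``C(T, 2)`` rows sharing the study's
    characteristic values, so the expanded table has ``sum_i C(T_i, 2)`` rows.
    """
    rows = []
    for st in ds.studies:
        for comp in st.comparisons():
            rows.append(ComparisonRow(st.study_id, comp, dict(st.values)))
    return ComparisonTable(rows, ds.specs)


def _parse_arms(row: pd.Series, arm_cols: list[str]) -> tuple:
    if "arms" in row.index and isinstance(row["arms"], str) and row["arms"].strip():
        arms = [a.strip() for a in str(row["arms"]).split(";") if a.strip()]
    else:
        arms = [str(row[c]).strip() for c in arm_cols
                if pd.notna(row[c]) and str(row[c]).strip()]
    return tuple(arms)


def load_dataset(
    table_path,
    config_path,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
) -> StudyDataset:
    """Read the study extraction CSV and characteristic YAML configuration.

    The CSV needs a ``study_id`` column and either a single semicolon-delimited
    ``arms`` column or wide ``arm1..armK`` columns, followed by one column per
    configured characteristic.  Cells equal to one of ``missing_tokens``
    (case-insensitive) parse as missing.
    """
    specs = load_config(config_path)
    df = pd.read_csv(table_path, dtype=str, keep_default_na=False)
    if "study_id" not in df.columns:
        raise ValueError(f"{table_path}: missing required column 'study_id'")
    arm_cols = sorted(
        (c for c in df.columns if c.lower().startswith("arm") and c.lower() != "arms"),
        key=lambda c: (len(c), c),
    )
    known = {"study_id", "arms", *arm_cols, *(s.name for s in specs)}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise ValueError(
            f"{table_path}: unknown column(s) {unknown}; every characteristic "
            "column must appear in the configuration"
        )
    missing_set = {t.lower() for t in missing_tokens}
    studies = []
    for i, row in df.iterrows():
        sid = str(row["study_id"]).strip()
        arms = _parse_arms(row, arm_cols)
        if len(arms) < 2:
            raise ValueError(f"{table_path} row {i} (study {sid!r}): fewer than two arms")
        values: dict = {}
        for spec in specs:
            if spec.name not in df.columns:
                raise ValueError(f"{table_path}: configured column {spec.name!r} absent")
            raw = str(row[spec.name]).strip()
            if raw.lower() in missing_set:
                values[spec.name] = None
            elif spec.is_quantitative:
                try:
                    values[spec.name] = float(raw)
                except ValueError:
                    raise ValueError(
                        f"{table_path} row {i}, column {spec.name!r}: "
                        f"non-numeric value {raw!r} in quantitative column"
                    ) from None
            else:
                values[spec.name] = raw
        studies.append(Study(sid, arms, values))
    return StudyDataset(studies, specs)
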