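"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from nmatransit import (
    CharacteristicSpec,
    Study,
    StudyDataset,
    expand_comparisons,
    fictional_fixture,
)


@pytest.fixture(scope="session")
def fictional():
    return fictional_fixture()


@pytest.fixture(scope="session")
def fictional_table(fictional):
    return expand_comparisons(fictional)


def random_mixed_dataset(seed: int, n_max: int = 10, z_max: int = 5,
                         missing_rate: float = 0.2) -> StudyDataset:
    """Random mixed-type dataset for oracle comparisons (deterministic in seed)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, n_max + 1))
    z = int(rng.integers(1, z_max + 1))
    specs = []
    for j in range(z):
        ctype = rng.choice(["quantitative", "binary", "nominal", "ordinal"])
        if ctype == "quantitative":
            specs.append(CharacteristicSpec(f"x{j}", "quantitative",
                                            weight=float(rng.uniform(0.1, 2.0))))
        elif ctype == "binary":
            specs.append(CharacteristicSpec(f"x{j}", "binary", levels=("no", "yes"),
                                            weight=float(rng.uniform(0.1, 2.0))))
        elif ctype == "nominal":
            specs.append(CharacteristicSpec(f"x{j}", "nominal",
                                            levels=("a", "b", "c"),
                                            weight=float(rng.uniform(0.1, 2.0))))
        else:
            specs.append(CharacteristicSpec(f"x{j}", "ordinal",
                                            levels=("low", "mid", "high"),
                                            weight=float(rng.uniform(0.1, 2.0))))
    treatments = ["A", "B", "C", "D"]
    studies = []
    for i in range(n):
        n_arms = int(rng.choice([2, 2, 2, 3]))
        arms = tuple(rng.choice(treatments, size=n_arms, replace=False))
        values = {}
        for spec in specs:
            if rng.random() < missing_rate:
                values[spec.name] = None
            elif spec.ctype == "quantitative":
                values[spec.name] = float(np.round(rng.uniform(-5, 5), 3))
            else:
                values[spec.name] = str(rng.choice(spec.levels))
        studies.append(Study(f"S{i}", arms, values))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # random designs may be disconnected
        return StudyDataset(studies, specs)


def oracle_gower(row_x: dict, row_y: dict, specs, ranges: dict) -> float:
    """Naive re-implementation of the weighted Gower coefficient.

    Loops characteristic by characteristic applying the defining formulas
    directly; independent of the vectorised production path.
    """
    num = den = 0.0
    for spec in specs:
        x, y = row_x.get(spec.name), row_y.get(spec.name)
        if x is None or y is None:
            continue
        if spec.ctype == "quantitative":
            r = ranges.get(spec.name, 0.0)
            d = 0.0 if float(x) == float(y) else abs(float(x) - float(y)) / r
        elif spec.ctype == "ordinal":
            rx = spec.levels.index(str(x))
            ry = spec.levels.index(str(y))
            r = ranges.get(spec.name, 0.0)
            d = 0.0 if rx == ry else abs(rx - ry) / r
        else:
            d = 0.0 if str(x) == str(y) else 1.0
        num += spec.weight * d
        den += spec.weight
    return num / den if den > 0 else float("nan")


def oracle_ranges(ds: StudyDataset) -> dict:
    """Observed study-level ranges, re-derived naively."""
    out = {}
    for spec in ds.specs:
        if spec.ctype == "quantitative":
            vals = [float(s.values[spec.name]) for s in ds.studies
                    if s.values.get(spec.name) is not None]
            out[spec.name] = (max(vals) - min(vals)) if vals else 0.0
        elif spec.ctype == "ordinal":
            codes = [spec.levels.index(str(s.values[spec.name])) for s in ds.studies
                     if s.values.get(spec.name) is not None]
            out[spec.name] = float(max(codes) - min(codes)) if codes else 0.0
    return out


def set_partitions(items):
    """All partitions of ``items`` into nonempty blocks (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part
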