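"""Characteristic metadata: type, weight, levels, range override.

Study-level aggregate characteristics in a treatment network come in mixed
types (quantitative, binary, nominal, ordinal).  Each characteristic carries a
nonnegative weight ``w_i`` used by the weighted Gower coefficient; when one
underlying quantity is represented by several summary statistics (e.g. minimum
and maximum of the same lung-function measure) the statistics share a
``summary_group`` and their weights are normalised to sum to one, so the
underlying characteristic still contributes a total weight of one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import yaml

CTYPES = ("quantitative", "binary", "nominal", "ordinal")


@dataclass(frozen=True)
class CharacteristicSpec:
    """Metadata for one study-level characteristic column.

    Parameters
    ----------
    name : str
        Column name in the extraction table.
    ctype : {"quantitative", "binary", "nominal", "ordinal"}
        Measurement type. Binary columns are handled as nominal with two
        levels.
    weight : float, default 1.0
        Nonnegative weight ``w_i`` in the weighted Gower coefficient.
    levels : tuple of str, optional
        Category labels; required for nominal/ordinal/binary. For ordinal
        columns the order of ``levels`` defines the rank order.
    range_override : float, optional
        User-supplied range ``R_i`` replacing the observed min-max range of a
        quantitative characteristic (e.g. a range taken from the systematic
        review's inclusion criteria, which is robust to outlying studies).
    summary_group : str, optional
        Tag shared by several summary statistics of one underlying
        characteristic; member weights are normalised to sum to one.
    """

    name: str
    ctype: str
    weight: float = 1.0
    levels: Optional[tuple] = None
    range_override: Optional[float] = None
    summary_group: Optional[str] = None

    def __post_init__(self):
        if self.ctype not in CTYPES:
            raise ValueError(
                f"characteristic {self.name!r}: unknown type {self.ctype!r}; "
                f"expected one of {CTYPES}"
            )
        if self.weight < 0:
            raise ValueError(f"characteristic {self.name!r}: weight must be >= 0")
        if self.ctype in ("binary", "nominal", "ordinal"):
            if self.levels is None or len(self.levels) < 2:
                raise ValueError(
                    f"characteristic {self.name!r}: {self.ctype} columns must "
                    "declare at least 2 levels"
                )
            if len(set(self.levels)) != len(self.levels):
                raise ValueError(f"characteristic {self.name!r}: duplicate levels")
            if self.ctype == "binary" and len(self.levels) != 2:
                raise ValueError(
                    f"characteristic {self.name!r}: binary columns take exactly 2 levels"
                )
        if self.levels is not None:
            object.__setattr__(self, "levels", tuple(str(v) for v in self.levels))
        if self.range_override is not None and self.range_override <= 0:
            raise ValueError(
                f"characteristic {self.name!r}: range override must be > 0"
            )

    @property
    def is_quantitative(self) -> bool:
        return self.ctype == "quantitative"

    @property
    def is_ordinal(self) -> bool:
        return self.ctype == "ordinal"

    def rank(self, value: str) -> int:
        """Integer code of ``value`` in the declared level order."""
        return self.levels.index(str(value))


def normalize_summary_weights(
    specs: Sequence[CharacteristicSpec],
) -> list[CharacteristicSpec]:
    """Rescale weights within each summary group to sum to one.

    Characteristics without a ``summary_group`` are left untouched.  A group
    whose declared weights sum to zero is rejected.
    """
    groups: dict[str, float] = {}
    for s in specs:
        if s.summary_group is not None:
            groups[s.summary_group] = groups.get(s.summary_group, 0.0) + s.weight
    out = []
    for s in specs:
        if s.summary_group is None:
            out.append(s)
            continue
        total = groups[s.summary_group]
        if total <= 0:
            raise ValueError(
                f"summary group {s.summary_group!r}: member weights sum to zero"
            )
        out.append(replace(s, weight=s.weight / total))
    return out


def load_config(path) -> list[CharacteristicSpec]:
    """Read a YAML characteristic configuration.

    The file holds a list (optionally under a ``characteristics`` key) of
    mappings with keys ``name``, ``type``, and optional ``weight``, ``levels``,
    ``range``, ``summary_group``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if isinstance(raw, dict):
        raw = raw.get("characteristics", raw)
    if not isinstance(raw, list):
        raise ValueError(f"{path}: expected a list of characteristic entries")
    specs = []
    for i, entry in enumerate(raw):
        if not isinstance(entry, dict) or "name" not in entry or "type" not in entry:
            raise ValueError(f"{path}: entry {i} must declare 'name' and 'type'")
        specs.append(
            CharacteristicSpec(
                name=str(entry["name"]),
                ctype=str(entry["type"]),
                weight=float(entry.get("weight", 1.0)),
                levels=tuple(entry["levels"]) if entry.get("levels") else None,
                range_override=entry.get("range"),
                summary_group=entry.get("summary_group"),
            )
        )
    return normalize_summary_weights(specs)


def dump_config(specs: Sequence[CharacteristicSpec], path) -> None:
    """Write specs back to YAML (inverse of :func:`load_config`)."""
    entries = []
    for s in specs:
        e: dict = {"name": s.name, "type": s.ctype, "weight": float(s.weight)}
        if s.levels is not None:
            e["levels"] = list(s.levels)
        if s.range_override is not None:
            e["range"] = float(s.range_override)
        if s.summary_group is not None:
            e["summary_group"] = s.summary_group
        entries.append(e)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"characteristics": entries}, fh, sort_keys=False)
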