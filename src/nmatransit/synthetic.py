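"""Synthetic treatment networks with planted clustering structure.

Two kinds of synthetic data live here:

* :func:`generate_network` draws networks of N studies over T treatments with
  characteristic values sampled per *planted cluster* — quantitative values
  from cluster-specific normal distributions whose means are separated by a
  configurable ``shift`` (in within-cluster standard deviation units) and
  qualitative values from cluster-specific category distributions whose
  concentration grows with ``shift``.  ``shift = 0`` removes all signal.
  Missingness is applied completely at random.

* Fixed fixtures: the 7-study fictional triangle network used to walk through
  the framework, and two *synthetic stand-ins* for published extraction
  tables (a 27-study rheumatoid arthritis network and a 39-study COPD
  network) that replicate every documented structural property of the
  originals — network shape, per-comparison study counts, arm structure,
  characteristic types and the COPD missing-data pattern — while the
  characteristic values themselves are simulated.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dataset import ComparisonTable, Study, StudyDataset, comparison_label
from .specs import CharacteristicSpec, normalize_summary_weights


@dataclass
class GeneratorConfig:
    """Configuration of the planted-cluster network generator.

    ``comparison_design`` maps a tuple of arms to the number of studies with
    exactly those arms; when omitted, a star design over ``treatments`` is
    used with studies spread as evenly as possible over the edges.  ``shift``
    is the between-cluster mean separation in units of the within-cluster
    standard deviation: cluster ``c`` centres quantitative characteristic
    ``c mod n_quant`` at ``shift`` (others at 0), so every cluster pair is
    separated by ``shift`` standard deviations along two characteristics, and
    each cluster prefers its own category level with odds ``(1 + shift)^2``.

    Defaults emulate a modest systematic-review extraction table: ten
    characteristics (five quantitative, five nominal) over 24 two-arm
    studies of a three-treatment star network.
    """

    n_studies: int = 24
    treatments: Sequence[str] = ("A", "B", "C")
    comparison_design: Optional[dict] = None
    n_quant: int = 5
    n_qual: int = 5
    n_levels: Optional[int] = None  # default max(3, planted_clusters)
    planted_clusters: int = 2
    shift: float = 3.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_studies < 2:
            raise ValueError("need at least two studies")
        if self.shift < 0:
            raise ValueError("shift must be >= 0")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.planted_clusters < 1:
            raise ValueError("need at least one planted cluster")
        if self.n_quant + self.n_qual < 1:
            raise ValueError("need at least one characteristic")
        if self.n_levels is None:
            self.n_levels = max(3, self.planted_clusters)
        if self.n_levels < max(2, self.planted_clusters):
            raise ValueError(
                "n_levels must cover the planted clusters so each cluster "
                "can prefer a distinct category level"
            )


def _default_design(cfg: GeneratorConfig) -> list[tuple]:
    """Star design: arm pairs (treatment[0], treatment[i]) cycled over studies."""
    t = list(cfg.treatments)
    if len(t) < 2:
        raise ValueError("need at least two treatments")
    edges = [(t[0], ti) for ti in t[1:]]
    return [edges[i % len(edges)] for i in range(cfg.n_studies)]


def _design_list(cfg: GeneratorConfig) -> list[tuple]:
    if cfg.comparison_design is None:
        return _default_design(cfg)
    out = []
    for arms, count in cfg.comparison_design.items():
        out.extend([tuple(arms)] * int(count))
    return out


def generate_network(cfg: GeneratorConfig) -> tuple[StudyDataset, np.ndarray]:
    """Draw a synthetic network; returns the dataset and per-study planted labels.

    Fully reproducible under ``cfg.seed``.  Raises if the implied treatment
    network is disconnected.
    """
    rng = np.random.default_rng(cfg.seed)
    design = _design_list(cfg)
    n = len(design)

    specs: list[CharacteristicSpec] = []
    for i in range(cfg.n_quant):
        specs.append(CharacteristicSpec(f"quant_{i + 1}", "quantitative"))
    levels = tuple(f"lvl{j + 1}" for j in range(cfg.n_levels))
    for i in range(cfg.n_qual):
        specs.append(CharacteristicSpec(f"qual_{i + 1}", "nominal", levels=levels))

    planted = np.array([i % cfg.planted_clusters for i in range(n)])
    rng.shuffle(planted)

    # cluster-specific category distributions: each cluster prefers its own
    # level with odds (1 + shift)^2; shift = 0 is uniform (no signal)
    L = cfg.n_levels
    cat_probs = []
    for c in range(cfg.planted_clusters):
        p = np.ones(L)
        p[c % L] *= (1.0 + cfg.shift) ** 2
        cat_probs.append(p / p.sum())

    studies = []
    for i, arms in enumerate(design):
        c = planted[i]
        values: dict = {}
        for q in range(cfg.n_quant):
            mu = cfg.shift if cfg.n_quant and q == c % cfg.n_quant else 0.0
            values[f"quant_{q + 1}"] = float(rng.normal(mu, 1.0))
        for q in range(cfg.n_qual):
            values[f"qual_{q + 1}"] = str(rng.choice(levels, p=cat_probs[c]))
        for name in list(values):
            if rng.random() < cfg.missing_rate:
                values[name] = None
        studies.append(Study(f"S{i + 1:02d}", tuple(arms), values))

    ds = StudyDataset(studies, specs)
    if not ds.is_connected():
        raise ValueError("the configured comparison design yields a disconnected network")
    return ds, planted


def expand_planted_labels(ds: StudyDataset, planted: np.ndarray) -> np.ndarray:
    """Per-row planted labels aligned with the expanded comparison table."""
    out = []
    for st, lab in zip(ds.studies, planted):
        out.extend([lab] * math.comb(st.n_arms, 2))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Fixed fixtures
# ---------------------------------------------------------------------------


def fictional_fixture() -> StudyDataset:
    """The 7-study fictional triangle network (comparisons BA, CA, CB).

    Three studies compare B with A, two compare C with A and two compare C
    with B, over two quantitative characteristics (sample size, mean age) and
    one binary (adequate randomisation).  The values are this package's own
    construction: B-vs-A studies are large with young populations and adequate
    randomisation, C-vs-A studies small with old populations and inadequate
    randomisation, and C-vs-B studies sit in between — so each comparison is
    internally homogeneous while the comparisons differ markedly from one
    another.
    """
    specs = [
        CharacteristicSpec("sample_size", "quantitative"),
        CharacteristicSpec("mean_age", "quantitative"),
        CharacteristicSpec("adequate_randomization", "binary", levels=("no", "yes")),
    ]
    rows = [
        # study_id, arms, sample size, mean age, adequate randomisation
        ("S1", ("A", "B"), 360.0, 40.0, "yes"),
        ("S2", ("A", "B"), 380.0, 42.0, "yes"),
        ("S3", ("A", "B"), 400.0, 44.0, "yes"),
        ("S4", ("A", "C"), 60.0, 70.0, "no"),
        ("S5", ("A", "C"), 70.0, 72.0, "no"),
        ("S6", ("B", "C"), 200.0, 55.0, "yes"),
        ("S7", ("B", "C"), 210.0, 57.0, "yes"),
    ]
    studies = [
        Study(sid, arms, {"sample_size": n, "mean_age": age,
                          "adequate_randomization": rand})
        for sid, arms, n, age, rand in rows
    ]
    return StudyDataset(studies, specs)


def synthetic_rheumatoid_network(seed: int = 20250414) -> StudyDataset:
    """Synthetic stand-in for a 27-study rheumatoid arthritis star network.

    Structure mirrors the published review it stands in for: six biologic
    agents (ABA, ADA, ANA, ETA, INF, RIT) each compared against placebo, 27
    two-arm studies (every comparison informed by at least three), ten
    characteristics (three quantitative, seven qualitative) with no missing
    cells, and the anti-TNF flag fixed to "yes" exactly for the ADA, ETA and
    INF studies.  The characteristic *values* are simulated — this is not the
    published extraction table — so dissimilarity magnitudes computed from it
    do not reproduce the published ones.
    """
    rng = np.random.default_rng(seed)
    specs = [
        CharacteristicSpec("sample_size", "quantitative"),
        CharacteristicSpec("study_duration_months", "quantitative"),
        CharacteristicSpec("disease_duration_years", "quantitative"),
        CharacteristicSpec("concomitant_mtx", "binary", levels=("no", "yes")),
        CharacteristicSpec("ra_duration", "ordinal",
                           levels=("early", "established", "late")),
        CharacteristicSpec("anti_tnf", "binary", levels=("no", "yes")),
        CharacteristicSpec("prior_drugs_failed", "nominal",
                           levels=("dmards", "biologic", "none")),
        CharacteristicSpec("prior_tnf_failure", "binary", levels=("no", "yes")),
        CharacteristicSpec("combination_biologic", "binary", levels=("no", "yes")),
        CharacteristicSpec("naive_biologic", "binary", levels=("no", "yes")),
    ]
    counts = {"ABA": 4, "ADA": 6, "ANA": 3, "ETA": 6, "INF": 5, "RIT": 3}
    anti_tnf_agents = {"ADA", "ETA", "INF"}
    studies = []
    i = 0
    for agent, h in counts.items():
        tnf = agent in anti_tnf_agents
        for _ in range(h):
            i += 1
            values = {
                "sample_size": float(round(rng.lognormal(5.3, 0.6))),
                "study_duration_months": float(round(rng.uniform(3, 24))),
                "disease_duration_years": float(round(rng.uniform(0.5, 13), 1)),
                "concomitant_mtx": str(rng.choice(["no", "yes"],
                                                  p=[0.2, 0.8] if tnf else [0.5, 0.5])),
                "ra_duration": str(rng.choice(["early", "established", "late"],
                                              p=[0.25, 0.3, 0.45])),
                "anti_tnf": "yes" if tnf else "no",
                "prior_drugs_failed": str(rng.choice(["dmards", "biologic", "none"],
                                                     p=[0.8, 0.1, 0.1] if tnf
                                                     else [0.4, 0.4, 0.2])),
                "prior_tnf_failure": str(rng.choice(["no", "yes"],
                                                    p=[1.0, 0.0] if tnf else [0.6, 0.4])),
                "combination_biologic": str(rng.choice(["no", "yes"], p=[0.85, 0.15])),
                "naive_biologic": "yes" if tnf else str(rng.choice(["no", "yes"],
                                                                   p=[0.7, 0.3])),
            }
            studies.append(Study(f"RA{i:02d}", ("PBO", agent), values))
    return StudyDataset(studies, specs)


def synthetic_copd_network(seed: int = 20250415) -> StudyDataset:
    """Synthetic stand-in for a 39-study COPD network of eight treatments.

    Mirrors the documented structure of the review it stands in for: 29
    two-arm, 4 three-arm and 6 four-arm studies (so the expanded comparison
    table has 29 + 4*3 + 6*6 = 77 rows) forming 16 comparisons of BUD, BUD+,
    FLU, FLU+, FOR, SAL, TIO and PBO, with TIO vs FLU+ and TIO vs FOR as
    single-study comparisons and a small four-treatment subnetwork of PBO,
    BUD, BUD+ and FOR.  Eleven characteristics: eight quantitative (minimum
    and maximum mean FEV1 share a summary group, weight 0.5 each) and three
    qualitative, of which random allocation concealment and double blinding
    are adequate in every study.  Thirty of the 847 expanded cells (3.54%)
    are missing, placed to match the documented per-characteristic pattern
    (6-7 expanded rows, i.e. 7.79%-9.09%, for FVC, smoking history and
    min/max FEV1; two studies for inclusion FEV1; one for withdrawal
    description).  The characteristic values themselves are simulated.
    """
    rng = np.random.default_rng(seed)
    specs = normalize_summary_weights([
        CharacteristicSpec("sample_size", "quantitative"),
        CharacteristicSpec("study_duration_weeks", "quantitative"),
        CharacteristicSpec("fev1_inclusion_pct", "quantitative"),
        CharacteristicSpec("fvc_inclusion_pct", "quantitative"),
        CharacteristicSpec("smoking_pack_years", "quantitative"),
        CharacteristicSpec("quality_score", "quantitative"),
        CharacteristicSpec("min_fev1_pct", "quantitative", weight=1.0,
                           summary_group="mean_fev1"),
        CharacteristicSpec("max_fev1_pct", "quantitative", weight=1.0,
                           summary_group="mean_fev1"),
        CharacteristicSpec("allocation_concealment", "binary",
                           levels=("inadequate", "adequate")),
        CharacteristicSpec("double_blinding", "binary",
                           levels=("inadequate", "adequate")),
        CharacteristicSpec("withdrawal_description", "binary", levels=("no", "yes")),
    ])

    # (arms, count) design: 29 two-arm + 4 three-arm + 6 four-arm = 39 studies,
    # sum of C(T,2) = 77 rows over 16 distinct comparisons
    design: list[tuple] = (
        [("PBO", "BUD", "BUD+", "FOR")] * 2        # small subnetwork, four-arm
        + [("PBO", "BUD+")] * 1 + [("PBO", "FOR")] * 1  # its two-arm studies
        + [("PBO", "FLU", "SAL", "FLU+")] * 4      # four-arm, main subnetwork
        + [("PBO", "SAL", "FLU+")] * 4             # three-arm
        + [("PBO", "FLU")] * 7
        + [("PBO", "SAL")] * 8
        + [("PBO", "FLU+")] * 4
        + [("PBO", "TIO")] * 4
        + [("FLU+", "TIO")] * 1                    # single-study comparison
        + [("FOR", "TIO")] * 1                     # single-study comparison
        + [("SAL", "TIO")] * 2
    )
    assert len(design) == 39
    assert sum(math.comb(len(a), 2) for a in design) == 77

    studies = []
    for i, arms in enumerate(design):
        sid = f"CO{i + 1:02d}"
        values = {
            "sample_size": float(round(rng.lognormal(6.0, 0.9))),
            "study_duration_weeks": float(round(rng.uniform(12, 156))),
            "fev1_inclusion_pct": float(round(rng.uniform(35, 55), 1)),
            "fvc_inclusion_pct": float(round(rng.uniform(55, 75), 1)),
            "smoking_pack_years": float(round(rng.uniform(35, 60), 1)),
            "quality_score": float(rng.integers(2, 6)),
            "allocation_concealment": "adequate",
            "double_blinding": "adequate",
            "withdrawal_description": "yes",
        }
        lo = round(rng.uniform(30, 45), 1)
        values["min_fev1_pct"] = float(lo)
        values["max_fev1_pct"] = float(round(lo + rng.uniform(2, 25), 1))
        studies.append(Study(sid, arms, values))

    def _amend(idx: int, **kw) -> None:
        st = studies[idx]
        studies[idx] = Study(st.study_id, st.arms, {**st.values, **kw})

    # missing-data pattern (expanded-cell multiplicities in comments)
    _amend(4, smoking_pack_years=None)              # four-arm: 6 rows
    _amend(5, fvc_inclusion_pct=None)               # four-arm: 6 rows
    _amend(35, fvc_inclusion_pct=None)              # TIO vs FLU+ single study: 1
    _amend(6, min_fev1_pct=None, max_fev1_pct=None)  # four-arm: 6 + 6 rows
    _amend(19, min_fev1_pct=None)                   # SAL vs PBO study: 1 row
    _amend(12, max_fev1_pct=None)                   # FLU vs PBO study: 1 row
    _amend(13, fev1_inclusion_pct=None)             # FLU vs PBO study: 1 row
    _amend(20, fev1_inclusion_pct=None)             # SAL vs PBO study: 1 row
    _amend(31, withdrawal_description=None)         # TIO vs PBO study: 1 row
    _amend(32, withdrawal_description="no")         # reported, inadequate

    ds = StudyDataset(studies, specs)
    assert abs(ds.missing_fraction(expanded=True) - 30 / 847) < 1e-12
    return ds
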