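"""Synthetic cohorts and annotation fixtures with planted ground truth.

Growth curves follow piecewise log-linear latent trajectories for three
archetypes seen in untreated immunogenic tumors — continued growth
(non-responsive), growth then sustained regression (regressing), and growth
then a plateau (exhausted) — with i.i.d. Gaussian noise on the log10 scale,
an undetectable floor at 1 mm², and humane-endpoint censoring above a size
cap. Differential-expression tables carry planted up/down gene blocks shared
across contrasts so the signature workflow can be checked against
construction truth; ortholog maps, transcription-factor lists and gene-set
collections are fabricated to match.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .growth import UNDETECTABLE_FLOOR_MM2, GrowthCurve

__all__ = [
    "ArchetypeSpec",
    "SyntheticCohort",
    "DEFAULT_ARCHETYPES",
    "CONTROL_ARCHETYPE",
    "DEFAULT_SCHEDULE",
    "simulate_cohort",
    "PlantedSizes",
    "DETables",
    "simulate_de_tables",
    "AnnotationFixtures",
    "simulate_annotation_fixtures",
    "SignatureBundle",
    "simulate_signature_bundle",
]

#: Measurement days: twice-weekly calipering from day 7 with classification
#: possible by day 17.
DEFAULT_SCHEDULE: tuple[int, ...] = (7, 10, 12, 14, 17)

#: Humane-endpoint stand-in: measurements after the area first exceeds this
#: cap are censored.
DEFAULT_SIZE_CAP_MM2 = 1500.0


@dataclass(frozen=True)
class ArchetypeSpec:
    """Latent piecewise log-linear growth pattern for one response class.

    ``log10 area(t) = baseline_log_area + growth_rate_phase1 * min(t, t0)
    + phase2_rate * max(t - t0, 0)`` with ``t0 = response_day`` (no second
    phase when ``response_day`` is None).
    """

    name: str
    baseline_log_area: float  # log10 mm² at day 0
    growth_rate_phase1: float  # log10 mm² per day
    response_day: float | None  # day growth reverses or stalls
    phase2_rate: float | None  # log10/day; negative = regression, ~0 = plateau
    noise_sd: float  # log10 units
    mixture_weight: float

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"{self.name}: noise_sd must be >= 0")
        if self.mixture_weight < 0:
            raise ValueError(f"{self.name}: mixture_weight must be >= 0")

    def latent_log_area(self, day: float) -> float:
        t0 = math.inf if self.response_day is None else self.response_day
        second = 0.0 if self.phase2_rate is None else self.phase2_rate
        return (self.baseline_log_area
                + self.growth_rate_phase1 * min(day, t0)
                + second * max(day - t0, 0.0))


# Cohort proportions follow the three observed response patterns
# (~48% regressing, ~26% exhausted, ~26% non-responsive).
DEFAULT_ARCHETYPES: tuple[ArchetypeSpec, ...] = (
    ArchetypeSpec("regressing", baseline_log_area=0.7,
                  growth_rate_phase1=0.13, response_day=10,
                  phase2_rate=-0.18, noise_sd=0.05, mixture_weight=0.478),
    ArchetypeSpec("exhausted", baseline_log_area=0.7,
                  growth_rate_phase1=0.13, response_day=10,
                  phase2_rate=0.0, noise_sd=0.05, mixture_weight=0.257),
    ArchetypeSpec("nonresponsive", baseline_log_area=0.7,
                  growth_rate_phase1=0.13, response_day=None,
                  phase2_rate=None, noise_sd=0.05, mixture_weight=0.265),
)

#: Single-archetype spec for control-only calibration cohorts.
CONTROL_ARCHETYPE = ArchetypeSpec(
    "control_like", baseline_log_area=0.7, growth_rate_phase1=0.13,
    response_day=None, phase2_rate=None, noise_sd=0.1, mixture_weight=1.0)


@dataclass(frozen=True)
class SyntheticCohort:
    curves: tuple[GrowthCurve, ...]
    true_labels: Mapping[str, str]  # animal_id -> archetype name
    seed: int
    schedule: tuple[float, ...]

    def to_frame(self, area_unit: str = "cm2") -> pd.DataFrame:
        """Long-format measurement table as the loader expects it."""
        rows = []
        for curve in self.curves:
            for day, mm2 in zip(curve.days, curve.areas_mm2):
                if area_unit == "cm2":
                    # the floor value 1 mm² round-trips through the loader
                    # as an undetectable (0 cm²) entry
                    area = 0.0 if mm2 == UNDETECTABLE_FLOOR_MM2 else mm2 / 100.0
                    rows.append({"animal_id": curve.animal_id, "day": day,
                                 "area_cm2": area})
                else:
                    rows.append({"animal_id": curve.animal_id, "day": day,
                                 "area_mm2": mm2})
        return pd.DataFrame(rows)

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.true_labels.items()),
            columns=["animal_id", "true_label"])


def _allocate_counts(n: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder rounding so counts always total n."""
    exact = [n * w for w in weights]
    counts = [int(math.floor(e)) for e in exact]
    remainder = n - sum(counts)
    order = sorted(range(len(weights)), key=lambda i: exact[i] - counts[i],
                   reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def simulate_cohort(
    n: int,
    specs: Sequence[ArchetypeSpec] = DEFAULT_ARCHETYPES,
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
    seed: int = 0,
    *,
    size_cap_mm2: float = DEFAULT_SIZE_CAP_MM2,
) -> SyntheticCohort:
    """Simulate one cohort of growth curves with known archetype labels.

    Archetype counts are allocated deterministically from the mixture
    weights (largest-remainder rounding), so composition is exact; noise is
    the only stochastic element and the whole cohort is reproducible from
    ``seed``.
    """
    if n < 4:
        raise ValueError("cohort needs n >= 4")
    schedule = tuple(sorted(float(d) for d in schedule))
    if len(schedule) < 4 or schedule[-1] <= 10:
        raise ValueError("schedule needs >= 4 days and must extend past day 10")
    total_w = sum(s.mixture_weight for s in specs)
    if not math.isclose(total_w, 1.0, abs_tol=1e-9):
        raise ValueError(f"mixture weights sum to {total_w}, expected 1")

    rng = np.random.default_rng(seed)
    counts = _allocate_counts(n, [s.mixture_weight for s in specs])
    width = max(4, len(str(n)))
    curves: list[GrowthCurve] = []
    labels: dict[str, str] = {}
    idx = 0
    for spec, count in zip(specs, counts):
        for _ in range(count):
            idx += 1
            animal_id = f"M{idx:0{width}d}"
            days, areas = [], []
            for day in schedule:
                latent = spec.latent_log_area(day)
                obs = latent + rng.normal(0.0, spec.noise_sd)
                area = max(10.0 ** obs, UNDETECTABLE_FLOOR_MM2)
                days.append(day)
                areas.append(area)
                if area > size_cap_mm2:  # censored thereafter
                    break
            curves.append(GrowthCurve(animal_id=animal_id, days=tuple(days),
                                      areas_mm2=tuple(areas),
                                      group=spec.name))
            labels[animal_id] = spec.name
    return SyntheticCohort(curves=tuple(curves), true_labels=labels,
                           seed=seed, schedule=schedule)


# ---------------------------------------------------------------------------
# differential-expression tables with planted signal
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSizes:
    """Planted DEG block sizes for the two exhausted-vs-activated contrasts."""

    shared_up: int = 40
    shared_down: int = 40
    invitro_only: int = 30
    invivo_only: int = 30

    @property
    def total(self) -> int:
        return (self.shared_up + self.shared_down
                + self.invitro_only + self.invivo_only)


@dataclass(frozen=True)
class DETables:
    invitro: pd.DataFrame  # columns gene, log2FoldChange, padj
    invivo: pd.DataFrame
    truth: Mapping[str, frozenset[str]]  # planted block name -> gene set


def _planted_effects(rng: np.random.Generator, genes: Sequence[str],
                     sign: int, effect_lfc: float) -> pd.DataFrame:
    lfc = sign * (effect_lfc + np.abs(rng.normal(0.0, 0.3, size=len(genes))))
    padj = rng.uniform(1e-8, 0.01, size=len(genes))
    return pd.DataFrame({"gene": genes, "log2FoldChange": lfc, "padj": padj})


def _background_effects(rng: np.random.Generator,
                        genes: Sequence[str]) -> pd.DataFrame:
    # each background gene fails at least one significance threshold
    n = len(genes)
    fail_lfc = rng.random(n) < 0.5
    lfc = np.where(fail_lfc, rng.uniform(-1.9, 1.9, n), rng.uniform(-4, 4, n))
    padj = np.where(fail_lfc, rng.uniform(0.0, 1.0, n),
                    rng.uniform(0.011, 1.0, n))
    return pd.DataFrame({"gene": genes, "log2FoldChange": lfc, "padj": padj})


def simulate_de_tables(
    n_genes: int = 4000,
    planted: PlantedSizes = PlantedSizes(),
    effect_lfc: float = 3.0,
    seed: int = 0,
) -> DETables:
    """Two DE tables with planted shared and contrast-specific DEG blocks.

    Planted genes pass FDR ≤ 0.01 and |log2FC| ≥ ``effect_lfc`` in their
    designated contrast(s); every background gene fails at least one
    threshold in each contrast. Gene symbols are mouse-style Title-case.
    """
    if planted.total > n_genes:
        raise ValueError(
            f"planted sizes total {planted.total} exceed n_genes={n_genes}")
    if effect_lfc < 2:
        raise ValueError("effect_lfc must be >= 2 to pass the DEG filter")
    rng = np.random.default_rng(seed)
    genes = [f"Simgene{i + 1:05d}" for i in range(n_genes)]
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        block = genes[cursor:cursor + k]
        cursor += k
        return block

    shared_up = take(planted.shared_up)
    shared_down = take(planted.shared_down)
    invitro_only = take(planted.invitro_only)
    invivo_only = take(planted.invivo_only)
    background = genes[cursor:]

    def build(sig_up: list[str], sig_down: list[str],
              only: list[str], other_only: list[str]) -> pd.DataFrame:
        parts = [
            _planted_effects(rng, sig_up, +1, effect_lfc),
            _planted_effects(rng, sig_down, -1, effect_lfc),
            _planted_effects(rng, only, +1, effect_lfc),
            _background_effects(rng, other_only),
            _background_effects(rng, background),
        ]
        return (pd.concat(parts, ignore_index=True)
                .set_index("gene").loc[genes].reset_index())

    invitro = build(shared_up, shared_down, invitro_only, invivo_only)
    invivo = build(shared_up, shared_down, invivo_only, invitro_only)
    truth = {
        "shared_up": frozenset(shared_up),
        "shared_down": frozenset(shared_down),
        "invitro_only": frozenset(invitro_only),
        "invivo_only": frozenset(invivo_only),
    }
    return DETables(invitro=invitro, invivo=invivo, truth=truth)


# ---------------------------------------------------------------------------
# annotation fixtures: ortholog map, TF list, gene sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationFixtures:
    ortholog_map: pd.DataFrame  # columns mouse_symbol, human_symbol
    tf_list: frozenset[str]  # human symbols
    gene_sets: Mapping[str, frozenset[str]]
    n_unmapped: int
    n_one_to_many: int


def simulate_annotation_fixtures(
    genes: Sequence[str],
    n_sets: int = 5,
    seed: int = 0,
    *,
    mapped_fraction: float = 1.0,
    one_to_many_fraction: float = 0.0,
    tf_fraction: float = 0.1,
) -> AnnotationFixtures:
    """Fabricate ortholog/TF/gene-set annotations over ``genes``.

    Human symbols are the upper-cased mouse symbols; one-to-many entries
    add a ``<SYMBOL>L1`` paralog. Gene sets have varied sizes drawn from
    the mapped human universe.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    n = len(genes)
    mapped_mask = rng.random(n) < mapped_fraction
    pairs: list[tuple[str, str]] = []
    n_one_to_many = 0
    for g, mapped in zip(genes, mapped_mask):
        if not mapped:
            continue
        human = g.upper()
        pairs.append((g, human))
        if rng.random() < one_to_many_fraction:
            pairs.append((g, human + "L1"))
            n_one_to_many += 1
    omap = pd.DataFrame(pairs, columns=["mouse_symbol", "human_symbol"])
    human_universe = sorted(omap["human_symbol"].unique())
    n_tf = max(1, int(round(tf_fraction * len(human_universe))))
    tf_list = frozenset(rng.choice(human_universe, size=n_tf, replace=False))
    gene_sets = {}
    for i in range(n_sets):
        size = int(rng.integers(5, max(6, len(human_universe) // 4)))
        members = rng.choice(human_universe, size=min(size, len(human_universe)),
                             replace=False)
        gene_sets[f"SET_{i + 1:03d}"] = frozenset(members)
    return AnnotationFixtures(
        ortholog_map=omap, tf_list=tf_list, gene_sets=gene_sets,
        n_unmapped=int((~mapped_mask).sum()), n_one_to_many=n_one_to_many)


# ---------------------------------------------------------------------------
# full signature-workflow bundle with planted end-to-end truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignatureBundle:
    """Everything the signature workflow consumes, plus construction truth."""

    de: DETables
    ortholog_map: pd.DataFrame
    human_exhausted_genes: frozenset[str]
    tf_list: frozenset[str]
    expected_experimental_up: frozenset[str]  # human symbols
    expected_experimental_down: frozenset[str]
    expected_exhausted_up: frozenset[str]
    expected_exhausted_down: frozenset[str]
    expected_tfs_up: frozenset[str]


def simulate_signature_bundle(
    seed: int = 0,
    *,
    n_genes: int = 4000,
    shared_up: int = 400,
    shared_down: int = 350,
    exhausted_up: int = 180,
    exhausted_down: int = 79,
    n_tfs_up: int = 25,
    n_decoy_human: int = 150,
    n_decoy_tfs: int = 40,
) -> SignatureBundle:
    """Plant a complete signature workflow with exact expected outputs.

    Defaults plant a 259-gene exhausted signature (180 up + 79 down) and 25
    upregulated transcription factors inside larger shared DEG blocks, with
    decoy human genes and TFs that must not leak into the results.
    """
    if exhausted_up > shared_up or exhausted_down > shared_down:
        raise ValueError("exhausted signature cannot exceed the shared blocks")
    if n_tfs_up > exhausted_up:
        raise ValueError("planted TFs must fit inside the up signature")
    rng = np.random.default_rng(seed)
    de = simulate_de_tables(
        n_genes=n_genes,
        planted=PlantedSizes(shared_up=shared_up, shared_down=shared_down,
                             invitro_only=50, invivo_only=50),
        effect_lfc=3.0, seed=int(rng.integers(0, 2**31 - 1)))
    up_mouse = sorted(de.truth["shared_up"])
    down_mouse = sorted(de.truth["shared_down"])
    all_genes = list(de.invitro["gene"])
    omap = pd.DataFrame({"mouse_symbol": all_genes,
                         "human_symbol": [g.upper() for g in all_genes]})

    up_human = [g.upper() for g in up_mouse]
    down_human = [g.upper() for g in down_mouse]
    exh_up = rng.choice(up_human, size=exhausted_up, replace=False)
    exh_down = rng.choice(down_human, size=exhausted_down, replace=False)
    decoys = [f"DECOY{i + 1:04d}" for i in range(n_decoy_human)]
    human_exhausted = frozenset(exh_up) | frozenset(exh_down) | frozenset(decoys)

    tfs_in = rng.choice(sorted(exh_up), size=n_tfs_up, replace=False)
    tf_decoys = [f"TFDECOY{i + 1:03d}" for i in range(n_decoy_tfs)]
    tf_list = frozenset(tfs_in) | frozenset(tf_decoys)

    return SignatureBundle(
        de=de,
        ortholog_map=omap,
        human_exhausted_genes=human_exhausted,
        tf_list=tf_list,
        expected_experimental_up=frozenset(up_human),
        expected_experimental_down=frozenset(down_human),
        expected_exhausted_up=frozenset(exh_up),
        expected_exhausted_down=frozenset(exh_down),
        expected_tfs_up=frozenset(tfs_in),
    )
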