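"""Synthetic kinome-array study generator with planted ground truth.

Emulates a PTK peptide-array study: 18 cases assayed in duplicate on a
144-peptide array read over the exposure series {10, 20, 50, 100, 200} ms.
Spot kinetics are linear in exposure time with a per-array intercept
(background fluorescence); a configurable subset of peptides is kinetically
flat (true slope exactly 0) and should fail QC.  Non-flat peptides carry one
of three planted log2 activity levels (clusters A intermediate / B high / C
low), and half of them additionally carry a log2 shift in the second of two
planted sample groups, giving downstream clustering and differential testing
something to recover.  Clinical follow-up is exponential survival per sample
group with independent exponential censoring and a multinomial best
response.

Noise model: per-reading Gaussian intensity noise with standard deviation
``noise_sd * ln2 * max(slope, 0.01) * sqrt(Sxx)`` where Sxx is the centered
sum of squares of the exposure grid.  Because the OLS slope error is the
reading error divided by sqrt(Sxx), this calibration makes ``noise_sd`` the
approximate standard deviation of the recovered *log2 activity value* — so
``sample_effect`` and ``noise_sd`` live on the same scale.  With
``noise_sd=0`` every reading is exact and the pipeline recovers the planted
slopes to machine precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    ClinicalTable,
    EdgeList,
    IntensityTable,
    KinaseAnnotationSource,
    PathwayCollection,
)

__all__ = ["SimulationConfig", "GroundTruth", "generate_kinome_dataset", "generate_reference_fixtures"]

_FLAT_FLOOR_SLOPE = 0.01  # slope of a log2-activity-0 spot; floors the noise scale


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic kinome dataset."""

    n_cases: int = 18
    n_replicates: int = 2
    n_peptides: int = 144
    exposure_times_ms: tuple[float, ...] = (10.0, 20.0, 50.0, 100.0, 200.0)
    n_flat_peptides: int = 42
    peptide_cluster_means: tuple[float, float, float] = (4.0, 6.0, 2.0)  # A, B, C (log2)
    peptide_cluster_sizes: tuple[int, int, int] | None = None  # default 34/29/39 pattern
    sample_effect: float = 0.5  # log2 shift of differential peptides in group 2
    differential_fraction: float = 0.5
    noise_sd: float = 0.25  # log2-activity units, see module docstring
    intercept: float = 200.0  # background fluorescence, a.u.
    saturation_ceiling: float | None = None  # optional intensity clipping, off by default
    hazard_by_group: tuple[float, float] = (math.log(2) / 20.7, math.log(2) / 39.4)  # /month
    os_hazard_factor: float = 0.6  # OS events accrue slower than PFS events
    censoring_rate: float = 0.015  # /month
    response_probs: Mapping[str, float] = field(
        default_factory=lambda: {"CR": 0.0, "PR": 15 / 19, "SD": 1 / 19, "PD": 1 / 19, "NE": 2 / 19}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 2:
            raise ValueError("n_cases must be >= 2")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_peptides < 1:
            raise ValueError("n_peptides must be >= 1")
        if not 0 <= self.n_flat_peptides < self.n_peptides:
            raise ValueError("n_flat_peptides must satisfy 0 <= n_flat_peptides < n_peptides")
        times = tuple(self.exposure_times_ms)
        if len(times) < 2 or any(t <= 0 for t in times):
            raise ValueError("exposure_times_ms must hold at least 2 positive times")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("exposure_times_ms must be strictly increasing")
        if len(self.peptide_cluster_means) != 3:
            raise ValueError("peptide_cluster_means must have exactly 3 levels")
        if self.sample_effect < 0:
            raise ValueError("sample_effect must be >= 0")
        if not 0 <= self.differential_fraction <= 1:
            raise ValueError("differential_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.hazard_by_group) != 2 or any(h <= 0 for h in self.hazard_by_group):
            raise ValueError("hazard_by_group must be two positive rates")
        if self.censoring_rate <= 0:
            raise ValueError("censoring_rate must be positive")
        probs = dict(self.response_probs)
        if abs(sum(probs.values()) - 1.0) > 1e-9 or any(v < 0 for v in probs.values()):
            raise ValueError("response_probs must be a probability distribution")
        sizes = self.cluster_sizes()
        if sum(sizes) != self.n_peptides - self.n_flat_peptides:
            raise ValueError("peptide_cluster_sizes must sum to n_peptides - n_flat_peptides")

    def cluster_sizes(self) -> tuple[int, int, int]:
        if self.peptide_cluster_sizes is not None:
            return tuple(self.peptide_cluster_sizes)  # type: ignore[return-value]
        # default proportions 34:29:39 over the non-flat peptides
        n = self.n_peptides - self.n_flat_peptides
        a = round(n * 34 / 102)
        b = round(n * 29 / 102)
        return (a, b, n - a - b)

    @property
    def sxx(self) -> float:
        t = np.asarray(self.exposure_times_ms, dtype=float)
        return float(((t - t.mean()) ** 2).sum())


@dataclass
class GroundTruth:
    peptide_cluster_labels: dict[str, str]  # peptide -> A/B/C/flat
    sample_group_labels: dict[str, str]  # case -> "1"/"2"
    true_slopes: pd.DataFrame  # peptides x cases
    differential_peptides: set[str]

    def __post_init__(self) -> None:
        flat = {p for p, lab in self.peptide_cluster_labels.items() if lab == "flat"}
        if self.differential_peptides & flat:
            raise ValueError("differential peptides must be non-flat")

    @property
    def flat_peptides(self) -> set[str]:
        return {p for p, lab in self.peptide_cluster_labels.items() if lab == "flat"}

    @property
    def nonflat_peptides(self) -> set[str]:
        return set(self.peptide_cluster_labels) - self.flat_peptides

    def to_json(self, path: str | Path) -> None:
        payload = {
            "peptide_cluster_labels": self.peptide_cluster_labels,
            "sample_group_labels": self.sample_group_labels,
            "differential_peptides": sorted(self.differential_peptides),
            "true_slopes": {
                pep: {case: float(v) for case, v in row.items()}
                for pep, row in self.true_slopes.iterrows()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _peptide_ids(n: int) -> list[str]:
    return [f"PRT{i + 1:03d}_{101}_{113}" for i in range(n)]


def _case_ids(n: int) -> list[str]:
    return [f"case{i + 1:02d}" for i in range(n)]


def generate_kinome_dataset(
    config: SimulationConfig,
) -> tuple[IntensityTable, ClinicalTable, GroundTruth]:
    """Simulate intensities, clinical follow-up and ground truth.

    Deterministic: the same config (including seed) yields identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    peptides = _peptide_ids(config.n_peptides)
    cases = _case_ids(config.n_cases)
    n_group1 = math.ceil(config.n_cases / 2)
    groups = {c: ("1" if i < n_group1 else "2") for i, c in enumerate(cases)}

    size_a, size_b, size_c = config.cluster_sizes()
    labels: dict[str, str] = {}
    nonflat = peptides[: config.n_peptides - config.n_flat_peptides]
    for i, pep in enumerate(nonflat):
        labels[pep] = "A" if i < size_a else ("B" if i < size_a + size_b else "C")
    for pep in peptides[len(nonflat):]:
        labels[pep] = "flat"

    # the differential peptides are the leading block of the non-flat panel:
    # deterministic, and aligned with the first reference pathway so the
    # enrichment stage has a real signal to find
    n_diff = round(config.differential_fraction * len(nonflat))
    differential = set(nonflat[:n_diff])

    mean_of = dict(zip("ABC", config.peptide_cluster_means))
    log2_level = np.zeros((config.n_peptides, config.n_cases))
    for pi, pep in enumerate(peptides):
        lab = labels[pep]
        for ci, case in enumerate(cases):
            if lab == "flat":
                log2_level[pi, ci] = -np.inf
            else:
                shift = config.sample_effect if (pep in differential and groups[case] == "2") else 0.0
                log2_level[pi, ci] = mean_of[lab] + shift
    slopes = np.where(np.isfinite(log2_level), 2.0 ** log2_level / 100.0, 0.0)
    true_slopes = pd.DataFrame(slopes, index=peptides, columns=cases)

    t = np.asarray(config.exposure_times_ms, dtype=float)
    noise_scale = config.noise_sd * math.log(2) * np.maximum(slopes, _FLAT_FLOOR_SLOPE) * math.sqrt(
        config.sxx
    )
    rows: list[pd.DataFrame] = []
    for ri in range(config.n_replicates):
        rep = f"r{ri + 1}"
        # signal: peptides x cases x exposures
        signal = config.intercept + slopes[:, :, None] * t[None, None, :]
        if config.noise_sd > 0:
            signal = signal + rng.normal(0.0, 1.0, size=signal.shape) * noise_scale[:, :, None]
        if config.saturation_ceiling is not None:
            signal = np.minimum(signal, config.saturation_ceiling)
        frame = pd.DataFrame(
            {
                "peptide_id": np.repeat(peptides, config.n_cases * len(t)),
                "sample": np.tile(np.repeat(cases, len(t)), config.n_peptides),
                "replicate": rep,
                "exposure_ms": np.tile(t, config.n_peptides * config.n_cases),
                "intensity": signal.reshape(-1),
            }
        )
        rows.append(frame)
    intensity = IntensityTable(pd.concat(rows, ignore_index=True))

    cats = list(config.response_probs)
    probs = np.array([config.response_probs[c] for c in cats], dtype=float)
    clin_rows = []
    for case in cases:
        g = int(groups[case]) - 1
        response = str(rng.choice(cats, p=probs))
        pfs_t = rng.exponential(1.0 / config.hazard_by_group[g])
        pfs_c = rng.exponential(1.0 / config.censoring_rate)
        os_t = rng.exponential(1.0 / (config.hazard_by_group[g] * config.os_hazard_factor))
        os_c = rng.exponential(1.0 / config.censoring_rate)
        clin_rows.append(
            {
                "case_id": case,
                "response": response,
                "pfs_months": min(pfs_t, pfs_c),
                "pfs_event": pfs_t <= pfs_c,
                "os_months": min(os_t, os_c),
                "os_event": os_t <= os_c,
                "group": groups[case],
            }
        )
    clinical = ClinicalTable(pd.DataFrame(clin_rows))
    truth = GroundTruth(
        peptide_cluster_labels=labels,
        sample_group_labels=groups,
        true_slopes=true_slopes,
        differential_peptides=differential,
    )
    return intensity, clinical, truth


def generate_reference_fixtures(
    config: SimulationConfig,
    agreement_fraction: float = 0.8,
    n_kinase_pool: int = 40,
    n_pathways: int = 12,
    pathway_size: int = 15,
    topology: str = "random",
) -> tuple[KinaseAnnotationSource, KinaseAnnotationSource, EdgeList, PathwayCollection]:
    """Annotation sources, PPI edges and pathway sets matching the dataset.

    * Two kinase-substrate sources annotate every non-flat peptide; a
      fraction ``agreement_fraction`` of peptides is annotated concordantly
      (both sources propose the same kinase, the second possibly with
      extras), the rest discordantly (disjoint proposals, so consensus
      calling returns the empty set).
    * The edge list spans the protein tokens of the non-flat peptides.  With
      ``topology="random"`` the first protein (``PRT001``) is wired as a
      planted high-degree hub on top of a sparse random graph; with
      ``topology="star"`` the list is a pure star centred on ``PRT001``,
      whose centre is then the unique hub-bottleneck by construction.
    * Pathway sets are drawn from the protein tokens; the first pathway is
      loaded with differential-peptide proteins so a real enrichment signal
      exists.  The universe is all peptide proteins on the array.
    """
    config.validate()
    if not 0.0 <= agreement_fraction <= 1.0:
        raise ValueError("agreement_fraction must lie in [0, 1]")
    rng = np.random.default_rng(config.seed + 1)
    peptides = _peptide_ids(config.n_peptides)
    nonflat = peptides[: config.n_peptides - config.n_flat_peptides]
    proteins = [p.rsplit("_", 2)[0] for p in peptides]
    nonflat_proteins = [p.rsplit("_", 2)[0] for p in nonflat]
    pool = [f"KIN{i + 1:02d}" for i in range(n_kinase_pool)]

    ann_a: dict[str, frozenset[str]] = {}
    ann_b: dict[str, frozenset[str]] = {}
    for pep in nonflat:
        k = pool[int(rng.integers(len(pool)))]
        if rng.random() < agreement_fraction:
            extra = pool[int(rng.integers(len(pool)))]
            ann_a[pep] = frozenset({k})
            ann_b[pep] = frozenset({k, extra})
        else:
            others = [x for x in pool if x != k]
            k2 = others[int(rng.integers(len(others)))]
            ann_a[pep] = frozenset({k})
            ann_b[pep] = frozenset({k2})
    source_a = KinaseAnnotationSource("sim_source_a", ann_a)
    source_b = KinaseAnnotationSource("sim_source_b", ann_b)

    hub = nonflat_proteins[0]
    records: list[tuple[str, str, float, str | None]] = []
    seen: set[tuple[str, str]] = set()

    def add_edge(a: str, b: str, conf: float) -> None:
        if a == b:
            return
        key = (a, b) if a <= b else (b, a)
        if key not in seen:
            seen.add(key)
            records.append((key[0], key[1], conf, None))

    if topology == "star":
        for leaf in nonflat_proteins[1:]:
            add_edge(hub, leaf, 0.9)
    elif topology == "random":
        n = len(nonflat_proteins)
        for i, a in enumerate(nonflat_proteins):
            for b in nonflat_proteins[i + 1 :]:
                if rng.random() < 0.05:
                    add_edge(a, b, float(rng.uniform(0.4, 1.0)))
        for leaf in nonflat_proteins[1:]:
            if rng.random() < 0.5:
                add_edge(hub, leaf, float(rng.uniform(0.7, 1.0)))
    else:
        raise ValueError(f"unknown topology {topology!r}")
    edges = EdgeList(records)

    # first pathway concentrates on the front of the non-flat block (where
    # planted differential peptides are dense); remaining pathways random
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    first = frozenset(nonflat_proteins[:pathway_size])
    pathways["PW01"] = ("synthetic pathway enriched in array proteins", first)
    for i in range(1, n_pathways):
        members = rng.choice(proteins, size=min(pathway_size, len(proteins)), replace=False)
        pathways[f"PW{i + 1:02d}"] = (f"synthetic pathway {i + 1}", frozenset(members))
    collection = PathwayCollection(pathways, frozenset(proteins))
    return source_a, source_b, edges, collection
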