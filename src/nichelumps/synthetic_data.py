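"""Seeded generators for lumpy species pools and co-occurrence samples.

Real size catalogues and ditch-survey tables are not redistributable, so
every downstream analysis in this package is exercised on synthetic inputs
that carry the statistical structure those analyses assume:

* species pools whose log body lengths cluster into lumps with geometric
  spacing between lump centers (a constant length ratio between adjacent
  lumps);
* co-occurrence samples drawing species from such a pool with a
  configurable per-sample richness law;
* three-species "aquifer" communities — one small, one medium, one large
  species with a fixed step ratio — emulating isolated groundwater
  habitats where this size structure evolved repeatedly;
* multi-region catalogues concatenating independent pools.

All log-scale generation uses the natural log.  Every generator is
deterministic given its spec (the seed is part of the spec).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._rng import substream_rng
from .ratio_pipeline import OccurrenceSample

__all__ = [
    "SpeciesRecord",
    "SpeciesPool",
    "LumpyPoolSpec",
    "SamplingSpec",
    "generate_lumpy_pool",
    "generate_cooccurrence_samples",
    "generate_aquifer_triplets",
    "generate_regional_catalogue",
    "truncated_poisson_mean",
]


@dataclass(frozen=True)
class SpeciesRecord:
    """One species: identifier, region tag, mean adult body length in mm."""

    species_id: str
    region: str
    length_mm: float

    def __post_init__(self) -> None:
        if not self.species_id:
            raise ValueError("species_id must be non-empty")
        if not self.length_mm > 0:
            raise ValueError(
                f"species {self.species_id!r}: length_mm must be > 0, "
                f"got {self.length_mm}"
            )


@dataclass(frozen=True)
class SpeciesPool:
    """A generated species pool with its lump bookkeeping."""

    records: tuple[SpeciesRecord, ...]
    lump_assignment: Mapping[str, int]

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.species_id not in self.lump_assignment:
                raise ValueError(
                    f"species {rec.species_id!r} missing a lump assignment"
                )

    @property
    def lengths_mm(self) -> np.ndarray:
        return np.array([r.length_mm for r in self.records])


@dataclass(frozen=True)
class LumpyPoolSpec:
    """Parameters of a lumpy species pool.

    Lump centers form the exact geometric sequence
    ``base_length * spacing_ratio**k`` (k = 0..n_lumps-1) in mm; species in
    lump k get log lengths Normal(log center_k, within_lump_sd).
    ``species_per_lump`` is one count for all lumps or a per-lump list.
    ``round_to_tenth`` optionally rounds emitted lengths to 0.1 mm, the
    granularity of printed catalogues (off by default: rounding changes
    ratio histograms).
    """

    n_lumps: int
    base_length: float
    spacing_ratio: float
    within_lump_sd: float
    species_per_lump: int | Sequence[int] = 20
    seed: int = 0
    region: str = "synthetic"
    round_to_tenth: bool = False

    def __post_init__(self) -> None:
        if self.n_lumps < 1:
            raise ValueError(f"n_lumps must be >= 1, got {self.n_lumps}")
        if not self.base_length > 0:
            raise ValueError(f"base_length must be > 0, got {self.base_length}")
        if not self.spacing_ratio > 1:
            raise ValueError(
                f"spacing_ratio must be > 1, got {self.spacing_ratio}"
            )
        if self.within_lump_sd < 0:
            raise ValueError(
                f"within_lump_sd must be >= 0, got {self.within_lump_sd}"
            )
        counts = self.counts_per_lump()
        if len(counts) != self.n_lumps:
            raise ValueError(
                f"species_per_lump has length {len(counts)}, "
                f"expected n_lumps={self.n_lumps}"
            )
        if any(c < 1 for c in counts):
            raise ValueError("species_per_lump entries must be >= 1")

    def counts_per_lump(self) -> list[int]:
        if isinstance(self.species_per_lump, int):
            return [self.species_per_lump] * self.n_lumps
        return [int(c) for c in self.species_per_lump]

    def lump_centers_mm(self) -> np.ndarray:
        return self.base_length * self.spacing_ratio ** np.arange(self.n_lumps)


@dataclass(frozen=True)
class SamplingSpec:
    """How co-occurrence samples draw species from a pool.

    ``richness_law`` is ``("fixed", n)`` or ``("truncated_poisson", mean)``
    — a zero-truncated Poisson with the stated *rate* (lambda), truncated
    below at 1 and above at the pool size.  ``detection_bias`` optionally
    gives per-lump relative detection weights.
    """

    n_samples: int
    richness_law: tuple[str, float] = ("truncated_poisson", 4.0)
    detection_bias: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")
        law, param = self.richness_law
        if law not in ("fixed", "truncated_poisson"):
            raise ValueError(f"unknown richness law {law!r}")
        if law == "fixed" and (param < 1 or param != int(param)):
            raise ValueError("fixed richness must be a positive integer")
        if law == "truncated_poisson" and not param > 0:
            raise ValueError("truncated-Poisson rate must be > 0")
        if self.detection_bias is not None and any(
            w < 0 for w in self.detection_bias
        ):
            raise ValueError("detection_bias weights must be >= 0")


def truncated_poisson_mean(lam: float) -> float:
    """Mean of a zero-truncated Poisson(lambda): lambda / (1 - exp(-lambda))."""
    return lam / (1.0 - np.exp(-lam))


def generate_lumpy_pool(spec: LumpyPoolSpec) -> SpeciesPool:
    """Draw a species pool with geometrically spaced size lumps.

    Species ids are ``"{region}_L{lump}_{index}"``.  With
    ``within_lump_sd=0`` every species sits exactly at its lump center, so
    all cross-lump pairwise ratios are exact powers of ``spacing_ratio``.
    """
    rng = substream_rng(spec.seed, "lumpy_pool")
    centers_mm = spec.lump_centers_mm()
    records: list[SpeciesRecord] = []
    assignment: dict[str, int] = {}
    for k, count in enumerate(spec.counts_per_lump()):
        # multiplicative form so within_lump_sd=0 yields the centers exactly
        factors = np.exp(rng.normal(0.0, 1.0, size=count) * spec.within_lump_sd)
        for i, f in enumerate(factors):
            length = float(centers_mm[k] * f)
            if spec.round_to_tenth:
                length = max(round(length, 1), 0.1)
            sid = f"{spec.region}_L{k}_{i}"
            records.append(SpeciesRecord(sid, spec.region, length))
            assignment[sid] = k
    return SpeciesPool(records=tuple(records), lump_assignment=assignment)


def _draw_richness(
    rng: np.random.Generator, spec: SamplingSpec, pool_size: int
) -> np.ndarray:
    law, param = spec.richness_law
    if law == "fixed":
        n = int(param)
        if n > pool_size:
            raise ValueError(
                f"fixed richness {n} exceeds pool size {pool_size}"
            )
        return np.full(spec.n_samples, n, dtype=int)
    # zero-truncated Poisson via rejection, capped at the pool size
    out = np.empty(spec.n_samples, dtype=int)
    filled = 0
    while filled < spec.n_samples:
        draws = rng.poisson(param, size=2 * (spec.n_samples - filled) + 8)
        draws = draws[draws >= 1][: spec.n_samples - filled]
        out[filled : filled + draws.size] = draws
        filled += draws.size
    return np.minimum(out, pool_size)


def generate_cooccurrence_samples(
    pool: SpeciesPool, spec: SamplingSpec
) -> list[OccurrenceSample]:
    """Draw seeded co-occurrence samples from a species pool.

    Each sample holds distinct species (drawn without replacement) with
    their pool body lengths; per-sample richness follows the spec's
    richness law.  Detection bias, if given, weights each species by its
    lump's relative weight.
    """
    if not pool.records:
        raise ValueError("cannot sample from an empty pool")
    rng = substream_rng(spec.seed, "cooccurrence")
    richness = _draw_richness(rng, spec, len(pool.records))
    p = None
    if spec.detection_bias is not None:
        bias = np.asarray(spec.detection_bias, dtype=float)
        weights = np.array(
            [bias[pool.lump_assignment[r.species_id]] for r in pool.records]
        )
        if weights.sum() <= 0:
            raise ValueError("detection_bias gives zero total weight")
        p = weights / weights.sum()
    samples = []
    n_digits = len(str(spec.n_samples - 1))
    for i, n in enumerate(richness):
        idx = rng.choice(len(pool.records), size=int(n), replace=False, p=p)
        members = tuple(
            (pool.records[j].species_id, pool.records[j].length_mm)
            for j in sorted(idx)
        )
        samples.append(OccurrenceSample(f"S{i:0{n_digits}d}", members))
    return samples


def generate_aquifer_triplets(
    n_aquifers: int,
    base_length_law: tuple = ("lognormal", 1.0, 0.15),
    step_ratio: float = 1.6,
    ratio_noise_sd: float = 0.0,
    seed: int = 0,
) -> list[OccurrenceSample]:
    """Generate three-species communities with a small/medium/large ladder.

    Each "aquifer" sample contains exactly 3 species at log lengths
    ``log(base) + {0, 1, 2} * log(step_ratio)`` plus Normal(0,
    ratio_noise_sd) noise; the default step ratio of 1.6 matches the wide
    niche spacing observed in species-poor isolated habitats.
    ``base_length_law`` is ``("fixed", mm)``, ``("uniform", lo, hi)`` or
    ``("lognormal", median_mm, sd_log)``.
    """
    if n_aquifers < 1:
        raise ValueError(f"n_aquifers must be >= 1, got {n_aquifers}")
    if not step_ratio > 1:
        raise ValueError(f"step_ratio must be > 1, got {step_ratio}")
    if ratio_noise_sd < 0:
        raise ValueError(f"ratio_noise_sd must be >= 0, got {ratio_noise_sd}")
    rng = substream_rng(seed, "aquifers")
    law = base_length_law[0]
    if law == "fixed":
        bases = np.full(n_aquifers, float(base_length_law[1]))
    elif law == "uniform":
        bases = rng.uniform(base_length_law[1], base_length_law[2], n_aquifers)
    elif law == "lognormal":
        bases = np.exp(
            np.log(base_length_law[1])
            + rng.normal(0.0, base_length_law[2], n_aquifers)
        )
    else:
        raise ValueError(f"unknown base_length_law {law!r}")
    if np.any(bases <= 0):
        raise ValueError("base lengths must be > 0")

    samples = []
    sizes = ("small", "medium", "large")
    for i, base in enumerate(bases):
        noise = np.exp(rng.normal(0.0, 1.0, 3) * ratio_noise_sd)
        members = tuple(
            (f"A{i}_{sizes[j]}", float(base * step_ratio**j * noise[j]))
            for j in range(3)
        )
        samples.append(OccurrenceSample(f"A{i}", members))
    return samples


def generate_regional_catalogue(
    regions: Sequence[LumpyPoolSpec],
) -> list[SpeciesRecord]:
    """Concatenate per-region lumpy pools into one tagged catalogue."""
    tags = [spec.region for spec in regions]
    dupes = {t for t in tags if tags.count(t) > 1}
    if dupes:
        raise ValueError(f"duplicate region tags: {sorted(dupes)}")
    records: list[SpeciesRecord] = []
    for spec in regions:
        records.extend(generate_lumpy_pool(spec).records)
    return records
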