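"""Pairwise body-length ratios of co-occurring species.

Field samples (e.g. macroinvertebrate surveys of individual ditches) list
the species found together at one site.  For every sample with enough
species, all unordered pairs are formed and the body-length ratio of each
pair is computed with the larger length in the numerator, so every ratio is
>= 1.  Ratios are pooled across samples — a species pair co-occurring in
ten samples contributes ten ratios, since each sample is an independent
observation of local co-existence — and the pooled log ratios are then
screened for multimodality.  In a community whose species sizes form a
geometric ladder with step rho, the pooled ratios concentrate near
1, rho, rho^2, ...
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .mode_analysis import ModeAnalysisResult, select_best_mixture

__all__ = [
    "OccurrenceSample",
    "RatioSet",
    "filter_samples_min_richness",
    "pairwise_length_ratios",
    "pool_ratios",
    "analyze_ratio_modes",
]


@dataclass(frozen=True)
class OccurrenceSample:
    """One field sample: the species observed together, with mean lengths.

    ``members`` holds ``(species_id, length_mm)`` pairs; species ids are
    unique within a sample and lengths are in mm.
    """

    sample_id: str
    members: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        ids = [sp for sp, _ in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError(
                f"sample {self.sample_id!r}: duplicate species ids"
            )

    @property
    def richness(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class RatioSet:
    """Pooled pairwise length ratios with per-sample provenance.

    ``provenance[i]`` is ``(sample_id, species_a, species_b)`` for
    ``ratios[i]``; species pairs are in canonical (lexicographic) order.
    """

    ratios: np.ndarray
    provenance: tuple[tuple[str, str, str], ...]
    n_samples_used: int
    n_pairs: int

    def __post_init__(self) -> None:
        if self.n_pairs != len(self.ratios) or self.n_pairs != len(self.provenance):
            raise ValueError("n_pairs inconsistent with ratios/provenance")
        if self.n_pairs and float(np.min(self.ratios)) < 1.0:
            raise ValueError("ratios must be >= 1 (larger/smaller convention)")


def filter_samples_min_richness(
    samples: Iterable[OccurrenceSample], min_species: int
) -> list[OccurrenceSample]:
    """Keep samples containing at least ``min_species`` distinct species.

    The field convention for ratio analyses is to use samples where more
    than two species were found, i.e. ``min_species=3``.  Order preserved.
    """
    if min_species < 1:
        raise ValueError(f"min_species must be >= 1, got {min_species}")
    return [s for s in samples if s.richness >= min_species]


def pairwise_length_ratios(
    sample: OccurrenceSample,
) -> list[tuple[tuple[str, str], float]]:
    """All within-sample pairwise ratios, larger length over smaller.

    Returns one ``((species_a, species_b), ratio)`` entry per unordered
    pair, species ids in lexicographic order, ratio >= 1.  A sample of n
    species yields n(n-1)/2 ratios; equal lengths give ratio exactly 1.
    """
    for sp, length in sample.members:
        if not length > 0:
            raise ValueError(
                f"sample {sample.sample_id!r}: species {sp!r} has "
                f"non-positive length {length}"
            )
    out = []
    for (sp_a, la), (sp_b, lb) in combinations(sample.members, 2):
        if sp_b < sp_a:
            sp_a, sp_b = sp_b, sp_a
        out.append(((sp_a, sp_b), max(la, lb) / min(la, lb)))
    return out


def pool_ratios(samples: Sequence[OccurrenceSample]) -> RatioSet:
    """Concatenate pairwise ratios across samples, keeping provenance.

    No deduplication: a species pair found together in several samples
    contributes one ratio per sample.  ``n_pairs`` equals the combinatorial
    total sum of n_s(n_s - 1)/2; samples with fewer than two species
    contribute nothing and are not counted in ``n_samples_used``.
    """
    ratios: list[float] = []
    provenance: list[tuple[str, str, str]] = []
    used = 0
    for sample in samples:
        pairs = pairwise_length_ratios(sample)
        if pairs:
            used += 1
        for (sp_a, sp_b), r in pairs:
            ratios.append(r)
            provenance.append((sample.sample_id, sp_a, sp_b))
    return RatioSet(
        ratios=np.asarray(ratios, dtype=float),
        provenance=tuple(provenance),
        n_samples_used=used,
        n_pairs=len(ratios),
    )


def analyze_ratio_modes(
    ratio_set: RatioSet,
    kmin: int = 1,
    kmax: int = 10,
    criterion: str = "bic",
    n_init: int = 10,
    seed: int = 0,
) -> ModeAnalysisResult:
    """Mixture-based mode detection on the pooled log ratios.

    Fitting is done on log(ratio), where a geometric size ladder becomes a
    set of equally spaced modes; ``result.modes_linear`` gives the mode
    locations back on the ratio scale (>= 1, increasing).  Degenerate
    inputs (all ratios identical, e.g. all species the same length)
    propagate the mixture stage's zero-variance error.
    """
    if ratio_set.n_pairs < 2 * kmin:
        raise ValueError(
            f"need at least {2 * kmin} pooled pairs for kmin={kmin}, "
            f"got {ratio_set.n_pairs}"
        )
    return select_best_mixture(
        np.log(ratio_set.ratios),
        kmin=kmin,
        kmax=kmax,
        criterion=criterion,
        n_init=n_init,
        seed=seed,
    )
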