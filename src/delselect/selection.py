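"""Two-class survival model of one selection round.

A library member survives the round (is biotinylated by its own catalysis
and captured on streptavidin beads) with a class-dependent Bernoulli
probability: ``p_cat`` for catalyst-bearing members, ``p_bg`` for inactive
members retained non-specifically.  Sequencing then observes a multinomial
sample of the surviving pool at finite depth.  Only the survival *ratio*
R = p_cat / p_bg is identified by enrichment data; the closed forms below
make that explicit.

Closed forms (spike pre-frequency f0):

    post-frequency  f1 = f0*p_cat / (f0*p_cat + (1-f0)*p_bg)
    fold enrichment E  = f1 / f0 = R / (1 + f0*(R - 1))

E is strictly increasing in R and saturates at the dilution ceiling 1/f0:
a spike-in diluted 500-fold can be enriched at most 500-fold, one diluted
2000-fold at most 2000-fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .counts import CountTable
from .library import CLASS_CATALYST, LibraryTable


class DegenerateModelError(ValueError):
    """Raised when no library member can survive (all survival mass zero)."""


@dataclass(frozen=True)
class SelectionParams:
    """Parameters of one stochastic selection + sequencing round.

    p_cat, p_bg:
        Per-round survival probabilities for catalyst and background
        members.  A meaningful selection has 0 <= p_bg < p_cat <= 1;
        p_cat == p_bg (neutral selection) is allowed for controls.
    depth_pre, depth_post:
        Sequencing depths (read pairs) for the naive and the
        post-selection sample.
    seed:
        Seed for the round's random generator; None defers seeding to the
        caller.
    """

    p_cat: float = 0.30
    p_bg: float = 1e-4
    depth_pre: int = 1_000_000
    depth_post: int = 1_000_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_cat <= 1.0 and 0.0 <= self.p_bg <= 1.0):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if self.depth_pre <= 0 or self.depth_post <= 0:
            raise ValueError("sequencing depths must be positive")

    @property
    def survival_ratio(self) -> float:
        """R = p_cat / p_bg (infinite when p_bg == 0)."""
        if self.p_bg == 0.0:
            return float("inf")
        return self.p_cat / self.p_bg


def params_from_ratio(
    ratio: float,
    p_bg: float = 1e-4,
    depth_pre: int = 1_000_000,
    depth_post: int = 1_000_000,
    seed: int | None = None,
) -> SelectionParams:
    """Build SelectionParams from a survival ratio with p_bg held fixed."""
    if ratio <= 0:
        raise ValueError("survival ratio must be positive")
    p_cat = ratio * p_bg
    if p_cat > 1.0:
        raise ValueError(f"ratio {ratio} with p_bg {p_bg} implies p_cat > 1")
    return SelectionParams(
        p_cat=p_cat, p_bg=p_bg, depth_pre=depth_pre, depth_post=depth_post, seed=seed
    )


def expected_post_frequency(f0: float, p_cat: float, p_bg: float) -> float:
    """Expected post-selection frequency of the spike-in.

    f1 = f0*p_cat / (f0*p_cat + (1-f0)*p_bg).
    """
    if not (0.0 <= f0 <= 1.0):
        raise ValueError("f0 must lie in [0, 1]")
    if not (0.0 <= p_cat <= 1.0 and 0.0 <= p_bg <= 1.0):
        raise ValueError("survival probabilities must lie in [0, 1]")
    denom = f0 * p_cat + (1.0 - f0) * p_bg
    if denom == 0.0:
        raise DegenerateModelError("no survival mass: f0*p_cat + (1-f0)*p_bg == 0")
    return f0 * p_cat / denom


def expected_enrichment(f0: float, ratio: float) -> float:
    """Expected fold enrichment E = R / (1 + f0*(R - 1)).

    Monotone increasing in R, equal to 1 at R = 1, and bounded above by
    the dilution ceiling 1/f0 as R -> infinity.
    """
    if not (0.0 < f0 <= 1.0):
        raise ValueError("spike pre-frequency f0 must lie in (0, 1]")
    if not ratio > 0:
        raise ValueError("survival ratio must be positive")
    return ratio / (1.0 + f0 * (ratio - 1.0))


def enrichment_ceiling(f0: float) -> float:
    """Maximum achievable fold enrichment, 1/f0 (the dilution factor)."""
    if not (0.0 < f0 <= 1.0):
        raise ValueError("spike pre-frequency f0 must lie in (0, 1]")
    return 1.0 / f0


def ratio_for_enrichment(f0: float, enrichment: float) -> float:
    """Invert the closed form: the survival ratio R giving a target E.

    R = E*(1 - f0) / (1 - E*f0); requires 0 < E < 1/f0.
    """
    if not (0.0 < f0 <= 1.0):
        raise ValueError("spike pre-frequency f0 must lie in (0, 1]")
    if not (0.0 < enrichment < 1.0 / f0):
        raise ValueError("target enrichment must lie in (0, 1/f0)")
    return enrichment * (1.0 - f0) / (1.0 - enrichment * f0)


def survival_weights(library: LibraryTable, params: SelectionParams) -> np.ndarray:
    """Normalised expected post-selection frequencies for every member."""
    probs = np.where(
        library.classes == CLASS_CATALYST, params.p_cat, params.p_bg
    )
    weights = library.frequencies * probs
    total = weights.sum()
    if total <= 0.0:
        raise DegenerateModelError("no library member has positive survival mass")
    return weights / total


def simulate_selection(
    library: LibraryTable,
    params: SelectionParams,
    rng: np.random.Generator | None = None,
) -> tuple[CountTable, CountTable]:
    """Simulate sequencing of the naive pool and of one selection round.

    Returns (pre_counts, post_counts): multinomial draws of depth_pre
    reads from the library frequencies and depth_post reads from the
    survival-reweighted frequencies.  Each table sums exactly to its
    depth.  Deterministic given ``params.seed`` (or the supplied ``rng``).
    """
    if len(library) == 0:
        raise ValueError("cannot select from an empty library")
    library.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    pre = rng.multinomial(params.depth_pre, library.frequencies)
    post = rng.multinomial(params.depth_post, survival_weights(library, params))
    order = np.argsort(library.barcodes)
    barcodes = library.barcodes[order]
    return (
        CountTable(barcodes=barcodes, counts=pre[order]),
        CountTable(barcodes=barcodes, counts=post[order]),
    )
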