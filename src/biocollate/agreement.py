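"""Inter-rater agreement and representativeness statistics.

Repeatability of categorical scoring (predominant land use, use
intensity) is measured with Cohen's kappa, which compares the observed
agreement between two raters to the agreement expected by chance from
their marginal category frequencies: kappa = (p_o - p_e) / (1 - p_e),
ranging from 0 (chance-level) to 1 (perfect).  A weighted variant gives
partial credit to pre-specified "near misses" (adjacent categories,
indeterminate vs. determinate); the default near-miss credit is 0.5.

Representativeness of sampled land-use/intensity combinations is tested
with a Pearson chi-squared goodness-of-fit of observed site counts
against the combinations' shares of terrestrial area.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Hashable, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats

Category = Hashable

_EPS = 1e-12


class UndefinedKappaError(ValueError):
    """Both raters used a single category throughout: chance agreement is
    1 and kappa is undefined."""


@dataclass(frozen=True)
class PairedRatings:
    """Paired categorical ratings of the same items by two raters."""

    items: Tuple[Tuple[Category, Category], ...]
    category_universe: Tuple[Category, ...]

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("at least one rated item required")
        universe = set(self.category_universe)
        for a, b in self.items:
            if a not in universe or b not in universe:
                raise ValueError(f"rating ({a!r}, {b!r}) outside the category universe")

    @classmethod
    def from_pairs(
        cls, pairs: Sequence[Tuple[Category, Category]], universe: Sequence[Category] = ()
    ) -> "PairedRatings":
        if not universe:
            universe = sorted({c for p in pairs for c in p}, key=repr)
        return cls(tuple(pairs), tuple(universe))

    def marginals(self) -> Tuple[Dict[Category, float], Dict[Category, float]]:
        n = len(self.items)
        c1: Dict[Category, int] = {c: 0 for c in self.category_universe}
        c2: Dict[Category, int] = {c: 0 for c in self.category_universe}
        for a, b in self.items:
            c1[a] += 1
            c2[b] += 1
        return {c: k / n for c, k in c1.items()}, {c: k / n for c, k in c2.items()}


@dataclass(frozen=True)
class KappaResult:
    observed_agreement: float
    expected_agreement: float
    kappa: float


def _kappa_from(p_o: float, p_e: float) -> float:
    if p_e >= 1.0 - _EPS:
        raise UndefinedKappaError(
            "expected agreement is 1 (single category, or saturating credit, "
            "for both raters); kappa undefined"
        )
    return (p_o - p_e) / (1.0 - p_e)


def exact_match_credit(a: Category, b: Category) -> float:
    return 1.0 if a == b else 0.0


def cohens_kappa(ratings: PairedRatings) -> KappaResult:
    """Plain (unweighted) Cohen's kappa.

    Raises :class:`UndefinedKappaError` when both raters used one single
    category for every item, since chance agreement is then 1.
    """
    n = len(ratings.items)
    p_o = sum(1.0 for a, b in ratings.items if a == b) / n
    m1, m2 = ratings.marginals()
    p_e = sum(m1[c] * m2[c] for c in ratings.category_universe)
    return KappaResult(p_o, p_e, _kappa_from(p_o, p_e))


def weighted_kappa(
    ratings: PairedRatings, credit: Callable[[Category, Category], float]
) -> KappaResult:
    """Cohen's kappa with partial credit.

    ``credit(a, b)`` gives the agreement weight in [0, 1] for a rating
    pair; it must be symmetric with unit diagonal.  Observed agreement is
    the mean credit over items; expected agreement is the credit-weighted
    product of the two raters' marginals.  With the exact-match indicator
    this reduces bit-for-bit to :func:`cohens_kappa`.
    """
    cats = ratings.category_universe
    for a in cats:
        if credit(a, a) != 1.0:
            raise ValueError(f"credit({a!r}, {a!r}) != 1: diagonal must be unit")
    for i, a in enumerate(cats):
        for b in cats[i + 1 :]:
            wab, wba = credit(a, b), credit(b, a)
            if wab != wba:
                raise ValueError(f"credit not symmetric at ({a!r}, {b!r})")
            if not 0.0 <= wab <= 1.0:
                raise ValueError(f"credit({a!r}, {b!r}) = {wab} outside [0, 1]")

    n = len(ratings.items)
    p_o = sum(credit(a, b) for a, b in ratings.items) / n
    m1, m2 = ratings.marginals()
    p_e = sum(credit(a, b) * m1[a] * m2[b] for a in cats for b in cats)
    return KappaResult(p_o, p_e, _kappa_from(p_o, p_e))


def near_miss_credit(
    near_miss: Callable[[Category, Category], bool], weight: float = 0.5
) -> Callable[[Category, Category], float]:
    """Adapt a boolean near-miss relation into a credit function: exact
    matches score 1, near misses ``weight`` (default 0.5), everything
    else 0."""

    def credit(a: Category, b: Category) -> float:
        if a == b:
            return 1.0
        return weight if near_miss(a, b) else 0.0

    return credit


# ---------------------------------------------------------------------------
# Representativeness


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    degrees_of_freedom: int
    p_value: float

    def p_value_text(self) -> str:
        """p-value for reporting; values below double-precision range
        are printed as a bound."""
        if self.p_value < 2.2e-16:
            return "< 2.2e-16"
        return f"{self.p_value:.6g}"


def representativeness_chisq(
    observed: Mapping[Category, float],
    expected_props: Mapping[Category, float],
    exclude: Sequence[Category] = (),
) -> ChiSquareResult:
    """Pearson goodness-of-fit of observed site counts per category
    (land-use x intensity combination) against expected proportions
    (shares of terrestrial area).

    Categories in ``exclude`` (e.g. combinations for which no area
    estimate exists) are dropped from both sides; the remaining expected
    proportions are renormalised to sum to 1.  df = k - 1 for the k
    included categories.
    """
    excluded = set(exclude)
    keys = [k for k in observed if k not in excluded]
    if not keys:
        raise ValueError("no categories left after exclusion")
    missing = [k for k in keys if k not in expected_props]
    if missing:
        raise ValueError(f"no expected proportion for categories {missing!r}")
    props = np.array([float(expected_props[k]) for k in keys])
    total_prop = props.sum()
    if total_prop <= 0:
        raise ValueError("expected proportions sum to zero after exclusion")
    props = props / total_prop
    zero = [keys[i] for i in np.nonzero(props <= 0)[0]]
    if zero:
        raise ValueError(f"zero expected proportion after renormalisation for {zero!r}")
    obs = np.array([float(observed[k]) for k in keys])
    n = obs.sum()
    expected = n * props
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = len(keys) - 1
    p = float(stats.chi2.sf(statistic, df))
    return ChiSquareResult(statistic, df, p)
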