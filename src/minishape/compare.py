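"""Predicted-vs-experimental profile comparison and outlier analysis.

The comparison pipeline scores agreement between an experimental SHAPE
profile and a 3D-structure-based predicted profile (Pearson correlation,
optionally disattenuated for replicate noise), forms the per-position
differential profile on the unit scale, identifies the heavy-tailed law
that best describes the differentials (Cauchy in practice), and calls
extreme outliers with Tukey fences at 3x the interquartile range.  Outliers
are then assigned to named structural regions, and candidate designs are
ranked by their correlation against a reference design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .construct import RegionAnnotation
from .errors import DegeneracyError, SpecificationError, StateError
from .reactivity import MISSING, ReactivityProfile


@dataclass(frozen=True)
class ComparisonResult:
    """Pearson agreement between an experimental and a predicted profile."""

    rho: float
    rho_noise_adjusted: float
    n_positions: int


def pearson_correlation(
    exp: ReactivityProfile,
    pred: ReactivityProfile,
    noise: np.ndarray | None = None,
) -> ComparisonResult:
    """Pearson correlation over pairwise-complete positions.

    When per-position error estimates are supplied, the correlation is also
    disattenuated: the reliability of the experimental profile is estimated
    as ``1 - mean(error^2) / var(exp)`` (clipped to (0, 1]) and the adjusted
    correlation is ``rho / sqrt(reliability)``, clipped to [-1, 1].  Without
    noise input the adjusted value equals the raw one.
    """
    if len(exp) != len(pred):
        raise SpecificationError("profiles differ in length")
    mask = exp.mask & pred.mask
    n = int(mask.sum())
    if n < 3:
        raise DegeneracyError(f"only {n} pairwise-complete positions (need >= 3)")
    x = exp.values[mask]
    y = pred.values[mask]
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegeneracyError("zero variance in one of the profiles")
    rho = float(stats.pearsonr(x, y).statistic)

    rho_adj = rho
    if noise is not None:
        err = np.asarray(noise, dtype=float)[mask]
        var_x = float(np.var(x, ddof=1))
        reliability = 1.0 - float(np.mean(err**2)) / var_x
        reliability = min(1.0, max(reliability, np.finfo(float).eps))
        rho_adj = float(np.clip(rho / np.sqrt(reliability), -1.0, 1.0))
    return ComparisonResult(rho=rho, rho_noise_adjusted=rho_adj, n_positions=n)


@dataclass(frozen=True)
class DifferentialProfile:
    """Per-position normalized experimental minus predicted reactivity.

    ``deltas`` uses the -999 sentinel where either input was missing;
    ``labels`` carries the construct's native labels when known.
    """

    deltas: np.ndarray
    labels: tuple[object, ...] | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.deltas, dtype=float)
        if self.labels is not None and len(self.labels) != len(d):
            raise SpecificationError("labels length must match deltas")
        object.__setattr__(self, "deltas", d)

    def __len__(self) -> int:
        return len(self.deltas)

    @property
    def mask(self) -> np.ndarray:
        return self.deltas != MISSING

    def finite_deltas(self) -> np.ndarray:
        return self.deltas[self.mask]

    def label_at(self, index: int):
        """Native label for 1-based position ``index`` (the index itself
        when the profile carries no labels)."""
        if self.labels is None:
            return index
        return self.labels[index - 1]


def differential_profile(
    exp_scaled: ReactivityProfile,
    pred_scaled: ReactivityProfile,
    labels: Sequence[object] | None = None,
) -> DifferentialProfile:
    """delta(i) = experimental(i) - predicted(i), both unit-scaled."""
    for p, which in ((exp_scaled, "experimental"), (pred_scaled, "predicted")):
        if p.state != "unit_scaled":
            raise StateError(
                f"{which} profile must be unit_scaled, got state {p.state!r}"
            )
    if len(exp_scaled) != len(pred_scaled):
        raise SpecificationError("profiles differ in length")
    mask = exp_scaled.mask & pred_scaled.mask
    deltas = np.full(len(exp_scaled), MISSING)
    deltas[mask] = exp_scaled.values[mask] - pred_scaled.values[mask]
    return DifferentialProfile(
        deltas, labels=tuple(labels) if labels is not None else None
    )


# ---------------------------------------------------------------------------
# distribution fitting

#: scipy names of the default candidate families for differential reactivity
DEFAULT_FAMILIES = ("cauchy", "norm", "laplace", "logistic")

#: histogram rule used for goodness-of-fit: fixed 0.1-wide bins over [-1, 1]
HISTOGRAM_BINS = np.round(np.arange(-1.0, 1.0 + 1e-9, 0.1), 10)


@dataclass(frozen=True)
class DistributionFit:
    """One candidate family fit to the differential distribution."""

    family: str
    parameters: tuple[float, ...]  # scipy shape params + (loc, scale)
    goodness: float  # SSE between fitted pdf and histogram density
    rank: int

    @property
    def location(self) -> float:
        return self.parameters[-2]

    @property
    def scale(self) -> float:
        return self.parameters[-1]


def fit_distribution(
    deltas: DifferentialProfile | np.ndarray,
    candidates: Sequence[str] = DEFAULT_FAMILIES,
    *,
    bins: np.ndarray | None = None,
) -> list[DistributionFit]:
    """Fit candidate families by maximum likelihood and rank by histogram SSE.

    Each family is fit with scipy's MLE; goodness is the sum of squared
    errors between the fitted density and the empirical histogram density
    on fixed 0.1-wide bins over [-1, 1].  Families are returned ascending by
    goodness (best first); exact ties keep the candidate listing order.
    """
    data = (
        deltas.finite_deltas()
        if isinstance(deltas, DifferentialProfile)
        else np.asarray(deltas, dtype=float)
    )
    if len(data) < 30:
        raise SpecificationError(f"need >= 30 deltas to fit, got {len(data)}")
    if len(candidates) < 2:
        raise SpecificationError("need >= 2 candidate families")
    if np.ptp(data) == 0:
        raise DegeneracyError("constant deltas: distribution fit undefined")

    edges = HISTOGRAM_BINS if bins is None else np.asarray(bins, dtype=float)
    density, edges = np.histogram(data, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    fits = []
    for order, name in enumerate(candidates):
        family = getattr(stats, name)
        params = family.fit(data)
        sse = float(np.sum((family.pdf(centers, *params) - density) ** 2))
        fits.append((sse, order, name, tuple(float(p) for p in params)))
    fits.sort(key=lambda t: (t[0], t[1]))
    return [
        DistributionFit(family=name, parameters=params, goodness=sse, rank=r + 1)
        for r, (sse, _, name, params) in enumerate(fits)
    ]


# ---------------------------------------------------------------------------
# extreme-outlier calling


@dataclass(frozen=True)
class OutlierCall:
    """One extreme differential-reactivity position."""

    position: object  # native label (or 1-based index when unlabelled)
    delta: float
    sign: str  # "high" | "low"
    region: str = "unassigned"


@dataclass(frozen=True)
class OutlierReport:
    """Quartiles, fences and the extreme-outlier calls they imply.

    In the default Tukey mode ``upper_fence = q3 + multiplier * iqr`` and
    ``lower_fence = q1 - multiplier * iqr``; in absolute mode the fences are
    symmetric at ``+-multiplier * iqr``.
    """

    q1: float
    q3: float
    multiplier: float
    upper_fence: float
    lower_fence: float
    outliers: tuple[OutlierCall, ...]
    n_positions: int

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def regions_hit(self) -> tuple[str, ...]:
        seen: list[str] = []
        for call in self.outliers:
            if call.region != "unassigned" and call.region not in seen:
                seen.append(call.region)
        return tuple(seen)


def iqr_outliers(
    deltas: DifferentialProfile,
    multiplier: float = 3.0,
    *,
    mode: str = "tukey",
) -> OutlierReport:
    """Call extreme outliers with fences at ``multiplier`` x IQR.

    Quartiles use linear interpolation between order statistics.  The
    default Tukey mode places fences at ``q1 - m*IQR`` and ``q3 + m*IQR``;
    ``mode="absolute"`` instead flags ``|delta| > m*IQR``, the alternative
    reading of the extreme-outlier rule.
    """
    data = deltas.finite_deltas()
    if len(data) < 4:
        raise SpecificationError(f"need >= 4 deltas for quartiles, got {len(data)}")
    if mode not in ("tukey", "absolute"):
        raise SpecificationError(f"unknown fence mode {mode!r}")
    q1, q3 = (float(q) for q in np.quantile(data, [0.25, 0.75]))
    iqr = q3 - q1
    if mode == "tukey":
        upper = q3 + multiplier * iqr
        lower = q1 - multiplier * iqr
    else:
        upper = multiplier * iqr
        lower = -multiplier * iqr

    calls = []
    for i, d in enumerate(deltas.deltas, start=1):
        if d == MISSING:
            continue
        if d > upper:
            calls.append(OutlierCall(deltas.label_at(i), float(d), "high"))
        elif d < lower:
            calls.append(OutlierCall(deltas.label_at(i), float(d), "low"))
    return OutlierReport(
        q1=q1,
        q3=q3,
        multiplier=multiplier,
        upper_fence=upper,
        lower_fence=lower,
        outliers=tuple(calls),
        n_positions=len(data),
    )


def assign_regions(
    report: OutlierReport, regions: Sequence[RegionAnnotation]
) -> OutlierReport:
    """Label each outlier with the first region (in declared order) that
    contains its native label, else "unassigned"."""
    names = [r.name for r in regions]
    if len(set(names)) != len(names):
        raise SpecificationError("region names must be unique")
    assigned = []
    for call in report.outliers:
        region = "unassigned"
        for r in regions:
            if call.position in r.positions:
                region = r.name
                break
        assigned.append(
            OutlierCall(call.position, call.delta, call.sign, region=region)
        )
    return OutlierReport(
        q1=report.q1,
        q3=report.q3,
        multiplier=report.multiplier,
        upper_fence=report.upper_fence,
        lower_fence=report.lower_fence,
        outliers=tuple(assigned),
        n_positions=report.n_positions,
    )


# ---------------------------------------------------------------------------
# design ranking


@dataclass(frozen=True)
class RankedDesign:
    """One design's standing relative to the reference."""

    design_name: str
    rho: float
    rho_noise_adjusted: float
    rank: int
    flag: str  # "reference" | "improved" | "worse"


def rank_designs(
    entries: Mapping[str, ComparisonResult] | Sequence[tuple[str, ComparisonResult]],
    reference_name: str,
) -> list[RankedDesign]:
    """Rank designs by noise-adjusted correlation against a reference.

    Descending by correlation, ties broken by design name for
    reproducibility.  Each non-reference design is flagged ``improved`` when
    strictly above the reference, else ``worse``.
    """
    items = list(entries.items()) if isinstance(entries, Mapping) else list(entries)
    by_name = dict(items)
    if reference_name not in by_name:
        raise SpecificationError(f"reference design {reference_name!r} not in entries")
    ref_rho = by_name[reference_name].rho_noise_adjusted
    ordered = sorted(items, key=lambda kv: (-kv[1].rho_noise_adjusted, kv[0]))
    out = []
    for rank, (name, res) in enumerate(ordered, start=1):
        if name == reference_name:
            flag = "reference"
        elif res.rho_noise_adjusted > ref_rho:
            flag = "improved"
        else:
            flag = "worse"
        out.append(
            RankedDesign(
                design_name=name,
                rho=res.rho,
                rho_noise_adjusted=res.rho_noise_adjusted,
                rank=rank,
                flag=flag,
            )
        )
    return out
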