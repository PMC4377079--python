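"""Core containers for summarized and individual-level Mendelian randomization data.

Summarized data are per-variant regression coefficients: the per-allele
association of each genetic variant with the risk factor X (``beta_x``, with
standard error ``se_x``) and with the outcome Y (``beta_y``, ``se_y``; a
log-odds or log-risk change for binary outcomes).  Individual-level data are a
genotype matrix of allele counts together with the risk factor and outcome
measured on the same people.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Z95",
    "VariantAssociation",
    "SummarySet",
    "CausalEstimate",
    "IndividualData",
]

# Normal 95% critical value; association SEs are treated as known throughout,
# so normal rather than t quantiles are used everywhere.
Z95 = 1.96


class UndefinedRatioError(ZeroDivisionError):
    """Raised when a ratio estimate is requested for a variant with beta_x == 0."""


@dataclass(frozen=True)
class VariantAssociation:
    """Summarized associations of one genetic variant.

    Parameters
    ----------
    label : str
        Variant identifier (e.g. an rsID); must be unique within a set.
    beta_x : float
        Per-allele change in the risk factor.
    se_x : float
        Standard error of ``beta_x``; must be positive.
    beta_y : float
        Per-allele change in the outcome (log-odds / log-risk if binary).
    se_y : float
        Standard error of ``beta_y``; must be positive.
    """

    label: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float

    def __post_init__(self) -> None:
        vals = (self.beta_x, self.se_x, self.beta_y, self.se_y)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"variant {self.label!r}: non-finite association value")
        if self.se_x <= 0:
            raise ValueError(f"variant {self.label!r}: se_x must be > 0, got {self.se_x}")
        if self.se_y <= 0:
            raise ValueError(f"variant {self.label!r}: se_y must be > 0, got {self.se_y}")


@dataclass(frozen=True)
class SummarySet:
    """An ordered collection of variant associations plus the correlation rho.

    ``rho`` is the correlation between the paired genetic association
    estimates (risk factor vs outcome) when both come from the same sample —
    approximately the observational X–Y correlation.  In a two-sample design
    the estimates are independent and rho is 0 (the default).
    """

    variants: tuple[VariantAssociation, ...]
    rho: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "variants", tuple(self.variants))
        if len(self.variants) < 1:
            raise ValueError("SummarySet requires at least one variant")
        labels = [v.label for v in self.variants]
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate variant labels: {dup}")
        if not (np.isfinite(self.rho) and abs(self.rho) < 1):
            raise ValueError(f"rho must satisfy |rho| < 1, got {self.rho}")

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self.variants)

    def with_rho(self, rho: float) -> "SummarySet":
        return SummarySet(self.variants, rho)

    @property
    def beta_x(self) -> np.ndarray:
        return np.array([v.beta_x for v in self.variants])

    @property
    def se_x(self) -> np.ndarray:
        return np.array([v.se_x for v in self.variants])

    @property
    def beta_y(self) -> np.ndarray:
        return np.array([v.beta_y for v in self.variants])

    @property
    def se_y(self) -> np.ndarray:
        return np.array([v.se_y for v in self.variants])


@dataclass(frozen=True)
class CausalEstimate:
    """A causal-effect estimate with Wald 95% confidence interval.

    ``method`` is one of ``ratio``, ``ivw``, ``mle``, ``tsls``, ``liml`` or
    ``ols``; ``k`` is the number of genetic variants used (0 for the
    observational OLS estimate, which uses none).
    """

    beta: float
    se: float
    method: str
    k: int
    ci_low: float = field(default=None)  # type: ignore[assignment]
    ci_high: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta):
            raise ValueError("non-finite causal estimate")
        if not (np.isfinite(self.se) and self.se > 0):
            raise ValueError(f"standard error must be > 0, got {self.se}")
        if self.ci_low is None:
            object.__setattr__(self, "ci_low", self.beta - Z95 * self.se)
        if self.ci_high is None:
            object.__setattr__(self, "ci_high", self.beta + Z95 * self.se)
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("confidence limits must bracket the point estimate")

    def covers(self, value: float) -> bool:
        """Whether the 95% CI contains ``value``."""
        return self.ci_low <= value <= self.ci_high


@dataclass
class IndividualData:
    """Individual-level data: genotypes, risk factor and outcome.

    ``genotypes`` is an n × K matrix of minor-allele counts in {0, 1, 2}.
    ``u`` optionally stores the simulated confounder for bookkeeping; it is
    never used by any estimator.
    """

    genotypes: np.ndarray
    x: np.ndarray
    y: np.ndarray
    u: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-d matrix")
        n, k = self.genotypes.shape
        if k < 1:
            raise ValueError("at least one variant required")
        if self.x.shape != (n,) or self.y.shape != (n,):
            raise ValueError("x and y must have one entry per genotype row")
        if self.u is not None:
            self.u = np.asarray(self.u, dtype=float)
            if self.u.shape != (n,):
                raise ValueError("u must have one entry per genotype row")
        if not np.isin(self.genotypes, (0.0, 1.0, 2.0)).all():
            raise ValueError("genotype entries must be allele counts in {0, 1, 2}")
        var = self.genotypes.var(axis=0)
        if (var == 0).any():
            bad = [int(j) for j in np.flatnonzero(var == 0)]
            raise ValueError(f"variant column(s) {bad} have zero in-sample variance")

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def k(self) -> int:
        return self.genotypes.shape[1]


def summary_set_from_arrays(
    beta_x: Sequence[float],
    se_x: Sequence[float],
    beta_y: Sequence[float],
    se_y: Sequence[float],
    labels: Sequence[str] | None = None,
    rho: float = 0.0,
) -> SummarySet:
    """Build a :class:`SummarySet` from parallel arrays (labels autogenerated)."""
    k = len(beta_x)
    if labels is None:
        labels = [f"g{j + 1}" for j in range(k)]
    variants = tuple(
        VariantAssociation(str(labels[j]), float(beta_x[j]), float(se_x[j]),
                           float(beta_y[j]), float(se_y[j]))
        for j in range(k)
    )
    return SummarySet(variants, rho)
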