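"""Concordance and cohort-summary statistics for platform validation.

Concordance between the platform's diagnostic level and the clinician's is
strict label equality on the three-level vocabulary — an Established versus
Probable disagreement counts as a mismatch, deliberately without partial
credit. Rates are reported as percentages to 2 decimal places; the pooled
95% confidence interval uses the plain (uncorrected) Wilson score interval,
reported to 1 decimal place. Rounding is half-up throughout, matching how
clinical reports print proportions.

Sensitivity and specificity are intentionally not computed: a single-arm
concordance study without negative controls cannot support them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional, Sequence, Union

from scipy.stats import norm


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def wilson_interval(successes: int, trials: int,
                    confidence: float = 0.95) -> tuple[float, float]:
    """Plain Wilson score interval for a binomial proportion.

    Returns (low, high) as proportions in [0, 1]. The normal critical value
    is computed from ``confidence``, so any level in (0, 1) works. No
    continuity correction is applied.
    """
    if not isinstance(successes, (int,)) or not isinstance(trials, (int,)):
        raise TypeError("successes and trials must be integers")
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes must be in [0, trials]")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    z = float(norm.ppf((1 + confidence) / 2))
    p = successes / trials
    denom = 1 + z * z / trials
    center = (p + z * z / (2 * trials)) / denom
    halfwidth = z * math.sqrt(p * (1 - p) / trials + z * z / (4 * trials * trials)) / denom
    return (max(0.0, center - halfwidth), min(1.0, center + halfwidth))


@dataclass(frozen=True)
class LabelPair:
    """One paired platform/clinician diagnosis."""

    platform_level: str
    clinician_level: str
    site: str
    subject_id: str = ""

    @property
    def concordant(self) -> bool:
        return self.platform_level == self.clinician_level


@dataclass(frozen=True)
class SiteConcordance:
    site: str
    n: int
    n_concordant: int
    rate: float  # percent, 2 dp


@dataclass(frozen=True)
class ConcordanceResult:
    per_site: tuple[SiteConcordance, ...]
    n: int
    n_concordant: int
    rate: float      # percent, 2 dp
    ci_low: float    # percent, 1 dp
    ci_high: float   # percent, 1 dp
    mismatches: tuple[LabelPair, ...]


_LEVELS = {"Clinically Established PD", "Clinically Probable PD", "Not PD"}

PairLike = Union[LabelPair, tuple]


def _as_pair(p: PairLike) -> LabelPair:
    if isinstance(p, LabelPair):
        return p
    platform, clinician, site = p[0], p[1], p[2]
    subject = p[3] if len(p) > 3 else ""
    return LabelPair(platform_level=str(platform), clinician_level=str(clinician),
                     site=str(site), subject_id=str(subject))


def concordance_report(pairs: Sequence[PairLike],
                       confidence: float = 0.95) -> ConcordanceResult:
    """Per-site and pooled concordance with a Wilson interval on the pooled rate.

    ``pairs`` holds (platform level, clinician level, site[, subject id])
    tuples or :class:`LabelPair` objects; levels must come from the
    three-level vocabulary. Permutation-invariant over the input order.
    """
    if not pairs:
        raise ValueError("concordance_report requires at least one pair")
    norm_pairs = [_as_pair(p) for p in pairs]
    for p in norm_pairs:
        for level in (p.platform_level, p.clinician_level):
            if level not in _LEVELS:
                raise ValueError(f"unknown diagnostic level: {level!r}")

    per_site = []
    for site in sorted({p.site for p in norm_pairs}):
        sp = [p for p in norm_pairs if p.site == site]
        k = sum(p.concordant for p in sp)
        per_site.append(SiteConcordance(
            site=site, n=len(sp), n_concordant=k,
            rate=_round_half_up(100.0 * k / len(sp), 2),
        ))
    n = len(norm_pairs)
    k = sum(p.concordant for p in norm_pairs)
    lo, hi = wilson_interval(k, n, confidence)
    mismatches = tuple(sorted(
        (p for p in norm_pairs if not p.concordant),
        key=lambda p: (p.site, p.subject_id),
    ))
    return ConcordanceResult(
        per_site=tuple(per_site), n=n, n_concordant=k,
        rate=_round_half_up(100.0 * k / n, 2),
        ci_low=_round_half_up(100.0 * lo, 1),
        ci_high=_round_half_up(100.0 * hi, 1),
        mismatches=mismatches,
    )


# ---------------------------------------------------------------------------
# Cohort summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SummaryRow:
    variable: str
    kind: str                       # "mean" or "count"
    per_site: dict                  # site -> value
    pooled: float


@dataclass(frozen=True)
class CohortSummary:
    site_ns: dict
    rows: tuple[SummaryRow, ...]

    def pooled(self, variable: str) -> float:
        for row in self.rows:
            if row.variable == variable:
                return row.pooled
        raise KeyError(f"unknown variable: {variable}")


def pooled_mean(site_means: Mapping[str, float], site_ns: Mapping[str, int],
                ndigits: int = 2) -> float:
    """Sample-size-weighted average of site means, rounded half-up."""
    if set(site_means) != set(site_ns):
        raise ValueError("site_means and site_ns must cover the same sites")
    total_n = sum(site_ns.values())
    if total_n <= 0:
        raise ValueError("total n must be positive")
    value = sum(site_means[s] * site_ns[s] for s in site_means) / total_n
    return _round_half_up(value, ndigits)


def cohort_summary_from_site_stats(
    site_means: Mapping[str, Mapping[str, float]],
    site_ns: Mapping[str, int],
) -> CohortSummary:
    """Build a pooled summary from per-site means (e.g. a printed site table).

    ``site_means`` maps site -> {variable -> mean}; the pooled column is the
    sample-size-weighted average of the site means, rounded to 2 decimals.
    """
    sites = sorted(site_ns)
    variables: list[str] = []
    for s in sites:
        for v in site_means[s]:
            if v not in variables:
                variables.append(v)
    rows = []
    for var in variables:
        per_site = {s: site_means[s][var] for s in sites}
        rows.append(SummaryRow(
            variable=var, kind="mean", per_site=per_site,
            pooled=pooled_mean(per_site, dict(site_ns)),
        ))
    return CohortSummary(site_ns=dict(site_ns), rows=tuple(rows))


_NUMERIC_EXTRACTORS = {
    "age": lambda r: r.demographics.age,
    "moca": lambda r: r.scales.moca_total,
    "upsit": lambda r: r.scales.upsit_total,
    "updrs_part1": lambda r: r.scales.updrs.part_sum(1),
    "updrs_part2": lambda r: r.scales.updrs.part_sum(2),
    "updrs_part3": lambda r: r.scales.updrs.part_sum(3),
    "updrs_part4": lambda r: r.scales.updrs.part_sum(4),
}

_COUNT_EXTRACTORS = {
    "n_female": lambda r: r.demographics.sex == "female",
    "n_male": lambda r: r.demographics.sex == "male",
    "n_not_hispanic": lambda r: r.demographics.ethnicity == "not_hispanic_or_latino",
}


def cohort_summary(records_by_site: Mapping[str, Sequence],
                   variables: Iterable[str] = ("age", "moca", "upsit")) -> CohortSummary:
    """Per-site and pooled summary of a cohort of patient records.

    Numeric variables are summarized by site means (pooled = weighted
    average, 2 dp); count variables (``n_female``, ``n_male``,
    ``n_not_hispanic``) by site counts (pooled = sum).
    """
    sites = sorted(records_by_site)
    site_ns = {s: len(records_by_site[s]) for s in sites}
    if any(n < 1 for n in site_ns.values()):
        raise ValueError("every site must contribute at least one record")
    rows = []
    for var in variables:
        if var in _NUMERIC_EXTRACTORS:
            fn = _NUMERIC_EXTRACTORS[var]
            per_site = {}
            for s in sites:
                vals = [fn(r) for r in records_by_site[s] if fn(r) is not None]
                if not vals:
                    raise ValueError(f"no recorded values for {var!r} at site {s}")
                per_site[s] = _round_half_up(sum(vals) / len(vals), 2)
            rows.append(SummaryRow(var, "mean", per_site,
                                   pooled_mean(per_site, site_ns)))
        elif var in _COUNT_EXTRACTORS:
            fn = _COUNT_EXTRACTORS[var]
            per_site = {s: sum(bool(fn(r)) for r in records_by_site[s]) for s in sites}
            rows.append(SummaryRow(var, "count", per_site,
                                   float(sum(per_site.values()))))
        else:
            raise KeyError(f"unknown summary variable: {var!r}")
    return CohortSummary(site_ns=site_ns, rows=tuple(rows))
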