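"""Domain-enrichment and 2x2 contingency statistics.

Overrepresentation of protein domains in a foreground protein set against
a background set is tested per domain with Fisher's exact test on the 2x2
table (foreground with/without domain, background with/without), corrected
across domains with Benjamini-Hochberg step-up FDR. The counting unit is
proteins carrying at least one copy of the domain, which keeps the table
margins fixed across domains; counting domain instances instead is
available behind a flag when building tables. A plain Pearson chi-square
(optionally Yates-corrected) covers two-proportion comparisons such as
lethal-phenotype fractions between ortholog classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class DomainCountTable:
    """Per-domain 2x2 counts: columns fg_with, fg_without, bg_with, bg_without."""

    data: pd.DataFrame

    REQUIRED = ("fg_with", "fg_without", "bg_with", "bg_without")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if (self.data[list(self.REQUIRED)] < 0).any().any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_membership(
        cls,
        fg_domains: dict[str, set[str]],
        bg_domains: dict[str, set[str]],
    ) -> "DomainCountTable":
        """Build the table from protein -> domain-set maps (presence counting)."""
        n_fg, n_bg = len(fg_domains), len(bg_domains)
        all_domains = sorted(
            set().union(*fg_domains.values(), *bg_domains.values(), set())
        )
        rows = []
        for domain in all_domains:
            a = sum(1 for doms in fg_domains.values() if domain in doms)
            c = sum(1 for doms in bg_domains.values() if domain in doms)
            rows.append(
                {
                    "domain": domain,
                    "fg_with": a,
                    "fg_without": n_fg - a,
                    "bg_with": c,
                    "bg_without": n_bg - c,
                }
            )
        return cls(pd.DataFrame(rows).set_index("domain"))


@dataclass(frozen=True)
class EnrichmentResult:
    domain: str
    odds_ratio: float
    p_value: float
    q_value: float


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up FDR adjustment; q-values are monotone in the p-ranking."""
    p = np.asarray(p_values, dtype=float)
    return stats.false_discovery_control(p, method="bh")


def fisher_enrichment(
    table: DomainCountTable,
    alternative: str = "greater",
) -> list[EnrichmentResult]:
    """Per-domain Fisher exact test with BH correction across domains.

    ``alternative='greater'`` (the default for overrepresentation) uses the
    upper hypergeometric tail; ``'two_sided'`` sums point probabilities no
    larger than the observed one. The odds ratio is ``(a*d)/(b*c)``,
    reported as infinity when ``b*c == 0``.
    """
    df = table.data
    if df.empty:
        raise ValueError("empty domain count table")
    a = df["fg_with"].to_numpy(dtype=np.int64)
    b = df["fg_without"].to_numpy(dtype=np.int64)
    c = df["bg_with"].to_numpy(dtype=np.int64)
    d = df["bg_without"].to_numpy(dtype=np.int64)
    if ((a + b + c + d) == 0).any():
        raise ValueError("all-zero 2x2 table encountered")

    if alternative == "greater":
        # P(X >= a) for X ~ Hypergeom(N, a+b, a+c)
        p = stats.hypergeom.sf(a - 1, a + b + c + d, a + b, a + c)
    elif alternative == "two_sided":
        p = np.array(
            [
                stats.fisher_exact([[ai, bi], [ci, di]], alternative="two-sided")[1]
                for ai, bi, ci, di in zip(a, b, c, d)
            ]
        )
    else:
        raise ValueError(f"unknown alternative: {alternative!r}")
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q = benjamini_hochberg(p)

    with np.errstate(divide="ignore", invalid="ignore"):
        odds = np.where(b * c == 0, np.inf, (a * d) / np.maximum(b * c, 1))
    return [
        EnrichmentResult(domain, float(o), float(pi), float(qi))
        for domain, o, pi, qi in zip(df.index, odds, p, q)
    ]


def chi2_2x2(
    a: int, b: int, c: int, d: int, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square test (1 df) on a 2x2 table of counts.

    Raises when any expected cell is zero — use Fisher's exact test for
    such sparse tables.
    """
    observed = np.array([[a, b], [c, d]], dtype=float)
    if (observed < 0).any():
        raise ValueError("counts must be non-negative")
    if observed.sum() < 1:
        raise ValueError("table total must be >= 1")
    expected = stats.contingency.expected_freq(observed)
    if (expected == 0).any():
        raise ValueError(
            "an expected cell is zero; use Fisher's exact test instead"
        )
    stat, p, _, _ = stats.chi2_contingency(observed, correction=yates)
    return float(stat), float(p)
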