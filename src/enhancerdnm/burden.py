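"""Exact-test statistics: case-control CNV burden, promoter-binding geneset
enrichment, coding DNV excess, and phenotype-frequency comparisons.

All categorical comparisons reduce to a 2x2 :class:`ContingencyTable` tested
with Fisher's exact test (one-sided unless stated).  Odds ratios are reported
in two conventions: the sample OR (a*d)/(b*c), infinite when a zero cell
makes it so, and the conditional maximum-likelihood OR from the noncentral
hypergeometric model, since published ORs alongside Fisher p-values typically
derive from the latter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cmle_odds_ratio

__all__ = [
    "ContingencyTable",
    "FisherResult",
    "fisher_exact",
    "geneset_binding_enrichment",
    "poisson_dnv_excess",
    "PhenotypeTable",
    "phenotype_compare",
    "symptom_count",
]

_ALTERNATIVES = {"greater", "less", "two_sided"}


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a/b exposed/unexposed in group 1, c/d in group 2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError(f"contingency counts must be nonnegative integers, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    @property
    def sample_odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return math.inf if self.a * self.d > 0 else math.nan
        return (self.a * self.d) / (self.b * self.c)


@dataclass(frozen=True)
class FisherResult:
    table: ContingencyTable
    p: float
    odds_ratio: float       # sample OR, inf on zero cells
    odds_ratio_cmle: float  # conditional-MLE OR


def fisher_exact(table: ContingencyTable, alternative: str = "greater") -> FisherResult:
    """Fisher's exact test on a 2x2 table.

    One-sided p-values sum hypergeometric tail probabilities; the two-sided
    p sums all tables at least as extreme as observed.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {sorted(_ALTERNATIVES)}")
    arr = table.as_array()
    _, p = stats.fisher_exact(arr, alternative=alternative.replace("two_sided", "two-sided"))
    try:
        cmle = float(_cmle_odds_ratio(arr, kind="conditional").statistic)
    except ValueError:
        cmle = math.nan
    return FisherResult(table, float(p), table.sample_odds_ratio, cmle)


def geneset_binding_enrichment(
    geneset: Iterable[str], bound: Iterable[str], universe: Iterable[str]
) -> tuple[ContingencyTable, float, float, float]:
    """Enrichment of a geneset for membership in a bound-promoter set.

    Builds the 2x2 table (in-set & bound, in-set & unbound, out-of-set &
    bound, out-of-set & unbound) over the gene universe and applies a
    one-sided (greater) Fisher test.  Returns
    ``(table, p, sample_odds_ratio, fraction_bound)``.
    """
    geneset = set(geneset)
    bound = set(bound)
    universe = set(universe)
    if not geneset:
        raise ValueError("geneset is empty")
    if not geneset <= universe:
        raise ValueError("geneset must be a subset of the universe")
    bound &= universe
    a = len(geneset & bound)
    b = len(geneset) - a
    c = len(bound) - a
    d = len(universe) - len(geneset) - c
    table = ContingencyTable(a, b, c, d)
    res = fisher_exact(table, alternative="greater")
    return table, res.p, res.odds_ratio, a / len(geneset)


def poisson_dnv_excess(n_obs: int, n_trios: int, per_gene_rate: float) -> float:
    """Excess test for coding DNVs in a gene: P(X >= n_obs), X ~ Poisson(2 N mu_g).

    ``per_gene_rate`` is the expected number of qualifying DNVs per chromosome
    per generation; computed through the regularized lower incomplete gamma
    function P(X >= n) = P_gamma(n, lam).
    """
    if n_obs < 0:
        raise ValueError("n_obs must be >= 0")
    if n_trios < 1:
        raise ValueError("n_trios must be >= 1")
    if per_gene_rate <= 0:
        raise ValueError("per_gene_rate must be positive")
    lam = 2.0 * n_trios * per_gene_rate
    if n_obs == 0:
        return 1.0
    from scipy.special import gammainc

    return float(gammainc(n_obs, lam))


PRESENT, ABSENT, MISSING = "+", "-", "NA"


@dataclass
class PhenotypeTable:
    """Individuals x phenotypes status matrix with +/-/NA codes.

    ``data`` is a DataFrame indexed by individual with a ``group`` column and
    one column per phenotype holding exactly one of the codes '+'
    (present), '-' (absent), 'NA' (assessment missing).  Missing individuals
    are excluded per phenotype, never globally.
    """

    data: pd.DataFrame
    group_col: str = "group"

    def __post_init__(self):
        codes = {PRESENT, ABSENT, MISSING}
        pheno = self.data.drop(columns=[self.group_col])
        bad = set(np.unique(pheno.astype(str).values)) - codes
        if bad:
            raise ValueError(f"invalid phenotype codes: {sorted(bad)}")

    @property
    def phenotypes(self) -> list[str]:
        return [c for c in self.data.columns if c != self.group_col]

    def counts(self, phenotype: str, group: str) -> tuple[int, int]:
        """(present, absent) among assessed individuals of a group."""
        if phenotype not in self.data.columns:
            raise KeyError(f"phenotype {phenotype!r} not in table")
        col = self.data.loc[self.data[self.group_col] == group, phenotype]
        return int((col == PRESENT).sum()), int((col == ABSENT).sum())


def phenotype_compare(
    table: PhenotypeTable,
    phenotype: str,
    group1: str,
    group2: str,
    alternative: str = "greater",
) -> tuple[ContingencyTable, float, float]:
    """One-sided Fisher comparison of a phenotype's frequency between groups.

    Only individuals with an assessment for the phenotype enter the counts;
    ``alternative='greater'`` tests for a higher rate in ``group1``.
    """
    a, b = table.counts(phenotype, group1)
    c, d = table.counts(phenotype, group2)
    if a + b == 0 or c + d == 0:
        raise ValueError(
            f"no assessed individuals for {phenotype!r} in one of the groups"
        )
    ct = ContingencyTable(a, b, c, d)
    res = fisher_exact(ct, alternative=alternative)
    return ct, res.p, res.odds_ratio


def symptom_count(
    row: pd.Series,
    neurological_prefix: str = "neuro_",
    diagnosis_prefix: str = "diag_",
    craniofacial_prefix: str = "cranio_",
) -> int:
    """Total symptom count for one individual.

    Counts present neurological abnormalities plus present other diagnoses,
    plus 1 if at least one craniofacial abnormality is present.  Missing
    entries contribute nothing.
    """
    neuro = sum(1 for c, v in row.items() if c.startswith(neurological_prefix) and v == PRESENT)
    diag = sum(1 for c, v in row.items() if c.startswith(diagnosis_prefix) and v == PRESENT)
    cranio = any(v == PRESENT for c, v in row.items() if c.startswith(craniofacial_prefix))
    return neuro + diag + (1 if cranio else 0)
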