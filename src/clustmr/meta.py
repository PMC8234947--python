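"""Fixed-effect inverse-variance meta-analysis.

Three uses share one engine:

* the summary-statistic genetic risk score (GRS): the pooled effect of a
  cluster's variants on a trait is the fixed-effect IVW combination of the
  per-variant (beta, se) pairs;
* Bonferroni control of the cluster × trait association grid;
* two-study GWAS meta-analysis (SE-weighted, i.e. the STDERR scheme of the
  classical GWAS meta-analysis tools), with allele harmonization of study B
  to study A per variant.

Weights are w_i = 1/se_i^2; the pooled beta is the w-weighted mean, pooled
se = (sum w)^(-1/2), and the two-sided p comes from the standard normal.
Cochran's Q is reported as a heterogeneity diagnostic but no random-effects
fallback is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError
from .sumstats import (
    AssociationRecord,
    HarmonizationAction,
    _orient_to,
)

__all__ = [
    "MetaResult",
    "GRSAssociationRow",
    "ivw_fixed_meta",
    "bonferroni_threshold",
    "cluster_grs_associations",
    "grs_table",
    "meta_two_gwas",
]


@dataclass(frozen=True)
class MetaResult:
    """Pooled fixed-effect estimate with heterogeneity diagnostics."""

    beta: float
    se: float
    z: float
    pval: float
    n_inputs: int
    q: float
    q_df: int


@dataclass(frozen=True)
class GRSAssociationRow:
    cluster_id: int
    trait_id: str
    result: Optional[MetaResult]
    n_variants_used: int
    estimable: bool
    significant: bool


def ivw_fixed_meta(effects: Sequence[Tuple[float, float]]) -> MetaResult:
    """Fixed-effect inverse-variance pooling of (beta, se) pairs."""
    if len(effects) == 0:
        raise ParameterError("ivw_fixed_meta requires at least one (beta, se) input")
    beta = np.asarray([e[0] for e in effects], dtype=float)
    se = np.asarray([e[1] for e in effects], dtype=float)
    if np.any(se <= 0):
        raise ParameterError("all standard errors must be positive")
    w = 1.0 / se**2
    beta_pooled = float(np.sum(w * beta) / np.sum(w))
    se_pooled = float(np.sum(w) ** -0.5)
    z = beta_pooled / se_pooled
    pval = float(max(2.0 * stats.norm.sf(abs(z)), np.nextafter(0, 1)))
    q = float(np.sum(w * (beta - beta_pooled) ** 2))
    return MetaResult(
        beta=beta_pooled,
        se=se_pooled,
        z=float(z),
        pval=pval,
        n_inputs=len(effects),
        q=q,
        q_df=len(effects) - 1,
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    if n_tests < 1:
        raise ParameterError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests


def cluster_grs_associations(
    labels: Mapping[str, int],
    tables: Mapping[str, Sequence[AssociationRecord]],
    threshold: float,
) -> list[GRSAssociationRow]:
    """Per-(cluster, trait) pooled GRS association.

    ``labels`` maps variant id to cluster id; ``tables`` maps trait id to its
    harmonized records.  Variants of a cluster absent from a trait's table are
    simply not pooled; the row records how many were used.  A cluster with no
    available variant for a trait yields a non-estimable row.
    """
    clusters = sorted(set(labels.values()))
    rows: list[GRSAssociationRow] = []
    for cluster in clusters:
        members = {v for v, c in labels.items() if c == cluster}
        for trait, records in tables.items():
            effects = [(r.beta, r.se) for r in records if r.variant_id in members]
            if not effects:
                rows.append(
                    GRSAssociationRow(cluster, trait, None, 0, estimable=False, significant=False)
                )
                continue
            res = ivw_fixed_meta(effects)
            rows.append(
                GRSAssociationRow(
                    cluster,
                    trait,
                    res,
                    len(effects),
                    estimable=True,
                    significant=res.pval < threshold,
                )
            )
    return rows


def grs_table(rows: Iterable[GRSAssociationRow]) -> pd.DataFrame:
    """Long-format cluster × trait grid of pooled beta, se, p and flags."""
    return pd.DataFrame(
        [
            {
                "cluster": r.cluster_id,
                "trait": r.trait_id,
                "n_variants": r.n_variants_used,
                "beta": r.result.beta if r.result else np.nan,
                "se": r.result.se if r.result else np.nan,
                "pval": r.result.pval if r.result else np.nan,
                "q": r.result.q if r.result else np.nan,
                "estimable": r.estimable,
                "significant": r.significant,
            }
            for r in rows
        ]
    )


def meta_two_gwas(
    table_a: Sequence[AssociationRecord],
    table_b: Sequence[AssociationRecord],
) -> tuple[list[AssociationRecord], pd.DataFrame]:
    """SE-weighted fixed-effect meta-analysis of two GWAS of the same trait.

    Per shared variant, study B's alleles are harmonized to study A's (direct
    match, allele flip, or strand complement; palindromic variants are paired
    by their labels), then the two (beta, se) pairs are pooled.  Variants
    present in only one study pass through unchanged.  Returns the merged
    records and a per-variant log with columns variant_id/source/action.
    """
    index_b = {r.variant_id: r for r in table_b}
    seen = set()
    out: list[AssociationRecord] = []
    log: list[dict] = []
    from dataclasses import replace

    for ra in table_a:
        seen.add(ra.variant_id)
        rb = index_b.get(ra.variant_id)
        if rb is None:
            out.append(ra)
            log.append({"variant_id": ra.variant_id, "source": "A_only", "action": "kept"})
            continue
        oriented, action, detail = _orient_to(
            rb, ra.effect_allele, ra.other_allele, "keep", 0.0, None
        )
        if oriented is None:
            log.append(
                {"variant_id": ra.variant_id, "source": "both", "action": f"dropped ({detail})"}
            )
            continue
        pooled = ivw_fixed_meta([(ra.beta, ra.se), (oriented.beta, oriented.se)])
        n_tot = (ra.n or 0) + (oriented.n or 0)
        out.append(
            replace(
                ra,
                beta=pooled.beta,
                se=pooled.se,
                pval=pooled.pval,
                n=n_tot if n_tot > 0 else None,
            )
        )
        log.append({"variant_id": ra.variant_id, "source": "meta", "action": action})
    for rb in table_b:
        if rb.variant_id in seen:
            continue
        out.append(rb)
        log.append({"variant_id": rb.variant_id, "source": "B_only", "action": "kept"})
    return out, pd.DataFrame(log, columns=["variant_id", "source", "action"])
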