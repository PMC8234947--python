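"""Synthetic GWAS summary statistics with known ground truth.

Every pipeline stage is exercisable without external downloads: this module
plants (i) variant clusters with per-cluster per-trait mean effects, (ii) an
instrument-exposure-outcome causal structure with configurable horizontal
pleiotropy, and (iii) two-study realizations of one GWAS — and serializes the
truth next to the data so recovery can be scored.

The summary-statistic model is the standard large-sample GWAS approximation
for a standardized quantitative trait: a variant with minor allele frequency
``maf`` analyzed in ``n`` samples has

    se = (2 * maf * (1 - maf) * n) ** -0.5

and the observed effect is beta ~ Normal(mu, se^2) around the planted mean.
Allele orientation of every emitted row is randomly scrambled so that
harmonization is genuinely exercised downstream.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .exceptions import ParameterError
from .mr import MRInput
from .sumstats import AssociationRecord, VariantPanelEntry, flip_record

__all__ = [
    "SimulationTruth",
    "simulate_clustered_sumstats",
    "simulate_mr_dataset",
    "simulate_two_gwas",
    "DEFAULT_TRAITS",
    "DEFAULT_CLUSTER_SIZES",
    "default_mu_matrix",
]

# Trait panel mirroring a 16-trait hormonal / insulin-resistance / lipid /
# adiposity layout (BMI-adjusted variants included as separate columns).
DEFAULT_TRAITS: tuple[str, ...] = (
    "SHBG",
    "LH",
    "FI",
    "FI_adjBMI",
    "FG",
    "FG_adjBMI",
    "HOMA_IR",
    "HDL",
    "LDL",
    "TG",
    "TC",
    "BMI",
    "WC",
    "WC_adjBMI",
    "WHR",
    "WHR_adjBMI",
)

#: planted cluster sizes of the 26-variant fixture: adiposity / insulin-resistant /
#: reproductive
DEFAULT_CLUSTER_SIZES: tuple[int, ...] = (4, 10, 12)

# Per-cluster per-trait mean effects (standardized-beta scale).  At the default
# per-trait n = 1e5 these give signature |z| around 5-10: a strong-signal
# recovery benchmark, deliberately cleaner than real susceptibility variants.
_MU = {
    # cluster 1: adiposity — BMI/WC/WHR up, SHBG down
    0: {
        "BMI": 0.045,
        "WC": 0.045,
        "WC_adjBMI": 0.025,
        "WHR": 0.030,
        "WHR_adjBMI": 0.015,
        "SHBG": -0.040,
        "FI": 0.010,
        "HDL": -0.015,
    },
    # cluster 2: insulin resistance — FI/FG/HOMA-IR up, lipids/SHBG down
    1: {
        "FI": 0.040,
        "FI_adjBMI": 0.036,
        "FG": 0.032,
        "FG_adjBMI": 0.024,
        "HOMA_IR": 0.036,
        "TC": -0.022,
        "TG": -0.015,
        "LDL": -0.015,
        "SHBG": -0.015,
    },
    # cluster 3: reproductive — SHBG up, mild negative FI/TG
    2: {
        "SHBG": 0.040,
        "FI": -0.010,
        "TG": -0.010,
    },
}

_NONPALINDROMIC_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))


def default_mu_matrix(
    k: int = 3, trait_ids: Sequence[str] = DEFAULT_TRAITS
) -> np.ndarray:
    """k × n_traits planted mean-effect matrix (zeros off the signatures)."""
    mu = np.zeros((k, len(trait_ids)))
    for c in range(min(k, 3)):
        for trait, val in _MU[c].items():
            if trait in trait_ids:
                mu[c, list(trait_ids).index(trait)] = val
    return mu


@dataclass
class SimulationTruth:
    """Ground truth serialized alongside simulated data."""

    seed: int
    kind: str
    cluster_labels: Optional[list[int]] = None
    variant_ids: Optional[list[str]] = None
    trait_ids: Optional[list[str]] = None
    mu_matrix: Optional[list[list[float]]] = None
    maf: Optional[list[float]] = None
    n_per_trait: Optional[dict] = None
    theta: Optional[float] = None
    invalid_instruments: Optional[list[int]] = None
    pleiotropy: Optional[dict] = None
    extra: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {k: v for k, v in dataclasses.asdict(self).items() if v is not None}, indent=2
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


def _pval(z: np.ndarray) -> np.ndarray:
    return np.maximum(2.0 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1))


def simulate_clustered_sumstats(
    n_variants: int = 26,
    trait_ids: Sequence[str] = DEFAULT_TRAITS,
    k: int = 3,
    mu_matrix: Optional[np.ndarray] = None,
    cluster_sizes: Optional[Sequence[int]] = DEFAULT_CLUSTER_SIZES,
    n_per_trait: float | Sequence[float] = 100_000,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    scramble: bool = True,
    proxy_variants: int = 0,
):
    """Per-trait summary tables with planted variant clusters.

    Variant i in cluster c gets beta_ij ~ Normal(mu[c, j], se_ij^2) with
    se_ij = (2 maf_i (1 - maf_i) n_j)^(-1/2).  Returns
    ``(tables, panel, truth)`` where ``tables`` maps trait id to records,
    ``panel`` is the matching risk-allele panel, and ``truth`` the planted
    structure.  With ``proxy_variants > 0`` the first that many panel variants
    appear in the tables only under a proxy id (r2 = 0.9), so proxy
    substitution is exercised end to end.
    """
    trait_ids = list(trait_ids)
    n_traits = len(trait_ids)
    if mu_matrix is None:
        mu_matrix = default_mu_matrix(k, trait_ids)
    mu_matrix = np.asarray(mu_matrix, dtype=float)
    if mu_matrix.shape != (k, n_traits):
        raise ParameterError(f"mu_matrix must be {k} x {n_traits}, got {mu_matrix.shape}")
    if k > n_variants:
        raise ParameterError(f"k={k} exceeds n_variants={n_variants}")
    if cluster_sizes is None:
        base = n_variants // k
        cluster_sizes = [base + (1 if i < n_variants % k else 0) for i in range(k)]
    if len(cluster_sizes) != k or sum(cluster_sizes) != n_variants:
        raise ParameterError("cluster_sizes must have length k and sum to n_variants")
    n_vec = np.broadcast_to(np.asarray(n_per_trait, dtype=float), (n_traits,))
    if np.any(n_vec <= 0):
        raise ParameterError("n_per_trait must be positive")

    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(k), cluster_sizes)
    variant_ids = [f"rs9{100000 + i}" for i in range(n_variants)]
    maf = rng.uniform(*maf_range, size=n_variants)
    pair_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=n_variants)
    risk_alt = [_NONPALINDROMIC_PAIRS[i] for i in pair_idx]

    se = (2.0 * maf[:, None] * (1.0 - maf[:, None]) * n_vec[None, :]) ** -0.5
    beta = rng.normal(mu_matrix[labels], se)
    z = beta / se
    pvals = _pval(z)

    panel: list[VariantPanelEntry] = []
    emit_id = list(variant_ids)
    proxies: dict[str, str] = {}
    for i in range(n_variants):
        risk, alt = risk_alt[i]
        if i < proxy_variants:
            proxy = f"rs8{200000 + i}"
            proxies[variant_ids[i]] = proxy
            emit_id[i] = proxy
            panel.append(
                VariantPanelEntry(
                    variant_id=variant_ids[i],
                    risk_allele=risk,
                    alt_allele=alt,
                    gene_label=f"GENE{i + 1}",
                    proxy_id=proxy,
                    proxy_r2=0.9,
                    proxy_risk_allele=risk,
                    proxy_alt_allele=alt,
                    risk_af=float(maf[i]),
                )
            )
        else:
            panel.append(
                VariantPanelEntry(
                    variant_id=variant_ids[i],
                    risk_allele=risk,
                    alt_allele=alt,
                    gene_label=f"GENE{i + 1}",
                    risk_af=float(maf[i]),
                )
            )

    tables: dict[str, list[AssociationRecord]] = {}
    for j, trait in enumerate(trait_ids):
        records = []
        for i in range(n_variants):
            risk, alt = risk_alt[i]
            rec = AssociationRecord(
                variant_id=emit_id[i],
                chrom=str(1 + i % 22),
                pos=1000 + i,
                effect_allele=risk,
                other_allele=alt,
                eaf=float(maf[i]),
                beta=float(beta[i, j]),
                se=float(se[i, j]),
                pval=float(pvals[i, j]),
                n=float(n_vec[j]),
            )
            if scramble and rng.random() < 0.5:
                rec = flip_record(rec)
            records.append(rec)
        tables[trait] = records

    truth = SimulationTruth(
        seed=seed,
        kind="clustered_sumstats",
        cluster_labels=(labels + 1).tolist(),
        variant_ids=variant_ids,
        trait_ids=trait_ids,
        mu_matrix=mu_matrix.tolist(),
        maf=maf.tolist(),
        n_per_trait={t: float(n) for t, n in zip(trait_ids, n_vec)},
        extra={"proxies": proxies, "scramble": scramble},
    )
    return tables, panel, truth


def simulate_mr_dataset(
    n_instruments: int = 50,
    theta: float = 0.5,
    beta_x_dist: tuple = ("uniform", 0.05, 0.35),
    se_x: float = 0.005,
    se_y: float = 0.005,
    pleiotropy_mean: float = 0.0,
    pleiotropy_sd: float = 0.0,
    invalid_frac: float = 0.0,
    seed: int = 0,
) -> tuple[MRInput, SimulationTruth]:
    """Instrument-exposure-outcome model with optional directional pleiotropy.

    True exposure effects are drawn from ``beta_x_dist`` (``("uniform", lo,
    hi)`` or ``("normal", mean, sd)``).  A fraction ``invalid_frac`` of
    instruments carries a direct outcome effect alpha ~ Normal(mean, sd^2);
    valid instruments have alpha = 0.  Observed effects are the truth plus
    Normal measurement noise with the given SEs (the degenerate limit
    se_x = se_y = 0 returns the truth exactly).  The default SEs correspond
    to biobank-scale GWAS (about 1e5 samples for a standardized trait at
    MAF 0.25).
    """
    if not 0 <= invalid_frac < 0.5:
        raise ParameterError(
            "invalid_frac must be in [0, 0.5): at half invalid weight the "
            "weighted median breaks down"
        )
    if n_instruments < 2:
        raise ParameterError("need at least 2 instruments")
    rng = np.random.default_rng(seed)
    kind, a, b = beta_x_dist
    if kind == "uniform":
        bx_true = rng.uniform(a, b, size=n_instruments)
    elif kind == "normal":
        bx_true = rng.normal(a, b, size=n_instruments)
    else:
        raise ParameterError(f"unknown beta_x_dist kind {kind!r}")
    n_invalid = int(round(invalid_frac * n_instruments))
    invalid_idx = rng.choice(n_instruments, size=n_invalid, replace=False)
    alpha = np.zeros(n_instruments)
    if n_invalid:
        alpha[invalid_idx] = rng.normal(pleiotropy_mean, pleiotropy_sd, size=n_invalid)
    by_true = theta * bx_true + alpha
    bx_obs = bx_true + (rng.normal(0.0, se_x, size=n_instruments) if se_x > 0 else 0.0)
    by_obs = by_true + (rng.normal(0.0, se_y, size=n_instruments) if se_y > 0 else 0.0)
    data = MRInput(
        beta_exposure=bx_obs,
        se_exposure=np.full(n_instruments, max(se_x, 1e-12)),
        beta_outcome=by_obs,
        se_outcome=np.full(n_instruments, max(se_y, 1e-12)),
        instrument_ids=tuple(f"iv{i + 1}" for i in range(n_instruments)),
    )
    truth = SimulationTruth(
        seed=seed,
        kind="mr_dataset",
        theta=theta,
        invalid_instruments=sorted(int(i) for i in invalid_idx),
        pleiotropy={
            "mean": pleiotropy_mean,
            "sd": pleiotropy_sd,
            "invalid_frac": invalid_frac,
            "planted_mean_intercept": invalid_frac * pleiotropy_mean,
        },
        extra={
            "beta_x_dist": list(beta_x_dist),
            "se_x": se_x,
            "se_y": se_y,
            "beta_x_true": bx_true.tolist(),
        },
    )
    return data, truth


def simulate_two_gwas(
    base_table: Sequence[AssociationRecord],
    n_ratio: float = 1.0,
    seed: int = 0,
    noise: bool = True,
) -> tuple[list[AssociationRecord], list[AssociationRecord]]:
    """Two noisy realizations of one GWAS, for two-study meta-analysis tests.

    The base table's betas play the role of the truth; study A keeps the base
    SEs, study B's are scaled by 1/sqrt(n_ratio) (n_ratio = n_B / n_A).
    Allele orientations of both studies are independently scrambled.  With
    ``noise=False`` both studies report the true betas exactly.
    """
    if n_ratio <= 0:
        raise ParameterError("n_ratio must be positive")
    rng = np.random.default_rng(seed)
    out_a: list[AssociationRecord] = []
    out_b: list[AssociationRecord] = []
    for rec in base_table:
        se_a = rec.se
        se_b = rec.se / np.sqrt(n_ratio)
        for se_s, out in ((se_a, out_a), (se_b, out_b)):
            beta_s = rec.beta + (rng.normal(0.0, se_s) if noise else 0.0)
            z = beta_s / se_s
            new = dataclasses.replace(
                rec,
                beta=float(beta_s),
                se=float(se_s),
                pval=float(_pval(np.asarray([z]))[0]),
            )
            if rng.random() < 0.5:
                new = flip_record(new)
            out.append(new)
    return out_a, out_b
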