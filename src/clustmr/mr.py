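"""Two-sample Mendelian randomization.

Genetic variants robustly associated with an exposure serve as instrumental
variables: under the instrumental assumptions, the ratio of a variant's
outcome effect to its exposure effect estimates the causal effect of the
exposure on the outcome.  With summary statistics from two non-overlapping
GWAS (exposure study and outcome study), three estimators are provided:

* **IVW** — weighted regression of outcome effects beta_y on exposure effects
  beta_x through the origin, weights 1/se_y^2.  The main analysis.  Standard
  errors either fixed-effect or inflated multiplicatively by max(1, phi) where
  phi^2 is the weighted residual mean square (the multiplicative
  random-effects model).
* **MR-Egger** — the same regression with a free intercept; a nonzero
  intercept estimates directional pleiotropy (valid under the InSIDE
  assumption), and the slope is a pleiotropy-adjusted causal estimate.
  Inference on n − 2 degrees of freedom with the same max(1, phi) inflation.
* **Weighted median** — the ratio-estimate value at cumulative standardized
  weight 1/2 (weights beta_x^2/se_y^2, the inverse first-order ratio
  variance); consistent when at least half of the weight comes from valid
  instruments.  Its SE comes from a seeded parametric bootstrap.

For binary outcomes beta_y is a log-odds ratio, so exp(beta) is the odds
ratio per unit of exposure.

The model/results surface follows the usual statistical-modelling idiom:
``MRModel(data).fit(method=...)`` returns an :class:`MREstimate` carrying the
estimate, its uncertainty, diagnostics, and a ``summary()`` table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import NotEstimableError, ParameterError
from .sumstats import AssociationRecord, VariantPanelEntry, harmonize_to_panel

__all__ = [
    "MRInput",
    "MREstimate",
    "MRModel",
    "mr_ivw",
    "mr_egger",
    "mr_weighted_median",
    "to_odds_ratio",
    "run_mr_suite",
    "mr_table",
]

METHOD_MIN_SNV = {"ivw": 2, "egger": 3, "weighted_median": 3}


@dataclass(frozen=True)
class MRInput:
    """Harmonized per-instrument summary statistics.

    All effects refer to the same allele per instrument; for binary outcomes
    ``beta_outcome`` is on the log-odds scale.
    """

    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    instrument_ids: Optional[tuple[str, ...]] = None

    def __post_init__(self):
        arrays = {
            "beta_exposure": np.asarray(self.beta_exposure, dtype=float),
            "se_exposure": np.asarray(self.se_exposure, dtype=float),
            "beta_outcome": np.asarray(self.beta_outcome, dtype=float),
            "se_outcome": np.asarray(self.se_outcome, dtype=float),
        }
        n = {len(a) for a in arrays.values()}
        if len(n) != 1:
            raise ParameterError("MRInput arrays must have equal length")
        for name in ("se_exposure", "se_outcome"):
            if np.any(arrays[name] <= 0):
                raise ParameterError(f"{name} must be strictly positive")
        for name, arr in arrays.items():
            object.__setattr__(self, name, arr)
        if self.instrument_ids is not None:
            object.__setattr__(self, "instrument_ids", tuple(self.instrument_ids))

    @property
    def n_snv(self) -> int:
        return len(self.beta_exposure)

    def subset(self, mask: np.ndarray) -> "MRInput":
        ids = (
            tuple(np.asarray(self.instrument_ids)[mask]) if self.instrument_ids else None
        )
        return MRInput(
            self.beta_exposure[mask],
            self.se_exposure[mask],
            self.beta_outcome[mask],
            self.se_outcome[mask],
            ids,
        )


def to_odds_ratio(beta: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """(OR, CI low, CI high) for a log-odds effect: exp(beta -/+ q*se)."""
    if se <= 0:
        raise ParameterError("se must be positive")
    if not 0 < level < 1:
        raise ParameterError("level must be in (0, 1)")
    q = stats.norm.ppf(0.5 + level / 2)
    with np.errstate(over="ignore"):
        return (
            float(np.exp(beta)),
            float(np.exp(beta - q * se)),
            float(np.exp(beta + q * se)),
        )


@dataclass
class MREstimate:
    """A causal-effect estimate from one MR method.

    ``beta`` is the causal effect per unit of exposure (log-odds for binary
    outcomes); ``or_point``/``or_ci_low``/``or_ci_high`` its odds-ratio form.
    ``extras`` carries method diagnostics (Egger intercept and its inference;
    phi; bootstrap settings for the weighted median).
    """

    method: str
    beta: float
    se: float
    pval: float
    n_snv: int
    or_point: float = float("nan")
    or_ci_low: float = float("nan")
    or_ci_high: float = float("nan")
    level: float = 0.95
    estimable: bool = True
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.estimable and math.isnan(self.or_point):
            self.or_point, self.or_ci_low, self.or_ci_high = to_odds_ratio(
                self.beta, self.se, self.level
            )

    def conf_int(self, level: Optional[float] = None) -> tuple[float, float]:
        """Normal-quantile CI for beta, matching the odds-ratio reporting
        convention (Egger keeps t-based p-values but Wald-style intervals)."""
        level = self.level if level is None else level
        q = stats.norm.ppf(0.5 + level / 2)
        return self.beta - q * self.se, self.beta + q * self.se

    def odds_ratio(self, level: Optional[float] = None) -> tuple[float, float, float]:
        return to_odds_ratio(self.beta, self.se, self.level if level is None else level)

    def summary(self) -> str:
        lines = [
            f"MR estimate ({self.method}), {self.n_snv} instruments",
            f"  beta = {self.beta:.4f}  SE = {self.se:.4f}  p = {self.pval:.3e}",
            f"  OR ({int(self.level * 100)}% CI) = "
            f"{self.or_point:.3f} [{self.or_ci_low:.3f}, {self.or_ci_high:.3f}]",
        ]
        if self.method == "egger":
            lines.append(
                "  Egger intercept = {egger_intercept:.4f}  SE = {egger_intercept_se:.4f}"
                "  p = {egger_intercept_pval:.3e}".format(**self.extras)
            )
        if "phi" in self.extras:
            lines.append(f"  residual scale phi = {self.extras['phi']:.3f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


def mr_ivw(data: MRInput, se_mode: str = "multiplicative_random", level: float = 0.95) -> MREstimate:
    """Inverse-variance-weighted estimate (regression through the origin)."""
    if se_mode not in ("fixed", "multiplicative_random"):
        raise ParameterError(f"unknown se_mode {se_mode!r}")
    if data.n_snv < METHOD_MIN_SNV["ivw"]:
        raise ParameterError(f"IVW requires >= 2 instruments, got {data.n_snv}")
    bx, by, sy = data.beta_exposure, data.beta_outcome, data.se_outcome
    if np.all(bx == 0):
        raise NotEstimableError("all exposure effects are zero")
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by) / denom)
    se = denom**-0.5
    resid = by - beta * bx
    phi2 = float(np.sum(w * resid**2) / (data.n_snv - 1))
    phi = math.sqrt(max(phi2, 0.0))
    if se_mode == "multiplicative_random":
        se *= max(1.0, phi)
    z = beta / se
    pval = float(max(2.0 * stats.norm.sf(abs(z)), np.nextafter(0, 1)))
    return MREstimate(
        method="ivw",
        beta=beta,
        se=se,
        pval=pval,
        n_snv=data.n_snv,
        level=level,
        extras={"phi": phi, "se_mode": se_mode},
    )


def mr_egger(data: MRInput, level: float = 0.95) -> MREstimate:
    """MR-Egger regression: weighted fit of beta_y = a + b*beta_x.

    Instruments are first oriented so beta_x >= 0 (both coordinates negated
    where needed — the estimate must not depend on arbitrary allele coding).
    The intercept estimates average directional pleiotropy.
    """
    if data.n_snv < METHOD_MIN_SNV["egger"]:
        raise ParameterError(f"MR-Egger requires >= 3 instruments, got {data.n_snv}")
    sign = np.where(data.beta_exposure < 0, -1.0, 1.0)
    bx = data.beta_exposure * sign
    by = data.beta_outcome * sign
    sy = data.se_outcome
    w = 1.0 / sy**2
    sw = w.sum()
    mx = float(np.sum(w * bx) / sw)
    my = float(np.sum(w * by) / sw)
    sxx = float(np.sum(w * (bx - mx) ** 2))
    if sxx <= np.sqrt(np.finfo(float).eps) * float(np.sum(w * bx**2)):
        raise NotEstimableError("no variance in exposure effects after orientation")
    sxy = float(np.sum(w * (bx - mx) * (by - my)))
    slope = sxy / sxx
    intercept = my - slope * mx
    df = data.n_snv - 2
    resid = by - intercept - slope * bx
    phi2 = float(np.sum(w * resid**2) / df)
    phi = math.sqrt(max(phi2, 0.0))
    scale = max(1.0, phi)
    se_slope = math.sqrt(1.0 / sxx) * scale
    se_intercept = math.sqrt(1.0 / sw + mx**2 / sxx) * scale
    p_slope = float(max(2.0 * stats.t.sf(abs(slope / se_slope), df=df), np.nextafter(0, 1)))
    p_int = float(max(2.0 * stats.t.sf(abs(intercept / se_intercept), df=df), np.nextafter(0, 1)))
    return MREstimate(
        method="egger",
        beta=slope,
        se=se_slope,
        pval=p_slope,
        n_snv=data.n_snv,
        level=level,
        extras={
            "egger_intercept": intercept,
            "egger_intercept_se": se_intercept,
            "egger_intercept_pval": p_int,
            "phi": phi,
        },
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: value at cumulative standardized weight 1/2.

    With S_j the running weight sum over ratio-sorted instruments, the
    cumulative position of instrument j is p_j = (S_j − w_j/2) / S_total; the
    estimate interpolates the sorted ratios linearly at p = 1/2.
    """
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order]
    cum = np.cumsum(w)
    p = (cum - w / 2.0) / cum[-1]
    return float(np.interp(0.5, p, r))


def _weighted_median_batch(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise interpolated weighted median for (B, n) arrays."""
    order = np.argsort(ratios, axis=1)
    r = np.take_along_axis(ratios, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    cum = np.cumsum(w, axis=1)
    p = (cum - w / 2.0) / cum[:, -1:]
    # index of first p >= 0.5 per row
    idx = (p < 0.5).sum(axis=1)
    n = r.shape[1]
    hi = np.clip(idx, 0, n - 1)
    lo = np.clip(idx - 1, 0, n - 1)
    rows = np.arange(r.shape[0])
    p_lo, p_hi = p[rows, lo], p[rows, hi]
    r_lo, r_hi = r[rows, lo], r[rows, hi]
    t = np.where(p_hi > p_lo, (0.5 - p_lo) / np.where(p_hi > p_lo, p_hi - p_lo, 1.0), 0.0)
    out = r_lo + t * (r_hi - r_lo)
    out = np.where(idx == 0, r[:, 0], out)  # p=0.5 below the first point
    out = np.where(idx == n, r[:, -1], out)
    return out


def mr_weighted_median(
    data: MRInput, n_boot: int = 1000, seed: int = 0, level: float = 0.95
) -> MREstimate:
    """Weighted-median estimate with a seeded parametric-bootstrap SE.

    Instruments with beta_x = 0 have no defined ratio and are rejected with a
    warning.  Weights are beta_x^2/se_y^2 (inverse first-order variance of the
    ratio beta_y/beta_x).
    """
    if n_boot < 100:
        raise ParameterError("n_boot must be >= 100")
    nonzero = data.beta_exposure != 0
    if not nonzero.all():
        warnings.warn(
            f"rejecting {int((~nonzero).sum())} instrument(s) with zero exposure effect",
            stacklevel=2,
        )
        data = data.subset(nonzero)
    if data.n_snv < METHOD_MIN_SNV["weighted_median"]:
        raise ParameterError(
            f"weighted median requires >= 3 usable instruments, got {data.n_snv}"
        )
    bx, sx, by, sy = data.beta_exposure, data.se_exposure, data.beta_outcome, data.se_outcome
    ratios = by / bx
    weights = bx**2 / sy**2
    estimate = _weighted_median(ratios, weights)
    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_boot, data.n_snv))
    by_star = rng.normal(by, sy, size=(n_boot, data.n_snv))
    bx_star = np.where(bx_star == 0, np.finfo(float).tiny, bx_star)
    boots = _weighted_median_batch(by_star / bx_star, bx_star**2 / sy**2)
    se = float(np.std(boots, ddof=1))
    z = estimate / se if se > 0 else math.inf
    pval = float(max(2.0 * stats.norm.sf(abs(z)), np.nextafter(0, 1)))
    return MREstimate(
        method="weighted_median",
        beta=estimate,
        se=se,
        pval=pval,
        n_snv=data.n_snv,
        level=level,
        extras={"n_boot": n_boot, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Model / results surface
# ---------------------------------------------------------------------------


class MRModel:
    """Two-sample MR model over a harmonized instrument set.

    Construct from arrays, a DataFrame, or two summary-statistics tables
    (in which case the outcome table is harmonized to the exposure's effect
    alleles).  ``fit`` dispatches to one estimator; ``fit_all`` runs the IVW
    main analysis plus both sensitivity analyses.
    """

    def __init__(self, data: MRInput):
        self.data = data

    @classmethod
    def from_arrays(cls, beta_exposure, se_exposure, beta_outcome, se_outcome, ids=None):
        return cls(MRInput(beta_exposure, se_exposure, beta_outcome, se_outcome, ids))

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        beta_exposure: str = "beta_exposure",
        se_exposure: str = "se_exposure",
        beta_outcome: str = "beta_outcome",
        se_outcome: str = "se_outcome",
        instrument_id: Optional[str] = "variant_id",
    ) -> "MRModel":
        ids = (
            tuple(df[instrument_id].astype(str))
            if instrument_id and instrument_id in df.columns
            else None
        )
        return cls(
            MRInput(
                df[beta_exposure].to_numpy(float),
                df[se_exposure].to_numpy(float),
                df[beta_outcome].to_numpy(float),
                df[se_outcome].to_numpy(float),
                ids,
            )
        )

    @classmethod
    def from_summary_tables(
        cls,
        exposure: Sequence[AssociationRecord],
        outcome: Sequence[AssociationRecord],
        palindrome_policy: str = "infer_by_eaf",
        eaf_window: float = 0.08,
    ) -> "MRModel":
        """Harmonize the outcome table to the exposure's effect alleles.

        The exposure's effect allele plays the reference role per instrument;
        outcome records that cannot be aligned are dropped.
        """
        panel = [
            VariantPanelEntry(
                variant_id=r.variant_id,
                risk_allele=r.effect_allele,
                alt_allele=r.other_allele,
                risk_af=r.eaf,
            )
            for r in exposure
        ]
        harmonized, _ = harmonize_to_panel(outcome, panel, palindrome_policy, eaf_window)
        out_by_id = {r.variant_id: r for r in harmonized}
        pairs = [(r, out_by_id[r.variant_id]) for r in exposure if r.variant_id in out_by_id]
        if not pairs:
            raise NotEstimableError("no shared instruments after harmonization")
        return cls(
            MRInput(
                np.array([e.beta for e, _ in pairs]),
                np.array([e.se for e, _ in pairs]),
                np.array([o.beta for _, o in pairs]),
                np.array([o.se for _, o in pairs]),
                tuple(e.variant_id for e, _ in pairs),
            )
        )

    def fit(self, method: str = "ivw", **kwargs) -> MREstimate:
        if method == "ivw":
            return mr_ivw(self.data, **kwargs)
        if method == "egger":
            return mr_egger(self.data, **kwargs)
        if method == "weighted_median":
            return mr_weighted_median(self.data, **kwargs)
        raise ParameterError(f"unknown MR method {method!r}")

    def fit_all(
        self,
        se_mode: str = "multiplicative_random",
        n_boot: int = 1000,
        seed: int = 0,
        level: float = 0.95,
    ) -> list[MREstimate]:
        """IVW + Egger + weighted median; methods short of instruments yield
        flagged non-estimable rows rather than raising."""
        out: list[MREstimate] = []
        for method, kwargs in (
            ("ivw", {"se_mode": se_mode, "level": level}),
            ("egger", {"level": level}),
            ("weighted_median", {"n_boot": n_boot, "seed": seed, "level": level}),
        ):
            try:
                out.append(self.fit(method, **kwargs))
            except (ParameterError, NotEstimableError) as exc:
                out.append(
                    MREstimate(
                        method=method,
                        beta=float("nan"),
                        se=float("nan"),
                        pval=float("nan"),
                        n_snv=self.data.n_snv,
                        level=level,
                        estimable=False,
                        extras={"reason": str(exc)},
                    )
                )
        return out


def run_mr_suite(
    exposure: Sequence[AssociationRecord],
    outcome: Sequence[AssociationRecord],
    se_mode: str = "multiplicative_random",
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    palindrome_policy: str = "infer_by_eaf",
    eaf_window: float = 0.08,
) -> list[MREstimate]:
    """Harmonize one exposure-outcome pair and run all three estimators."""
    model = MRModel.from_summary_tables(exposure, outcome, palindrome_policy, eaf_window)
    return model.fit_all(se_mode=se_mode, n_boot=n_boot, seed=seed, level=level)


def mr_table(estimates: Mapping[str, Sequence[MREstimate]]) -> pd.DataFrame:
    """Reporting grid: trait, method, nSNV, beta, SE, OR (95% CI), p."""
    rows = []
    for trait, ests in estimates.items():
        for e in ests:
            rows.append(
                {
                    "trait": trait,
                    "method": e.method,
                    "n_snv": e.n_snv,
                    "beta": e.beta,
                    "se": e.se,
                    "or": e.or_point,
                    "or_ci_low": e.or_ci_low,
                    "or_ci_high": e.or_ci_high,
                    "pval": e.pval,
                    "estimable": e.estimable,
                }
            )
    return pd.DataFrame(rows)
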