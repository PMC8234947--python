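"""Reading, validation, and risk-allele harmonization of GWAS summary statistics.

A GWAS summary-statistics table reports, per variant, the additive effect
(``beta``) of one allele (the *effect allele*) on a trait, its standard error,
p-value, effect-allele frequency (EAF), and sample size.  Different studies
report effects relative to different alleles and sometimes on opposite DNA
strands, so before any cross-trait analysis every effect must be re-expressed
relative to a single reference allele per variant — here, the disease
risk-increasing allele declared in a variant panel.

Conventions
-----------
* Alleles are single uppercase bases (biallelic SNVs only; indels and
  multi-allelic rows are rejected at read time).
* Flipping a record (referring the effect to the other allele) swaps the
  alleles, negates beta, and replaces EAF by 1 − EAF; se/p/n are unchanged.
* Strand flips replace both alleles by their complements and change nothing
  else: the same allele observed on the other strand has the same frequency
  and the same effect.
* Palindromic SNVs (A/T or C/G) cannot be strand-resolved from allele labels;
  they are handled by a configurable policy (drop / infer from EAF / keep).
* Positions are 1-based and carried through but never used in computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .exceptions import ConfigurationError, TableValidationError

__all__ = [
    "AssociationRecord",
    "VariantPanelEntry",
    "HarmonizationAction",
    "DEFAULT_COLUMN_MAP",
    "read_association_table",
    "write_association_table",
    "read_variant_panel",
    "write_variant_panel",
    "flip_record",
    "complement_record",
    "is_palindromic",
    "harmonize_to_panel",
    "substitute_proxies",
    "actions_to_frame",
    "records_to_frame",
]

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: logical field -> default physical column name in a tab-delimited table
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "variant_id": "variant_id",
    "chrom": "chrom",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
}

_MANDATORY_FIELDS = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pval")


@dataclass(frozen=True)
class AssociationRecord:
    """One variant's summary statistic for one trait."""

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str = ""
    pos: int = 0
    eaf: Optional[float] = None
    n: Optional[float] = None

    def __post_init__(self):
        if self.effect_allele not in _VALID_ALLELES or self.other_allele not in _VALID_ALLELES:
            raise ValueError(
                f"{self.variant_id}: alleles must be single bases A/C/G/T, "
                f"got {self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele are identical")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValueError(f"{self.variant_id}: se must be positive, got {self.se}")
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.variant_id}: beta is not finite")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.variant_id}: pval must be in (0, 1], got {self.pval}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValueError(f"{self.variant_id}: eaf outside [0, 1]: {self.eaf}")
        if self.n is not None and not self.n > 0:
            raise ValueError(f"{self.variant_id}: n must be positive, got {self.n}")

    @property
    def zscore(self) -> float:
        return self.beta / self.se


@dataclass(frozen=True)
class VariantPanelEntry:
    """One disease-panel variant: its risk allele and optional LD proxy.

    ``risk_af`` is an optional reference frequency of the risk allele, used
    only to strand-resolve palindromic records under the ``infer_by_eaf``
    policy.  Proxy orientation must be declared (``proxy_risk_allele``); no
    LD-based phasing is attempted.
    """

    variant_id: str
    risk_allele: str
    alt_allele: str
    gene_label: str = ""
    proxy_id: Optional[str] = None
    proxy_r2: Optional[float] = None
    proxy_risk_allele: Optional[str] = None
    proxy_alt_allele: Optional[str] = None
    risk_af: Optional[float] = None

    def __post_init__(self):
        if self.risk_allele not in _VALID_ALLELES or self.alt_allele not in _VALID_ALLELES:
            raise ValueError(f"{self.variant_id}: panel alleles must be A/C/G/T")
        if self.risk_allele == self.alt_allele:
            raise ValueError(f"{self.variant_id}: risk and alt allele are identical")
        if (self.proxy_id is None) != (self.proxy_r2 is None):
            raise ValueError(f"{self.variant_id}: proxy_id and proxy_r2 must be given together")
        if self.proxy_r2 is not None and not (0 <= self.proxy_r2 <= 1):
            raise ValueError(f"{self.variant_id}: proxy_r2 outside [0, 1]")


@dataclass(frozen=True)
class HarmonizationAction:
    """Audit-trail entry: what happened to one panel variant in one table."""

    variant_id: str
    action: str  # kept | allele_flipped | strand_flipped | proxy_substituted |
    #              dropped_palindromic | dropped_mismatch | dropped_missing
    detail: str = ""


_ACTIONS = frozenset(
    {
        "kept",
        "allele_flipped",
        "strand_flipped",
        "proxy_substituted",
        "dropped_palindromic",
        "dropped_mismatch",
        "dropped_missing",
    }
)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def _parse_float(value, what: str, optional: bool = False) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        if optional:
            return None
        raise ValueError(f"missing {what}")
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValueError(f"cannot parse {what}: {value!r}") from None


def read_association_table(
    path, column_map: Optional[Mapping[str, str]] = None
) -> list[AssociationRecord]:
    """Read a tab-delimited summary-statistics table into validated records.

    ``column_map`` maps logical field names (keys of :data:`DEFAULT_COLUMN_MAP`)
    to the physical column names of the file.  Row-level failures (bad alleles,
    se <= 0, eaf outside [0, 1], unparsable numbers) are collected and raised
    together as :class:`TableValidationError` naming the offending rows.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [cmap[f] for f in _MANDATORY_FIELDS if cmap[f] not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing mandatory column(s) {missing}; present: {list(df.columns)}"
        )

    def col(row, logical, default=""):
        name = cmap.get(logical)
        return row[name] if name in df.columns else default

    records: list[AssociationRecord] = []
    errors: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        try:
            pos_raw = col(row, "pos")
            records.append(
                AssociationRecord(
                    variant_id=str(col(row, "variant_id")).strip(),
                    chrom=str(col(row, "chrom")).strip(),
                    pos=int(float(pos_raw)) if pos_raw not in ("", None) else 0,
                    effect_allele=str(col(row, "effect_allele")).strip().upper(),
                    other_allele=str(col(row, "other_allele")).strip().upper(),
                    eaf=_parse_float(col(row, "eaf"), "eaf", optional=True),
                    beta=_parse_float(col(row, "beta"), "beta"),
                    se=_parse_float(col(row, "se"), "se"),
                    pval=_parse_float(col(row, "pval"), "pval"),
                    n=_parse_float(col(row, "n"), "n", optional=True),
                )
            )
        except ValueError as exc:
            errors.append((i, str(exc)))
    if errors:
        raise TableValidationError(errors)
    return records


def records_to_frame(records: Iterable[AssociationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant_id": r.variant_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pval": r.pval,
                "n": r.n,
            }
            for r in records
        ],
        columns=list(DEFAULT_COLUMN_MAP),
    )


def write_association_table(records: Iterable[AssociationRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_variant_panel(path) -> list[VariantPanelEntry]:
    """Read a panel TSV (variant_id, risk_allele, alt_allele, gene_label,
    proxy_id, proxy_r2, optionally proxy_risk_allele/proxy_alt_allele/risk_af)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = {"variant_id", "risk_allele", "alt_allele"}
    if not needed.issubset(df.columns):
        raise ConfigurationError(f"{path}: panel needs columns {sorted(needed)}")

    def opt(row, name):
        v = row.get(name, "")
        return None if v in ("", None) else v

    entries = []
    for _, row in df.iterrows():
        row = row.to_dict()
        r2 = opt(row, "proxy_r2")
        af = opt(row, "risk_af")
        entries.append(
            VariantPanelEntry(
                variant_id=row["variant_id"].strip(),
                risk_allele=row["risk_allele"].strip().upper(),
                alt_allele=row["alt_allele"].strip().upper(),
                gene_label=str(row.get("gene_label", "")).strip(),
                proxy_id=opt(row, "proxy_id"),
                proxy_r2=float(r2) if r2 is not None else None,
                proxy_risk_allele=opt(row, "proxy_risk_allele"),
                proxy_alt_allele=opt(row, "proxy_alt_allele"),
                risk_af=float(af) if af is not None else None,
            )
        )
    return entries


def write_variant_panel(panel: Iterable[VariantPanelEntry], path) -> None:
    pd.DataFrame(
        [
            {
                "variant_id": e.variant_id,
                "risk_allele": e.risk_allele,
                "alt_allele": e.alt_allele,
                "gene_label": e.gene_label,
                "proxy_id": e.proxy_id or "",
                "proxy_r2": "" if e.proxy_r2 is None else e.proxy_r2,
                "proxy_risk_allele": e.proxy_risk_allele or "",
                "proxy_alt_allele": e.proxy_alt_allele or "",
                "risk_af": "" if e.risk_af is None else e.risk_af,
            }
            for e in panel
        ]
    ).to_csv(path, sep="\t", index=False)


def actions_to_frame(actions: Iterable[HarmonizationAction]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"variant_id": a.variant_id, "action": a.action, "detail": a.detail} for a in actions],
        columns=["variant_id", "action", "detail"],
    )


# ---------------------------------------------------------------------------
# Allele algebra
# ---------------------------------------------------------------------------


def flip_record(record: AssociationRecord) -> AssociationRecord:
    """Re-express the effect relative to the other allele.

    Swaps the alleles, negates beta, and replaces eaf by 1 − eaf (when
    present); se, p and n are unchanged.  Applying it twice recovers the
    original record (up to floating-point round-trip on eaf).
    """
    return replace(
        record,
        effect_allele=record.other_allele,
        other_allele=record.effect_allele,
        beta=-record.beta,
        eaf=None if record.eaf is None else 1.0 - record.eaf,
    )


def complement_record(record: AssociationRecord) -> AssociationRecord:
    """Express both alleles on the opposite strand; effect and eaf unchanged."""
    return replace(
        record,
        effect_allele=_COMPLEMENT[record.effect_allele],
        other_allele=_COMPLEMENT[record.other_allele],
    )


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    return {effect_allele, other_allele} in ({"A", "T"}, {"C", "G"})


def _orient_to(
    record: AssociationRecord,
    risk: str,
    alt: str,
    palindrome_policy: str,
    eaf_window: float,
    risk_af: Optional[float],
) -> tuple[Optional[AssociationRecord], str, str]:
    """Align one record to (risk, alt); returns (record-or-None, action, detail)."""
    ea, oa = record.effect_allele, record.other_allele
    if is_palindromic(ea, oa):
        if {ea, oa} != {risk, alt}:
            return None, "dropped_mismatch", f"alleles {ea}/{oa} vs panel {risk}/{alt}"
        if palindrome_policy == "drop":
            return None, "dropped_palindromic", "policy=drop"
        if palindrome_policy == "keep":
            if ea == risk:
                return record, "kept", "palindromic, labels trusted"
            return flip_record(record), "allele_flipped", "palindromic, labels trusted"
        if palindrome_policy == "infer_by_eaf":
            if record.eaf is None:
                return None, "dropped_palindromic", "no eaf to infer strand"
            if abs(record.eaf - 0.5) < eaf_window:
                return (
                    None,
                    "dropped_palindromic",
                    f"eaf {record.eaf:.3f} within {eaf_window} of 0.5",
                )
            nominal = record if ea == risk else flip_record(record)
            nominal_action = "kept" if ea == risk else "allele_flipped"
            if risk_af is not None and abs(risk_af - 0.5) >= eaf_window:
                # Frequencies on opposite sides of 0.5 mean the record's labels
                # refer to the opposite strand: reverse the nominal orientation.
                if (nominal.eaf - 0.5) * (risk_af - 0.5) < 0:
                    return (
                        complement_record(flip_record(nominal)),
                        "strand_flipped",
                        f"palindromic, eaf {record.eaf:.3f} vs risk_af {risk_af:.3f}",
                    )
            return nominal, nominal_action, "palindromic, eaf-consistent"
        raise ConfigurationError(f"unknown palindrome_policy {palindrome_policy!r}")
    # Non-palindromic: try direct match, then strand complement.
    if {ea, oa} == {risk, alt}:
        if ea == risk:
            return record, "kept", ""
        return flip_record(record), "allele_flipped", ""
    comp = complement_record(record)
    if {comp.effect_allele, comp.other_allele} == {risk, alt}:
        if comp.effect_allele == risk:
            return comp, "strand_flipped", "complemented"
        return flip_record(comp), "strand_flipped", "complemented and flipped"
    return None, "dropped_mismatch", f"alleles {ea}/{oa} vs panel {risk}/{alt}"


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------


def harmonize_to_panel(
    records: Sequence[AssociationRecord],
    panel: Sequence[VariantPanelEntry],
    palindrome_policy: str = "infer_by_eaf",
    eaf_window: float = 0.08,
) -> tuple[list[AssociationRecord], list[HarmonizationAction]]:
    """Align each panel variant's record to the panel risk allele.

    Every panel variant yields exactly one :class:`HarmonizationAction`;
    harmonized records are returned in panel order with
    ``effect_allele == risk_allele``.
    """
    if palindrome_policy not in ("drop", "infer_by_eaf", "keep"):
        raise ConfigurationError(f"unknown palindrome_policy {palindrome_policy!r}")
    index = {r.variant_id: r for r in records}
    out: list[AssociationRecord] = []
    actions: list[HarmonizationAction] = []
    for entry in panel:
        rec = index.get(entry.variant_id)
        if rec is None:
            actions.append(
                HarmonizationAction(entry.variant_id, "dropped_missing", "not in table")
            )
            continue
        oriented, action, detail = _orient_to(
            rec, entry.risk_allele, entry.alt_allele, palindrome_policy, eaf_window, entry.risk_af
        )
        actions.append(HarmonizationAction(entry.variant_id, action, detail))
        if oriented is not None:
            out.append(oriented)
    return out, actions


def substitute_proxies(
    records: Sequence[AssociationRecord],
    panel: Sequence[VariantPanelEntry],
    r2_min: float = 0.5,
) -> tuple[list[AssociationRecord], list[HarmonizationAction]]:
    """Represent absent panel variants by their declared LD proxies.

    For each panel variant with no record but a declared proxy present in the
    table and ``proxy_r2 >= r2_min``, the proxy's statistics are oriented to
    the declared proxy risk allele and relabelled with the panel variant's id
    and alleles, so downstream stages key on the panel variant.  Provenance is
    recorded in the action detail.  Variants that remain unrepresentable give
    ``dropped_missing`` (not an exception).
    """
    index = {r.variant_id: r for r in records}
    out = list(records)
    actions: list[HarmonizationAction] = []
    for entry in panel:
        if entry.variant_id in index:
            continue
        if entry.proxy_id is None or entry.proxy_id not in index:
            actions.append(
                HarmonizationAction(entry.variant_id, "dropped_missing", "no record, no proxy")
            )
            continue
        if entry.proxy_r2 < r2_min:
            actions.append(
                HarmonizationAction(
                    entry.variant_id,
                    "dropped_missing",
                    f"proxy {entry.proxy_id} r2={entry.proxy_r2} < {r2_min}",
                )
            )
            continue
        if entry.proxy_risk_allele is None:
            actions.append(
                HarmonizationAction(
                    entry.variant_id,
                    "dropped_missing",
                    f"proxy {entry.proxy_id} has no declared risk allele",
                )
            )
            continue
        proxy_rec = index[entry.proxy_id]
        proxy_alt = entry.proxy_alt_allele or _other_of(proxy_rec, entry.proxy_risk_allele)
        oriented, action, detail = _orient_to(
            proxy_rec, entry.proxy_risk_allele, proxy_alt, "keep", 0.0, None
        )
        if oriented is None:
            actions.append(
                HarmonizationAction(
                    entry.variant_id,
                    "dropped_mismatch",
                    f"proxy {entry.proxy_id}: {detail}",
                )
            )
            continue
        out.append(
            replace(
                oriented,
                variant_id=entry.variant_id,
                effect_allele=entry.risk_allele,
                other_allele=entry.alt_allele,
                # the proxy's frequency does not transfer to the index variant
                eaf=None,
            )
        )
        actions.append(
            HarmonizationAction(
                entry.variant_id,
                "proxy_substituted",
                f"statistics from {entry.proxy_id} (r2={entry.proxy_r2}, {action})",
            )
        )
    return out, actions


def _other_of(record: AssociationRecord, allele: str) -> str:
    """The allele of ``record`` that pairs with ``allele`` (strand-aware)."""
    pair = {record.effect_allele, record.other_allele}
    if allele in pair:
        return (pair - {allele}).pop()
    comp_pair = {_COMPLEMENT[a] for a in pair}
    if allele in comp_pair:
        return (comp_pair - {allele}).pop()
    return record.other_allele
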