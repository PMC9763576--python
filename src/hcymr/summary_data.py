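"""Data model and I/O for two-sample GWAS summary statistics.

A two-sample Mendelian randomization analysis consumes per-SNP association
estimates from two independent GWAS: one for the exposure (here plasma
homocysteine, a quantitative trait) and one for each binary outcome
(log-odds scale).  This module defines the record types, reads and writes
delimited summary-statistic tables, aligns ("harmonizes") exposure and
outcome tables to a common effect allele per SNP, and converts log-scale
causal estimates into exponentiated effects with confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class ValidationError(ValueError):
    """Input data violates an invariant (bad SE, bad allele, bad frequency)."""


class ConfigurationError(ValueError):
    """A required column or configuration entry could not be resolved."""


class HarmonizationError(ValueError):
    """Exposure and outcome tables cannot be joined into a usable dataset."""


#: complementary DNA bases, used to detect palindromic (strand-ambiguous) SNPs
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(a1: str | None, a2: str | None) -> bool:
    if not a1 or not a2:
        return False
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


@dataclass(frozen=True)
class SNPAssociation:
    """One variant's summary association with one trait.

    ``beta`` is on the trait's native scale: log-odds per effect allele for a
    binary trait, per-unit (or per-SD) for a quantitative one.  ``other_allele``,
    ``eaf`` and ``pvalue`` may be missing (``None``); ``se`` must be positive
    whenever ``beta`` is present.
    """

    rsid: str
    effect_allele: str
    beta: float
    se: float
    other_allele: str | None = None
    chrom: str | None = None
    eaf: float | None = None
    pvalue: float | None = None
    gene: str | None = None

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValidationError("rsid must be a nonempty string")
        if not math.isfinite(self.beta):
            raise ValidationError(f"{self.rsid}: beta must be finite")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValidationError(f"{self.rsid}: se must be > 0, got {self.se}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValidationError(f"{self.rsid}: eaf {self.eaf} outside [0, 1]")
        if self.pvalue is not None and not (0.0 < self.pvalue <= 1.0):
            raise ValidationError(f"{self.rsid}: pvalue {self.pvalue} outside (0, 1]")

    @property
    def is_palindromic(self) -> bool:
        return _is_palindromic(self.effect_allele, self.other_allele)

    def pvalue_or_wald(self) -> float:
        """Stored p-value, or the two-sided normal p from beta/se if absent."""
        if self.pvalue is not None:
            return self.pvalue
        return float(2.0 * stats.norm.sf(abs(self.beta / self.se)))


# default header names accepted by read_summary_table, per canonical field
_DEFAULT_COLUMNS: dict[str, tuple[str, ...]] = {
    "rsid": ("rsid", "snp", "rsids", "variant", "id"),
    "effect_allele": ("effect_allele", "ea", "a1"),
    "other_allele": ("other_allele", "oa", "a2", "ref_allele"),
    "beta": ("beta", "b", "effect"),
    "se": ("se", "standard_error", "stderr"),
    "chrom": ("chrom", "chr", "chromosome"),
    "eaf": ("eaf", "effect_allele_frequency", "freq"),
    "pvalue": ("pvalue", "p", "p_value", "pval"),
    "gene": ("gene", "nearest_gene"),
}
_REQUIRED = ("rsid", "effect_allele", "beta", "se")


def _resolve_columns(
    header: Sequence[str], column_map: Mapping[str, str] | None
) -> dict[str, str]:
    lower = {c.lower(): c for c in header}
    resolved: dict[str, str] = {}
    column_map = column_map or {}
    for canon, aliases in _DEFAULT_COLUMNS.items():
        if canon in column_map:
            name = column_map[canon]
            if name not in header:
                raise ConfigurationError(
                    f"column {name!r} (mapped to {canon!r}) not found in header"
                )
            resolved[canon] = name
        else:
            for alias in aliases:
                if alias in lower:
                    resolved[canon] = lower[alias]
                    break
    missing = [c for c in _REQUIRED if c not in resolved]
    if missing:
        raise ConfigurationError(
            f"required column(s) {missing} not found in header {list(header)}"
        )
    return resolved


def read_summary_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[SNPAssociation]:
    """Read a tab- or comma-delimited summary-statistics file.

    ``column_map`` maps canonical field names (``rsid``, ``effect_allele``,
    ``beta``, ``se``, optionally ``other_allele``, ``chrom``, ``eaf``,
    ``pvalue``, ``gene``) to header names; unmapped fields fall back to the
    common aliases.  Missing optional fields are recorded as absent, not zero.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    cols = _resolve_columns(list(df.columns), column_map)

    def _get(row: pd.Series, canon: str) -> str | None:
        if canon not in cols:
            return None
        raw = row[cols[canon]]
        if raw is None or (isinstance(raw, float) and math.isnan(raw)):
            return None
        raw = str(raw).strip()
        return None if raw in ("", "NA", "NaN", "nan", ".") else raw

    def _num(row: pd.Series, canon: str, rownum: int) -> float | None:
        raw = _get(row, canon)
        if raw is None:
            return None
        try:
            return float(raw)
        except ValueError:
            raise ValidationError(
                f"row {rownum}: non-numeric value {raw!r} in column {cols[canon]!r}"
            ) from None

    records: list[SNPAssociation] = []
    bad_se: list[str] = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        rsid = _get(row, "rsid")
        if rsid is None:
            raise ValidationError(f"row {i}: missing rsid")
        beta = _num(row, "beta", i)
        se = _num(row, "se", i)
        if beta is None or se is None:
            raise ValidationError(f"row {i} ({rsid}): missing beta or se")
        if se <= 0:
            bad_se.append(rsid)
            continue
        records.append(
            SNPAssociation(
                rsid=rsid,
                effect_allele=(_get(row, "effect_allele") or "").upper(),
                other_allele=(lambda a: a.upper() if a else None)(_get(row, "other_allele")),
                beta=beta,
                se=se,
                chrom=_get(row, "chrom"),
                eaf=_num(row, "eaf", i),
                pvalue=_num(row, "pvalue", i),
                gene=_get(row, "gene"),
            )
        )
    if bad_se:
        raise ValidationError(f"non-positive se for rsid(s): {', '.join(bad_se)}")
    seen: set[str] = set()
    for r in records:
        if r.rsid in seen:
            raise ValidationError(f"duplicate rsid {r.rsid}")
        seen.add(r.rsid)
    return records


def write_summary_table(records: Iterable[SNPAssociation], path: str | Path) -> None:
    """Write records back to TSV, preserving numeric values via repr round-trip."""
    rows = []
    for r in records:
        rows.append(
            {
                "rsid": r.rsid,
                "gene": r.gene,
                "chrom": r.chrom,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": repr(r.beta),
                "se": repr(r.se),
                "pvalue": repr(r.pvalue) if r.pvalue is not None else None,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass
class HarmonizedDataset:
    """Aligned per-SNP exposure/outcome effect pairs — the estimator input.

    All vectors share length J >= 1 with no missing entries and strictly
    positive standard errors; ``flip_log`` records every allele flip applied
    during harmonization and ``palindromic`` flags strand-ambiguous SNPs.
    """

    snps: list[str]
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    exposure_label: str = "exposure"
    outcome_label: str = "outcome"
    flip_log: list[str] = field(default_factory=list)
    palindromic: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beta_exposure = np.asarray(self.beta_exposure, dtype=float)
        self.se_exposure = np.asarray(self.se_exposure, dtype=float)
        self.beta_outcome = np.asarray(self.beta_outcome, dtype=float)
        self.se_outcome = np.asarray(self.se_outcome, dtype=float)
        n = len(self.snps)
        if n < 1:
            raise ValidationError("harmonized dataset must contain at least one SNP")
        for name in ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome"):
            v = getattr(self, name)
            if v.shape != (n,):
                raise ValidationError(f"{name} has shape {v.shape}, expected ({n},)")
            if not np.all(np.isfinite(v)):
                raise ValidationError(f"{name} contains non-finite entries")
        if np.any(self.se_exposure <= 0) or np.any(self.se_outcome <= 0):
            raise ValidationError("all standard errors must be strictly positive")
        if len(set(self.snps)) != n:
            raise ValidationError("snps must be unique")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def subset(self, keep: Sequence[str]) -> "HarmonizedDataset":
        keep_set = set(keep)
        idx = [i for i, s in enumerate(self.snps) if s in keep_set]
        if not idx:
            raise ValidationError("subset would remove every SNP")
        return HarmonizedDataset(
            snps=[self.snps[i] for i in idx],
            beta_exposure=self.beta_exposure[idx],
            se_exposure=self.se_exposure[idx],
            beta_outcome=self.beta_outcome[idx],
            se_outcome=self.se_outcome[idx],
            exposure_label=self.exposure_label,
            outcome_label=self.outcome_label,
            palindromic=[s for s in self.palindromic if s in keep_set],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": self.snps,
                "beta_exposure": self.beta_exposure,
                "se_exposure": self.se_exposure,
                "beta_outcome": self.beta_outcome,
                "se_outcome": self.se_outcome,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(
        cls, path: str | Path, exposure_label: str = "exposure", outcome_label: str = "outcome"
    ) -> "HarmonizedDataset":
        df = pd.read_csv(path, sep="\t")
        return cls(
            snps=list(df["rsid"].astype(str)),
            beta_exposure=df["beta_exposure"].to_numpy(float),
            se_exposure=df["se_exposure"].to_numpy(float),
            beta_outcome=df["beta_outcome"].to_numpy(float),
            se_outcome=df["se_outcome"].to_numpy(float),
            exposure_label=exposure_label,
            outcome_label=outcome_label,
        )


def harmonize(
    exposure: Sequence[SNPAssociation],
    outcome: Sequence[SNPAssociation],
    policy: str = "flag",
    exposure_label: str = "exposure",
    outcome_label: str = "outcome",
) -> HarmonizedDataset:
    """Align an outcome table to the exposure's effect alleles.

    The exposure rsids define the instrument set; the join is an inner join
    on rsid.  Where the outcome's effect allele equals the exposure's other
    allele the outcome beta is negated (and EAF complemented conceptually);
    allele pairs that are neither identical nor swapped cause the SNP to be
    dropped with a warning.  Palindromic (A/T or C/G) SNPs are handled per
    ``policy``: ``"flag"`` (default) keeps and flags them, ``"drop"`` removes
    them, ``"keep"`` keeps silently.
    """
    if policy not in ("flag", "drop", "keep"):
        raise ConfigurationError(f"unknown palindromic policy {policy!r}")
    if not exposure or not outcome:
        raise HarmonizationError("exposure and outcome tables must be nonempty")
    out_by_rsid = {r.rsid: r for r in outcome}
    if not set(r.rsid for r in exposure) & set(out_by_rsid):
        raise HarmonizationError("no overlapping rsids between exposure and outcome")

    snps: list[str] = []
    bx, sx, by, sy = [], [], [], []
    flip_log: list[str] = []
    palindromic: list[str] = []
    dropped: list[str] = []
    for exp in exposure:
        out = out_by_rsid.get(exp.rsid)
        if out is None:
            dropped.append(exp.rsid)
            continue
        e_ea = exp.effect_allele.upper()
        o_ea = out.effect_allele.upper()
        o_oa = out.other_allele.upper() if out.other_allele else None
        e_oa = exp.other_allele.upper() if exp.other_allele else None
        if o_ea == e_ea and (e_oa is None or o_oa is None or o_oa == e_oa):
            beta_out = out.beta
            flipped = False
        elif (e_oa is not None and o_ea == e_oa) or (o_oa is not None and o_oa == e_ea):
            beta_out = -out.beta
            flipped = True
        else:
            dropped.append(exp.rsid)
            continue
        if exp.is_palindromic or _is_palindromic(o_ea, o_oa):
            if policy == "drop":
                dropped.append(exp.rsid)
                continue
            if policy == "flag":
                palindromic.append(exp.rsid)
        snps.append(exp.rsid)
        bx.append(exp.beta)
        sx.append(exp.se)
        by.append(beta_out)
        sy.append(out.se)
        if flipped:
            flip_log.append(exp.rsid)
    if not snps:
        raise HarmonizationError(
            "every overlapping SNP was dropped by allele checks; nothing to analyse"
        )
    return HarmonizedDataset(
        snps=snps,
        beta_exposure=np.array(bx),
        se_exposure=np.array(sx),
        beta_outcome=np.array(by),
        se_outcome=np.array(sy),
        exposure_label=exposure_label,
        outcome_label=outcome_label,
        flip_log=flip_log,
        palindromic=palindromic,
        dropped=dropped,
    )


@dataclass(frozen=True)
class EffectWithCI:
    """A causal-effect estimate on both log and exponentiated scales."""

    estimate_log: float
    se_log: float
    ci_low: float
    ci_high: float
    or_scale: float
    pvalue: float
    n_snps: int
    method: str
    alpha: float = 0.05

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.method}: OR={self.or_scale:.3f} "
            f"({100 * (1 - self.alpha):.0f}% CI {self.ci_low:.3f}-{self.ci_high:.3f}, "
            f"p={self.pvalue:.3f}, n_snps={self.n_snps})"
        )


def to_effect_with_ci(
    estimate_log: float,
    se_log: float,
    n_snps: int,
    method: str,
    alpha: float = 0.05,
) -> EffectWithCI:
    """Wrap a log-scale estimate into an exponentiated effect with a z-interval.

    CI bounds are exp(estimate +/- z_{1-alpha/2} * se); the p-value is the
    two-sided standard-normal tail of the Wald statistic estimate/se.
    """
    if not (se_log > 0 and math.isfinite(se_log)):
        raise ValidationError(f"se_log must be > 0, got {se_log}")
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    p = float(2.0 * stats.norm.sf(abs(estimate_log / se_log)))
    return EffectWithCI(
        estimate_log=float(estimate_log),
        se_log=float(se_log),
        ci_low=float(np.exp(estimate_log - z * se_log)),
        ci_high=float(np.exp(estimate_log + z * se_log)),
        or_scale=float(np.exp(estimate_log)),
        pvalue=min(p, 1.0) if p > 0 else 5e-324,
        n_snps=int(n_snps),
        method=method,
        alpha=alpha,
    )
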