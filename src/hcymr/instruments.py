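"""Instrument selection: significance filtering, LD pruning, rsid exclusion.

Candidate variants become instruments by (1) passing a genome-wide
significance threshold in the exposure GWAS, (2) surviving greedy pruning
against a local pairwise LD (r-squared) matrix so that retained instruments
are mutually near-independent, and (3) not appearing on an explicit
exclusion list (e.g. variants lacking outcome-GWAS information, or flagged
as associated with confounders).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .summary_data import SNPAssociation, ValidationError

log = logging.getLogger(__name__)


@dataclass
class LDMatrix:
    """Symmetric pairwise LD r-squared matrix over named variants."""

    rsids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.rsids)
        if self.r2.shape != (n, n):
            raise ValidationError(f"r2 has shape {self.r2.shape}, expected ({n}, {n})")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise ValidationError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-12):
            raise ValidationError("LD matrix diagonal must be 1")
        if np.any(self.r2 < 0) or np.any(self.r2 > 1):
            raise ValidationError("LD r-squared entries must lie in [0, 1]")
        self._index = {rs: i for i, rs in enumerate(self.rsids)}
        if len(self._index) != n:
            raise ValidationError("LD matrix rsids must be unique")

    def r2_between(self, a: str, b: str) -> float:
        try:
            return float(self.r2[self._index[a], self._index[b]])
        except KeyError as e:
            raise ValidationError(f"rsid {e.args[0]} absent from LD matrix") from None

    @classmethod
    def identity(cls, rsids: Sequence[str]) -> "LDMatrix":
        return cls(list(rsids), np.eye(len(rsids)))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LDMatrix":
        """Read a square matrix with an rsid header row and first column."""
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValidationError("LD matrix row and column rsids disagree")
        return cls(list(df.columns.astype(str)), df.to_numpy(float))


def select_by_pvalue(
    assocs: Sequence[SNPAssociation], threshold: float = 5e-8
) -> list[SNPAssociation]:
    """Keep associations with exposure p-value strictly below ``threshold``.

    Order is preserved.  Every record must carry a p-value: silently
    treating a missing p as significant would defeat the relevance check.
    """
    missing = [a.rsid for a in assocs if a.pvalue is None]
    if missing:
        raise ValidationError(f"records lacking a p-value: {', '.join(missing)}")
    return [a for a in assocs if a.pvalue < threshold]


def ld_prune(
    assocs: Sequence[SNPAssociation],
    ld: LDMatrix,
    r2_threshold: float = 0.05,
) -> list[SNPAssociation]:
    """Greedy LD clumping against a local r-squared matrix.

    Candidates are visited in order of ascending exposure p-value (ties
    broken by rsid); a candidate is accepted iff its r-squared with every
    already-accepted variant is strictly below ``r2_threshold``.  The
    accepted set is returned in the original input order.  The default
    threshold 0.05 demands near-independence; 1.0 disables pruning.
    """
    if not (0.0 <= r2_threshold <= 1.0):
        raise ValidationError(f"r2_threshold must be in [0, 1], got {r2_threshold}")
    for a in assocs:
        if a.rsid not in ld._index:
            raise ValidationError(f"rsid {a.rsid} absent from LD matrix")

    def sort_key(a: SNPAssociation) -> tuple[float, str]:
        return (a.pvalue_or_wald(), a.rsid)

    accepted: list[str] = []
    for a in sorted(assocs, key=sort_key):
        if all(ld.r2_between(a.rsid, b) < r2_threshold for b in accepted):
            accepted.append(a.rsid)
    accepted_set = set(accepted)
    kept = [a for a in assocs if a.rsid in accepted_set]
    removed = [a.rsid for a in assocs if a.rsid not in accepted_set]
    if removed:
        log.info("ld_prune removed %d SNP(s): %s", len(removed), ", ".join(removed))
    return kept


def exclude_rsids(
    assocs: Sequence[SNPAssociation],
    excluded: Iterable[str],
    reason: str = "excluded",
) -> list[SNPAssociation]:
    """Remove listed rsids; excluding an absent rsid is a warning, not an error."""
    excluded = set(excluded)
    present = {a.rsid for a in assocs}
    absent = excluded - present
    if absent:
        log.warning(
            "exclusion list (%s) names %d rsid(s) not present: %s",
            reason,
            len(absent),
            ", ".join(sorted(absent)),
        )
    kept = [a for a in assocs if a.rsid not in excluded]
    n_removed = len(assocs) - len(kept)
    if n_removed:
        log.info("excluded %d SNP(s) (%s)", n_removed, reason)
    return kept


def read_exclusion_list(path: str | Path) -> list[str]:
    """One rsid per line; blank lines and '#' comments ignored."""
    out: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out
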