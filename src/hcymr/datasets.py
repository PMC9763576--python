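"""Packaged datasets: the 12-instrument homocysteine table and the
synthetic instrument-selection fixtures.

The main fixture is the published summary table for 12 homocysteine-
associated SNPs (exposure beta/SE/p from a 44,147-person GWAS meta-analysis
of plasma homocysteine) joined with log-odds associations for three FinnGen
binary liver outcomes: NAFLD (1,578 cases), NASH (99 cases) and Cirrhosis
(826 cases).

The candidate-selection fixtures reconstruct the published instrument
accounting (18 candidates, 3 removed by LD pruning, 3 removed for missing
outcome information, 12 retained).  The 6 extra candidate rows and the LD
matrix are synthetic: the source study reports which rsids were removed and
why, but not their summary statistics or pairwise r-squared values, so
plausible values are filled in (each LD-removed SNP is given r-squared 0.9
with a stronger partner at the same locus).  Note one inconsistency
inherited from the source: rs12780845 is listed among the variants lacking
outcome information yet also appears in the final 12-SNP table; the
estimation fixture follows the table.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .instruments import LDMatrix, read_exclusion_list
from .summary_data import SNPAssociation, read_summary_table

OUTCOMES = ("NAFLD", "NASH", "Cirrhosis")

_OUTCOME_FILES = {
    "NAFLD": "outcome_nafld.tsv",
    "NASH": "outcome_nash.tsv",
    "Cirrhosis": "outcome_cirrhosis.tsv",
}

#: named in the source as removed by LD pruning (r-squared with a retained
#: partner above threshold)
LD_EXCLUDED = ("rs12134663", "rs957140", "rs12921383")
#: named in the source as lacking outcome-GWAS information
INFO_LACKING = ("rs7422339", "rs2851391", "rs12780845")


def data_path(name: str) -> Path:
    return Path(str(resources.files("hcymr").joinpath("data", name)))


def load_exposure() -> list[SNPAssociation]:
    """The 12 homocysteine instruments (exposure associations)."""
    return read_summary_table(data_path("hcy_exposure.tsv"))


def load_outcome(name: str) -> list[SNPAssociation]:
    """Outcome associations for one of NAFLD, NASH, Cirrhosis."""
    try:
        fname = _OUTCOME_FILES[name]
    except KeyError:
        raise KeyError(f"unknown outcome {name!r}; expected one of {OUTCOMES}") from None
    return read_summary_table(data_path(fname))


def load_candidates() -> list[SNPAssociation]:
    """The synthetic 18-SNP candidate set for the selection walk-through."""
    return read_summary_table(data_path("candidates_18_synthetic.tsv"))


def load_ld_matrix() -> LDMatrix:
    """Synthetic 18x18 LD r-squared matrix over the candidate set."""
    return LDMatrix.from_tsv(data_path("ld_matrix_synthetic.tsv"))


def load_info_exclusions() -> list[str]:
    """rsids excluded for lacking outcome-GWAS information."""
    return read_exclusion_list(data_path("exclusion_no_outcome_info.txt"))
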