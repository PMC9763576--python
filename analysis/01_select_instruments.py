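"""Instrument selection walk-through: 18 candidates -> 12 instruments.

Starting from the packaged 18-SNP candidate table (12 published rows plus
6 synthetic stand-ins for the removed candidates), applies the genome-wide
significance filter, prunes at LD r-squared < 0.05 against the synthetic
LD matrix, and removes the variants lacking outcome information.  Writes
the per-stage accounting to results/instrument_selection.tsv.
"""

from pathlib import Path

import pandas as pd

from hcymr import datasets
from hcymr.instruments import exclude_rsids, ld_prune, select_by_pvalue

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cands = datasets.load_candidates()
    sig = select_by_pvalue(cands, 5e-8)
    pruned = ld_prune(sig, datasets.load_ld_matrix(), 0.05)
    final = exclude_rsids(pruned, datasets.load_info_exclusions(), reason="no outcome info")

    stages = [
        ("candidates", cands),
        ("p<5e-8", sig),
        ("ld_r2<0.05", pruned),
        ("exclusion_list", final),
    ]
    rows = []
    for name, snps in stages:
        rows.append({"stage": name, "n_snps": len(snps), "rsids": ",".join(a.rsid for a in snps)})
        print(f"{name:15s} {len(snps):2d} SNPs")
    removed_ld = {a.rsid for a in sig} - {a.rsid for a in pruned}
    print(f"removed by LD pruning: {', '.join(sorted(removed_ld))}")
    print(f"removed by exclusion list: {', '.join(datasets.load_info_exclusions())}")

    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "instrument_selection.tsv", sep="\t", index=False)
    print(f"wrote {OUT / 'instrument_selection.tsv'}")


if __name__ == "__main__":
    main()
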