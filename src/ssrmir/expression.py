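"""RPKM expression quantification and class binning.

RPKM for gene A = 10^9 * C / (N * L) where C is the number of reads
uniquely aligned to A, N the total uniquely aligned reads, and L the gene
length in bases. Genes are binned into four named expression tiers:
low [0, 100), moderate [100, 1000], high (1000, 10000], very_high
(10000, inf).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

EXPRESSION_CLASSES = ("low", "moderate", "high", "very_high")


def rpkm(C: int, N: int, L: int) -> float:
    """Reads per kilobase of transcript per million uniquely mapped reads."""
    if N <= 0:
        raise ValueError(f"total read count N must be positive, got {N}")
    if L <= 0:
        raise ValueError(f"gene length L must be positive, got {L}")
    if C < 0:
        raise ValueError(f"gene read count C must be non-negative, got {C}")
    return 1e9 * C / (N * L)


def expression_class(rpkm_value: float) -> str:
    """Named expression tier for an RPKM value."""
    if rpkm_value < 0:
        raise ValueError(f"negative RPKM {rpkm_value}")
    if rpkm_value < 100:
        return "low"
    if rpkm_value <= 1000:
        return "moderate"
    if rpkm_value <= 10000:
        return "high"
    return "very_high"


@dataclass
class ExpressionRecord:
    gene_id: str
    C: int
    N: int
    L: int
    rpkm: float
    klass: str


def quantify(counts: pd.DataFrame, N: int | None = None) -> pd.DataFrame:
    """Compute RPKM and expression class for a gene_id/C/L count table.

    N (total uniquely aligned reads) defaults to the sum of C.
    """
    required = {"gene_id", "C", "L"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    total = int(counts["C"].sum()) if N is None else int(N)
    out = counts.copy()
    out["rpkm"] = [rpkm(int(c), total, int(l)) for c, l in zip(out["C"], out["L"])]
    out["klass"] = [expression_class(v) for v in out["rpkm"]]
    return out


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")
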