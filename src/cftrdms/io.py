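"""Readers and writers for the pipeline's plain-text formats.

TSV is the canonical interchange format; every writer here has a paired
reader that round-trips values exactly. FASTQ (Phred+33) is emitted for
simulated reads and parsed with Biopython. The per-variant supplementary
intensity workbook (Excel) is read-only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .scoring import FRACTION_COLUMNS, FractionCountTable, UmiWhitelist
from .variants import normalize_variant_id, parse_residue

# ---------------------------------------------------------------------------
# count tables / fraction means / whitelist


def write_count_table(table: FractionCountTable, path) -> None:
    table.counts.to_csv(path, sep="\t")


def read_count_table(path, fraction_means, replicate_id="rep1",
                     cell_line="parental", treatment="vehicle") -> FractionCountTable:
    counts = pd.read_csv(path, sep="\t", index_col="variant_id")
    counts = counts[FRACTION_COLUMNS].astype(np.int64)
    return FractionCountTable(
        counts=counts,
        fraction_means=np.asarray(fraction_means, float),
        replicate_id=replicate_id,
        cell_line=cell_line,
        treatment=treatment,
    )


def write_fraction_means(means, path) -> None:
    pd.DataFrame(
        {"fraction": [f"frac{k+1}" for k in range(4)], "mean_F": np.asarray(means, float)}
    ).to_csv(path, sep="\t", index=False)


def read_fraction_means(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("fraction").loc[[f"frac{k+1}" for k in range(4)], "mean_F"].to_numpy(float)


def write_whitelist(whitelist: UmiWhitelist, path) -> None:
    pd.DataFrame(
        sorted(whitelist.entries.items()), columns=["umi", "variant_id"]
    ).to_csv(path, sep="\t", index=False)


def read_whitelist(path) -> UmiWhitelist:
    df = pd.read_csv(path, sep="\t")
    return UmiWhitelist(dict(zip(df["umi"], df["variant_id"])))


# ---------------------------------------------------------------------------
# FASTQ

_Q30 = chr(30 + 33)
_Q10 = chr(10 + 33)


def write_fastq(reads: pd.DataFrame, path, flank: str = "") -> None:
    """Emit simulated reads as 4-line FASTQ records (Phred+33).

    Bases are Q30 except corrupted positions (where the read differs from its
    true barcode), written at Q10 so the expected-error filter is exercised.
    An optional constant ``flank`` is appended after the barcode.
    """
    flank_q = _Q30 * len(flank)
    with open(path, "w") as fh:
        for i, row in enumerate(reads.itertuples(index=False)):
            qual = "".join(
                _Q10 if a != b else _Q30 for a, b in zip(row.umi, row.true_umi)
            )
            fh.write(f"@read{i} variant={row.true_variant}\n{row.umi}{flank}\n+\n{qual}{flank_q}\n")


def read_fastq(path):
    """Parse a FASTQ file into Biopython SeqRecords (list)."""
    from Bio import SeqIO

    return list(SeqIO.parse(str(path), "fastq"))


# ---------------------------------------------------------------------------
# PME / response tables


def write_pme(pme: pd.DataFrame, path, cell_line="parental", treatment="vehicle") -> None:
    out = pme.copy()
    out.insert(0, "condition", f"{cell_line}:{treatment}")
    out.to_csv(path, sep="\t")


def read_pme(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="variant_id")
    return df


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


# ---------------------------------------------------------------------------
# supplementary per-variant intensity workbook

_VARIANT_ALIASES = ("variant", "variant_id", "mutation", "mutant", "cftr variant", "cftr2 variant")


@dataclass
class Sd1Table:
    """Per-variant intensity/PME values per condition from a workbook."""

    data: pd.DataFrame  # indexed by canonical variant_id; numeric columns
    unparsed: list[str]  # variant ids with no parseable residue position

    def residues(self) -> pd.Series:
        out = {}
        for vid in self.data.index:
            try:
                out[vid] = parse_residue(vid)
            except ValueError:
                out[vid] = np.nan
        return pd.Series(out, name="residue")


def load_sd1(path, sheet=0) -> Sd1Table:
    """Load a per-variant intensity workbook with tolerant column matching.

    The variant column is found by name (aliases: variant, variant_id,
    mutation, mutant, ...); remaining numeric columns are kept as condition
    scores. Rows whose variant id has no parseable residue are reported in
    ``unparsed``, not dropped. Duplicate variant rows are an error.
    """
    path = Path(path)
    df = pd.read_excel(path, sheet_name=sheet)
    var_col = None
    for col in df.columns:
        if str(col).strip().lower() in _VARIANT_ALIASES:
            var_col = col
            break
    if var_col is None:
        raise ValueError(
            f"no recognizable variant column; headers found: {list(df.columns)}"
        )
    ids = df[var_col].astype(str).map(normalize_variant_id)
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate variant row(s): {sorted(set(dup))}")
    numeric = df.drop(columns=[var_col]).apply(pd.to_numeric, errors="coerce")
    numeric = numeric.dropna(axis=1, how="all")
    numeric.index = pd.Index(ids, name="variant_id")
    unparsed = []
    for vid in numeric.index:
        try:
            parse_residue(vid)
        except ValueError:
            unparsed.append(vid)
    return Sd1Table(data=numeric, unparsed=unparsed)
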