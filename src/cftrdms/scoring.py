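"""Per-variant plasma-membrane-expression (PME) scoring from sort-seq counts.

The estimator is the read-weighted average of FACS-quartile mean
fluorescences:

    <I>_variant = sum_k <F>_k * N_k / sum_k N_k      (k over the 4 quartiles)

where N_k is the variant's read count in quartile k after quality filtering
and depth equalisation, and <F>_k the mean surface fluorescence of cells in
that quartile. Scores are normalised by the read-weighted population mean of
the same experiment, scored twice from independent down-sampling draws, and
a variant measurement is rejected when the two draws disagree by more than
40% of their mean. Reported PME is the average of passing normalised scores
over iterations and replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

UMI_LENGTH = 10
_VALID = set("ACGT")

FRACTION_COLUMNS = ["frac1", "frac2", "frac3", "frac4"]


@dataclass
class FractionCountTable:
    """Variant x FACS-quartile read counts plus per-quartile mean fluorescence.

    ``counts`` is indexed by variant_id with integer columns frac1..frac4;
    ``fraction_means`` holds the linear-scale mean fluorescence of cells in
    each quartile, strictly increasing with quartile index.
    """

    counts: pd.DataFrame
    fraction_means: np.ndarray
    replicate_id: str = "rep1"
    cell_line: str = "parental"
    treatment: str = "vehicle"

    def __post_init__(self) -> None:
        self.fraction_means = np.asarray(self.fraction_means, dtype=float)
        if list(self.counts.columns) != FRACTION_COLUMNS:
            raise ValueError(f"counts must have columns {FRACTION_COLUMNS}")
        if self.fraction_means.shape != (4,):
            raise ValueError("fraction_means must have exactly 4 entries")
        if not np.all(np.diff(self.fraction_means) > 0):
            raise ValueError("fraction_means must be strictly increasing")
        if np.any(self.fraction_means <= 0):
            raise ValueError("fraction_means must be positive")
        arr = self.counts.to_numpy()
        if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    def fraction_totals(self) -> np.ndarray:
        return self.counts.to_numpy().sum(axis=0)


class UmiWhitelist:
    """Mapping from 10-base barcode to variant id; one barcode per variant."""

    def __init__(self, entries: Mapping[str, str]):
        self.entries = dict(entries)
        if len(self.entries) == 0:
            raise ValueError("whitelist is empty")
        for umi in self.entries:
            if len(umi) != UMI_LENGTH or not set(umi) <= _VALID:
                raise ValueError(f"invalid UMI {umi!r}")
        if len(set(self.entries.values())) != len(self.entries):
            raise ValueError("variant ids must be unique (one UMI per variant)")

    def __len__(self) -> int:
        return len(self.entries)


def expected_errors(phred: Iterable[int]) -> float:
    """Sum of per-base error probabilities 10^(-Q/10)."""
    q = np.asarray(list(phred), dtype=float)
    return float(np.sum(10.0 ** (-q / 10.0)))


def filter_reads(records, max_expected_errors: float = 1.0,
                 umi_start: int = 0, umi_length: int = UMI_LENGTH) -> list:
    """Drop reads whose expected error count over the UMI bases exceeds the cap.

    ``records`` are Biopython ``SeqRecord`` objects with Phred+33 qualities
    (as produced by ``SeqIO.parse(..., "fastq")``). Order is preserved.
    """
    kept = []
    for i, rec in enumerate(records):
        quals = rec.letter_annotations.get("phred_quality")
        if quals is None or len(rec.seq) < umi_start + umi_length:
            raise ValueError(f"malformed FASTQ record at index {i}")
        if expected_errors(quals[umi_start : umi_start + umi_length]) <= max_expected_errors:
            kept.append(rec)
    return kept


def count_umis(reads, whitelist: UmiWhitelist,
               umi_start: int = 0) -> tuple[pd.Series, int]:
    """Exact-match UMI counting.

    ``reads`` may be SeqRecords or plain sequence strings; the UMI is the
    10-base substring at ``umi_start``. Returns (per-variant counts, number
    of unmatched reads); matched + unmatched equals the number of reads.
    """
    counts: dict[str, int] = {v: 0 for v in whitelist.entries.values()}
    unmatched = 0
    for rec in reads:
        seq = str(rec.seq) if hasattr(rec, "seq") else str(rec)
        variant = whitelist.entries.get(seq[umi_start : umi_start + UMI_LENGTH])
        if variant is None:
            unmatched += 1
        else:
            counts[variant] += 1
    return pd.Series(counts, name="count"), unmatched


def downsample_counts(table: FractionCountTable, seed: int) -> FractionCountTable:
    """Equalise sequencing depth across the four fractions.

    Reads within each fraction are sampled without replacement (multivariate
    hypergeometric over variants) down to the minimum fraction total; a
    fraction already at the minimum is returned unchanged.
    """
    totals = table.fraction_totals()
    if np.any(totals == 0):
        raise ValueError("cannot equalize: a fraction has zero total reads")
    t_min = int(totals.min())
    rng = np.random.default_rng(seed)
    new = table.counts.to_numpy().copy()
    for k in range(4):
        if totals[k] > t_min:
            new[:, k] = rng.multivariate_hypergeometric(new[:, k], t_min)
    return FractionCountTable(
        counts=pd.DataFrame(new, index=table.counts.index, columns=FRACTION_COLUMNS),
        fraction_means=table.fraction_means,
        replicate_id=table.replicate_id,
        cell_line=table.cell_line,
        treatment=table.treatment,
    )


def weighted_average_intensity(table: FractionCountTable) -> pd.Series:
    """Raw weighted-average fluorescence <I> per variant.

    Variants with zero total reads are unscored (NaN), never zero.
    """
    n = table.counts.to_numpy(dtype=float)
    tot = n.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = (n @ table.fraction_means) / tot
    raw[tot == 0] = np.nan
    return pd.Series(raw, index=table.counts.index, name="raw_intensity")


def population_mean(table: FractionCountTable) -> float:
    """Read-weighted mean fluorescence of the whole pool for one experiment."""
    totals = table.fraction_totals().astype(float)
    m = float((table.fraction_means * totals).sum() / totals.sum())
    if m <= 0:
        raise ValueError("population mean must be positive")
    return m


def normalize_intensities(raw: pd.Series, table: FractionCountTable) -> pd.Series:
    """Scores in population-mean units: raw / read-weighted pool mean."""
    return (raw / population_mean(table)).rename("normalized_intensity")


def variation_filter(score_iter1: pd.Series, score_iter2: pd.Series,
                     threshold: float = 0.40) -> pd.DataFrame:
    """QC across the two independent down-sampling iterations.

    variation v = |I1 - I2| / ((I1 + I2) / 2); a measurement is rejected only
    when v exceeds the threshold strictly (the 40% boundary passes). Both
    scores zero, or either missing, yields an unscored (failed) flag rather
    than a division error. The aggregated score of a passing measurement is
    the mean of the two iterations.
    """
    i1, i2 = score_iter1.align(score_iter2)
    mean = (i1 + i2) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        v = (i1 - i2).abs() / mean
    scored = mean.notna() & (mean != 0)
    passes = scored & (v <= threshold)
    return pd.DataFrame(
        {
            "iter1": i1,
            "iter2": i2,
            "variation": v,
            "qc_pass": passes,
            "score": mean.where(passes),
        }
    )


def score_replicate(table: FractionCountTable, seed: int,
                    variation_threshold: float = 0.40) -> pd.DataFrame:
    """Score one replicate: two down-sampling iterations, normalise, QC.

    The two iterations use documented sub-seeds spawned from ``seed``.
    Returns the variation_filter frame plus the table's condition labels.
    """
    ss = np.random.SeedSequence(seed)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    iters = []
    for s in sub:
        ds = downsample_counts(table, seed=s)
        raw = weighted_average_intensity(ds)
        iters.append(normalize_intensities(raw, ds))
    out = variation_filter(iters[0], iters[1], threshold=variation_threshold)
    out["replicate_id"] = table.replicate_id
    out["cell_line"] = table.cell_line
    out["treatment"] = table.treatment
    return out


def aggregate_pme(replicate_scores: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Average passing normalised scores over iterations x replicates.

    Each passing replicate measurement contributes its two iteration scores
    with equal weight. Variants with no passing measurement are reported as
    missing (NaN pme, qc_pass False), never as zero.
    """
    frames = list(replicate_scores)
    if not frames:
        raise ValueError("no replicate scores given")
    pieces = []
    for df in frames:
        ok = df[df["qc_pass"]]
        long = pd.concat(
            [ok["iter1"], ok["iter2"]], axis=0
        ).rename("score")
        pieces.append(long)
    allscores = pd.concat(pieces, axis=0) if pieces else pd.Series(dtype=float)
    grouped = allscores.groupby(level=0)
    pme = grouped.mean()
    n = grouped.size()
    all_variants = frames[0].index
    for df in frames[1:]:
        all_variants = all_variants.union(df.index)
    out = pd.DataFrame(index=all_variants.rename("variant_id"))
    out["pme"] = pme.reindex(all_variants)
    out["n_contributing"] = n.reindex(all_variants).fillna(0).astype(int)
    out["qc_pass"] = out["n_contributing"] > 0
    return out
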