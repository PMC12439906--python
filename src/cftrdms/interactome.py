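"""AP-MS interactome statistics: normalization, mock comparison, curved filter.

The interactor-calling chain for multiplexed (TMT) co-immunoprecipitation
runs against a mock (GFP) pull-down:

1. within-run normalization — channel medians equalised, then bait (CFTR)
   channels rescaled so the bait abundance is equal within each run;
2. per-run log2 fold change over the run-matched mock mean, averaged into a
   consensus value per protein, with a paired two-tailed t test across runs;
3. the background fold-change histogram is fit to a Gaussian by nonlinear
   least squares to estimate its spread sigma;
4. a reciprocal "curved" filter calls interactors beyond a 2*sigma fold
   change cutoff x0 when the significance clears c / (x - x0), curvature
   c = 0.8 by default;
5. per-condition pass sets are pooled into a master interactor list;
6. knockout-vs-parental changes are summarised as differences of log2
   grouped abundances and tested per pathway class (one-sample t, Wilcoxon
   signed-rank, repeated-measures ANOVA with Greenhouse-Geisser correction
   and Tukey post hoc comparisons).

Normalization targets are fixed constants (channel median -> 1; bait -> the
run's typical bait/median ratio), which makes the map exactly idempotent and
exactly invariant to per-channel loading factors; every downstream statistic
is a log-ratio, so the arbitrary overall unit cancels.

The filter's printed form ``y > c/(x - x0)`` with y "the p-value" would
select the *least* significant proteins if taken literally; the default
implements the standard curved-volcano convention y = -log10(p), and
``literal_p=True`` applies the inequality to the raw p-value instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

MOCK = "MOCK"
BAIT_PROTEIN = "CFTR"

PATHWAY_CLASSES = ("translation", "folding", "trafficking", "proteasome", "autophagy", "other")


class SigmaFitError(RuntimeError):
    """Gaussian histogram fit failed; carries a robust fallback estimate."""

    def __init__(self, message: str, robust_sd: float):
        super().__init__(message)
        self.robust_sd = robust_sd


def _check_design(design: pd.DataFrame) -> None:
    required = {"channel", "run", "bait", "cell_line", "treatment", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    for run, grp in design.groupby("run"):
        if grp["channel"].duplicated().any():
            raise ValueError(f"duplicate channel ids in run {run}")


def normalize_abundances(
    matrix: pd.DataFrame, design: pd.DataFrame, bait_protein: str = BAIT_PROTEIN
) -> pd.DataFrame:
    """Median normalization followed by within-run bait normalization.

    Mock channels are scaled so their median protein abundance is 1; bait
    channels are scaled so the bait protein is equal across the run's bait
    channels, anchored at the run's geometric-mean bait/median ratio so a
    typical bait channel is scaled exactly like a mock channel.
    """
    _check_design(design)
    out = matrix.astype(float).copy()
    for run, grp in design.groupby("run"):
        bait_channels = grp.loc[grp["bait"] != MOCK, "channel"].tolist()
        ratios = {}
        for ch in grp["channel"]:
            med = out[ch].median(skipna=True)
            if not np.isfinite(med) or med <= 0:
                raise ValueError(f"channel {ch} has non-positive median")
            if ch in bait_channels:
                bait_val = out.at[bait_protein, ch] if bait_protein in out.index else np.nan
                if not np.isfinite(bait_val) or bait_val <= 0:
                    raise ValueError(f"bait {bait_protein} missing in bait channel {ch}")
                ratios[ch] = (bait_val, med)
            else:
                out[ch] = out[ch] / med
        if bait_channels:
            g = float(np.exp(np.mean([np.log(b / m) for b, m in ratios.values()])))
            for ch in bait_channels:
                bait_val, _ = ratios[ch]
                out[ch] = out[ch] * (g / bait_val)
    return out


def log2fc_vs_mock(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    bait: str | None = None,
    cell_line: str | None = None,
    treatment: str | None = None,
    min_runs: int = 2,
) -> pd.DataFrame:
    """Consensus log2 fold change over mock with a paired two-tailed t test.

    For each protein and each run holding both the selected bait channels and
    mock channels, the run's fold change is the difference of mean log2
    abundances (bait minus run-matched mock). The consensus is the mean over
    runs; the p-value is a paired t test of the per-run bait and mock log2
    means. Zero-variance differences give an undefined p, reported NaN and
    treated as non-significant downstream. Proteins observed in fewer than
    ``min_runs`` qualifying runs are flagged undefined.
    """
    _check_design(design)
    sel = design["bait"] != MOCK
    if bait is not None:
        sel &= design["bait"] == bait
    if cell_line is not None:
        sel &= design["cell_line"] == cell_line
    if treatment is not None:
        sel &= design["treatment"] == treatment
    bait_by_run = design[sel].groupby("run")["channel"].apply(list)
    mock_sel = design["bait"] == MOCK
    if cell_line is not None:
        mock_sel &= design["cell_line"] == cell_line
    mock_by_run = design[mock_sel].groupby("run")["channel"].apply(list)
    runs = [r for r in bait_by_run.index if r in mock_by_run.index]
    if not runs:
        raise ValueError("no run contains both bait and mock channels for the selection")

    logm = np.log2(matrix.where(matrix > 0))
    lb_runs = pd.DataFrame({r: logm[bait_by_run[r]].mean(axis=1) for r in runs})
    lm_runs = pd.DataFrame({r: logm[mock_by_run[r]].mean(axis=1) for r in runs})
    both = lb_runs.notna() & lm_runs.notna()
    n_runs = both.sum(axis=1)
    fc = (lb_runs - lm_runs).where(both)
    mean_fc = fc.mean(axis=1)

    pvals = np.full(len(matrix.index), np.nan)
    for i, prot in enumerate(matrix.index):
        mask = both.loc[prot].to_numpy()
        if mask.sum() >= max(min_runs, 2):
            b = lb_runs.loc[prot].to_numpy(float)[mask]
            m = lm_runs.loc[prot].to_numpy(float)[mask]
            if np.ptp(b - m) > 0:
                pvals[i] = stats.ttest_rel(b, m).pvalue
    out = pd.DataFrame(
        {
            "mean_log2fc": mean_fc.where(n_runs >= min_runs),
            "p_value": pvals,
            "n_runs": n_runs,
        },
        index=matrix.index,
    )
    out["defined"] = out["mean_log2fc"].notna()
    return out


@dataclass
class SigmaFit:
    sigma: float
    mu: float
    amplitude: float
    n_bins: int
    robust_sd: float


def estimate_sigma(values, min_values: int = 50) -> SigmaFit:
    """Spread of the background log2-fold-change distribution.

    The histogram (Freedman-Diaconis binning) is fit to a Gaussian
    A*exp(-(x-mu)^2 / (2 sigma^2)) by nonlinear least squares. Initial
    parameters come from robust statistics (median, 1.4826*MAD, tallest
    bin). Fitting the *peak* rather than the raw SD keeps heavy enrichment
    tails from inflating the estimate.
    """
    v = np.asarray(pd.Series(values).dropna(), float)
    if len(v) < min_values:
        raise ValueError(f"need at least {min_values} values, got {len(v)}")
    robust = float(stats.median_abs_deviation(v, scale="normal"))
    counts, edges = np.histogram(v, bins="fd")
    centers = (edges[:-1] + edges[1:]) / 2.0

    def gauss(x, a, mu, sig):
        return a * np.exp(-((x - mu) ** 2) / (2.0 * sig**2))

    p0 = (float(counts.max()), float(np.median(v)), robust if robust > 0 else np.std(v))
    try:
        popt, _ = curve_fit(gauss, centers, counts, p0=p0, maxfev=10_000)
    except RuntimeError as exc:
        raise SigmaFitError(f"Gaussian histogram fit did not converge: {exc}", robust) from exc
    sigma = abs(float(popt[2]))
    if sigma <= 0 or not np.isfinite(sigma):
        raise SigmaFitError("Gaussian histogram fit returned a degenerate sigma", robust)
    return SigmaFit(sigma=sigma, mu=float(popt[1]), amplitude=float(popt[0]),
                    n_bins=len(counts), robust_sd=robust)


def curved_filter(
    calls: pd.DataFrame,
    sigma: float,
    c: float = 0.8,
    sigma_multiplier: float = 2.0,
    literal_p: bool = False,
) -> pd.DataFrame:
    """Reciprocal-curve interactor filter.

    A protein with consensus fold change x and p-value p passes iff
    x > x0 = ``sigma_multiplier * sigma`` and, by default,
    -log10(p) > c / (x - x0). ``literal_p=True`` instead applies
    p > c / (x - x0) as printed in the source convention some tools use.
    Proteins at or below x0, or with undefined p, never pass.
    """
    if sigma <= 0 or c <= 0:
        raise ValueError("sigma and c must be positive")
    x0 = sigma_multiplier * sigma
    x = calls["mean_log2fc"]
    p = calls["p_value"]
    beyond = x > x0
    with np.errstate(divide="ignore", invalid="ignore"):
        bar = c / (x - x0)
        score = np.log10(p) * -1.0 if not literal_p else p
    passes = beyond & p.notna() & (score > bar)
    out = calls.copy()
    out["passes"] = passes.fillna(False)
    out["sigma_used"] = sigma
    out["x0_used"] = x0
    out["c_used"] = c
    return out


def master_interactor_list(pass_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Pool per-condition pass sets into a master list with provenance."""
    if not pass_sets:
        raise ValueError("need at least one condition")
    rows: dict[str, list[str]] = {}
    for cond, prots in pass_sets.items():
        for p in prots:
            rows.setdefault(p, []).append(cond)
    out = pd.DataFrame(
        {
            "protein_id": sorted(rows),
            "conditions": [",".join(sorted(rows[p])) for p in sorted(rows)],
            "n_conditions": [len(rows[p]) for p in sorted(rows)],
        }
    )
    return out.set_index("protein_id")


def grouped_delta(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    master_list,
    bait: str | None = None,
    treatment: str | None = None,
    ko_line: str = "CANX_KO",
    parental_line: str = "parental",
) -> pd.DataFrame:
    """Change of log2 grouped abundance, knockout minus parental.

    The grouped abundance of a protein in a cell line is the mean of its
    log2-transformed (normalized) abundances over that line's bait channels.
    Proteins missing from either line are flagged undefined.
    """
    _check_design(design)
    sel = design["bait"] != MOCK
    if bait is not None:
        sel &= design["bait"] == bait
    if treatment is not None:
        sel &= design["treatment"] == treatment
    ko_ch = design.loc[sel & (design["cell_line"] == ko_line), "channel"].tolist()
    par_ch = design.loc[sel & (design["cell_line"] == parental_line), "channel"].tolist()
    if not ko_ch or not par_ch:
        raise ValueError("need bait channels in both cell lines")
    prots = [p for p in master_list if p in matrix.index]
    logm = np.log2(matrix.loc[prots].where(matrix.loc[prots] > 0))
    ko = logm[ko_ch].mean(axis=1)
    par = logm[par_ch].mean(axis=1)
    out = pd.DataFrame(
        {
            "log2_grouped_ko": ko,
            "log2_grouped_parental": par,
            "delta_log2": ko - par,
            "n_ko": logm[ko_ch].notna().sum(axis=1),
            "n_parental": logm[par_ch].notna().sum(axis=1),
        }
    )
    out["defined"] = out["delta_log2"].notna()
    return out


def pathway_zero_tests(deltas: pd.Series, pathways: pd.Series,
                       min_per_class: int = 3) -> pd.DataFrame:
    """Per pathway class: is the KO-vs-parental delta centred at zero?

    Two-sided one-sample t test and Wilcoxon signed-rank test against zero.
    Classes with fewer than ``min_per_class`` proteins, or an undefined
    Wilcoxon (all deltas zero), report NaN for the affected statistic.
    """
    d, cls = deltas.align(pathways)
    rows = []
    for name, grp in d.groupby(cls):
        vals = grp.dropna().to_numpy(float)
        t_p = w_p = np.nan
        if len(vals) >= min_per_class:
            if np.ptp(vals) > 0 or vals[0] != 0:
                t_p = float(stats.ttest_1samp(vals, 0.0).pvalue)
            if np.any(vals != 0):
                try:
                    w_p = float(stats.wilcoxon(vals).pvalue)
                except ValueError:
                    w_p = np.nan
        rows.append((name, len(vals), float(np.mean(vals)) if len(vals) else np.nan, t_p, w_p))
    return pd.DataFrame(
        rows, columns=["pathway", "n", "mean_delta", "t_p", "wilcoxon_p"]
    ).set_index("pathway")


def rm_anova_gg(long: pd.DataFrame, dv: str = "delta_log2",
                within: str = "condition", subject: str = "protein_id") -> dict:
    """Repeated-measures one-way ANOVA with Greenhouse-Geisser correction,
    plus Tukey HSD post hoc pairwise comparisons.

    ``long`` holds one row per subject x condition. Returns the F statistic,
    uncorrected and epsilon-corrected p-values, the Greenhouse-Geisser
    epsilon (1 by construction for two conditions), and the Tukey table.
    """
    import pingouin as pg
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    k = long[within].nunique()
    if k < 2:
        raise ValueError("need at least 2 conditions")
    complete = long.pivot(index=subject, columns=within, values=dv).dropna()
    if len(complete) < 2:
        raise ValueError("need at least 2 complete subjects")
    tidy = complete.reset_index().melt(id_vars=subject, var_name=within, value_name=dv)
    aov = pg.rm_anova(data=tidy, dv=dv, within=within, subject=subject,
                      correction=True, detailed=False)
    row = aov.iloc[0]
    eps = float(row["eps"]) if "eps" in aov.columns and np.isfinite(row.get("eps", np.nan)) else 1.0
    p_unc = float(row["p_unc"])
    gg_col = "p_GG_corr"
    p_gg = (
        float(row[gg_col])
        if gg_col in aov.columns and np.isfinite(row.get(gg_col, np.nan))
        else p_unc
    )
    tukey = pairwise_tukeyhsd(tidy[dv].to_numpy(float), tidy[within].to_numpy(str))
    tukey_df = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
    return {
        "F": float(row["F"]),
        "p_uncorrected": p_unc,
        "p_gg": p_gg,
        "epsilon": eps,
        "n_subjects": int(len(complete)),
        "tukey": tukey_df,
    }
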