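"""Comparative variant metrics: knockout deltas, corrector responses, domain tests.

Quantities derived from PME profiles measured under different cell lines and
treatments:

* ``delta_pme`` — PME(KO) - PME(parental) under vehicle; negative means the
  variant depends on calnexin for surface expression.
* ``corrector_response_ratio`` — PME(drug) / PME(vehicle) within a cell line.
* ``delta_response`` — KO ratio minus parental ratio; negative means the
  corrector works less well without calnexin.
* ``domain_compare`` — Mann-Whitney U between structural domains.
* ``fit_library_trend`` — ordinary least squares + Pearson R^2 over the
  variant library (e.g. KO intensities against parental).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .variants import DomainMap


def delta_pme(ko: pd.Series, parental: pd.Series) -> pd.Series:
    """Per-variant PME difference, KO - parental; missing propagates."""
    k, p = ko.align(parental)
    return (k - p).rename("delta_pme")


def corrector_response_ratio(pme_drug, pme_vehicle, floor: float = 0.0):
    """Fold change in PME under drug; undefined when the vehicle score is
    below ``floor`` (near-zero denominators give meaningless ratios).

    Scalar or aligned Series inputs; undefined entries are NaN.
    """
    drug = pd.Series(pme_drug) if not isinstance(pme_drug, pd.Series) else pme_drug
    veh = pd.Series(pme_vehicle) if not isinstance(pme_vehicle, pd.Series) else pme_vehicle
    drug, veh = drug.align(veh)
    if (drug.dropna() < 0).any() or (veh.dropna() < 0).any():
        raise ValueError("PME scores must be non-negative")
    ratio = drug / veh
    ratio = ratio.where(veh >= floor)
    ratio = ratio.where(veh > 0)  # floor=0 still cannot divide by exactly zero
    out = ratio.rename("response_ratio")
    if np.isscalar(pme_drug):
        return float(out.iloc[0]) if out.notna().iloc[0] else float("nan")
    return out


def delta_response(ko_ratio, parental_ratio):
    """KO response ratio minus parental; undefined inputs propagate NaN."""
    if np.isscalar(ko_ratio):
        return ko_ratio - parental_ratio
    k, p = ko_ratio.align(parental_ratio)
    return (k - p).rename("delta_response")


def build_response_table(
    pme: dict[tuple[str, str], pd.Series], drug: str, floor: float = 0.0
) -> pd.DataFrame:
    """Assemble the per-variant response table for one corrector.

    ``pme`` maps (cell_line, treatment) -> PME Series; required keys are the
    vehicle and ``drug`` entries for 'parental' and 'CANX_KO'.
    """
    pv = pme[("parental", "vehicle")]
    pd_ = pme[("parental", drug)]
    kv = pme[("CANX_KO", "vehicle")]
    kd = pme[("CANX_KO", drug)]
    out = pd.DataFrame(index=pv.index.union(kv.index).rename("variant_id"))
    out["pme_parental_vehicle"] = pv
    out["pme_ko_vehicle"] = kv
    out["delta_pme"] = delta_pme(kv, pv)
    out["ratio_parental"] = corrector_response_ratio(pd_, pv, floor=floor)
    out["ratio_ko"] = corrector_response_ratio(kd, kv, floor=floor)
    out["delta_response"] = delta_response(out["ratio_ko"], out["ratio_parental"])
    out["defined"] = out["delta_response"].notna()
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney U

_EXACT_LIMIT = 20  # pooled size up to which the exact enumeration runs


def mann_whitney_exact(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by full enumeration (handles ties).

    Enumerates every assignment of the pooled values to the two groups and
    computes p = Pr(|U - n_a n_b / 2| >= |u_obs - n_a n_b / 2|). Identical
    samples give p = 1.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n_a, n_b = len(a), len(b)
    ranks = stats.rankdata(np.concatenate([a, b]))
    const = n_a * (n_a + 1) / 2.0
    u_obs = float(ranks[:n_a].sum() - const)
    mu = n_a * n_b / 2.0
    dev = abs(u_obs - mu)
    rlist = ranks.tolist()
    hits = 0
    total = 0
    for idx in itertools.combinations(range(n_a + n_b), n_a):
        u = sum(rlist[i] for i in idx) - const
        if abs(u - mu) >= dev - 1e-12:
            hits += 1
        total += 1
    return u_obs, hits / total


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U with two-sided p.

    Exact enumeration for small pooled samples; tie-corrected normal
    approximation (scipy, with continuity correction) otherwise.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if len(a) + len(b) <= _EXACT_LIMIT:
        return mann_whitney_exact(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


@dataclass
class DomainTestResult:
    domain_a: str
    domain_b: str
    n_a: int
    n_b: int
    u: float
    p: float
    unassigned: list[str]


def domain_compare(values: pd.Series, domain_map: DomainMap,
                   domain_a: str, domain_b: str) -> DomainTestResult:
    """Mann-Whitney U between the values of two structural domains.

    Variants are assigned by the residue number parsed from their id;
    unparseable or out-of-map variants are excluded and reported.
    """
    groups: dict[str, list[float]] = {domain_a: [], domain_b: []}
    unassigned: list[str] = []
    for vid, val in values.dropna().items():
        dom = domain_map.assign(str(vid))
        if dom in groups:
            groups[dom].append(float(val))
        elif dom is None:
            unassigned.append(str(vid))
    a, b = groups[domain_a], groups[domain_b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per domain")
    u, p = mann_whitney(a, b)
    return DomainTestResult(domain_a, domain_b, len(a), len(b), u, p, unassigned)


@dataclass
class TrendFit:
    slope: float
    intercept: float
    pearson_r2: float
    n_used: int
    n_dropped: int


def fit_library_trend(x: pd.Series, y: pd.Series) -> TrendFit:
    """OLS fit of y on x over the variant library, with Pearson R^2.

    Pairs with any missing value are dropped (and counted).
    """
    xs, ys = x.align(y)
    ok = xs.notna() & ys.notna()
    n_dropped = int((~ok).sum())
    xv = xs[ok].to_numpy(float)
    yv = ys[ok].to_numpy(float)
    if len(xv) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(xv) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(xv, yv)
    return TrendFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r2=float(res.rvalue) ** 2,
        n_used=len(xv),
        n_dropped=n_dropped,
    )
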