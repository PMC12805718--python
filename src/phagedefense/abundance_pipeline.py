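"""Microbiome rank-abundance stratification and investment comparisons.

Species observed in a panel of metagenome samples are ranked within each
sample by relative abundance (larger rank = more abundant).  A species is
*high-abundant* when the first quartile of its rank distribution across the
samples containing it lies above an integer threshold ``T_a``, and
*low-abundant* when the third quartile lies below ``T_a``; species whose
rank distribution straddles the threshold are discarded as intermediate.
``T_a`` is chosen to maximise the size of the smaller of the two groups
among species with available genomes.  Group contrasts of genomic
investment use the two-sided Mann-Whitney test, and deviations of per-system
investment from the genome-size expectation use Wilcoxon signed-rank tests
on residuals of a log-log regression fitted to the full species reference
set, reported as signed log10 p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpeciesRankStats",
    "DeviationResult",
    "rank_abundance_stats",
    "classify_abundance",
    "choose_threshold",
    "compare_groups",
    "genome_size_deviation",
    "quadrant_label",
]

MIN_SAMPLES = 100


@dataclass
class SpeciesRankStats:
    species_id: str
    n_present: int
    q1: float
    q3: float
    cls: str = "unclassified"  # high | low | intermediate | excluded


@dataclass
class DeviationResult:
    system_id: str
    slp_high: float  # signed log10 p of the high-abundant group's deviation
    slp_low: float
    n_high: int
    n_low: int
    quadrant: str
    low_power: bool = False


def rank_abundance_stats(
    table: pd.DataFrame,
    min_samples: int = MIN_SAMPLES,
) -> list[SpeciesRankStats]:
    """Per-species quartiles of within-sample abundance ranks.

    ``table`` is long format with columns ``sample_id, species_id,
    relative_abundance``.  Within each sample, present species (abundance
    > 0) receive average ranks with larger rank meaning more abundant.
    Ranks are collected only over samples in which the species occurs;
    species present in fewer than ``min_samples`` samples are excluded.
    """
    need = {"sample_id", "species_id", "relative_abundance"}
    if not need <= set(table.columns):
        raise ValueError(f"abundance table needs columns {sorted(need)}")
    tab = table[table["relative_abundance"] > 0].copy()
    empty = set(table["sample_id"].unique()) - set(tab["sample_id"].unique())
    if empty:
        warnings.warn(f"{len(empty)} empty samples skipped", stacklevel=2)
    tab["rank"] = tab.groupby("sample_id")["relative_abundance"].rank(
        method="average", ascending=True)
    out = []
    for sp, grp in tab.groupby("species_id", sort=True):
        n = len(grp)
        if n < min_samples:
            out.append(SpeciesRankStats(str(sp), n, np.nan, np.nan, "excluded"))
            continue
        q1, q3 = np.percentile(grp["rank"], [25, 75])
        out.append(SpeciesRankStats(str(sp), n, float(q1), float(q3)))
    return out


def classify_abundance(
    stats_list: Sequence[SpeciesRankStats], T_a: int
) -> list[SpeciesRankStats]:
    """Label species as high/low/intermediate at rank threshold ``T_a``.

    high iff q1 > T_a (reliably near the top of the community), low iff
    q3 < T_a, intermediate otherwise; excluded species stay excluded.
    """
    out = []
    for s in stats_list:
        if s.cls == "excluded":
            out.append(s)
            continue
        if s.q1 > T_a:
            cls = "high"
        elif s.q3 < T_a:
            cls = "low"
        else:
            cls = "intermediate"
        out.append(SpeciesRankStats(s.species_id, s.n_present, s.q1, s.q3, cls))
    return out


def choose_threshold(
    stats_list: Sequence[SpeciesRankStats],
    genomes_available: Iterable[str],
) -> int:
    """Rank threshold maximising the smaller classified group.

    Scans every integer threshold within the observed rank range and returns
    the ``T_a`` maximising ``min(|high ∩ genomes|, |low ∩ genomes|)``; ties
    break toward the smaller threshold.
    """
    genomes = set(genomes_available)
    usable = [s for s in stats_list if s.cls != "excluded"
              and s.species_id in genomes]
    if not usable:
        raise ValueError("no species with both rank statistics and genomes")
    lo = int(np.floor(min(s.q1 for s in usable)))
    hi = int(np.ceil(max(s.q3 for s in usable))) + 1
    best_T, best_score = None, -1
    for T in range(lo, hi + 1):
        n_high = sum(1 for s in usable if s.q1 > T)
        n_low = sum(1 for s in usable if s.q3 < T)
        score = min(n_high, n_low)
        if score > best_score:
            best_T, best_score = T, score
    if best_score <= 0:
        raise ValueError("every candidate threshold leaves an empty group")
    return int(best_T)


def compare_groups(
    high_values: Sequence[float],
    low_values: Sequence[float],
) -> tuple[float, int]:
    """Two-sided Mann-Whitney comparison of an investment metric.

    Returns ``(p, direction)`` where direction is the sign of the median
    difference (high minus low).  Groups smaller than 3 yield a warning and
    an unreliable p.
    """
    hv = np.asarray(high_values, dtype=float)
    lv = np.asarray(low_values, dtype=float)
    if len(hv) == 0 or len(lv) == 0:
        raise ValueError("both groups must be non-empty")
    if min(len(hv), len(lv)) < 3:
        warnings.warn("group smaller than 3: p-value unreliable", stacklevel=2)
    stat = stats.mannwhitneyu(hv, lv, alternative="two-sided")
    direction = int(np.sign(np.median(hv) - np.median(lv)))
    return float(stat.pvalue), direction


def quadrant_label(slp_high: float, slp_low: float) -> str:
    """Quadrant name from the signs of the two signed log p-values.

    The first word reports the low-abundant group's deviation, the second
    the high-abundant group's: e.g. a system overinvested in high-abundant
    but underinvested in low-abundant species is ``low-high``.
    """
    w_low = "high" if slp_low > 0 else "low"
    w_high = "high" if slp_high > 0 else "low"
    return f"{w_low}-{w_high}"


def _signed_log10_p(residuals: np.ndarray) -> float:
    """Wilcoxon signed-rank deviation of residuals from zero, as
    -log10(p) * sign(median residual)."""
    res = np.asarray(residuals, dtype=float)
    res = res[res != 0] if np.any(res != 0) else res
    if len(res) == 0 or np.all(res == 0):
        return 0.0
    p = float(stats.wilcoxon(res).pvalue)
    p = max(p, 1e-300)
    return float(-np.log10(p) * np.sign(np.median(res)))


def genome_size_deviation(
    reference: pd.DataFrame,
    high_ids: Iterable[str],
    low_ids: Iterable[str],
    system_id: str = "",
    nt_col: str = "total_nt",
) -> DeviationResult:
    """Deviation of one system's investment from the genome-size expectation.

    ``reference`` has one row per species with columns ``species_id,
    genome_length`` and ``nt_col`` (total nucleotides of the system in that
    species).  The expectation model ``log(nt + 1) ~ log(genome_length)`` is
    fitted by least squares on the full reference set; each group's
    residuals are then tested against zero by the Wilcoxon signed-rank test
    and summarised as a signed log10 p-value.  The quadrant combines the
    low- and high-abundant group signs.
    """
    need = {"species_id", "genome_length", nt_col}
    if not need <= set(reference.columns):
        raise ValueError(f"reference table needs columns {sorted(need)}")
    x = np.log(reference["genome_length"].to_numpy(dtype=float))
    y = np.log1p(reference[nt_col].to_numpy(dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = pd.Series(y - (intercept + slope * x),
                      index=reference["species_id"].astype(str))
    high_ids = [str(s) for s in high_ids if str(s) in resid.index]
    low_ids = [str(s) for s in low_ids if str(s) in resid.index]
    slp_h = _signed_log10_p(resid.loc[high_ids].to_numpy()) if high_ids else 0.0
    slp_l = _signed_log10_p(resid.loc[low_ids].to_numpy()) if low_ids else 0.0
    return DeviationResult(
        system_id=system_id, slp_high=slp_h, slp_low=slp_l,
        n_high=len(high_ids), n_low=len(low_ids),
        quadrant=quadrant_label(slp_h, slp_l),
        low_power=min(len(high_ids), len(low_ids)) < 5)
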