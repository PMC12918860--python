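"""Telomere-based division estimates, mutation-rate normalizations and the
cohort statistics (one-sided Spearman age correlations, Wilcoxon rank-sum
group comparisons)."""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

EXACT_SPEARMAN_MAX_N = 8
EXACT_RANKSUM_MAX_N = 12


@dataclass(frozen=True)
class TelomereParams:
    """Constants of the telomere-loss division clock.

    newborn TRF ~11 kb; +1 kb for non-telomeric DNA retained in TRF assays;
    +2 kb for the ~20 culture generations; 100 bp lost per division; diploid
    genome 6e9 nt.
    """

    newborn_trf_kb: float = 11.0
    trf_offset_kb: float = 1.0
    culture_addback_kb: float = 2.0
    loss_per_division_bp: float = 100.0
    genome_nt: float = 6e9

    def __post_init__(self):
        for name in ("newborn_trf_kb", "trf_offset_kb", "culture_addback_kb",
                     "loss_per_division_bp", "genome_nt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def estimate_divisions(telomere_kb: float,
                       params: TelomereParams = TelomereParams()) -> float:
    """Cell divisions since birth implied by measured telomere length (kb).

    progenitor = telomere + trf_offset + culture_addback; loss = newborn TRF
    minus progenitor; divisions = 1000 * loss_kb / loss_per_division_bp,
    clamped at 0 (with a warning) when the progenitor exceeds the newborn TRF.
    """
    if telomere_kb <= 0:
        raise ValueError("telomere_kb must be positive")
    progenitor = telomere_kb + params.trf_offset_kb + params.culture_addback_kb
    loss_kb = params.newborn_trf_kb - progenitor
    if loss_kb < 0:
        log.warning(
            "progenitor telomere %.2f kb exceeds newborn TRF %.2f kb; "
            "clamping divisions to 0", progenitor, params.newborn_trf_kb)
        return 0.0
    return 1000.0 * loss_kb / params.loss_per_division_bp


def mutation_rates(total_mutations: float, divisions: float,
                   donor_age: float | None = None,
                   params: TelomereParams = TelomereParams()) -> Dict[str, float]:
    """Per-genome-per-division, per-nt-per-division and per-genome-per-year rates."""
    if divisions > 0:
        per_genome = total_mutations / divisions
        per_nt = per_genome / params.genome_nt
    else:
        per_genome = per_nt = math.nan
    per_year = (total_mutations / donor_age
                if donor_age is not None and donor_age > 0 else math.nan)
    return {
        "per_genome_per_division": per_genome,
        "per_nt_per_division": per_nt,
        "per_genome_per_year": per_year,
    }


def _spearman_exact(x: np.ndarray, y: np.ndarray, sided: str) -> Tuple[float, float]:
    """Exact permutation p for Spearman rho (all n! rank permutations)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    n = len(rx)
    rho_obs = float(np.mean(rx * ry))
    perms = np.array(list(itertools.permutations(range(n))))
    rhos = (rx[perms] * ry).mean(axis=1)
    eps = 1e-12
    if sided == "one":
        p = float(np.mean(rhos >= rho_obs - eps))
    else:
        p = float(np.mean(np.abs(rhos) >= abs(rho_obs) - eps))
    return rho_obs, p


def age_correlation(donor_values: Mapping[str, float],
                    ages: Mapping[str, float],
                    sided: str = "one") -> Tuple[float, float]:
    """Spearman rank correlation of a per-donor quantity with donor age.

    One-sided (positive association) by default, matching the convention that
    mutation loads are expected to increase with age.  Exact permutation p for
    n <= 8 donors, t-approximation above.  Returns (rho, p); rho is NaN for
    constant input.
    """
    donors = sorted(set(donor_values) & set(ages))
    if len(donors) < 4:
        raise ValueError(f"need >=4 donors with both values, got {len(donors)}")
    v = np.array([donor_values[d] for d in donors], dtype=float)
    a = np.array([ages[d] for d in donors], dtype=float)
    if np.all(v == v[0]) or np.all(a == a[0]):
        return math.nan, math.nan
    if len(donors) <= EXACT_SPEARMAN_MAX_N:
        return _spearman_exact(a, v, sided)
    rho, p_two = stats.spearmanr(a, v)
    if sided == "one":
        p = p_two / 2.0 if rho > 0 else 1.0 - p_two / 2.0
    else:
        p = p_two
    return float(rho), float(p)


def rank_sum_test(x: Sequence[float], y: Sequence[float],
                  sided: str = "two") -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p value.

    Exact for tie-free groups of <= 12 each, otherwise the normal
    approximation with tie correction.  Two singletons (or fully tied input,
    where the statistic is degenerate) return NaN / 1.0 respectively.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("groups must be non-empty")
    if len(x) == 1 and len(y) == 1:
        return math.nan
    alternative = "two-sided" if sided == "two" else "greater"
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.all(pooled == pooled[0]):
        return 1.0
    small = len(x) <= EXACT_RANKSUM_MAX_N and len(y) <= EXACT_RANKSUM_MAX_N
    method = "exact" if (small and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative=alternative, method=method)[1])


def group_compare(values_by_group: Mapping[str, Sequence[float]],
                  sided: str = "two") -> pd.DataFrame:
    """Pairwise rank-sum p values for >= 2 groups (one row per pair)."""
    groups = sorted(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for g1, g2 in itertools.combinations(groups, 2):
        rows.append({
            "group1": g1, "group2": g2,
            "n1": len(values_by_group[g1]), "n2": len(values_by_group[g2]),
            "p": rank_sum_test(values_by_group[g1], values_by_group[g2], sided),
        })
    return pd.DataFrame(rows)


def rates_table(samples: pd.DataFrame,
                params: TelomereParams = TelomereParams()) -> pd.DataFrame:
    """Per-sample division and rate estimates.

    ``samples`` needs columns sample_id, donor_id, telomere_kb, total_snvs,
    age; returns those plus divisions and the three rates.
    """
    required = {"sample_id", "donor_id", "telomere_kb", "total_snvs", "age"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)}")
    rows = []
    for r in samples.itertuples(index=False):
        divisions = estimate_divisions(float(r.telomere_kb), params)
        rates = mutation_rates(float(r.total_snvs), divisions, float(r.age), params)
        rows.append({
            "sample_id": r.sample_id, "donor_id": r.donor_id,
            "telomere_kb": r.telomere_kb, "total_snvs": r.total_snvs,
            "age": r.age, "divisions": divisions, **rates,
        })
    return pd.DataFrame(rows)
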