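"""Two-group comparison machinery.

Distributions are compared with the total variation distance (tvd) of
shared-bin histograms and a normalized mean distance (d/r, mean difference
over the 2.5%-trimmed pooled range).  Significance is assessed with a
trajectory-level permutation test: whole simulations are reassigned between
the groups, group sizes preserved; the observed statistics are ranked
against the permutation null and mapped to a verbal category at the
0.90 / 0.95 / 0.99 percentile thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDenominatorError, InputError

N_PERM_DEFAULT = 2000
CATEGORY_THRESHOLDS = ((0.99, "strong"), (0.95, "difference"), (0.90, "slight"))
CATEGORIES = ("none", "slight", "difference", "strong")
TRIM_FRACTION = 0.025
MIN_BINS = 10


@dataclass
class SampleDistribution:
    """Per-frame scalar values tagged with their source simulation."""

    values: np.ndarray
    sim_ids: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.sim_ids = np.asarray(self.sim_ids, dtype=object)
        if self.values.shape != self.sim_ids.shape:
            raise InputError("values and sim_ids must have equal length")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise InputError("non-finite values in sample distribution")

    @property
    def simulations(self) -> list:
        return list(pd.unique(self.sim_ids))


@dataclass
class GroupSplit:
    groupM_ids: list
    groupL_ids: list
    excluded_ids: list

    def __post_init__(self):
        m, l, e = map(set, (self.groupM_ids, self.groupL_ids, self.excluded_ids))
        if m & l or m & e or l & e:
            raise InputError("group memberships must be disjoint")


@dataclass
class ComparisonResult:
    observed_tvd: float
    observed_dr: float
    null_tvd: np.ndarray
    null_dr: np.ndarray
    pct_tvd: float
    pct_dr: float
    category: str
    descriptor: str = ""

    def report_row(self) -> dict:
        return {
            "descriptor": self.descriptor,
            "observed_tvd": self.observed_tvd,
            "observed_dr": self.observed_dr,
            "pct_tvd": self.pct_tvd,
            "pct_dr": self.pct_dr,
            "category": self.category,
        }


def _bin_edges(pooled: np.ndarray, binning: int | Sequence[float] | None) -> np.ndarray:
    """Shared equal-width bin edges over the pooled (untrimmed) range.

    Default bin count: Freedman-Diaconis on the pooled sample, floored at
    MIN_BINS (and capped at 1000 for sanity).
    """
    if binning is not None and not np.isscalar(binning):
        return np.asarray(binning, dtype=float)
    lo, hi = float(pooled.min()), float(pooled.max())
    if hi <= lo:
        hi = lo + 1.0  # all mass in one bin; distributions identical there
    if binning is None:
        q75, q25 = np.percentile(pooled, [75, 25])
        width = 2.0 * (q75 - q25) / pooled.size ** (1.0 / 3.0)
        n_bins = int(np.ceil((hi - lo) / width)) if width > 0 else MIN_BINS
        n_bins = min(max(n_bins, MIN_BINS), 1000)
    else:
        n_bins = int(binning)
    return np.linspace(lo, hi, n_bins + 1)


def total_variation_distance(
    sample1: Sequence[float],
    sample2: Sequence[float],
    binning: int | Sequence[float] | None = None,
) -> float:
    """tvd = 1/2 sum_i |p_i - q_i| of shared-bin normalized histograms.

    0 means perfect overlap, 1 means disjoint support.  Symmetric.
    """
    s1 = np.asarray(sample1, dtype=float)
    s2 = np.asarray(sample2, dtype=float)
    if s1.size == 0 or s2.size == 0:
        raise InputError("empty sample")
    edges = _bin_edges(np.concatenate([s1, s2]), binning)
    p, _ = np.histogram(s1, bins=edges)
    q, _ = np.histogram(s2, bins=edges)
    return 0.5 * float(np.abs(p / s1.size - q / s2.size).sum())


def trimmed_range(pooled: np.ndarray, trim: float = TRIM_FRACTION) -> float:
    lo, hi = np.quantile(pooled, [trim, 1.0 - trim])
    return float(hi - lo)


def normalized_mean_distance(
    sample1: Sequence[float],
    sample2: Sequence[float],
    trim: float = TRIM_FRACTION,
) -> float:
    """|mean1 - mean2| over the trimmed range of the combined samples."""
    s1 = np.asarray(sample1, dtype=float)
    s2 = np.asarray(sample2, dtype=float)
    if s1.size == 0 or s2.size == 0:
        raise InputError("empty sample")
    denom = trimmed_range(np.concatenate([s1, s2]), trim)
    if denom <= 0:
        raise DegenerateDenominatorError("trimmed pooled range is zero")
    return float(abs(s1.mean() - s2.mean()) / denom)


def categorize(pct: float) -> str:
    for threshold, name in CATEGORY_THRESHOLDS:
        if pct >= threshold:
            return name
    return "none"


class _SimStats:
    """Per-simulation histogram counts and value sums on shared bins.

    Lets each permutation's tvd and d/r be assembled in O(bins + n_sims)
    instead of rebinning all frames.
    """

    def __init__(self, dist_a: SampleDistribution, dist_b: SampleDistribution,
                 binning=None, trim: float = TRIM_FRACTION):
        sims_a, sims_b = dist_a.simulations, dist_b.simulations
        if len(sims_a) < 2 or len(sims_b) < 2:
            raise InputError("each group needs >= 2 simulations")
        if set(sims_a) & set(sims_b):
            raise InputError("a simulation appears in both groups")
        pooled = np.concatenate([dist_a.values, dist_b.values])
        self.edges = _bin_edges(pooled, binning)
        self.denom = trimmed_range(pooled, trim)
        if self.denom <= 0:
            raise DegenerateDenominatorError("trimmed pooled range is zero")
        self.sims = sims_a + sims_b
        self.n_a = len(sims_a)
        hists, sums, counts = [], [], []
        for dist in (dist_a, dist_b):
            for sim in (sims_a if dist is dist_a else sims_b):
                vals = dist.values[dist.sim_ids == sim]
                h, _ = np.histogram(vals, bins=self.edges)
                hists.append(h)
                sums.append(vals.sum())
                counts.append(vals.size)
        self.hists = np.array(hists, dtype=float)
        self.sums = np.array(sums, dtype=float)
        self.counts = np.array(counts, dtype=float)

    def stats(self, members_a: np.ndarray) -> tuple[float, float]:
        """(tvd, d/r) for the split defined by boolean membership of group A."""
        ha = self.hists[members_a].sum(axis=0)
        hb = self.hists[~members_a].sum(axis=0)
        na, nb = ha.sum(), hb.sum()
        tvd = 0.5 * float(np.abs(ha / na - hb / nb).sum())
        ma = self.sums[members_a].sum() / self.counts[members_a].sum()
        mb = self.sums[~members_a].sum() / self.counts[~members_a].sum()
        dr = abs(ma - mb) / self.denom
        return tvd, dr


def permutation_test(
    distributionA: SampleDistribution,
    distributionB: SampleDistribution,
    n_perm: int = N_PERM_DEFAULT,
    seed: int | None = None,
    binning: int | Sequence[float] | None = None,
    trim: float = TRIM_FRACTION,
) -> ComparisonResult:
    """Trajectory-level permutation test of tvd and d/r.

    The permutation unit is the whole simulation: every frame of a
    simulation moves together, and group sizes are preserved.  Percentiles
    count permutations with a *strictly* smaller statistic (ties count
    against significance).  The verbal category is driven by
    ``max(pct_tvd, pct_dr)``.
    """
    if seed is None:
        raise InputError("seed is required for the permutation test")
    stats = _SimStats(distributionA, distributionB, binning, trim)
    n_sims = len(stats.sims)
    members_obs = np.zeros(n_sims, dtype=bool)
    members_obs[: stats.n_a] = True
    obs_tvd, obs_dr = stats.stats(members_obs)

    rng = np.random.default_rng(seed)
    null_tvd = np.empty(n_perm)
    null_dr = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n_sims)
        members = np.zeros(n_sims, dtype=bool)
        members[perm[: stats.n_a]] = True
        null_tvd[i], null_dr[i] = stats.stats(members)

    pct_tvd = float(np.mean(null_tvd < obs_tvd))
    pct_dr = float(np.mean(null_dr < obs_dr))
    return ComparisonResult(
        observed_tvd=obs_tvd,
        observed_dr=obs_dr,
        null_tvd=null_tvd,
        null_dr=null_dr,
        pct_tvd=pct_tvd,
        pct_dr=pct_dr,
        category=categorize(max(pct_tvd, pct_dr)),
    )


def compare_descriptor(
    name: str,
    groupM_series: SampleDistribution,
    groupL_series: SampleDistribution,
    n_perm: int = N_PERM_DEFAULT,
    seed: int | None = None,
    binning: int | Sequence[float] | None = None,
) -> ComparisonResult:
    """Permutation comparison of one named descriptor; labelled result."""
    result = permutation_test(groupM_series, groupL_series, n_perm=n_perm,
                              seed=seed, binning=binning)
    result.descriptor = name
    return result


# ---------------------------------------------------------------------------
# Immunogenicity-based group split

NEVER_TOKENS = {"never", "", "na", "nan", "none"}
LYSIS_THRESHOLD_NEG_LOG10 = 6.94  # concentration 10^-6.94 M or less -> groupM


def _parse_immunogenicity(value) -> float | None:
    """-log10 molar lysis-50 concentration, or None for 'never'."""
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    if isinstance(value, str):
        token = value.strip().lower()
        if token in NEVER_TOKENS:
            return None
        try:
            return float(token)
        except ValueError:
            raise InputError(f"malformed immunogenicity value {value!r}") from None
    return float(value)


def split_groups(
    immunogenicity_table: pd.DataFrame | Mapping,
    threshold_neg_log10: float = LYSIS_THRESHOLD_NEG_LOG10,
    n_top: int | None = None,
) -> GroupSplit:
    """Assign peptides to the more/less immunogenic groups.

    groupL = every peptide that never induces 50% lysis.  groupM = peptides
    inducing 50% lysis at a concentration of 10**-threshold M or less
    (i.e. -log10 concentration >= threshold); with ``n_top`` the groupM rule
    is instead "the n most immunogenic peptides".  Everything else is
    excluded.
    """
    if isinstance(immunogenicity_table, pd.DataFrame):
        items = list(zip(immunogenicity_table["peptide_sequence"],
                         immunogenicity_table["lysis50_neg_log10_molar"]))
    else:
        items = list(immunogenicity_table.items())

    parsed = [(pid, _parse_immunogenicity(v)) for pid, v in items]
    group_l = [pid for pid, v in parsed if v is None]
    measurable = [(pid, v) for pid, v in parsed if v is not None]
    if n_top is not None:
        ranked = sorted(measurable, key=lambda t: -t[1])
        group_m = [pid for pid, _ in ranked[:n_top]]
    else:
        group_m = [pid for pid, v in measurable if v >= threshold_neg_log10]
    in_groups = set(group_l) | set(group_m)
    excluded = [pid for pid, _ in parsed if pid not in in_groups]
    return GroupSplit(groupM_ids=group_m, groupL_ids=group_l, excluded_ids=excluded)


def restrict_to_group(dist: SampleDistribution, member_ids: Sequence) -> SampleDistribution:
    """Subset of a distribution belonging to the given simulations."""
    mask = np.isin(dist.sim_ids, list(member_ids))
    return SampleDistribution(dist.values[mask], dist.sim_ids[mask])
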