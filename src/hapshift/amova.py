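"""Hierarchical analysis of molecular variance (year > site > individual).

The decomposition follows the classical molecular-variance framework:
sums of squares are computed from squared inter-individual distances
(here raw nucleotide difference counts, i.e. squared Euclidean distances
of a one-hot sequence embedding), partitioned into among-years,
among-sites-within-years and within-sites strata; variance components use
the standard expected-mean-square coefficients for unequal sample sizes,
and Phi statistics are ratios of those components.  Significance comes
from permutation tests with stratum-appropriate resampling schemes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._seq import hamming_matrix


@dataclass
class AmovaResult:
    ss: dict[str, float]
    df: dict[str, int]
    variance_components: dict[str, float]
    percent_variance: dict[str, float]
    phi: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0
    seed: int | None = None
    flags: list[str] = field(default_factory=list)


def pairwise_distance_matrix(seqs: list[str]) -> np.ndarray:
    """Squared-distance matrix: pairwise nucleotide difference counts."""
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    return hamming_matrix(seqs).astype(float)


def _group_ss(d2: np.ndarray, indices: np.ndarray) -> float:
    """(1/n) * sum of squared distances over all pairs within the index set."""
    sub = d2[np.ix_(indices, indices)]
    return float(sub.sum() / (2.0 * len(indices)))


def _partition(years: np.ndarray, sites: np.ndarray):
    """Index arrays for each year group and each (year, site) population."""
    year_groups = {y: np.nonzero(years == y)[0] for y in np.unique(years)}
    pops = {}
    for y, idx in year_groups.items():
        for s in np.unique(sites[idx]):
            pops[(y, s)] = idx[sites[idx] == s]
    return year_groups, pops


def amova_fit(
    d2: np.ndarray, years: np.ndarray | list, sites: np.ndarray | list
) -> AmovaResult:
    """Two-level hierarchical AMOVA from a squared-distance matrix.

    ``years`` and ``sites`` give, per sequence, the top-level group and the
    population nested within it.  Negative variance components are
    reported as-is and flagged; percent variance is computed on the raw
    component sum.
    """
    d2 = np.asarray(d2, dtype=float)
    years = np.asarray(years)
    sites = np.asarray(sites)
    N = d2.shape[0]
    if d2.shape != (N, N):
        raise ValueError("distance matrix must be square")
    if len(years) != N or len(sites) != N:
        raise ValueError("strata length mismatch")

    year_groups, pops = _partition(years, sites)
    G, P = len(year_groups), len(pops)
    flags = []
    if G < 2:
        flags.append("single year group: among-year stratum is degenerate")
    for y, idx in year_groups.items():
        if len(np.unique(sites[idx])) < 2:
            warnings.warn(
                f"year {y} contains a single site; the top level collapses there",
                stacklevel=2,
            )

    ss_total = _group_ss(d2, np.arange(N))
    ss_wp = sum(_group_ss(d2, idx) for idx in pops.values())
    ss_wg = sum(_group_ss(d2, idx) for idx in year_groups.values())
    ss_ap = ss_wg - ss_wp  # among sites within years
    ss_ag = ss_total - ss_wg  # among years

    df_ag = G - 1
    df_ap = P - G
    df_wp = N - P

    # expected-mean-square coefficients for unequal sizes
    pop_sizes = {k: len(v) for k, v in pops.items()}
    group_sizes = {y: len(v) for y, v in year_groups.items()}
    sum_np2_over_ng = sum(
        sum(pop_sizes[(y, s)] ** 2 for (yy, s) in pops if yy == y) / group_sizes[y]
        for y in year_groups
    )
    sum_np2_over_N = sum(n ** 2 for n in pop_sizes.values()) / N
    sum_ng2_over_N = sum(n ** 2 for n in group_sizes.values()) / N

    n_coef = (N - sum_np2_over_ng) / df_ap if df_ap > 0 else np.nan
    n1_coef = (sum_np2_over_ng - sum_np2_over_N) / df_ag if df_ag > 0 else np.nan
    n2_coef = (N - sum_ng2_over_N) / df_ag if df_ag > 0 else np.nan

    ms_wp = ss_wp / df_wp if df_wp > 0 else np.nan
    ms_ap = ss_ap / df_ap if df_ap > 0 else np.nan
    ms_ag = ss_ag / df_ag if df_ag > 0 else np.nan

    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n_coef if df_ap > 0 else np.nan
    sigma_a = (
        (ms_ag - sigma_c - n1_coef * sigma_b) / n2_coef if df_ag > 0 else np.nan
    )
    if np.nan_to_num(sigma_a) < 0 or np.nan_to_num(sigma_b) < 0:
        flags.append("negative variance component (retained, not truncated)")

    components = {
        "among_years": float(sigma_a),
        "among_sites_within_years": float(sigma_b),
        "within_sites": float(sigma_c),
    }
    total_var = np.nansum([sigma_a, sigma_b, sigma_c])
    if total_var == 0 or np.isnan(total_var):
        flags.append("zero total variance: Phi statistics undefined")
        percent = {k: float("nan") for k in components}
        phi = {"Phi_CT": float("nan"), "Phi_SC": float("nan"), "Phi_ST": float("nan")}
    else:
        percent = {k: 100.0 * v / total_var for k, v in components.items()}
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = {
                "Phi_CT": float(sigma_a / total_var),
                "Phi_SC": float(sigma_b / (sigma_b + sigma_c))
                if (sigma_b + sigma_c) != 0
                else float("nan"),
                "Phi_ST": float((np.nansum([sigma_a, sigma_b])) / total_var),
            }

    return AmovaResult(
        ss={
            "among_years": float(ss_ag),
            "among_sites_within_years": float(ss_ap),
            "within_sites": float(ss_wp),
            "total": float(ss_total),
        },
        df={"among_years": df_ag, "among_sites_within_years": df_ap, "within_sites": df_wp},
        variance_components=components,
        percent_variance=percent,
        phi=phi,
        flags=flags,
    )


def amova_permutation_test(
    d2: np.ndarray,
    years: np.ndarray | list,
    sites: np.ndarray | list,
    n_permutations: int = 999,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation p-values for the three Phi statistics.

    Phi_ST: individuals permuted among all sites; Phi_SC: individuals
    permuted among sites within their year; Phi_CT: whole site-populations
    permuted among years.  p = (1 + #{perm >= observed}) / (1 + n).
    """
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    d2 = np.asarray(d2, dtype=float)
    years = np.asarray(years)
    sites = np.asarray(sites)
    rng = np.random.default_rng(seed)
    obs = amova_fit(d2, years, sites).phi

    exceed = {k: 0 for k in ("Phi_CT", "Phi_SC", "Phi_ST")}
    year_groups, pops = _partition(years, sites)
    pop_keys = list(pops)
    pop_year = np.array([y for y, _ in pop_keys], dtype=object)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_permutations):
            # Phi_ST: permute individuals among all sites (year follows site)
            perm = rng.permutation(len(years))
            phi_st = amova_fit(d2, years[perm], sites[perm]).phi["Phi_ST"]
            if not np.isnan(obs["Phi_ST"]) and phi_st >= obs["Phi_ST"] - 1e-12:
                exceed["Phi_ST"] += 1

            # Phi_SC: permute individuals among sites within each year
            sites_sc = sites.copy()
            for idx in year_groups.values():
                sites_sc[idx] = sites_sc[idx][rng.permutation(len(idx))]
            phi_sc = amova_fit(d2, years, sites_sc).phi["Phi_SC"]
            if not np.isnan(obs["Phi_SC"]) and phi_sc >= obs["Phi_SC"] - 1e-12:
                exceed["Phi_SC"] += 1

            # Phi_CT: permute whole site-populations among years
            perm_years = pop_year[rng.permutation(len(pop_keys))]
            years_ct = years.copy().astype(object)
            for (key, idx), new_year in zip(pops.items(), perm_years):
                years_ct[idx] = new_year
            phi_ct = amova_fit(d2, years_ct, _relabel_sites(sites, pops)).phi["Phi_CT"]
            if not np.isnan(obs["Phi_CT"]) and phi_ct >= obs["Phi_CT"] - 1e-12:
                exceed["Phi_CT"] += 1

    p = {}
    for k in exceed:
        p[k] = (
            float("nan")
            if np.isnan(obs[k])
            else (1.0 + exceed[k]) / (1.0 + n_permutations)
        )
    return p


def _relabel_sites(sites: np.ndarray, pops: dict) -> np.ndarray:
    """Give every (year, site) population a unique site label.

    When whole populations are reassigned to years, two populations that
    shared a site code must not merge by accident.
    """
    out = np.empty(len(sites), dtype=object)
    for i, (key, idx) in enumerate(pops.items()):
        out[idx] = f"pop{i}"
    return out


def amova(
    seqs: list[str],
    years: list,
    sites: list,
    n_permutations: int = 999,
    seed: int = 0,
) -> AmovaResult:
    """Convenience wrapper: distances + fit + permutation tests."""
    d2 = pairwise_distance_matrix(seqs)
    result = amova_fit(d2, years, sites)
    result.p_values = amova_permutation_test(
        d2, years, sites, n_permutations=n_permutations, seed=seed
    )
    result.n_permutations = n_permutations
    result.seed = seed
    return result
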