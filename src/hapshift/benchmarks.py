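"""Reference scenarios exercising the pipeline under the study conditions.

These functions regenerate, from a seed alone, the standard evaluation
scenarios used by the test-suite and the reproduction script: the
spread-rate worked example, denoiser recovery under realistic error
rates, AMOVA parameter recovery in the year-stable / site-variable
regime, permutation-test calibration under the null, and the
marker-specific (18S-style) assignment failure mechanism.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import synthdata, taxonomy
from ._seq import hamming_matrix
from .amova import amova_permutation_test, pairwise_distance_matrix
from .denoise import dereplicate, filter_reads, unoise_denoise
from .rangeshift import RangeChange, RangeResult, density_concordance, range_change


def spread_rate_example() -> RangeChange:
    """Worked example: a 168.4 km expansion between the 2009 and 2017 surveys.

    The 2017 survey adds occupied sites 50.0 km west and 118.4 km east of
    the 2009 bounds, so the extent grows by 168.4 km over eight years.
    """
    r2009 = RangeResult("Clavelina lepadiformis", 2009, 330.0, 1010.0, 7)
    r2017 = RangeResult("Clavelina lepadiformis", 2017, 280.0, 1128.4, 9)
    return range_change(r2009, r2017, 2009, 2017)


def _recovery_pool(seed: int, n_haplotypes: int = 5, min_pairwise: int = 2):
    """A haplotype pool whose members are mutually >= min_pairwise apart."""
    pool_seed = seed
    while True:
        pool = synthdata.generate_haplotype_pool(
            "Recovery target", 313, n_haplotypes, max_steps=2, seed=pool_seed
        )
        D = hamming_matrix(pool.sequences)
        if D[np.triu_indices(n_haplotypes, 1)].min() >= min_pairwise:
            return pool
        pool_seed += 10_000


def denoiser_recovery(
    n_seeds: int = 20,
    seed: int = 0,
    depth: int = 10_000,
    error_rate: float = 0.001,
    alpha: float = 5.0,
    min_frequency: float = 0.02,
) -> dict:
    """Fraction of seeds where denoising recovers exactly the true haplotypes.

    Per seed: one site, three water replicates at ``depth`` reads each,
    five true haplotypes (pairwise distance >= 2) at frequencies >= 2%.
    A seed scores as perfect when every true haplotype appears as a
    centroid and no spurious centroid is emitted.
    """
    n_perfect = 0
    missed, spurious = 0, 0
    for i in range(n_seeds):
        pool = _recovery_pool(seed * 1000 + i)
        k = len(pool.haplotypes)
        rng = np.random.default_rng(seed * 777 + i)
        f = rng.dirichlet(np.full(k, 5.0))
        while f.min() < min_frequency:
            f = rng.dirichlet(np.full(k, 5.0))
        sf = synthdata.SiteFrequencies(
            "S1", 0.0, 2017, {pool.species_id: f}, {pool.species_id: "common"}
        )
        reads, _, _ = synthdata.simulate_edna_reads(
            {pool.species_id: pool}, [sf], depth=depth, n_replicates=3,
            error_rate=error_rate, seed=seed * 555 + i,
        )
        pooled = [r for rs in reads.values() for r in filter_reads(rs)]
        centroids = unoise_denoise(dereplicate(pooled), alpha=alpha)
        got = {c.sequence for c in centroids}
        true = set(pool.sequences)
        if got == true:
            n_perfect += 1
        missed += len(true - got)
        spurious += len(got - true)
    return {
        "n_seeds": n_seeds,
        "n_perfect": n_perfect,
        "fraction_perfect": n_perfect / n_seeds,
        "missed_haplotypes": missed,
        "spurious_centroids": spurious,
    }


def _tissue_design(
    seed: int,
    n_sites: int = 6,
    n_individuals: int = 15,
    n_haplotypes: int = 6,
    concentration: float = 1.0,
    drift: float = 0.0,
):
    """Year-stable, site-variable tissue samples across two survey years."""
    pool = synthdata.generate_haplotype_pool(
        "Amova target", 313, n_haplotypes, 2, seed=seed
    )
    sites = [(f"S{i + 1}", float(i * 100)) for i in range(n_sites)]
    freqs = synthdata.generate_metapopulation(
        pool, sites, concentration=concentration,
        occupancy_map={s: "common" for s, _ in sites},
        seed=seed + 1, drift=drift,
    )
    seqs, years, labels = [], [], []
    for j, sf in enumerate(freqs):
        recs = synthdata.sample_tissue(sf, pool, n_individuals, seed=seed * 100 + j)
        seqs.extend(s for _, s in recs)
        years.extend([sf.year] * len(recs))
        labels.extend([sf.site_id] * len(recs))
    return seqs, years, labels


def amova_parameter_recovery(
    n_seeds: int = 50, seed: int = 0, n_permutations: int = 999
) -> dict:
    """How often AMOVA reports the year-stable / site-variable regime.

    Success per seed: year effect p > 0.05 AND site-within-year effect
    p < 0.05 on tissue samples from a metapopulation with identical
    haplotype frequencies across years but independent frequencies across
    sites.
    """
    n_success, year_ps, site_ps = 0, [], []
    for i in range(n_seeds):
        seqs, years, labels = _tissue_design(seed * 1000 + i)
        d2 = pairwise_distance_matrix(seqs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = amova_permutation_test(
                d2, years, labels, n_permutations=n_permutations, seed=seed * 31 + i
            )
        year_ps.append(p["Phi_CT"])
        site_ps.append(p["Phi_SC"])
        if p["Phi_CT"] > 0.05 and p["Phi_SC"] < 0.05:
            n_success += 1
    return {
        "n_seeds": n_seeds,
        "n_success": n_success,
        "fraction_success": n_success / n_seeds,
        "median_year_p": float(np.median(year_ps)),
        "median_site_p": float(np.median(site_ps)),
    }


def amova_type_i_error(
    n_sims: int = 200, seed: int = 0, n_permutations: int = 199, alpha: float = 0.05
) -> dict:
    """Rejection rates of the AMOVA permutation tests under the null.

    Null data: sequences drawn from one global haplotype mixture and
    assigned to 2 years x 6 sites x 3 individuals arbitrarily, so no
    stratum carries real structure.  Six site-populations per year keep the
    whole-site permutation space large enough (C(12,6) = 924 arrangements)
    for the year-level test's p-values to be reasonably continuous.
    """
    pool = synthdata.generate_haplotype_pool("Null target", 120, 5, 2, seed=seed)
    k = len(pool.haplotypes)
    rejections = {"Phi_CT": 0, "Phi_SC": 0, "Phi_ST": 0}
    rng = np.random.default_rng(seed)
    n_ind = 2 * 6 * 3
    years = np.repeat([2009, 2017], n_ind // 2)
    sites = np.tile(np.repeat([f"S{i}" for i in range(6)], 3), 2)
    for _ in range(n_sims):
        f = rng.dirichlet(np.full(k, 2.0))
        idx = rng.choice(k, size=n_ind, p=f)
        seqs = [pool.sequences[i] for i in idx]
        if len(set(seqs)) < 2:
            continue
        d2 = pairwise_distance_matrix(seqs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = amova_permutation_test(
                d2, years, sites, n_permutations=n_permutations,
                seed=int(rng.integers(2 ** 31)),
            )
        for key in rejections:
            if not np.isnan(p[key]) and p[key] <= alpha:
                rejections[key] += 1
    return {
        "n_sims": n_sims,
        **{f"rate_{k.lower()}": v / n_sims for k, v in rejections.items()},
    }


def concordance_type_i_error(
    n_sims: int = 200, seed: int = 0, n_permutations: int = 199,
    n_sites: int = 8, alpha: float = 0.05,
) -> dict:
    """Rejection rate of the density-concordance test when RRA is independent
    of the ordinal field ranks."""
    rng = np.random.default_rng(seed)
    n_reject = 0
    for _ in range(n_sims):
        rra = rng.random(n_sites)
        ranks = rng.integers(1, 4, size=n_sites)
        while len(set(ranks)) < 2:
            ranks = rng.integers(1, 4, size=n_sites)
        _, p = density_concordance(
            rra, ranks, n_permutations=n_permutations, seed=int(rng.integers(2 ** 31))
        )
        if p <= alpha:
            n_reject += 1
    return {"n_sims": n_sims, "rate": n_reject / n_sims}


def marker_failure_mechanism(seed: int = 0) -> dict:
    """Reproduce the marker-specific false-negative structure.

    Two congeneric species share an identical sequence at a conserved
    (18S-style) locus but are well diverged at COI.  The COI rule keeps
    assigning the target; the exact-match rule with the congener check
    refuses every assignment for the affected species.
    """
    target_coi = synthdata.generate_haplotype_pool(
        "Ciona robusta", 313, 4, 2, seed=seed
    )
    target_18s = synthdata.generate_haplotype_pool(
        "Ciona robusta", 313, 1, 1, seed=seed + 1
    )
    coi_refs, coi_tax = synthdata.generate_reference_db(
        [target_coi], congener_divergence=30, include_congeners=True, seed=seed
    )
    s18_refs, s18_tax = synthdata.generate_reference_db(
        [target_18s], congener_divergence=0, include_congeners=True, seed=seed
    )
    coi_asvs = {f"coi_{i}": s for i, s in enumerate(target_coi.sequences)}
    s18_asvs = {f"s18_{i}": s for i, s in enumerate(target_18s.sequences)}
    coi_assign = taxonomy.assign_all(coi_asvs, coi_refs, coi_tax, marker="COI")
    s18_assign = taxonomy.assign_all(s18_asvs, s18_refs, s18_tax, marker="18S")
    return {
        "coi_assigned": sum(a.status == "assigned" for a in coi_assign.values()),
        "coi_total": len(coi_assign),
        "s18_assigned": sum(a.status == "assigned" for a in s18_assign.values()),
        "s18_total": len(s18_assign),
    }
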