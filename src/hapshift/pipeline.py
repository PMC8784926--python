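"""End-to-end orchestration: simulate -> denoise -> qc -> assign ->
haplotypes / amova / range, with a manifest and deterministic per-stage seeds.

Per-stage seeds are derived from the master seed by hashing the stage
name (CRC32), so adding a stage never perturbs the randomness of earlier
stages and every run is reproducible from its config alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import haplotypes as hap_mod
from . import qc as qc_mod
from . import rangeshift as range_mod
from . import synthdata, taxonomy
from .amova import amova as run_amova
from .containers import write_fasta, write_fastq, write_sample_sheet
from .denoise import DenoiseParams, denoise_pipeline

DEFAULT_SPECIES = [
    "Ciona robusta",
    "Clavelina lepadiformis",
    "Microcosmus squamiger",
    "Styela plicata",
]


@dataclass
class RunConfig:
    outdir: str = "run"
    seed: int = 42
    species: list[str] = field(default_factory=lambda: list(DEFAULT_SPECIES))
    n_sites: int = 12
    coast_length_km: float = 1540.0
    amplicon_length: int = 313
    n_haplotypes: int = 6
    max_mutation_steps: int = 2
    concentration: float = 1.0
    depth: int = 2000
    n_replicates: int = 3
    n_negatives: int = 2
    error_rate: float = 0.001
    contamination_rate: float = 0.0
    tissue_n: int = 15
    years: tuple[int, int] = (2009, 2017)
    n_permutations: int = 199
    congener_divergence_coi: int = 30
    identical_18s_congeners: list[str] = field(
        default_factory=lambda: DEFAULT_SPECIES[:2]
    )
    denoise: DenoiseParams = field(default_factory=DenoiseParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "denoise" in data:
            data["denoise"] = DenoiseParams(**data["denoise"])
        if "years" in data:
            data["years"] = tuple(data["years"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["years"] = list(self.years)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def stage_seed(self, stage: str) -> int:
        return zlib.crc32(f"{self.seed}:{stage}".encode()) & 0x7FFFFFFF


def _scenario(config: RunConfig) -> tuple[list[tuple[str, float]], dict, dict]:
    """Demo study design: 12 sites, contiguous occupancy blocks, mixed trajectories."""
    positions = [
        (f"S{i + 1:02d}", round(i * config.coast_length_km / (config.n_sites - 1), 1))
        for i in range(config.n_sites)
    ]
    ids = [s for s, _ in positions]
    n = len(ids)
    species = config.species
    baseline: dict[str, dict[str, str]] = {}
    trajectories: dict[str, tuple] = {}
    patterns = [
        # (occupied slice, categories cycle, trajectory)
        (slice(0, n - 1), ["common", "dominant", "scarce"], ("contract_east", 1)),
        (slice(2, n - 3), ["common", "scarce", "common"], ("expand_both", 1)),
        (slice(n // 2, n), ["dominant", "common", "common"], ("stable",)),
        (slice(n // 3, n - 1), ["scarce", "common", "common"], ("stable",)),
    ]
    for sp, (sl, cats, traj) in zip(species, patterns):
        occupied = ids[sl]
        baseline[sp] = {
            s: cats[i % len(cats)] for i, s in enumerate(occupied)
        }
        trajectories[sp] = traj
    return positions, baseline, trajectories


def _year_occupancy(survey: pd.DataFrame, species: str, year: int) -> dict[str, str]:
    sub = survey[(survey["species"] == species) & (survey["year"] == year)]
    return dict(zip(sub["site_id"], sub["category"]))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the result summary dictionary.

    All stage outputs are written under ``config.outdir`` along with the
    verbatim config and a manifest of output hashes.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    warnings_log: list[str] = []

    # ---- simulate ---------------------------------------------------------
    positions, baseline, trajectories = _scenario(config)
    survey = synthdata.generate_survey_scenario(
        positions,
        config.years,
        trajectories,
        baseline,
        seed=config.stage_seed("survey"),
    )
    survey.to_csv(out / "survey.csv", index=False)
    pd.DataFrame(positions, columns=["site_id", "position_km"]).to_csv(
        out / "sites.csv", index=False
    )

    pools: dict[str, synthdata.HaplotypePool] = {}
    site_freqs_by_year: dict[int, list[synthdata.SiteFrequencies]] = {
        y: [] for y in config.years
    }
    per_species_freqs = []
    for i, sp in enumerate(config.species):
        pools[sp] = synthdata.generate_haplotype_pool(
            sp,
            length=config.amplicon_length,
            n_haplotypes=config.n_haplotypes,
            max_steps=config.max_mutation_steps,
            seed=config.stage_seed(f"pool:{sp}"),
        )
        union_occ = {}
        for year in config.years:
            for site, cat in _year_occupancy(survey, sp, year).items():
                if cat != "absent":
                    union_occ.setdefault(site, cat)
        freqs = synthdata.generate_metapopulation(
            pools[sp],
            positions,
            concentration=config.concentration,
            occupancy_map=union_occ,
            seed=config.stage_seed(f"metapop:{sp}"),
            years=config.years,
        )
        # occupancy per year comes from the survey scenario; frequencies are
        # year-stable but zeroed where the species is absent that year
        for sf in freqs:
            cat = _year_occupancy(survey, sp, sf.year).get(sf.site_id, "absent")
            sf.occupancy[sp] = cat
            if cat == "absent":
                sf.frequencies[sp] = np.zeros_like(sf.frequencies[sp])
        per_species_freqs.append(freqs)

    merged = synthdata.merge_site_frequencies(per_species_freqs)
    for sf in merged:
        site_freqs_by_year[sf.year].append(sf)

    # tissue samples for both years
    tissue_records: dict[str, list[tuple[str, str]]] = {sp: [] for sp in config.species}
    for sp in config.species:
        pool = pools[sp]
        for sf in merged:
            if not sf.occupied(sp):
                continue
            recs = synthdata.sample_tissue(
                sf,
                pool,
                config.tissue_n,
                seed=config.stage_seed(f"tissue:{sp}:{sf.site_id}:{sf.year}"),
            )
            tissue_records[sp].extend(recs)
        write_fasta(out / f"tissue_{synthdata._slug(sp)}.fasta", tissue_records[sp])

    # eDNA reads for the second survey year (the eDNA campaign year)
    edna_year = config.years[1]
    reads, samples, origins = synthdata.simulate_edna_reads(
        pools,
        site_freqs_by_year[edna_year],
        depth=config.depth,
        n_replicates=config.n_replicates,
        error_rate=config.error_rate,
        contamination_rate=config.contamination_rate,
        n_negatives=config.n_negatives,
        seed=config.stage_seed("edna"),
        marker="COI",
    )
    fastq_dir = out / "fastq"
    fastq_dir.mkdir(exist_ok=True)
    for sid, recs in reads.items():
        write_fastq(fastq_dir / f"{sid}.fastq", recs)
    write_sample_sheet(out / "sample_sheet.csv", samples)

    truth = synthdata.SyntheticTruth(
        pools=pools,
        site_frequencies=merged,
        contamination_rate=config.contamination_rate,
        error_rate=config.error_rate,
        seed=config.seed,
        read_origins=origins,
    )
    truth.to_json(out / "truth.json")

    # reference databases: COI with diverged congeners; an 18S-style exact-match
    # database where configured species carry an identical congener
    coi_refs, coi_tax = synthdata.generate_reference_db(
        list(pools.values()),
        congener_divergence=config.congener_divergence_coi,
        include_congeners=True,
        seed=config.stage_seed("refdb:coi"),
    )
    write_fasta(out / "refdb_coi.fasta", coi_refs)
    coi_tax.to_csv(out / "refdb_coi.csv", index=False)

    # ---- denoise ----------------------------------------------------------
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        table = denoise_pipeline(reads, samples, config.denoise)
        # ---- qc ----------------------------------------------------------
        site_props, filtered = qc_mod.qc_pipeline(table)
        warnings_log.extend(str(w.message) for w in caught)
    table.counts.to_csv(out / "asv_counts.tsv", sep="\t", index_label="asv_id")
    write_fasta(out / "asvs.fasta", [(a, table.sequences[a]) for a in table.counts.index])
    site_props.to_csv(out / "site_proportions.tsv", sep="\t", index_label="asv_id")

    # ---- taxonomy ---------------------------------------------------------
    asv_seqs = {a: table.sequences[a] for a in site_props.index}
    assignments = taxonomy.assign_all(asv_seqs, coi_refs, coi_tax, marker="COI")
    taxonomy.assignments_to_frame(assignments).to_csv(out / "assignments_coi.csv")
    species_rra = taxonomy.merge_by_species(site_props, assignments)
    species_rra.to_csv(out / "species_rra_coi.csv")

    # 18S: a conserved locus with a single haplotype per species.  Species in
    # identical_18s_congeners carry an identical same-genus reference, which
    # the exact-match rule refuses — COI detections persist, 18S goes dark.
    pools_18s = {
        sp: synthdata.generate_haplotype_pool(
            sp,
            length=config.amplicon_length,
            n_haplotypes=1,
            max_steps=1,
            seed=config.stage_seed(f"pool18s:{sp}"),
        )
        for sp in config.species
    }
    freqs_18s = []
    for sf in site_freqs_by_year[edna_year]:
        freqs_18s.append(
            synthdata.SiteFrequencies(
                site_id=sf.site_id,
                position_km=sf.position_km,
                year=sf.year,
                frequencies={
                    sp: np.array([1.0 if sf.occupied(sp) else 0.0])
                    for sp in config.species
                },
                occupancy=dict(sf.occupancy),
            )
        )
    reads_18s, samples_18s, _ = synthdata.simulate_edna_reads(
        pools_18s,
        freqs_18s,
        depth=config.depth,
        n_replicates=config.n_replicates,
        error_rate=config.error_rate,
        contamination_rate=config.contamination_rate,
        n_negatives=config.n_negatives,
        seed=config.stage_seed("edna:18s"),
        marker="18S",
    )
    affected = [pools_18s[sp] for sp in config.species if sp in config.identical_18s_congeners]
    clean = [pools_18s[sp] for sp in config.species if sp not in config.identical_18s_congeners]
    refs_a, tax_a = synthdata.generate_reference_db(
        affected, congener_divergence=0, include_congeners=True,
        seed=config.stage_seed("refdb:18s:a"),
    )
    refs_b, tax_b = synthdata.generate_reference_db(
        clean, congener_divergence=5, include_congeners=True,
        seed=config.stage_seed("refdb:18s:b"),
    )
    refs_18s = refs_a + refs_b
    tax_18s = pd.concat([tax_a, tax_b], ignore_index=True)
    write_fasta(out / "refdb_18s.fasta", refs_18s)
    tax_18s.to_csv(out / "refdb_18s.csv", index=False)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table_18s = denoise_pipeline(reads_18s, samples_18s, config.denoise)
        site_props_18s, _ = qc_mod.qc_pipeline(table_18s)
    asv_seqs_18s = {a: table_18s.sequences[a] for a in site_props_18s.index}
    assignments_18s = taxonomy.assign_all(asv_seqs_18s, refs_18s, tax_18s, marker="18S")
    taxonomy.assignments_to_frame(assignments_18s).to_csv(out / "assignments_18s.csv")
    species_rra_18s = taxonomy.merge_by_species(site_props_18s, assignments_18s)
    species_rra_18s.to_csv(out / "species_rra_18s.csv")

    # ---- haplotypes & concordance ----------------------------------------
    summary: dict = {"species": {}}
    for sp in config.species:
        slug = synthdata._slug(sp)
        sp_result: dict = {}
        tis = tissue_records[sp]
        sp_asvs = [
            (a, asv_seqs[a])
            for a, asg in assignments.items()
            if asg.status == "assigned" and asg.species == sp and a in asv_seqs
        ]
        if tis:
            tissue_set = hap_mod.collapse_haplotypes(tis, species=sp, prefix="T")
            sp_result["tissue_haplotypes"] = len(tissue_set.haplotypes)
            if sp_asvs:
                trimmed, window = hap_mod.extract_overlap(tis, sp_asvs)
                t_trim = [(n, trimmed[n]) for n, _ in tis]
                e_trim = [(n, trimmed[n]) for n, _ in sp_asvs]
                tset = hap_mod.collapse_haplotypes(t_trim, species=sp, prefix="T")
                eset = hap_mod.collapse_haplotypes(e_trim, species=sp, prefix="E")
                shared, t_only, e_only, conc_table = hap_mod.concordance(tset, eset)
                conc_table.to_csv(out / f"concordance_{slug}.csv", index=False)
                sp_result["concordance"] = {
                    "shared": shared,
                    "tissue_only": t_only,
                    "edna_only": e_only,
                    "window": list(window),
                }
            # diversity per year
            sp_result["diversity"] = {}
            for year in config.years:
                seqs = [s for n, s in tis if f"|{year}|" in n]
                if len(seqs) >= 2:
                    d = hap_mod.diversity_stats(seqs)
                    sp_result["diversity"][str(year)] = {
                        "pi": d.pi, "hd": d.hd, "n": d.n, "L": d.L
                    }
            # minimum spanning network
            msn = hap_mod.minimum_spanning_network(tissue_set)
            edge_rows = [
                {"from": u, "to": v, "mutation_steps": d["weight"]}
                for u, v, d in msn.edges(data=True)
            ]
            pd.DataFrame(edge_rows, columns=["from", "to", "mutation_steps"]).to_csv(
                out / f"msn_{slug}.tsv", sep="\t", index=False
            )

            # ---- amova ---------------------------------------------------
            years_lab = [n.split("|")[2] for n, _ in tis]
            sites_lab = [n.split("|")[0] for n, _ in tis]
            seqs = [s for _, s in tis]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                am = run_amova(
                    seqs,
                    years_lab,
                    sites_lab,
                    n_permutations=config.n_permutations,
                    seed=config.stage_seed(f"amova:{sp}"),
                )
            sp_result["amova"] = {
                "ss": am.ss,
                "df": am.df,
                "variance_components": am.variance_components,
                "percent_variance": am.percent_variance,
                "phi": am.phi,
                "p_values": am.p_values,
                "flags": am.flags,
            }
            (out / f"amova_{slug}.json").write_text(
                json.dumps(sp_result["amova"], indent=1, default=float)
            )

        # ---- range --------------------------------------------------------
        r1 = range_mod.range_extent(survey, sp, config.years[0])
        r2 = range_mod.range_extent(survey, sp, config.years[1])
        if r1 and r2:
            change = range_mod.range_change(r1, r2, *config.years)
            sp_result["range"] = {
                "extent_y1_km": r1.extent_km,
                "extent_y2_km": r2.extent_km,
                "delta_extent_km": change.delta_extent_km,
                "rate_km_per_year": change.rate_km_per_year,
                "classification": change.classification,
            }
        summary["species"][sp] = sp_result

    # detection comparison across markers
    field_y2 = survey[survey["year"] == edna_year]
    detect = range_mod.detection_comparison(
        field_y2, {"COI": species_rra, "18S": species_rra_18s}
    )
    detect.to_csv(out / "detection_comparison.csv", index=False)
    summary["detections"] = (
        detect.groupby(["marker", "species", "status"]).size().to_dict()
    )
    summary["detections"] = {
        f"{m}|{sp}|{st}": int(v) for (m, sp, st), v in summary["detections"].items()
    }
    summary["warnings"] = warnings_log

    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    _write_manifest(out)
    return summary


def _write_manifest(out: Path) -> None:
    entries = []
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            entries.append({"path": str(path.relative_to(out)), "sha256": digest})
    (out / "manifest.json").write_text(json.dumps(entries, indent=1))


def report(run_dir: str | Path) -> str:
    """Plain-text summary of a completed run (idempotent)."""
    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(f"no summary.json in {run_dir}: incomplete run")
    summary = json.loads(summary_path.read_text())
    lines = ["hapshift run report", "==================="]
    for sp, res in summary["species"].items():
        lines.append(f"\n{sp}")
        if "range" in res:
            r = res["range"]
            lines.append(
                f"  range: {r['extent_y1_km']:.1f} -> {r['extent_y2_km']:.1f} km "
                f"({r['classification']}, {r['rate_km_per_year']:+.1f} km/yr)"
            )
        else:
            lines.append("  range: absent in at least one survey year")
        for year, d in res.get("diversity", {}).items():
            lines.append(
                f"  {year}: n={d['n']} pi={d['pi']:.4f} Hd={d['hd']:.3f} ({d['L']} bp)"
            )
        if "amova" in res:
            p = res["amova"]["p_values"]
            lines.append(
                f"  AMOVA: p(year)={p['Phi_CT']:.3f} p(site|year)={p['Phi_SC']:.3f} "
                f"p(overall)={p['Phi_ST']:.3f}"
            )
        if "concordance" in res:
            c = res["concordance"]
            lines.append(
                f"  eDNA vs tissue haplotypes: shared={c['shared']} "
                f"tissue_only={c['tissue_only']} edna_only={c['edna_only']}"
            )
    text = "\n".join(lines) + "\n"
    (run_dir / "report.txt").write_text(text)
    return text
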