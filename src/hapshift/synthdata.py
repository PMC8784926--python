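"""Ground-truthed synthetic data emulating a coastal eDNA + tissue study design.

The generator produces, for a configurable set of non-native species on a
1-D coastline transect: a haplotype pool per species (a connected mutation
network around a root sequence), per-site haplotype frequencies for two
survey years, multinomial tissue samples, pre-merged eDNA amplicon reads
with per-base substitution errors and negative controls, a labelled
reference database (optionally with congeneric decoys), and ordinal
rapid-assessment survey tables with known range trajectories.

Everything is deterministic for a fixed seed, and the :class:`SyntheticTruth`
object retains the ground truth needed for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import BASES, encode, hamming

# Ordinal substrate-cover categories used by rapid assessment surveys and
# the midpoint biomass weight used when allocating eDNA reads to species.
CATEGORIES = ("absent", "scarce", "common", "dominant")
OCCUPANCY_WEIGHT = {"absent": 0.0, "scarce": 0.05, "common": 0.30, "dominant": 0.75}

_BASE_CODES = np.frombuffer("ACGT".encode(), dtype=np.uint8)


@dataclass(frozen=True)
class Haplotype:
    haplotype_id: str
    sequence: str
    mutation_steps: int  # Hamming distance to the parent it was derived from


@dataclass
class HaplotypePool:
    """A species' haplotypes as a connected mutation network around a root."""

    species_id: str
    root_sequence: str
    haplotypes: list[Haplotype]

    @property
    def length(self) -> int:
        return len(self.root_sequence)

    @property
    def sequences(self) -> list[str]:
        return [h.sequence for h in self.haplotypes]

    @property
    def ids(self) -> list[str]:
        return [h.haplotype_id for h in self.haplotypes]


@dataclass
class SiteFrequencies:
    """Haplotype frequencies and ordinal occupancy at one site in one year."""

    site_id: str
    position_km: float
    year: int
    frequencies: dict[str, np.ndarray]  # species -> frequency vector over pool order
    occupancy: dict[str, str]  # species -> ordinal category

    def occupied(self, species: str) -> bool:
        return self.occupancy.get(species, "absent") != "absent"


@dataclass
class SyntheticTruth:
    """Everything needed to regenerate the synthetic study and to score recovery."""

    pools: dict[str, HaplotypePool]
    site_frequencies: list[SiteFrequencies]
    contamination_rate: float
    error_rate: float
    seed: int
    read_origins: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "error_rate": self.error_rate,
            "contamination_rate": self.contamination_rate,
            "pools": {
                sp: {
                    "root_sequence": p.root_sequence,
                    "haplotypes": [
                        [h.haplotype_id, h.sequence, h.mutation_steps]
                        for h in p.haplotypes
                    ],
                }
                for sp, p in self.pools.items()
            },
            "site_frequencies": [
                {
                    "site_id": sf.site_id,
                    "position_km": sf.position_km,
                    "year": sf.year,
                    "occupancy": sf.occupancy,
                    "frequencies": {k: list(map(float, v)) for k, v in sf.frequencies.items()},
                }
                for sf in self.site_frequencies
            ],
            "read_origins": self.read_origins,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        pools = {
            sp: HaplotypePool(
                species_id=sp,
                root_sequence=p["root_sequence"],
                haplotypes=[Haplotype(*h) for h in p["haplotypes"]],
            )
            for sp, p in d["pools"].items()
        }
        sfs = [
            SiteFrequencies(
                site_id=s["site_id"],
                position_km=s["position_km"],
                year=s["year"],
                occupancy=s["occupancy"],
                frequencies={k: np.asarray(v, dtype=float) for k, v in s["frequencies"].items()},
            )
            for s in d["site_frequencies"]
        ]
        return cls(
            pools=pools,
            site_frequencies=sfs,
            contamination_rate=d["contamination_rate"],
            error_rate=d["error_rate"],
            seed=d["seed"],
            read_origins=d.get("read_origins", {}),
        )


# ---------------------------------------------------------------------------
# haplotype pools
# ---------------------------------------------------------------------------

def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _mutate(sequence: str, n_steps: int, rng: np.random.Generator) -> str:
    arr = bytearray(sequence.encode())
    positions = rng.choice(len(arr), size=n_steps, replace=False)
    for pos in positions:
        alternatives = [b for b in _BASE_CODES if b != arr[pos]]
        arr[pos] = alternatives[rng.integers(0, 3)]
    return arr.decode()


def generate_haplotype_pool(
    species_id: str,
    length: int = 313,
    n_haplotypes: int = 8,
    max_steps: int = 2,
    seed: int = 0,
) -> HaplotypePool:
    """Grow a connected mutation network of ``n_haplotypes`` distinct sequences.

    Each non-root haplotype is derived from a uniformly chosen existing
    haplotype by 1..max_steps substitutions, so the pool always forms a
    connected network and every haplotype records its mutation distance
    to its parent.
    """
    if length < 50:
        raise ValueError("amplicon length must be >= 50 bp")
    if n_haplotypes < 1 or max_steps < 1:
        raise ValueError("n_haplotypes and max_steps must be >= 1")
    if n_haplotypes > 4 ** length:
        raise ValueError("n_haplotypes exceeds the sequence space 4^length")
    rng = np.random.default_rng(seed)
    root = _random_sequence(length, rng)
    haps = [Haplotype(f"{_slug(species_id)}_h1", root, 0)]
    seen = {root}
    attempts = 0
    while len(haps) < n_haplotypes:
        parent = haps[int(rng.integers(0, len(haps)))]
        steps = int(rng.integers(1, max_steps + 1))
        candidate = _mutate(parent.sequence, steps, rng)
        attempts += 1
        if candidate in seen:
            if attempts > 1000 * n_haplotypes:
                raise RuntimeError("could not generate distinct haplotypes")
            continue
        seen.add(candidate)
        haps.append(Haplotype(f"{_slug(species_id)}_h{len(haps) + 1}", candidate, steps))
    return HaplotypePool(species_id=species_id, root_sequence=root, haplotypes=haps)


def _slug(species_id: str) -> str:
    return species_id.replace(" ", "_")


# ---------------------------------------------------------------------------
# metapopulation frequencies
# ---------------------------------------------------------------------------

def generate_metapopulation(
    pool: HaplotypePool,
    site_positions: list[tuple[str, float]],
    concentration: float = 1.0,
    occupancy_map: dict[str, str] | None = None,
    seed: int = 0,
    years: tuple[int, int] = (2009, 2017),
    drift: float = 0.0,
) -> list[SiteFrequencies]:
    """Draw per-site haplotype frequencies, stable across the two survey years.

    Occupied sites receive one Dirichlet(concentration) draw over the
    pool's haplotypes; with ``drift`` = 0 (the default, matching temporally
    stable populations) the second year reuses the first year's vector,
    otherwise the second-year vector is a mixture
    ``(1 - drift) * f + drift * g`` with an independent draw ``g``.
    """
    if not site_positions:
        raise ValueError("empty site list")
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    if any(pos < 0 for _, pos in site_positions):
        raise ValueError("positions must be non-negative")
    occupancy_map = occupancy_map or {s: "common" for s, _ in site_positions}
    rng = np.random.default_rng(seed)
    k = len(pool.haplotypes)
    out: list[SiteFrequencies] = []
    for site_id, pos in site_positions:
        cat = occupancy_map.get(site_id, "absent")
        if cat == "absent":
            f1 = np.zeros(k)
            f2 = np.zeros(k)
        else:
            f1 = rng.dirichlet(np.full(k, concentration))
            if drift > 0:
                g = rng.dirichlet(np.full(k, concentration))
                f2 = (1.0 - drift) * f1 + drift * g
            else:
                f2 = f1.copy()
        for year, f in zip(years, (f1, f2)):
            out.append(
                SiteFrequencies(
                    site_id=site_id,
                    position_km=float(pos),
                    year=int(year),
                    frequencies={pool.species_id: f},
                    occupancy={pool.species_id: cat},
                )
            )
    return out


def merge_site_frequencies(per_species: list[list[SiteFrequencies]]) -> list[SiteFrequencies]:
    """Merge single-species SiteFrequencies lists into multi-species records."""
    merged: dict[tuple[str, int], SiteFrequencies] = {}
    for sf_list in per_species:
        for sf in sf_list:
            key = (sf.site_id, sf.year)
            if key not in merged:
                merged[key] = SiteFrequencies(
                    site_id=sf.site_id,
                    position_km=sf.position_km,
                    year=sf.year,
                    frequencies={},
                    occupancy={},
                )
            merged[key].frequencies.update(sf.frequencies)
            merged[key].occupancy.update(sf.occupancy)
    return list(merged.values())


# ---------------------------------------------------------------------------
# tissue sampling
# ---------------------------------------------------------------------------

def sample_tissue(
    freqs: SiteFrequencies,
    pool: HaplotypePool,
    n_individuals: int,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Multinomial draw of individual COI sequences at one site.

    Record ids encode site, species, year and individual index, e.g.
    ``SITE01|Ciona_robusta|2017|ind003``.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if not freqs.occupied(pool.species_id):
        raise ValueError(
            f"{pool.species_id} is not occupied at {freqs.site_id} in {freqs.year}"
        )
    rng = np.random.default_rng(seed)
    f = freqs.frequencies[pool.species_id]
    counts = rng.multinomial(n_individuals, f)
    records = []
    i = 0
    for hap, c in zip(pool.haplotypes, counts):
        for _ in range(int(c)):
            i += 1
            name = f"{freqs.site_id}|{_slug(pool.species_id)}|{freqs.year}|ind{i:03d}"
            records.append((name, hap.sequence))
    return records


# ---------------------------------------------------------------------------
# eDNA read simulation
# ---------------------------------------------------------------------------

def _apply_errors(mat: np.ndarray, error_rate: float, rng: np.random.Generator) -> None:
    """Independent per-base substitutions, in place on an (n, L) uint8 matrix."""
    if error_rate <= 0 or mat.size == 0:
        return
    n, L = mat.shape
    n_err = rng.binomial(L, error_rate, size=n)
    for i in np.nonzero(n_err)[0]:
        positions = rng.choice(L, size=n_err[i], replace=False)
        for pos in positions:
            alternatives = _BASE_CODES[_BASE_CODES != mat[i, pos]]
            mat[i, pos] = alternatives[rng.integers(0, 3)]


def _jitter_read(seq: str, jitter: int, rng: np.random.Generator) -> str:
    delta = int(rng.integers(-jitter, jitter + 1))
    if delta < 0:
        return seq[: len(seq) + delta]
    if delta > 0:
        return seq + _random_sequence(delta, rng)
    return seq


def simulate_edna_reads(
    pools: dict[str, HaplotypePool],
    site_freqs: list[SiteFrequencies],
    depth: int = 10_000,
    n_replicates: int = 3,
    error_rate: float = 0.001,
    contamination_rate: float = 0.0,
    n_negatives: int = 2,
    seed: int = 0,
    length_jitter: int = 0,
    quality_phred: int = 30,
    marker: str = "COI",
) -> tuple[dict[str, list[tuple[str, str, str]]], pd.DataFrame, dict[str, dict[str, int]]]:
    """Simulate pre-merged, correctly oriented amplicon reads per water replicate.

    Reads at each site are drawn from the site's haplotype mixture with
    species weighted by the ordinal-occupancy midpoint (absent 0, scarce
    0.05, common 0.30, dominant 0.75); each read then receives independent
    per-base substitutions at ``error_rate``.  Negative controls receive
    reads only through ``contamination_rate`` (per-read probability,
    binomial on ``depth``).  Quality strings are constant Q``quality_phred``.

    Returns ``(reads_by_sample, sample_sheet, read_origins)`` where
    ``read_origins[sample][haplotype_id]`` counts the true template of
    every read before errors.
    """
    if depth < 1 or n_replicates < 1:
        raise ValueError("depth and n_replicates must be >= 1")
    if not 0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be within [0, 0.05]")
    rng = np.random.default_rng(seed)
    qual_char = chr(quality_phred + 33)

    # template catalogue: (species, haplotype_id, encoded sequence)
    templates: list[tuple[str, str, str]] = []
    for sp, pool in pools.items():
        for h in pool.haplotypes:
            templates.append((sp, h.haplotype_id, h.sequence))
    tpl_index = {(sp, hid): i for i, (sp, hid, _) in enumerate(templates)}

    def site_mixture(sf: SiteFrequencies) -> np.ndarray:
        w = np.zeros(len(templates))
        for sp, pool in pools.items():
            weight = OCCUPANCY_WEIGHT.get(sf.occupancy.get(sp, "absent"), 0.0)
            if weight <= 0:
                continue
            f = sf.frequencies[sp]
            for hid, fv in zip(pool.ids, f):
                w[tpl_index[(sp, hid)]] = weight * fv
        total = w.sum()
        return w / total if total > 0 else w

    reads_by_sample: dict[str, list[tuple[str, str, str]]] = {}
    origins: dict[str, dict[str, int]] = {}
    rows = []
    global_mix = np.zeros(len(templates))

    for sf in site_freqs:
        mix = site_mixture(sf)
        global_mix += mix
        for rep in range(1, n_replicates + 1):
            sample_id = f"{sf.site_id}_{marker}_R{rep}"
            rows.append((sample_id, sf.site_id, rep, False, marker))
            if mix.sum() == 0:
                reads_by_sample[sample_id] = []
                origins[sample_id] = {}
                continue
            counts = rng.multinomial(depth, mix)
            reads_by_sample[sample_id] = _emit_reads(
                sample_id, templates, counts, error_rate, length_jitter, qual_char, rng
            )
            origins[sample_id] = {
                templates[i][1]: int(c) for i, c in enumerate(counts) if c > 0
            }

    if global_mix.sum() > 0:
        global_mix = global_mix / global_mix.sum()
    for neg in range(1, n_negatives + 1):
        sample_id = f"NEG_{marker}_R{neg}"
        rows.append((sample_id, "NEG", neg, True, marker))
        n_cont = int(rng.binomial(depth, contamination_rate)) if global_mix.sum() > 0 else 0
        counts = rng.multinomial(n_cont, global_mix) if n_cont > 0 else np.zeros(
            len(templates), dtype=int
        )
        reads_by_sample[sample_id] = _emit_reads(
            sample_id, templates, counts, error_rate, length_jitter, qual_char, rng
        )
        origins[sample_id] = {templates[i][1]: int(c) for i, c in enumerate(counts) if c > 0}

    samples = pd.DataFrame(
        rows, columns=["sample_id", "site_id", "replicate", "is_negative_control", "marker"]
    ).set_index("sample_id")
    return reads_by_sample, samples, origins


def _emit_reads(
    sample_id: str,
    templates: list[tuple[str, str, str]],
    counts: np.ndarray,
    error_rate: float,
    length_jitter: int,
    qual_char: str,
    rng: np.random.Generator,
) -> list[tuple[str, str, str]]:
    reads: list[tuple[str, str, str]] = []
    r = 0
    for i, c in enumerate(counts):
        if c == 0:
            continue
        sp, hid, seq = templates[i]
        mat = np.tile(encode(seq), (int(c), 1))
        _apply_errors(mat, error_rate, rng)
        for row in mat:
            r += 1
            read_seq = row.tobytes().decode()
            if length_jitter > 0:
                read_seq = _jitter_read(read_seq, length_jitter, rng)
            reads.append((f"{sample_id}_r{r:06d}|{hid}", read_seq, qual_char * len(read_seq)))
    return reads


# ---------------------------------------------------------------------------
# reference database
# ---------------------------------------------------------------------------

def generate_reference_db(
    pools: list[HaplotypePool],
    congener_divergence: int = 30,
    include_congeners: bool = True,
    seed: int = 0,
    refs_per_species: int = 2,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Build a labelled reference FASTA with >=2 records per target species.

    When ``include_congeners`` is set, a same-genus decoy species is added
    at exactly ``congener_divergence`` substitutions from each target's
    root sequence; divergence 0 yields an identical congener, the failure
    mode that defeats exact-match (18S-style) assignment.
    """
    if congener_divergence < 0:
        raise ValueError("congener_divergence must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    rows = []
    for pool in pools:
        genus = pool.species_id.split()[0]
        for i in range(refs_per_species):
            # independent accessions of the same species: the root plus, when
            # available, a true haplotype one mutation network step away
            seq = pool.haplotypes[min(i, len(pool.haplotypes) - 1)].sequence
            ref_id = f"REF_{_slug(pool.species_id)}_{i + 1}"
            records.append((ref_id, seq))
            rows.append((ref_id, pool.species_id, genus))
        if include_congeners:
            decoy_species = f"{genus} decoyi"
            decoy_seq = (
                pool.root_sequence
                if congener_divergence == 0
                else _mutate(pool.root_sequence, congener_divergence, rng)
            )
            ref_id = f"REF_{_slug(decoy_species)}_1"
            records.append((ref_id, decoy_seq))
            rows.append((ref_id, decoy_species, genus))
    taxonomy = pd.DataFrame(rows, columns=["reference_id", "species", "genus"])
    return records, taxonomy


# ---------------------------------------------------------------------------
# survey scenarios
# ---------------------------------------------------------------------------

def generate_survey_scenario(
    site_positions: list[tuple[str, float]],
    years: tuple[int, int],
    trajectories: dict[str, tuple],
    baseline: dict[str, dict[str, str]],
    seed: int = 0,
) -> pd.DataFrame:
    """Build two-year ordinal survey tables with known range trajectories.

    ``baseline[species]`` maps site_id -> category for the first year;
    ``trajectories[species]`` is ``("stable",)``, ``("expand_east", k)``,
    ``("expand_west", k)``, ``("contract_east", k)`` or
    ``("contract_west", k)`` where k counts sites added or removed at the
    range margin for the second year (added sites enter as "scarce").
    """
    if len(site_positions) < 2:
        raise ValueError("need >= 2 sites")
    y1, y2 = years
    if y1 == y2:
        raise ValueError("survey years must be distinct")
    ordered = sorted(site_positions, key=lambda t: t[1])
    site_order = [s for s, _ in ordered]
    positions = dict(site_positions)

    rows = []
    for species, base in baseline.items():
        occ1 = {s: base.get(s, "absent") for s in site_order}
        occ2 = dict(occ1)
        traj = trajectories.get(species, ("stable",))
        kind = traj[0]
        k = traj[1] if len(traj) > 1 else 0
        occupied_idx = [i for i, s in enumerate(site_order) if occ1[s] != "absent"]
        known = {
            "stable", "expand_east", "expand_west", "expand_both",
            "contract_east", "contract_west",
        }
        if kind not in known:
            raise ValueError(f"unknown trajectory {kind!r}")
        if occupied_idx and kind != "stable":
            west_i, east_i = occupied_idx[0], occupied_idx[-1]
            if kind in ("expand_east", "expand_both"):
                for i in range(east_i + 1, min(east_i + 1 + k, len(site_order))):
                    occ2[site_order[i]] = "scarce"
            if kind in ("expand_west", "expand_both"):
                for i in range(max(0, west_i - k), west_i):
                    occ2[site_order[i]] = "scarce"
            if kind == "contract_east":
                for i in occupied_idx[-k:]:
                    occ2[site_order[i]] = "absent"
            if kind == "contract_west":
                for i in occupied_idx[:k]:
                    occ2[site_order[i]] = "absent"
        for year, occ in ((y1, occ1), (y2, occ2)):
            for s in site_order:
                rows.append((s, positions[s], year, species, occ[s]))
    return pd.DataFrame(
        rows, columns=["site_id", "position_km", "year", "species", "category"]
    )
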