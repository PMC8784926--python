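"""Rule-based species assignment of ASVs against a local labelled reference set.

Two marker-specific decision rules are implemented.  COI: species-level
assignment requires multiple independent reference records of the species
above 97% identity at 100% coverage with no other species reaching 97%.
18S: an exact (100/100) match is required, and any same-genus reference of
a different species must differ from the query by at least one base; an
identical congener therefore blocks assignment — the mechanism behind
marker-specific false negatives for recently diverged taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._seq import identity_coverage


@dataclass(frozen=True)
class ReferenceHit:
    asv_id: str
    reference_id: str
    species: str
    genus: str
    identity: float  # percent, 0-100
    coverage: float  # percent of query aligned, 0-100

    def __post_init__(self) -> None:
        if not (0 <= self.identity <= 100 and 0 <= self.coverage <= 100):
            raise ValueError("identity and coverage must be percentages")


@dataclass
class SpeciesAssignment:
    asv_id: str
    status: str  # assigned | unassigned | ambiguous
    species: str = ""
    rule: str = "COI"
    evidence: list[ReferenceHit] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status == "assigned" and not (self.species and self.evidence):
            raise ValueError("assigned status requires species and evidence")


def align_identity(query: str, reference: str) -> tuple[float, float]:
    """(identity %, query coverage %) of the best end-gap-free alignment."""
    if not query or not reference:
        raise ValueError("empty sequence")
    return identity_coverage(query, reference)


def compute_hits(
    asv_sequences: dict[str, str],
    references: list[tuple[str, str]],
    taxonomy_map: pd.DataFrame,
) -> dict[str, list[ReferenceHit]]:
    """All-vs-all identity/coverage of ASVs against the labelled references."""
    tax = taxonomy_map.set_index("reference_id")
    hits: dict[str, list[ReferenceHit]] = {a: [] for a in asv_sequences}
    for asv_id, seq in asv_sequences.items():
        for ref_id, ref_seq in references:
            ident, cov = align_identity(seq, ref_seq)
            hits[asv_id].append(
                ReferenceHit(
                    asv_id=asv_id,
                    reference_id=ref_id,
                    species=tax.loc[ref_id, "species"],
                    genus=tax.loc[ref_id, "genus"],
                    identity=ident,
                    coverage=cov,
                )
            )
    return hits


def assign_coi(asv_id: str, hits: list[ReferenceHit]) -> SpeciesAssignment:
    """COI rule: >=2 independent references of one species above 97/100, no
    competing species at >=97% identity."""
    by_species: dict[str, list[ReferenceHit]] = {}
    for h in hits:
        by_species.setdefault(h.species, []).append(h)

    candidates = []
    for species, sp_hits in by_species.items():
        strong = {
            h.reference_id for h in sp_hits if h.identity > 97.0 and h.coverage == 100.0
        }
        if len(strong) >= 2:
            candidates.append(species)

    for species in sorted(candidates):
        competitors = [
            h for h in hits if h.species != species and h.identity >= 97.0
        ]
        if competitors:
            return SpeciesAssignment(
                asv_id=asv_id,
                status="ambiguous",
                rule="COI",
                evidence=sorted(
                    competitors, key=lambda h: -h.identity
                ),
                flags=[f"competing species within 97%: {competitors[0].species}"],
            )
        return SpeciesAssignment(
            asv_id=asv_id,
            status="assigned",
            species=species,
            rule="COI",
            evidence=[h for h in by_species[species] if h.identity > 97.0],
        )
    return SpeciesAssignment(asv_id=asv_id, status="unassigned", rule="COI")


def assign_18s(asv_id: str, hits: list[ReferenceHit]) -> SpeciesAssignment:
    """18S rule: exact 100/100 match plus >=1 bp distance to every congener."""
    exact = [h for h in hits if h.identity == 100.0 and h.coverage == 100.0]
    if not exact:
        return SpeciesAssignment(asv_id=asv_id, status="unassigned", rule="18S")
    species = exact[0].species
    congeners = [
        h for h in hits if h.species != species and h.genus == exact[0].genus
    ]
    identical_congener = [h for h in congeners if h.identity == 100.0 and h.coverage == 100.0]
    if identical_congener:
        return SpeciesAssignment(
            asv_id=asv_id,
            status="unassigned",
            rule="18S",
            flags=[f"identical congener: {identical_congener[0].species}"],
        )
    flags = [] if congeners else ["no congener check possible"]
    return SpeciesAssignment(
        asv_id=asv_id,
        status="assigned",
        species=species,
        rule="18S",
        evidence=exact,
        flags=flags,
    )


def assign_all(
    asv_sequences: dict[str, str],
    references: list[tuple[str, str]],
    taxonomy_map: pd.DataFrame,
    marker: str = "COI",
) -> dict[str, SpeciesAssignment]:
    hits = compute_hits(asv_sequences, references, taxonomy_map)
    rule = assign_coi if marker.upper() == "COI" else assign_18s
    return {a: rule(a, h) for a, h in hits.items()}


def merge_by_species(
    site_props: pd.DataFrame, assignments: dict[str, SpeciesAssignment]
) -> pd.DataFrame:
    """Sum relative read abundance of same-species ASVs per site.

    Unassigned and ambiguous ASVs are excluded.  The input ASV-level table
    is left untouched for haplotype-level analyses.
    """
    missing = set(site_props.index) - set(assignments)
    if missing:
        raise ValueError(f"assignments missing for ASVs: {sorted(missing)}")
    species_of = {
        a: assignments[a].species
        for a in site_props.index
        if assignments[a].status == "assigned"
    }
    assigned = site_props.loc[list(species_of)]
    if assigned.empty:
        return pd.DataFrame(columns=site_props.columns)
    return assigned.groupby(pd.Series(species_of)).sum()


def assignments_to_frame(assignments: dict[str, SpeciesAssignment]) -> pd.DataFrame:
    rows = [
        {
            "asv_id": a.asv_id,
            "status": a.status,
            "species": a.species,
            "rule": a.rule,
            "n_supporting_hits": len(a.evidence),
            "flags": ";".join(a.flags),
        }
        for a in assignments.values()
    ]
    return pd.DataFrame(rows).set_index("asv_id")
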