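"""Ploidy estimation, multilocus-genotype (MLG) indexing and clonal diversity.

Samples with identical allelic phenotypes at every locus are putative clones
and receive the same MLG index. Two indices are kept: a *global* index, under
which identical phenotypes match regardless of provenance, and a *per-unit*
index, under which identical phenotypes from different (site, species) units
are treated as distinct genotypes. Clonal richness R = (G-1)/(N-1), Shannon
diversity H and Pielou evenness E = H/ln(G) summarize clonality per group.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import logging

from .genotype_io import LocusPanel, SampleRecord

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

#: Sections whose members typically carry one duplicated (bivalent) allele,
#: so apparent allele counts understate ploidy by one.
CANINAE_SECTION = "Caninae"

GROUP_KEYS = {
    "site": lambda r: r.site_id,
    "species": lambda r: r.species,
    "subsection": lambda r: r.subsection or "",
    "section": lambda r: r.section,
}


class ClonalityError(ValueError):
    pass


@dataclass(frozen=True)
class MLGAssignment:
    """Dual MLG indexing: dense integer ids in first-appearance order."""

    global_ids: Mapping[str, int]
    per_unit_ids: Mapping[str, int]

    def n_global(self) -> int:
        return len(set(self.global_ids.values()))

    def n_per_unit(self) -> int:
        return len(set(self.per_unit_ids.values()))


@dataclass
class ClonalitySummary:
    group: str
    n: int
    g: int
    sg: int
    r: float | None
    h: float
    e: float | None


@dataclass
class SharedMLGRecord:
    mlg_id: int
    n_samples: int
    site_ids: tuple[str, ...]
    species: tuple[str, ...]
    max_pairwise_distance_km: float


def estimate_ploidy(record: SampleRecord, panel: LocusPanel) -> int:
    """Ploidy estimate for one sample.

    A measured value (e.g. flow cytometry) takes precedence. Otherwise the
    maximum number of distinct alleles across loci is used, plus one for
    section Caninae samples (which typically carry at least one allele in two
    copies), floored at 2.
    """
    if record.ploidy_measured is not None:
        return record.ploidy_measured
    counts = [len(record.phenotype[locus]) for locus in panel.locus_ids
              if record.phenotype.get(locus)]
    if not counts:
        raise ClonalityError(f"sample {record.sample_id}: all loci missing")
    estimate = max(counts)
    if record.section == CANINAE_SECTION:
        estimate += 1
    return max(estimate, 2)


def estimate_ploidies(records: Iterable[SampleRecord],
                      panel: LocusPanel) -> dict[str, int]:
    return {r.sample_id: estimate_ploidy(r, panel) for r in records}


def index_mlgs(records: Sequence[SampleRecord],
               panel: LocusPanel | None = None) -> MLGAssignment:
    """Assign global and per-(site, species) MLG ids.

    Missing loci are a distinct token: profiles match only when their missing
    patterns are identical too. Ids are dense and deterministic given input
    order (first appearance).
    """
    locus_order = panel.locus_ids if panel is not None else tuple(
        sorted({locus for r in records for locus in r.phenotype}))
    global_ids: dict[str, int] = {}
    per_unit_ids: dict[str, int] = {}
    seen_global: dict[tuple, int] = {}
    seen_unit: dict[tuple, int] = {}
    for r in records:
        key = r.mlg_key(locus_order)
        global_ids[r.sample_id] = seen_global.setdefault(key, len(seen_global))
        unit_key = (r.site_id, r.species, key)
        per_unit_ids[r.sample_id] = seen_unit.setdefault(unit_key, len(seen_unit))
    return MLGAssignment(global_ids=global_ids, per_unit_ids=per_unit_ids)


def clonal_richness(g: int, n: int) -> float | None:
    """R = (G-1)/(N-1); undefined (None) for single-sample groups."""
    if g > n:
        raise ClonalityError(f"G={g} exceeds N={n}")
    if g < 1 or n < 1:
        raise ClonalityError("G and N must be >= 1")
    if n == 1:
        return None
    return (g - 1) / (n - 1)


def diversity_indices(mlg_counts: Sequence[int]) -> tuple[float, float | None]:
    """Shannon H (natural log) over MLG frequencies and Pielou E = H/ln G."""
    counts = [int(c) for c in mlg_counts]
    if not counts:
        raise ClonalityError("empty count vector")
    if any(c <= 0 for c in counts):
        raise ClonalityError("counts must be positive")
    n = sum(counts)
    h = -sum((c / n) * math.log(c / n) for c in counts)
    g = len(counts)
    e = h / math.log(g) if g > 1 else None
    return h, e


def summarize_clonality(records: Sequence[SampleRecord],
                        assignment: MLGAssignment,
                        group_by: str) -> list[ClonalitySummary]:
    """Per-group N, G, sG, R, H, E.

    Per-site summaries use the global index (clones spanning sites count
    once); all other groupings use the per-unit index, so identical
    phenotypes from different sites/species count as distinct genotypes.
    """
    if group_by not in GROUP_KEYS:
        raise ClonalityError(f"unknown grouping key {group_by!r}; "
                             f"expected one of {sorted(GROUP_KEYS)}")
    key_of = GROUP_KEYS[group_by]
    groups: dict[str, list[SampleRecord]] = defaultdict(list)
    for r in records:
        groups[key_of(r)].append(r)
    use_global = group_by == "site"
    summaries = []
    for label in sorted(groups):
        members = groups[label]
        n = len(members)
        gids = [assignment.global_ids[r.sample_id] for r in members]
        uids = [assignment.per_unit_ids[r.sample_id] for r in members]
        g, sg = len(set(gids)), len(set(uids))
        used = gids if use_global else uids
        counts = list(Counter(used).values())
        h, e = diversity_indices(counts)
        summaries.append(ClonalitySummary(
            group=label, n=n, g=g, sg=sg,
            r=clonal_richness(len(set(used)), n), h=h, e=e))
    return summaries


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance on a sphere of mean Earth radius 6371.0 km."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def shared_mlg_geography(records: Sequence[SampleRecord],
                         assignment: MLGAssignment) -> list[SharedMLGRecord]:
    """For every global MLG found at >= 2 sites: its sites, species and the
    maximum great-circle distance between carrier samples.

    Samples without coordinates are skipped from the distance (with a logged
    warning) but still counted towards sites.
    """
    by_mlg: dict[int, list[SampleRecord]] = defaultdict(list)
    for r in records:
        by_mlg[assignment.global_ids[r.sample_id]].append(r)
    out = []
    for mlg_id in sorted(by_mlg):
        members = by_mlg[mlg_id]
        sites = tuple(sorted({r.site_id for r in members}))
        if len(sites) < 2:
            continue
        located = [r for r in members if r.latitude is not None and r.longitude is not None]
        if len(located) < len(members):
            log.warning("MLG %d: %d sample(s) without coordinates skipped",
                        mlg_id, len(members) - len(located))
        max_d = 0.0
        for i in range(len(located)):
            for j in range(i + 1, len(located)):
                a, b = located[i], located[j]
                max_d = max(max_d, haversine_km(a.latitude, a.longitude,
                                                b.latitude, b.longitude))
        out.append(SharedMLGRecord(
            mlg_id=mlg_id, n_samples=len(members), site_ids=sites,
            species=tuple(sorted({r.species for r in members})),
            max_pairwise_distance_km=max_d))
    return out
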