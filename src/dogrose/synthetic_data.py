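"""Forward simulator of hemisexual canina meiosis with planted truth.

Dogrose meiosis is asymmetric: of m chromosome sets, two pair as bivalents
and recombine sexually (one transmitted via the egg, one via the pollen),
while the remaining u = m - 2 univalent sets pass intact through the egg
only. The simulator plants, per lineage and locus, a fixed set of u
univalent alleles and a bivalent allele pool with one allele near fixation,
then transmits genomes forward with stepwise mutation, optional vegetative
cloning, selfing, and phenotype-level null alleles. The emitted allelic
phenotypes have the statistical structure the analysis modules assume, and
the planted truth makes every pipeline stage testable end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genotype_io import LocusPanel, SampleRecord, write_genotype_table
from .mfac import GroupSpec, MFACReport, Thresholds, analyze_mfac


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class LineageSpec:
    """Planted truth for one evolutionary lineage.

    ``univalent_alleles[locus]`` holds the u = ploidy - 2 clonally transmitted
    allele sizes; ``bivalent_pool[locus]`` maps allele size to its founding
    frequency (sums to 1), with one allele near fixation by default.
    """

    lineage_id: str
    subsection: str
    ploidy: int
    univalent_alleles: Mapping[str, tuple[int, ...]]
    bivalent_pool: Mapping[str, Mapping[int, float]]

    def __post_init__(self):
        if self.ploidy not in (4, 5, 6):
            raise SimulationError(f"ploidy {self.ploidy} outside {{4,5,6}}")
        u = self.ploidy - 2
        for locus, alleles in self.univalent_alleles.items():
            if len(alleles) != u:
                raise SimulationError(
                    f"lineage {self.lineage_id}, locus {locus}: expected {u} "
                    f"univalent alleles, got {len(alleles)}")
            if any(a <= 0 for a in alleles):
                raise SimulationError("univalent alleles must be positive")
        for locus, pool in self.bivalent_pool.items():
            total = sum(pool.values())
            if abs(total - 1.0) > 1e-9:
                raise SimulationError(
                    f"lineage {self.lineage_id}, locus {locus}: bivalent "
                    f"frequencies sum to {total}, not 1")

    @property
    def n_univalent(self) -> int:
        return self.ploidy - 2


@dataclass
class SimulationConfig:
    """Study conditions for one simulated survey.

    Defaults emulate a scaled-down multi-site European survey of the four
    tetra-/pentaploid dogrose analysis groups: several sites, a couple dozen
    plants per lineage and site, modest vegetative clonality and selfing,
    small stepwise mutation and null-allele rates, and flow-cytometry ploidy
    available for roughly a third of samples.
    """

    lineages: tuple[LineageSpec, ...]
    n_sites: int = 6
    samples_per_site: int = 25            # per lineage, final sample
    generations: int = 10
    founders_per_site: int = 5            # per lineage
    mu_univalent: float = 1e-3            # stepwise rate per allele per transmission
    mu_bivalent: float = 1e-3
    null_allele_p: float = 0.01           # per genome copy per locus at phenotyping
    clonal_p: float = 0.1                 # probability an offspring is a clone
    selfing_p: float = 0.1
    measured_ploidy_fraction: float = 0.36
    allow_two_step: bool = False          # also permit +-2 motif mutation steps
    seed: int = 0
    site_coords: tuple[tuple[float, float], ...] | None = None
    bbox: tuple[float, float, float, float] = (40.0, 60.0, -5.0, 25.0)

    def __post_init__(self):
        for name in ("mu_univalent", "mu_bivalent", "null_allele_p",
                     "clonal_p", "selfing_p", "measured_ploidy_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")
        if self.generations < 1:
            raise SimulationError("generations must be >= 1")
        if self.n_sites < 1 or self.samples_per_site < 1:
            raise SimulationError("need at least one site and one sample")


@dataclass
class SimulatedPopulation:
    records: list[SampleRecord]
    truth_genomes: dict[str, dict[str, tuple[int, ...]]]  # sample -> locus -> m alleles
    truth_lineage: dict[str, str]                         # sample -> lineage_id
    lineages: tuple[LineageSpec, ...]
    config: SimulationConfig


def make_lineage_spec(lineage_id: str, subsection: str, ploidy: int,
                      panel: LocusPanel, rng: np.random.Generator,
                      f_b: float = 0.9, n_minor: int = 2,
                      forbidden: Mapping[str, set[int]] | None = None,
                      bivalent_pool: Mapping[str, Mapping[int, float]] | None = None,
                      ) -> LineageSpec:
    """Draw a lineage's planted univalent set and bivalent pool per locus.

    Allele sizes sit on the locus' motif lattice so stepwise mutation stays
    in-register. ``forbidden`` excludes sizes already used (e.g. by other
    lineages, to plant disjoint sets); a shared ``bivalent_pool`` may be
    passed in instead of drawing one.
    """
    u = ploidy - 2
    univalents: dict[str, tuple[int, ...]] = {}
    pools: dict[str, dict[int, float]] = {}
    for idx, locus in enumerate(panel.locus_ids):
        motif = panel.motif(locus)
        lattice = 120 + 3 * idx + motif * np.arange(60)
        avoid = set(forbidden.get(locus, set())) if forbidden else set()
        if bivalent_pool is not None:
            avoid |= set(bivalent_pool[locus])
        candidates = [int(a) for a in lattice if int(a) not in avoid]
        need = u if bivalent_pool is not None else u + 1 + n_minor
        drawn = rng.choice(len(candidates), size=need, replace=False)
        sizes = [candidates[i] for i in drawn]
        univalents[locus] = tuple(sorted(sizes[:u]))
        if bivalent_pool is None:
            dom, minors = sizes[u], sizes[u + 1:]
            pool = {dom: f_b}
            for mnr in minors:
                pool[mnr] = (1.0 - f_b) / len(minors)
            pools[locus] = pool
        else:
            pools[locus] = dict(bivalent_pool[locus])
    return LineageSpec(lineage_id=lineage_id, subsection=subsection,
                       ploidy=ploidy, univalent_alleles=univalents,
                       bivalent_pool=pools)


def default_lineages(panel: LocusPanel, rng: np.random.Generator,
                     f_b: float = 0.9) -> tuple[LineageSpec, ...]:
    """The four study lineages: Caninae 5x, Rubigineae 5x, Vestitae 5x/4x.

    Univalent sets are planted disjoint across lineages (the lineage-specific
    co-inherited sets the analysis looks for); the bivalent pool is shared
    across lineages, mirroring alleles frequently present in all subsections.
    """
    shared_rng = np.random.default_rng(rng.integers(2 ** 31))
    shared_pool: dict[str, dict[int, float]] = {}
    for idx, locus in enumerate(panel.locus_ids):
        motif = panel.motif(locus)
        lattice = 120 + 3 * idx + motif * np.arange(60)
        drawn = shared_rng.choice(60, size=3, replace=False)
        dom, m1, m2 = (int(lattice[i]) for i in drawn)
        shared_pool[locus] = {dom: f_b, m1: (1 - f_b) / 2, m2: (1 - f_b) / 2}
    defs = (("Caninae_5x", "Caninae", 5), ("Rubigineae_5x", "Rubigineae", 5),
            ("Vestitae_5x", "Vestitae", 5), ("Vestitae_4x", "Vestitae", 4))
    forbidden: dict[str, set[int]] = {locus: set(pool)
                                      for locus, pool in shared_pool.items()}
    lineages = []
    for lineage_id, subsection, ploidy in defs:
        spec = make_lineage_spec(lineage_id, subsection, ploidy, panel, rng,
                                 f_b=f_b, forbidden=forbidden,
                                 bivalent_pool=shared_pool)
        for locus, alleles in spec.univalent_alleles.items():
            forbidden[locus].update(alleles)
        lineages.append(spec)
    return tuple(lineages)


def default_config(seed: int = 0, panel: LocusPanel | None = None,
                   **overrides) -> SimulationConfig:
    panel = panel or LocusPanel()
    rng = np.random.default_rng(seed)
    lineages = default_lineages(panel, rng)
    return SimulationConfig(lineages=lineages, seed=seed, **overrides)


def _mutate(rng, alleles: np.ndarray, rate: float, motifs: np.ndarray,
            allow_two_step: bool) -> np.ndarray:
    """Stepwise mutation: +-1 motif unit (optionally +-2) with equal sign odds."""
    if rate <= 0:
        return alleles
    mask = rng.random(alleles.shape) < rate
    signs = rng.choice((-1, 1), size=alleles.shape)
    steps = rng.choice((1, 2), size=alleles.shape) if allow_two_step \
        else np.ones(alleles.shape, dtype=int)
    return alleles + mask * signs * steps * motifs


def simulate_population(config: SimulationConfig,
                        panel: LocusPanel | None = None) -> SimulatedPopulation:
    """Run the forward simulation and emit phenotyped sample records.

    Per site and lineage, a constant-size population is seeded from a few
    founders and propagated for the configured number of generations; each
    offspring is either an exact clone of its mother (probability
    ``clonal_p``) or sexual: it inherits the mother's univalent genomes
    (stepwise-mutated at ``mu_univalent``), one maternal and one paternal
    bivalent allele (father random within site and lineage, or the mother
    with probability ``selfing_p``; mutated at ``mu_bivalent``). The final
    generation is phenotyped with per-copy null-allele dropout. Fully
    deterministic under a fixed seed.
    """
    panel = panel or LocusPanel()
    rng = np.random.default_rng(config.seed)
    loci = panel.locus_ids
    motifs = np.array([panel.motif(l) for l in loci])

    if config.site_coords is not None:
        if len(config.site_coords) != config.n_sites:
            raise SimulationError("site_coords length != n_sites")
        coords = [tuple(c) for c in config.site_coords]
    else:
        lat0, lat1, lon0, lon1 = config.bbox
        coords = [(float(rng.uniform(lat0, lat1)), float(rng.uniform(lon0, lon1)))
                  for _ in range(config.n_sites)]

    records: list[SampleRecord] = []
    truth_genomes: dict[str, dict[str, tuple[int, ...]]] = {}
    truth_lineage: dict[str, str] = {}

    for site_idx in range(config.n_sites):
        site_id = f"S{site_idx + 1:02d}"
        lat, lon = coords[site_idx]
        for spec in config.lineages:
            m, u = spec.ploidy, spec.n_univalent
            n = config.samples_per_site
            n_f = config.founders_per_site
            L = len(loci)
            genomes = np.empty((n, m, L), dtype=np.int64)
            for li, locus in enumerate(loci):
                genomes[:, :u, li] = np.asarray(spec.univalent_alleles[locus])
                pool = spec.bivalent_pool[locus]
                sizes = np.array(list(pool))
                probs = np.array([pool[a] for a in sizes])
                founder_biv = rng.choice(sizes, size=(n_f, 2), p=probs)
                reps = -(-n // n_f)  # founders tiled to population size
                genomes[:, u:, li] = np.tile(founder_biv, (reps, 1))[:n]

            for _ in range(config.generations):
                mothers = rng.integers(0, n, n)
                offspring = genomes[mothers].copy()
                sexual = rng.random(n) >= config.clonal_p
                # univalents: maternal, mutation-only
                mutated_u = _mutate(rng, offspring[:, :u, :],
                                    config.mu_univalent,
                                    motifs[None, None, :], config.allow_two_step)
                offspring[sexual, :u, :] = mutated_u[sexual]
                # bivalents: one maternal + one paternal allele
                mat_slot = u + rng.integers(0, 2, n)
                mat = genomes[mothers, mat_slot, :]
                fathers = np.where(rng.random(n) < config.selfing_p,
                                   mothers, rng.integers(0, n, n))
                pat_slot = u + rng.integers(0, 2, n)
                pat = genomes[fathers, pat_slot, :]
                mat = _mutate(rng, mat, config.mu_bivalent, motifs[None, :],
                              config.allow_two_step)
                pat = _mutate(rng, pat, config.mu_bivalent, motifs[None, :],
                              config.allow_two_step)
                offspring[sexual, u, :] = mat[sexual]
                offspring[sexual, u + 1, :] = pat[sexual]
                genomes = offspring

            null_mask = rng.random(genomes.shape) < config.null_allele_p
            measured = rng.random(n) < config.measured_ploidy_fraction
            for i in range(n):
                sid = f"SIM-{site_id}-{spec.lineage_id}-{i:03d}"
                phenotype: dict[str, tuple[int, ...] | None] = {}
                truth: dict[str, tuple[int, ...]] = {}
                for li, locus in enumerate(loci):
                    copies = genomes[i, :, li]
                    truth[locus] = tuple(int(a) for a in copies)
                    kept = copies[~null_mask[i, :, li]]
                    phenotype[locus] = (tuple(sorted(set(int(a) for a in kept)))
                                        if kept.size else None)
                records.append(SampleRecord(
                    sample_id=sid, dataset_tag="SIM",
                    species=f"sim_{spec.lineage_id}", section="Caninae",
                    subsection=spec.subsection, site_id=site_id,
                    latitude=lat, longitude=lon,
                    ploidy_measured=m if measured[i] else None,
                    phenotype=phenotype))
                truth_genomes[sid] = truth
                truth_lineage[sid] = spec.lineage_id
    return SimulatedPopulation(records=records, truth_genomes=truth_genomes,
                               truth_lineage=truth_lineage,
                               lineages=config.lineages, config=config)


@dataclass
class RecoveryRow:
    lineage_id: str
    locus: str
    planted: tuple[int, ...]
    detected: tuple[int, ...] | None
    category: str
    contains_planted: bool
    equals_planted: bool


@dataclass
class RecoveryReport:
    rows: list[RecoveryRow]
    recovery_fraction: float            # share of locus x lineage cells where
    planted_containment: float          # the detected MFAC contains the planted
    reports: list[MFACReport] = field(default_factory=list)


def truth_recovery_report(pop: SimulatedPopulation,
                          panel: LocusPanel | None = None,
                          thresholds: Thresholds | None = None,
                          ks: Sequence[int] = (2, 3, 4)) -> RecoveryReport:
    """Validate MFAC detection against the simulator's planted truth.

    Samples are grouped by their *true* lineage (from the truth tables, so
    recovery measures the detector given correct lineage assignment, not the
    ploidy-estimation step), the MFAC pipeline is run per lineage, and each
    locus×lineage cell is scored for whether the detected MFAC contains /
    equals the planted univalent set. ``planted_containment`` is the overall
    fraction of phenotypes that contain their lineage's planted set.
    """
    panel = panel or LocusPanel()
    by_lineage: dict[str, list[str]] = {spec.lineage_id: []
                                        for spec in pop.lineages}
    for sid, lin in pop.truth_lineage.items():
        by_lineage[lin].append(sid)
    specs = {spec.lineage_id: spec for spec in pop.lineages}
    groups = [GroupSpec(label=lin, subsection=specs[lin].subsection,
                        ploidy=specs[lin].ploidy,
                        sample_ids=tuple(sorted(sids)))
              for lin, sids in by_lineage.items() if sids]
    ploidies = {sid: specs[lin].ploidy for sid, lin in pop.truth_lineage.items()}
    reports = analyze_mfac(pop.records, panel, ploidies=ploidies,
                           groups=groups, ks=ks, thresholds=thresholds)

    rows = []
    for rep in reports:
        planted = set(specs[rep.group].univalent_alleles[rep.locus])
        detected = set(rep.mfac) if rep.mfac else set()
        rows.append(RecoveryRow(
            lineage_id=rep.group, locus=rep.locus,
            planted=tuple(sorted(planted)), detected=rep.mfac,
            category=rep.category,
            contains_planted=planted <= detected,
            equals_planted=planted == detected))
    recovery = (sum(r.contains_planted for r in rows) / len(rows)) if rows else 0.0

    by_id = {r.sample_id: r for r in pop.records}
    hits = total = 0
    for sid, lin in pop.truth_lineage.items():
        spec = specs[lin]
        for locus in panel.locus_ids:
            ph = by_id[sid].phenotype.get(locus)
            total += 1
            if ph is not None and set(spec.univalent_alleles[locus]) <= set(ph):
                hits += 1
    return RecoveryReport(rows=rows, recovery_fraction=recovery,
                          planted_containment=hits / total if total else 0.0,
                          reports=reports)


def write_simulation(pop: SimulatedPopulation, outdir: str | Path,
                     panel: LocusPanel | None = None) -> None:
    """Emit genotypes.tsv (genotype dialect), truth_genomes.tsv and
    truth_lineages.json."""
    panel = panel or LocusPanel()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genotype_table(pop.records, outdir / "genotypes.tsv", panel)
    with (outdir / "truth_genomes.tsv").open("w", encoding="utf-8") as fh:
        fh.write("sample_id\tlineage\t" + "\t".join(panel.locus_ids) + "\n")
        for sid in sorted(pop.truth_genomes):
            cells = ["|".join(map(str, pop.truth_genomes[sid][l]))
                     for l in panel.locus_ids]
            fh.write(sid + "\t" + pop.truth_lineage[sid] + "\t"
                     + "\t".join(cells) + "\n")
    payload = []
    for spec in pop.lineages:
        payload.append({
            "lineage_id": spec.lineage_id, "subsection": spec.subsection,
            "ploidy": spec.ploidy,
            "univalent_alleles": {l: list(v)
                                  for l, v in spec.univalent_alleles.items()},
            "bivalent_pool": {l: {str(a): f for a, f in p.items()}
                              for l, p in spec.bivalent_pool.items()},
        })
    with (outdir / "truth_lineages.json").open("w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
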