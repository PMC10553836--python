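"""Most frequent allele combinations (MFACs) per locus and sample group.

Under canina meiosis the univalent chromosome sets pass clonally through the
egg, so the alleles they carry should travel as a fixed *set*: in a group of
pentaploid (tetraploid) dogroses we expect a combination of four (three)
alleles per locus — the univalent alleles plus a near-fixed bivalent allele —
that is carried by most samples. This module ranks size-k allele
combinations by carrier frequency (a sample carries S iff its phenotype
contains S), tests the top candidate against a random-mating null (binomial
test with an inclusion–exclusion carrier probability) and for
group-specificity (hypergeometric test), links combinations differing by one
allele into networks, and sorts each locus×group into the categories
A / B / BC / C.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy import stats

from .genotype_io import LocusPanel, SampleRecord

log = logging.getLogger(__name__)


class MFACError(ValueError):
    pass


#: Default analysis groups: subsection × estimated-ploidy class. Hexaploid and
#: higher samples are excluded (frequent inter-subsection hybrids); only the
#: morphologically heterogeneous Vestitae are split by ploidy.
DEFAULT_GROUP_DEFS = (
    ("Caninae_5x", "Caninae", 5),
    ("Rubigineae_5x", "Rubigineae", 5),
    ("Vestitae_5x", "Vestitae", 5),
    ("Vestitae_4x", "Vestitae", 4),
)

CATEGORIES = ("A", "B", "BC", "C")


@dataclass
class Thresholds:
    """Tunable decision thresholds for MFAC categorization and marking."""

    freq_threshold: float = 0.2     # minimum f(MFAC) to call a dominant set
    fade_threshold: float = 0.2     # below this the network plot is faded
    near_equal_rel: float = 0.10    # ties within 10% relative frequency
    cf_threshold: float = 0.5       # "most samples show ploidy-1 alleles"
    alpha: float = 0.001            # binomial significance for categorization
    degree_alpha: float = 0.01      # hypergeometric specificity mark
    bonferroni: bool = False        # optional correction across locus×groups
    n_tests: int = 28


@dataclass
class GroupSpec:
    label: str
    subsection: str
    ploidy: int
    sample_ids: tuple[str, ...]


@dataclass
class AlleleFrequencyEntry:
    locus: str
    n: int                               # samples scored at the locus
    prevalence: dict[int, float]         # fraction of samples carrying allele
    relative_frequency: dict[int, float]  # allele share of all observations


@dataclass
class AlleleCombination:
    locus: str
    alleles: tuple[int, ...]
    carriers: int
    n: int

    @property
    def k(self) -> int:
        return len(self.alleles)

    @property
    def frequency(self) -> float:
        return self.carriers / self.n


@dataclass
class CombinationNetwork:
    locus: str
    k: int
    combinations: tuple[AlleleCombination, ...]   # decreasing frequency
    edges: tuple[tuple[int, int], ...]            # node-index pairs
    node_sizes: tuple[float, ...]                 # f / f(MFAC)
    positions: tuple[tuple[float, float], ...]    # counter-clockwise layout
    fade: bool

    def to_networkx(self):
        import networkx as nx
        g = nx.Graph()
        for i, combo in enumerate(self.combinations):
            g.add_node(i, alleles=",".join(map(str, combo.alleles)),
                       frequency=combo.frequency, size=self.node_sizes[i],
                       x=self.positions[i][0], y=self.positions[i][1])
        g.add_edges_from(self.edges)
        return g


@dataclass
class MFACReport:
    group: str
    locus: str
    ploidy: int
    n: int
    top_by_k: dict[int, list[AlleleCombination]]
    mfac: tuple[int, ...] | None
    ana: int | None                      # apparent number of alleles in MFAC
    cf_ana: float | None                 # fraction of samples with >= ANA alleles
    f_mfac: float | None
    p_binomial: float | None
    p_hypergeometric: float | None
    stars: str
    degree: bool
    category: str
    rule: str = ""
    specific: bool = False               # MFAC found in no other group's MFAC

    def marks(self) -> str:
        return self.stars + ("°" if self.degree else "")


def filter_mfac_groups(records: Sequence[SampleRecord],
                       ploidies: Mapping[str, int],
                       group_defs: Sequence[tuple[str, str, int]] = DEFAULT_GROUP_DEFS,
                       dedup_mlg: bool = False,
                       panel: LocusPanel | None = None) -> list[GroupSpec]:
    """Assign tetra-/pentaploid samples to subsection×ploidy groups.

    ``dedup_mlg=True`` keeps one copy of each phenotype per (species, site),
    removing local clonal amplification; the default keeps all samples.
    """
    pool = list(records)
    if dedup_mlg:
        locus_order = panel.locus_ids if panel else tuple(
            sorted({locus for r in records for locus in r.phenotype}))
        seen: set[tuple] = set()
        deduped = []
        for r in pool:
            key = (r.species, r.site_id, r.mlg_key(locus_order))
            if key not in seen:
                seen.add(key)
                deduped.append(r)
        pool = deduped
    groups = []
    for label, subsection, ploidy in group_defs:
        members = tuple(r.sample_id for r in pool
                        if r.subsection == subsection
                        and ploidies.get(r.sample_id) == ploidy)
        if not members:
            log.warning("MFAC group %s is empty and will be skipped", label)
        groups.append(GroupSpec(label=label, subsection=subsection,
                                ploidy=ploidy, sample_ids=members))
    return groups


def _group_phenotypes(records_by_id: Mapping[str, SampleRecord],
                      group: GroupSpec, locus: str) -> list[tuple[int, ...]]:
    out = []
    for sid in group.sample_ids:
        alleles = records_by_id[sid].phenotype.get(locus)
        if alleles:
            out.append(alleles)
    return out


def allele_stats(phenotypes: Sequence[tuple[int, ...]],
                 locus: str) -> AlleleFrequencyEntry:
    """Allele prevalence and relative frequency at one locus.

    Each sample contributes each of its distinct alleles once; dosage is
    unknown, so relative frequencies are 'apparent' proportions among all
    detected alleles.
    """
    if not phenotypes:
        raise MFACError(f"no samples scored at locus {locus}")
    n = len(phenotypes)
    counts: Counter[int] = Counter()
    for ph in phenotypes:
        counts.update(ph)
    total = sum(counts.values())
    return AlleleFrequencyEntry(
        locus=locus, n=n,
        prevalence={a: c / n for a, c in sorted(counts.items())},
        relative_frequency={a: c / total for a, c in sorted(counts.items())})


def apparent_allele_counts(phenotypes: Sequence[tuple[int, ...]]) -> dict:
    """Distribution of per-sample distinct-allele counts, cf(m) and the median.

    cf(m) is the fraction of samples showing at least m alleles.
    """
    counts = sorted(len(ph) for ph in phenotypes)
    n = len(counts)
    dist = Counter(counts)
    max_k = counts[-1] if counts else 0

    def cf(m: int) -> float:
        if n == 0:
            return 0.0
        return sum(1 for c in counts if c >= m) / n

    median = float(stats.scoreatpercentile(counts, 50)) if counts else float("nan")
    return {"distribution": dict(dist), "cf": cf, "median": median, "max": max_k}


def combination_frequencies(phenotypes: Sequence[tuple[int, ...]], locus: str,
                            k: int, top: int = 10,
                            exact_match: bool = False) -> list[AlleleCombination]:
    """Top (<= `top`) size-k allele combinations by carrier count.

    A sample carries S iff its phenotype contains S (containment semantics;
    ``exact_match=True`` counts only phenotypes equal to S). Ties rank the
    lexicographically smaller allele set first.
    """
    if k < 1:
        raise MFACError("k must be >= 1")
    n = len(phenotypes)
    counter: Counter[tuple[int, ...]] = Counter()
    for ph in phenotypes:
        if exact_match:
            if len(ph) == k:
                counter[ph] += 1
        else:
            for combo in itertools.combinations(ph, k):
                counter[combo] += 1
    ranked = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))[:top]
    return [AlleleCombination(locus=locus, alleles=alleles, carriers=c, n=n)
            for alleles, c in ranked]


def null_carrier_probability(alleles: Sequence[int],
                             relative_frequency: Mapping[int, float],
                             ploidy: int) -> float:
    """P(a random size-m allele multiset contains every allele of S).

    The null draws m = ploidy alleles iid from the relative allele
    frequencies — the carrier probability of S at Hardy–Weinberg equilibrium
    under fully sexual polysomic inheritance, duplicates modelling hidden
    same-length alleles. Computed by inclusion–exclusion:
    p0 = sum_{T subseteq S} (-1)^|T| (1 - sum_{a in T} p_a)^m.
    """
    s = tuple(alleles)
    if len(s) > ploidy:
        raise MFACError(f"|S|={len(s)} exceeds ploidy {ploidy}")
    missing = [a for a in s if a not in relative_frequency]
    if missing:
        raise MFACError(f"allele(s) {missing} absent from frequency table")
    p0 = 0.0
    for r in range(len(s) + 1):
        for subset in itertools.combinations(s, r):
            rest = 1.0 - sum(relative_frequency[a] for a in subset)
            p0 += (-1) ** r * rest ** ploidy
    return min(max(p0, 0.0), 1.0)


def mfac_binomial_test(combo: AlleleCombination,
                       freq: AlleleFrequencyEntry,
                       ploidy: int) -> float:
    """Upper-tail binomial p-value: observed carriers vs the random-draw null."""
    p0 = null_carrier_probability(combo.alleles, freq.relative_frequency, ploidy)
    return float(stats.binom.sf(combo.carriers - 1, combo.n, p0))


def mfac_specificity_test(focal_carriers: int, focal_n: int,
                          pooled_carriers: int, pooled_n: int) -> float:
    """Upper-tail hypergeometric p-value for group specificity.

    With N pooled samples of which K carry S, the probability that a group of
    n samples contains >= x carriers when carriers are distributed without
    replacement; group sizes enter through n and N, which realizes the
    sample-size weighting of the comparison against the pooled mean.
    """
    if focal_carriers > pooled_carriers or focal_n > pooled_n:
        raise MFACError("focal counts exceed pooled counts")
    if pooled_carriers == 0:
        return 1.0
    return float(stats.hypergeom.sf(focal_carriers - 1, pooled_n,
                                    pooled_carriers, focal_n))


def build_network(ranked: Sequence[AlleleCombination],
                  fade_threshold: float = 0.2) -> CombinationNetwork:
    """Network of up to 10 equal-k combinations; edges join combinations
    sharing k-1 alleles (one allele exchanged, no mutation-model assumption).

    Nodes are laid out counter-clockwise from the top with decreasing
    frequency; node size is frequency relative to the MFAC.
    """
    combos = tuple(ranked)
    if not combos:
        raise MFACError("no combinations to build a network from")
    if len(combos) > 10:
        raise MFACError("network holds at most 10 combinations")
    ks = {c.k for c in combos}
    if len(ks) > 1:
        raise MFACError(f"mixed combination sizes {sorted(ks)} in one network")
    k = ks.pop()
    for a, b in zip(combos, combos[1:]):
        if a.carriers < b.carriers:
            raise MFACError("combinations must be ordered by decreasing frequency")
    edges = tuple(
        (i, j) for i in range(len(combos)) for j in range(i + 1, len(combos))
        if len(set(combos[i].alleles) & set(combos[j].alleles)) == k - 1)
    f_max = combos[0].frequency
    sizes = tuple(c.frequency / f_max for c in combos)
    n = len(combos)
    positions = tuple(
        (math.cos(math.pi / 2 + 2 * math.pi * i / n),
         math.sin(math.pi / 2 + 2 * math.pi * i / n))
        for i in range(n))
    return CombinationNetwork(locus=combos[0].locus, k=k, combinations=combos,
                              edges=edges, node_sizes=sizes,
                              positions=positions, fade=f_max < fade_threshold)


def _stars(p: float, alpha_levels=(0.05, 0.01, 0.001)) -> str:
    n = sum(1 for a in alpha_levels if p <= a)
    return "*" * n


def categorize_locus_group(top_by_k: Mapping[int, Sequence[AlleleCombination]],
                           ploidy: int,
                           cf, p_binomial_of,
                           thresholds: Thresholds) -> tuple[str, str,
                                                            AlleleCombination | None]:
    """Ordered category rules for one locus×group.

    Rule order (first hit wins):
      BC1 — several near-equal top combinations at the candidate size, each
            below the fade threshold: MFAC hardly discernible.
      BC2 — nesting inconsistency: the top combination at k is not a subset
            of the top combination at k+1.
      A   — a frequent, binomially significant (ploidy-1)-allele combination.
      B   — a frequent, significant combination of fewer alleles.
      C   — most samples show ploidy-1 alleles but no combination of that
            size is frequent (or no rule fires): MFAC not discernible.
    Returns (category, rule id, chosen MFAC combination or None).
    """
    k_max = min(ploidy - 1, 4)
    available = sorted(k for k in top_by_k if top_by_k[k])
    if not available:
        raise MFACError("no combination reports available")
    k_cand = k_max if k_max in available else max(available)
    top_cand = top_by_k[k_cand]

    # BC1: near-equal faded candidates
    f_top = top_cand[0].frequency
    if f_top < thresholds.fade_threshold:
        near = [c for c in top_cand
                if c.frequency >= f_top * (1 - thresholds.near_equal_rel)]
        if len(near) >= 2:
            return "BC", "BC1:near-equal faded candidates", top_cand[0]

    # BC2: nesting inconsistency across consecutive k
    for k in available:
        if k + 1 in available and k + 1 <= k_cand:
            small = set(top_by_k[k][0].alleles)
            big = set(top_by_k[k + 1][0].alleles)
            if not small <= big:
                return "BC", f"BC2:top {k}-set not nested in top {k + 1}-set", \
                    top_by_k[k_cand][0]

    alpha = thresholds.alpha / thresholds.n_tests if thresholds.bonferroni \
        else thresholds.alpha

    # A: dominant (ploidy-1)-allele combination
    if k_cand == k_max and f_top >= thresholds.freq_threshold \
            and p_binomial_of(top_cand[0]) <= alpha:
        return "A", "A:frequent significant ploidy-1 set", top_cand[0]

    # B: dominant combination of fewer alleles
    for k in sorted((k for k in available if k < k_max), reverse=True):
        cand = top_by_k[k][0]
        if cand.frequency >= thresholds.freq_threshold \
                and p_binomial_of(cand) <= alpha:
            return "B", f"B:frequent significant {k}-set", cand

    # C: many alleles per sample but no dominant set
    if cf(k_max) >= thresholds.cf_threshold:
        return "C", "C:cf high, no frequent ploidy-1 set", top_by_k[k_cand][0]
    return "C", "C:fallback, no dominant combination", top_by_k[k_cand][0]


def analyze_mfac(records: Sequence[SampleRecord], panel: LocusPanel,
                 ploidies: Mapping[str, int] | None = None,
                 groups: Sequence[GroupSpec] | None = None,
                 ks: Sequence[int] = (2, 3, 4),
                 thresholds: Thresholds | None = None,
                 dedup_mlg: bool = False,
                 exact_match: bool = False,
                 pool_excludes_focal: bool = False) -> list[MFACReport]:
    """Full MFAC analysis: one report per locus×group.

    The specificity (hypergeometric) test compares each group's MFAC carrier
    count against the pool of all groups; by default the pool includes the
    focal group itself (``pool_excludes_focal=True`` switches to the
    complement).
    """
    thresholds = thresholds or Thresholds()
    if ploidies is None:
        from .clonality import estimate_ploidies
        ploidies = estimate_ploidies(records, panel)
    if groups is None:
        groups = filter_mfac_groups(records, ploidies, dedup_mlg=dedup_mlg,
                                    panel=panel)
    records_by_id = {r.sample_id: r for r in records}
    reports: list[MFACReport] = []
    # carrier counts of each group's MFAC in every group are needed for the
    # specificity pool, so collect phenotypes per group x locus first
    phenos: dict[tuple[str, str], list[tuple[int, ...]]] = {}
    for group in groups:
        for locus in panel.locus_ids:
            phenos[(group.label, locus)] = _group_phenotypes(
                records_by_id, group, locus)

    for group in groups:
        if not group.sample_ids:
            continue
        for locus in panel.locus_ids:
            ph = phenos[(group.label, locus)]
            if not ph:
                log.warning("group %s has no data at locus %s", group.label, locus)
                continue
            freq = allele_stats(ph, locus)
            counts = apparent_allele_counts(ph)
            top_by_k = {
                k: combination_frequencies(ph, locus, k, exact_match=exact_match)
                for k in ks if k <= counts["max"]}
            if not any(top_by_k.values()):
                continue

            def p_binom(combo: AlleleCombination) -> float:
                return mfac_binomial_test(combo, freq, group.ploidy)

            category, rule, chosen = categorize_locus_group(
                top_by_k, group.ploidy, counts["cf"], p_binom, thresholds)
            log.info("%s x %s -> category %s (%s)", group.label, locus,
                     category, rule)

            p_b = p_binom(chosen) if chosen else None
            p_h = None
            if chosen is not None:
                s = set(chosen.alleles)
                focal_x, focal_n = chosen.carriers, chosen.n
                pooled_x, pooled_n = 0, 0
                for other in groups:
                    o_ph = phenos[(other.label, locus)]
                    if pool_excludes_focal and other.label == group.label:
                        continue
                    pooled_n += len(o_ph)
                    pooled_x += sum(1 for p in o_ph if s <= set(p))
                if pool_excludes_focal:
                    pooled_n += focal_n
                    pooled_x += focal_x
                p_h = mfac_specificity_test(focal_x, focal_n, pooled_x, pooled_n)

            reports.append(MFACReport(
                group=group.label, locus=locus, ploidy=group.ploidy,
                n=len(ph), top_by_k=top_by_k,
                mfac=chosen.alleles if chosen else None,
                ana=chosen.k if chosen else None,
                cf_ana=counts["cf"](chosen.k) if chosen else None,
                f_mfac=chosen.frequency if chosen else None,
                p_binomial=p_b, p_hypergeometric=p_h,
                stars=_stars(p_b) if p_b is not None else "",
                degree=(p_h is not None and p_h <= thresholds.degree_alpha),
                category=category, rule=rule))

    # subsection-specific MFACs: sets not appearing as any other group's MFAC
    by_locus: dict[str, list[MFACReport]] = defaultdict(list)
    for rep in reports:
        by_locus[rep.locus].append(rep)
    for locus, reps in by_locus.items():
        for rep in reps:
            if rep.mfac is None:
                continue
            others = {r.mfac for r in reps if r.group != rep.group}
            rep.specific = rep.mfac not in others
    return reports


def reports_to_frame(reports: Sequence[MFACReport]):
    """MFAC reports as a pandas DataFrame mirroring the per-locus summary."""
    import pandas as pd
    rows = []
    for r in reports:
        rows.append({
            "group": r.group, "locus": r.locus, "ploidy": r.ploidy, "n": r.n,
            "mfac": "" if r.mfac is None else ",".join(map(str, r.mfac)),
            "ana": r.ana, "cf_ana": r.cf_ana, "f_mfac": r.f_mfac,
            "p_binomial": r.p_binomial, "p_hypergeometric": r.p_hypergeometric,
            "marks": r.marks(), "category": r.category, "specific": r.specific,
        })
    return pd.DataFrame(rows)


def write_network_graphml(net: CombinationNetwork, path) -> None:
    import networkx as nx
    nx.write_graphml(net.to_networkx(), path)


def write_network_dot(net: CombinationNetwork, path) -> None:
    # minimal hand-written DOT (graphviz writers need extra dependencies)
    lines = ["graph mfac {"]
    for i, combo in enumerate(net.combinations):
        label = ",".join(map(str, combo.alleles))
        lines.append(
            f'  n{i} [label="{label}" frequency="{combo.frequency:.4f}" '
            f'width="{net.node_sizes[i]:.3f}"];')
    for i, j in net.edges:
        lines.append(f"  n{i} -- n{j};")
    lines.append("}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def plot_network(net: CombinationNetwork, ax=None, title: str | None = None):
    """Render a combination network (counter-clockwise by frequency)."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    alpha = 0.3 if net.fade else 1.0
    for i, j in net.edges:
        xs = [net.positions[i][0], net.positions[j][0]]
        ys = [net.positions[i][1], net.positions[j][1]]
        ax.plot(xs, ys, color="grey", alpha=alpha, zorder=1)
    for i, combo in enumerate(net.combinations):
        x, y = net.positions[i]
        color = "tab:red" if i == 0 else "tab:blue"
        ax.scatter([x], [y], s=1200 * net.node_sizes[i] + 30, color=color,
                   alpha=alpha, zorder=2)
        ax.annotate(",".join(map(str, combo.alleles)), (x, y),
                    ha="center", va="center", fontsize=7)
    f_max = net.combinations[0].frequency
    ax.text(0, 0, f"{f_max:.2f}", ha="center", va="center", fontsize=12)
    ax.set_xlim(-1.5, 1.5)
    ax.set_ylim(-1.5, 1.5)
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    return ax
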