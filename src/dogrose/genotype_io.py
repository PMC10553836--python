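"""Reading, validation, harmonization and merging of allelic-phenotype tables.

Microsatellite genotypes of polyploids are recorded as *allelic phenotypes*:
per sample and locus, the set of distinct fragment lengths (bp) observed,
without dosage. The native table format is a plain tab-separated dialect::

    sample_id  dataset  species  section  subsection  site_id  latitude
    longitude  ploidy_measured  <locus1> ... <locusN>

Allele cells are comma-separated ascending integers; an empty cell marks a
missing locus. Fragment lengths scored in different laboratories can carry a
small constant offset per locus; :func:`estimate_size_shift` estimates that
offset from modal fragment lengths and :func:`harmonize_and_merge` applies it
before pooling datasets.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

#: The seven microsatellite loci scored in the dogrose panel.
DEFAULT_LOCI = (
    "RhAB73", "RhP50", "RhP518", "RhO517", "RhD201", "RhE506", "RhB303",
)

#: Alternative spellings that occur in the literature for the same primer pairs.
LOCUS_ALIASES = {"RhEO506": "RhE506", "Rh303": "RhB303"}

#: Loci known to share a linkage group.
DEFAULT_LINKAGE_PAIRS = (("RhO517", "RhD201"), ("RhE506", "RhB303"))

#: Maximum credible laboratory size shift in bp.
MAX_SHIFT_BP = 3

METADATA_COLUMNS = (
    "sample_id", "dataset", "species", "section", "subsection",
    "site_id", "latitude", "longitude", "ploidy_measured",
)


class GenotypeTableError(ValueError):
    """Raised for malformed genotype tables or invalid records."""


@dataclass(frozen=True)
class LocusPanel:
    """Ordered locus panel with per-locus repeat-motif lengths.

    Motif lengths feed the Bruvo distance (repeat-unit differences); the
    default of 2 bp reflects the dinucleotide-repeat-rich origin of the panel
    and is deliberately configurable per locus.
    """

    locus_ids: tuple[str, ...] = DEFAULT_LOCI
    motif_lengths: Mapping[str, int] = field(default_factory=dict)
    linkage_pairs: tuple[tuple[str, str], ...] = DEFAULT_LINKAGE_PAIRS

    def __post_init__(self):
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise GenotypeTableError("duplicate locus ids in panel")
        motifs = dict(self.motif_lengths)
        for locus in self.locus_ids:
            motifs.setdefault(locus, 2)
        for locus, m in motifs.items():
            if locus not in self.locus_ids:
                raise GenotypeTableError(f"motif length for unknown locus {locus!r}")
            if int(m) < 1:
                raise GenotypeTableError(f"motif length for {locus!r} must be >= 1")
        object.__setattr__(self, "motif_lengths", motifs)
        for a, b in self.linkage_pairs:
            if a not in self.locus_ids or b not in self.locus_ids:
                raise GenotypeTableError(f"linkage pair ({a}, {b}) not in panel")

    def motif(self, locus: str) -> int:
        return int(self.motif_lengths[locus])

    def resolve(self, name: str) -> str:
        """Map a locus-name variant to its canonical panel id."""
        return LOCUS_ALIASES.get(name, name)


@dataclass
class SampleRecord:
    """One plant: metadata plus per-locus allele sets (allelic phenotype).

    ``phenotype`` maps locus id to an ascending tuple of distinct allele sizes
    in bp, or ``None`` for a missing locus.
    """

    sample_id: str
    dataset_tag: str
    species: str
    section: str
    subsection: str | None
    site_id: str
    latitude: float | None
    longitude: float | None
    ploidy_measured: int | None
    phenotype: dict[str, tuple[int, ...] | None]

    def __post_init__(self):
        if not self.sample_id:
            raise GenotypeTableError("empty sample_id")
        if self.ploidy_measured is not None and not 2 <= self.ploidy_measured <= 8:
            raise GenotypeTableError(
                f"sample {self.sample_id}: ploidy_measured {self.ploidy_measured} "
                "outside 2..8")
        clean: dict[str, tuple[int, ...] | None] = {}
        for locus, alleles in self.phenotype.items():
            if alleles is None:
                clean[locus] = None
                continue
            sizes = sorted(set(int(a) for a in alleles))
            if any(a <= 0 for a in sizes):
                raise GenotypeTableError(
                    f"sample {self.sample_id}, locus {locus}: non-positive allele size")
            clean[locus] = tuple(sizes)
        self.phenotype = clean

    def alleles(self, locus: str) -> tuple[int, ...] | None:
        return self.phenotype.get(locus)

    def n_nonmissing(self) -> int:
        return sum(1 for v in self.phenotype.values() if v is not None)

    def mlg_key(self, locus_order: Sequence[str]) -> tuple:
        """Hashable multilocus-genotype key; missing loci are a distinct token."""
        return tuple(self.phenotype.get(locus) for locus in locus_order)


@dataclass(frozen=True)
class ShiftTable:
    """Per-(dataset, locus) integer fragment-size shifts, each within +-3 bp."""

    shifts: Mapping[tuple[str, str], int]

    def __post_init__(self):
        for (tag, locus), s in self.shifts.items():
            if abs(int(s)) > MAX_SHIFT_BP:
                raise GenotypeTableError(
                    f"shift {s} bp for ({tag}, {locus}) exceeds {MAX_SHIFT_BP} bp")

    def get(self, dataset_tag: str, locus: str) -> int:
        return int(self.shifts.get((dataset_tag, locus), 0))


def _parse_allele_cell(cell: str, row: int, column: str) -> tuple[int, ...] | None:
    cell = cell.strip()
    if not cell:
        return None
    sizes = []
    for token in cell.split(","):
        token = token.strip()
        try:
            size = int(token)
        except ValueError:
            raise GenotypeTableError(
                f"row {row}, column {column!r}: malformed allele token {token!r}")
        if size <= 0:
            raise GenotypeTableError(
                f"row {row}, column {column!r}: non-positive allele size {size}")
        sizes.append(size)
    return tuple(sorted(set(sizes)))


def _parse_float(cell: str) -> float | None:
    cell = cell.strip()
    return float(cell) if cell else None


def read_genotype_table(path: str | Path, panel: LocusPanel) -> list[SampleRecord]:
    """Read and validate a genotype TSV into :class:`SampleRecord` objects."""
    path = Path(path)
    records: list[SampleRecord] = []
    seen: set[str] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise GenotypeTableError(f"{path}: empty file")
        if tuple(header[: len(METADATA_COLUMNS)]) != METADATA_COLUMNS:
            raise GenotypeTableError(
                f"{path}: header must start with {' '.join(METADATA_COLUMNS)}")
        locus_columns = [panel.resolve(h) for h in header[len(METADATA_COLUMNS):]]
        unknown = [h for h in locus_columns if h not in panel.locus_ids]
        if unknown:
            raise GenotypeTableError(f"{path}: unknown locus column(s) {unknown}")
        for i, row in enumerate(reader, start=2):
            if not any(cell.strip() for cell in row):
                continue
            if len(row) != len(header):
                raise GenotypeTableError(
                    f"{path}, row {i}: expected {len(header)} fields, got {len(row)}")
            meta = dict(zip(METADATA_COLUMNS, row))
            sid = meta["sample_id"].strip()
            if sid in seen:
                raise GenotypeTableError(f"{path}, row {i}: duplicate sample_id {sid!r}")
            seen.add(sid)
            phenotype = {
                locus: _parse_allele_cell(cell, i, locus)
                for locus, cell in zip(locus_columns, row[len(METADATA_COLUMNS):])
            }
            ploidy = meta["ploidy_measured"].strip()
            records.append(SampleRecord(
                sample_id=sid,
                dataset_tag=meta["dataset"].strip(),
                species=meta["species"].strip(),
                section=meta["section"].strip(),
                subsection=meta["subsection"].strip() or None,
                site_id=meta["site_id"].strip(),
                latitude=_parse_float(meta["latitude"]),
                longitude=_parse_float(meta["longitude"]),
                ploidy_measured=int(ploidy) if ploidy else None,
                phenotype=phenotype,
            ))
    return records


def _format_float(x: float | None) -> str:
    if x is None:
        return ""
    return repr(float(x))


def write_genotype_table(records: Iterable[SampleRecord], path: str | Path,
                         panel: LocusPanel) -> None:
    """Write records as a genotype TSV in canonical order.

    Column order follows the panel; rows are sorted by sample_id, so
    write -> read -> write is byte-stable.
    """
    path = Path(path)
    rows = sorted(records, key=lambda r: r.sample_id)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(list(METADATA_COLUMNS) + list(panel.locus_ids))
        for r in rows:
            cells = [
                r.sample_id, r.dataset_tag, r.species, r.section,
                r.subsection or "", r.site_id,
                _format_float(r.latitude), _format_float(r.longitude),
                "" if r.ploidy_measured is None else str(r.ploidy_measured),
            ]
            for locus in panel.locus_ids:
                alleles = r.phenotype.get(locus)
                cells.append("" if alleles is None else ",".join(str(a) for a in alleles))
            writer.writerow(cells)


def modal_alleles(records: Iterable[SampleRecord], locus: str) -> tuple[int, ...]:
    """All modal allele sizes at a locus (each sample counts each distinct
    allele once). Returns an ascending tuple of the tied modes."""
    counts: Counter[int] = Counter()
    for r in records:
        alleles = r.phenotype.get(locus)
        if alleles:
            counts.update(alleles)
    if not counts:
        raise GenotypeTableError(f"no observations at locus {locus}: modal allele undefined")
    top = max(counts.values())
    return tuple(sorted(a for a, c in counts.items() if c == top))


def estimate_size_shift(source_records: Sequence[SampleRecord],
                        reference_records: Sequence[SampleRecord],
                        locus: str) -> int:
    """Shift (bp) aligning the source's modal fragment to the reference's.

    Among candidate shifts from tied modes, the smallest |shift| wins, then
    the negative one. A required shift beyond +-3 bp is treated as evidence
    against a simple laboratory offset and raises.
    """
    src_modes = modal_alleles(source_records, locus)
    ref_modes = modal_alleles(reference_records, locus)
    candidates = sorted({rm - sm for sm in src_modes for rm in ref_modes},
                        key=lambda s: (abs(s), s))
    best = candidates[0]
    if abs(best) > MAX_SHIFT_BP:
        raise GenotypeTableError(
            f"locus {locus}: required shift {best} bp exceeds {MAX_SHIFT_BP} bp")
    return best


def build_shift_table(datasets: Mapping[str, Sequence[SampleRecord]],
                      reference_tag: str, panel: LocusPanel) -> ShiftTable:
    """Estimate shifts for every (non-reference dataset, locus) pair."""
    if reference_tag not in datasets:
        raise GenotypeTableError(f"reference dataset {reference_tag!r} not supplied")
    reference = datasets[reference_tag]
    shifts: dict[tuple[str, str], int] = {}
    for tag, records in datasets.items():
        if tag == reference_tag:
            continue
        for locus in panel.locus_ids:
            has_src = any(r.phenotype.get(locus) for r in records)
            has_ref = any(r.phenotype.get(locus) for r in reference)
            if not (has_src and has_ref):
                log.warning("no data to estimate shift for (%s, %s); using 0", tag, locus)
                continue
            s = estimate_size_shift(records, reference, locus)
            if s:
                shifts[(tag, locus)] = s
    return ShiftTable(shifts)


def harmonize_and_merge(dataset_list: Sequence[Sequence[SampleRecord]],
                        shift_table: ShiftTable) -> list[SampleRecord]:
    """Apply per-(dataset, locus) shifts and pool datasets.

    Shifting is a translation of every allele at the (dataset, locus), so
    within-dataset Bruvo distances are unchanged. Provenance stays in
    ``dataset_tag``; colliding sample ids across datasets raise.
    """
    merged: list[SampleRecord] = []
    seen: set[str] = set()
    for records in dataset_list:
        for r in records:
            if r.sample_id in seen:
                raise GenotypeTableError(
                    f"sample_id collision across datasets: {r.sample_id!r}")
            seen.add(r.sample_id)
            phenotype = {}
            for locus, alleles in r.phenotype.items():
                s = shift_table.get(r.dataset_tag, locus)
                phenotype[locus] = (None if alleles is None
                                    else tuple(a + s for a in alleles))
            merged.append(replace(r, phenotype=phenotype))
    return merged


def convert_s1_workbook(path: str | Path, panel: LocusPanel,
                        sheet: int | str = 0) -> list[SampleRecord]:
    """Import an XLSX deposit whose first sheet follows the genotype-table
    layout (same column names as the TSV dialect; allele cells are comma- or
    slash-separated fragment lengths). Values are validated exactly as for
    the TSV reader."""
    import pandas as pd

    df = pd.read_excel(path, sheet_name=sheet, dtype=str)
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise GenotypeTableError(f"{path}: missing metadata column(s) {missing}")
    records = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        def cell(name):
            v = row.get(name)
            return "" if v is None or (isinstance(v, float) and v != v) else str(v).strip()
        sid = cell("sample_id")
        if not sid:
            continue
        if sid in seen:
            raise GenotypeTableError(f"{path}, row {i + 2}: duplicate sample_id {sid!r}")
        seen.add(sid)
        phenotype = {}
        for col in df.columns:
            locus = panel.resolve(col)
            if locus in panel.locus_ids:
                phenotype[locus] = _parse_allele_cell(
                    cell(col).replace("/", ","), i + 2, col)
        ploidy = cell("ploidy_measured")
        records.append(SampleRecord(
            sample_id=sid, dataset_tag=cell("dataset"), species=cell("species"),
            section=cell("section"), subsection=cell("subsection") or None,
            site_id=cell("site_id"),
            latitude=_parse_float(cell("latitude")),
            longitude=_parse_float(cell("longitude")),
            ploidy_measured=int(float(ploidy)) if ploidy else None,
            phenotype=phenotype,
        ))
    return records


def write_genalex(records: Sequence[SampleRecord], path: str | Path,
                  panel: LocusPanel, n_columns: int = 8) -> None:
    """Codominant GenAlEx-style export: one column per allele slot, 0 = missing.

    Dosage is unknown for allelic phenotypes, so each distinct allele is
    written once and remaining slots padded with zeros."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        header = ["sample_id", "site_id"]
        for locus in panel.locus_ids:
            header += [locus] + [""] * (n_columns - 1)
        writer.writerow(header)
        for r in sorted(records, key=lambda x: x.sample_id):
            row = [r.sample_id, r.site_id]
            for locus in panel.locus_ids:
                alleles = list(r.phenotype.get(locus) or ())[:n_columns]
                row += [str(a) for a in alleles] + ["0"] * (n_columns - len(alleles))
            writer.writerow(row)


def check_source_effects(records: Sequence[SampleRecord],
                         coordinates: Mapping[str, Sequence[float]]) -> dict:
    """Report (not gate on) data-source effects in an ordination.

    Given PCoA coordinates per sample, returns per-dataset centroids on the
    first two axes and the ratio of between-centroid dispersion to total
    dispersion; a ratio near 0 means no visible source-specific effect."""
    import numpy as np

    tags = sorted({r.dataset_tag for r in records})
    coords = np.array([coordinates[r.sample_id][:2] for r in records], dtype=float)
    grand = coords.mean(axis=0)
    total = float(((coords - grand) ** 2).sum())
    centroids, between = {}, 0.0
    for tag in tags:
        sub = coords[[i for i, r in enumerate(records) if r.dataset_tag == tag]]
        centroids[tag] = sub.mean(axis=0).tolist()
        between += len(sub) * float(((sub.mean(axis=0) - grand) ** 2).sum())
    return {
        "centroids": centroids,
        "between_to_total_ratio": between / total if total > 0 else 0.0,
    }
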