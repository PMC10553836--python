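"""End-to-end orchestration: merge -> ploidy/MLG -> structure -> MFAC.

One top-level seed derives the per-stage seeds deterministically, so a single
number reproduces every numeric output of a run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotype_io import (LocusPanel, build_shift_table, harmonize_and_merge,
                          read_genotype_table, write_genotype_table,
                          GenotypeTableError)
from .clonality import (estimate_ploidies, index_mlgs, shared_mlg_geography,
                        summarize_clonality)
from .structure import (amova, bruvo_distance_matrix, one_mlg_per_species,
                        pcoa, write_distance_matrix)
from .mfac import Thresholds, analyze_mfac, reports_to_frame

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    inputs: tuple[str, ...]
    out_dir: str
    reference_tag: str | None = None
    seed: int = 0
    n_permutations: int = 999
    amova_group_by: str = "subsection"
    strategy: str = "mean_completion"
    use_one_mlg_per_species: bool = True
    dedup_mlg: bool = False
    motif_lengths: dict = field(default_factory=dict)
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def from_json(cls, path: str | Path, seed: int | None = None,
                  out_dir: str | None = None) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        thresholds = Thresholds(**raw.pop("thresholds", {}))
        cfg = cls(thresholds=thresholds, **raw)
        if seed is not None:
            cfg.seed = seed
        if out_dir is not None:
            cfg.out_dir = out_dir
        return cfg

    def canonical_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, sort_keys=True, default=str)


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a manifest dict (also written to out_dir)."""
    panel = LocusPanel(motif_lengths={k: int(v)
                                      for k, v in config.motif_lengths.items()})
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "merge"
    try:
        datasets = {}
        for path in config.inputs:
            if not Path(path).exists():
                raise PipelineError(f"input path does not exist: {path}")
            records = read_genotype_table(path, panel)
            for r in records:
                datasets.setdefault(r.dataset_tag, []).append(r)
        if len(datasets) > 1:
            ref = config.reference_tag or max(datasets, key=lambda t: len(datasets[t]))
            shifts = build_shift_table(datasets, ref, panel)
        else:
            from .genotype_io import ShiftTable
            shifts = ShiftTable({})
        records = harmonize_and_merge(list(datasets.values()), shifts)
        write_genotype_table(records, out / "merged.tsv", panel)

        stage = "mlg"
        ploidies = estimate_ploidies(records, panel)
        assignment = index_mlgs(records, panel)
        pd.DataFrame({
            "sample_id": list(assignment.global_ids),
            "global_mlg": list(assignment.global_ids.values()),
            "per_unit_mlg": [assignment.per_unit_ids[s]
                             for s in assignment.global_ids],
            "ploidy_estimate": [ploidies[s] for s in assignment.global_ids],
        }).to_csv(out / "mlg_assignment.tsv", sep="\t", index=False)
        for group_by in ("site", "species"):
            rows = [asdict(s) for s in
                    summarize_clonality(records, assignment, group_by)]
            pd.DataFrame(rows).to_csv(out / f"clonality_{group_by}.tsv",
                                      sep="\t", index=False)
        shared = shared_mlg_geography(records, assignment)
        pd.DataFrame([{
            "mlg_id": s.mlg_id, "n_samples": s.n_samples,
            "n_sites": len(s.site_ids), "sites": ";".join(s.site_ids),
            "species": ";".join(s.species),
            "max_distance_km": s.max_pairwise_distance_km,
        } for s in shared]).to_csv(out / "shared_mlgs.tsv", sep="\t", index=False)

        stage = "structure"
        subset = one_mlg_per_species(records, panel) \
            if config.use_one_mlg_per_species else records
        dm = bruvo_distance_matrix(subset, panel, config.strategy, ploidies)
        write_distance_matrix(dm, out / "bruvo_distances.tsv")
        ordination = pcoa(dm)
        coords = pd.DataFrame(
            ordination.coordinates[:, : min(5, ordination.coordinates.shape[1])],
            index=list(ordination.ids))
        coords.columns = [f"axis{i + 1}" for i in range(coords.shape[1])]
        coords.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
        labels = {r.sample_id: (r.subsection or r.section) for r in subset}
        if config.amova_group_by == "section":
            labels = {r.sample_id: r.section for r in subset}
        elif config.amova_group_by == "species":
            labels = {r.sample_id: r.species for r in subset}
        amova_res = amova(dm, [labels[i] for i in dm.ids],
                          n_perm=config.n_permutations,
                          seed=_stage_seed(config.seed, "amova"))
        with (out / "amova.json").open("w", encoding="utf-8") as fh:
            json.dump(asdict(amova_res), fh, indent=1)

        stage = "mfac"
        reports = analyze_mfac(records, panel, ploidies=ploidies,
                               thresholds=config.thresholds,
                               dedup_mlg=config.dedup_mlg)
        reports_to_frame(reports).to_csv(out / "mfac_reports.tsv", sep="\t",
                                         index=False)

        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(
                config.canonical_json().encode()).hexdigest(),
            "n_samples": len(records),
            "n_mlgs_global": assignment.n_global(),
            "n_mlgs_per_unit": assignment.n_per_unit(),
            "pcoa_axis1_percent": float(ordination.percent_variance[0]),
            "amova_percent_among": amova_res.percent_among,
            "amova_phi_st": amova_res.phi_st,
            "n_mfac_reports": len(reports),
            "outputs": sorted(p.name for p in out.iterdir()),
        }
        with (out / "manifest.json").open("w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest
    except (GenotypeTableError, ValueError, OSError) as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
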