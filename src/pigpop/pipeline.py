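"""End-to-end orchestration: per-population QC through Ne estimation.

``run_pipeline`` executes, for every population in the input panel (or
a simulated demo panel): QC -> misplaced-SNP screen -> diversity ->
inbreeding and cross-estimator correlations -> ROH -> GRM/PCA -> LD
decay and useful-LD fractions -> Ne trajectory; then phase persistence
for every population pair on the shared post-QC markers.  Every table
is written as TSV and listed, with a SHA-256 checksum, in a JSON
manifest, so identical inputs + config + seed give identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    apply_qc,
    build_grm,
    detect_misplaced_snps,
    detect_roh,
    diversity_summary,
    estimate_ne,
    f_roh,
    inbreeding_correlations,
    inbreeding_summary,
    inbreeding_table,
    ld_scan,
    phase_persistence,
    principal_components,
    read_pedigree,
    read_plink_text,
    simulate_population,
    summarize_ld,
    summarize_roh,
)
from .io import GenotypePanel, Pedigree
from .qc import misplaced_flags_frame
from .roh import segments_frame
from .sim import SimConfig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str
    ped_path: str | None = None
    map_path: str | None = None
    pedigree_path: str | None = None
    simulate: SimConfig | None = None
    qc_enabled: bool = True
    snp_cr_min: float = 0.90
    maf_min: float = 0.05
    hwe_p_min: float = 1e-6
    animal_cr_min: float = 0.90
    ld_max_distance_mbp: float = 5.0
    ne_max_distance_mbp: float = 20.0
    roh_min_snps: int = 40
    roh_max_het: int = 1
    roh_max_missing: int = 2
    phase_bin_width_mbp: float = 0.05
    n_components: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = SimConfig(**sim)
        return cfg


def demo_config(out_dir: str, seed: int = 0) -> RunConfig:
    """Small three-population synthetic run (two purebreds + their F1)."""
    return RunConfig(
        out_dir=out_dir,
        simulate=SimConfig(
            chromosomes=2,
            chrom_length_cm=50.0,
            n_markers=250,
            ne=60,
            burn_in_generations=60,
            seed=seed,
        ),
        seed=seed,
    )


def _write(df: pd.DataFrame, path: Path, manifest: dict, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest["artifacts"][path.name] = digest


def _load_inputs(config: RunConfig) -> tuple[GenotypePanel, Pedigree | None]:
    if config.simulate is not None:
        sim_cfg = config.simulate
        base = simulate_population(sim_cfg)
        from .sim import make_f1, split_populations

        pop_a, pop_b = split_populations(base, 30, names=("LINE_A", "LINE_B"))
        f1 = make_f1(pop_a, pop_b, n_offspring=max(20, pop_a.panel.n_animals // 2))
        panels = [pop_a.panel, pop_b.panel, f1.panel]
        animals = pd.concat([p.animals for p in panels], ignore_index=True)
        dosages = np.vstack([p.dosages for p in panels])
        panel = GenotypePanel(
            animals=animals,
            dosages=dosages,
            map=pop_a.panel.map,
            counted_allele=pop_a.panel.counted_allele,
            other_allele=pop_a.panel.other_allele,
        )
        pedigree = Pedigree(
            pd.concat(
                [pop_a.pedigree.table, pop_b.pedigree.table, f1.pedigree.table],
                ignore_index=True,
            ).drop_duplicates(subset="animal")
        )
        return panel, pedigree
    if not (config.ped_path and config.map_path):
        raise ValueError("config needs either input paths or a simulate block")
    panel = read_plink_text(config.ped_path, config.map_path)
    pedigree = read_pedigree(config.pedigree_path) if config.pedigree_path else None
    return panel, pedigree


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; return the manifest (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _config_dict(config), "artifacts": {}, "stages": []}

    panel, pedigree = _load_inputs(config)
    manifest["n_animals_in"] = panel.n_animals
    manifest["n_markers_in"] = panel.n_markers

    clean_panels: dict[str, GenotypePanel] = {}
    qc_rows = []
    for pop, sub in panel.split_by_population().items():
        if config.qc_enabled:
            clean, report = apply_qc(
                sub,
                snp_cr_min=config.snp_cr_min,
                maf_min=config.maf_min,
                hwe_p_min=config.hwe_p_min,
                animal_cr_min=config.animal_cr_min,
            )
            row = report.to_frame()
            row.insert(0, "population", pop)
            qc_rows.append(row)
        else:
            clean = sub
        clean_panels[pop] = clean
    if qc_rows:
        _write(pd.concat(qc_rows, ignore_index=True), out / "qc_report.tsv", manifest)
    manifest["stages"].append("qc")

    flag_frames = []
    for pop, clean in clean_panels.items():
        flags = misplaced_flags_frame(detect_misplaced_snps(clean))
        flags.insert(0, "population", pop)
        flag_frames.append(flags)
    _write(pd.concat(flag_frames, ignore_index=True), out / "misplaced_snps.tsv", manifest)
    manifest["stages"].append("misplaced_snps")

    div_rows = []
    for pop, clean in clean_panels.items():
        div_rows.append(diversity_summary(clean))
    _write(pd.concat(div_rows), out / "diversity.tsv", manifest, index=True)
    manifest["stages"].append("diversity")

    inb_frames = []
    records_by_pop: dict[str, pd.DataFrame] = {}
    for pop, clean in clean_panels.items():
        segments = detect_roh(
            clean,
            min_snps=config.roh_min_snps,
            max_het=config.roh_max_het,
            max_missing=config.roh_max_missing,
        )
        froh = f_roh(segments, clean.map, clean.animal_ids)
        tab = inbreeding_table(clean, f_roh=froh, pedigree=pedigree)
        inb_frames.append(tab)
        roh_sum = summarize_roh(segments, clean)
        _write(segments_frame(segments), out / f"roh_segments_{pop}.tsv", manifest)
        _write(
            roh_sum["per_population"], out / f"roh_summary_{pop}.tsv", manifest,
            index=True,
        )
        _write(roh_sum["histogram"], out / f"roh_histogram_{pop}.tsv", manifest)
    inb = pd.concat(inb_frames)
    _write(inb, out / "inbreeding.tsv", manifest, index=True)
    _write(inbreeding_summary(inb), out / "inbreeding_summary.tsv", manifest, index=True)
    corr = inbreeding_correlations(inb)
    if not corr.empty:
        _write(corr, out / "inbreeding_correlations.tsv", manifest)
    manifest["stages"].append("inbreeding_roh")

    merged_panel = panel if not config.qc_enabled else _merge(clean_panels)
    pcs = principal_components(build_grm(merged_panel), k=config.n_components)
    pca = pcs.to_frame(populations=merged_panel.populations)
    for i, vf in enumerate(pcs.variance_fractions):
        pca[f"PC{i+1}_variance_fraction"] = vf
    _write(pca, out / "pca_scores.tsv", manifest)
    manifest["stages"].append("grm_pca")

    for pop, clean in clean_panels.items():
        rec = ld_scan(clean, max_distance_mbp=config.ne_max_distance_mbp)
        records_by_pop[pop] = rec
        decay = rec[rec["distance_mbp"] <= config.ld_max_distance_mbp]
        if decay.empty:
            continue
        summary = summarize_ld(decay)
        adj = ld_scan(clean, max_distance_mbp=config.ld_max_distance_mbp,
                      adjacent_only=True)
        adj_summary = summarize_ld(adj) if not adj.empty else None
        _write(summary.bins, out / f"ld_decay_{pop}.tsv", manifest)
        _write(summary.class_means, out / f"ld_classes_{pop}.tsv", manifest)
        useful = pd.DataFrame(
            {
                "threshold": list(summary.useful_fractions),
                "fraction_all_pairs": list(summary.useful_fractions.values()),
                "fraction_adjacent": [
                    adj_summary.useful_fractions[t] if adj_summary else np.nan
                    for t in summary.useful_fractions
                ],
                "mean_adjacent_r2": (
                    adj["r2"].mean() if not adj.empty else np.nan
                ),
            }
        )
        _write(useful, out / f"ld_useful_{pop}.tsv", manifest)
        ne = estimate_ne(rec)
        if not ne.empty:
            _write(ne, out / f"ne_trajectory_{pop}.tsv", manifest)
    manifest["stages"].append("ld_ne")

    pops = list(records_by_pop)
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            pp = phase_persistence(
                records_by_pop[a], records_by_pop[b],
                bin_width_mbp=config.phase_bin_width_mbp,
            )
            if not pp.empty:
                _write(pp, out / f"phase_persistence_{a}_vs_{b}.tsv", manifest)
    manifest["stages"].append("phase_persistence")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _merge(panels: dict[str, GenotypePanel]) -> GenotypePanel:
    """Merge per-population post-QC panels on the intersection of markers."""
    pops = list(panels.values())
    shared = set(pops[0].map.marker_ids)
    for p in pops[1:]:
        shared &= set(p.map.marker_ids)
    parts = []
    for p in pops:
        keep = np.flatnonzero(np.isin(p.map.marker_ids, sorted(shared)))
        parts.append(p.subset(marker_idx=keep))
    animals = pd.concat([p.animals for p in parts], ignore_index=True)
    dosages = np.vstack([p.dosages for p in parts])
    return GenotypePanel(
        animals=animals,
        dosages=dosages,
        map=parts[0].map,
        counted_allele=parts[0].counted_allele,
        other_allele=parts[0].other_allele,
    )


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    return d
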