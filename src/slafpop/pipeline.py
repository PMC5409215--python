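"""Pipeline orchestration: configuration, staged execution, provenance.

``run_pipeline`` executes digestion, SNP statistics, relatedness,
structure, and LD/blocks over a genome + genotype panel (either loaded
from FASTA/VCF or simulated in place), writing every stage's outputs plus
a JSON provenance record into the output directory. One top-level seed
derives per-stage seeds by a documented hash so each stochastic stage is
independently reproducible; deterministic stages are bit-identical across
reruns with the same config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._util import derive_seed
from .digest import ENZYMES, digest, evaluate_scheme, select_tags, tagset_spacing
from .genome import Genome
from .io import (
    read_fasta,
    read_vcf,
    write_bed,
    write_fasta,
    write_metadata,
    write_vcf,
)
from .ld_blocks import block_summary, gabriel_blocks, ld_decay_scopes
from .relatedness import fraction_below, kinship_matrix, neighbor_joining, p_distance, pca
from .simulate import SimGenomeSpec, SimPopSpec, simulate_genome, simulate_population
from .snp_stats import (
    _column_stats,
    call_hotspots,
    compare_rich_regions_by_ecotype,
    filter_markers,
    snp_rich_regions,
    windowed_snp_counts,
)
from .structure import admixture_em, choose_k

log = logging.getLogger("slafpop")


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, with the standard defaults.

    Defaults: RsaI + HaeIII, 314-414 bp tags, 100-kb windows, top 1%
    rich-region fraction, MAF > 0.05, integrity > 0.8, hotspot frequency
    > 0.8, LD threshold r^2 = 0.1 with 1-kb bins, K from 1 to 10 with
    5-fold cross-validation.
    """

    out_dir: Path = Path("slafpop-out")
    fasta: Path | None = None
    vcf: Path | None = None
    simulate: bool = False
    enzymes: tuple[str, ...] = ("RsaI", "HaeIII")
    min_tag_len: int = 314
    max_tag_len: int = 414
    window_bp: int = 100_000
    top_fraction: float = 0.01
    maf_min: float = 0.05
    integrity_min: float = 0.8
    hotspot_threshold: float = 0.8
    ld_threshold: float = 0.1
    ld_bin_bp: int = 1000
    ld_max_distance_bp: int | None = None
    block_max_distance_bp: int | None = 100_000
    k_min: int = 1
    k_max: int = 10
    cv_folds: int = 5
    n_pca: int = 3
    seed: int = 0
    genome_spec: SimGenomeSpec | None = None
    pop_spec: SimPopSpec | None = None
    run_blocks: bool = True
    run_structure: bool = True

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.min_tag_len > self.max_tag_len:
            raise ValueError("min_tag_len > max_tag_len")
        for frac in (self.top_fraction, self.maf_min, self.integrity_min,
                     self.hotspot_threshold, self.ld_threshold):
            if not 0 <= frac <= 1:
                raise ValueError("thresholds must be within [0, 1]")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("invalid K range")
        if not self.simulate and (self.fasta is None or self.vcf is None):
            raise ValueError("provide fasta+vcf inputs or set simulate=True")


def _provenance(cfg: PipelineConfig, stage: str, params: dict, outputs: list[str]) -> dict:
    return {
        "stage": stage,
        "version": __version__,
        "seed": cfg.seed,
        "stage_seed": derive_seed(cfg.seed, stage),
        "parameters": params,
        "outputs": outputs,
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns a summary dict mirroring what is on disk."""
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    provenance: list[dict] = []
    summary: dict = {}

    stage = "inputs"
    try:
        if cfg.simulate:
            gspec = cfg.genome_spec or SimGenomeSpec(seed=derive_seed(cfg.seed, "genome-spec"))
            genome = simulate_genome(gspec)
            pspec = cfg.pop_spec or SimPopSpec(seed=derive_seed(cfg.seed, "pop-spec"))
            gm, truth = simulate_population(genome, pspec)
            write_fasta(genome, out / "genome.fa")
            write_vcf(gm, out / "panel.vcf", genome.lengths)
            write_metadata(gm, out / "samples.tsv")
            with open(out / "truth.json", "w") as fh:
                json.dump(
                    {
                        "true_q": truth.true_q.tolist(),
                        "true_f": truth.true_f.tolist(),
                        "true_labels": truth.true_labels,
                        "group_ecotype": truth.group_ecotype,
                    },
                    fh,
                )
        else:
            genome = read_fasta(cfg.fasta)
            gm = read_vcf(cfg.vcf)
        provenance.append(_provenance(cfg, stage, {"simulate": cfg.simulate}, []))

        stage = "digest"
        enzymes = [ENZYMES[e] for e in cfg.enzymes]
        fragments = digest(genome, enzymes)
        tags = select_tags(fragments, cfg.min_tag_len, cfg.max_tag_len)
        report = evaluate_scheme(tags, genome, cfg.window_bp)
        per, overall = tagset_spacing(tags, genome.lengths)
        tag_df = pd.DataFrame(
            [(t.chrom, t.start, t.end) for t in tags.tags],
            columns=["chrom", "start", "end"],
        )
        write_bed(tag_df, out / "tags.bed")
        pd.DataFrame(
            [
                (c, n, sp if sp is not None else "NA")
                for c, (n, sp) in per.items()
            ],
            columns=["chrom", "tag_count", "avg_spacing_bp"],
        ).to_csv(out / "scheme_report.tsv", sep="\t", index=False)
        summary["digest"] = {
            "tag_count": report.tag_count,
            "genome_spacing_bp": overall,
            "repeat_fraction": report.repeat_fraction,
            "evenness_cv": report.evenness_cv,
        }
        provenance.append(
            _provenance(
                cfg,
                stage,
                {"enzymes": list(cfg.enzymes), "min_len": cfg.min_tag_len,
                 "max_len": cfg.max_tag_len, "window_bp": cfg.window_bp},
                ["tags.bed", "scheme_report.tsv"],
            )
        )

        stage = "snp_stats"
        filtered = filter_markers(gm, cfg.maf_min, cfg.integrity_min)
        log.info("filter: MAF > %s and integrity > %s kept %d of %d markers",
                 cfg.maf_min, cfg.integrity_min, filtered.n_markers, gm.n_markers)
        maf, integ, mut = _column_stats(filtered)
        stats = filtered.markers.copy()
        stats["maf"], stats["integrity"], stats["mutation_freq"] = maf, integ, mut
        stats.to_csv(out / "marker_stats.tsv", sep="\t", index=False)
        hot = call_hotspots(filtered, cfg.hotspot_threshold)
        hot_df = filtered.markers.iloc[hot]
        write_bed(
            pd.DataFrame(
                {"chrom": hot_df["chrom"], "start": hot_df["pos"] - 1, "end": hot_df["pos"]}
            ),
            out / "hotspots.bed",
        )
        wc = windowed_snp_counts(filtered, genome.lengths, cfg.window_bp)
        rich = snp_rich_regions(wc, cfg.top_fraction)
        write_bed(rich.regions, out / "rich_regions.bed")
        summary["snp_stats"] = {
            "n_markers_raw": gm.n_markers,
            "n_markers_filtered": filtered.n_markers,
            "n_hotspots": int(hot.size),
            "n_rich_regions": len(rich),
        }
        if filtered.ecotype is not None and len(set(filtered.ecotype)) >= 2:
            eco_tab = compare_rich_regions_by_ecotype(
                filtered, genome.lengths, cfg.window_bp, cfg.top_fraction
            )
            eco_tab.to_csv(out / "rich_regions_by_ecotype.tsv", sep="\t", index=False)
        provenance.append(
            _provenance(
                cfg,
                stage,
                {"maf_min": cfg.maf_min, "integrity_min": cfg.integrity_min,
                 "hotspot_threshold": cfg.hotspot_threshold,
                 "window_bp": cfg.window_bp, "top_fraction": cfg.top_fraction},
                ["marker_stats.tsv", "hotspots.bed", "rich_regions.bed"],
            )
        )

        stage = "relatedness"
        km = kinship_matrix(filtered)
        pd.DataFrame(km.values, index=km.accessions, columns=km.accessions).to_csv(
            out / "kinship.tsv", sep="\t"
        )
        dm = p_distance(filtered)
        pd.DataFrame(dm.values, index=dm.accessions, columns=dm.accessions).to_csv(
            out / "distance.tsv", sep="\t"
        )
        (out / "tree.nwk").write_text(neighbor_joining(dm) + "\n")
        pc = pca(filtered, cfg.n_pca)
        pd.DataFrame(
            pc.scores, index=filtered.accessions,
            columns=[f"PC{i + 1}" for i in range(pc.scores.shape[1])],
        ).to_csv(out / "pca_scores.tsv", sep="\t")
        summary["relatedness"] = {
            "kinship_estimator": km.estimator_name,
            "fraction_kinship_below_0.05": fraction_below(km, 0.05),
            "pca_variance_explained": pc.variance_explained.tolist(),
        }
        provenance.append(
            _provenance(cfg, stage, {"n_pca": cfg.n_pca},
                        ["kinship.tsv", "distance.tsv", "tree.nwk", "pca_scores.tsv"])
        )

        if cfg.run_structure:
            stage = "structure"
            seed = derive_seed(cfg.seed, stage)
            curve = choose_k(filtered, range(cfg.k_min, cfg.k_max + 1),
                             cfg.cv_folds, seed)
            pd.DataFrame({"K": curve.k_values, "cv_error": curve.cv_error}).to_csv(
                out / "cv_curve.tsv", sep="\t", index=False
            )
            fit = admixture_em(filtered, curve.best_k, seed=seed)
            qtab = pd.DataFrame(
                fit.q, index=filtered.accessions,
                columns=[f"Q{k + 1}" for k in range(curve.best_k)],
            )
            # order accessions by dominant component then its value, as in
            # the usual ancestry bar plots
            dom = qtab.to_numpy().argmax(axis=1)
            strength = qtab.to_numpy().max(axis=1)
            qtab.iloc[np.lexsort((-strength, dom))].to_csv(out / "structure_q.tsv", sep="\t")
            summary["structure"] = {"best_k": curve.best_k,
                                    "cv_error": dict(zip(curve.k_values, curve.cv_error))}
            provenance.append(
                _provenance(cfg, stage,
                            {"k_range": [cfg.k_min, cfg.k_max], "folds": cfg.cv_folds},
                            ["cv_curve.tsv", "structure_q.tsv"])
            )

        stage = "ld"
        scopes = ld_decay_scopes(
            filtered, genome.subgenomes, cfg.ld_threshold, cfg.ld_bin_bp,
            cfg.ld_max_distance_bp, cfg.maf_min,
        )
        decay = {
            name: {"decay_distance_bp": c.decay_distance,
                   "n_bins": int(len(c.bin_centers))}
            for name, c in scopes.items()
        }
        with open(out / "ld_decay.json", "w") as fh:
            json.dump(decay, fh, indent=1)
        summary["ld"] = {k: v["decay_distance_bp"] for k, v in decay.items()}
        provenance.append(
            _provenance(cfg, stage,
                        {"threshold": cfg.ld_threshold, "bin_bp": cfg.ld_bin_bp},
                        ["ld_decay.json"])
        )

        if cfg.run_blocks:
            stage = "blocks"
            blocksets = {
                c: gabriel_blocks(filtered, c, max_distance_bp=cfg.block_max_distance_bp)
                for c in filtered.chroms
            }
            all_blocks = pd.concat(
                [b.blocks for b in blocksets.values() if len(b)], ignore_index=True
            ) if any(len(b) for b in blocksets.values()) else pd.DataFrame(
                columns=["chrom", "first", "last", "start_bp", "end_bp", "length_bp"]
            )
            if len(all_blocks):
                write_bed(
                    pd.DataFrame(
                        {"chrom": all_blocks["chrom"],
                         "start": all_blocks["start_bp"] - 1,
                         "end": all_blocks["end_bp"]}
                    ),
                    out / "blocks.bed",
                )
            else:
                (out / "blocks.bed").write_text("")
            bsum = block_summary(blocksets, genome.lengths, genome.subgenomes)
            bsum["per_chrom"].to_csv(out / "block_summary.tsv", sep="\t", index=False)
            summary["blocks"] = {
                "n_blocks": int(bsum["genome"]["n_blocks"].iloc[0]),
                "genome_frequency_pct": float(bsum["genome"]["frequency_pct"].iloc[0]),
            }
            provenance.append(
                _provenance(cfg, stage, {"max_distance_bp": cfg.block_max_distance_bp},
                            ["blocks.bed", "block_summary.tsv"])
            )
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    return summary
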