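"""End-to-end orchestration: QC -> windows -> correlations -> enrichment.

A :class:`RunConfig` (usually loaded from YAML) names the inputs and
parameters; :func:`run_all` executes the stages in order and writes every
result as plain TSV plus a machine-readable JSON manifest (seed, input
hashes, record counts, output hashes).  Outputs contain no timestamps, so
re-running an identical configuration on identical inputs is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .correlation_stats import (
    genome_level_correlations,
    qtl_vs_study_trait_correlation,
    window_level_matrix,
    write_correlations_tsv,
)
from .enrichment_stats import (
    binomial_tests_frame,
    chromosome_enrichment,
    hypergeom_tests_frame,
    trait_window_enrichment,
    window_enrichment,
)
from .genome_io import (
    read_assembly,
    read_gene_set,
    read_genes,
    read_qtl_gff,
    read_snps,
    write_qtl_tsv,
)
from .overlap_permutation import (
    permutation_overlap_test,
    prepare_unique_qtl,
    rank_candidate_genes,
)
from .qc_merge import QCConfig, run_qc, write_ledger_tsv, write_removed_tsv
from .windowing import (
    DEFAULT_SCALES,
    chromosome_density_summary,
    count_features,
    genome_coverage,
    make_grid,
    write_grid_tsv,
)

logger = logging.getLogger("qtlome")

STAGES = ("qc", "windows", "correlate", "enrich", "traits", "overlap")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    assembly_path: str
    qtl_gff_path: str
    genes_path: str
    out_dir: str
    snps_path: Optional[str] = None
    gene_set_paths: dict[str, str] = field(default_factory=dict)
    qc: QCConfig = field(default_factory=QCConfig)
    window_scales: Sequence[int] = DEFAULT_SCALES
    regional_scale: int = 1_000_000
    n_permutations: int = 1000
    seed: int = 0
    bh_family: str = "per_label"
    trait_levels: Sequence[str] = ("class", "type", "trait")
    overlap_null_mode: str = "random_genes"
    min_windows: int = 10
    species_label: str = ""

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "qc" in data:
            data["qc"] = QCConfig(**data["qc"])
        for key in ("window_scales", "trait_levels"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(cfg: RunConfig, stages: Sequence[str] = STAGES) -> dict:
    """Run the requested stages in pipeline order; returns the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "qtlome",
        "version": __version__,
        "seed": cfg.seed,
        "inputs": {},
        "counts": {},
        "outputs": {},
    }
    for name, p in (
        ("assembly", cfg.assembly_path),
        ("qtl_gff", cfg.qtl_gff_path),
        ("genes", cfg.genes_path),
    ):
        path = Path(p)
        if not path.exists():
            raise StageError("config", FileNotFoundError(p))
        manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(path)}

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["outputs"][name] = _sha256(path)

    t0 = time.perf_counter()

    def tick(stage: str) -> None:
        nonlocal t0
        logger.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)
        t0 = time.perf_counter()

    try:
        assembly = read_assembly(cfg.assembly_path, cfg.species_label)
        raw = read_qtl_gff(cfg.qtl_gff_path, assembly)
        manifest["counts"]["qtl_raw"] = len(raw)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("load", exc) from exc

    try:
        clean, ledger, removed = run_qc(raw, assembly, cfg.qc)
        manifest["counts"]["qtl_clean"] = len(clean)
        manifest["counts"]["qc_ledger"] = dict(ledger.as_rows())
        emit("qc_ledger.tsv", lambda p: write_ledger_tsv(ledger, p))
        emit("qtl_removed.tsv", lambda p: write_removed_tsv(removed, p))
        emit("qtl_clean.tsv", lambda p: write_qtl_tsv(clean, p))
        tick("qc")
    except Exception as exc:  # noqa: BLE001
        raise StageError("qc", exc) from exc
    if "qc" == stages[-1]:
        return _finish(manifest, out)

    try:
        genes = read_genes(cfg.genes_path, assembly)
        snps = read_snps(cfg.snps_path) if cfg.snps_path else []
        grids = {}
        for scale in cfg.window_scales:
            grid = make_grid(assembly, scale)
            count_features(grid, clean, genes, snps)
            grids[scale] = grid
            emit(f"window_counts_{scale}.tsv", lambda p, g=grid: write_grid_tsv(g, p))
        emit(
            "chromosome_density.tsv",
            lambda p: chromosome_density_summary(grids[cfg.regional_scale]).to_csv(
                p, sep="\t", index=False
            ),
        )
        coverage = genome_coverage(clean, assembly)
        manifest["counts"]["coverage_fraction"] = coverage.fraction
        emit(
            "coverage.tsv",
            lambda p: Path(p).write_text(
                "species\tcovered_bp\ttotal_bp\tfraction\n"
                f"{assembly.species_label}\t{coverage.covered_bp}"
                f"\t{coverage.total_bp}\t{coverage.fraction:.6f}\n"
            ),
        )
        tick("windows")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("windows", exc) from exc
    if "windows" == stages[-1]:
        return _finish(manifest, out)

    if "correlate" in stages:
        try:
            regional = grids[cfg.regional_scale]
            per_chrom_qtl = {
                c: int(regional.qtl_count[regional.chrom_slice(c)].sum())
                for c in assembly.names
            }
            per_chrom_genes = {
                c: int(regional.gene_count[regional.chrom_slice(c)].sum())
                for c in assembly.names
            }
            genome_corr = genome_level_correlations(
                assembly, per_chrom_qtl, per_chrom_genes,
                n_perm=cfg.n_permutations, seed=cfg.seed,
            )
            pleio = qtl_vs_study_trait_correlation(
                regional, n_perm=cfg.n_permutations, seed=cfg.seed
            )
            emit(
                "genome_correlations.tsv",
                lambda p: write_correlations_tsv(list(genome_corr) + list(pleio), p),
            )
            matrix = window_level_matrix(
                grids, min_windows=cfg.min_windows,
                n_perm=cfg.n_permutations, seed=cfg.seed,
            )
            emit("window_correlation_matrix.tsv", matrix.to_tsv)
            tick("correlate")
        except Exception as exc:  # noqa: BLE001
            raise StageError("correlate", exc) from exc

    if "enrich" in stages:
        try:
            regional = grids[cfg.regional_scale]
            per_chrom_qtl = {
                c: int(regional.qtl_count[regional.chrom_slice(c)].sum())
                for c in assembly.names
            }
            chrom_tests = chromosome_enrichment(assembly, per_chrom_qtl)
            emit(
                "chromosome_enrichment.tsv",
                lambda p: binomial_tests_frame(chrom_tests).to_csv(p, sep="\t", index=False),
            )
            win_tests, skipped = window_enrichment(regional)
            manifest["counts"]["windows_tested"] = len(win_tests)
            manifest["counts"]["windows_skipped"] = len(skipped)
            emit(
                "window_enrichment.tsv",
                lambda p: binomial_tests_frame(win_tests).to_csv(p, sep="\t", index=False),
            )
            emit(
                "window_enrichment_skipped.tsv",
                lambda p: pd.DataFrame(
                    [(s.unit, s.reason) for s in skipped], columns=["unit", "reason"]
                ).to_csv(p, sep="\t", index=False),
            )
            tick("enrich")
        except Exception as exc:  # noqa: BLE001
            raise StageError("enrich", exc) from exc

    if "traits" in stages:
        try:
            regional = grids[cfg.regional_scale]
            for level in cfg.trait_levels:
                tests = trait_window_enrichment(
                    regional, clean, level=level, bh_family=cfg.bh_family
                )
                emit(
                    f"trait_enrichment_{level}.tsv",
                    lambda p, t=tests: hypergeom_tests_frame(t).to_csv(
                        p, sep="\t", index=False
                    ),
                )
            tick("traits")
        except Exception as exc:  # noqa: BLE001
            raise StageError("traits", exc) from exc

    if "overlap" in stages:
        try:
            intervals = prepare_unique_qtl(clean, assembly, dedup_key=cfg.qc.dedup_key)
            ranked = rank_candidate_genes(clean)
            emit(
                "candidate_genes.tsv",
                lambda p: pd.DataFrame(ranked, columns=["symbol", "reports"]).to_csv(
                    p, sep="\t", index=False
                ),
            )
            rows = []
            for label, path in sorted(cfg.gene_set_paths.items()):
                gene_set = read_gene_set(path, genes, label=label)
                res = permutation_overlap_test(
                    intervals,
                    gene_set,
                    genes if cfg.overlap_null_mode == "random_genes" else assembly,
                    n_perm=cfg.n_permutations,
                    null_mode=cfg.overlap_null_mode,
                    seed=cfg.seed,
                )
                rows.append(
                    {
                        "gene_set": label,
                        "observed": res.observed_overlaps,
                        "null_mean": float(res.null_overlaps.mean()),
                        "p_value": res.p_value,
                        "z_score": "" if res.z_score is None else f"{res.z_score:.4f}",
                        "null_mode": res.null_mode,
                    }
                )
                emit(f"overlap_null_{label}.tsv", lambda p, r=res: r.null_to_tsv(p))
            if rows:
                emit(
                    "overlap_tests.tsv",
                    lambda p: pd.DataFrame(rows).to_csv(p, sep="\t", index=False),
                )
            tick("overlap")
        except Exception as exc:  # noqa: BLE001
            raise StageError("overlap", exc) from exc

    return _finish(manifest, out)


def _finish(manifest: dict, out: Path) -> dict:
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
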