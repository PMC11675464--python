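"""Synthetic QTL-catalog generator with known ground truth.

Emulates, at desk scale, the statistical structure of a livestock QTL
database and its companion genome annotation: a multi-chromosome genome
with non-uniformly distributed genes, a study/trait hierarchy
(class -> type -> trait), a QTL placement mixture (uniform by length,
gene-proportional, planted hotspot windows), a large fraction of 1 bp
SNP-type records, and injected data defects — exact duplicates, coordinate
anomalies, and over-long intervals — at configured rates.  Every planted
quantity is recorded in :class:`SyntheticTruth` so the QC ledger, the
enrichment tests, and the correlation machinery can be validated against
known answers.

Defects are injected as corrupted *copies* appended after the clean
records, so the clean set remains the truth baseline.  All randomness
flows from one seed through named substreams (genome, placement,
corruption).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .genome_io import (
    GeneRecord,
    GenomeAssembly,
    QTLRecord,
    write_assembly,
    write_genes_gff3,
    write_qtl_gff,
)

_SUBSTREAMS = {"genome": 0, "placement": 1, "corruption": 2}


def _rng(seed: int, substream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _SUBSTREAMS[substream]]))


@dataclass(frozen=True)
class Hotspot:
    """A planted QTL-dense window: fold-enrichment ``fold`` (> 1) of
    placement mass on one window, optionally forcing a trait label."""

    chrom: str
    window_start: int
    fold: float
    trait_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ValueError("hotspot fold-enrichment must exceed 1")


@dataclass(frozen=True)
class TraitHierarchy:
    n_classes: int = 4
    n_types: int = 12
    n_traits: int = 36

    def __post_init__(self) -> None:
        if not (1 <= self.n_classes <= self.n_types <= self.n_traits):
            raise ValueError("need n_classes <= n_types <= n_traits, all >= 1")

    def tables(self) -> pd.DataFrame:
        """trait -> type -> class assignment (traits cycle over types)."""
        rows = []
        for t in range(self.n_traits):
            ty = t % self.n_types
            rows.append(
                {
                    "trait": f"trait_{t + 1:03d}",
                    "type": f"type_{ty + 1:02d}",
                    "class": f"class_{ty % self.n_classes + 1}",
                }
            )
        return pd.DataFrame(rows)


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset (lengths in bp)."""

    seed: int = 0
    species_label: str = "synthetic"
    n_chromosomes: int = 8
    chromosome_lengths: Optional[Sequence[int]] = None
    chrom_length_log_mean: float = math.log(16_000_000)
    chrom_length_log_sigma: float = 0.35
    n_genes: int = 1_500
    gene_density_segments: int = 4
    gene_density_log_sigma: float = 0.6
    gene_length_range: tuple[int, int] = (2_000, 50_000)
    n_studies: int = 50
    trait_hierarchy: TraitHierarchy = field(default_factory=TraitHierarchy)
    n_qtl: int = 4_000
    placement_mixture: tuple[float, float, float] = (0.25, 0.65, 0.10)
    hotspot_window: int = 1_000_000
    hotspots: tuple[Hotspot, ...] = (
        Hotspot("chr1", 2_000_000, 5.0),
        Hotspot("chr2", 1_000_000, 5.0, trait_label="trait_001"),
    )
    snp_length_fraction: float = 0.79
    qtl_length_range: tuple[int, int] = (5_000, 5_000_000)
    duplicate_rate: float = 0.10
    anomaly_rate: float = 0.03
    overlength_rate: float = 0.02
    max_qtl_length: int = 10_000_000  # over-long injections exceed this

    def __post_init__(self) -> None:
        if abs(sum(self.placement_mixture) - 1.0) > 1e-9:
            raise ValueError("placement_mixture fractions must sum to 1")
        if any(f < 0 for f in self.placement_mixture):
            raise ValueError("placement_mixture fractions must be non-negative")
        if self.placement_mixture[2] > 0 and not self.hotspots:
            raise ValueError("hotspot mixture mass requires at least one hotspot")
        for rate in (self.duplicate_rate, self.anomaly_rate, self.overlength_rate):
            if not 0 <= rate < 1:
                raise ValueError("rates must lie in [0, 1)")
        if not 0 <= self.snp_length_fraction <= 1:
            raise ValueError("snp_length_fraction must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "trait_hierarchy" in data:
            data["trait_hierarchy"] = TraitHierarchy(**data["trait_hierarchy"])
        if "hotspots" in data:
            data["hotspots"] = tuple(Hotspot(**h) for h in data["hotspots"])
        for key in ("placement_mixture", "gene_length_range", "qtl_length_range"):
            if key in data:
                data[key] = tuple(data[key])
        if "chromosome_lengths" in data and data["chromosome_lengths"] is not None:
            data["chromosome_lengths"] = list(data["chromosome_lengths"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {
            "seed": self.seed,
            "species_label": self.species_label,
            "n_chromosomes": self.n_chromosomes,
            "chromosome_lengths": (
                None if self.chromosome_lengths is None else list(self.chromosome_lengths)
            ),
            "chrom_length_log_mean": self.chrom_length_log_mean,
            "chrom_length_log_sigma": self.chrom_length_log_sigma,
            "n_genes": self.n_genes,
            "gene_density_segments": self.gene_density_segments,
            "gene_density_log_sigma": self.gene_density_log_sigma,
            "gene_length_range": list(self.gene_length_range),
            "n_studies": self.n_studies,
            "trait_hierarchy": {
                "n_classes": self.trait_hierarchy.n_classes,
                "n_types": self.trait_hierarchy.n_types,
                "n_traits": self.trait_hierarchy.n_traits,
            },
            "n_qtl": self.n_qtl,
            "placement_mixture": list(self.placement_mixture),
            "hotspot_window": self.hotspot_window,
            "hotspots": [
                {
                    "chrom": h.chrom,
                    "window_start": h.window_start,
                    "fold": h.fold,
                    "trait_label": h.trait_label,
                }
                for h in self.hotspots
            ],
            "snp_length_fraction": self.snp_length_fraction,
            "qtl_length_range": list(self.qtl_length_range),
            "duplicate_rate": self.duplicate_rate,
            "anomaly_rate": self.anomaly_rate,
            "overlength_rate": self.overlength_rate,
            "max_qtl_length": self.max_qtl_length,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class SyntheticTruth:
    """Everything planted into one synthetic dataset."""

    hotspots: tuple[Hotspot, ...]
    planted_counts: dict[str, int]  # per QC-ledger removal reason
    window_intensity: pd.DataFrame  # chrom, start, end, expected QTL
    trait_table: pd.DataFrame
    study_weights: pd.DataFrame
    clean_records: list[QTLRecord]


# ---------------------------------------------------------------------------
# Genome and genes
# ---------------------------------------------------------------------------


def simulate_genome(cfg: SimConfig) -> tuple[GenomeAssembly, list[GeneRecord]]:
    """Draw chromosome lengths and place genes by a piecewise-constant
    inhomogeneous intensity (per-segment log-normal multipliers)."""
    rng = _rng(cfg.seed, "genome")
    if cfg.chromosome_lengths is not None:
        lengths = [int(v) for v in cfg.chromosome_lengths]
    else:
        draws = rng.lognormal(cfg.chrom_length_log_mean, cfg.chrom_length_log_sigma,
                              cfg.n_chromosomes)
        lengths = [max(2_000_000, int(v)) for v in draws]
        if cfg.overlength_rate > 0 and max(lengths) <= cfg.max_qtl_length:
            # over-long injections need one chromosome that can hold them
            scale = 1.5 * cfg.max_qtl_length / max(lengths)
            lengths = [int(v * scale) for v in lengths]
    assembly = GenomeAssembly(
        cfg.species_label,
        tuple((f"chr{i + 1}", length) for i, length in enumerate(lengths)),
    )
    if cfg.n_genes > assembly.total_length // max(1, cfg.gene_length_range[0]):
        raise ValueError("more genes requested than the genome can hold")

    # per-chromosome segments with log-normal density multipliers
    seg_chrom: list[str] = []
    seg_bounds: list[tuple[int, int]] = []
    seg_weight: list[float] = []
    for name, length in assembly.chromosomes:
        edges = np.linspace(0, length, cfg.gene_density_segments + 1).astype(int)
        mults = rng.lognormal(0.0, cfg.gene_density_log_sigma, cfg.gene_density_segments)
        for (a, b), m in zip(zip(edges[:-1], edges[1:]), mults):
            seg_chrom.append(name)
            seg_bounds.append((int(a), int(b)))
            seg_weight.append(float(m) * (b - a))
    weights = np.array(seg_weight)
    weights /= weights.sum()

    genes: list[GeneRecord] = []
    seg_idx = rng.choice(len(weights), size=cfg.n_genes, p=weights)
    lo, hi = cfg.gene_length_range
    for i, si in enumerate(seg_idx):
        chrom = seg_chrom[si]
        a, b = seg_bounds[si]
        glen = int(rng.integers(lo, hi + 1))
        chrom_len = assembly.length_of(chrom)
        glen = min(glen, chrom_len)
        start = int(rng.integers(a, b))
        start = min(start, chrom_len - glen)
        genes.append(
            GeneRecord(chrom, start, start + glen, f"gene_{i + 1:05d}",
                       f"GENE{i + 1:05d}", "protein_coding")
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    return assembly, genes


# ---------------------------------------------------------------------------
# QTL placement
# ---------------------------------------------------------------------------


def _window_table(assembly: GenomeAssembly, window: int) -> pd.DataFrame:
    rows = []
    for name, length in assembly.chromosomes:
        edges = list(range(0, length, window)) + [length]
        for a, b in zip(edges[:-1], edges[1:]):
            rows.append({"chrom": name, "start": a, "end": b})
    return pd.DataFrame(rows)


def _zipf_weights(n: int, exponent: float = 0.8) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** exponent
    return w / w.sum()


def simulate_qtl_records(
    cfg: SimConfig,
    assembly: GenomeAssembly,
    genes: Sequence[GeneRecord],
) -> tuple[list[QTLRecord], list[QTLRecord], SyntheticTruth]:
    """Generate clean QTL records plus a corrupted full record list.

    Returns ``(clean, full, truth)`` where ``full`` is the clean list with
    duplicates, anomalies, and over-long copies appended — what the emitted
    GFF contains.
    """
    rng = _rng(cfg.seed, "placement")
    f_uniform, f_gene, f_hot = cfg.placement_mixture

    windows = _window_table(assembly, cfg.hotspot_window)
    win_len = (windows["end"] - windows["start"]).to_numpy(dtype=float)
    # genes per window, by gene midpoint
    gene_mid = pd.DataFrame(
        {"chrom": [g.chrom for g in genes], "mid": [g.midpoint for g in genes]}
    )
    win_genes = np.zeros(len(windows), dtype=float)
    win_gene_members: list[list[int]] = [[] for _ in range(len(windows))]
    win_lookup = {
        (row.chrom, row.start): i for i, row in enumerate(windows.itertuples(index=False))
    }
    n_win_per_chrom = windows.groupby("chrom").size().to_dict()
    for gi, g in enumerate(genes):
        w_start = (g.midpoint // cfg.hotspot_window) * cfg.hotspot_window
        key = (g.chrom, w_start)
        if key not in win_lookup:  # midpoint in final partial window
            w_start = ((assembly.length_of(g.chrom) - 1) // cfg.hotspot_window) * cfg.hotspot_window
            key = (g.chrom, w_start)
        idx = win_lookup[key]
        win_genes[idx] += 1
        win_gene_members[idx].append(gi)

    hot_mass = np.zeros(len(windows), dtype=float)
    for h in cfg.hotspots:
        key = (h.chrom, h.window_start)
        if key not in win_lookup:
            raise ValueError(f"hotspot window {key} outside the assembly grid")
        hot_mass[win_lookup[key]] += h.fold
    if hot_mass.sum() > 0:
        hot_mass /= hot_mass.sum()

    p_window = (
        f_uniform * win_len / win_len.sum()
        + (f_gene * win_genes / win_genes.sum() if win_genes.sum() else 0.0)
        + f_hot * hot_mass
    )
    p_window /= p_window.sum()

    trait_table = cfg.trait_hierarchy.tables()
    trait_weights = _zipf_weights(len(trait_table))
    study_ids = [f"{10_000_001 + i}" for i in range(cfg.n_studies)]
    study_weights = _zipf_weights(cfg.n_studies)
    forced_trait = {}
    for h in cfg.hotspots:
        if h.trait_label is not None:
            if h.trait_label not in set(trait_table["trait"]):
                raise ValueError(f"hotspot trait {h.trait_label!r} not in the hierarchy")
            forced_trait[win_lookup[(h.chrom, h.window_start)]] = h.trait_label

    n = cfg.n_qtl
    win_idx = rng.choice(len(windows), size=n, p=p_window)
    # within-window source mirrors the window-level mixture composition
    comp_probs = np.stack(
        [
            f_uniform * win_len / win_len.sum(),
            (f_gene * win_genes / win_genes.sum()) if win_genes.sum() else np.zeros_like(win_len),
            f_hot * hot_mass,
        ],
        axis=1,
    )
    row_sums = comp_probs.sum(axis=1, keepdims=True)
    degenerate = row_sums[:, 0] == 0
    comp_probs[degenerate] = [1.0, 0.0, 0.0]
    row_sums[degenerate] = 1.0
    comp_cum = np.cumsum(comp_probs / row_sums, axis=1)[win_idx]
    comp = (rng.random(n)[:, None] > comp_cum).sum(axis=1)

    w_start = windows["start"].to_numpy()[win_idx]
    w_end = windows["end"].to_numpy()[win_idx]
    mids = w_start + (rng.random(n) * (w_end - w_start)).astype(np.int64)
    gene_pick = rng.random(n)
    is_snp = rng.random(n) < cfg.snp_length_fraction
    lo, hi = cfg.qtl_length_range
    qlens = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n)).astype(np.int64)
    trait_idx = rng.choice(len(trait_table), size=n, p=trait_weights)
    study_idx = rng.choice(cfg.n_studies, size=n, p=study_weights)

    trait_names = trait_table["trait"].to_list()
    trait_rows = {row["trait"]: (row["type"], row["class"]) for _, row in trait_table.iterrows()}
    records: list[QTLRecord] = []
    lengths_map = assembly.lengths
    chrom_arr = windows["chrom"].to_numpy()
    for i in range(n):
        wi = int(win_idx[i])
        chrom = chrom_arr[wi]
        chrom_len = lengths_map[chrom]
        gene_symbol = ""
        mid = int(mids[i])
        if comp[i] == 1 and win_gene_members[wi]:
            members = win_gene_members[wi]
            g = genes[members[int(gene_pick[i] * len(members))]]
            mid = g.midpoint
            gene_symbol = g.symbol  # the reported associated gene
        if is_snp[i]:
            start, end = mid, mid + 1
        else:
            qlen = min(int(qlens[i]), chrom_len)
            start = mid - qlen // 2
            end = start + qlen
            if start < 0:
                start, end = 0, qlen
            elif end > chrom_len:
                start, end = chrom_len - qlen, chrom_len
        trait_name = trait_names[int(trait_idx[i])]
        if comp[i] == 2 and wi in forced_trait:
            trait_name = forced_trait[wi]
        ttype, tclass = trait_rows[trait_name]
        records.append(
            QTLRecord(
                chrom=chrom,
                start=start,
                end=end,
                qtl_id=f"SYN{i + 1:06d}",
                trait_name=trait_name,
                trait_type=ttype,
                trait_class=tclass,
                study_id=study_ids[int(study_idx[i])],
                gene_symbol=gene_symbol,
            )
        )

    _make_unique(records, lengths_map)
    full, planted = _corrupt(cfg, assembly, records)

    truth = SyntheticTruth(
        hotspots=cfg.hotspots,
        planted_counts=planted,
        window_intensity=windows.assign(expected=p_window * cfg.n_qtl),
        trait_table=trait_table,
        study_weights=pd.DataFrame({"study_id": study_ids, "weight": study_weights}),
        clean_records=list(records),
    )
    return records, full, truth


def _make_unique(records: list[QTLRecord], lengths_map: dict[str, int]) -> None:
    """Nudge colliding records by a few bp so the clean set has no exact
    duplicates under the (chrom, start, end, trait, study) key."""
    seen: set[tuple] = set()
    for i, r in enumerate(records):
        key = (r.chrom, r.start, r.end, r.trait_name, r.study_id)
        length = r.end - r.start  # type: ignore[operator]
        n_positions = lengths_map[r.chrom] - length + 1
        shift = 1
        while key in seen:
            new_start = (r.start + shift) % n_positions  # type: ignore[operator]
            key = (r.chrom, new_start, new_start + length, r.trait_name, r.study_id)
            shift += 1
        if shift > 1:
            r = replace(r, start=key[1], end=key[2])
        seen.add(key)
        records[i] = r


_ANOMALY_KINDS = ("missing", "zero_span", "negative_start", "off_chromosome", "beyond_end")


def _corrupt(
    cfg: SimConfig, assembly: GenomeAssembly, clean: Sequence[QTLRecord]
) -> tuple[list[QTLRecord], dict[str, int]]:
    rng = _rng(cfg.seed, "corruption")
    full = list(clean)
    n = len(clean)
    planted = {
        "missing_coordinates": 0,
        "anomalous_position": 0,
        "out_of_bounds": 0,
        "over_length": 0,
        "duplicate": 0,
    }

    n_dup = round(cfg.duplicate_rate * n)
    for j, idx in enumerate(rng.choice(n, size=n_dup, replace=True)):
        full.append(replace(clean[int(idx)], qtl_id=f"DUP{j + 1:05d}"))
    planted["duplicate"] = n_dup

    n_over = round(cfg.overlength_rate * n)
    if n_over:
        long_chroms = [
            (name, length)
            for name, length in assembly.chromosomes
            if length > cfg.max_qtl_length + 1
        ]
        if not long_chroms:
            raise ValueError(
                "over-length injection requires a chromosome longer than max_qtl_length"
            )
        for j in range(n_over):
            name, length = long_chroms[int(rng.choice(len(long_chroms)))]
            qlen = int(rng.integers(cfg.max_qtl_length + 1, length + 1))
            start = int(rng.integers(0, length - qlen + 1))
            base = clean[int(rng.choice(n))]
            full.append(
                replace(base, chrom=name, start=start, end=start + qlen,
                        qtl_id=f"OVER{j + 1:05d}")
            )
    planted["over_length"] = n_over

    n_anom = round(cfg.anomaly_rate * n)
    for j in range(n_anom):
        kind = _ANOMALY_KINDS[j % len(_ANOMALY_KINDS)]
        base = clean[int(rng.choice(n))]
        rid = f"ANOM{j + 1:05d}"
        if kind == "missing":
            full.append(replace(base, start=None, end=None, qtl_id=rid))
            planted["missing_coordinates"] += 1
        elif kind == "zero_span":
            full.append(replace(base, end=base.start, qtl_id=rid))
            planted["anomalous_position"] += 1
        elif kind == "negative_start":
            full.append(replace(base, start=-1, qtl_id=rid))
            planted["anomalous_position"] += 1
        elif kind == "off_chromosome":
            full.append(replace(base, chrom="chrUn_1", qtl_id=rid))
            planted["out_of_bounds"] += 1
        else:  # beyond_end
            chrom_len = assembly.length_of(base.chrom)
            full.append(
                replace(base, start=chrom_len - 1, end=chrom_len + 50_000, qtl_id=rid)
            )
            planted["out_of_bounds"] += 1
    return full, planted


# ---------------------------------------------------------------------------
# Bundle emission
# ---------------------------------------------------------------------------


def simulate_qtl(
    cfg: SimConfig,
    assembly: GenomeAssembly,
    genes: Sequence[GeneRecord],
    gff_path,
) -> tuple[Path, SyntheticTruth]:
    """Place QTL, inject defects, and emit the catalog GFF."""
    _, full, truth = simulate_qtl_records(cfg, assembly, genes)
    gff_path = Path(gff_path)
    write_qtl_gff(full, gff_path)
    return gff_path, truth


def simulate_bundle(cfg: SimConfig, out_dir) -> tuple[dict[str, Path], SyntheticTruth]:
    """Emit a complete input bundle: assembly TSV, gene GFF3, QTL GFF,
    config YAML, and truth tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    assembly, genes = simulate_genome(cfg)
    paths = {
        "assembly": out / "assembly.tsv",
        "genes": out / "genes.gff3",
        "qtl": out / "qtl.gff",
        "config": out / "sim_config.yaml",
        "truth_counts": out / "truth_counts.tsv",
        "truth_hotspots": out / "truth_hotspots.tsv",
        "truth_window_intensity": out / "truth_window_intensity.tsv",
    }
    write_assembly(assembly, paths["assembly"])
    write_genes_gff3(genes, paths["genes"])
    _, truth = simulate_qtl(cfg, assembly, genes, paths["qtl"])
    cfg.to_yaml(paths["config"])
    pd.DataFrame(
        sorted(truth.planted_counts.items()), columns=["reason", "count"]
    ).to_csv(paths["truth_counts"], sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "chrom": h.chrom,
                "window_start": h.window_start,
                "fold": h.fold,
                "trait_label": h.trait_label or "",
            }
            for h in truth.hotspots
        ]
    ).to_csv(paths["truth_hotspots"], sep="\t", index=False)
    truth.window_intensity.to_csv(paths["truth_window_intensity"], sep="\t", index=False)
    return paths, truth
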