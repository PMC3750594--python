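"""Synthetic methylation-array datasets with known ground truth.

The generator emulates the salient features of array methylation data so the
whole pipeline can be exercised and benchmarked without external downloads:

* a bimodal marginal beta distribution (most CpGs near 0.1 or 0.9);
* local co-methylation: probes within 1 kb share a baseline up to jitter;
* per-individual random offsets (the individual term of the per-CpG model),
  shared across tissues for a configurable fraction of probes;
* planted regions of consecutive probes with a tissue-specific mean shift
  (the ground-truth regions the caller should recover);
* SNP-like probes whose signal is a genotype-driven trimodal mean
  {0.05, 0.5, 0.95}, identical in every tissue of an individual;
* additive residual noise on the beta scale, clamped to [0, 1].

The default configuration is a matched design of four tissues by five
individuals with residual sd 0.03, individual sd 0.02 and 200 planted
5-probe regions of effect 0.25 - the bench conditions used throughout the
test-suite and the acceptance checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io_formats import (
    BetaMatrix,
    GeneModel,
    IntervalTrack,
    ProbeManifest,
    SampleSheet,
)

__all__ = [
    "PlantedDMR",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_methylation",
    "simulate_tracks",
    "write_dataset",
]


@dataclass(frozen=True)
class PlantedDMR:
    n_probes: int = 5
    effect: float = 0.25
    tissue: str = "liver"


def _default_planted() -> tuple[PlantedDMR, ...]:
    tissues = ("liver", "muscle", "fat")
    return tuple(
        PlantedDMR(n_probes=5, effect=0.25, tissue=tissues[i % len(tissues)])
        for i in range(200)
    )


@dataclass(frozen=True)
class SimulationConfig:
    n_probes: int = 6000
    tissues: tuple[str, ...] = ("blood", "liver", "muscle", "fat")
    individuals_per_tissue: int = 5
    # mean inter-probe gap; 700 bp puts ~85% of probes inside <1 kb runs,
    # the array-density regime the background correction exists for
    probe_spacing: float = 700.0
    min_gap: int = 2
    baseline_low: float = 0.1
    baseline_high: float = 0.9
    high_weight: float = 0.5
    baseline_concentration: float = 30.0
    comethylation_window: int = 1000
    comethylation_jitter: float = 0.02
    planted_dmrs: tuple[PlantedDMR, ...] = field(default_factory=_default_planted)
    individual_sd: float = 0.02
    residual_sd: float = 0.03
    snp_fraction: float = 0.02
    snp_maf: float = 0.3
    correlated_fraction: float = 1.0
    chromosome: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.individual_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.high_weight <= 1:
            raise ValueError("high_weight must be in [0, 1]")
        need = sum(d.n_probes for d in self.planted_dmrs) + 2 * len(self.planted_dmrs)
        if need > self.n_probes:
            raise ValueError(
                f"{len(self.planted_dmrs)} planted regions need {need} probes "
                f"but n_probes={self.n_probes}"
            )
        for d in self.planted_dmrs:
            if d.tissue not in self.tissues:
                raise ValueError(f"planted tissue {d.tissue!r} not in tissues")


class SimulatedDataset(NamedTuple):
    matrix: BetaMatrix
    sheet: SampleSheet
    manifest: ProbeManifest
    truth: pd.DataFrame


def _place_regions(cfg: SimulationConfig, rng) -> list[tuple[int, int]]:
    """Disjoint (start_index, size) for planted regions, spread over probes."""
    k = len(cfg.planted_dmrs)
    if k == 0:
        return []
    block = cfg.n_probes // k
    out = []
    for i, d in enumerate(cfg.planted_dmrs):
        lo = i * block + 1
        hi = (i + 1) * block - d.n_probes - 1
        start = int(rng.integers(lo, max(lo + 1, hi)))
        out.append((start, d.n_probes))
    return out


def simulate_methylation(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Draw a full dataset (matrix, sheet, manifest, truth) from the config.

    Planted region probes are consecutive with gaps well under 1 kb and are
    separated from background probes by at least 2 kb so truth regions are
    unambiguous; the seed fully determines the output.
    """
    cfg = config if config is not None else SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_probes
    tissues = list(cfg.tissues)
    indivs = [f"ind{i + 1}" for i in range(cfg.individuals_per_tissue)]

    # --- probe placement -------------------------------------------------
    regions = _place_regions(cfg, rng)
    dmr_id = np.full(n, -1, dtype=np.int64)
    for rid, (start, size) in enumerate(regions):
        dmr_id[start : start + size] = rid
    gaps = np.maximum(
        cfg.min_gap, rng.geometric(min(1.0, 1.0 / cfg.probe_spacing), size=n)
    ).astype(np.int64)
    # a probe is "within" a region if the previous probe is in the same
    # region; those gaps are forced under 1 kb, region boundaries over 2 kb
    within = np.zeros(n, dtype=bool)
    within[1:] = (dmr_id[1:] >= 0) & (dmr_id[1:] == dmr_id[:-1])
    gaps[within] = rng.integers(50, 251, size=int(within.sum()))
    boundary = np.zeros(n, dtype=bool)
    boundary[1:] = (dmr_id[1:] != dmr_id[:-1]) & ((dmr_id[1:] >= 0) | (dmr_id[:-1] >= 0))
    gaps[boundary] = np.maximum(gaps[boundary], 2001)
    positions = 1000 + np.cumsum(gaps)
    probe_ids = np.array([f"cg{i:07d}" for i in range(n)])

    # --- baseline with local co-methylation ------------------------------
    baseline = np.empty(n)
    new_block = np.ones(n, dtype=bool)
    new_block[1:] = gaps[1:] >= cfg.comethylation_window
    conc = cfg.baseline_concentration
    for i in range(n):
        if new_block[i]:
            mode = (
                cfg.baseline_high
                if rng.random() < cfg.high_weight
                else cfg.baseline_low
            )
            baseline[i] = rng.beta(mode * conc, (1.0 - mode) * conc)
        else:
            baseline[i] = baseline[i - 1] + rng.normal(0.0, cfg.comethylation_jitter)
    baseline = np.clip(baseline, 0.02, 0.98)

    # --- probe roles ------------------------------------------------------
    free = np.flatnonzero(dmr_id < 0)
    n_snp = int(round(cfg.snp_fraction * n))
    snp_idx = rng.choice(free, size=min(n_snp, len(free)), replace=False)
    is_snp = np.zeros(n, dtype=bool)
    is_snp[snp_idx] = True
    is_corr = rng.random(n) < cfg.correlated_fraction
    is_corr[is_snp] = False

    # --- tissue effects ---------------------------------------------------
    t_index = {t: i for i, t in enumerate(tissues)}
    effect = np.zeros((n, len(tissues)))
    affected = np.full(n, "", dtype=object)
    effect_size = np.zeros(n)
    for rid, (start, size) in enumerate(regions):
        spec = cfg.planted_dmrs[rid]
        sl = slice(start, start + size)
        sign = np.where(baseline[sl] > 0.5, -1.0, 1.0)
        effect[sl, t_index[spec.tissue]] = sign * spec.effect
        affected[sl] = spec.tissue
        effect_size[sl] = spec.effect

    # --- individual offsets ----------------------------------------------
    m = len(indivs)
    shared_off = rng.normal(0.0, cfg.individual_sd, size=(n, m))
    per_tissue_off = rng.normal(0.0, cfg.individual_sd, size=(n, m, len(tissues)))
    genotype = rng.binomial(2, cfg.snp_maf, size=(n, m))
    geno_mean = np.array([0.05, 0.5, 0.95])[genotype]

    # --- assemble ---------------------------------------------------------
    sample_rows = []
    columns = {}
    for t in tissues:
        ti = t_index[t]
        for ii, indiv in enumerate(indivs):
            sid = f"{t}_{indiv}"
            sample_rows.append({"sample_id": sid, "tissue": t, "individual": indiv})
            mu = baseline + effect[:, ti]
            off = np.where(is_corr, shared_off[:, ii], per_tissue_off[:, ii, ti])
            y = mu + off
            y = np.where(is_snp, geno_mean[:, ii], y)
            y = y + rng.normal(0.0, cfg.residual_sd, size=n)
            columns[sid] = np.clip(y, 0.0, 1.0)

    manifest = ProbeManifest(
        pd.DataFrame(
            {
                "probe_id": probe_ids,
                "chromosome": cfg.chromosome,
                "position": positions,
                "strand": rng.choice(["+", "-"], size=n),
            }
        )
    )
    sheet = SampleSheet(pd.DataFrame(sample_rows))
    values = pd.DataFrame(columns, index=pd.Index(probe_ids, name="probe_id"))
    matrix = BetaMatrix(values=values, manifest=manifest, samples=sheet)
    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chromosome": cfg.chromosome,
            "position": positions,
            "dmr_id": np.where(dmr_id >= 0, dmr_id, pd.NA),
            "affected_tissue": np.where(dmr_id >= 0, affected, pd.NA),
            "effect": effect_size,
            "baseline": baseline,
            "is_snp_like": is_snp,
            "is_cross_tissue_correlated": is_corr,
        }
    )
    return SimulatedDataset(matrix=matrix, sheet=sheet, manifest=manifest, truth=truth)


def simulate_tracks(
    manifest: ProbeManifest,
    n_genes: int = 40,
    n_islands: int = 60,
    island_length: tuple[int, int] = (200, 1500),
    n_random_tracks: int = 2,
    track_coverage: float = 0.2,
    coupling: float = 0.0,
    dmr_spans: list[tuple[str, int, int]] | None = None,
    seed: int = 0,
) -> tuple[list[GeneModel], IntervalTrack, dict[str, IntervalTrack]]:
    """Random gene models, a CGI track and binary annotation tracks.

    With ``coupling = 0`` islands and tracks are placed independently of any
    planted regions; with ``coupling > 0`` that fraction of islands is laid
    directly over the provided ``dmr_spans`` (1-based spans) to create true
    enrichment for power tests.
    """
    rng = np.random.default_rng(seed)
    tab = manifest.sorted().table
    lo = int(tab["position"].min())
    hi = int(tab["position"].max())
    chroms = tab["chromosome"].unique()

    genes: list[GeneModel] = []
    for i in range(n_genes):
        chrom = str(rng.choice(chroms))
        tss = int(rng.integers(lo, hi))
        length = int(rng.integers(2_000, 50_000))
        strand = str(rng.choice(["+", "-"]))
        if strand == "+":
            genes.append(GeneModel(f"G{i:03d}", chrom, "+", tss, tss + length))
        else:
            genes.append(GeneModel(f"G{i:03d}", chrom, "-", tss + length, tss))

    islands: list[tuple[str, int, int]] = []
    n_coupled = int(round(coupling * n_islands)) if dmr_spans else 0
    for j in range(n_coupled):
        chrom, s, e = dmr_spans[j % len(dmr_spans)]
        islands.append((chrom, max(0, s - 1), e))  # 1-based span -> BED
    for _ in range(n_islands - n_coupled):
        chrom = str(rng.choice(chroms))
        start = int(rng.integers(lo, hi))
        islands.append((chrom, start, start + int(rng.integers(*island_length))))
    cgi = IntervalTrack.from_tuples("CGI", islands)

    tracks: dict[str, IntervalTrack] = {}
    n = len(tab)
    for k in range(n_random_tracks):
        pick = rng.random(n) < track_coverage
        tuples = [
            (row.chromosome, row.position - 1, row.position)
            for row, flag in zip(tab.itertuples(index=False), pick)
            if flag
        ]
        name = f"track{k + 1}"
        tracks[name] = (
            IntervalTrack.from_tuples(name, tuples)
            if tuples
            else IntervalTrack(name=name, intervals={})
        )
    return genes, cgi, tracks


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the standard input files (beta TSV, sheet, manifest) plus truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": out_dir / "beta.tsv",
        "sheet": out_dir / "samples.tsv",
        "manifest": out_dir / "manifest.tsv",
        "truth": out_dir / "truth.tsv",
    }
    dataset.matrix.values.to_csv(paths["beta"], sep="\t", na_rep="NA")
    dataset.sheet.table.to_csv(paths["sheet"], sep="\t", index=False)
    dataset.manifest.table.to_csv(paths["manifest"], sep="\t", index=False)
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False, na_rep="NA")
    return paths
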