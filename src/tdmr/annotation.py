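"""Gene-centric, CpG-density and interval-track annotation of probes.

The genome is partitioned into five gene-centric classes measured in the
strand-oriented coordinates of the nearest-TSS gene (offset s = signed bp
from the TSS, L = gene length):

* distal promoter   : -10,000 <= s < -1,500
* proximal promoter : -1,500 <= s <= +500
* gene body         : +500 < s <= L
* downstream        : L < s <= L + 5,000
* intergenic        : everything else

CpG-density classes relative to merged CpG islands: inside an island = cgi,
within 2 kb of an island edge = shore, within the next 2 kb = shelf, else
non_cgi; where bands of neighbouring islands overlap the precedence is
cgi > shore > shelf.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel, IntervalTrack, ProbeManifest, normalize_chromosome

__all__ = [
    "GENE_LABELS",
    "CGI_LABELS",
    "gene_centric_label",
    "cgi_label",
    "annotate_probes",
    "map_dmr_to_nearest_gene",
]

GENE_LABELS = (
    "intergenic",
    "distal_promoter",
    "proximal_promoter",
    "gene_body",
    "downstream",
)
CGI_LABELS = ("cgi", "shore", "shelf", "non_cgi")

SHORE_BP = 2_000
SHELF_BP = 2_000
DISTAL_BP = 10_000
PROXIMAL_UP_BP = 1_500
PROXIMAL_DOWN_BP = 500
DOWNSTREAM_BP = 5_000


class NearestGene(NamedTuple):
    gene_id: str | None
    distance: int | None
    tie: bool


def _genes_by_chrom(genes: Sequence[GeneModel]):
    by: dict[str, list[GeneModel]] = {}
    for g in genes:
        by.setdefault(g.chromosome, []).append(g)
    out = {}
    for chrom, gs in by.items():
        # order by TSS, ties by gene_id so the lexically first wins searches
        gs.sort(key=lambda g: (g.tss, g.gene_id))
        out[chrom] = (
            np.asarray([g.tss for g in gs], dtype=np.int64),
            gs,
        )
    return out


def _nearest_gene_obj(
    position: int, tss: np.ndarray, gs: list[GeneModel]
) -> tuple[GeneModel, int, bool]:
    idx = int(np.searchsorted(tss, position))
    cand = [i for i in (idx - 1, idx) if 0 <= i < len(gs)]
    best_d = int(min(abs(position - int(tss[i])) for i in cand))
    winners: list[GeneModel] = []
    for target in {position - best_d, position + best_d}:
        lo = int(np.searchsorted(tss, target, side="left"))
        hi = int(np.searchsorted(tss, target, side="right"))
        winners.extend(gs[lo:hi])
    winners.sort(key=lambda g: g.gene_id)
    return winners[0], best_d, len(winners) > 1


def _nearest_gene(position: int, tss: np.ndarray, gs: list[GeneModel]) -> NearestGene:
    gene, d, tie = _nearest_gene_obj(position, tss, gs)
    return NearestGene(gene.gene_id, d, tie)


def _classify_offset(s: int, gene_length: int) -> str:
    if -PROXIMAL_UP_BP <= s <= PROXIMAL_DOWN_BP:
        return "proximal_promoter"
    if -DISTAL_BP <= s < -PROXIMAL_UP_BP:
        return "distal_promoter"
    if PROXIMAL_DOWN_BP < s <= gene_length:
        return "gene_body"
    if gene_length < s <= gene_length + DOWNSTREAM_BP:
        return "downstream"
    return "intergenic"


def gene_centric_label(
    position: tuple[str, int], genes: Sequence[GeneModel]
) -> tuple[str, NearestGene]:
    """Class and nearest-TSS gene for a single (chromosome, 1-based bp)."""
    chrom, pos = normalize_chromosome(position[0]), int(position[1])
    by = _genes_by_chrom(genes)
    if chrom not in by:
        return "intergenic", NearestGene(None, None, False)
    tss, gs = by[chrom]
    gene, d, tie = _nearest_gene_obj(pos, tss, gs)
    s = pos - gene.tss if gene.strand == "+" else gene.tss - pos
    return _classify_offset(s, gene.length), NearestGene(gene.gene_id, d, tie)


def _island_distance(pos: np.ndarray, ivs: np.ndarray) -> np.ndarray:
    """bp from each 1-based position to the nearest merged island (0 inside)."""
    starts, ends = ivs[:, 0], ivs[:, 1]
    idx = np.searchsorted(starts, pos, side="left")
    d = np.full(pos.shape, np.iinfo(np.int64).max, dtype=np.int64)
    left = idx - 1
    ok = left >= 0
    # island to the left: inside if pos <= end, else distance pos - end
    d_left = np.where(
        pos[ok] <= ends[left[ok]], 0, pos[ok] - ends[left[ok]]
    )
    d[ok] = d_left
    right = idx
    ok = right < len(starts)
    d_right = starts[right[ok]] - pos[ok] + 1  # pos == start -> 1 bp outside
    d[ok] = np.minimum(d[ok], np.maximum(d_right, 0))
    return d


def cgi_label(position: tuple[str, int], cgis: IntervalTrack) -> str:
    """CpG-density class of a single (chromosome, 1-based bp)."""
    chrom = normalize_chromosome(position[0])
    ivs = cgis.intervals.get(chrom)
    if ivs is None or len(ivs) == 0:
        return "non_cgi"
    d = int(_island_distance(np.asarray([int(position[1])], dtype=np.int64), ivs)[0])
    if d == 0:
        return "cgi"
    if d <= SHORE_BP:
        return "shore"
    if d <= SHORE_BP + SHELF_BP:
        return "shelf"
    return "non_cgi"


def annotate_probes(
    manifest: ProbeManifest,
    genes: Sequence[GeneModel],
    cgis: IntervalTrack,
    extra_tracks: Iterable[IntervalTrack] = (),
) -> pd.DataFrame:
    """Full annotation table, one row per manifest probe.

    Columns: probe_id, gene_label, nearest_gene, nearest_gene_tie, cgi_label,
    then one boolean column per extra track (true iff the probe position lies
    inside any interval of that track).
    """
    manifest = manifest.sorted()
    tab = manifest.table
    by = _genes_by_chrom(genes)
    n = len(tab)
    gene_label = np.empty(n, dtype=object)
    nearest = np.empty(n, dtype=object)
    near_tie = np.zeros(n, dtype=bool)
    cgi_out = np.empty(n, dtype=object)

    for chrom, sub in tab.groupby("chromosome", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["position"].to_numpy(dtype=np.int64)
        if chrom in by:
            tss, gs = by[chrom]
            for i, p in zip(idx, pos):
                gene, _, tie = _nearest_gene_obj(int(p), tss, gs)
                s = p - gene.tss if gene.strand == "+" else gene.tss - p
                gene_label[i] = _classify_offset(int(s), gene.length)
                nearest[i] = gene.gene_id
                near_tie[i] = tie
        else:
            gene_label[idx] = "intergenic"
            nearest[idx] = None
        ivs = cgis.intervals.get(chrom)
        if ivs is None or len(ivs) == 0:
            cgi_out[idx] = "non_cgi"
        else:
            d = _island_distance(pos, ivs)
            lab = np.where(
                d == 0,
                "cgi",
                np.where(
                    d <= SHORE_BP,
                    "shore",
                    np.where(d <= SHORE_BP + SHELF_BP, "shelf", "non_cgi"),
                ),
            )
            cgi_out[idx] = lab

    out = pd.DataFrame(
        {
            "probe_id": tab["probe_id"].to_numpy(),
            "chromosome": tab["chromosome"].to_numpy(),
            "position": tab["position"].to_numpy(),
            "gene_label": gene_label,
            "nearest_gene": nearest,
            "nearest_gene_tie": near_tie,
            "cgi_label": cgi_out,
        }
    )
    for track in extra_tracks:
        flags = np.zeros(n, dtype=bool)
        for chrom, sub in tab.groupby("chromosome", sort=False):
            flags[sub.index.to_numpy()] = track.contains(
                str(chrom), sub["position"].to_numpy()
            )
        out[track.name] = flags
    return out.reset_index(drop=True)


def map_dmr_to_nearest_gene(dmr, genes: Sequence[GeneModel]) -> NearestGene:
    """Nearest-TSS gene from the region midpoint; lexical tie-break, flagged."""
    if not genes:
        raise ValueError("empty gene list")
    by = _genes_by_chrom(genes)
    chrom = normalize_chromosome(dmr.chromosome)
    if chrom not in by:
        return NearestGene(None, None, False)
    tss, gs = by[chrom]
    return _nearest_gene(dmr.midpoint, tss, gs)
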