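"""Inter-individual variability and blood-as-surrogate correlation.

Epidemiological studies usually can only sample peripheral tissues such as
blood.  A CpG in an internal tissue is a candidate for indirect study if
(1) it varies between individuals in that tissue (mean sum of squares of the
per-individual means > ``mss_min``) and (2) the inter-individual pairwise
differences in that tissue track the corresponding differences in the
reference tissue (Pearson r of the two difference vectors > ``r_min``).

CpGs overlapping SNPs are removed first, since a polymorphism under the CpG
or the probe body produces genotype-driven trimodal signal; a CpG selected
in *all* tissues is likewise flagged as possibly SNP-driven rather than a
genuine epigenetic correlation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import BetaMatrix, IntervalTrack, ProbeManifest, normalize_chromosome

__all__ = [
    "VariabilityParams",
    "filter_snp_probes",
    "interindividual_mss",
    "cross_tissue_correlation",
    "correlation_overlap",
]


@dataclass(frozen=True)
class VariabilityParams:
    mss_min: float = 0.025
    r_min: float = 0.8
    snp_window_bp: int = 50
    reference_tissue: str = "blood"

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_min <= 1.0:
            raise ValueError("r_min must be in [0, 1]")
        if self.snp_window_bp < 0:
            raise ValueError("snp_window_bp must be >= 0")


def _snp_positions(snps) -> dict[str, np.ndarray]:
    """Per-chromosome sorted 1-based SNP positions from a track or list."""
    by: dict[str, list[int]] = {}
    if isinstance(snps, IntervalTrack):
        for chrom, start, end in snps.to_tuples():
            by.setdefault(chrom, []).extend(range(start + 1, end + 1))
    else:
        for chrom, pos in snps:
            by.setdefault(normalize_chromosome(chrom), []).append(int(pos))
    return {c: np.unique(np.asarray(p, dtype=np.int64)) for c, p in by.items()}


def filter_snp_probes(
    manifest: ProbeManifest, snps, window: int = 50
) -> tuple[pd.Index, int]:
    """Remove probes whose CpG or probe body overlaps a SNP.

    A probe is removed iff a SNP falls on the CpG dinucleotide (position or
    position + 1) or within ``window`` bp of the CpG on the probe-body side:
    lower coordinates for + strand probes, higher for -, both sides when the
    strand is unknown.  Returns (retained probe ids, number removed).
    """
    pos_by = _snp_positions(snps)
    tab = manifest.table
    removed = np.zeros(len(tab), dtype=bool)
    for chrom, sub in tab.groupby("chromosome", sort=False):
        sp = pos_by.get(str(chrom))
        if sp is None or len(sp) == 0:
            continue
        pos = sub["position"].to_numpy(dtype=np.int64)
        strand = sub["strand"].to_numpy()
        lo = np.where(strand == "-", pos, pos - window)
        hi = np.where(strand == "+", pos + 1, pos + 1 + window)
        # [lo, hi] inclusive 1-based window; any SNP inside removes the probe
        left = np.searchsorted(sp, lo, side="left")
        right = np.searchsorted(sp, hi, side="right")
        removed[sub.index.to_numpy()] = right > left
    retained = pd.Index(tab.loc[~removed, "probe_id"])
    return retained, int(removed.sum())


def _per_individual_means(matrix: BetaMatrix, tissue: str) -> pd.DataFrame:
    """Probes x individuals mean beta within one tissue (NaN if no data)."""
    sheet = matrix.samples.table
    cols = sheet.loc[sheet["tissue"] == tissue]
    if cols.empty:
        raise ValueError(f"tissue {tissue!r} absent from the sample sheet")
    groups = cols.groupby("individual")["sample_id"].apply(list)
    out = {}
    for indiv, samples in groups.items():
        block = matrix.values[samples].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            out[indiv] = np.nanmean(block, axis=1)
    return pd.DataFrame(out, index=matrix.values.index)


def interindividual_mss(matrix: BetaMatrix, tissue: str) -> pd.Series:
    """Per-probe mean sum of squares of per-individual means in one tissue.

    The analogue of the tissue effect size with individuals in place of
    tissues; probes with data for fewer than two individuals get NaN.
    """
    means = _per_individual_means(matrix, tissue).to_numpy(dtype=float)
    valid = np.isfinite(means)
    m = valid.sum(axis=1)
    with np.errstate(invalid="ignore"):
        overall = np.nansum(np.where(valid, means, 0.0), axis=1) / np.maximum(m, 1)
        dev = np.where(valid, means - overall[:, None], 0.0)
        mss = np.einsum("ij,ij->i", dev, dev) / np.maximum(m, 1)
    mss = np.where(m >= 2, mss, np.nan)
    return pd.Series(mss, index=matrix.values.index, name="mss")


def _pairwise_differences(means: pd.DataFrame) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Probe x pair matrix of beta differences over unordered pairs p < q."""
    indivs = sorted(means.columns)
    pairs = list(itertools.combinations(indivs, 2))
    arr = means[indivs].to_numpy(dtype=float)
    idx_p = [indivs.index(p) for p, _ in pairs]
    idx_q = [indivs.index(q) for _, q in pairs]
    return arr[:, idx_p] - arr[:, idx_q], pairs


def _rowwise_pearson(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r per row with pairwise-complete observations.

    Returns (r, n_pairs); r is NaN where fewer than 3 complete pairs exist or
    either vector has zero variance.
    """
    ok = np.isfinite(X) & np.isfinite(Y)
    n = ok.sum(axis=1)
    Xm = np.where(ok, X, 0.0)
    Ym = np.where(ok, Y, 0.0)
    denom = np.maximum(n, 1)
    mx = Xm.sum(axis=1) / denom
    my = Ym.sum(axis=1) / denom
    dx = np.where(ok, X - mx[:, None], 0.0)
    dy = np.where(ok, Y - my[:, None], 0.0)
    cov = np.einsum("ij,ij->i", dx, dy)
    vx = np.einsum("ij,ij->i", dx, dx)
    vy = np.einsum("ij,ij->i", dy, dy)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / np.sqrt(vx * vy)
    r = np.where((n >= 3) & (vx > 0) & (vy > 0), r, np.nan)
    return r, n


def cross_tissue_correlation(
    matrix: BetaMatrix,
    tissue: str,
    params: VariabilityParams | None = None,
    probes: pd.Index | None = None,
) -> pd.DataFrame:
    """Correlate inter-individual differences in one tissue with the reference.

    For every probe (optionally restricted to ``probes``, e.g. the SNP-filtered
    set) the per-individual mean betas are reduced to all unordered pairwise
    differences with a fixed p < q orientation, in the target tissue and the
    reference tissue; ``r_with_reference`` is their Pearson correlation over
    pairwise-complete pairs.  ``selected`` requires both mss_individual >
    mss_min and r > r_min.
    """
    if params is None:
        params = VariabilityParams()
    if tissue == params.reference_tissue:
        raise ValueError("target tissue equals the reference tissue")
    mss = interindividual_mss(matrix, tissue)
    means_t = _per_individual_means(matrix, tissue)
    means_r = _per_individual_means(matrix, params.reference_tissue)
    common = sorted(set(means_t.columns) & set(means_r.columns))
    if len(common) < 3:
        raise ValueError("need >= 3 individuals shared with the reference tissue")
    D_t, _ = _pairwise_differences(means_t[common])
    D_r, _ = _pairwise_differences(means_r[common])
    r, n_pairs = _rowwise_pearson(D_r, D_t)
    out = pd.DataFrame(
        {
            "probe_id": matrix.values.index,
            "tissue": tissue,
            "mss_individual": mss.to_numpy(),
            "r_with_reference": r,
            "n_pairs": n_pairs,
        }
    )
    if probes is not None:
        out = out[out["probe_id"].isin(set(probes))].reset_index(drop=True)
    out["selected"] = (
        (out["mss_individual"] > params.mss_min)
        & (out["r_with_reference"] > params.r_min)
    ).fillna(False)
    return out


def correlation_overlap(records: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Venn-style tissue-set membership of selected probes.

    ``records`` maps tissue name to a ``cross_tissue_correlation`` table over
    the same probe universe.  Probes selected in every tissue are flagged
    ``all_tissue_flag`` (possible SNP-driven correlation).
    """
    tissues = sorted(records)
    if not tissues:
        raise ValueError("no per-tissue records given")
    membership: dict[str, list[str]] = {}
    for tissue in tissues:
        tab = records[tissue]
        for pid in tab.loc[tab["selected"], "probe_id"]:
            membership.setdefault(pid, []).append(tissue)
    rows = [
        {
            "probe_id": pid,
            "tissues": ",".join(sorted(ts)),
            "n_tissues": len(ts),
            "all_tissue_flag": len(ts) == len(tissues),
        }
        for pid, ts in sorted(membership.items())
    ]
    return pd.DataFrame(
        rows, columns=["probe_id", "tissues", "n_tissues", "all_tissue_flag"]
    )
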