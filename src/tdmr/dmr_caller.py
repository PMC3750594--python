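"""Chain differentially methylated positions into regions.

A region is a run of consecutive called positions (DMPs) on one chromosome
with every gap between consecutive DMPs at most ``max_gap_bp``, at least
``min_dmps`` DMPs, and at most ``max_non_dmps`` interrogated-but-uncalled
probes inside the span.  Regions grow greedily left to right, close when the
next DMP is too far or would exceed the non-DMP budget, and are trimmed to
start and end on a DMP; this makes the caller deterministic and directly
checkable against exhaustive enumeration.

Probes that could not be tested (degenerate per-probe design) count as
non-DMPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import BetaMatrix

__all__ = [
    "DMRParams",
    "DMRRecord",
    "call_dmrs",
    "scan_parameters",
    "summarize_dmr",
    "dmrs_to_frame",
]


@dataclass(frozen=True)
class DMRParams:
    min_dmps: int = 3
    max_gap_bp: int = 1000
    max_non_dmps: int = 3

    def __post_init__(self) -> None:
        if self.min_dmps < 2:
            raise ValueError("min_dmps must be >= 2")
        if self.max_gap_bp <= 0:
            raise ValueError("max_gap_bp must be > 0")
        if self.max_non_dmps < 0:
            raise ValueError("max_non_dmps must be >= 0")


@dataclass(frozen=True)
class DMRRecord:
    """A called region; start/end are the 1-based positions of the first and
    last member DMP, so ``length_bp = end - start``."""

    chromosome: str
    start: int
    end: int
    member_probes: tuple[str, ...]
    n_dmps: int
    n_non_dmps: int
    per_tissue_mean: dict[str, float] = field(default_factory=dict)
    hypomethylated_tissue: str | None = None
    tie_flag: bool = False

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def _check_sorted(dmps: pd.DataFrame) -> None:
    chrom = dmps["chromosome"].to_numpy()
    pos = dmps["position"].to_numpy()
    for c in pd.unique(chrom):
        p = pos[chrom == c]
        if np.any(np.diff(p) < 0):
            raise ValueError("DMP table must be sorted by (chromosome, position)")
        if np.any(np.diff(p) == 0):
            raise ValueError(f"duplicate probe positions on {c}")
    order_ok = (
        pd.DataFrame({"c": chrom, "p": pos})
        .sort_values(["c", "p"], kind="mergesort")
        .index.equals(dmps.reset_index(drop=True).index)
    )
    if not order_ok:
        raise ValueError("DMP table must be sorted by (chromosome, position)")


def call_dmrs(dmps: pd.DataFrame, params: DMRParams | None = None) -> list[DMRRecord]:
    """Greedy left-to-right chaining of DMPs into maximal valid regions.

    ``dmps`` must be sorted by (chromosome, position) and carry columns
    ``probe_id, chromosome, position, is_dmp`` (the output of
    ``classify_dmps``); untested probes are non-DMPs.
    """
    if params is None:
        params = DMRParams()
    required = {"probe_id", "chromosome", "position", "is_dmp"}
    if not required <= set(dmps.columns):
        raise ValueError(f"DMP table needs columns {sorted(required)}")
    _check_sorted(dmps)

    regions: list[DMRRecord] = []
    for chrom, sub in dmps.groupby("chromosome", sort=True):
        pos = sub["position"].to_numpy(dtype=np.int64)
        flag = sub["is_dmp"].to_numpy(dtype=bool)
        pid = sub["probe_id"].to_numpy()
        didx = np.where(flag)[0]  # probe indices of DMPs
        k = 0
        while k < len(didx):
            j = k  # last DMP included, as index into didx
            while j + 1 < len(didx):
                nxt = didx[j + 1]
                if pos[nxt] - pos[didx[j]] > params.max_gap_bp:
                    break
                n_non = (nxt - didx[k] + 1) - (j + 2 - k)
                if n_non > params.max_non_dmps:
                    break
                j += 1
            n_dmps = j - k + 1
            if n_dmps >= params.min_dmps:
                lo, hi = didx[k], didx[j]
                members = tuple(pid[lo : hi + 1])
                regions.append(
                    DMRRecord(
                        chromosome=str(chrom),
                        start=int(pos[lo]),
                        end=int(pos[hi]),
                        member_probes=members,
                        n_dmps=n_dmps,
                        n_non_dmps=len(members) - n_dmps,
                    )
                )
                k = j + 1
            else:
                k += 1
    return regions


def scan_parameters(
    dmps: pd.DataFrame,
    gap_grid,
    mismatch_grid,
    min_dmps: int = 3,
) -> pd.DataFrame:
    """Region counts and lengths over a grid of caller settings.

    One row per (max_gap_bp, max_non_dmps) combination; used to check the
    stability of the called set against the chaining parameters.
    """
    gap_grid = list(gap_grid)
    mismatch_grid = list(mismatch_grid)
    if not gap_grid or not mismatch_grid:
        raise ValueError("parameter grids must be non-empty")
    rows = []
    for gap in gap_grid:
        for mism in mismatch_grid:
            regs = call_dmrs(
                dmps, DMRParams(min_dmps=min_dmps, max_gap_bp=gap, max_non_dmps=mism)
            )
            lengths = [r.length_bp for r in regs]
            rows.append(
                {
                    "max_gap_bp": gap,
                    "max_non_dmps": mism,
                    "n_dmrs": len(regs),
                    "n_dmps_covered": int(sum(r.n_dmps for r in regs)),
                    "mean_length_bp": float(np.mean(lengths)) if lengths else np.nan,
                    "median_length_bp": float(np.median(lengths)) if lengths else np.nan,
                }
            )
    return pd.DataFrame(rows)


def summarize_dmr(
    dmr: DMRRecord, matrix: BetaMatrix, dmps: pd.DataFrame | None = None
) -> DMRRecord:
    """Fill per-tissue mean methylation over the region's member DMPs.

    Only member probes flagged as DMPs enter the means (non-DMP members are
    interior passengers).  The hypomethylated tissue is the one with the
    minimum mean; ties are broken by lexical tissue order and flagged.
    """
    if dmps is not None:
        flags = dmps.set_index("probe_id")["is_dmp"]
        member_dmps = [p for p in dmr.member_probes if bool(flags.get(p, False))]
    else:
        member_dmps = list(dmr.member_probes)
    missing = [p for p in member_dmps if p not in matrix.values.index]
    if missing:
        raise KeyError(f"member probes absent from the matrix: {missing[:3]}")
    block = matrix.values.loc[member_dmps]
    tissue_of = matrix.samples.tissue_of()
    means: dict[str, float] = {}
    for tissue in matrix.samples.tissues:
        cols = tissue_of.index[tissue_of == tissue]
        vals = block[cols].to_numpy(dtype=float)
        finite = np.isfinite(vals)
        means[tissue] = float(vals[finite].mean()) if finite.any() else float("nan")
    defined = {t: m for t, m in means.items() if np.isfinite(m)}
    if defined:
        lo = min(defined.values())
        winners = sorted(t for t, m in defined.items() if m == lo)
        hypo, tie = winners[0], len(winners) > 1
    else:
        hypo, tie = None, False
    return replace(
        dmr, per_tissue_mean=means, hypomethylated_tissue=hypo, tie_flag=tie
    )


def dmrs_to_frame(dmrs) -> pd.DataFrame:
    """Flat table of regions for TSV output; probe lists comma-joined."""
    tissues: list[str] = sorted(
        {t for r in dmrs for t in getattr(r, "per_tissue_mean", {})}
    )
    rows = []
    for r in dmrs:
        row = {
            "chromosome": r.chromosome,
            "start": r.start,
            "end": r.end,
            "length_bp": r.length_bp,
            "n_dmps": r.n_dmps,
            "n_non_dmps": r.n_non_dmps,
            "member_probes": ",".join(r.member_probes),
            "hypomethylated_tissue": r.hypomethylated_tissue,
            "tie_flag": r.tie_flag,
        }
        for t in tissues:
            row[f"mean_{t}"] = r.per_tissue_mean.get(t, float("nan"))
        rows.append(row)
    cols = [
        "chromosome",
        "start",
        "end",
        "length_bp",
        "n_dmps",
        "n_non_dmps",
        "member_probes",
        "hypomethylated_tissue",
        "tie_flag",
    ] + [f"mean_{t}" for t in tissues]
    return pd.DataFrame(rows, columns=cols)
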