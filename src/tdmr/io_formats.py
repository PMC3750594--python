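"""Readers, writers and validated in-memory containers for methylation array data.

Conventions used throughout the package:

* Probe positions are **1-based** genome coordinates (the manifest convention
  of methylation arrays).  BED input/output is 0-based half-open and is
  converted exactly at the I/O boundary: a 1-based position ``p`` maps to the
  BED interval ``(p - 1, p)``.
* Chromosome names are normalised to carry a ``chr`` prefix; after
  normalisation comparison is string-exact.
* Beta values are methylation fractions in ``[0, 1]``; missing values are
  permitted (``NaN``) and propagate as per-CpG sample exclusion downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "ParseError",
    "ProbeManifest",
    "SampleSheet",
    "BetaMatrix",
    "IntervalTrack",
    "GeneModel",
    "load_dataset",
    "read_beta_matrix",
    "read_sample_sheet",
    "read_manifest",
    "read_interval_track",
    "read_gene_models",
    "write_results",
    "read_results",
    "normalize_chromosome",
]


class ValidationError(ValueError):
    """An input violated a structural invariant (duplicate ids, bad range...)."""


class ParseError(ValueError):
    """A file could not be parsed; the message carries row/column context."""


_STRAND_MAP = {
    "+": "+",
    "-": "-",
    "−": "-",  # unicode minus occasionally found in exported tables
    ".": "unknown",
    "*": "unknown",
    "unknown": "unknown",
    "": "unknown",
}


def normalize_chromosome(chrom: str) -> str:
    """Return the chromosome name with a ``chr`` prefix."""
    chrom = str(chrom).strip()
    return chrom if chrom.startswith("chr") else "chr" + chrom


def _normalize_strand(strand: str) -> str:
    s = str(strand).strip()
    try:
        return _STRAND_MAP[s]
    except KeyError:
        raise ValidationError(f"unrecognised strand value {strand!r}") from None


@dataclass(frozen=True)
class ProbeManifest:
    """Genomic mapping of array probes.

    ``table`` has columns ``probe_id``, ``chromosome``, ``position`` (1-based
    bp of the interrogated CpG) and ``strand`` (``+``/``-``/``unknown``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["probe_id", "chromosome", "position", "strand"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"manifest is missing columns {missing}")
        tab = self.table.loc[:, required].copy()
        tab["probe_id"] = tab["probe_id"].astype(str)
        tab["chromosome"] = tab["chromosome"].map(normalize_chromosome)
        tab["position"] = pd.to_numeric(tab["position"], errors="raise").astype(np.int64)
        tab["strand"] = tab["strand"].map(_normalize_strand)
        if tab["probe_id"].duplicated().any():
            dup = tab.loc[tab["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValidationError(f"duplicate probe id {dup!r} in manifest")
        if (tab["position"] < 1).any():
            bad = tab.loc[tab["position"] < 1].iloc[0]
            raise ValidationError(
                f"probe {bad['probe_id']!r} has position {bad['position']} < 1"
            )
        tab = tab.reset_index(drop=True)
        object.__setattr__(self, "table", tab)

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.table["probe_id"])

    def __len__(self) -> int:
        return len(self.table)

    def sorted(self) -> "ProbeManifest":
        """Manifest ordered by (chromosome, position)."""
        tab = self.table.sort_values(
            ["chromosome", "position"], kind="mergesort"
        ).reset_index(drop=True)
        return ProbeManifest(tab)

    def subset(self, probe_ids: Iterable[str]) -> "ProbeManifest":
        keep = set(probe_ids)
        return ProbeManifest(self.table[self.table["probe_id"].isin(keep)])


@dataclass(frozen=True)
class SampleSheet:
    """Sample metadata: ``sample_id``, ``tissue``, ``individual``."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample_id", "tissue", "individual"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"sample sheet is missing columns {missing}")
        tab = self.table.loc[:, required].copy()
        for col in required:
            tab[col] = tab[col].astype(str).str.strip()
        if tab["sample_id"].duplicated().any():
            dup = tab.loc[tab["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample id {dup!r} in sample sheet")
        for col in ("tissue", "individual"):
            if (tab[col] == "").any():
                bad = tab.loc[tab[col] == "", "sample_id"].iloc[0]
                raise ValidationError(f"sample {bad!r} has an empty {col} label")
        object.__setattr__(self, "table", tab.reset_index(drop=True))

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample_id"])

    @property
    def tissues(self) -> list[str]:
        return sorted(self.table["tissue"].unique())

    @property
    def individuals(self) -> list[str]:
        return sorted(self.table["individual"].unique())

    def tissue_of(self) -> pd.Series:
        return self.table.set_index("sample_id")["tissue"]

    def individual_of(self) -> pd.Series:
        return self.table.set_index("sample_id")["individual"]

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class BetaMatrix:
    """Probes x samples methylation fractions with tissue/individual labels.

    ``values`` is a DataFrame indexed by probe_id with sample_id columns;
    entries are in [0, 1] or NaN (missing).
    """

    values: pd.DataFrame
    manifest: ProbeManifest
    samples: SampleSheet

    def __post_init__(self) -> None:
        vals = self.values
        if vals.index.has_duplicates:
            raise ValidationError("duplicate probe rows in beta matrix")
        if vals.columns.has_duplicates:
            raise ValidationError("duplicate sample columns in beta matrix")
        if set(vals.index) != set(self.manifest.probe_ids):
            raise ValidationError("beta matrix rows do not match the manifest")
        if set(vals.columns) != set(self.samples.sample_ids):
            raise ValidationError("beta matrix columns do not match the sample sheet")
        arr = vals.to_numpy(dtype=float)
        bad = np.isfinite(arr) & ((arr < 0.0) | (arr > 1.0))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"beta value {arr[i, j]!r} outside [0, 1] at probe "
                f"{vals.index[i]!r}, sample {vals.columns[j]!r}"
            )
        # align rows to manifest order, columns to sheet order
        ordered = vals.loc[self.manifest.probe_ids, self.samples.sample_ids]
        ordered = ordered.astype(float)
        object.__setattr__(self, "values", ordered)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sorted(self) -> "BetaMatrix":
        man = self.manifest.sorted()
        return BetaMatrix(self.values.loc[man.probe_ids], man, self.samples)


@dataclass(frozen=True)
class IntervalTrack:
    """A named set of genomic intervals in 0-based half-open coordinates.

    Intervals are merged to non-overlapping form at construction; merging
    never changes membership queries.
    """

    name: str
    intervals: Mapping[str, np.ndarray] = field(default_factory=dict)
    # intervals: chrom -> (k, 2) int array of merged [start, end) rows

    @classmethod
    def from_tuples(
        cls, name: str, tuples: Iterable[tuple[str, int, int]]
    ) -> "IntervalTrack":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in tuples:
            start, end = int(start), int(end)
            if start >= end:
                raise ValidationError(
                    f"interval ({chrom}, {start}, {end}) has start >= end"
                )
            if start < 0:
                raise ValidationError(f"interval start {start} < 0")
            by_chrom.setdefault(normalize_chromosome(chrom), []).append((start, end))
        merged: dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            out: list[list[int]] = []
            for s, e in ivs:
                if out and s <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            merged[chrom] = np.asarray(out, dtype=np.int64)
        return cls(name=name, intervals=merged)

    def contains(self, chrom: str, positions) -> np.ndarray:
        """Membership of 1-based positions; vectorised."""
        pos = np.atleast_1d(np.asarray(positions, dtype=np.int64))
        ivs = self.intervals.get(normalize_chromosome(chrom))
        if ivs is None or len(ivs) == 0:
            return np.zeros(pos.shape, dtype=bool)
        # 1-based p lies in [s, e) iff s < p <= e
        idx = np.searchsorted(ivs[:, 0], pos, side="left") - 1
        ok = idx >= 0
        res = np.zeros(pos.shape, dtype=bool)
        res[ok] = pos[ok] <= ivs[idx[ok], 1]
        return res

    def to_tuples(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self.intervals):
            for s, e in self.intervals[chrom]:
                out.append((chrom, int(s), int(e)))
        return out

    @property
    def n_intervals(self) -> int:
        return sum(len(v) for v in self.intervals.values())


@dataclass(frozen=True)
class GeneModel:
    """A gene anchored by its 5' (TSS) and 3' (TES) ends in 1-based coords.

    On the + strand ``tss < tes``; on the - strand ``tss > tes`` since both
    are stored as genomic coordinates of the 5'/3' ends.
    """

    gene_id: str
    chromosome: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        strand = _normalize_strand(self.strand)
        if strand == "unknown":
            raise ValidationError(f"gene {self.gene_id!r} has no strand")
        object.__setattr__(self, "strand", strand)
        if strand == "+" and not self.tss < self.tes:
            raise ValidationError(f"+strand gene {self.gene_id!r} needs tss < tes")
        if strand == "-" and not self.tss > self.tes:
            raise ValidationError(f"-strand gene {self.gene_id!r} needs tss > tes")

    @property
    def length(self) -> int:
        return abs(self.tes - self.tss)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, comment="#", **kwargs)


def read_manifest(path: str | Path) -> ProbeManifest:
    tab = _read_table(path)
    tab.columns = [c.strip().lower() for c in tab.columns]
    ren = {"chrom": "chromosome", "chr": "chromosome", "pos": "position"}
    tab = tab.rename(columns=ren)
    return ProbeManifest(tab)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    tab = _read_table(path)
    tab.columns = [c.strip().lower() for c in tab.columns]
    return SampleSheet(tab)


def read_beta_matrix(path: str | Path) -> pd.DataFrame:
    """Raw probe x sample beta table (first column = probe_id)."""
    tab = _read_table(path)
    tab = tab.set_index(tab.columns[0])
    tab.index = tab.index.astype(str)
    tab.index.name = "probe_id"
    out = pd.DataFrame(index=tab.index)
    for col in tab.columns:
        converted = pd.to_numeric(tab[col], errors="coerce")
        bad = converted.isna() & tab[col].notna() & (tab[col].str.strip() != "NA")
        if bad.any():
            row = tab.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"non-numeric beta value {tab.loc[row, col]!r} at probe "
                f"{row!r}, sample {col!r} in {path}"
            )
        out[col] = converted
    return out


def load_dataset(
    beta_path: str | Path, sheet_path: str | Path, manifest_path: str | Path
) -> BetaMatrix:
    """Read and cross-validate the three standard inputs.

    Probes absent from the manifest are dropped with a logged count; beta
    values outside [0, 1] raise :class:`ValidationError`.
    """
    beta = read_beta_matrix(beta_path)
    sheet = read_sample_sheet(sheet_path)
    manifest = read_manifest(manifest_path)
    known = beta.index.isin(set(manifest.probe_ids))
    n_dropped = int((~known).sum())
    if n_dropped:
        log.warning("dropping %d probe(s) absent from the manifest", n_dropped)
        beta = beta.loc[known]
    manifest = manifest.subset(beta.index)
    return BetaMatrix(values=beta, manifest=manifest, samples=sheet)


def read_interval_track(path: str | Path, name: str) -> IntervalTrack:
    """Read a BED3+ file (0-based half-open); comment/track lines skipped."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    tuples: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{ln}: expected >=3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"{path}:{ln}: non-integer BED coordinates") from None
            tuples.append((parts[0], start, end))
    return IntervalTrack.from_tuples(name, tuples)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED6 (0-based) or minimal GTF (1-based).

    The 5' end becomes the TSS; internal coordinates are 1-based, so BED
    starts are shifted by +1.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) >= 9 and parts[2] in {"gene", "transcript"}:
                # minimal GTF: 1-based inclusive coordinates
                chrom, start, end, strand = parts[0], int(parts[3]), int(parts[4]), parts[6]
                attrs = parts[8]
                gene_id = None
                for tokidx in ("gene_id", "transcript_id"):
                    key = tokidx + ' "'
                    if key in attrs:
                        gene_id = attrs.split(key, 1)[1].split('"', 1)[0]
                        break
                if gene_id is None:
                    raise ParseError(f"{path}:{ln}: no gene_id in GTF attributes")
                lo, hi = start, end
            elif len(parts) >= 6:
                chrom, strand = parts[0], parts[5]
                lo, hi = int(parts[1]) + 1, int(parts[2])  # BED -> 1-based inclusive
                gene_id = parts[3]
            else:
                raise ParseError(
                    f"{path}:{ln}: expected BED6 or GTF record with a strand"
                )
            if strand not in ("+", "-", "−"):
                raise ValidationError(f"{path}:{ln}: gene {gene_id!r} lacks a strand")
            if gene_id in seen:
                raise ValidationError(f"{path}:{ln}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            if strand == "+":
                tss, tes = lo, hi
            else:
                tss, tes = hi, lo
            genes.append(GeneModel(gene_id, chrom, strand, tss, tes))
    return genes


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

DMR_BED = "dmrs.bed"
DMR_TSV = "dmrs.tsv"
DMP_TSV = "dmps.tsv"
ENRICH_TSV = "enrichment.tsv"
CROSS_TSV = "cross_tissue.tsv"


def _fmt_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype == bool:
            out[col] = out[col].map({True: "True", False: "False"})
    return out


def write_results(
    dmps: pd.DataFrame | None = None,
    dmrs: Sequence | None = None,
    enrichments: pd.DataFrame | None = None,
    correlations: pd.DataFrame | None = None,
    out_dir: str | Path = ".",
) -> dict[str, Path]:
    """Write result tables with a deterministic row order.

    DMRs are written twice: a BED file with the region span converted to
    0-based half-open coordinates, and a TSV carrying probe lists and
    per-tissue means.  Repeated runs on identical inputs produce
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if dmps is not None:
        path = out_dir / DMP_TSV
        df = dmps.sort_values(["chromosome", "position"], kind="mergesort")
        _fmt_frame(df).to_csv(path, sep="\t", index=False, na_rep="NA")
        written["dmps"] = path

    if dmrs is not None:
        from .dmr_caller import dmrs_to_frame  # local import avoids a cycle

        frame = dmrs_to_frame(dmrs)
        frame = frame.sort_values(["chromosome", "start"], kind="mergesort")
        bed_path = out_dir / DMR_BED
        with open(bed_path, "w") as fh:
            for i, row in enumerate(frame.itertuples(index=False)):
                # span start is a 1-based CpG position -> BED start = pos - 1
                fh.write(
                    f"{row.chromosome}\t{row.start - 1}\t{row.end}\ttDMR_{i + 1}"
                    f"\t{row.n_dmps}\t.\n"
                )
        tsv_path = out_dir / DMR_TSV
        _fmt_frame(frame).to_csv(tsv_path, sep="\t", index=False, na_rep="NA")
        written["dmrs_bed"] = bed_path
        written["dmrs"] = tsv_path

    if enrichments is not None:
        path = out_dir / ENRICH_TSV
        df = enrichments.sort_values("annotation", kind="mergesort")
        _fmt_frame(df).to_csv(path, sep="\t", index=False, na_rep="NA")
        written["enrichments"] = path

    if correlations is not None:
        path = out_dir / CROSS_TSV
        order = [c for c in ("tissue", "probe_id") if c in correlations.columns]
        df = correlations.sort_values(order, kind="mergesort") if order else correlations
        _fmt_frame(df).to_csv(path, sep="\t", index=False, na_rep="NA")
        written["correlations"] = path

    return written


def read_results(out_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Read back tables produced by :func:`write_results`."""
    out_dir = Path(out_dir)
    out: dict[str, pd.DataFrame] = {}
    names = {
        "dmps": DMP_TSV,
        "dmrs": DMR_TSV,
        "enrichments": ENRICH_TSV,
        "correlations": CROSS_TSV,
    }
    for key, fname in names.items():
        path = out_dir / fname
        if path.exists():
            out[key] = pd.read_csv(path, sep="\t")
    return out
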