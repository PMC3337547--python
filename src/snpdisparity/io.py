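"""Domain types and readers/writers for paired SNP-array data.

The canonical exchange format is five tab-separated files: four numeric
matrices (blood/tumour B-allele frequency and log R ratio; header row of
sample ids, first column of locus ids) plus a locus annotation table
(locus_id, chromosome, position, allele_a, allele_b, gene, cytoband).
Missing values are written as ``NaN``; empty cells are also treated as
missing on input.

Coordinate conventions: annotation positions are 1-based (array-manifest
convention); cytoband files use the UCSC 0-based half-open convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AlignmentError",
    "AnnotationError",
    "FormatError",
    "ValidationError",
    "SnpLocus",
    "PairedArrayData",
    "ClinicalTable",
    "GeneSet",
    "CytobandMap",
    "CHROMOSOMES",
    "chromosome_sort_key",
    "read_paired_matrices",
    "write_paired_matrices",
    "read_cytobands",
    "read_clinical",
    "read_gene_list",
    "write_disparity_report",
    "read_disparity_report",
]


class ValidationError(ValueError):
    """A value violates a domain invariant (e.g. BAF outside [0, 1])."""


class AlignmentError(ValueError):
    """Sample or locus sets disagree across the input matrices."""


class AnnotationError(KeyError):
    """A locus present in the matrices is missing from the annotation."""


class FormatError(ValueError):
    """A file does not follow its declared dialect."""


#: Allowed chromosome labels, in canonical sort order.
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

_CHROM_RANK: dict[str, int] = {c: i for i, c in enumerate(CHROMOSOMES)}


def normalize_chromosome(label: object) -> str:
    """Map ``chr2``/``2``/``x`` style labels onto the canonical set."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.upper() in ("X", "Y"):
        s = s.upper()
    if s not in _CHROM_RANK:
        raise ValidationError(f"unknown chromosome label: {label!r}")
    return s


def chromosome_sort_key(label: str) -> int:
    """Rank of a chromosome label in the canonical order 1..22, X, Y."""
    return _CHROM_RANK[normalize_chromosome(label)]


@dataclass(frozen=True)
class SnpLocus:
    """A single SNP with its genomic annotation.

    ``position`` is 1-based; ``allele_a``/``allele_b`` are the array design
    alleles (the B allele is the one whose frequency BAF measures).
    """

    locus_id: str
    chromosome: str
    position: int
    allele_a: str
    allele_b: str
    gene: str | None = None
    cytoband: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        if self.position < 1:
            raise ValidationError(
                f"locus {self.locus_id}: position must be >= 1, got {self.position}"
            )
        if self.allele_a == self.allele_b:
            raise ValidationError(
                f"locus {self.locus_id}: design alleles must differ "
                f"({self.allele_a}/{self.allele_b})"
            )


_LOCUS_COLUMNS = ["chromosome", "position", "allele_a", "allele_b", "gene", "cytoband"]


@dataclass
class PairedArrayData:
    """Aligned loci x samples BAF and LRR matrices for blood and tumour.

    ``loci`` is a DataFrame indexed by locus id with columns ``chromosome``
    (canonical labels), ``position`` (1-based int), ``allele_a``,
    ``allele_b``, ``gene`` and ``cytoband`` (the last two may be missing).
    The four matrices share the loci index and an identical sample-id
    column order; column ``j`` is the same patient everywhere.
    """

    loci: pd.DataFrame
    blood_baf: pd.DataFrame
    tumour_baf: pd.DataFrame
    blood_lrr: pd.DataFrame
    tumour_lrr: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.blood_baf.columns)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.loci.index)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return self.blood_baf.shape[1]

    def matrices(self) -> dict[str, pd.DataFrame]:
        return {
            "blood_baf": self.blood_baf,
            "tumour_baf": self.tumour_baf,
            "blood_lrr": self.blood_lrr,
            "tumour_lrr": self.tumour_lrr,
        }

    def validate(self) -> None:
        shape = self.blood_baf.shape
        for name, m in self.matrices().items():
            if m.shape != shape:
                raise AlignmentError(f"{name} has shape {m.shape}, expected {shape}")
            if list(m.index) != self.locus_ids:
                raise AlignmentError(f"{name} locus index differs from annotation")
            if list(m.columns) != self.sample_ids:
                raise AlignmentError(f"{name} sample columns differ from blood_baf")
        for name in ("blood_baf", "tumour_baf"):
            m = getattr(self, name)
            bad = (m < 0) | (m > 1)
            if bad.any().any():
                loc = bad.stack()
                loc = loc[loc]
                locus, sample = loc.index[0]
                raise ValidationError(
                    f"{name}: BAF outside [0, 1] at locus {locus}, sample {sample}"
                )
        ranks = self.loci["chromosome"].map(_CHROM_RANK)
        order = np.lexsort(
            (self.loci.index.to_numpy(), self.loci["position"].to_numpy(), ranks.to_numpy())
        )
        if not np.array_equal(order, np.arange(len(order))):
            raise ValidationError("loci are not sorted by (chromosome, position)")

    def sorted(self) -> "PairedArrayData":
        """Return a copy sorted by (chromosome, position, locus id)."""
        ranks = self.loci["chromosome"].map(_CHROM_RANK)
        order = np.lexsort(
            (self.loci.index.to_numpy(), self.loci["position"].to_numpy(), ranks.to_numpy())
        )
        idx = self.loci.index[order]
        return PairedArrayData(
            loci=self.loci.loc[idx],
            **{name: m.loc[idx] for name, m in self.matrices().items()},
        )

    def subset_loci(self, locus_ids: Sequence[str]) -> "PairedArrayData":
        idx = pd.Index(locus_ids)
        return PairedArrayData(
            loci=self.loci.loc[idx],
            **{name: m.loc[idx] for name, m in self.matrices().items()},
        )


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates; any field may be missing.

    Wraps a DataFrame indexed by sample id. Recognised columns and levels:
    grade {1,2,3}, er/pr/her2/lymph_node {neg,pos}, tp53 {wildtype,mutate},
    tumour_size {T1,T2,T3+4}, subtype {luminalA,basal,other}.
    """

    table: pd.DataFrame

    LEVELS: Mapping[str, tuple] = field(
        default_factory=lambda: dict(_CLINICAL_LEVELS), repr=False
    )

    def __post_init__(self) -> None:
        for col in self.table.columns:
            levels = _CLINICAL_LEVELS.get(col)
            if levels is None:
                continue
            vals = self.table[col].dropna()
            bad = set(vals) - set(levels)
            if bad:
                raise ValidationError(f"clinical column {col!r}: unknown levels {sorted(map(str, bad))}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def covariate(self, name: str) -> pd.Series:
        if name not in self.table.columns:
            raise KeyError(
                f"unknown covariate {name!r}; available: {sorted(self.table.columns)}"
            )
        return self.table[name]


_CLINICAL_LEVELS: dict[str, tuple] = {
    "grade": (1, 2, 3),
    "er": ("neg", "pos"),
    "pr": ("neg", "pos"),
    "her2": ("neg", "pos"),
    "tp53": ("wildtype", "mutate"),
    "tumour_size": ("T1", "T2", "T3+4"),
    "lymph_node": ("neg", "pos"),
    "subtype": ("luminalA", "basal", "other"),
}


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (duplicates collapsed on load)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if any(not g for g in self.genes):
            raise ValidationError(f"gene set {self.name!r} contains an empty symbol")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


# ---------------------------------------------------------------------------
# readers / writers


def _read_matrix(path: str | Path) -> pd.DataFrame:
    """Read one numeric matrix TSV; unparseable cells and "NaN" -> missing."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    out = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    out.columns = [str(c) for c in df.columns]
    return out


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the locus annotation TSV into a validated, typed DataFrame."""
    ann = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"locus_id", "chromosome", "position", "allele_a", "allele_b"}
    missing = required - set(ann.columns)
    if missing:
        raise FormatError(f"annotation lacks required columns: {sorted(missing)}")
    ann = ann.set_index("locus_id")
    ann["chromosome"] = ann["chromosome"].map(normalize_chromosome)
    ann["position"] = pd.to_numeric(ann["position"], errors="raise").astype(int)
    for col in ("gene", "cytoband"):
        if col not in ann.columns:
            ann[col] = ""
        ann[col] = ann[col].replace("", None)
    if (ann["position"] < 1).any():
        bad = ann.index[ann["position"] < 1][0]
        raise ValidationError(f"locus {bad}: position must be >= 1")
    same = ann["allele_a"] == ann["allele_b"]
    if same.any():
        raise ValidationError(f"locus {ann.index[same][0]}: design alleles must differ")
    return ann[_LOCUS_COLUMNS]


def read_paired_matrices(
    blood_baf_path: str | Path,
    tumour_baf_path: str | Path,
    blood_lrr_path: str | Path,
    tumour_lrr_path: str | Path,
    annotation_path: str | Path,
) -> PairedArrayData:
    """Load and align the four matrices and the annotation.

    Sample columns are aligned across files by id (order taken from the
    blood BAF file); loci are sorted by (chromosome, position, locus id).
    """
    mats = {
        "blood_baf": _read_matrix(blood_baf_path),
        "tumour_baf": _read_matrix(tumour_baf_path),
        "blood_lrr": _read_matrix(blood_lrr_path),
        "tumour_lrr": _read_matrix(tumour_lrr_path),
    }
    ref = mats["blood_baf"]
    samples = list(ref.columns)
    loci = set(ref.index)
    for name, m in mats.items():
        if set(m.columns) != set(samples):
            raise AlignmentError(
                f"{name}: sample ids differ from blood_baf "
                f"(extra: {sorted(set(m.columns) - set(samples))}, "
                f"missing: {sorted(set(samples) - set(m.columns))})"
            )
        if set(m.index) != loci:
            raise AlignmentError(f"{name}: locus ids differ from blood_baf")
        mats[name] = m.loc[ref.index, samples]

    ann = read_annotation(annotation_path)
    unannotated = loci - set(ann.index)
    if unannotated:
        raise AnnotationError(
            f"{len(unannotated)} loci missing from annotation, e.g. "
            f"{sorted(unannotated)[:3]}"
        )
    data = PairedArrayData(loci=ann.loc[ref.index], **mats).sorted()
    data.validate()
    return data


def write_paired_matrices(data: PairedArrayData, out_dir: str | Path, prefix: str = "") -> dict[str, Path]:
    """Write the five canonical TSVs; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, m in data.matrices().items():
        p = out_dir / f"{prefix}{name}.tsv"
        m.to_csv(p, sep="\t", index_label="locus_id", na_rep="NaN")
        paths[name] = p
    p = out_dir / f"{prefix}annotation.tsv"
    data.loci.to_csv(p, sep="\t", index_label="locus_id", na_rep="")
    paths["annotation"] = p
    return paths


class CytobandMap:
    """Per-chromosome ordered cytogenetic band intervals (0-based, half-open)."""

    def __init__(self, bands: Mapping[str, pd.DataFrame]):
        #: chromosome -> DataFrame(start, end, band) sorted by start
        self.bands = dict(bands)

    def __len__(self) -> int:
        return sum(len(df) for df in self.bands.values())

    def band_at(self, chromosome: str, position: int) -> str | None:
        """Band containing a 1-based position, or None if unassigned."""
        try:
            chrom = normalize_chromosome(chromosome)
        except ValidationError:
            return None
        df = self.bands.get(chrom)
        if df is None or df.empty:
            return None
        pos0 = position - 1  # 1-based -> 0-based
        i = int(np.searchsorted(df["start"].to_numpy(), pos0, side="right")) - 1
        if i < 0 or pos0 >= df["end"].iloc[i]:
            return None
        return str(df["band"].iloc[i])

    def assign(self, chromosomes: Iterable[str], positions: Iterable[int]) -> list[str | None]:
        return [self.band_at(c, p) for c, p in zip(chromosomes, positions)]


def read_cytobands(path: str | Path) -> CytobandMap:
    """Parse a UCSC cytoBand.txt file (chrom, chromStart, chromEnd, name, stain).

    Band labels are formed as chromosome-without-"chr"-prefix plus the band
    name (e.g. ``2p15``). Overlapping bands on one chromosome raise
    :class:`FormatError`. An empty file yields an empty mapping.
    """
    try:
        raw = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            names=["chrom", "start", "end", "name", "stain"],
            dtype={"chrom": str, "name": str, "stain": str},
            comment="#",
        )
    except pd.errors.EmptyDataError:
        return CytobandMap({})
    if raw.empty:
        return CytobandMap({})
    out: dict[str, pd.DataFrame] = {}
    for chrom_raw, grp in raw.groupby("chrom", sort=False):
        try:
            chrom = normalize_chromosome(chrom_raw)
        except ValidationError:
            continue  # alternate/random contigs ignored
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy(int)
        ends = grp["end"].to_numpy(int)
        if (ends <= starts).any():
            raise FormatError(f"cytoband with non-positive extent on chromosome {chrom}")
        if (starts[1:] < ends[:-1]).any():
            raise FormatError(f"overlapping cytobands on chromosome {chrom}")
        out[chrom] = pd.DataFrame(
            {"start": starts, "end": ends, "band": chrom + grp["name"].astype(str).to_numpy()}
        ).reset_index(drop=True)
    return CytobandMap(out)


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical covariate CSV with a ``sample_id`` column."""
    df = pd.read_csv(path, dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError("clinical file needs a 'sample_id' column")
    df = df.set_index("sample_id")
    df = df.replace("", np.nan)
    if "grade" in df.columns:
        df["grade"] = pd.to_numeric(df["grade"], errors="coerce").astype("Int64")
    return ClinicalTable(df)


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a gene list, one symbol per line; blank lines and '#' comments skipped."""
    symbols = set()
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if s and not s.startswith("#"):
            symbols.add(s)
    return GeneSet(name=name or Path(path).stem, genes=frozenset(symbols))


# one decimal for percentages, as in the published per-locus tables
_REPORT_PCT_COLS = ("pct_het", "r_AA", "r_BB", "r_AB", "delta", "score")
_REPORT_COLUMNS = [
    "locus_id", "gene", "chromosome", "cytoband",
    "n_AA", "n_AB", "n_BB", "pct_het", "maf",
    "hwe_chi2", "in_hwe",
    "n_shift_AA", "n_shift_BB",
    "r_AA", "r_BB", "r_AB", "delta", "score", "preferential_allele",
]


def write_disparity_report(records: pd.DataFrame, path: str | Path) -> None:
    """Write a per-locus disparity report TSV (one row per locus).

    ``records`` is the table produced by
    :func:`snpdisparity.disparity.compute_disparity`; percentage columns are
    written with one decimal, MAF and the HWE statistic with four.
    """
    out = records.reset_index() if records.index.name == "locus_id" else records.copy()
    for col in _REPORT_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out = out[_REPORT_COLUMNS]
    for col in _REPORT_PCT_COLS:
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.1f}")
    for col in ("maf", "hwe_chi2"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.4f}")
    out.to_csv(path, sep="\t", index=False, na_rep="")


def read_disparity_report(path: str | Path) -> pd.DataFrame:
    """Read back a report written by :func:`write_disparity_report`."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "locus_id": str})
    return df.set_index("locus_id")
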