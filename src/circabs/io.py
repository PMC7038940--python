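"""Input/output and normalization for back-splice junction data.

Junction tables are BED6-like TSV files (chrom, start, end, name, read
count, strand) as emitted by back-splice junction callers.  All genomic
intervals are handled 0-based half-open (BED convention) and every circRNA
is keyed by ``(chrom, strand, start, end)``.  The strand decides which end
of the interval plays the acceptor (3' back-splice site) and which the
donor (5' back-splice site) role: on "+" the acceptor is the interval
start, on "-" the roles swap.

Expression values are RPM: back-splice junction reads per million mapped
reads.  circRNAs reaching ``DEFAULT_MIN_RPM`` (0.1) in at least one tissue
are flagged high-confidence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: Row key of every expression matrix, in order.
KEY_FIELDS = ("chrom", "strand", "start", "end")

#: High-confidence RPM threshold (inclusive).
DEFAULT_MIN_RPM = 0.1

_STRANDS = {"+", "-"}


class JunctionParseError(ValueError):
    """A malformed line in a junction table."""


def acceptor_pos(strand: str, start: int, end: int) -> int:
    """Genomic coordinate of the 3' back-splice (acceptor) site."""
    return start if strand == "+" else end


def donor_pos(strand: str, start: int, end: int) -> int:
    """Genomic coordinate of the 5' back-splice (donor) site."""
    return end if strand == "+" else start


def _norm_strand(s: str) -> str:
    s = s.strip().replace("−", "-")  # tolerate unicode minus
    if s not in _STRANDS:
        raise JunctionParseError(f"invalid strand {s!r}")
    return s


def read_junction_table(path: str | Path, sample_id: str) -> pd.DataFrame:
    """Read one per-sample back-splice junction table.

    Parameters
    ----------
    path
        BED6-like TSV: chrom, start, end, name, back-splice read count,
        strand.  Coordinates are 0-based half-open.
    sample_id
        Identifier attached to every record.

    Returns
    -------
    DataFrame with columns ``chrom, strand, start, end, name, read_count,
    sample_id``; duplicate junctions within the file have their read
    counts summed.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise JunctionParseError(
                    f"{path}:{lineno}: expected >=6 tab-separated columns, got {len(parts)}"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
                count = int(parts[4])
            except ValueError as exc:
                raise JunctionParseError(f"{path}:{lineno}: {exc}") from None
            if count < 0:
                raise ValueError(f"{path}:{lineno}: negative read count {count}")
            if not start < end:
                raise JunctionParseError(f"{path}:{lineno}: start must be < end")
            rows.append(
                (parts[0], _norm_strand(parts[5]), start, end, parts[3], count)
            )
    df = pd.DataFrame(
        rows, columns=["chrom", "strand", "start", "end", "name", "read_count"]
    )
    if not df.empty:
        df = (
            df.groupby(list(KEY_FIELDS), sort=True)
            .agg(name=("name", "first"), read_count=("read_count", "sum"))
            .reset_index()
        )
    df["sample_id"] = sample_id
    return df


def read_junction_tables(paths: Mapping[str, str | Path]) -> pd.DataFrame:
    """Read and concatenate junction tables for ``{sample_id: path}``."""
    frames = [read_junction_table(p, sid) for sid, p in paths.items()]
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "strand", "start", "end", "name", "read_count", "sample_id"]
        )
    return pd.concat(frames, ignore_index=True)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet (CSV or TSV with a header) indexed by sample_id.

    Required columns: ``sample_id, tissue, individual, cohort, replicate,
    mapped_reads``; optional ``tissue_group``.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    sheet = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    return validate_sample_sheet(sheet.set_index("sample_id"))


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    required = {"tissue", "individual", "cohort", "replicate", "mapped_reads"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet.index.has_duplicates:
        raise ValueError("duplicate sample_id in sample sheet")
    if (sheet["mapped_reads"] <= 0).any():
        raise ValueError("mapped_reads must be > 0")
    dup = sheet.duplicated(subset=["tissue", "individual", "replicate"])
    if dup.any():
        raise ValueError(
            "(tissue, individual, replicate) not unique: "
            + ", ".join(sheet.index[dup].astype(str))
        )
    return sheet


def normalize_rpm(junctions: pd.DataFrame, sample_sheet: pd.DataFrame) -> pd.DataFrame:
    """Normalize junction read counts to RPM per sample.

    RPM = read_count / mapped_reads * 1e6.  Returns a dense matrix with
    circRNA keys as a ``(chrom, strand, start, end)`` MultiIndex and one
    column per sample; junctions absent from a sample are 0.
    """
    unknown = set(junctions["sample_id"]) - set(sample_sheet.index)
    if unknown:
        raise KeyError(f"sample_id not in sample sheet: {sorted(unknown)}")
    mat = junctions.pivot_table(
        index=list(KEY_FIELDS),
        columns="sample_id",
        values="read_count",
        aggfunc="sum",
        fill_value=0,
    ).astype(float)
    mat.columns.name = None
    depth = sample_sheet.loc[mat.columns, "mapped_reads"].to_numpy(dtype=float)
    return mat / depth * 1e6


def average_replicates(
    matrix: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    by: str | Sequence[str] = "tissue",
) -> pd.DataFrame:
    """Average RPMs across replicate samples.

    ``by`` names the sample-sheet column(s) that define the output unit
    (default "tissue"; use ``("tissue", "individual")`` to keep individuals
    apart).  A circRNA absent from a replicate contributes 0 to the mean.
    """
    cols = [by] if isinstance(by, str) else list(by)
    labels = sample_sheet.loc[matrix.columns, cols].astype(str).agg("/".join, axis=1)
    out = matrix.T.groupby(labels.to_numpy()).mean().T
    out.columns.name = None
    return out


def filter_high_confidence(
    matrix: pd.DataFrame, min_rpm: float = DEFAULT_MIN_RPM
) -> pd.Series:
    """Flag circRNAs reaching ``min_rpm`` (inclusive) in >=1 column.

    Returns a boolean Series aligned to the matrix rows; rows are retained
    either way so low-confidence members stay visible to downstream code.
    """
    flags = matrix.max(axis=1) >= min_rpm
    flags.name = "high_confidence"
    return flags


@dataclass
class RNaseREnrichment:
    """Per-circRNA fold enrichment after RNase R treatment."""

    fold: pd.Series
    median: float

    @property
    def is_empty(self) -> bool:
        return self.fold.empty


def rnase_r_enrichment(
    treated: pd.DataFrame | pd.Series, untreated: pd.DataFrame | pd.Series
) -> RNaseREnrichment:
    """Fold enrichment (treated RPM / untreated RPM) per circRNA.

    Evaluated only for circRNAs detected (RPM > 0) in the untreated
    sample; circRNAs undetected after treatment get fold 0 (depleted).
    Matrices with several columns are averaged (replicates) first.
    """
    t = treated.mean(axis=1) if isinstance(treated, pd.DataFrame) else treated
    u = untreated.mean(axis=1) if isinstance(untreated, pd.DataFrame) else untreated
    u = u[u > 0]
    if u.empty:
        return RNaseREnrichment(fold=pd.Series(dtype=float), median=float("nan"))
    fold = (t.reindex(u.index).fillna(0.0) / u).rename("fold_enrichment")
    return RNaseREnrichment(fold=fold, median=float(fold.median()))


# ---------------------------------------------------------------------------
# gene models and repeats


@dataclass(frozen=True)
class GeneModel:
    """A transcript model: ordered, non-overlapping exons on one strand."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    name: str | None = None  # transcript id when distinct from gene_id

    def __post_init__(self):
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if not s < e:
                raise ValueError(f"{self.gene_id}: empty exon ({s}, {e})")
            if s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, genomic order, half-open."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]


def read_genepred(path: str | Path) -> list[GeneModel]:
    """Read gene models in genePred (10 cols) or refFlat (11 cols) dialect."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) >= 11:  # refFlat: geneName, name, chrom, ...
                gene_id, name = parts[0], parts[1]
                parts = parts[1:]
            elif len(parts) >= 10:
                gene_id = name = parts[0]
            else:
                raise ValueError(f"{path}:{lineno}: not a genePred/refFlat line")
            chrom, strand = parts[1], _norm_strand(parts[2])
            starts = [int(x) for x in parts[8].rstrip(",").split(",")]
            ends = [int(x) for x in parts[9].rstrip(",").split(",")]
            if len(starts) != len(ends):
                raise ValueError(f"{path}:{lineno}: exonStarts/exonEnds mismatch")
            genes.append(
                GeneModel(gene_id, chrom, strand, tuple(zip(starts, ends)), name=name)
            )
    return genes


def write_genepred(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            starts = ",".join(str(s) for s, _ in g.exons) + ","
            ends = ",".join(str(e) for _, e in g.exons) + ","
            fh.write(
                "\t".join(
                    [
                        g.name or g.gene_id,
                        g.chrom,
                        g.strand,
                        str(g.tx_start),
                        str(g.tx_end),
                        str(g.tx_start),
                        str(g.tx_start),  # non-coding: empty CDS
                        str(len(g.exons)),
                        starts,
                        ends,
                    ]
                )
                + "\n"
            )


_RMSK_ALU_PREFIX = "Alu"


def read_repeats(
    path: str | Path, fmt: str = "bed", alu_only: bool = True
) -> pd.DataFrame:
    """Read repeat elements as a DataFrame (chrom, start, end, strand, family).

    ``fmt="bed"``: BED6 with the repeat family in the name column.
    ``fmt="rmsk"``: UCSC rmsk.txt dump (17 columns).  With ``alu_only``
    (default) only families starting with "Alu" are kept.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            p = line.split("\t")
            if fmt == "bed":
                chrom, start, end, fam, strand = p[0], int(p[1]), int(p[2]), p[3], p[5]
            elif fmt == "rmsk":
                chrom, start, end = p[5], int(p[6]), int(p[7])
                strand = "+" if p[9] == "+" else "-"
                fam = p[10]
            else:
                raise ValueError(f"unknown repeat format {fmt!r}")
            if start >= end:
                raise ValueError(f"repeat with start >= end at {chrom}:{start}")
            if alu_only and not fam.startswith(_RMSK_ALU_PREFIX):
                continue
            rows.append((chrom, start, end, _norm_strand(strand), fam))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "family"])


def write_repeats_bed(repeats: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in repeats.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.family}\t0\t{r.strand}\n")


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write an expression or PCU matrix as TSV with the key flattened."""
    out = matrix.copy()
    if isinstance(out.index, pd.MultiIndex):
        out.index = [
            f"{c}:{s}-{e}:{st}" for c, st, s, e in out.index
        ]
    out.to_csv(path, sep="\t", index_label="key", na_rep="NA")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read back a matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col="key", na_values=["NA"])
    keys = []
    for k in df.index:
        chrom, span, strand = k.rsplit(":", 2)
        start, end = span.split("-")
        keys.append((chrom, _norm_strand(strand), int(start), int(end)))
    df.index = pd.MultiIndex.from_tuples(keys, names=list(KEY_FIELDS))
    return df


def write_manifest(path: str | Path, **entries) -> None:
    """Write a small JSON run manifest (parameters, counts, file names)."""
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
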