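"""Readers and writers for the external formats the pipeline touches.

Every genomic interval is normalised to 0-based half-open coordinates on
read: GFF3 (1-based inclusive) and 1-based cytosine reports are shifted,
BED is consumed and written natively.  Parsers validate their closed
vocabularies (strand, cytosine context, TE superfamily codes) and fail
with a located :class:`FormatError` on malformed rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from mchh_islands.islands import IslandCall

CONTEXTS = ("CG", "CHG", "CHH")

#: Wicker three-letter TE superfamily codes (DNA transposons D--, LTR and
#: non-LTR retroelements R--) plus the catch-all "unknown".
WICKER_SUPERFAMILIES = frozenset(
    {
        "DHH", "DTA", "DTC", "DTH", "DTM", "DTT", "DTX",
        "RIX", "RLC", "RLG", "RLX", "RSX", "unknown",
    }
)

#: Standard 12 columns of BLAST tabular output (-outfmt 6).
BLAST_COLUMNS = (
    "query_id", "subject_id", "pct_identity", "aln_length", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "evalue", "bitscore",
)


class FormatError(ValueError):
    """A malformed record, annotated with file and line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


@dataclass(frozen=True)
class CytosineRecord:
    """One cytosine's strand, trinucleotide context and read counts.

    ``pos`` is 0-based.  ``low_coverage`` marks records whose total depth
    fell below the reader's ``min_reads`` — they are retained, because
    filtering decisions belong to consumers.
    """

    chrom: str
    pos: int
    strand: str
    context: str
    n_meth: int
    n_total: int
    low_coverage: bool = False

    def __post_init__(self):
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if not (0 <= self.n_meth <= self.n_total):
            raise ValueError(
                f"require 0 <= n_meth <= n_total, got {self.n_meth}/{self.n_total}"
            )


@dataclass
class GeneModel:
    """A gene with 0-based half-open span and exons of its longest transcript."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if not self.exons:
            self.exons = [(self.start, self.end)]
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.gene_id}: exon outside gene span")

    @property
    def tss(self) -> int:
        """Strand-aware transcription start coordinate."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        """Strand-aware transcription termination coordinate."""
        return self.end - 1 if self.strand == "+" else self.start

    def flank5(self, flank: int) -> tuple[int, int]:
        """Half-open interval covering ``flank`` bp upstream of the TSS."""
        if self.strand == "+":
            return (self.start - flank, self.start)
        return (self.end, self.end + flank)

    def flank3(self, flank: int) -> tuple[int, int]:
        """Half-open interval covering ``flank`` bp downstream of the TTS."""
        if self.strand == "+":
            return (self.end, self.end + flank)
        return (self.start - flank, self.start)


@dataclass(frozen=True)
class RepeatFeature:
    """An annotated repeat/TE with its Wicker superfamily code."""

    chrom: str
    start: int
    end: int
    superfamily: str = "unknown"

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("repeat start must be < end")
        if self.superfamily not in WICKER_SUPERFAMILIES:
            raise ValueError(f"unknown TE superfamily {self.superfamily!r}")


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("e-value must be >= 0")


@dataclass(frozen=True)
class SpeciesMeta:
    """Per-species metadata: 1C genome size and the tree tip label."""

    species: str
    genome_size_mb: float
    tip_label: str | None = None

    def __post_init__(self):
        if self.genome_size_mb <= 0:
            raise ValueError("genome_size_mb must be > 0")


# ---------------------------------------------------------------------------
# cytosine reports


def read_cytosine_report(path, min_reads: int = 1) -> Iterator[CytosineRecord]:
    """Stream per-cytosine records from a Bismark-style cytosine report.

    Expected tab-separated columns: chromosome, 1-based position, strand,
    methylated read count, unmethylated read count, context.  Positions are
    converted to 0-based.  Records with total depth below ``min_reads`` are
    yielded with ``low_coverage=True`` rather than dropped.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                parts = line.split()
            if len(parts) < 6:
                raise FormatError("expected 6 columns", path, lineno)
            chrom, pos_s, strand, meth_s, unmeth_s, context = parts[:6]
            try:
                pos = int(pos_s)
                n_meth = int(meth_s)
                n_unmeth = int(unmeth_s)
            except ValueError as exc:
                raise FormatError(f"non-integer field: {exc}", path, lineno) from None
            if context not in CONTEXTS:
                raise FormatError(f"unknown context {context!r}", path, lineno)
            if strand not in ("+", "-"):
                raise FormatError(f"bad strand {strand!r}", path, lineno)
            if pos < 1 or n_meth < 0 or n_unmeth < 0:
                raise FormatError("negative count or position < 1", path, lineno)
            n_total = n_meth + n_unmeth
            yield CytosineRecord(
                chrom, pos - 1, strand, context, n_meth, n_total,
                low_coverage=n_total < min_reads,
            )


class Methylome:
    """Columnar container for a full per-cytosine methylation report.

    Wraps a DataFrame with columns ``chrom, pos, strand, context, n_meth,
    n_total`` (``pos`` 0-based), sorted by chromosome and position, with a
    per-chromosome index for fast range queries.
    """

    COLUMNS = ("chrom", "pos", "strand", "context", "n_meth", "n_total")

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"methylome table missing columns {sorted(missing)}")
        bad = ~df["context"].isin(CONTEXTS)
        if bad.any():
            raise ValueError(
                f"unknown contexts: {sorted(df.loc[bad, 'context'].unique())}"
            )
        if (df["n_meth"] > df["n_total"]).any() or (df["n_meth"] < 0).any():
            raise ValueError("require 0 <= n_meth <= n_total")
        self.df = (
            df.loc[:, list(self.COLUMNS)]
            .sort_values(["chrom", "pos"], kind="mergesort")
            .reset_index(drop=True)
        )
        self._by_chrom: dict[str, pd.DataFrame] = {
            c: g for c, g in self.df.groupby("chrom", sort=True)
        }

    @classmethod
    def from_report(cls, path, **read_kwargs) -> "Methylome":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "pos", "strand", "n_meth", "n_unmeth", "context"],
            dtype={"chrom": str}, **read_kwargs,
        )
        df["pos"] = df["pos"].astype(np.int64) - 1  # to 0-based
        df["n_total"] = df["n_meth"] + df["n_unmeth"]
        return cls(df.drop(columns="n_unmeth"))

    @classmethod
    def from_records(cls, records: Iterable[CytosineRecord]) -> "Methylome":
        rows = [
            (r.chrom, r.pos, r.strand, r.context, r.n_meth, r.n_total)
            for r in records
        ]
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def chrom_sites(self, chrom: str) -> pd.DataFrame:
        return self._by_chrom.get(
            chrom, self.df.iloc[0:0]
        )

    def sites(self, chrom: str, start: int, end: int,
              context: str | None = None) -> pd.DataFrame:
        """Sites with ``start <= pos < end`` on ``chrom``."""
        g = self.chrom_sites(chrom)
        if g.empty:
            return g
        pos = g["pos"].to_numpy()
        lo, hi = np.searchsorted(pos, [start, end])
        sub = g.iloc[lo:hi]
        if context is not None:
            sub = sub[sub["context"] == context]
        return sub

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# gene annotations


def _gff3_attributes(s: str) -> dict[str, str]:
    out = {}
    for chunk in s.strip().split(";"):
        if not chunk:
            continue
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_gff3_genes(path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    transcripts: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError("GFF3 rows need 9 columns", path, lineno)
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs_s = parts
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError("non-integer coordinates", path, lineno) from None
            start, end = start1 - 1, end1  # to 0-based half-open
            attrs = _gff3_attributes(attrs_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise FormatError("gene without ID", path, lineno)
                if strand not in ("+", "-"):
                    raise FormatError(f"gene {gid} without strand", path, lineno)
                if gid in genes:
                    raise FormatError(f"duplicate gene id {gid}", path, lineno)
                genes[gid] = dict(chrom=chrom, start=start, end=end, strand=strand)
            elif ftype in ("mRNA", "transcript"):
                tid = attrs.get("ID")
                parent = attrs.get("Parent")
                if tid is None or parent is None:
                    raise FormatError("transcript without ID/Parent", path, lineno)
                transcripts[tid] = dict(gene=parent, exons=[])
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise FormatError("exon without Parent", path, lineno)
                for tid in parent.split(","):
                    if tid in transcripts:
                        transcripts[tid]["exons"].append((start, end))
                    elif tid in genes:
                        # exon attached directly to a gene record
                        genes[tid].setdefault("exons", []).append((start, end))

    models = []
    for gid, g in genes.items():
        # exons come from the longest transcript; ties broken by smallest id
        cands = [
            (tid, sorted(t["exons"]))
            for tid, t in transcripts.items()
            if t["gene"] == gid and t["exons"]
        ]
        if cands:
            cands.sort(key=lambda te: (-sum(e - s for s, e in te[1]), te[0]))
            exons = cands[0][1]
        else:
            exons = sorted(g.get("exons", [])) or [(g["start"], g["end"])]
        models.append(
            GeneModel(gid, g["chrom"], g["start"], g["end"], g["strand"], exons)
        )
    return models


def _read_bed_genes(path) -> list[GeneModel]:
    models = []
    seen = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError("gene BED needs >= 6 columns (strand)", path, lineno)
            chrom, start_s, end_s, name, _score, strand = parts[:6]
            if strand not in ("+", "-"):
                raise FormatError(f"gene {name} without strand", path, lineno)
            if name in seen:
                raise FormatError(f"duplicate gene id {name}", path, lineno)
            seen.add(name)
            models.append(GeneModel(name, chrom, int(start_s), int(end_s), strand))
    return models


def read_gene_annotation(path, format: str | None = None) -> list[GeneModel]:
    """Read gene models from GFF3 or BED6, normalised to 0-based half-open.

    ``format`` is inferred from the file suffix when not given.
    """
    if format is None:
        suffix = Path(path).suffix.lower()
        format = "bed" if suffix == ".bed" else "gff3"
    if format == "gff3":
        return _read_gff3_genes(path)
    if format == "bed":
        return _read_bed_genes(path)
    raise ValueError(f"unknown gene annotation format {format!r}")


# ---------------------------------------------------------------------------
# repeats, expression, orthologs, BLAST, trees


def read_repeat_annotation(path, format: str | None = None) -> list[RepeatFeature]:
    """Read TE/repeat features from a BED-like TSV or GFF3.

    BED-like rows are ``chrom  start  end  superfamily`` (0-based half-open);
    GFF3 rows take the superfamily from an ``ID=``/``Name=``-independent
    ``superfamily=`` attribute, else from the type column, else "unknown".
    """
    if format is None:
        suffix = Path(path).suffix.lower()
        format = "gff3" if suffix in (".gff", ".gff3") else "bed"
    feats = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                if format == "gff3":
                    if len(parts) != 9:
                        raise FormatError("GFF3 rows need 9 columns", path, lineno)
                    chrom, start, end = parts[0], int(parts[3]) - 1, int(parts[4])
                    attrs = _gff3_attributes(parts[8])
                    fam = attrs.get("superfamily", parts[2])
                    if fam not in WICKER_SUPERFAMILIES:
                        fam = "unknown"
                else:
                    if len(parts) < 4:
                        raise FormatError("repeat BED needs >= 4 columns", path, lineno)
                    chrom, start, end, fam = parts[0], int(parts[1]), int(parts[2]), parts[3]
                    if fam not in WICKER_SUPERFAMILIES:
                        raise FormatError(
                            f"unknown TE superfamily {fam!r}", path, lineno
                        )
                feats.append(RepeatFeature(chrom, start, end, fam))
            except ValueError as exc:
                if isinstance(exc, FormatError):
                    raise
                raise FormatError(str(exc), path, lineno) from None
    return feats


def read_expression_table(path) -> dict[str, float]:
    """Read a two-column ``gene_id <tab> rpkm`` table.

    Genes absent from the file stay absent from the mapping — distinct from
    an explicit RPKM of zero.
    """
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError("expected gene_id<TAB>rpkm", path, lineno)
            if lineno == 1 and parts[1].lower() in ("rpkm", "expression"):
                continue  # header
            try:
                rpkm = float(parts[1])
            except ValueError:
                raise FormatError(f"non-numeric RPKM {parts[1]!r}", path, lineno) from None
            if rpkm < 0 or math.isnan(rpkm):
                raise FormatError("RPKM must be >= 0", path, lineno)
            out[parts[0]] = rpkm
    return out


def read_ortholog_table(path) -> pd.DataFrame:
    """Read a 1-to-1 ortholog table: ortholog_id plus one gene-id column per species."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("ortholog table needs >= 2 columns", path)
    df = df.set_index(df.columns[0])
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate ortholog id {dup!r}", path)
    if df.isna().any().any():
        raise FormatError("1-to-1 ortholog table must have one gene per species", path)
    return df


def read_blast_tab(path) -> pd.DataFrame:
    """Read 12-column BLAST tabular output (-outfmt 6), one row per HSP."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=list(BLAST_COLUMNS),
        dtype={"query_id": str, "subject_id": str},
    )
    if (df["evalue"] < 0).any():
        raise FormatError("negative e-value", path)
    return df


def read_newick(path):
    """Read a rooted newick tree with branch lengths (dendropy Tree)."""
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick")


# ---------------------------------------------------------------------------
# island BED


def _bed_score(q: float) -> int:
    if q <= 0:
        return 1000
    return int(min(1000, round(-10.0 * math.log10(q))))


def write_island_bed(islands: "Iterable[IslandCall]", path) -> None:
    """Write island calls as BED6, sorted by chromosome then start.

    name = ``win_<chrom>_<start>``; score = ``-10*log10(q)`` capped at 1000.
    """
    rows = sorted(
        (
            (isl.chrom, isl.start, isl.end,
             f"win_{isl.chrom}_{isl.start}",
             _bed_score(isl.q_value if isl.q_value is not None else 1.0))
            for isl in islands
        ),
        key=lambda r: (r[0], r[1]),
    )
    with open(path, "w") as fh:
        for chrom, start, end, name, score in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t.\n")


def read_island_bed(path) -> pd.DataFrame:
    """Read a BED6 island file back into a DataFrame (chrom, start, end, name, score)."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise FormatError("island BED needs >= 5 columns", path, lineno)
            rows.append(
                (parts[0], int(parts[1]), int(parts[2]), parts[3], float(parts[4]))
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])


def validate_file(path, kind: str) -> int:
    """Parse ``path`` as ``kind`` and return the number of records.

    ``kind`` is one of: cytosine_report, genes, repeats, expression,
    orthologs, blast, newick, island_bed.  Raises on the first malformed
    record.
    """
    readers = {
        "cytosine_report": lambda p: sum(1 for _ in read_cytosine_report(p)),
        "genes": lambda p: len(read_gene_annotation(p)),
        "repeats": lambda p: len(read_repeat_annotation(p)),
        "expression": lambda p: len(read_expression_table(p)),
        "orthologs": lambda p: len(read_ortholog_table(p)),
        "blast": lambda p: len(read_blast_tab(p)),
        "newick": lambda p: len(read_newick(p).leaf_nodes()),
        "island_bed": lambda p: len(read_island_bed(p)),
    }
    if kind not in readers:
        raise ValueError(f"unknown kind {kind!r}; choose from {sorted(readers)}")
    return readers[kind](path)
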