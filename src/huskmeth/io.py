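"""Readers/writers for the on-disk formats and the shared genomic data model.

Coordinate conventions
----------------------
Cytosine reports are 1-based (Bismark CX convention). Everything held in
memory is 0-based half-open. BED output is 0-based half-open; GFF3 input is
1-based inclusive and converted on read. Symmetric CG sites on opposite
strands are kept as separate sites; window statistics count sites as
reported. Zero-coverage rows are retained on read and excluded by
downstream coverage filters, so filters -- not parsers -- own the
minimum-read rule.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")

_REPORT_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "count_methylated",
    "count_unmethylated",
    "context",
    "trinucleotide",
]


class ParseError(ValueError):
    """A file violated its format (bad column count, bad coordinates...)."""


class ValidationError(ValueError):
    """Well-formed input with semantically invalid content."""


@dataclass(frozen=True)
class CytosineSite:
    """One cytosine in one sample: strand, context and read counts."""

    chrom: str
    pos: int  # 1-based, as in the cytosine report
    strand: str
    context: str
    n_meth: int
    n_total: int

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValidationError(f"unknown context {self.context!r}")
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if not (0 <= self.n_meth <= self.n_total):
            raise ValidationError(
                f"need 0 <= n_meth <= n_total, got {self.n_meth}/{self.n_total}"
            )

    @property
    def zero_coverage(self) -> bool:
        return self.n_total == 0

    @property
    def fraction(self) -> float:
        """Per-site methylation fraction; NaN when uncovered."""
        return self.n_meth / self.n_total if self.n_total else float("nan")


class MethylomeSample:
    """All cytosine calls of one sample, keyed by (chrom, pos, strand).

    Internally a pandas DataFrame with columns
    ``chrom, pos, strand, context, n_meth, n_total`` (pos 1-based), which the
    window statistics operate on directly.
    """

    def __init__(self, sample_id: str, group: str, data: pd.DataFrame):
        if not group:
            raise ValidationError("group label must be non-empty")
        expected = ["chrom", "pos", "strand", "context", "n_meth", "n_total"]
        missing = [c for c in expected if c not in data.columns]
        if missing:
            raise ValidationError(f"missing columns: {missing}")
        if data.duplicated(["chrom", "pos", "strand"]).any():
            raise ValidationError("duplicate (chrom, pos, strand) keys")
        if (data["n_meth"] < 0).any() or (data["n_meth"] > data["n_total"]).any():
            raise ValidationError("counts must satisfy 0 <= n_meth <= n_total")
        bad = ~data["context"].isin(CONTEXTS)
        if bad.any():
            raise ValidationError(
                f"unknown context values: {sorted(data.loc[bad, 'context'].unique())}"
            )
        self.sample_id = sample_id
        self.group = group
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_sites(
        cls, sample_id: str, group: str, sites: Iterable[CytosineSite]
    ) -> "MethylomeSample":
        rows = [
            (s.chrom, s.pos, s.strand, s.context, s.n_meth, s.n_total) for s in sites
        ]
        df = pd.DataFrame(
            rows, columns=["chrom", "pos", "strand", "context", "n_meth", "n_total"]
        )
        return cls(sample_id, group, df)

    def __len__(self) -> int:
        return len(self.data)

    def sites(self) -> list[CytosineSite]:
        return [
            CytosineSite(r.chrom, int(r.pos), r.strand, r.context, int(r.n_meth), int(r.n_total))
            for r in self.data.itertuples(index=False)
        ]

    def get(self, chrom: str, pos: int, strand: str) -> CytosineSite | None:
        m = self.data[
            (self.data["chrom"] == chrom)
            & (self.data["pos"] == pos)
            & (self.data["strand"] == strand)
        ]
        if m.empty:
            return None
        r = m.iloc[0]
        return CytosineSite(r.chrom, int(r.pos), r.strand, r.context, int(r.n_meth), int(r.n_total))

    def global_weighted_level(self, context: str) -> float:
        """Genome-wide weighted level Σ n_meth / Σ n_total for one context."""
        sub = self.data[self.data["context"] == context]
        total = int(sub["n_total"].sum())
        return float(sub["n_meth"].sum() / total) if total else float("nan")


@dataclass(frozen=True)
class GeneModel:
    """Transcript interval (0-based half-open, UTRs included)."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    feature_class: str = "gene"  # gene | TE

    def __post_init__(self) -> None:
        if self.tx_start >= self.tx_end:
            raise ValidationError(
                f"{self.gene_id}: tx_start {self.tx_start} >= tx_end {self.tx_end}"
            )


@dataclass
class SampleSheet:
    """Sample-to-group assignment with an optional phenotype value per sample."""

    data: pd.DataFrame  # columns: sample_id, group, [phenotype]

    def __post_init__(self) -> None:
        if self.data["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in sample sheet")
        if self.data["group"].nunique() < 1:
            raise ValidationError("at least one group required")

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.data["group"]))

    def samples_in(self, group: str) -> list[str]:
        return list(self.data.loc[self.data["group"] == group, "sample_id"])

    def phenotypes_by_group(self) -> dict[str, np.ndarray]:
        if "phenotype" not in self.data.columns:
            raise ValidationError("sample sheet has no phenotype column")
        out = {}
        for g in self.groups:
            v = pd.to_numeric(
                self.data.loc[self.data["group"] == g, "phenotype"], errors="coerce"
            ).dropna()
            out[g] = v.to_numpy(dtype=float)
        return out


@dataclass
class PopAlignment:
    """Equal-length haploid sequences with a population label per sequence."""

    ids: list[str]
    seqs: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        if len({len(s) for s in self.seqs} or {0}) > 1:
            raise ValidationError("alignment sequences have unequal lengths")
        if len(self.ids) != len(set(self.ids)):
            raise ValidationError("duplicate sequence ids in alignment")
        if not (len(self.ids) == len(self.seqs) == len(self.labels)):
            raise ValidationError("ids, seqs and labels must align")

    @property
    def n_seqs(self) -> int:
        return len(self.seqs)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def matrix(self) -> np.ndarray:
        """(n_seqs, length) array of single characters."""
        return np.array([list(s) for s in self.seqs], dtype="U1")

    def subset(self, label: str) -> "PopAlignment":
        keep = [i for i, l in enumerate(self.labels) if l == label]
        if not keep:
            raise ValidationError(f"no sequences labelled {label!r}")
        return PopAlignment(
            [self.ids[i] for i in keep],
            [self.seqs[i] for i in keep],
            [self.labels[i] for i in keep],
        )


# ---------------------------------------------------------------------------
# Cytosine (CX) reports


def read_cytosine_report(path, sample_id: str, group: str) -> MethylomeSample:
    """Read a Bismark-style 7-column cytosine report into a sample.

    Columns: chrom, pos (1-based), strand, count_methylated,
    count_unmethylated, context, trinucleotide. Zero-coverage rows are kept.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ParseError(
                    f"{path}:{lineno}: expected 7 tab-separated columns, got {len(fields)}"
                )
            rows.append(fields)
    df = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    try:
        df["pos"] = df["pos"].astype(np.int64)
        df["count_methylated"] = df["count_methylated"].astype(np.int64)
        df["count_unmethylated"] = df["count_unmethylated"].astype(np.int64)
    except ValueError as exc:
        raise ParseError(f"{path}: non-integer coordinate or count: {exc}") from None
    if (df["count_methylated"] < 0).any() or (df["count_unmethylated"] < 0).any():
        raise ValidationError(f"{path}: negative read counts")
    if (df["pos"] < 1).any():
        raise ValidationError(f"{path}: positions must be 1-based (>= 1)")
    df["context"] = df["context"].str.upper()
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"],
            "strand": df["strand"],
            "context": df["context"],
            "n_meth": df["count_methylated"],
            "n_total": df["count_methylated"] + df["count_unmethylated"],
        }
    )
    return MethylomeSample(sample_id, group, out)


def write_cytosine_report(sample: MethylomeSample, path) -> None:
    """Write a sample back out in 7-column cytosine-report format.

    The trinucleotide column is reconstructed as the bare context (the
    analysis never consumes it).
    """
    df = sample.data
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"],
            "strand": df["strand"],
            "count_methylated": df["n_meth"],
            "count_unmethylated": df["n_total"] - df["n_meth"],
            "context": df["context"],
            "trinucleotide": df["context"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# DMR BED

_BED_EXTRA = ["context", "direction", "level_a", "level_b", "difference", "p_value", "n_windows"]


def write_dmr_bed(dmrs: Sequence, path) -> None:
    """Write DMRs as BED6 plus extra columns (levels, difference, P).

    name = context:direction; score = round(1000*|difference|); strand '.'.
    """
    lines = []
    for d in dmrs:
        if d.start >= d.end:
            raise ValidationError(f"DMR interval start >= end: {d.chrom}:{d.start}-{d.end}")
        p = "" if d.p_value is None else repr(float(d.p_value))
        lines.append(
            "\t".join(
                [
                    d.chrom,
                    str(d.start),
                    str(d.end),
                    f"{d.context}:{d.direction}",
                    str(int(round(1000 * abs(d.difference)))),
                    ".",
                    d.context,
                    d.direction,
                    repr(float(d.level_a)),
                    repr(float(d.level_b)),
                    repr(float(d.difference)),
                    p,
                    str(int(d.n_windows)),
                ]
            )
        )
    Path(path).write_text("".join(l + "\n" for l in lines))


def read_dmr_bed(path) -> list:
    """Read a DMR BED written by :func:`write_dmr_bed`."""
    from .dmr import MethRegion  # local import: io must not depend on dmr at import time

    out = []
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        f = line.split("\t")
        if len(f) != 13:
            raise ParseError(f"{path}:{lineno}: expected 13 columns, got {len(f)}")
        out.append(
            MethRegion(
                chrom=f[0],
                start=int(f[1]),
                end=int(f[2]),
                context=f[6],
                n_windows=int(f[12]),
                level_a=float(f[8]),
                level_b=float(f[9]),
                difference=float(f[10]),
                p_value=float(f[11]) if f[11] else None,
                direction=f[7],
            )
        )
    return out


# ---------------------------------------------------------------------------
# Gene / TE annotations


def read_gff_genes(path) -> list[GeneModel]:
    """Parse gene-level features from GFF3 into 0-based half-open models."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="warning"
    )
    genes = []
    for feat in db.features_of_type("gene"):
        if feat.end < feat.start:
            raise ValidationError(f"{feat.id}: end < start in GFF3 input")
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=feat.seqid,
                strand=feat.strand,
                tx_start=feat.start - 1,  # GFF3 1-based inclusive -> half-open
                tx_end=feat.end,
            )
        )
    return genes


def write_gff_genes(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\t.\tgene\t{g.tx_start + 1}\t{g.tx_end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_te_bed(path) -> list[GeneModel]:
    """Read transposable-element intervals from a BED file (class TE)."""
    tes = []
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        if len(f) < 3:
            raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
        name = f[3] if len(f) > 3 else f"te_{lineno}"
        start, end = int(f[1]), int(f[2])
        if start >= end:
            raise ValidationError(f"{path}:{lineno}: start >= end")
        strand = f[5] if len(f) > 5 else "."
        tes.append(GeneModel(name, f[0], strand, start, end, feature_class="TE"))
    return tes


# ---------------------------------------------------------------------------
# Alignments and sample sheets


def read_fasta_alignment(path, labels: Mapping[str, str] | None = None) -> PopAlignment:
    """Read an aligned FASTA; attach a population label per sequence.

    ``labels`` maps sequence id -> population label; ids absent from the
    mapping raise. With ``labels=None`` every sequence gets label "pop".
    Gap characters are retained, never stripped.
    """
    from Bio import SeqIO

    ids, seqs, labs = [], [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
        if labels is None:
            labs.append("pop")
        else:
            if rec.id not in labels:
                raise ValidationError(f"sequence {rec.id!r} has no population label")
            labs.append(labels[rec.id])
    return PopAlignment(ids, seqs, labs)


def write_fasta_alignment(aln: PopAlignment, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{sid}\n{seq}\n")


def read_label_table(path) -> dict[str, str]:
    """TSV with header ``sequence_id<TAB>population`` -> id->label dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df["sequence_id"].duplicated().any():
        raise ValidationError("duplicate sequence_id in label table")
    return dict(zip(df["sequence_id"], df["population"]))


def read_sample_sheet(path) -> SampleSheet:
    """TSV with header sample_id, group, [phenotype]; blanks become NaN."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if "phenotype" in df.columns:
        df["phenotype"] = pd.to_numeric(df["phenotype"], errors="coerce")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.data.to_csv(path, sep="\t", index=False)
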