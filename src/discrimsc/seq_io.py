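"""Promoter and expression table I/O.

Coordinate conventions used throughout the package:

* Genome coordinates in tables are 1-based inclusive.
* Promoter-internal offsets are contiguous integers with the transcription
  start site (TSS) base at offset 0; upstream bases are negative.
* Display positions follow the biology convention (TSS printed as +1,
  no position 0): display ``-k`` equals internal ``-k`` for ``k >= 1`` and
  display ``+j`` equals internal ``j - 1`` for ``j >= 1``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger("discrimsc")

VALID_BASES = frozenset("ACGT")
CALLS = ("act", "rep", "non")


class TableFormatError(ValueError):
    """A table is missing mandatory columns or is otherwise malformed."""


class CoordinateError(ValueError):
    """A genomic window or promoter-internal offset is out of range."""


class OperonMappingError(ValueError):
    """A promoter cannot be linked to any gene-level expression call."""


def display_to_internal(pos: int) -> int:
    """Map a display position (no zero, TSS = +1) to an internal offset."""
    return pos - 1 if pos >= 1 else pos


def internal_to_display(offset: int) -> int:
    """Map an internal offset (TSS = 0) to a display position."""
    return offset + 1 if offset >= 0 else offset


@dataclass
class PromoterRecord:
    """One promoter: a TSS-anchored sequence window plus annotation.

    ``seq`` is the coding-strand sequence; its first base sits at internal
    offset ``-up``, so the TSS base is ``seq[up]``.  ``minus10_offset`` is
    the internal offset of the first base of the -10 hexamer (typically
    -12) and may be ``None`` for TSS-aligned promoter sets.
    """

    id: str
    seq: str
    up: int
    tss_genome_pos: int = 0
    strand: str = "+"
    minus10_offset: int | None = None
    sigma: str = ""
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()

    @property
    def min_offset(self) -> int:
        return -self.up

    @property
    def max_offset(self) -> int:
        return len(self.seq) - self.up - 1

    def covers(self, start: int, end: int) -> bool:
        """Whether internal offsets [start, end] lie inside the window."""
        return start >= self.min_offset and end <= self.max_offset

    def base_at(self, offset: int) -> str:
        if not self.covers(offset, offset):
            raise CoordinateError(
                f"promoter {self.id}: internal offset {offset} outside "
                f"[{self.min_offset}, {self.max_offset}]"
            )
        return self.seq[offset + self.up]

    def subseq(self, start: int, end: int) -> str:
        """Bases at internal offsets ``start..end`` inclusive."""
        if not self.covers(start, end):
            raise CoordinateError(
                f"promoter {self.id}: offsets [{start}, {end}] outside "
                f"[{self.min_offset}, {self.max_offset}]"
            )
        return self.seq[start + self.up : end + self.up + 1]

    def validate(self, require_minus10: bool = False) -> None:
        """Raise ``ValueError`` if any type invariant is violated."""
        if not set(self.seq) <= VALID_BASES:
            bad = sorted(set(self.seq) - VALID_BASES)
            raise ValueError(f"promoter {self.id}: non-ACGT symbols {bad}")
        if self.up < 0 or self.up >= len(self.seq):
            raise ValueError(f"promoter {self.id}: TSS outside sequence window")
        if self.strand not in "+-":
            raise ValueError(f"promoter {self.id}: strand must be + or -")
        if self.minus10_offset is not None:
            if self.minus10_offset >= 0:
                raise ValueError(
                    f"promoter {self.id}: minus10_offset must be negative"
                )
            if not self.covers(self.minus10_offset, self.minus10_offset + 13):
                raise ValueError(
                    f"promoter {self.id}: window does not cover the 14-bp "
                    f"bubble starting at {self.minus10_offset}"
                )
        elif require_minus10:
            raise ValueError(f"promoter {self.id}: minus10_offset missing")


@dataclass
class ExpressionRecord:
    """A differential-expression measurement for one promoter or gene."""

    id: str
    log2fc: float
    padj: float | None = None
    call: str | None = None


def read_genome(path) -> dict[str, str]:
    """Read a FASTA genome into a chromosome-name -> sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def extract_window(
    genome: Mapping[str, str] | str,
    tss: int,
    strand: str,
    up: int,
    down: int,
    chrom: str | None = None,
) -> str:
    """Extract a coding-strand window of length ``up + down + 1``.

    The TSS base (1-based genome coordinate ``tss``) lands at internal
    offset 0.  For minus-strand promoters the reverse complement of the
    mirrored genomic slice is returned.
    """
    if isinstance(genome, Mapping):
        if chrom is None:
            if len(genome) == 1:
                (chromseq,) = genome.values()
            else:
                raise CoordinateError("chrom required for multi-sequence genome")
        else:
            try:
                chromseq = genome[chrom]
            except KeyError as exc:
                raise CoordinateError(f"unknown chromosome {chrom!r}") from exc
    else:
        chromseq = genome
    if up < 0 or down < 0:
        raise ValueError("up and down must be non-negative")
    if strand == "+":
        start, end = tss - 1 - up, tss + down  # python half-open
    elif strand == "-":
        start, end = tss - 1 - down, tss + up
    else:
        raise ValueError(f"strand must be + or -, got {strand!r}")
    if start < 0 or end > len(chromseq) or tss < 1 or tss > len(chromseq):
        raise CoordinateError(
            f"window [{start + 1}, {end}] outside chromosome of length "
            f"{len(chromseq)} (tss={tss})"
        )
    window = chromseq[start:end]
    if strand == "-":
        window = str(Seq(window).reverse_complement())
    return window


# ---------------------------------------------------------------------------
# promoter tables

_PROMOTER_COLUMNS = ["id", "chrom", "strand", "tss", "minus10_offset", "sigma"]


def read_promoter_table(
    path,
    sigma_filter: str | None = None,
    genome: Mapping[str, str] | None = None,
    up: int = 50,
    down: int = 20,
    default_minus10_offset: int | None = None,
) -> list[PromoterRecord]:
    """Read a TSV promoter table into validated :class:`PromoterRecord` s.

    The table needs columns id, chrom, strand, tss, minus10_offset, sigma
    and either a ``seq`` column (with optional ``up`` giving the number of
    bases upstream of the TSS) or a genome mapping from which windows are
    extracted.  Rows violating record invariants are skipped with a
    warning; ``sigma_filter`` keeps only promoters of one sigma class.
    An empty ``minus10_offset`` cell yields ``default_minus10_offset``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str})
    missing = [c for c in _PROMOTER_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"promoter table missing columns {missing}")
    if "seq" not in df.columns and genome is None:
        raise TableFormatError("promoter table has no 'seq' column and no genome given")

    records: list[PromoterRecord] = []
    n_skipped = 0
    for row in df.itertuples(index=False):
        if sigma_filter is not None and str(row.sigma) != sigma_filter:
            continue
        try:
            m10 = getattr(row, "minus10_offset", None)
            m10 = default_minus10_offset if pd.isna(m10) else int(m10)
            genes_raw = getattr(row, "genes", "")
            genes = (
                str(genes_raw).split(",")
                if isinstance(genes_raw, str) and genes_raw
                else []
            )
            if "seq" in df.columns and isinstance(row.seq, str) and row.seq:
                row_up = int(getattr(row, "up", up))
                seq = row.seq
            else:
                row_up = up
                seq = extract_window(
                    genome, int(row.tss), str(row.strand), up, down, str(row.chrom)
                )
            rec = PromoterRecord(
                id=str(row.id),
                seq=seq,
                up=row_up,
                tss_genome_pos=int(row.tss),
                strand=str(row.strand),
                minus10_offset=m10,
                sigma=str(row.sigma),
                genes=genes,
            )
            rec.validate()
        except (ValueError, CoordinateError) as exc:
            n_skipped += 1
            logger.warning("skipping promoter row: %s", exc)
            continue
        records.append(rec)
    if n_skipped:
        logger.warning("read_promoter_table: skipped %d invalid rows", n_skipped)
    return records


def write_promoter_table(records: Iterable[PromoterRecord], path) -> None:
    """Write promoters as a TSV readable by :func:`read_promoter_table`."""
    rows = [
        {
            "id": r.id,
            "chrom": "",
            "strand": r.strand,
            "tss": r.tss_genome_pos,
            "minus10_offset": "" if r.minus10_offset is None else r.minus10_offset,
            "sigma": r.sigma,
            "seq": r.seq,
            "up": r.up,
            "genes": ",".join(r.genes),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression calls

def read_expression_table(path) -> list[ExpressionRecord]:
    """Read a TSV with columns id, log2fc and (optionally) padj."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str})
    for col in ("id", "log2fc"):
        if col not in df.columns:
            raise TableFormatError(f"expression table missing column {col!r}")
    out = []
    for row in df.itertuples(index=False):
        padj = getattr(row, "padj", None)
        padj = None if padj is None or pd.isna(padj) else float(padj)
        out.append(ExpressionRecord(str(row.id), float(row.log2fc), padj))
    return out


def call_expression(
    records: Sequence[ExpressionRecord] | pd.DataFrame,
    padj_max: float = 0.05,
    lfc_min: float | None = None,
) -> pd.DataFrame:
    """Classify responses as activated / repressed / unaffected.

    Significance is ``padj <= padj_max`` (the transcriptome convention,
    threshold 0.05; 0.3 for low-power data sets) or, when ``lfc_min`` is
    given, ``|log2fc| >= lfc_min`` for data sets lacking p-values.  The
    call is then set by the sign of the fold change; a fold change of
    exactly zero is never a response.  Returns a CallTable data frame with
    columns id, call, log2fc, padj.
    """
    if isinstance(records, pd.DataFrame):
        records = [
            ExpressionRecord(
                str(r.id),
                float(r.log2fc),
                None if pd.isna(getattr(r, "padj", None)) else float(r.padj),
            )
            for r in records.itertuples(index=False)
        ]
    rows = []
    for rec in records:
        if lfc_min is not None:
            significant = abs(rec.log2fc) >= lfc_min
        else:
            if rec.padj is None:
                raise ValueError(
                    f"record {rec.id}: padj missing and no lfc_min threshold given"
                )
            significant = rec.padj <= padj_max
        if significant and rec.log2fc > 0:
            call = "act"
        elif significant and rec.log2fc < 0:
            call = "rep"
        else:
            call = "non"
        rec.call = call
        rows.append(
            {"id": rec.id, "call": call, "log2fc": rec.log2fc, "padj": rec.padj}
        )
    return pd.DataFrame(rows, columns=["id", "call", "log2fc", "padj"])


def propagate_operon_calls(
    operon_map: Mapping[str, Sequence[str]],
    gene_calls: pd.DataFrame,
) -> pd.DataFrame:
    """Lift gene-level calls to promoters controlling operons.

    A promoter is responsive if at least one of its genes is; when several
    genes respond, the call of the gene with the largest ``|log2fc|`` wins
    (tie-break for operons carrying both activated and repressed genes).
    """
    indexed = gene_calls.set_index("id")
    rows = []
    for prom_id, genes in operon_map.items():
        if not genes:
            raise OperonMappingError(f"promoter {prom_id} maps to no genes")
        try:
            sub = indexed.loc[list(genes)]
        except KeyError as exc:
            raise OperonMappingError(
                f"promoter {prom_id}: gene without expression call ({exc})"
            ) from exc
        responsive = sub[sub["call"] != "non"]
        pool = responsive if len(responsive) else sub
        best = pool.loc[pool["log2fc"].abs().idxmax()]
        call = best["call"] if len(responsive) else "non"
        rows.append(
            {
                "id": prom_id,
                "call": call,
                "log2fc": float(best["log2fc"]),
                "padj": best["padj"],
            }
        )
    return pd.DataFrame(rows, columns=["id", "call", "log2fc", "padj"])
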