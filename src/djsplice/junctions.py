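"""Splice-junction tables, annotation models, and junction classification.

Junctions are keyed by the genomic coordinates of the excised intron:
1-based, inclusive first and last intron base (the STAR ``SJ.out.tab``
convention). A junction joining exon A (ending at genomic position p) to
exon B (starting at q) therefore has ``intron_start = p + 1`` and
``intron_end = q - 1``.

A :class:`JunctionTable` holds a junction-by-sample matrix of
uniquely-mapping read counts together with per-sample library sizes
(total mapped reads, which may exceed the junction-count column sums).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Junction",
    "JunctionTable",
    "GeneModel",
    "GeneAnnotation",
    "JunctionParseError",
    "read_sj_tab",
    "write_sj_tab",
    "merge_samples",
    "annotate_junctions",
    "ANNOTATED",
    "NOVEL_COMBINATION",
    "NOVEL_DONOR",
    "NOVEL_ACCEPTOR",
    "NOVEL_BOTH",
    "UNASSIGNED",
]

ANNOTATED = "annotated"
NOVEL_COMBINATION = "novel_combination"
NOVEL_DONOR = "novel_donor"
NOVEL_ACCEPTOR = "novel_acceptor"
NOVEL_BOTH = "novel_both"
UNASSIGNED = "unassigned"

_STRAND_CODES = {0: ".", 1: "+", 2: "-"}


class JunctionParseError(ValueError):
    """Raised for malformed junction input files."""


@dataclass(frozen=True, order=True)
class Junction:
    """A splice junction keyed by its intron interval (1-based inclusive)."""

    chrom: str
    strand: str  # '+', '-' or '.' (undetermined)
    intron_start: int
    intron_end: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.intron_start <= 0 or self.intron_end <= 0:
            raise ValueError("intron coordinates must be positive")
        if self.intron_start > self.intron_end:
            raise ValueError("intron_start must be <= intron_end")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.intron_start}-{self.intron_end}:{self.strand}"

    @classmethod
    def from_key(cls, key: str) -> "Junction":
        try:
            chrom, span, strand = key.rsplit(":", 2)
            start, end = span.split("-")
            return cls(chrom, strand, int(start), int(end))
        except Exception as exc:  # pragma: no cover - defensive
            raise JunctionParseError(f"malformed junction key {key!r}") from exc


class JunctionTable:
    """Junction x sample read-count matrix with per-sample library sizes."""

    def __init__(
        self,
        junctions: Sequence[Junction],
        counts: pd.DataFrame,
        library_sizes: pd.Series | Mapping[str, float] | None = None,
    ) -> None:
        keys = [j.key for j in junctions]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate junction keys")
        counts = counts.copy()
        counts.index = pd.Index(keys, name="junction")
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        colsums = counts.sum(axis=0)
        if library_sizes is None:
            library_sizes = colsums
        library_sizes = pd.Series(library_sizes, dtype=float).reindex(counts.columns)
        if library_sizes.isna().any():
            raise ValueError("library size missing for some samples")
        if (library_sizes + 1e-9 < colsums).any():
            raise ValueError("library sizes smaller than junction-count column sums")
        self.junctions: list[Junction] = list(junctions)
        self.counts: pd.DataFrame = counts
        self.library_sizes: pd.Series = library_sizes.rename("library_size")

    # -- basic protocol -------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def keys(self) -> list[str]:
        return list(self.counts.index)

    def __len__(self) -> int:
        return len(self.junctions)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, JunctionTable):
            return NotImplemented
        return (
            self.counts.equals(other.counts)
            and self.library_sizes.equals(other.library_sizes)
        )

    def subset(self, keys: Sequence[str]) -> "JunctionTable":
        """Row-subset by junction keys, preserving library sizes."""
        keyset = set(keys)
        juncs = [j for j in self.junctions if j.key in keyset]
        return JunctionTable(juncs, self.counts.loc[[j.key for j in juncs]],
                             self.library_sizes)

    # -- TSV round trip -------------------------------------------------
    def to_tsv(self, path: str | os.PathLike) -> None:
        """Write the merged matrix TSV (row id ``chrom:start-end:strand``).

        Library sizes are stored in ``#library_size`` header comments so
        the file round-trips exactly.
        """
        with open(path, "w") as fh:
            fh.write("# junction key convention: chrom:first_intron_base-"
                     "last_intron_base:strand (1-based inclusive)\n")
            for s, v in self.library_sizes.items():
                fh.write(f"#library_size\t{s}\t{v:.0f}\n")
            self.counts.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "JunctionTable":
        libsizes: dict[str, float] = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = len(lines)
        for i, line in enumerate(lines):
            if line.startswith("#library_size\t"):
                _, sample, value = line.rstrip("\n").split("\t")
                libsizes[sample] = float(value)
            elif not line.startswith("#"):
                body_start = i
                break
        import io

        counts = pd.read_csv(io.StringIO("".join(lines[body_start:])),
                             sep="\t", index_col=0)
        juncs = [Junction.from_key(k) for k in counts.index]
        return cls(juncs, counts, libsizes or None)


# ---------------------------------------------------------------------------
# STAR SJ.out.tab dialect
# ---------------------------------------------------------------------------

def read_sj_tab(path: str | os.PathLike, sample_id: str | None = None,
                library_size: float | None = None) -> JunctionTable:
    """Read one STAR ``SJ.out.tab`` file as a single-sample table fragment.

    Column 7 (uniquely-mapping reads) is loaded; strand codes 0/1/2 map to
    './+/-'. The library size defaults to the junction-count sum (callers
    with external totals should pass ``library_size``).
    """
    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    juncs: list[Junction] = []
    counts: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise JunctionParseError(
                    f"{path}: line {lineno}: expected >=9 tab-separated "
                    f"columns, got {len(fields)}")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                strand_code = int(fields[3])
                n_unique = int(fields[6])
            except ValueError as exc:
                raise JunctionParseError(
                    f"{path}: line {lineno}: non-numeric field") from exc
            if strand_code not in _STRAND_CODES:
                raise JunctionParseError(
                    f"{path}: line {lineno}: strand code {strand_code} "
                    "outside {0,1,2}")
            if n_unique < 0:
                raise JunctionParseError(
                    f"{path}: line {lineno}: negative count")
            juncs.append(Junction(chrom, _STRAND_CODES[strand_code], start, end))
            counts.append(n_unique)
    df = pd.DataFrame({sample_id: counts},
                      index=[j.key for j in juncs])
    libs = None if library_size is None else {sample_id: library_size}
    return JunctionTable(juncs, df, libs)


def write_sj_tab(table: JunctionTable, sample: str,
                 path: str | os.PathLike) -> None:
    """Write one sample of a table in the 9-column STAR dialect."""
    inv = {v: k for k, v in _STRAND_CODES.items()}
    with open(path, "w") as fh:
        for j in table.junctions:
            c = int(table.counts.at[j.key, sample])
            fh.write("\t".join(map(str, [
                j.chrom, j.intron_start, j.intron_end, inv[j.strand],
                0, 0, c, 0, 0])) + "\n")


def merge_samples(*fragments: JunctionTable) -> JunctionTable:
    """Union-merge table fragments; unobserved junctions are zero-filled.

    Junctions are ordered by (chrom, intron_start, intron_end); duplicate
    sample ids raise an error.
    """
    if not fragments:
        raise ValueError("at least one fragment required")
    sample_ids: list[str] = []
    for f in fragments:
        for s in f.samples:
            if s in sample_ids:
                raise ValueError(f"duplicate sample id {s!r}")
            sample_ids.append(s)
    by_key: dict[str, Junction] = {}
    for f in fragments:
        for j in f.junctions:
            by_key.setdefault(j.key, j)
    juncs = sorted(by_key.values(),
                   key=lambda j: (j.chrom, j.intron_start, j.intron_end))
    keys = [j.key for j in juncs]
    counts = pd.DataFrame(0, index=keys, columns=sample_ids, dtype=int)
    libs = pd.Series(0.0, index=sample_ids)
    for f in fragments:
        counts.loc[f.counts.index, f.samples] = f.counts.values
        libs[f.samples] = f.library_sizes.values
    return JunctionTable(juncs, counts, libs)


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """Exon structure of one gene: transcripts of ordered exon intervals."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, tuple[tuple[int, int], ...]] = field(default_factory=dict)

    @property
    def span(self) -> tuple[int, int]:
        starts = [s for tx in self.transcripts.values() for s, _ in tx]
        ends = [e for tx in self.transcripts.values() for _, e in tx]
        return min(starts), max(ends)

    def exon_starts(self) -> set[int]:
        return {s for tx in self.transcripts.values() for s, _ in tx}

    def exon_ends(self) -> set[int]:
        return {e for tx in self.transcripts.values() for _, e in tx}

    def introns(self) -> set[tuple[int, int]]:
        out: set[tuple[int, int]] = set()
        for tx in self.transcripts.values():
            exons = sorted(tx)
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                out.add((e1 + 1, s2 - 1))
        return out


class GeneAnnotation:
    """A collection of :class:`GeneModel` indexed by gene id."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {g.gene_id: g for g in genes}
        for g in self.genes.values():
            for tx_id, exons in g.transcripts.items():
                ordered = sorted(exons)
                for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
                    if s2 <= e1:
                        raise ValueError(
                            f"overlapping exons in transcript {tx_id}")
                g.transcripts[tx_id] = tuple(ordered)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __len__(self) -> int:
        return len(self.genes)

    # -- GTF I/O --------------------------------------------------------
    def to_gtf(self, path: str | os.PathLike, source: str = "djsplice") -> None:
        with open(path, "w") as fh:
            for g in self.genes.values():
                s, e = g.span
                attrs = f'gene_id "{g.gene_id}";'
                fh.write("\t".join(map(str, [
                    g.chrom, source, "gene", s, e, ".", g.strand, ".",
                    attrs])) + "\n")
                for tx_id, exons in g.transcripts.items():
                    tattrs = f'gene_id "{g.gene_id}"; transcript_id "{tx_id}";'
                    fh.write("\t".join(map(str, [
                        g.chrom, source, "transcript", exons[0][0],
                        exons[-1][1], ".", g.strand, ".", tattrs])) + "\n")
                    for (es, ee) in exons:
                        fh.write("\t".join(map(str, [
                            g.chrom, source, "exon", es, ee, ".", g.strand,
                            ".", tattrs])) + "\n")

    @classmethod
    def from_gtf(cls, path: str | os.PathLike) -> "GeneAnnotation":
        """Parse a GTF2.2 file (gene_id/transcript_id attributes) via gffutils."""
        import gffutils

        db = gffutils.create_db(
            os.fspath(path), ":memory:", force=True, keep_order=True,
            disable_infer_genes=True, disable_infer_transcripts=True)
        genes: dict[str, GeneModel] = {}
        tx_gene: dict[str, str] = {}
        for feat in db.features_of_type("exon"):
            gene_id = feat.attributes["gene_id"][0]
            tx_id = feat.attributes.get("transcript_id", [f"{gene_id}.t1"])[0]
            g = genes.setdefault(
                gene_id, GeneModel(gene_id, feat.seqid, feat.strand, {}))
            exons = list(g.transcripts.get(tx_id, ()))
            exons.append((feat.start, feat.end))
            g.transcripts[tx_id] = tuple(exons)
            tx_gene[tx_id] = gene_id
        return cls(genes.values())


# ---------------------------------------------------------------------------
# Junction -> gene assignment and novelty classification
# ---------------------------------------------------------------------------

def _classify(j: Junction, gene: GeneModel) -> str:
    left_known = (j.intron_start - 1) in gene.exon_ends()
    right_known = (j.intron_end + 1) in gene.exon_starts()
    if (j.intron_start, j.intron_end) in gene.introns():
        return ANNOTATED
    if left_known and right_known:
        return NOVEL_COMBINATION
    if not left_known and not right_known:
        return NOVEL_BOTH
    # Donor = transcription-upstream splice site: the left (lower-coordinate)
    # flank on '+' genes, the right flank on '-' genes.
    strand = j.strand if j.strand in "+-" else gene.strand
    if strand == "+":
        return NOVEL_ACCEPTOR if not right_known else NOVEL_DONOR
    return NOVEL_ACCEPTOR if not left_known else NOVEL_DONOR


def annotate_junctions(table: JunctionTable,
                       annotation: GeneAnnotation) -> pd.DataFrame:
    """Assign each junction to a gene and classify it against the annotation.

    Returns a DataFrame indexed by junction key with columns ``gene_id``
    (or None), ``status`` and ``txn_index`` (1-based position of the
    junction along the direction of transcription among the table's
    junctions of the same gene; reverse-strand genes are numbered
    right-to-left).

    Assignment rule: the gene whose span contains both splice sites;
    among several candidates, prefer matching strand, then smallest
    genomic span; remaining ties -> unassigned.
    """
    rows = []
    assigned: dict[str, list[Junction]] = {}
    for j in table.junctions:
        cands = []
        for g in annotation.genes.values():
            if g.chrom != j.chrom:
                continue
            s, e = g.span
            if s <= j.intron_start - 1 and j.intron_end + 1 <= e:
                cands.append(g)
        gene_id = None
        status = UNASSIGNED
        if cands:
            if j.strand in "+-":
                matching = [g for g in cands if g.strand == j.strand]
                if matching:
                    cands = matching
            cands.sort(key=lambda g: g.span[1] - g.span[0])
            best_span = cands[0].span[1] - cands[0].span[0]
            best = [g for g in cands if g.span[1] - g.span[0] == best_span]
            if len(best) == 1:
                gene_id = best[0].gene_id
                status = _classify(j, best[0])
                assigned.setdefault(gene_id, []).append(j)
        rows.append({"junction": j.key, "gene_id": gene_id, "status": status})
    df = pd.DataFrame(rows).set_index("junction")
    df["txn_index"] = pd.array([None] * len(df), dtype="Int64")
    for gene_id, juncs in assigned.items():
        strand = annotation[gene_id].strand
        ordered = sorted(juncs, key=lambda j: (j.intron_start, j.intron_end),
                         reverse=(strand == "-"))
        for i, j in enumerate(ordered, start=1):
            df.at[j.key, "txn_index"] = i
    return df
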